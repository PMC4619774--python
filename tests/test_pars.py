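"""PARS scoring, the load filter, and metagene profiles."""

import numpy as np
import pytest

import parstools as pt
from parstools.pars import metagene, pars_score, transcript_load

from conftest import make_pars, make_track, simple_transcript


def _two_tracks(v1_counts, at1_counts, n=8, library=1_000_000):
    lens = {"chr1": n}
    v1 = make_track({("chr1", "+"): v1_counts}, lens, library_size=library)
    at1 = make_track({("chr1", "+"): at1_counts}, lens, library_size=library)
    return v1, at1


def test_pars_score_closed_forms():
    # rpM equals raw counts at library size 1e6
    v1, at1 = _two_tracks([1, 3, 0, 0, 0, 0, 0, 0], [1, 1, 0, 0, 0, 0, 0, 0])
    genome = {"chr1": "CCCCCCCC"}
    track = pars_score(v1, at1, genome)
    k = ("chr1", "+")
    assert track.score[k][0] == 0.0  # symmetric counts
    assert track.score[k][1] == pytest.approx(1.0)  # log2(4/2)
    assert track.nodata[k][2] and track.score[k][2] == 0.0


def test_adenines_always_missing():
    v1, at1 = _two_tracks([5] * 8, [1] * 8)
    track = pars_score(v1, at1, {"chr1": "ACGTACGT"})
    # transcript-strand adenine: A on plus, T on minus
    assert list(np.nonzero(track.missing[("chr1", "+")])[0]) == [0, 4]
    assert list(np.nonzero(track.missing[("chr1", "-")])[0]) == [3, 7]


def test_swapping_nucleases_negates_scores(dataset, pars_track):
    swapped = pt.pars_score(dataset.at1, dataset.v1, dataset.truth.genome)
    for k in pars_track.score:
        ok = ~pars_track.missing[k]
        np.testing.assert_allclose(
            swapped.score[k][ok], -pars_track.score[k][ok], atol=1e-12)


def test_rpm_scale_invariance(dataset):
    """Scaling counts and library sizes together leaves every score fixed."""
    def scaled(tracks, c):
        out = []
        for t in tracks:
            s = make_track({k: v * c for k, v in t.data.items()},
                           t.chrom_lengths, library_size=t.library_size * c)
            out.append(s)
        return out

    base = pt.pars_score(dataset.v1, dataset.at1, dataset.truth.genome)
    big = pt.pars_score(scaled(dataset.v1, 7), scaled(dataset.at1, 7),
                        dataset.truth.genome)
    for k in base.score:
        np.testing.assert_allclose(base.score[k], big.score[k], atol=1e-12)


def test_transcript_load_boundary_and_mask():
    rec = simple_transcript(cds_len=900, utr5=50, utr3=50)  # tx_len 1000
    lens = {"chr1": 1100}
    ones = np.zeros(1100, dtype=int)
    ones[rec.tx_start : rec.tx_end] = 1  # 1000 combined readouts
    v1 = make_track({("chr1", "+"): ones}, lens, library_size=10_000)
    at1 = make_track({("chr1", "+"): np.zeros(1100, dtype=int)}, lens,
                     library_size=10_000)
    assert transcript_load(v1, at1, rec) == pytest.approx(1.0)
    assert pt.load_filter(v1, at1, [rec]) == [rec]  # boundary inclusive

    # 500 readouts, 600 nt masked -> 500 / 400 = 1.25
    half = np.zeros(1100, dtype=int)
    half[rec.tx_start : rec.tx_start + 500] = 1
    v1b = make_track({("chr1", "+"): half}, lens, library_size=10_000)
    mask = {(c, s): np.zeros(1100, dtype=bool) for c in lens for s in "+-"}
    mask[("chr1", "+")][rec.tx_start : rec.tx_start + 600] = True
    assert transcript_load(v1b, at1, rec, mask) == pytest.approx(1.25)

    # zero readouts -> load 0, excluded
    assert transcript_load(at1, at1, rec) == 0.0
    assert pt.load_filter(at1, at1, [rec]) == []


def test_noiseless_scores_are_sign_perfect():
    """With epsilon = 0, sign(score) equals ground-truth pairedness at every
    scored non-adenine position carrying any signal."""
    from parstools.simulate import SimConfig, simulate_dataset

    ds = simulate_dataset(SimConfig(seed=5, n_genes=30, epsilon=0.0))
    track = pt.pars_score(ds.v1, ds.at1, ds.truth.genome)
    for rec in ds.truth.transcripts:
        s = track.transcript_scores(rec)
        nodata = track.transcript_nodata(rec)
        paired = ds.truth.paired_local(rec)
        ok = ~np.isnan(s) & ~nodata
        assert np.all(s[ok & paired] > 0)
        assert np.all(s[ok & ~paired] < 0)


def test_metagene_means_and_counts():
    lens = {"chr1": 400}
    g1 = simple_transcript(cds_len=90, utr5=30, utr3=30, gene_id="g1", offset=0)
    g2 = simple_transcript(cds_len=90, utr5=30, utr3=30, gene_id="g2", offset=200)
    genome = {"chr1": "C" * 400}
    scores = np.zeros(400)
    scores[g1.tx_start : g1.tx_end] = 0.5
    scores[g2.tx_start : g2.tx_end] = 0.5
    track = make_pars({("chr1", "+"): scores}, lens)
    prof = metagene(track, [g1], genome, "start_codon", (-20, 20))
    np.testing.assert_allclose(prof.mean_pars, 0.5)

    # distinct values at one offset average, n records contributions
    scores2 = scores.copy()
    scores2[g1.cds_start - 20] = 0.2
    scores2[g2.cds_start - 20] = 0.6
    track2 = make_pars({("chr1", "+"): scores2}, lens)
    prof2 = metagene(track2, [g1, g2], genome, "start_codon", (-20, 20))
    i = list(prof2.offsets).index(-20)
    assert prof2.mean_pars[i] == pytest.approx(0.4)
    assert prof2.n_contributing[i] == 2


def test_metagene_empty_gene_set_errors(pars_track, dataset):
    with pytest.raises(ValueError):
        metagene(pars_track, [], dataset.truth.genome)


def test_metagene_gc_uses_only_nonzero_scores():
    lens = {"chr1": 200}
    rec = simple_transcript(cds_len=90, utr5=30, utr3=30, gene_id="g1")
    genome = {"chr1": "G" * 100 + "T" * 100}
    scores = np.zeros(200)
    scores[rec.cds_start] = 1.0  # position 30, base G: contributes to GC
    track = make_pars({("chr1", "+"): scores}, lens)
    # zero-score positions are excluded from GC even though scored
    prof = metagene(track, [rec], genome, "start_codon", (-5, 5))
    i = list(prof.offsets).index(0)
    assert prof.gc[i] == pytest.approx(1.0)
    assert np.isnan(prof.gc[list(prof.offsets).index(1)])


def test_docking_site_is_profile_minimum_upstream(dataset, pars_track, passing):
    """The planted unpaired docking window (-30..-12) is the least structured
    region of the start-anchored profile."""
    prof = metagene(pars_track, passing, dataset.truth.genome,
                    "start_codon", (-60, 60))
    min_offset = int(prof.offsets[np.nanargmin(prof.mean_pars)])
    assert -30 <= min_offset <= -12
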