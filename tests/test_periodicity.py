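"""DFT periodicity, codon-position means, and reading-frame KL."""

import numpy as np
import pandas as pd
import pytest

from parstools.pars import MetageneProfile, metagene
from parstools.periodicity import (
    RegionSpec,
    codon_position_means,
    dft_power,
    frame_kl,
    kl_from_uniform,
    spectrum_of,
)

from conftest import make_pars, simple_transcript


def _profile(values, first_offset):
    offsets = np.arange(first_offset, first_offset + len(values))
    v = np.asarray(values, dtype=float)
    return MetageneProfile("start_codon", offsets, v, np.zeros_like(v),
                           np.ones_like(v, dtype=int))


def test_pure_three_nt_signal_peaks_at_one_third():
    x = np.cos(2 * np.pi * np.arange(90) / 3)
    prof = _profile(x, 10)
    spec = dft_power(prof, RegionSpec("start", 10, 99))
    assert spec.dominant_frequency == pytest.approx(1 / 3, abs=1e-9)


def test_constant_profile_has_no_power():
    spec = spectrum_of(np.full(60, 2.5))
    assert np.allclose(spec.power[spec.frequencies > 0], 0.0)


def test_parseval_identity():
    rng = np.random.default_rng(9)
    x = rng.normal(size=91)
    spec = spectrum_of(x)
    assert spec.power[spec.frequencies > 0].sum() == pytest.approx(
        np.var(x), rel=1e-9)


def test_missing_offsets_error():
    prof = _profile([1.0, np.nan] + [0.0] * 40, 10)
    with pytest.raises(ValueError):
        dft_power(prof, RegionSpec("start", 10, 40))


def test_codon_position_means_frame_extraction():
    rec = simple_transcript(cds_len=300, utr5=30, utr3=30)
    lens = {"chr1": 400}
    scores = np.zeros(400)
    # frame-1 positions (first nt of each codon) score 1, rest 0
    scores[rec.cds_start : rec.cds_end : 3] = 1.0
    track = make_pars({("chr1", "+"): scores}, lens)
    m = codon_position_means(track, [rec], RegionSpec("start", 9, 98))
    assert m == pytest.approx((1.0, 0.0, 0.0))

    uniform = make_pars({("chr1", "+"): np.full(400, 0.3)}, lens)
    m2 = codon_position_means(uniform, [rec], RegionSpec("start", 9, 98))
    assert m2[0] == pytest.approx(m2[1]) == pytest.approx(m2[2])


def test_planted_periodicity_recovered(dataset, pars_track, passing):
    """The generator plants extra pairing at codon position 1; the metagene
    spectrum peaks at 1/3 and position-1 means dominate."""
    prof = metagene(pars_track, passing, dataset.truth.genome,
                    "start_codon", (-110, 110))
    spec = dft_power(prof, RegionSpec("start", 10, 99))
    assert spec.dominant_frequency == pytest.approx(1 / 3, abs=1e-9)
    m1, m2, m3 = codon_position_means(pars_track, passing)
    assert m1 > m2 and m1 > m3


@pytest.mark.parametrize(
    "p,expected",
    [((1.0, 0.0, 0.0), np.log2(3)), ((1 / 3, 1 / 3, 1 / 3), 0.0)],
)
def test_kl_reference_points(p, expected):
    assert kl_from_uniform(p) == pytest.approx(expected)


def _reads_with_frames(rec, n_per_frame, length=24):
    rows = []
    for frame, n in enumerate(n_per_frame):
        for j in range(n):
            p3_local = rec.cds_local_start + 30 + 3 * (j % 20) + frame
            p3 = rec.local_to_genomic(p3_local)
            q = rec.local_to_genomic(p3_local - length + 1)
            rows.append((rec.chrom, min(q, p3), max(q, p3) + 1, rec.gene_id,
                         0, rec.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "score", "strand"])


def test_frame_kl_matches_closed_form_exactly():
    rec = simple_transcript(cds_len=300, utr5=30, utr3=30, gene_id="g1")
    reads = _reads_with_frames(rec, (700, 200, 100))
    counts = pd.DataFrame({"gene_id": ["g1"], "raw": [1000], "rpkM": [1.0]})
    out = frame_kl(reads, [rec], counts, read_lengths=(24,))
    assert out[24] == pytest.approx(kl_from_uniform((0.7, 0.2, 0.1)))


def test_frame_kl_on_simulated_rpf(dataset):
    """Simulated 3'-end frame bias (0.7, 0.2, 0.1) yields KL near the closed
    form for every footprint length; unbiased reads give KL near 0."""
    import parstools as pt
    from parstools.simulate import SimConfig, simulate_dataset

    counts = pt.assign_gene_counts(
        dataset.mrna_reads, dataset.truth.transcripts,
        max(len(dataset.mrna_reads), 1), dataset.truth.chrom_lengths)
    kl = frame_kl(dataset.rpf_reads, dataset.truth.transcripts, counts)
    target = kl_from_uniform(dataset.config.frame_bias)
    for L in (23, 24, 25):
        assert kl[L] == pytest.approx(target, abs=0.05)

    flat = simulate_dataset(SimConfig(seed=12, n_genes=40,
                                      frame_bias=(1 / 3, 1 / 3, 1 / 3)))
    counts_f = pt.assign_gene_counts(
        flat.mrna_reads, flat.truth.transcripts,
        max(len(flat.mrna_reads), 1), flat.truth.chrom_lengths)
    kl_f = frame_kl(flat.rpf_reads, flat.truth.transcripts, counts_f)
    for L in (23, 24, 25):
        assert kl_f[L] == pytest.approx(0.0, abs=0.01)
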