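"""Structured-stretch detection and the L1/L2 pausing statistic."""

import numpy as np
import pandas as pd
import pytest

from parstools.pausing import (
    StructuredStretch,
    detect_stretches_from_scores,
    l1_l2,
    select_pausing,
    tm_distance,
)

from conftest import make_track, simple_transcript


# -- independent oracle ------------------------------------------------------

def oracle_windows(scores, window=10, min_positive=6):
    pos = np.nan_to_num(scores, nan=0.0) > 0
    return [
        i for i in range(len(scores) - window + 1)
        if pos[i : i + window].sum() >= min_positive
    ]


def oracle_merged(scores, window=10, min_positive=6):
    runs = []
    for i in oracle_windows(scores, window, min_positive):
        if runs and i < runs[-1][1]:  # extents overlap -> same stretch
            runs[-1][1] = i + window
        else:
            runs.append([i, i + window])
    return [tuple(r) for r in runs]


def test_six_of_ten_qualifies():
    scores = np.array([0.5] * 6 + [-0.5] * 4)
    out = detect_stretches_from_scores(scores)
    assert len(out) == 1 and (out[0].start, out[0].end) == (0, 10)
    assert out[0].n_positive == 6


def test_no_positive_scores_no_stretches():
    assert detect_stretches_from_scores(np.full(50, -0.2)) == []


def test_missing_positions_count_as_non_positive():
    scores = np.array([0.5] * 5 + [np.nan] + [0.5] * 0 + [-0.1] * 4)
    assert detect_stretches_from_scores(scores) == []


def test_detector_equals_brute_force_oracle():
    """Window-level and merged outputs match an exhaustive enumeration on
    200 random tracks."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(10, 80))
        scores = rng.normal(0, 1, size=n)
        scores[rng.random(n) < 0.15] = np.nan  # adenines
        got = detect_stretches_from_scores(scores, merge=False)
        assert [(s.start, s.end) for s in got] == [
            (i, i + 10) for i in oracle_windows(scores)
        ]
        merged = detect_stretches_from_scores(scores, merge=True)
        assert [(s.start, s.end) for s in merged] == oracle_merged(scores)


def test_raising_min_positive_never_adds_stretches():
    rng = np.random.default_rng(7)
    scores = rng.normal(0.2, 1, size=300)
    counts = [
        len(detect_stretches_from_scores(scores, min_positive=k, merge=False))
        for k in range(4, 9)
    ]
    assert counts == sorted(counts, reverse=True)


def _rpf_for(rec, upstream, downstream, stretch):
    lens = {rec.chrom: rec.tx_end + 50}
    counts = np.zeros(lens[rec.chrom], dtype=int)
    cds0 = rec.cds_start
    # place the requested totals one count per nt from the stretch boundary
    for j in range(upstream):
        counts[cds0 + stretch.start - 1 - (j % 29)] += 1
    for j in range(downstream):
        counts[cds0 + stretch.end + (j % 29)] += 1
    return make_track({(rec.chrom, "+"): counts}, lens)


from hypothesis import given, settings
from hypothesis import strategies as st


@given(st.integers(min_value=0, max_value=10_000),
       st.integers(min_value=0, max_value=10_000))
@settings(deadline=None, derandomize=True, max_examples=60)
def test_l1_l2_conservation_property(rpf1, rpf2):
    """L1 + L2 = 1 exactly whenever RPF1 + RPF2 > 0; otherwise unevaluable."""
    rec = simple_transcript(cds_len=300, utr5=30, utr3=30)
    stretch = StructuredStretch("g", 100, 115, 10)
    out = l1_l2(_rpf_for(rec, rpf1, rpf2, stretch), rec, stretch)
    if rpf1 + rpf2 == 0:
        assert out.exclusion == "no_rpf_reads"
    else:
        assert out.l1 + out.l2 == 1.0
        assert out.l1 == rpf1 / (rpf1 + rpf2)


@pytest.mark.parametrize(
    "rpf1,rpf2,l1,l2",
    [(30, 10, 0.75, 0.25), (0, 5, 0.0, 1.0)],
)
def test_l1_l2_normalization(rpf1, rpf2, l1, l2):
    rec = simple_transcript(cds_len=300, utr5=30, utr3=30)
    stretch = StructuredStretch("g", 100, 115, 10)
    rpf = _rpf_for(rec, rpf1, rpf2, stretch)
    out = l1_l2(rpf, rec, stretch)
    assert (out.rpf1, out.rpf2) == (rpf1, rpf2)
    assert out.l1 == pytest.approx(l1) and out.l2 == pytest.approx(l2)
    assert out.l1 + out.l2 == 1.0


def test_zero_counts_unevaluable_and_flank_bounds():
    rec = simple_transcript(cds_len=300, utr5=30, utr3=30)
    rpf = _rpf_for(rec, 0, 0, StructuredStretch("g", 100, 115, 10))
    out = l1_l2(rpf, rec, StructuredStretch("g", 100, 115, 10))
    assert out.exclusion == "no_rpf_reads" and not out.evaluable
    near_start = l1_l2(rpf, rec, StructuredStretch("g", 5, 15, 10))
    assert near_start.exclusion == "flank_outside_cds"


def test_l1_l2_conservation_on_synthetic_stretches(dataset, pars_track, passing):
    from parstools.pausing import detect_stretches

    for rec in passing[:40]:
        for s in detect_stretches(pars_track, rec):
            out = l1_l2(dataset.rpf_5p, rec, s)
            if out.evaluable:
                assert out.l1 + out.l2 == 1.0


def test_percentile_selection_uniform_null():
    """L1 ~ U(0,1): ~20% pass the 80th-percentile cut, all with L1 > L2."""
    rng = np.random.default_rng(3)
    stretches = [
        StructuredStretch("g", 0, 10, 6, rpf1=1, rpf2=1, l1=v, l2=1 - v)
        for v in rng.random(100)
    ]
    selected, report = select_pausing(stretches, percentile=80)
    assert 10 <= len(selected) <= 30
    assert all(s.l1 > s.l2 for s in selected)
    assert report["n_evaluable"] == 100


def test_ties_fail_strict_percentile():
    stretches = [
        StructuredStretch("g", 0, 10, 6, rpf1=1, rpf2=1, l1=0.5, l2=0.5)
        for _ in range(20)
    ]
    selected, _ = select_pausing(stretches)
    assert selected == []


def test_too_few_evaluable_stretches_error():
    stretches = [StructuredStretch("g", 0, 10, 6, rpf1=1, rpf2=0, l1=1.0, l2=0.0)]
    with pytest.raises(ValueError):
        select_pausing(stretches)


def test_null_simulation_selected_fraction():
    """Without planted pauses the selected fraction tracks the percentile
    cut (the top-L1 quintile lies almost surely above the 0.5 median)."""
    from parstools.simulate import SimConfig, simulate_dataset
    from parstools.pausing import detect_stretches
    import parstools as pt

    ds = simulate_dataset(SimConfig(seed=31, n_genes=80, pause_fraction=0.0))
    track = pt.pars_score(ds.v1, ds.at1, ds.truth.genome)
    passing = pt.load_filter(ds.v1, ds.at1, ds.truth.transcripts)
    evaluated = []
    for rec in passing:
        for s in detect_stretches(track, rec):
            evaluated.append(l1_l2(ds.rpf_5p, rec, s))
    selected, report = select_pausing(evaluated, percentile=80)
    frac = len(selected) / report["n_evaluable"]
    assert 0.12 <= frac <= 0.28


@pytest.mark.parametrize(
    "helix_end,stretch_codon,expected",
    [(100, 140, 40), (100, 50, -50)],
)
def test_tm_distance(helix_end, stretch_codon, expected):
    tm = pd.DataFrame({"gene_id": ["g"], "aa_start": [helix_end - 20],
                       "aa_end": [helix_end]})
    stretch = StructuredStretch("g", (stretch_codon - 1) * 3, 0, 6)
    assert tm_distance(stretch, tm) == expected


def test_tm_distance_absent_without_annotation():
    tm = pd.DataFrame({"gene_id": ["other"], "aa_start": [1], "aa_end": [10]})
    assert tm_distance(StructuredStretch("g", 30, 40, 6), tm) is None
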