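"""Shine-Dalgarno MHE scan, classification, controls and associations."""

import numpy as np
import pandas as pd
import pytest

from parstools.sd import (
    classify_sd,
    duplex_energy,
    exhaustive_8mer_energies,
    mhe_scan,
    random_8mer_control,
    sd_association,
)
from parstools._util import revcomp


def test_aagg_motif_energy_matches_reported_value():
    """The naturally occurring weak SD AAGG hybridizes to the anti-SD at
    about -2.9 kcal/mol (energy-parameter tolerance +-0.3)."""
    upstream = "C" * 10 + "AAGG" + "C" * 11  # C pairs nothing in the anti-SD
    a = mhe_scan(upstream)
    assert a.mhe == pytest.approx(-2.9, abs=0.3)
    assert "AAGG" in a.best_8mer
    assert a.sd_class == "weak"


def test_homopolymer_a_has_no_sd():
    assert mhe_scan("A" * 25).sd_class == "none"


def test_ggagg_core_is_strong():
    upstream = "C" * 9 + "GGAGG" + "C" * 11
    a = mhe_scan(upstream)
    assert a.mhe < -8.5 and a.sd_class == "strong"


@pytest.mark.parametrize(
    "mhe,expected",
    [
        (-9.0, "strong"), (-8.5, "medium"), (-5.0, "medium"), (-4.4, "weak"),
        (-3.0, "weak"), (-2.0, "none"), (-1.0, "none"), (0.0, "none"),
    ],
)
def test_classification_thresholds_partition(mhe, expected):
    assert classify_sd(mhe) == expected


from hypothesis import given, settings
from hypothesis import strategies as st

_CLASS_ORDER = {"strong": 0, "medium": 1, "weak": 2, "none": 3}


@given(st.floats(min_value=-30, max_value=5, allow_nan=False),
       st.floats(min_value=-30, max_value=5, allow_nan=False))
@settings(deadline=None, derandomize=True)
def test_every_energy_maps_to_exactly_one_class(e1, e2):
    """classify_sd partitions the energy axis and is monotone: a more
    negative MHE never yields a weaker class."""
    c1, c2 = classify_sd(e1), classify_sd(e2)
    assert c1 in _CLASS_ORDER and c2 in _CLASS_ORDER
    if e1 <= e2:
        assert _CLASS_ORDER[c1] <= _CLASS_ORDER[c2]


def test_spacing_convention_and_tie_break():
    # spacing is the window-energy key of the minimum (nt strictly between
    # the 7th SD base and the start codon), ties resolved 3'-most
    a = mhe_scan("C" * 17 + "AGGAGGCC", keep_windows=True)
    best = min(a.window_energies.values())
    expected = min(k for k, v in a.window_energies.items() if v == best)
    assert a.mhe == best and a.spacing == expected
    # two identical motifs: the scan lands on the 3'-most copy, matching a
    # sequence that carries only that copy
    dup = mhe_scan("AGGAGGCC" + "C" * 4 + "AGGAGGCC" + "C" * 5)
    single = mhe_scan("C" * 12 + "AGGAGGCC" + "C" * 5)
    assert (dup.best_8mer, dup.mhe, dup.spacing) == (
        single.best_8mer, single.mhe, single.spacing)


def test_scan_handles_short_and_bad_input():
    assert mhe_scan("ACG").sd_class == "none"
    with pytest.raises(ValueError):
        mhe_scan("ACGTNACGTNACGTN")


def test_exhaustive_control_enumerates_all_8mers():
    table = exhaustive_8mer_energies()
    assert len(table) == 65_536
    assert table.seq.is_unique
    # the full reverse complement of the anti-SD sits at (or within dangle
    # contributions of) the global minimum of the whole enumeration
    anti_5to3 = "UCCUCCAC"[::-1]
    rc = revcomp(anti_5to3).replace("T", "U")
    rank = (table.mhe < table.loc[table.seq == rc, "mhe"].iloc[0]).sum()
    assert rank <= 5
    assert table.mhe.min() <= table.loc[table.seq == rc, "mhe"].iloc[0]


def test_window_energy_matches_independent_oracle():
    """Spot-check scan energies against direct duplex evaluation."""
    rng = np.random.default_rng(17)
    table = exhaustive_8mer_energies()
    idx = rng.integers(0, len(table), size=50)
    for i in idx:
        seq = table.seq.iloc[int(i)]
        assert duplex_energy(seq) == pytest.approx(table.mhe.iloc[int(i)])


def test_sampled_control_reproducible():
    a = random_8mer_control("sampled", sample_size=444_000, seed=4)
    b = random_8mer_control("sampled", sample_size=444_000, seed=4)
    assert len(a) == 444_000
    pd.testing.assert_frame_equal(a, b)
    sub = random_8mer_control("exhaustive", sample_size=4_400, seed=4)
    assert len(sub) == 4_400 and sub.seq.is_unique


def test_planted_classes_recovered_from_genome():
    """Cross-module check: a genome generated with only strong SDs scans to
    class strong for every gene."""
    from parstools.sd import scan_transcripts
    from parstools.simulate import SimConfig, make_genome

    gt = make_genome(SimConfig(seed=6, n_genes=15, operon_fraction=0.0,
                               sd_class_mix=(1.0, 0.0, 0.0, 0.0)))
    table = scan_transcripts(gt.genome, gt.transcripts)
    assert (table.sd_class == "strong").all()
    # and the generator's own record agrees
    assert all(gt.sd_class[g] == "strong" for g in table.gene_id)


def _counts(gene_ids, rpkm):
    return pd.DataFrame({"gene_id": gene_ids, "raw": 100, "rpkM": rpkm})


def test_association_null_and_planted():
    rng = np.random.default_rng(8)
    n = 400
    table = exhaustive_8mer_energies()
    mhe = rng.choice(table.mhe.to_numpy(), size=n)
    genes = [f"g{i}" for i in range(n)]
    assignments = pd.DataFrame(
        {"gene_id": genes, "mhe": mhe,
         "sd_class": [classify_sd(e) for e in mhe]})
    # efficiency independent of SD strength
    te_null = rng.lognormal(0, 0.5, size=n)
    rep = sd_association(assignments, _counts(genes, te_null),
                         _counts(genes, np.ones(n)))
    assert abs(rep["pearson_r"]) < 0.15
    assert rep["chi2_p"] > 0.01
    # efficiency proportional to SD strength (-mhe) -> strong negative R
    te_alt = -mhe + rng.normal(0, 0.3, size=n)
    rep2 = sd_association(assignments, _counts(genes, te_alt - te_alt.min() + 0.1),
                          _counts(genes, np.ones(n)))
    assert rep2["pearson_r"] < -0.8


def test_association_single_class_errors():
    assignments = pd.DataFrame(
        {"gene_id": ["a", "b"], "mhe": [-1.0, -0.5], "sd_class": ["none", "none"]})
    with pytest.raises(ValueError):
        sd_association(assignments, _counts(["a", "b"], [1, 2]),
                       _counts(["a", "b"], [1, 1]))
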