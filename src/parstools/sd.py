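"""Shine-Dalgarno detection by minimum hybridization energy (MHE) scan.

Every 8-mer window of the 25 nt upstream of a start codon is hybridized
against the anti-SD tail of the 16S rRNA (3'-UCCUCCAC-5') with the
nearest-neighbor RNA-RNA duplex model (ViennaRNA, Turner 2004 parameters,
37 C, intermolecular pairing only).  Each window's energy is assigned to its
8th (3'-most) base; the global minimum identifies the SD, its spacing, and
its strength class:

    strong  MHE < -8.5 kcal/mol
    medium  -8.5 <= MHE < -4.4
    weak    -4.4 <= MHE < -2
    none    MHE >= -2

(the half-open boundaries resolve values sitting exactly on a threshold).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import RNA
from scipy import stats

from ._util import to_rna
from .io import TranscriptRecord

ANTI_SD_3TO5 = "UCCUCCAC"  # as printed 3'->5'; reversed before folding
UPSTREAM_LEN = 25
SD_CLASS_THRESHOLDS = (-8.5, -4.4, -2.0)
_NO_DUPLEX = 1e4  # ViennaRNA returns a huge sentinel energy when nothing pairs


def duplex_energy(seq: str, anti_sd_3to5: str = ANTI_SD_3TO5) -> float:
    """Intermolecular duplex free energy (kcal/mol) of an RNA window against
    the anti-SD; 0.0 when no stable duplex forms."""
    s = to_rna(seq)
    if any(b not in "ACGU" for b in s):
        raise ValueError(f"non-RNA characters in {seq!r}")
    e = RNA.duplexfold(s, to_rna(anti_sd_3to5)[::-1]).energy
    if e >= _NO_DUPLEX or e > 0:
        return 0.0
    return float(e)


def classify_sd(mhe: float) -> str:
    t1, t2, t3 = SD_CLASS_THRESHOLDS
    if mhe < t1:
        return "strong"
    if mhe < t2:
        return "medium"
    if mhe < t3:
        return "weak"
    return "none"


@dataclass
class SDAssignment:
    gene_id: str
    best_8mer: str | None
    mhe: float  # kcal/mol, <= 0
    spacing: int | None  # nt strictly between the 7th SD base and the start codon
    sd_class: str
    window_energies: dict | None = None  # energy assigned to the 8th base
    # position, as distance of that base upstream of the start codon (1 = adjacent)


def mhe_scan(
    upstream: str,
    gene_id: str = "",
    anti_sd_3to5: str = ANTI_SD_3TO5,
    keep_windows: bool = False,
) -> SDAssignment:
    """MHE scan of the (up to 25 nt) sequence immediately 5' of a start codon.

    ``upstream`` is given 5'->3' and ends at the base adjacent to the start
    codon.  Ties for the minimum go to the 3'-most window (nearest the start
    codon).  Shorter sequences scan the available windows only; fewer than
    8 nt (or nothing pairing) yields class 'none' with MHE 0.
    """
    seq = to_rna(upstream)[-UPSTREAM_LEN:]
    if any(b not in "ACGU" for b in seq):
        raise ValueError(f"non-RNA characters in upstream sequence of {gene_id!r}")
    L = len(seq)
    if L < 8:
        return SDAssignment(gene_id, None, 0.0, None, "none",
                            {} if keep_windows else None)
    best_i, best_e = None, 0.0
    windows = {}
    for i in range(L - 7):
        e = duplex_energy(seq[i : i + 8], anti_sd_3to5)
        if keep_windows:
            windows[L - (i + 7)] = e  # distance of the 8th base upstream of start
        if e < best_e or (e == best_e and e < 0):
            best_i, best_e = i, e  # later windows win ties (3'-most)
    if best_i is None:
        return SDAssignment(gene_id, None, 0.0, None, "none",
                            windows if keep_windows else None)
    spacing = L - (best_i + 7)
    return SDAssignment(
        gene_id, seq[best_i : best_i + 8], best_e, spacing, classify_sd(best_e),
        windows if keep_windows else None,
    )


def upstream_sequence(rec: TranscriptRecord, genome: Mapping[str, str]) -> str:
    """The (up to 25 nt) 5'UTR sequence immediately upstream of the start."""
    n = min(UPSTREAM_LEN, rec.utr5_len)
    seq = rec.sequence(genome)
    return seq[rec.cds_local_start - n : rec.cds_local_start]


def scan_transcripts(
    genome: Mapping[str, str],
    transcripts: Iterable[TranscriptRecord],
    anti_sd_3to5: str = ANTI_SD_3TO5,
) -> pd.DataFrame:
    rows = []
    for rec in transcripts:
        a = mhe_scan(upstream_sequence(rec, genome), rec.gene_id, anti_sd_3to5)
        rows.append((a.gene_id, a.best_8mer, a.mhe, a.spacing, a.sd_class))
    return pd.DataFrame(
        rows, columns=["gene_id", "best_8mer", "mhe", "spacing", "sd_class"]
    )


# ---------------------------------------------------------------------------
# randomized controls

_exhaustive_cache: dict[str, pd.DataFrame] = {}


def exhaustive_8mer_energies(anti_sd_3to5: str = ANTI_SD_3TO5) -> pd.DataFrame:
    """Duplex energy of every one of the 4^8 = 65,536 RNA 8-mers (cached)."""
    if anti_sd_3to5 not in _exhaustive_cache:
        seqs = ["".join(t) for t in itertools.product("ACGU", repeat=8)]
        energies = [duplex_energy(s, anti_sd_3to5) for s in seqs]
        _exhaustive_cache[anti_sd_3to5] = pd.DataFrame(
            {"seq": seqs, "mhe": energies}
        )
    return _exhaustive_cache[anti_sd_3to5].copy()


def random_8mer_control(
    mode: str = "exhaustive",
    sample_size: int | None = None,
    seed: int = 0,
    anti_sd_3to5: str = ANTI_SD_3TO5,
) -> pd.DataFrame:
    """MHE distribution of random 8-mers.

    ``exhaustive`` enumerates all 65,536 sequences; ``sampled`` draws
    ``sample_size`` i.i.d. uniform-base 8-mers (with replacement).  With
    ``mode='exhaustive'`` and a ``sample_size``, a seeded subsample of the
    enumeration is returned.
    """
    table = exhaustive_8mer_energies(anti_sd_3to5)
    rng = np.random.default_rng(seed)
    if mode == "exhaustive":
        if sample_size is not None:
            idx = rng.choice(len(table), size=sample_size, replace=False)
            return table.iloc[np.sort(idx)].reset_index(drop=True)
        return table
    if mode == "sampled":
        if sample_size is None:
            raise ValueError("sampled mode requires sample_size")
        idx = rng.integers(0, len(table), size=sample_size)
        return table.iloc[idx].reset_index(drop=True)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# association with translation efficiency


def sd_association(
    assignments: pd.DataFrame,
    gene_counts_rpf: pd.DataFrame,
    gene_counts_mrna: pd.DataFrame,
    top_fraction: float = 0.30,
) -> dict:
    """Translation efficiency (RPF rpkM per mRNA rpkM) vs SD strength.

    Returns the Pearson correlation of MHE with efficiency and a chi-square
    test of whether the top-translated genes distribute across the four SD
    classes in proportion to class sizes.  Diagnostics, data-dependent.
    """
    df = (
        assignments.merge(
            gene_counts_rpf[["gene_id", "rpkM"]].rename(columns={"rpkM": "rpf_rpkM"}),
            on="gene_id",
        ).merge(
            gene_counts_mrna[["gene_id", "rpkM"]].rename(columns={"rpkM": "mrna_rpkM"}),
            on="gene_id",
        )
    )
    df = df[df.mrna_rpkM > 0].copy()
    df["translation_efficiency"] = df.rpf_rpkM / df.mrna_rpkM
    classes = sorted(df.sd_class.unique())
    if len(classes) < 2:
        raise ValueError("chi-square undefined with a single SD class")
    r, r_p = stats.pearsonr(df.mhe, df.translation_efficiency)
    n_top = max(1, int(round(top_fraction * len(df))))
    top = df.nlargest(n_top, "translation_efficiency")
    class_sizes = df.sd_class.value_counts()
    observed = np.array([ (top.sd_class == c).sum() for c in classes ])
    expected = np.array([class_sizes[c] for c in classes], dtype=float)
    expected = expected / expected.sum() * observed.sum()
    chi2, chi_p = stats.chisquare(observed, expected)
    return {
        "n_genes": int(len(df)),
        "pearson_r": float(r),
        "pearson_p": float(r_p),
        "chi2": float(chi2),
        "chi2_p": float(chi_p),
        "per_gene": df,
    }
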