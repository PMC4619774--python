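"""Structured-stretch detection in CDSs and the L1/L2 pausing statistic.

A structured stretch is a CDS window in which at least ``min_positive`` of
``window`` consecutive nucleotides carry a positive PARS score (missing
adenines count as non-positive).  Ribosome-protected-fragment counts over
the 29 nt immediately 5' (RPF1) and 3' (RPF2) of a stretch are normalized
to L1 = RPF1/(RPF1+RPF2) and L2 = 1 - L1; stretches whose L1 ranks above a
percentile cut with L1 > L2 are called pausing sites.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTrack, TranscriptRecord
from .pars import ParsTrack


@dataclass
class StructuredStretch:
    """Detected double-stranded window, coordinates local to the CDS
    (0-based half-open)."""

    gene_id: str
    start: int
    end: int
    n_positive: int
    rpf1: int | None = None
    rpf2: int | None = None
    l1: float | None = None
    l2: float | None = None
    percentile_rank: float | None = None
    exclusion: str | None = None  # flank_outside_cds / no_rpf_reads

    @property
    def evaluable(self) -> bool:
        return self.l1 is not None and self.exclusion is None


def detect_stretches(
    pars: ParsTrack,
    rec: TranscriptRecord,
    window: int = 10,
    min_positive: int = 6,
    merge: bool = True,
) -> list[StructuredStretch]:
    """Slide a window (step 1) across the CDS; qualifying windows are those
    with >= min_positive positions scoring > 0.  Overlapping qualifying
    windows are merged into maximal stretches unless ``merge`` is False."""
    scores = pars.transcript_scores(rec)[rec.cds_local_start : rec.cds_local_end]
    return detect_stretches_from_scores(
        scores, rec.gene_id, window=window, min_positive=min_positive, merge=merge
    )


def detect_stretches_from_scores(
    scores: np.ndarray,
    gene_id: str = "",
    window: int = 10,
    min_positive: int = 6,
    merge: bool = True,
) -> list[StructuredStretch]:
    n = scores.size
    if n < window:
        return []
    pos = np.nan_to_num(scores, nan=0.0) > 0
    counts = np.convolve(pos.astype(np.int64), np.ones(window, dtype=np.int64),
                         mode="valid")
    qual = np.nonzero(counts >= min_positive)[0]
    stretches: list[StructuredStretch] = []
    if not merge:
        for i in qual:
            stretches.append(
                StructuredStretch(gene_id, int(i), int(i + window), int(counts[i]))
            )
        return stretches
    runs: list[list[int]] = []  # overlapping qualifying windows merge
    for i in qual:
        if runs and i < runs[-1][1]:
            runs[-1][1] = int(i) + window
        else:
            runs.append([int(i), int(i) + window])
    for start, end in runs:
        stretches.append(
            StructuredStretch(gene_id, start, end, int(pos[start:end].sum()))
        )
    return stretches


def detect_stretches_mean(
    scores: np.ndarray,
    gene_id: str = "",
    window: int = 10,
    min_mean: float = 0.0,
    min_nonzero: int = 5,
    merge: bool = True,
) -> list[StructuredStretch]:
    """Mean-PARS detector variant: a window qualifies when its mean score
    (missing as 0) is >= min_mean and at least min_nonzero entries are
    non-zero."""
    n = scores.size
    if n < window:
        return []
    filled = np.nan_to_num(scores, nan=0.0)
    kernel = np.ones(window)
    means = np.convolve(filled, kernel, mode="valid") / window
    nz = np.convolve((filled != 0).astype(float), kernel, mode="valid")
    qual = np.nonzero((means >= min_mean) & (nz >= min_nonzero))[0]
    out: list[StructuredStretch] = []
    if not merge:
        for i in qual:
            out.append(StructuredStretch(
                gene_id, int(i), int(i) + window,
                int((filled[i : i + window] > 0).sum())))
        return out
    runs: list[list[int]] = []
    for i in qual:
        if runs and i < runs[-1][1]:
            runs[-1][1] = int(i) + window
        else:
            runs.append([int(i), int(i) + window])
    for start, end in runs:
        out.append(StructuredStretch(
            gene_id, start, end, int((filled[start:end] > 0).sum())))
    return out


def l1_l2(
    rpf: CountTrack,
    rec: TranscriptRecord,
    stretch: StructuredStretch,
    flank: int = 29,
) -> StructuredStretch:
    """Attach RPF1/RPF2 (raw counts over the flanks inside the CDS) and the
    normalized L1/L2 to a stretch."""
    cds = rpf.transcript_counts(rec)[rec.cds_local_start : rec.cds_local_end]
    if stretch.start - flank < 0 or stretch.end + flank > cds.size:
        return replace(stretch, exclusion="flank_outside_cds")
    rpf1 = int(cds[stretch.start - flank : stretch.start].sum())
    rpf2 = int(cds[stretch.end : stretch.end + flank].sum())
    if rpf1 + rpf2 == 0:
        return replace(stretch, rpf1=rpf1, rpf2=rpf2, exclusion="no_rpf_reads")
    l1 = rpf1 / (rpf1 + rpf2)
    return replace(stretch, rpf1=rpf1, rpf2=rpf2, l1=l1, l2=1.0 - l1)


def select_pausing(
    stretches: Iterable[StructuredStretch],
    percentile: float = 80.0,
) -> tuple[list[StructuredStretch], dict]:
    """Pausing calls: stretches with percentile_rank(L1) strictly above the
    cut and L1 > L2.  Also returns the KS comparison of the L1 and L2
    distributions (diagnostic)."""
    evaluable = [s for s in stretches if s.evaluable]
    if len(evaluable) < 5:
        raise ValueError("fewer than 5 evaluable stretches")
    l1s = np.array([s.l1 for s in evaluable])
    ranked = [
        replace(s, percentile_rank=stats.percentileofscore(l1s, s.l1, kind="strict"))
        for s in evaluable
    ]
    selected = [
        s for s in ranked if s.percentile_rank > percentile and s.l1 > s.l2
    ]
    ks = stats.ks_2samp(l1s, 1.0 - l1s)
    report = {
        "n_evaluable": len(evaluable),
        "n_selected": len(selected),
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
    }
    return selected, report


def tm_distance(
    stretch: StructuredStretch,
    tm_domains: pd.DataFrame,
) -> int | None:
    """Distance in codons (= amino acids) from the last residue of the
    nearest upstream transmembrane helix to the codon holding the stretch's
    first nt; negative if the stretch precedes every helix.  ``None`` when
    the gene has no TM annotation."""
    rows = tm_domains[tm_domains.gene_id == stretch.gene_id]
    if rows.empty:
        return None
    stretch_codon = stretch.start // 3 + 1  # 1-based codon index
    ends = rows.aa_end.to_numpy()
    upstream = ends[ends <= stretch_codon]
    if upstream.size == 0:
        return int(stretch_codon - ends.min())  # negative: precedes all helices
    return int(stretch_codon - upstream.max())


def stretches_frame(stretches: Iterable[StructuredStretch]) -> pd.DataFrame:
    rows = [
        (s.gene_id, s.start, s.end, s.n_positive, s.rpf1, s.rpf2, s.l1, s.l2,
         s.percentile_rank, s.exclusion)
        for s in stretches
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "start", "end", "n_positive", "RPF1", "RPF2",
                 "L1", "L2", "percentile_rank", "exclusion"],
    )
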