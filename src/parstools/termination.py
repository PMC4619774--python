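"""Stop-codon-stratified structure, readthrough, and downstream in-frame
stop-codon frequency.

Readthrough is the mean per-nt RPF density over offsets +3..+27 downstream
of the stop codon's last base, divided by the mean per-nt RPF density over
the CDS — a proxy for termination leakiness.  Genes in the overlapping
operon class are excluded (terminating and initiating ribosomes cannot be
distinguished there), as are genes under the read-coverage threshold.
"""

from __future__ import annotations

from itertools import groupby
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountTrack, TranscriptRecord, classify_operon_context
from .pars import MetageneProfile, ParsTrack, metagene

STOP_SET = {"TAA", "TAG", "TGA"}


def readthrough_ratio(
    rpf: CountTrack,
    rec: TranscriptRecord,
    window: tuple[int, int] = (3, 27),
    min_reads: int = 60,
) -> float | None:
    """RPF density downstream of the stop relative to the CDS mean.

    Offsets are inclusive, relative to the last nt of the stop codon
    (+1 = first 3'UTR nt).  Returns None when the gene is unevaluable:
    overlapping operon context, coverage below ``min_reads``, CDS density 0,
    or a 3'UTR shorter than the window.
    """
    if classify_operon_context(rec) == "overlapping":
        return None
    local = rpf.transcript_counts(rec)
    cds = local[rec.cds_local_start : rec.cds_local_end]
    if cds.sum() < min_reads:
        return None
    if rec.utr3_len < window[1]:
        return None
    last = rec.cds_local_end - 1  # last nt of the stop codon
    down = local[last + window[0] : last + window[1] + 1]
    cds_mean = cds.mean()
    if cds_mean == 0:
        return None
    return float(down.mean() / cds_mean)


def readthrough_table(
    rpf: CountTrack,
    transcripts: Iterable[TranscriptRecord],
    window: tuple[int, int] = (3, 27),
    min_reads: int = 60,
) -> pd.DataFrame:
    rows = []
    for rec in transcripts:
        rt = readthrough_ratio(rpf, rec, window, min_reads)
        rows.append(
            (rec.gene_id, rec.stop_codon, classify_operon_context(rec), rt)
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "stop_codon", "operon_context", "readthrough"]
    )


def downstream_inframe_stop(
    genome: Mapping[str, str],
    rec: TranscriptRecord,
    window_codons: int = 9,
) -> bool:
    """Whether an in-frame stop codon occurs within ``window_codons`` codons
    3' of the annotated stop (scanned on the transcript strand)."""
    seq = rec.sequence(genome)
    for c in range(window_codons):
        i = rec.cds_local_end + 3 * c
        codon = seq[i : i + 3]
        if len(codon) < 3:
            break
        if codon in STOP_SET:
            return True
    return False


def downstream_stop_frequency(
    genome: Mapping[str, str],
    transcripts: Iterable[TranscriptRecord],
    window_codons: int = 9,
) -> pd.DataFrame:
    """Fraction of genes per stop-codon group with >= 1 downstream in-frame
    stop within the window."""
    rows = []
    for rec in transcripts:
        rows.append((rec.stop_codon,
                     downstream_inframe_stop(genome, rec, window_codons)))
    df = pd.DataFrame(rows, columns=["stop_codon", "has_stop"])
    out = (
        df.groupby("stop_codon")
        .agg(n_genes=("has_stop", "size"), fraction=("has_stop", "mean"))
        .reset_index()
    )
    return out


def stop_codon_usage(transcripts: Iterable[TranscriptRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.stop_codon, classify_operon_context(r)) for r in transcripts],
        columns=["stop_codon", "operon_context"],
    )
    out = (
        df.groupby(["operon_context", "stop_codon"]).size().rename("n").reset_index()
    )
    out["frequency"] = out.groupby("operon_context")["n"].transform(
        lambda x: x / x.sum()
    )
    return out


def stop_metagene(
    pars: ParsTrack,
    transcripts: Iterable[TranscriptRecord],
    genome: Mapping[str, str],
    group_by: tuple[str, ...] = ("stop_codon",),
    window: tuple[int, int] = (-100, 100),
    prestop_window: tuple[int, int] = (-30, -4),
    min_group_size: int = 1,
) -> tuple[dict, dict]:
    """Stop-anchored metagene profiles per gene group, plus Mann-Whitney
    comparisons of per-gene mean PARS over the pre-stop window (diagnostic).

    Groups are tuples over the requested keys ('stop_codon',
    'operon_context'); empty groups are omitted.
    """
    def key_of(rec):
        parts = []
        for k in group_by:
            parts.append(rec.stop_codon if k == "stop_codon"
                         else classify_operon_context(rec))
        return tuple(parts)

    groups: dict[tuple, list[TranscriptRecord]] = {}
    for rec in transcripts:
        groups.setdefault(key_of(rec), []).append(rec)
    groups = {k: v for k, v in groups.items() if len(v) >= min_group_size}

    profiles = {
        k: metagene(pars, recs, genome, anchor="stop_codon", window=window)
        for k, recs in groups.items()
    }

    prestop: dict[tuple, np.ndarray] = {}
    for k, recs in groups.items():
        vals = []
        for rec in recs:
            scores = pars.transcript_scores(rec)
            a0 = rec.cds_local_end - 3
            lo, hi = a0 + prestop_window[0], a0 + prestop_window[1]
            if lo < 0:
                continue
            seg = scores[lo : hi + 1]
            if np.isfinite(seg).any():
                vals.append(np.nanmean(seg))
        prestop[k] = np.array(vals)

    comparisons = {}
    keys = sorted(prestop)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            if prestop[a].size and prestop[b].size:
                u = stats.mannwhitneyu(prestop[a], prestop[b],
                                       alternative="two-sided")
                comparisons[(a, b)] = {
                    "u": float(u.statistic), "p": float(u.pvalue),
                    "mean_a": float(prestop[a].mean()),
                    "mean_b": float(prestop[b].mean()),
                }
    return profiles, comparisons
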