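"""Per-nucleotide PARS scores, transcript load filter, metagene profiles.

The PARS score at a position is log2((v1_rpM + 1) / (at1_rpM + 1)) where
v1/at1 are read-per-million-scaled counts from the double-strand-specific
(RNase V1) and single-strand-specific (RNase A/T1) digestions.  Positive
scores indicate preferential involvement in double-stranded structure.
Adenines carry no single-strand information (RNase A cleaves C/U, T1 cleaves
G) and are always masked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountTrack, TranscriptRecord

log = logging.getLogger(__name__)

LOAD_THRESHOLD = 1.0  # minimum combined probing readouts per effective nt


class ParsTrack:
    """Per-position PARS score with missing mask.

    ``score`` and boolean masks are dense per ``(chrom, strand)`` arrays.
    ``missing`` marks adenines (transcript-strand A) — no score is defined
    there.  ``nodata`` marks positions where both digestion counts are zero:
    their score is 0 by construction and they are excluded from
    GC-on-nonzero computations.
    """

    def __init__(self, chrom_lengths: Mapping[str, int]):
        self.chrom_lengths = dict(chrom_lengths)
        keys = [(c, s) for c in chrom_lengths for s in "+-"]
        self.score = {k: np.zeros(self.chrom_lengths[k[0]]) for k in keys}
        self.missing = {k: np.zeros(self.chrom_lengths[k[0]], dtype=bool) for k in keys}
        self.nodata = {k: np.zeros(self.chrom_lengths[k[0]], dtype=bool) for k in keys}

    def defined(self, key: tuple[str, str]) -> np.ndarray:
        return ~self.missing[key]

    def transcript_scores(self, rec: TranscriptRecord) -> np.ndarray:
        """Local 5'->3' scores with missing positions as NaN."""
        k = (rec.chrom, rec.strand)
        s = rec.local_view(self.score[k]).astype(float).copy()
        s[rec.local_view(self.missing[k])] = np.nan
        return s

    def transcript_nodata(self, rec: TranscriptRecord) -> np.ndarray:
        return rec.local_view(self.nodata[(rec.chrom, rec.strand)])

    def to_bedgraph(self, path_plus: str | Path, path_minus: str | Path) -> None:
        for strand, path in (("+", path_plus), ("-", path_minus)):
            with open(path, "w") as fh:
                fh.write("track type=bedGraph name=pars_score\n")
                for chrom in self.chrom_lengths:
                    k = (chrom, strand)
                    sc, ok = self.score[k], ~self.missing[k]
                    for pos in np.nonzero(ok & (sc != 0))[0]:
                        fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{sc[pos]:.6g}\n")


_TRANSCRIPT_A = {"+": "A", "-": "T"}  # genomic base that is A on the transcript


def pars_score(
    v1: CountTrack | Sequence[CountTrack],
    at1: CountTrack | Sequence[CountTrack],
    genome: Mapping[str, str],
    pseudocount: float = 1.0,
) -> ParsTrack:
    """PARS score per position; replicate tracks are summed before scoring.

    The pseudocount is applied on the rpM scale.  Transcript-strand adenines
    are masked as missing.
    """
    v1 = _combine(v1)
    at1 = _combine(at1)
    for t in (v1, at1):
        if set(t.chrom_lengths) != set(genome):
            raise ValueError("track chromosomes do not match genome")
        if t.library_size <= 0:
            raise ValueError("library_size must be positive")

    track = ParsTrack(v1.chrom_lengths)
    v1_rpm, at1_rpm = v1.rpm(), at1.rpm()
    for chrom, seq in genome.items():
        base = np.frombuffer(seq.encode(), dtype="S1")
        for strand in "+-":
            k = (chrom, strand)
            track.score[k] = np.log2(
                (v1_rpm[k] + pseudocount) / (at1_rpm[k] + pseudocount)
            )
            track.missing[k] = base == _TRANSCRIPT_A[strand].encode()
            track.nodata[k] = (v1.data[k] == 0) & (at1.data[k] == 0)
    return track


def _combine(tracks: CountTrack | Sequence[CountTrack]) -> CountTrack:
    if isinstance(tracks, CountTrack):
        return tracks
    out = tracks[0]
    for t in tracks[1:]:
        out = out.add(t)
    return out


def transcript_load(
    v1: CountTrack | Sequence[CountTrack],
    at1: CountTrack | Sequence[CountTrack],
    rec: TranscriptRecord,
    mask: Mapping[tuple[str, str], np.ndarray] | None = None,
) -> float:
    """Combined probing readouts per effective transcript nt.

    Effective length is the annotated transcript length minus masked
    (unmappable) positions.  Transcripts with load below 1.0 are excluded
    by :func:`load_filter`; an effective length of 0 yields load 0 with a
    warning.
    """
    v1 = _combine(v1)
    at1 = _combine(at1)
    k = (rec.chrom, rec.strand)
    total = int(
        rec.local_view(v1.data[k]).sum() + rec.local_view(at1.data[k]).sum()
    )
    eff_len = rec.tx_len
    if mask is not None:
        eff_len -= int(rec.local_view(mask[k]).sum())
    if eff_len <= 0:
        log.warning("%s: effective length 0, excluded", rec.gene_id)
        return 0.0
    return total / eff_len


def load_filter(
    v1, at1, transcripts: Iterable[TranscriptRecord], mask=None,
    threshold: float = LOAD_THRESHOLD,
) -> list[TranscriptRecord]:
    """Transcripts passing the minimum-coverage load filter (boundary
    inclusive: load == threshold is retained)."""
    return [
        r for r in transcripts
        if transcript_load(v1, at1, r, mask) >= threshold
    ]


# ---------------------------------------------------------------------------
# metagene profiles


@dataclass
class MetageneProfile:
    """Cross-gene mean PARS and GC per offset around a common anchor.

    Offset 0 is the first nt of the anchor codon (start or stop); negative
    offsets are 5' of it.  GC is computed only over positions contributing a
    non-missing, non-zero PARS score.
    """

    anchor: str
    offsets: np.ndarray
    mean_pars: np.ndarray
    gc: np.ndarray
    n_contributing: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "mean_pars": self.mean_pars,
                "gc": self.gc,
                "n": self.n_contributing,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def region(self, from_nt: int, to_nt: int) -> np.ndarray:
        """mean_pars over offsets from_nt..to_nt (inclusive both ends)."""
        lo = int(self.offsets[0])
        if from_nt < lo or to_nt > int(self.offsets[-1]):
            raise ValueError("region outside profile window")
        return self.mean_pars[from_nt - lo : to_nt - lo + 1]


def _anchor_local(rec: TranscriptRecord, anchor: str) -> int:
    if anchor == "start_codon":
        return rec.cds_local_start
    if anchor == "stop_codon":
        return rec.cds_local_end - 3
    raise ValueError(f"unknown anchor {anchor!r}")


def metagene(
    pars: ParsTrack,
    transcripts: Iterable[TranscriptRecord],
    genome: Mapping[str, str],
    anchor: str = "start_codon",
    window: tuple[int, int] = (-100, 100),
) -> MetageneProfile:
    """Mean PARS score (and GC over non-zero scored positions) per offset,
    across genes aligned at the start or stop codon."""
    transcripts = list(transcripts)
    if not transcripts:
        raise ValueError("empty transcript set")
    offsets = np.arange(window[0], window[1] + 1)
    total = np.zeros(offsets.size)
    n = np.zeros(offsets.size, dtype=np.int64)
    gc_hits = np.zeros(offsets.size, dtype=np.int64)
    gc_n = np.zeros(offsets.size, dtype=np.int64)

    for rec in transcripts:
        scores = pars.transcript_scores(rec)
        nodata = pars.transcript_nodata(rec)
        seq = rec.sequence(genome)
        a0 = _anchor_local(rec, anchor)
        lo = max(window[0], -a0)
        hi = min(window[1], rec.tx_len - 1 - a0)
        if lo > hi:
            continue
        idx = np.arange(lo, hi + 1) + a0
        off_idx = np.arange(lo, hi + 1) - window[0]
        vals = scores[idx]
        ok = ~np.isnan(vals)
        total[off_idx[ok]] += vals[ok]
        n[off_idx[ok]] += 1
        nz = ok & (vals != 0) & ~nodata[idx]
        isgc = np.frombuffer(seq.encode(), dtype="S1")[idx[nz]]
        gc_hits[off_idx[nz]] += np.isin(isgc, [b"G", b"C"])
        gc_n[off_idx[nz]] += 1

    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
        gc = np.where(gc_n > 0, gc_hits / np.maximum(gc_n, 1), np.nan)
    return MetageneProfile(anchor, offsets, mean, gc, n)
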