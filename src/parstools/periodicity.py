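"""Three-nt periodicity diagnostics: DFT of metagene PARS profiles,
per-codon-position PARS means, and KL-divergence reading-frame analysis of
RPF 3'-ends."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TranscriptRecord
from .pars import MetageneProfile, ParsTrack


@dataclass(frozen=True)
class RegionSpec:
    """Signed offset range (inclusive both ends) relative to an anchor codon:
    e.g. start anchor, 10..99 = the 90 nt starting 10 nt into the CDS."""

    anchor: str  # 'start' or 'stop'
    from_nt: int
    to_nt: int

    def __post_init__(self):
        if self.to_nt - self.from_nt + 1 < 9:
            raise ValueError("region shorter than 9 nt")
        if self.anchor not in ("start", "stop"):
            raise ValueError("anchor must be 'start' or 'stop'")

    @property
    def length(self) -> int:
        return self.to_nt - self.from_nt + 1


@dataclass
class Spectrum:
    """One-sided power spectrum; power is normalized so that the sum over
    non-zero frequencies equals the variance of the mean-subtracted input
    (Parseval)."""

    frequencies: np.ndarray  # cycles per nt, in [0, 0.5]
    power: np.ndarray

    @property
    def dominant_frequency(self) -> float:
        nz = self.frequencies > 0
        return float(self.frequencies[nz][np.argmax(self.power[nz])])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency": self.frequencies, "power": self.power})


def dft_power(profile: MetageneProfile, region: RegionSpec) -> Spectrum:
    """Mean-subtracted DFT power spectrum of the cross-gene mean PARS profile
    over a region."""
    anchor = "start_codon" if region.anchor == "start" else "stop_codon"
    if profile.anchor != anchor:
        raise ValueError(
            f"profile anchored at {profile.anchor}, region wants {anchor}")
    x = profile.region(region.from_nt, region.to_nt)
    return spectrum_of(x)


def spectrum_of(x: np.ndarray) -> Spectrum:
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError("region contains missing offsets")
    n = x.size
    x = x - x.mean()
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n)
    power = (np.abs(X) / n) ** 2
    # double the interior one-sided terms so the spectrum sums to var(x)
    interior = (freqs > 0) & (freqs < 0.5)
    power[interior] *= 2.0
    return Spectrum(freqs, power)


def codon_position_means(
    pars: ParsTrack,
    transcripts: Iterable[TranscriptRecord],
    region: RegionSpec = RegionSpec("start", 10, 99),
) -> tuple[float, float, float]:
    """Mean PARS over each of the three codon positions, frame anchored at
    the annotated start, pooled over in-frame positions of the region."""
    totals = np.zeros(3)
    counts = np.zeros(3, dtype=np.int64)
    for rec in transcripts:
        scores = pars.transcript_scores(rec)
        if region.anchor == "start":
            a0 = rec.cds_local_start
        else:
            a0 = rec.cds_local_end - 3
        for off in range(region.from_nt, region.to_nt + 1):
            i = a0 + off
            if i < 0 or i >= scores.size:
                continue
            v = scores[i]
            if np.isnan(v):
                continue
            frame = (i - rec.cds_local_start) % 3
            totals[frame] += v
            counts[frame] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, totals / np.maximum(counts, 1), np.nan)
    return tuple(float(m) for m in means)


def kl_from_uniform(p: Sequence[float]) -> float:
    """KL(P || Uniform(1/3)) in bits."""
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(3.0 * p[nz])))


def frame_kl(
    reads: pd.DataFrame,
    transcripts: Iterable[TranscriptRecord],
    gene_counts: pd.DataFrame,
    read_lengths: Sequence[int] = (23, 24, 25),
    top_n: int = 1000,
) -> dict[int, float]:
    """Reading-frame bias of RPF 3'-ends, per read length.

    Reads of the given lengths mapping within the CDSs of the ``top_n`` most
    expressed genes are binned by the frame of their 3'-end (modulo 3
    relative to the reading frame fixed by the annotated stop codon); the
    deviation of that distribution from uniform is KL divergence in bits.
    Lengths with no qualifying reads are absent from the result.
    """
    ranked = gene_counts.sort_values("rpkM", ascending=False).gene_id.head(top_n)
    keep = set(ranked)
    recs = {r.gene_id: r for r in transcripts if r.gene_id in keep}
    by_loc: dict[tuple[str, str], list[TranscriptRecord]] = {}
    for r in recs.values():
        by_loc.setdefault((r.chrom, r.strand), []).append(r)

    length = (reads["end"] - reads["start"]).to_numpy()
    three_prime = np.where(
        reads["strand"].to_numpy() == "+",
        reads["end"].to_numpy() - 1,
        reads["start"].to_numpy(),
    )
    out: dict[int, float] = {}
    for L in read_lengths:
        counts = np.zeros(3, dtype=np.int64)
        sel = length == L
        sub = reads[sel]
        for (chrom, strand), grp in sub.assign(_tp=three_prime[sel]).groupby(
            ["chrom", "strand"], sort=False
        ):
            for rec in by_loc.get((chrom, strand), []):
                tp = grp["_tp"].to_numpy()
                local = np.where(
                    strand == "+", tp - rec.tx_start, rec.tx_end - 1 - tp
                )
                inside = (local >= rec.cds_local_start) & (local < rec.cds_local_end)
                frames = (local[inside] - rec.cds_local_start) % 3
                np.add.at(counts, frames, 1)
        if counts.sum() > 0:
            out[L] = kl_from_uniform(counts)
    return out
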