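"""Replicate counting-noise model and read-count threshold selection.

Two replicates partition a gene's n total reads binomially; the standard
deviation of the ratio r1/(r1+r2) across genes with similar n then follows

    SD(n) = sqrt( p(1-p)/n + s^2 )

where p is the probability a read falls in replicate 1 and s is the excess
(biological) standard deviation that remains at infinite counts.  Technical
replicates are dominated by counting noise, so s = 0 there.  (The model is
a variance sum; the printed form of the expression is read as
Var = p(1-p)/n + s^2, the only reading with the correct binomial limit.)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class NoiseBin:
    lo: float
    hi: float
    mean_n: float
    sd_ratio: float
    n_genes: int


@dataclass
class NoiseFit:
    """Fitted noise model; behaves as a results object."""

    p: float
    s: float
    bins: list[NoiseBin] = field(default_factory=list)

    def model_sd(self, n: np.ndarray | float) -> np.ndarray | float:
        return np.sqrt(self.p * (1 - self.p) / np.asarray(n, dtype=float) + self.s**2)

    def summary(self) -> str:
        lines = [
            "Replicate noise model  SD(n) = sqrt(p(1-p)/n + s^2)",
            f"  p (replicate-1 probability) : {self.p:.4f}",
            f"  s (excess biological SD)    : {self.s:.4f}",
            f"  bins used                   : {len(self.bins)}",
        ]
        return "\n".join(lines)

    def bins_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b.lo, b.hi, b.mean_n, b.sd_ratio, b.n_genes) for b in self.bins],
            columns=["bin_lo", "bin_hi", "mean_n", "sd_ratio", "n_genes"],
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"p": self.p, "s": self.s}, fh, indent=1)


class ReplicateNoiseModel:
    """Bin genes logarithmically by total counts and fit (p, s).

    ``mode='biological'`` fits both parameters; ``mode='technical'`` fixes
    s = 0 (pure counting noise).
    """

    def __init__(self, counts_rep1, counts_rep2, n_bins: int = 20,
                 min_genes_per_bin: int = 10):
        self.r1 = np.asarray(counts_rep1, dtype=float)
        self.r2 = np.asarray(counts_rep2, dtype=float)
        if self.r1.shape != self.r2.shape:
            raise ValueError("replicate count vectors differ in length")
        self.n_bins = n_bins
        self.min_genes_per_bin = min_genes_per_bin

    def _bin(self) -> list[NoiseBin]:
        n = self.r1 + self.r2
        keep = n > 0
        n, r1 = n[keep], self.r1[keep]
        if n.size == 0 or n.min() == n.max():
            raise ValueError("degenerate data: no spread in total counts")
        edges = np.geomspace(n.min(), n.max() + 1, self.n_bins + 1)
        ratio = r1 / n
        bins = []
        which = np.clip(np.searchsorted(edges, n, side="right") - 1, 0, self.n_bins - 1)
        for b in range(self.n_bins):
            sel = which == b
            cnt = int(sel.sum())
            if cnt < self.min_genes_per_bin:
                continue
            bins.append(
                NoiseBin(edges[b], edges[b + 1], float(n[sel].mean()),
                         float(ratio[sel].std(ddof=1)), cnt)
            )
        if len(bins) < 2:
            raise ValueError("fewer than 2 usable bins; supply more genes")
        return bins

    def fit(self, mode: str = "biological") -> NoiseFit:
        # p(1-p) alone enters the SD curve, so the SDs identify only the
        # product; p itself comes from the pooled read split (its MLE under
        # binomial partitioning), then s is fit to the bin SDs.
        bins = self._bin()
        mean_n = np.array([b.mean_n for b in bins])
        sd_obs = np.array([b.sd_ratio for b in bins])
        p = float(self.r1.sum() / (self.r1.sum() + self.r2.sum()))

        if mode == "technical":
            return NoiseFit(p=p, s=0.0, bins=bins)

        def resid(theta):
            (s,) = theta
            return np.sqrt(p * (1 - p) / mean_n + s**2) - sd_obs

        sol = least_squares(resid, x0=[0.05], bounds=([0.0], [0.5]))
        return NoiseFit(p=p, s=float(sol.x[0]), bins=bins)


def fit_noise(counts_rep1, counts_rep2, n_bins: int = 20,
              mode: str = "biological") -> NoiseFit:
    return ReplicateNoiseModel(counts_rep1, counts_rep2, n_bins=n_bins).fit(mode)


def select_threshold(fit: NoiseFit, alpha: float = 0.05) -> int:
    """Smallest total count n at which the technical (counting) variance is
    at most ``alpha`` times the biological variance s^2.

    Returns the total-count threshold; the per-replicate convention is
    threshold/2.  Undefined when s = 0.
    """
    if fit.s <= 0:
        raise ValueError("threshold undefined for s = 0 (no biological variance)")
    return int(np.ceil(fit.p * (1 - fit.p) / (alpha * fit.s**2)))


def simulate_replicate_counts(
    n_genes: int, p: float = 0.5, s: float = 0.0, seed: int = 0,
    log10_n_range: tuple[float, float] = (1.0, 5.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic replicate pair: totals log-uniform over the given range,
    per-gene replicate-1 probability Normal(p, s) truncated to (0, 1)."""
    rng = np.random.default_rng(seed)
    n = np.floor(10 ** rng.uniform(*log10_n_range, size=n_genes)).astype(np.int64)
    p_gene = np.clip(rng.normal(p, s, size=n_genes), 1e-3, 1 - 1e-3)
    r1 = rng.binomial(n, p_gene)
    return r1, n - r1
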