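"""Configuration-driven pipeline wiring all analysis stages.

A run is described by a YAML file::

    inputs:
      fasta: genome.fasta
      gff: annotation.gff3
      v1:  [{plus: v1_rep1.plus.bedgraph, minus: v1_rep1.minus.bedgraph}, ...]
      at1: [{plus: ..., minus: ...}, ...]
      rpf_5p: {plus: ..., minus: ...}
      rpf_3p: {plus: ..., minus: ...}      # optional, frame analysis
      mrna_5p: {plus: ..., minus: ...}     # optional
      rpf_reads: rpf_reads.bed             # optional, gene counting
      mrna_reads: mrna_reads.bed           # optional
      mask: mask.bed                       # optional
      cleavage_sites: sites.tsv            # optional
      tm_domains: tm.tsv                   # optional
    params:
      metagene_window: [-100, 100]
      pausing: {window: 10, min_positive: 6, percentile: 80, flank: 29}
      noise: {bins: 20, alpha: 0.05}
      termination: {window: [3, 27], min_reads: 60}
      cleavage: {window: 50, offset_shift: 0}
      anti_sd: UCCUCCAC
    outdir: out/

Each stage writes TSV/JSON reports into ``outdir`` and the manifest records
package version, parameters and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cleavage as cl, noise as noise_mod, pausing as pausing_mod
from . import periodicity as per_mod, sd as sd_mod, termination as term_mod
from .io import (
    CountTrack, assign_gene_counts, classify_operon_context, load_annotation,
    read_mask_bed, read_reads_bed, read_sites_tsv, read_tm_domains_tsv,
)
from .pars import ParsTrack, load_filter, metagene, pars_score
from .periodicity import RegionSpec

log = logging.getLogger(__name__)

STAGES = ("score", "metagene", "noise", "pausing", "periodicity", "sd",
          "termination", "cleavage")


@dataclass
class RunConfig:
    inputs: dict
    params: dict = field(default_factory=dict)
    outdir: str = "parstools_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "inputs" not in raw:
            raise ValueError("config must be a mapping with an 'inputs' block")
        return cls(inputs=raw["inputs"], params=raw.get("params", {}),
                   outdir=raw.get("outdir", "parstools_out"))

    def require(self, *keys: str, stage: str = "") -> None:
        missing = [k for k in keys if k not in self.inputs]
        if missing:
            raise ValueError(
                f"stage {stage!r} needs missing input(s): {', '.join(missing)}")

    def param(self, *path, default=None):
        node = self.params
        for p in path:
            if not isinstance(node, dict) or p not in node:
                return default
            node = node[p]
        return node


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Run:
    """Loaded inputs and lazily computed shared intermediates."""

    def __init__(self, config: RunConfig):
        self.config = config
        config.require("fasta", "gff", stage="load")
        self.genome, self.transcripts = load_annotation(
            config.inputs["fasta"], config.inputs["gff"])
        self.chrom_lengths = {c: len(s) for c, s in self.genome.items()}
        self._pars = None
        self._passing = None
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)

    def _track(self, spec: dict, sample_id: str, end="five_prime") -> CountTrack:
        return CountTrack.from_bedgraph(
            sample_id, self.chrom_lengths, spec["plus"], spec["minus"], end=end)

    def tracks(self, key: str, end="five_prime") -> list[CountTrack]:
        spec = self.config.inputs[key]
        if isinstance(spec, dict):
            spec = [spec]
        return [self._track(s, f"{key}_{i}", end) for i, s in enumerate(spec, 1)]

    @property
    def mask(self):
        if "mask" in self.config.inputs:
            return read_mask_bed(self.config.inputs["mask"], self.chrom_lengths)
        return None

    @property
    def pars(self) -> ParsTrack:
        if self._pars is None:
            self.config.require("v1", "at1", stage="score")
            self._v1 = self.tracks("v1")
            self._at1 = self.tracks("at1")
            self._pars = pars_score(self._v1, self._at1, self.genome)
        return self._pars

    @property
    def passing(self):
        _ = self.pars
        if self._passing is None:
            self._passing = load_filter(self._v1, self._at1, self.transcripts,
                                        self.mask)
        return self._passing


# ---------------------------------------------------------------------------
# stages


def stage_score(run: Run) -> dict:
    run.pars.to_bedgraph(run.outdir / "pars.plus.bedgraph",
                         run.outdir / "pars.minus.bedgraph")
    ids = [r.gene_id for r in run.passing]
    pd.Series(ids, name="gene_id").to_csv(
        run.outdir / "transcripts_passing_load.tsv", sep="\t", index=False)
    return {"n_transcripts": len(run.transcripts), "n_passing_load": len(ids)}


def stage_metagene(run: Run) -> dict:
    window = tuple(run.config.param("metagene_window", default=(-100, 100)))
    for anchor in ("start_codon", "stop_codon"):
        prof = metagene(run.pars, run.passing, run.genome, anchor, window)
        prof.to_tsv(run.outdir / f"metagene_{anchor}.tsv")
    return {"window": list(window)}


def stage_noise(run: Run) -> dict:
    run.config.require("noise_counts_rep1", "noise_counts_rep2", stage="noise")
    c1 = pd.read_csv(run.config.inputs["noise_counts_rep1"], sep="\t")
    c2 = pd.read_csv(run.config.inputs["noise_counts_rep2"], sep="\t")
    merged = c1.merge(c2, on="gene_id", suffixes=("_1", "_2"))
    fit = noise_mod.fit_noise(merged.raw_1, merged.raw_2,
                              n_bins=run.config.param("noise", "bins", default=20))
    fit.to_json(run.outdir / "noise_fit.json")
    fit.bins_frame().to_csv(run.outdir / "noise_bins.tsv", sep="\t", index=False)
    alpha = run.config.param("noise", "alpha", default=0.05)
    thr = noise_mod.select_threshold(fit, alpha) if fit.s > 0 else None
    return {"p": fit.p, "s": fit.s, "threshold_total": thr,
            "threshold_per_replicate": None if thr is None else thr / 2}


def stage_pausing(run: Run) -> dict:
    run.config.require("rpf_5p", stage="pausing")
    rpf = run.tracks("rpf_5p")[0]
    p = run.config.param("pausing", default={}) or {}
    window = p.get("window", 10)
    min_positive = p.get("min_positive", 6)
    percentile = p.get("percentile", 80)
    flank = p.get("flank", 29)
    tm = (read_tm_domains_tsv(run.config.inputs["tm_domains"])
          if "tm_domains" in run.config.inputs else None)
    evaluated = []
    for rec in run.passing:
        for s in pausing_mod.detect_stretches(run.pars, rec, window, min_positive):
            evaluated.append(pausing_mod.l1_l2(rpf, rec, s, flank))
    selected, report = pausing_mod.select_pausing(evaluated, percentile)
    df = pausing_mod.stretches_frame(evaluated)
    if tm is not None:
        df["tm_distance"] = [
            pausing_mod.tm_distance(s, tm) for s in evaluated
        ]
    df.to_csv(run.outdir / "stretches.tsv", sep="\t", index=False)
    pausing_mod.stretches_frame(selected).to_csv(
        run.outdir / "pausing_selected.tsv", sep="\t", index=False)
    return report


def stage_periodicity(run: Run) -> dict:
    out: dict = {}
    prof_start = metagene(run.pars, run.passing, run.genome, "start_codon",
                          (-110, 110))
    spec = per_mod.dft_power(prof_start, RegionSpec("start", 10, 99))
    spec.to_frame().to_csv(run.outdir / "dft_cds_start.tsv", sep="\t", index=False)
    out["dominant_frequency"] = spec.dominant_frequency
    out["codon_position_means"] = list(
        per_mod.codon_position_means(run.pars, run.passing))
    if "rpf_reads" in run.config.inputs and "mrna_reads" in run.config.inputs:
        rpf_reads = read_reads_bed(run.config.inputs["rpf_reads"])
        mrna_reads = read_reads_bed(run.config.inputs["mrna_reads"])
        counts = assign_gene_counts(
            mrna_reads, run.transcripts, max(len(mrna_reads), 1),
            run.chrom_lengths)
        out["frame_kl"] = per_mod.frame_kl(rpf_reads, run.transcripts, counts)
    return out


def stage_sd(run: Run) -> dict:
    anti = run.config.param("anti_sd", default=sd_mod.ANTI_SD_3TO5)
    table = sd_mod.scan_transcripts(run.genome, run.transcripts, anti)
    table.to_csv(run.outdir / "sd_assignments.tsv", sep="\t", index=False)
    out = {"n_per_class": table.sd_class.value_counts().to_dict()}
    if "rpf_reads" in run.config.inputs and "mrna_reads" in run.config.inputs:
        rpf_reads = read_reads_bed(run.config.inputs["rpf_reads"])
        mrna_reads = read_reads_bed(run.config.inputs["mrna_reads"])
        rpf_counts = assign_gene_counts(rpf_reads, run.transcripts,
                                        max(len(rpf_reads), 1), run.chrom_lengths)
        mrna_counts = assign_gene_counts(mrna_reads, run.transcripts,
                                         max(len(mrna_reads), 1), run.chrom_lengths)
        try:
            assoc = sd_mod.sd_association(table, rpf_counts, mrna_counts)
            assoc["per_gene"].to_csv(run.outdir / "sd_association.tsv",
                                     sep="\t", index=False)
            out.update({k: v for k, v in assoc.items() if k != "per_gene"})
        except ValueError as exc:
            out["association"] = f"skipped: {exc}"
    return out


def stage_termination(run: Run) -> dict:
    run.config.require("rpf_5p", stage="termination")
    rpf = run.tracks("rpf_5p")[0]
    p = run.config.param("termination", default={}) or {}
    window = tuple(p.get("window", (3, 27)))
    min_reads = p.get("min_reads", 60)
    rt = term_mod.readthrough_table(rpf, run.passing, window, min_reads)
    rt.to_csv(run.outdir / "readthrough.tsv", sep="\t", index=False)
    freq = term_mod.downstream_stop_frequency(run.genome, run.transcripts)
    freq.to_csv(run.outdir / "downstream_stop_frequency.tsv", sep="\t",
                index=False)
    profiles, comparisons = term_mod.stop_metagene(
        run.pars, run.passing, run.genome)
    for key, prof in profiles.items():
        name = "_".join(key)
        prof.to_tsv(run.outdir / f"stop_metagene_{name}.tsv")
    med = rt.dropna(subset=["readthrough"]).groupby("stop_codon").readthrough.median()
    return {"median_readthrough": med.to_dict(),
            "prestop_comparisons": {f"{a}|{b}": v["p"]
                                    for (a, b), v in comparisons.items()}}


def stage_cleavage(run: Run) -> dict:
    run.config.require("cleavage_sites", stage="cleavage")
    df = read_sites_tsv(run.config.inputs["cleavage_sites"])
    shift = run.config.param("cleavage", "offset_shift", default=0)
    window = run.config.param("cleavage", "window", default=50)
    sites = cl.sites_from_frame(df, shift)
    out: dict = {}
    labels = sorted({s.source_label for s in sites})
    for label in labels:
        sub = [s for s in sites if s.source_label == label]
        prof = cl.site_metagene(run.pars, sub, run.genome, window)
        prof.to_tsv(run.outdir / f"cleavage_metagene_{label or 'all'}.tsv")
        mat = cl.nucleotide_frequency_matrix(run.genome, sub)
        mat.to_csv(run.outdir / f"cleavage_basefreq_{label or 'all'}.tsv", sep="\t")
        out[label or "all"] = len(sub)
    if len(labels) == 2:
        a = [s for s in sites if s.source_label == labels[0]]
        b = [s for s in sites if s.source_label == labels[1]]
        out["comparison"] = cl.compare_signatures(run.pars, a, b)
    return out


_STAGE_FN = {
    "score": stage_score, "metagene": stage_metagene, "noise": stage_noise,
    "pausing": stage_pausing, "periodicity": stage_periodicity,
    "sd": stage_sd, "termination": stage_termination, "cleavage": stage_cleavage,
}


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in dependency order; returns and writes
    the run manifest."""
    bad = [s for s in stages if s not in _STAGE_FN]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")
    # validate inputs for requested stages before any computation
    cfg = config
    needs = {"noise": ("noise_counts_rep1", "noise_counts_rep2"),
             "pausing": ("rpf_5p",), "termination": ("rpf_5p",),
             "cleavage": ("cleavage_sites",)}
    for s in stages:
        for key in needs.get(s, ()):
            cfg.require(key, stage=s)

    run = Run(config)
    manifest = {
        "version": __version__,
        "params": config.params,
        "inputs": {
            k: (_sha256(v) if isinstance(v, str) and Path(v).exists() else "nested")
            for k, v in config.inputs.items()
        },
        "stages": {},
    }
    ordered = [s for s in STAGES if s in stages]
    for s in ordered:
        try:
            manifest["stages"][s] = _STAGE_FN[s](run)
        except Exception as exc:  # record partial completion
            manifest["stages"][s] = {"error": str(exc)}
            log.error("stage %s failed: %s", s, exc)
            _write_manifest(run, manifest)
            raise
    _write_manifest(run, manifest)
    return manifest


def _write_manifest(run: Run, manifest: dict) -> None:
    with open(run.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
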