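"""Seeded generator of a toy bacterial genome with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised against a known answer:

* a single chromosome of operon and singleton transcription units on both
  strands, each gene with 5'/3'UTRs, a Shine-Dalgarno element of a chosen
  strength class, and a stop codon drawn from a UAA-heavy mix;
* a per-nucleotide paired/unpaired ground-truth mask with planted features:
  an unpaired ribosome docking window at -30..-12 upstream of the start,
  fully paired CDS stretches (optionally acting as pause sites), a paired
  block 4-8 nt 5' of the stop for a fraction of UAA-terminated genes, and
  RNase-E-like cleavage signatures (paired -8..-2, unpaired 0..+2);
* base-specific nuclease cleavage counts: Poisson counts whose rate is the
  signal rate at informative positions (V1 at paired bases; A/T1 at
  unpaired G/C/U, never at adenines) and a leak rate epsilon elsewhere;
* ribosome footprints (23-25 nt) with kappa-fold 5'-end enrichment over the
  29 nt upstream of pause stretches, a 3-nt reading-frame bias on 3'-ends,
  and UGA-gene-specific readthrough leak into the 3'UTR;
* mRNA-seq reads uniform along transcripts, abundances log-normal.

Structure is a binary mask, not a folded molecule: the analyses consume
pairedness only, so no thermodynamic folding is simulated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import revcomp, spawn_rngs
from .cleavage import CleavageSite
from .io import (
    CountTrack,
    TranscriptRecord,
    compute_downstream_gaps,
    write_fasta,
    write_gff,
    write_reads_bed,
)
from . import sd as sd_mod

CHROM = "chr1"
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic transcriptome."""

    seed: int = 0
    n_genes: int = 60
    # layout
    operon_fraction: float = 0.5
    operon_size_range: tuple[int, int] = (2, 4)
    overlap_fraction: float = 0.5  # of operon junctions in the <30 nt class
    overlap_gap_range: tuple[int, int] = (5, 25)
    nonoverlap_gap_range: tuple[int, int] = (35, 80)
    minus_strand_fraction: float = 0.3
    utr5_len: int = 60
    utr3_len: int = 60
    spacer_len: int = 50
    cds_codons: tuple[int, int] = (60, 150)
    # structure ground truth
    background_paired_p: float = 0.45
    codon_period_bias: float = 0.25  # extra paired probability at codon position 1
    cds_stretch_len: int = 15
    docking_window: tuple[int, int] = (-30, -12)  # rel. first nt of start codon
    prestop_block_fraction: float = 0.7  # of UAA-terminated genes
    prestop_block_len: int = 6
    prestop_block_offset: tuple[int, int] = (4, 8)  # nt 5' of the stop codon
    sd_occlusion_fraction: float = 0.0
    stop_codon_mix: tuple[float, float, float] = (0.6, 0.1, 0.3)  # UAA, UAG, UGA
    inframe_stop_fraction: float = 0.10
    sd_class_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    # cleavage-site planting
    n_rnase_e_sites: int = 0
    n_other_endo_sites: int = 0
    # probing counts
    coverage: float = 20.0  # mean probing counts per signal nt, median gene
    r_paired_v1: float = 1.0
    r_unpaired_at1: float = 1.0
    epsilon: float = 0.1  # leak rate relative to the signal rates
    n_probing_replicates: int = 2
    # expression
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    # ribosome profiling
    rpf_density: float = 2.0  # reads per CDS nt for a median-abundance gene
    pause_fraction: float = 0.15  # genes whose CDS stretch is a pause site
    kappa: float = 4.0
    pause_flank: int = 29
    frame_bias: tuple[float, float, float] = (0.7, 0.2, 0.1)
    rpf_lengths: tuple[int, ...] = (23, 24, 25)
    readthrough_leak: float = 0.05  # UGA genes only
    # mRNA-seq
    mrna_density: float = 2.0
    mrna_lengths: tuple[int, ...] = (24, 26, 28, 30)

    def __post_init__(self):
        if self.epsilon < 0 or self.r_paired_v1 < 0 or self.r_unpaired_at1 < 0:
            raise ValueError("rates must be non-negative")
        if self.epsilon >= min(self.r_paired_v1, self.r_unpaired_at1):
            raise ValueError("epsilon must be below the signal rates")
        if self.kappa < 1:
            raise ValueError("kappa must be >= 1")
        if self.utr5_len < -self.docking_window[0]:
            raise ValueError("5'UTR shorter than the docking window")
        if self.utr3_len < 27:
            raise ValueError("3'UTR shorter than the readthrough window")


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed by gene."""

    genome: dict[str, str]
    transcripts: list[TranscriptRecord]
    paired: dict[str, np.ndarray]  # genomic bool mask per chromosome
    features: dict[str, list[tuple[str, int, int]]]  # (kind, tx-local start, len)
    abundance: dict[str, float]  # relative to the median gene
    pause_sites: dict[str, list[tuple[int, int, float]]]  # (cds start, len, kappa)
    sd_class: dict[str, str]
    inframe_stop: dict[str, bool]  # only genes with a controllable window
    cleavage_sites: list[CleavageSite] = field(default_factory=list)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def paired_local(self, rec: TranscriptRecord) -> np.ndarray:
        return rec.local_view(self.paired[rec.chrom])

    def record(self, gene_id: str) -> TranscriptRecord:
        return next(r for r in self.transcripts if r.gene_id == gene_id)


# ---------------------------------------------------------------------------
# SD planting


_SD_BANDS = {  # stand-alone 8-mer energy bands with margin for context dangles
    "strong": (-np.inf, -9.2),
    "medium": (-8.0, -5.0),
    "weak": (-3.8, -2.7),
    "none": (-0.5, 0.1),
}


def _sd_pool(cls: str) -> pd.DataFrame:
    table = sd_mod.exhaustive_8mer_energies()
    lo, hi = _SD_BANDS[cls]
    return table[(table.mhe > lo) & (table.mhe <= hi)].reset_index(drop=True)


def _plant_sd(rng: np.random.Generator, cls: str, length: int,
              max_tries: int = 60) -> tuple[str, str]:
    """A ``length``-nt upstream sequence (5'->3', DNA) whose MHE scan lands
    in class ``cls``; rejection-sampled against the scan itself.  Returns
    (sequence, achieved class)."""
    pool = _sd_pool(cls) if cls != "none" else None
    best = None
    for _ in range(max_tries):
        ctx = "".join(rng.choice(["C", "A"], size=length, p=[0.65, 0.35]))
        if cls != "none" and length >= 15:
            motif = pool.seq.iloc[int(rng.integers(len(pool)))]
            motif_dna = motif.replace("U", "T")
            i = length - 14  # 8th base 7 nt upstream of the start (spacing 7)
            ctx = ctx[:i] + motif_dna + ctx[i + 8 :]
        got = sd_mod.mhe_scan(ctx).sd_class
        if got == cls:
            return ctx, got
        best = (ctx, got)
    return best  # best-effort; caller records the achieved class


# ---------------------------------------------------------------------------
# genome construction


class _GeneDraft:
    """Scratch state for one gene while its unit is being assembled."""

    def __init__(self, gene_id, cds_len, utr5, utr3, stop_codon, operon_id):
        self.gene_id = gene_id
        self.cds_len = cds_len
        self.utr5 = utr5
        self.utr3 = utr3
        self.stop_codon = stop_codon
        self.operon_id = operon_id
        self.features: list[tuple[str, int, int]] = []  # CDS-local for now
        self.pause: list[tuple[int, int, float]] = []
        self.sd_class = "none"
        self.inframe_stop: bool | None = None
        self.cleavage: list[tuple[int, str]] = []  # (CDS-local pos, label)


def _random_cds(rng: np.random.Generator, n_codons: int, stop: str) -> str:
    codons = rng.choice(_NON_STOP_CODONS, size=n_codons - 1)
    body = "ATG" + "".join(codons[1:])
    return body + stop


def _low_a_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(["G", "C", "T"], size=n))


def make_genome(config: SimConfig) -> GroundTruth:
    """Build the toy genome, annotation and ground truth (deterministic)."""
    rng = spawn_rngs(config.seed, 4)[0]
    stop_names = ("TAA", "TAG", "TGA")

    # -- assign genes to units --------------------------------------------
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    units: list[list[str]] = []
    i = 0
    op_counter = 0
    while i < len(gene_ids):
        if (rng.random() < config.operon_fraction
                and len(gene_ids) - i >= config.operon_size_range[0]):
            size = int(rng.integers(config.operon_size_range[0],
                                    config.operon_size_range[1] + 1))
            size = min(size, len(gene_ids) - i)
            units.append(gene_ids[i : i + size])
            i += size
        else:
            units.append([gene_ids[i]])
            i += 1

    sd_classes = ["strong", "medium", "weak", "none"]
    chrom_seq: list[str] = []
    chrom_mask: list[np.ndarray] = []
    cursor = 0
    records: list[TranscriptRecord] = []
    truth_features: dict[str, list] = {}
    pauses: dict[str, list] = {}
    sd_class_of: dict[str, str] = {}
    inframe: dict[str, bool] = {}
    cleavage_sites: list[CleavageSite] = []
    n_rnase_left = config.n_rnase_e_sites
    n_other_left = config.n_other_endo_sites

    for u_idx, unit in enumerate(units):
        operon_id = None
        if len(unit) > 1:
            operon_id = f"op{u_idx:03d}"
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        gaps = []
        for _ in range(len(unit) - 1):
            if rng.random() < config.overlap_fraction:
                gaps.append(int(rng.integers(*config.overlap_gap_range)))
            else:
                gaps.append(int(rng.integers(*config.nonoverlap_gap_range)))

        # ---- per-gene drafts
        gdrafts = []
        for k, gid in enumerate(unit):
            n_codons = int(rng.integers(*config.cds_codons))
            stop = stop_names[int(rng.choice(3, p=config.stop_codon_mix))]
            utr5 = config.utr5_len if k == 0 else min(config.utr5_len, gaps[k - 1])
            utr3 = config.utr3_len if k == len(unit) - 1 else min(
                config.utr3_len, gaps[k])
            gdrafts.append(_GeneDraft(gid, 3 * n_codons, utr5, utr3, stop, operon_id))

        # ---- unit sequence and mask, gene by gene
        seq_parts: list[str] = []
        mask_parts: list[np.ndarray] = []
        local_cds: list[tuple[int, int]] = []
        start_codon_local: list[int] = []
        protected: list[tuple[int, int]] = []  # unit-local paired features
        pos = 0

        def emit(s: str, m: np.ndarray):
            nonlocal pos
            seq_parts.append(s)
            mask_parts.append(m)
            pos += len(s)

        for k, g in enumerate(gdrafts):
            # leading region: full 5'UTR for the first gene; the operon gap
            # (shared 3'UTR/5'UTR annotation) before the others
            lead = config.utr5_len if k == 0 else gaps[k - 1]
            lead_seq = list("".join(rng.choice(list("ACGT"), size=lead)))
            lead_mask = rng.random(lead) < config.background_paired_p

            # in-frame stop control for the upstream gene's trailing window
            # (written into this shared gap region when part of an operon)
            prev = gdrafts[k - 1] if k > 0 else None
            if prev is not None:
                _control_stops(rng, config, prev, lead_seq,
                               reserve_tail=min(25, lead), inframe=inframe)

            # SD context: last up-to-25 nt of the lead
            want = sd_classes[int(rng.choice(4, p=config.sd_class_mix))]
            n_ctx = min(25, lead)
            if n_ctx >= 8:
                ctx, got = _plant_sd(rng, want, n_ctx)
                lead_seq[lead - n_ctx :] = list(ctx)
                g.sd_class = got
            else:
                g.sd_class = "none"
            sd_class_of[g.gene_id] = g.sd_class

            start_codon_local.append(pos + lead)
            emit("".join(lead_seq), lead_mask)

            # ---- CDS
            cds_start_local = pos
            n_codons = g.cds_len // 3
            cds_seq = list(_random_cds(rng, n_codons, g.stop_codon))
            p_codon = np.clip(
                np.array([
                    config.background_paired_p + config.codon_period_bias,
                    config.background_paired_p - config.codon_period_bias / 2,
                    config.background_paired_p - config.codon_period_bias / 2,
                ]), 0.0, 1.0,
            )
            cds_mask = rng.random(g.cds_len) < np.tile(p_codon, n_codons)

            occupied = np.zeros(g.cds_len, dtype=bool)
            # planted structured stretch (margin for the 29-nt RPF flanks)
            margin = config.pause_flank + 3
            hi = g.cds_len - margin - config.cds_stretch_len - 12
            if hi > margin:
                s0 = int(rng.integers(margin, hi))
                sl = config.cds_stretch_len
                cds_mask[s0 : s0 + sl] = True
                cds_seq[s0 : s0 + sl] = list(_low_a_bases(rng, sl))
                occupied[max(0, s0 - config.pause_flank) : s0 + sl + config.pause_flank] = True
                g.features.append(("cds_stretch", s0, sl))
                protected.append((cds_start_local + s0, cds_start_local + s0 + sl))
                if rng.random() < config.pause_fraction:
                    g.pause.append((s0, sl, config.kappa))
            # pre-stop paired block for a fraction of UAA genes
            if g.stop_codon == "TAA" and rng.random() < config.prestop_block_fraction:
                off = int(rng.integers(*config.prestop_block_offset))
                bl = config.prestop_block_len
                b0 = g.cds_len - 3 - off - bl
                if b0 > 0 and not occupied[b0 : b0 + bl].any():
                    cds_mask[b0 : b0 + bl] = True
                    cds_seq[b0 : b0 + bl] = list(_low_a_bases(rng, bl))
                    occupied[b0 : b0 + bl] = True
                    g.features.append(("pre_stop_block", b0, bl))
                    protected.append((cds_start_local + b0, cds_start_local + b0 + bl))
            # cleavage-site signatures
            for label_left in ("rnase_e", "other_endo"):
                want_n = n_rnase_left if label_left == "rnase_e" else n_other_left
                if want_n <= 0 or rng.random() > 0.8:
                    continue
                lo_c, hi_c = 15, g.cds_len - 15
                if hi_c <= lo_c:
                    continue
                c0 = int(rng.integers(lo_c, hi_c))
                if occupied[c0 - 10 : c0 + 4].any():
                    continue
                if label_left == "rnase_e":
                    cds_mask[c0 - 8 : c0 - 1] = True  # paired -8..-2
                    cds_seq[c0 - 8 : c0 - 1] = list(_low_a_bases(rng, 7))
                    n_rnase_left -= 1
                else:
                    cds_mask[c0 - 8 : c0 - 1] = False
                    n_other_left -= 1
                cds_mask[c0 : c0 + 3] = False  # unpaired 0..+2
                # A/U-rich unpaired core, typical of endonuclease targets
                cds_seq[c0 : c0 + 3] = list(rng.choice(["A", "T"], size=3))
                occupied[c0 - 10 : c0 + 4] = True
                protected.append((cds_start_local + c0 - 10, cds_start_local + c0 + 4))
                g.cleavage.append((c0, label_left))

            local_cds.append((cds_start_local, cds_start_local + g.cds_len))
            emit("".join(cds_seq), cds_mask)

        # ---- trailing 3'UTR of the last gene + stop control
        last = gdrafts[-1]
        tail = config.utr3_len
        tail_seq = list("".join(rng.choice(list("ACGT"), size=tail)))
        tail_mask = rng.random(tail) < config.background_paired_p
        _control_stops(rng, config, last, tail_seq, reserve_tail=0, inframe=inframe)
        emit("".join(tail_seq), tail_mask)

        unit_seq = "".join(seq_parts)
        unit_mask = np.concatenate(mask_parts) if mask_parts else np.zeros(0, bool)
        unit_len = len(unit_seq)

        # ---- docking windows: unpaired at -30..-12 of each start codon,
        # skipping positions inside planted paired features
        d0, d1 = config.docking_window
        for g, sc in zip(gdrafts, start_codon_local):
            run_start, run_len, best_run = None, 0, (0, 0)
            for off in range(d0, d1 + 1):
                p = sc + off
                free = 0 <= p < unit_len and not any(a <= p < b for a, b in protected)
                if free:
                    unit_mask[p] = False
                    if run_start is None:
                        run_start, run_len = off, 1
                    else:
                        run_len += 1
                    if run_len > best_run[1]:
                        best_run = (run_start, run_len)
                else:
                    run_start, run_len = None, 0
            if best_run[1] >= 5:
                g.features.append(("docking_site", best_run[0], best_run[1]))

        # ---- place on the chromosome
        if strand == "-":
            genome_seq = revcomp(unit_seq)
            genome_mask = unit_mask[::-1]
        else:
            genome_seq = unit_seq
            genome_mask = unit_mask
        chrom_seq.append(genome_seq)
        chrom_mask.append(genome_mask)

        for g, (a, b) in zip(gdrafts, local_cds):
            if strand == "+":
                cds_start, cds_end = cursor + a, cursor + b
            else:
                cds_start, cds_end = cursor + unit_len - b, cursor + unit_len - a
            rec = TranscriptRecord(
                gene_id=g.gene_id, chrom=CHROM, strand=strand,
                cds_start=cds_start, cds_end=cds_end,
                utr5_len=g.utr5, utr3_len=g.utr3,
                stop_codon=g.stop_codon.replace("T", "U"),
                operon_id=g.operon_id,
            )
            records.append(rec)
            # translate feature coordinates to transcript-local
            # (docking fs is relative to the start codon; others are CDS-local)
            feats = []
            for kind, fs, fl in g.features:
                local = g.utr5 + fs
                if local >= 0:
                    feats.append((kind, local, fl))
            truth_features[g.gene_id] = feats
            pauses[g.gene_id] = g.pause
            for c0, label in g.cleavage:
                gpos = (cds_start + c0) if strand == "+" else (cds_end - 1 - c0)
                cleavage_sites.append(CleavageSite(CHROM, gpos, strand, label))

        cursor += unit_len
        spacer = "".join(rng.choice(list("ACGT"), size=config.spacer_len))
        chrom_seq.append(spacer)
        chrom_mask.append(rng.random(config.spacer_len) < config.background_paired_p)
        cursor += config.spacer_len

    genome = {CHROM: "".join(chrom_seq)}
    paired = {CHROM: (np.concatenate(chrom_mask) if chrom_mask
                      else np.zeros(0, dtype=bool))}
    records = compute_downstream_gaps(records)

    # abundances, relative to the median gene
    abund_raw = rng.lognormal(config.abundance_mu, config.abundance_sigma,
                              size=len(records))
    med = np.median(abund_raw) if len(records) else 1.0
    abundance = {r.gene_id: float(a / med) for r, a in zip(records, abund_raw)}

    return GroundTruth(
        genome=genome, transcripts=records, paired=paired,
        features=truth_features, abundance=abundance, pause_sites=pauses,
        sd_class=sd_class_of, inframe_stop=inframe,
        cleavage_sites=cleavage_sites,
    )


def _control_stops(rng, config, g: _GeneDraft, region_seq: list[str],
                   reserve_tail: int, inframe: dict) -> None:
    """Plant or scrub in-frame stop codons in the first 9 codons of the
    region 3' of ``g``'s stop codon.  Skipped (not recorded) when the
    27-nt window would collide with the next gene's SD context."""
    window = 27
    if len(region_seq) - reserve_tail < window:
        return
    flag = rng.random() < config.inframe_stop_fraction
    stop_at = int(rng.integers(0, 9)) if flag else -1
    for c in range(9):
        codon = "".join(region_seq[3 * c : 3 * c + 3])
        if c == stop_at:
            region_seq[3 * c : 3 * c + 3] = list(
                ("TAA", "TAG", "TGA")[int(rng.choice(3, p=config.stop_codon_mix))])
        elif codon in ("TAA", "TAG", "TGA"):
            region_seq[3 * c : 3 * c + 3] = list(
                _NON_STOP_CODONS[int(rng.integers(len(_NON_STOP_CODONS)))])
    inframe[g.gene_id] = flag


# ---------------------------------------------------------------------------
# count tracks


def simulate_probing(
    truth: GroundTruth, config: SimConfig, rng: np.random.Generator | None = None,
) -> tuple[list[CountTrack], list[CountTrack]]:
    """Per-replicate V1 (paired-specific) and A/T1 (unpaired-specific,
    adenine-blind) 5'-end count tracks."""
    if rng is None:
        rng = spawn_rngs(config.seed, 4)[1]
    lens = truth.chrom_lengths
    n_rep = config.n_probing_replicates
    cov = config.coverage / n_rep

    v1_rate = {(c, s): np.zeros(n) for c, n in lens.items() for s in "+-"}
    at1_rate = {(c, s): np.zeros(n) for c, n in lens.items() for s in "+-"}
    for rec in truth.transcripts:
        a = truth.abundance[rec.gene_id]
        sl = slice(rec.tx_start, rec.tx_end)
        paired = truth.paired[rec.chrom][sl]
        base = np.frombuffer(truth.genome[rec.chrom][sl].encode(), dtype="S1")
        is_a = base == (b"A" if rec.strand == "+" else b"T")
        k = (rec.chrom, rec.strand)
        v1_rate[k][sl] += cov * a * np.where(
            paired, config.r_paired_v1, config.epsilon)
        at1_rate[k][sl] += cov * a * np.where(
            ~paired & ~is_a, config.r_unpaired_at1, config.epsilon)

    v1_tracks, at1_tracks = [], []
    for rep in range(n_rep):
        v1 = CountTrack(f"v1_rep{rep + 1}", lens)
        at1 = CountTrack(f"at1_rep{rep + 1}", lens)
        for k in v1_rate:
            v1.data[k] = rng.poisson(v1_rate[k])
            at1.data[k] = rng.poisson(at1_rate[k])
        v1_tracks.append(v1)
        at1_tracks.append(at1)
    return v1_tracks, at1_tracks


def _reads_to_tracks_and_frame(
    truth, rec, q_tx, p3_tx,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Map local (5', 3') read coordinates to genomic start/end/5'pos/3'pos."""
    g5 = np.array([rec.local_to_genomic(int(t)) for t in q_tx])
    g3 = np.array([rec.local_to_genomic(int(t)) for t in p3_tx])
    start = np.minimum(g5, g3)
    end = np.maximum(g5, g3) + 1
    return start, end, g5, g3


def simulate_rpf(
    truth: GroundTruth, config: SimConfig, rng: np.random.Generator | None = None,
) -> tuple[CountTrack, CountTrack, pd.DataFrame]:
    """RPF 5'-end and 3'-end tracks plus the read-position table."""
    if rng is None:
        rng = spawn_rngs(config.seed, 4)[2]
    lens = truth.chrom_lengths
    t5 = CountTrack("rpf", lens, end="five_prime")
    t3 = CountTrack("rpf", lens, end="three_prime")
    rows = []
    lengths = np.array(config.rpf_lengths)
    pi = np.array(config.frame_bias, dtype=float)
    pi = pi / pi.sum()

    for rec in truth.transcripts:
        a = truth.abundance[rec.gene_id]
        n = rng.poisson(config.rpf_density * a * rec.cds_len)
        if n == 0 and config.readthrough_leak == 0:
            continue
        w = np.ones(rec.cds_len)
        for s0, sl, kappa in truth.pause_sites.get(rec.gene_id, []):
            w[max(0, s0 - config.pause_flank) : s0] *= kappa
        q = rng.choice(rec.cds_len, size=n, p=w / w.sum())  # 5'-end, CDS-local
        L = lengths[rng.integers(0, lengths.size, size=n)]
        p3 = q + L - 1
        f = rng.choice(3, size=n, p=pi)
        delta = f - (p3 % 3)
        q, p3 = q + delta, p3 + delta
        ok = (q >= 0) & (p3 < rec.cds_len)
        q, p3, L = q[ok], p3[ok], L[ok]
        q_tx = q + rec.cds_local_start
        p3_tx = p3 + rec.cds_local_start

        # readthrough leak into the 3'UTR (UGA-terminated genes)
        if rec.stop_codon == "UGA" and config.readthrough_leak > 0:
            n_leak = rng.poisson(config.readthrough_leak * config.rpf_density * a * 25)
            if n_leak:
                off = rng.integers(3, 28, size=n_leak)
                ql = rec.cds_local_end - 1 + off  # 5'-end in the +3..+27 window
                Ll = lengths[rng.integers(0, lengths.size, size=n_leak)]
                p3l = np.minimum(ql + Ll - 1, rec.tx_len - 1)
                q_tx = np.concatenate([q_tx, ql])
                p3_tx = np.concatenate([p3_tx, p3l])
                L = np.concatenate([L, Ll])

        if q_tx.size == 0:
            continue
        start, end, g5, g3 = _reads_to_tracks_and_frame(truth, rec, q_tx, p3_tx)
        k = (rec.chrom, rec.strand)
        np.add.at(t5.data[k], g5, 1)
        np.add.at(t3.data[k], g3, 1)
        for s, e in zip(start, end):
            rows.append((rec.chrom, int(s), int(e), rec.gene_id, 0, rec.strand))

    reads = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return t5, t3, reads


def simulate_rnaseq(
    truth: GroundTruth, config: SimConfig, rng: np.random.Generator | None = None,
) -> tuple[CountTrack, pd.DataFrame]:
    """mRNA-seq 5'-end track plus the read-position table (uniform reads)."""
    if rng is None:
        rng = spawn_rngs(config.seed, 4)[3]
    lens = truth.chrom_lengths
    t5 = CountTrack("mrna", lens, end="five_prime")
    rows = []
    lengths = np.array(config.mrna_lengths)
    for rec in truth.transcripts:
        a = truth.abundance[rec.gene_id]
        n = rng.poisson(config.mrna_density * a * rec.tx_len)
        if n == 0:
            continue
        L = lengths[rng.integers(0, lengths.size, size=n)]
        q_tx = rng.integers(0, np.maximum(rec.tx_len - L + 1, 1))
        p3_tx = np.minimum(q_tx + L - 1, rec.tx_len - 1)
        start, end, g5, g3 = _reads_to_tracks_and_frame(truth, rec, q_tx, p3_tx)
        k = (rec.chrom, rec.strand)
        np.add.at(t5.data[k], g5, 1)
        for s, e in zip(start, end):
            rows.append((rec.chrom, int(s), int(e), rec.gene_id, 0, rec.strand))
    reads = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )
    return t5, reads


# ---------------------------------------------------------------------------
# bundled dataset


@dataclass
class SyntheticDataset:
    config: SimConfig
    truth: GroundTruth
    v1: list[CountTrack]
    at1: list[CountTrack]
    rpf_5p: CountTrack
    rpf_3p: CountTrack
    rpf_reads: pd.DataFrame
    mrna_5p: CountTrack
    mrna_reads: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.truth.genome, out / "genome.fasta")
        write_gff(self.truth.transcripts, out / "annotation.gff3")
        for i, (v1, at1) in enumerate(zip(self.v1, self.at1), start=1):
            v1.to_bedgraph(out / f"v1_rep{i}.plus.bedgraph",
                           out / f"v1_rep{i}.minus.bedgraph")
            at1.to_bedgraph(out / f"at1_rep{i}.plus.bedgraph",
                            out / f"at1_rep{i}.minus.bedgraph")
        self.rpf_5p.to_bedgraph(out / "rpf_5p.plus.bedgraph",
                                out / "rpf_5p.minus.bedgraph")
        self.rpf_3p.to_bedgraph(out / "rpf_3p.plus.bedgraph",
                                out / "rpf_3p.minus.bedgraph")
        self.mrna_5p.to_bedgraph(out / "mrna_5p.plus.bedgraph",
                                 out / "mrna_5p.minus.bedgraph")
        write_reads_bed(self.rpf_reads, out / "rpf_reads.bed")
        write_reads_bed(self.mrna_reads, out / "mrna_reads.bed")
        feats = [
            (gid, kind, start, length)
            for gid, lst in self.truth.features.items()
            for kind, start, length in lst
        ]
        pd.DataFrame(feats, columns=["gene_id", "kind", "start", "length"]).to_csv(
            out / "truth_features.tsv", sep="\t", index=False)
        sidecar = {
            "config": asdict(self.config),
            "abundance": self.truth.abundance,
            "pause_sites": self.truth.pause_sites,
            "sd_class": self.truth.sd_class,
            "inframe_stop": self.truth.inframe_stop,
            "cleavage_sites": [
                [s.chrom, s.position, s.strand, s.source_label]
                for s in self.truth.cleavage_sites
            ],
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Full synthetic study: genome plus all four count-track types."""
    rngs = spawn_rngs(config.seed, 4)
    truth = make_genome(config)
    v1, at1 = simulate_probing(truth, config, rngs[1])
    rpf5, rpf3, rpf_reads = simulate_rpf(truth, config, rngs[2])
    mrna5, mrna_reads = simulate_rnaseq(truth, config, rngs[3])
    return SyntheticDataset(config, truth, v1, at1, rpf5, rpf3, rpf_reads,
                            mrna5, mrna_reads)
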