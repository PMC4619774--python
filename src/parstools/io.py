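"""Genome/annotation/count-track ingestion and gene-level counting.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open, on the forward genomic
strand (``cds_start <= pos < cds_end``).  GFF3 input (1-based, closed) is
converted on load and converted back on write.  All per-position tracks are
strand-specific; transcript-local views are returned 5'->3' so downstream
analyses are strand-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import revcomp, to_rna

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TranscriptRecord:
    """A protein-coding gene with CDS/UTR extents and operon context.

    ``downstream_gap`` is the signed nt distance from this gene's CDS end to
    the CDS start of the next gene in the same operon (transcription order);
    negative values denote overlapping ORFs.  ``None`` when the gene has no
    downstream operon partner.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds_start: int  # 0-based half-open genomic coords, cds_start < cds_end
    cds_end: int
    utr5_len: int = 0
    utr3_len: int = 0
    stop_codon: str = ""  # RNA alphabet: UAA / UAG / UGA
    operon_id: str | None = None
    downstream_gap: int | None = None

    def __post_init__(self) -> None:
        if self.cds_end - self.cds_start <= 0:
            raise ValueError(f"{self.gene_id}: empty CDS")
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError(f"{self.gene_id}: negative UTR length")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    # -- derived geometry ---------------------------------------------------
    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def tx_start(self) -> int:
        """Genomic start (leftmost) of the transcript including UTRs."""
        return self.cds_start - (self.utr5_len if self.strand == "+" else self.utr3_len)

    @property
    def tx_end(self) -> int:
        return self.cds_end + (self.utr3_len if self.strand == "+" else self.utr5_len)

    @property
    def tx_len(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def cds_local_start(self) -> int:
        """Offset of the first CDS nt in transcript-local (5'->3') coords."""
        return self.utr5_len

    @property
    def cds_local_end(self) -> int:
        return self.utr5_len + self.cds_len

    def local_view(self, genomic: np.ndarray) -> np.ndarray:
        """Transcript-local 5'->3' slice of a genomic per-position array."""
        sl = genomic[self.tx_start : self.tx_end]
        return sl[::-1] if self.strand == "-" else sl

    def local_to_genomic(self, local: int) -> int:
        if self.strand == "+":
            return self.tx_start + local
        return self.tx_end - 1 - local

    def genomic_to_local(self, pos: int) -> int:
        if self.strand == "+":
            return pos - self.tx_start
        return self.tx_end - 1 - pos

    def sequence(self, genome: Mapping[str, str]) -> str:
        """Transcript sequence 5'->3' (DNA alphabet)."""
        s = genome[self.chrom][self.tx_start : self.tx_end]
        return revcomp(s) if self.strand == "-" else s.upper()


class CountTrack:
    """Strand-specific per-position read-end counts for one sample.

    ``data`` maps ``(chrom, strand)`` to a dense int64 array covering the
    chromosome; ``end`` records whether counts mark read 5'- or 3'-ends.
    """

    def __init__(
        self,
        sample_id: str,
        chrom_lengths: Mapping[str, int],
        end: str = "five_prime",
        library_size: int | None = None,
    ):
        if end not in ("five_prime", "three_prime"):
            raise ValueError(f"bad end type {end!r}")
        self.sample_id = sample_id
        self.end = end
        self.chrom_lengths = dict(chrom_lengths)
        self.data: dict[tuple[str, str], np.ndarray] = {
            (c, s): np.zeros(n, dtype=np.int64)
            for c, n in self.chrom_lengths.items()
            for s in "+-"
        }
        self._library_size = library_size

    @property
    def library_size(self) -> int:
        if self._library_size is not None:
            return self._library_size
        return self.total_counts()

    @library_size.setter
    def library_size(self, v: int) -> None:
        if v <= 0:
            raise ValueError("library_size must be positive")
        if v < self.total_counts():
            raise ValueError("library_size smaller than total track counts")
        self._library_size = v

    def total_counts(self) -> int:
        return int(sum(a.sum() for a in self.data.values()))

    def add(self, other: "CountTrack") -> "CountTrack":
        """Position-wise sum (replicate combination); library sizes add."""
        out = CountTrack(self.sample_id, self.chrom_lengths, self.end)
        for k in self.data:
            out.data[k] = self.data[k] + other.data[k]
        out._library_size = self.library_size + other.library_size
        return out

    def rpm(self) -> dict[tuple[str, str], np.ndarray]:
        """Counts scaled to reads per million mapped."""
        scale = 1e6 / self.library_size
        return {k: a * scale for k, a in self.data.items()}

    def transcript_counts(self, rec: TranscriptRecord) -> np.ndarray:
        return rec.local_view(self.data[(rec.chrom, rec.strand)])

    # -- bedGraph serialization --------------------------------------------
    def to_bedgraph(self, path_plus: str | Path, path_minus: str | Path) -> None:
        for strand, path in (("+", path_plus), ("-", path_minus)):
            with open(path, "w") as fh:
                fh.write(
                    f"track type=bedGraph name={self.sample_id}{strand} "
                    f"library_size={self.library_size} end={self.end}\n"
                )
                for chrom in self.chrom_lengths:
                    a = self.data[(chrom, strand)]
                    (pos,) = np.nonzero(a)
                    if pos.size == 0:
                        continue
                    # merge adjacent equal-valued positions into intervals
                    brk = np.nonzero((np.diff(pos) != 1) | (np.diff(a[pos]) != 0))[0]
                    starts = np.concatenate(([0], brk + 1))
                    ends = np.concatenate((brk, [pos.size - 1]))
                    for i, j in zip(starts, ends):
                        fh.write(f"{chrom}\t{pos[i]}\t{pos[j] + 1}\t{a[pos[i]]}\n")

    @classmethod
    def from_bedgraph(
        cls,
        sample_id: str,
        chrom_lengths: Mapping[str, int],
        path_plus: str | Path,
        path_minus: str | Path,
        end: str = "five_prime",
        library_size: int | None = None,
    ) -> "CountTrack":
        track = cls(sample_id, chrom_lengths, end=end)
        for strand, path in (("+", path_plus), ("-", path_minus)):
            with open(path) as fh:
                header = fh.readline()
                if header.startswith("track") and library_size is None:
                    for tok in header.split():
                        if tok.startswith("library_size="):
                            track._library_size = int(tok.split("=", 1)[1])
                df = pd.read_csv(
                    fh, sep="\t", names=["chrom", "start", "end", "value"],
                    dtype={"chrom": str},
                )
            for row in df.itertuples(index=False):
                if row.chrom not in chrom_lengths:
                    raise KeyError(f"bedGraph chrom {row.chrom!r} not in genome")
                track.data[(row.chrom, strand)][row.start : row.end] += int(row.value)
        if library_size is not None:
            track._library_size = library_size
        return track


# ---------------------------------------------------------------------------
# genome + annotation


def load_genome(fasta_path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}


def _parse_attributes(s: str) -> dict[str, str]:
    out = {}
    for item in s.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff(gff_path: str | Path) -> pd.DataFrame:
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    return pd.read_csv(
        gff_path, sep="\t", comment="#", names=cols,
        dtype={"seqid": str, "start": int, "end": int},
    )


def compute_downstream_gaps(records: list[TranscriptRecord]) -> list[TranscriptRecord]:
    """Fill ``downstream_gap`` from operon membership and coordinates."""
    by_operon: dict[str, list[TranscriptRecord]] = {}
    for r in records:
        if r.operon_id is not None:
            by_operon.setdefault(r.operon_id, []).append(r)
    gaps: dict[str, int] = {}
    for members in by_operon.values():
        members = sorted(members, key=lambda r: r.cds_start)
        if members[0].strand == "-":
            members = members[::-1]
        for cur, nxt in zip(members, members[1:]):
            if cur.strand == "+":
                gaps[cur.gene_id] = nxt.cds_start - cur.cds_end
            else:
                gaps[cur.gene_id] = cur.cds_start - nxt.cds_end
    return [
        replace(r, downstream_gap=gaps[r.gene_id]) if r.gene_id in gaps else r
        for r in records
    ]


def load_annotation(
    fasta_path: str | Path, gff_path: str | Path
) -> tuple[dict[str, str], list[TranscriptRecord]]:
    """Load genome + GFF3 and return one record per valid protein-coding gene.

    GFF3 layout expected: a ``gene`` feature spanning the transcript (UTRs
    included) and a ``CDS`` feature with ``Parent=`` pointing at it.  Genes
    whose CDS length is not a multiple of 3 are excluded with a warning;
    a CDS referencing a missing chromosome is a hard error.
    """
    genome = load_genome(fasta_path)
    gff = read_gff(gff_path)

    genes = {}
    for row in gff[gff.type == "gene"].itertuples(index=False):
        attrs = _parse_attributes(row.attributes)
        genes[attrs["ID"]] = (row, attrs)

    records: list[TranscriptRecord] = []
    for row in gff[gff.type == "CDS"].itertuples(index=False):
        attrs = _parse_attributes(row.attributes)
        gid = attrs.get("Parent", attrs.get("ID", f"{row.seqid}:{row.start}"))
        if row.seqid not in genome:
            raise KeyError(f"GFF chrom {row.seqid!r} absent from FASTA")
        cds_start, cds_end = row.start - 1, row.end  # 1-based closed -> half-open
        if (cds_end - cds_start) % 3 != 0:
            log.warning("excluding %s: CDS length %d not divisible by 3",
                        gid, cds_end - cds_start)
            continue
        utr5 = utr3 = 0
        operon = None
        if gid in genes:
            grow, gattrs = genes[gid]
            operon = gattrs.get("operon_id")
            if row.strand == "+":
                utr5 = cds_start - (grow.start - 1)
                utr3 = grow.end - cds_end
            else:
                utr5 = grow.end - cds_end
                utr3 = cds_start - (grow.start - 1)
        if row.strand == "+":
            stop = genome[row.seqid][cds_end - 3 : cds_end]
        else:
            stop = revcomp(genome[row.seqid][cds_start : cds_start + 3])
        records.append(
            TranscriptRecord(
                gene_id=gid, chrom=row.seqid, strand=row.strand,
                cds_start=cds_start, cds_end=cds_end,
                utr5_len=utr5, utr3_len=utr3,
                stop_codon=to_rna(stop), operon_id=operon,
            )
        )
    return genome, compute_downstream_gaps(records)


def write_gff(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            op = f";operon_id={r.operon_id}" if r.operon_id else ""
            fh.write(
                f"{r.chrom}\tparstools\tgene\t{r.tx_start + 1}\t{r.tx_end}\t.\t"
                f"{r.strand}\t.\tID={r.gene_id}{op}\n"
            )
            fh.write(
                f"{r.chrom}\tparstools\tCDS\t{r.cds_start + 1}\t{r.cds_end}\t.\t"
                f"{r.strand}\t0\tID={r.gene_id}.cds;Parent={r.gene_id}\n"
            )


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# read tables + gene counting


READ_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(path, sep="\t", header=False, index=False, columns=READ_COLUMNS)


def read_reads_bed(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=READ_COLUMNS, dtype={"chrom": str})


def middle_positions(reads: pd.DataFrame) -> np.ndarray:
    """Middle nucleotide of each read; for even lengths, the nt 5' of the
    mid-position (strand-aware)."""
    length = (reads["end"] - reads["start"]).to_numpy()
    plus = reads["strand"].to_numpy() == "+"
    mid = np.where(
        plus,
        reads["start"].to_numpy() + (length - 1) // 2,
        reads["end"].to_numpy() - 1 - (length - 1) // 2,
    )
    return mid


def assign_gene_counts(
    reads: pd.DataFrame,
    transcripts: Iterable[TranscriptRecord],
    library_size: int,
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Per-gene raw counts (reads whose middle nt falls in the CDS) and rpkM."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    transcripts = list(transcripts)
    gene_index: dict[tuple[str, str], np.ndarray] = {
        (c, s): np.full(n, -1, dtype=np.int64)
        for c, n in chrom_lengths.items()
        for s in "+-"
    }
    for i, r in enumerate(transcripts):
        gene_index[(r.chrom, r.strand)][r.cds_start : r.cds_end] = i

    raw = np.zeros(len(transcripts), dtype=np.int64)
    mids = middle_positions(reads)
    for (chrom, strand), sub in reads.assign(_mid=mids).groupby(
        ["chrom", "strand"], sort=False
    ):
        idx = gene_index[(chrom, strand)][sub["_mid"].to_numpy()]
        hits = idx[idx >= 0]
        np.add.at(raw, hits, 1)

    rows = []
    for r, n in zip(transcripts, raw):
        rpkm = n / ((r.cds_len / 1e3) * (library_size / 1e6))
        rows.append((r.gene_id, int(n), rpkm))
    return pd.DataFrame(rows, columns=["gene_id", "raw", "rpkM"])


def classify_operon_context(rec: TranscriptRecord) -> str:
    """Operon context: overlapping (< 30 nt to the downstream operon gene),
    non_overlapping (>= 30 nt), or non_operon (no downstream partner)."""
    if rec.downstream_gap is None:
        return "non_operon"
    return "overlapping" if rec.downstream_gap < 30 else "non_overlapping"


# ---------------------------------------------------------------------------
# masks and site/TM tables


def read_mask_bed(path: str | Path, chrom_lengths: Mapping[str, int]) -> dict:
    """Unmappable-position mask from BED; strand '.' masks both strands."""
    mask = {
        (c, s): np.zeros(n, dtype=bool)
        for c, n in chrom_lengths.items()
        for s in "+-"
    }
    bed = pd.read_csv(
        path, sep="\t", names=READ_COLUMNS[: 6], dtype={"chrom": str}
    )
    for row in bed.itertuples(index=False):
        strands = "+-" if row.strand not in ("+", "-") else row.strand
        for s in strands:
            mask[(row.chrom, s)][row.start : row.end] = True
    return mask


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    """Cleavage-site table: chrom, position, strand[, label]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "position", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")
    return df


def read_tm_domains_tsv(path: str | Path) -> pd.DataFrame:
    """Transmembrane-helix table: gene_id, aa_start, aa_end (1-based codons)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "aa_start", "aa_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"TM table must have columns {sorted(required)}")
    return df
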