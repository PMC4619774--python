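"""Small shared helpers: sequence ops, strand handling, GC content."""

from __future__ import annotations

import urllib.request

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA-alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def gc_percent(seq: str) -> float:
    """GC content of a sequence in percent, ignoring non-ACGTU characters."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGTU")
    if acgt == 0:
        return float("nan")
    return 100.0 * (s.count("G") + s.count("C")) / acgt


def fetch_ncbi_fasta(accession: str, timeout: float = 60.0) -> str:
    """Download a nucleotide record from NCBI efetch and return the sequence.

    Requires network access; raises URLError/timeout otherwise.
    """
    url = (
        "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
        f"?db=nuccore&id={accession}&rettype=fasta&retmode=text"
    )
    with urllib.request.urlopen(url, timeout=timeout) as fh:
        text = fh.read().decode()
    lines = [ln.strip() for ln in text.splitlines() if ln and not ln.startswith(">")]
    return "".join(lines)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators from one seed (order-stable)."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]
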