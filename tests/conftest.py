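"""Shared fixtures: one session-scoped synthetic study plus small builders."""

from __future__ import annotations

import numpy as np
import pytest

import parstools as pt
from parstools.io import CountTrack, TranscriptRecord
from parstools.pars import ParsTrack
from parstools.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default study conditions: 120 genes, 20x probing coverage,
    epsilon = 0.1 of the signal rate, kappa = 4 pauses."""
    return simulate_dataset(SimConfig(seed=11, n_genes=120))


@pytest.fixture(scope="session")
def pars_track(dataset):
    return pt.pars_score(dataset.v1, dataset.at1, dataset.truth.genome)


@pytest.fixture(scope="session")
def passing(dataset):
    return pt.load_filter(dataset.v1, dataset.at1, dataset.truth.transcripts)


def make_track(counts_by_key, chrom_lengths, library_size=None, end="five_prime",
               sample_id="t"):
    """CountTrack from {(chrom, strand): array-like} (testing helper)."""
    t = CountTrack(sample_id, chrom_lengths, end=end)
    for k, v in counts_by_key.items():
        t.data[k] = np.asarray(v, dtype=np.int64)
    if library_size is not None:
        t.library_size = library_size
    return t


def make_pars(score_by_key, chrom_lengths, missing_by_key=None):
    """ParsTrack with given scores, nothing missing unless specified."""
    p = ParsTrack(chrom_lengths)
    for k, v in score_by_key.items():
        p.score[k] = np.asarray(v, dtype=float)
    if missing_by_key:
        for k, v in missing_by_key.items():
            p.missing[k] = np.asarray(v, dtype=bool)
    return p


def simple_transcript(cds_len=90, utr5=30, utr3=30, strand="+", chrom="chr1",
                      gene_id="g", offset=0, **kw):
    """A transcript whose UTR5 starts at ``offset`` on the chromosome."""
    cds_start = offset + (utr5 if strand == "+" else utr3)
    return TranscriptRecord(
        gene_id=gene_id, chrom=chrom, strand=strand,
        cds_start=cds_start, cds_end=cds_start + cds_len,
        utr5_len=utr5, utr3_len=utr3, stop_codon="UAA", **kw,
    )
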