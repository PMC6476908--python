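"""Shared fixtures: hand-built annotations and read sets small enough to
check against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spermkit.io import GenomeAnnotation, ReadIntervalSet


def make_reads(sample_id: str, intervals: list[tuple[str, int, int]],
               total: int | None = None) -> ReadIntervalSet:
    rec = pd.DataFrame(
        [(c, s, e, ".") for c, s, e in intervals],
        columns=["chrom", "start", "end", "strand"],
    )
    return ReadIntervalSet(sample_id=sample_id, records=rec,
                           total_mapped_count=len(rec) if total is None else total)


def make_annotation(genes: list[dict]) -> GenomeAnnotation:
    """Build an annotation from dicts with keys gene_id, chrom, start, end,
    strand, biotype, exons=[(start, end), ...] (one transcript per gene,
    transcript id = gene id with G -> T)."""
    grows, trows, erows = [], [], []
    for g in genes:
        grows.append((g["gene_id"], g["chrom"], g["start"], g["end"],
                      g.get("strand", "+"), g.get("biotype", "protein_coding")))
        tid = g.get("transcript_id", g["gene_id"].replace("G", "T", 1))
        trows.append((tid, g["gene_id"]))
        for s, e in g["exons"]:
            erows.append((tid, g["chrom"], s, e, g.get("strand", "+")))
    return GenomeAnnotation(
        genes=pd.DataFrame(grows, columns=["gene_id", "chrom", "start", "end",
                                           "strand", "biotype"]),
        transcripts=pd.DataFrame(trows, columns=["transcript_id", "gene_id"]),
        exons=pd.DataFrame(erows, columns=["transcript_id", "chrom", "start",
                                           "end", "strand"]),
    )


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two coding genes and one lncRNA on two chromosomes.

    chr1: G00001 at [1000, 3000) with exons [1000,1400) and [2600,3000);
          L00001 (lncRNA) at [20000, 21000), exon = full span.
    chr2: G00002 at [5000, 6000), exon = full span.
    """
    return make_annotation([
        {"gene_id": "G00001", "chrom": "chr1", "start": 1000, "end": 3000,
         "exons": [(1000, 1400), (2600, 3000)]},
        {"gene_id": "L00001", "chrom": "chr1", "start": 20000, "end": 21000,
         "biotype": "lncRNA", "transcript_id": "TL0001",
         "exons": [(20000, 21000)]},
        {"gene_id": "G00002", "chrom": "chr2", "start": 5000, "end": 6000,
         "exons": [(5000, 6000)]},
    ])


def coverage_oracle(intervals: list[tuple[int, int]], length: int) -> np.ndarray:
    """Per-base coverage by brute force over a [0, length) axis."""
    cov = np.zeros(length, dtype=int)
    for s, e in intervals:
        cov[max(s, 0):min(e, length)] += 1
    return cov


def segment_oracle(cov: np.ndarray, min_support: int, max_gap: int
                   ) -> list[tuple[int, int]]:
    """Brute-force SRE segmentation of a per-base coverage vector: covered
    runs merged across gaps <= max_gap, kept iff peak coverage >= min_support."""
    covered = cov > 0
    runs = []
    i = 0
    while i < len(cov):
        if covered[i]:
            j = i
            while j < len(cov) and covered[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return [(s, e) for s, e in merged if cov[s:e].max() >= min_support]
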