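"""Repeat-element composition of the mapped reads and lncRNA profiling.

The repeat summary reports, per repeat class, how many reads overlap the
class (>= 1 bp, read-level accounting: a read spanning two intervals of the
same class counts once for it), the proportion of the sample's mapped
reads that represents, a length-and-depth normalized abundance, and the
genomic span the class covers.  A read overlapping several classes counts
once per class but only once in the any-repeat total.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GenomeAnnotation, ReadIntervalSet, RepeatTrack
from .sre import AbundanceMatrix

__all__ = ["re_read_fraction", "lncrna_profile", "cis_targets", "gene_distance"]


def re_read_fraction(reads: ReadIntervalSet, track: RepeatTrack) -> pd.DataFrame:
    """Per-class repeat summary plus an ``any_RE`` row.

    Columns: ``read_count`` (reads overlapping the class by >= 1 bp),
    ``proportion`` (of ``total_mapped_count``), ``normalized_abundance``
    (``count * 1e9 / (class_span_bp * total_mapped_count)``) and
    ``span_bp`` (union length of the class's intervals).
    """
    classes = sorted(track.records["re_class"].unique()) if len(track) else []
    span = track.class_span() if len(track) else pd.Series(dtype=int)
    trees: dict[str, dict[str, IntervalTree]] = {}
    for r in track.records.itertuples(index=False):
        trees.setdefault(r.chrom, {}).setdefault(r.re_class, IntervalTree()).addi(
            r.start, r.end)
    counts = {cls: 0 for cls in classes}
    any_count = 0
    for rd in reads.records.itertuples(index=False):
        by_class = trees.get(rd.chrom)
        if not by_class:
            continue
        hit_any = False
        for cls, tree in by_class.items():
            if tree.overlaps(rd.start, rd.end):
                counts[cls] += 1
                hit_any = True
        if hit_any:
            any_count += 1
    total = reads.total_mapped_count
    rows = []
    for cls in classes:
        sp = int(span.get(cls, 0))
        norm = counts[cls] * 1e9 / (sp * total) if sp and total else 0.0
        rows.append((cls, counts[cls],
                     counts[cls] / total if total else 0.0, norm, sp))
    any_span = int(span.sum()) if len(span) else 0
    rows.append(("any_RE", any_count,
                 any_count / total if total else 0.0,
                 any_count * 1e9 / (any_span * total) if any_span and total else 0.0,
                 any_span))
    return pd.DataFrame(rows, columns=["re_class", "read_count", "proportion",
                                       "normalized_abundance", "span_bp"]
                        ).set_index("re_class")


def lncrna_profile(matrix: AbundanceMatrix,
                   annotation: GenomeAnnotation) -> pd.DataFrame:
    """Annotated lncRNA genes detected in the abundance matrix.

    A lncRNA is detected if its abundance is > 0 in at least one sample.
    Returns the detected subset of the matrix (lncRNA features only); warns
    and returns empty when the annotation carries no lncRNA biotype.
    """
    lnc = annotation.genes_with_biotype("lncRNA")
    if not lnc:
        warnings.warn("annotation has no lncRNA biotype; nothing to profile")
        return pd.DataFrame(columns=matrix.values.columns)
    present = [g for g in lnc if g in matrix.values.index]
    sub = matrix.values.loc[present]
    detected = sub[(sub > 0).any(axis=1)]
    return detected


def gene_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap between two gene spans (0 when they overlap), unstranded."""
    return max(a[0] - b[1], b[0] - a[1], 0)


def cis_targets(lncrna_ids: set[str], annotation: GenomeAnnotation,
                window: int = 20_000) -> pd.DataFrame:
    """Candidate cis-regulated coding targets of lncRNAs.

    Emits (lncrna_id, coding_id, distance) for every protein-coding gene
    whose span lies strictly closer than ``window`` bp (gap; 0 when
    overlapping) to a lncRNA gene span on the same chromosome.
    """
    genes = annotation.genes.set_index("gene_id")
    coding = annotation.genes[annotation.genes["biotype"] == "protein_coding"]
    rows = []
    for lid in sorted(lncrna_ids):
        if lid not in genes.index:
            continue
        lrow = genes.loc[lid]
        same = coding[coding["chrom"] == lrow["chrom"]]
        for c in same.itertuples(index=False):
            d = gene_distance((int(lrow["start"]), int(lrow["end"])),
                              (c.start, c.end))
            if d < window:
                rows.append((lid, c.gene_id, d))
    return pd.DataFrame(rows, columns=["lncrna_id", "coding_id", "distance"])
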