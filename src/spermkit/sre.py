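"""Sperm RNA element (SRE) detection, quantification and classification.

An SRE is a short genomic interval defined by RNA-seq reads clustering at a
locus, quantified on its own rather than through a whole-transcript model —
the natural unit for sperm, whose transcripts are heavily fragmented.

The caller pools reads from all samples, segments pooled per-base coverage
into maximal covered intervals (allowing an inter-read gap of at most
``max_gap`` bp), and keeps intervals whose peak pooled coverage reaches
``min_support``.  Each SRE is then quantified per sample in RPKM, ranked
into abundance deciles, and classified against the annotation with the
precedence EXON > NOVEL_INTRONIC > UPDOWN10K > ORPHAN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GenomeAnnotation, ReadIntervalSet

__all__ = [
    "AbundanceMatrix",
    "call_sres",
    "quantify_sres",
    "partition_deciles",
    "classify_sres",
    "orphan_proximity",
    "abundant_gene_set",
    "plot_cumulative_abundance",
    "SRE_CLASSES",
]

SRE_CLASSES = ("EXON", "NOVEL_INTRONIC", "UPDOWN10K", "ORPHAN")


@dataclass
class AbundanceMatrix:
    """Features x samples normalized abundance with sample metadata.

    ``unit`` records the normalization (RPKM, FPKM or CPM).  ``samples`` is
    an optional sample sheet with at least ``sample_id`` plus any design
    columns (season, batch).
    """

    values: pd.DataFrame
    unit: str
    samples: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("RPKM", "FPKM", "CPM"):
            raise ValueError(f"unknown abundance unit {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be >= 0")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids in abundance matrix")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def mean_sd(self) -> pd.DataFrame:
        """Per-feature mean and sample (n-1) SD across samples."""
        return pd.DataFrame({
            "mean_abundance": self.values.mean(axis=1),
            "abundance_sd": self.values.std(axis=1, ddof=1),
        })


# ---------------------------------------------------------------------------
# calling


def _coverage_segments(starts: np.ndarray, ends: np.ndarray
                       ) -> list[tuple[int, int, int]]:
    """Maximal constant-coverage pieces with coverage > 0, as (start, end, cov)."""
    pos = np.concatenate([starts, ends])
    delta = np.concatenate([np.ones(len(starts), dtype=int),
                            -np.ones(len(ends), dtype=int)])
    upos, inv = np.unique(pos, return_inverse=True)
    d = np.zeros(len(upos), dtype=int)
    np.add.at(d, inv, delta)
    cov = np.cumsum(d)
    segs = []
    for i in range(len(upos) - 1):
        if cov[i] > 0:
            segs.append((int(upos[i]), int(upos[i + 1]), int(cov[i])))
    return segs


def call_sres(reads: list[ReadIntervalSet], min_support: int = 3,
              max_gap: int = 0) -> pd.DataFrame:
    """Call SRE intervals from reads pooled across samples.

    Covered segments separated by an uncovered gap of at most ``max_gap`` bp
    are merged; a merged interval is emitted iff its peak pooled per-base
    coverage is >= ``min_support``.  Returns a DataFrame with columns
    ``sre_id, chrom, start, end`` sorted by (chrom, start); intervals are
    disjoint.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if reads:
        pooled = pd.concat([r.records for r in reads], ignore_index=True)
    else:
        pooled = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    rows = []
    for chrom in sorted(pooled["chrom"].unique()):
        sub = pooled[pooled["chrom"] == chrom]
        segs = _coverage_segments(sub["start"].to_numpy(), sub["end"].to_numpy())
        # merge covered pieces across gaps <= max_gap, tracking peak coverage
        cur: list[int] | None = None  # [start, end, peak]
        for s, e, c in segs + [(None, None, None)]:
            if s is None:
                flush = cur is not None
            else:
                if cur is not None and s - cur[1] <= max_gap:
                    cur[1] = e
                    cur[2] = max(cur[2], c)
                    continue
                flush = cur is not None
            if flush and cur[2] >= min_support:
                rows.append((chrom, cur[0], cur[1]))
            cur = None if s is None else [s, e, c]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df.insert(0, "sre_id", [f"SRE{i + 1:06d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# quantification


def _overlap_counts(sres: pd.DataFrame, reads: ReadIntervalSet) -> np.ndarray:
    """Reads overlapping each SRE by >= 1 bp (a read counts once per SRE)."""
    counts = np.zeros(len(sres), dtype=int)
    for chrom, sub in sres.groupby("chrom", sort=False):
        rsub = reads.records[reads.records["chrom"] == chrom]
        if not len(rsub):
            continue
        s_starts = sub["start"].to_numpy()
        s_ends = sub["end"].to_numpy()
        order = np.argsort(s_starts)
        s_starts, s_ends = s_starts[order], s_ends[order]
        idx = sub.index.to_numpy()[order]
        # SREs are disjoint & sorted: a read [a, b) overlaps the run of SREs
        # with end > a and start < b
        a = rsub["start"].to_numpy()
        b = rsub["end"].to_numpy()
        i0 = np.searchsorted(s_ends, a, side="right")
        i1 = np.searchsorted(s_starts, b, side="left")
        diff = np.zeros(len(sub) + 1, dtype=int)
        valid = i1 > i0
        np.add.at(diff, i0[valid], 1)
        np.add.at(diff, i1[valid], -1)
        local = np.cumsum(diff[:-1])
        pos = {ix: k for k, ix in enumerate(sres.index)}
        for j, ix in enumerate(idx):
            counts[pos[ix]] += local[j]
    return counts


def quantify_sres(sres: pd.DataFrame, reads: list[ReadIntervalSet]
                  ) -> AbundanceMatrix:
    """Per-sample RPKM for each SRE.

    ``RPKM = overlapping_reads * 1e9 / (sre_length_bp * total_mapped_count)``
    with the sample's declared total mapped count as denominator.
    """
    lengths = (sres["end"] - sres["start"]).to_numpy()
    values = {}
    for r in reads:
        if r.total_mapped_count == 0:
            raise ZeroDivisionError(
                f"sample {r.sample_id}: total_mapped_count is 0, RPKM undefined")
        counts = _overlap_counts(sres, r)
        values[r.sample_id] = counts * 1e9 / (lengths * r.total_mapped_count)
    mat = pd.DataFrame(values, index=list(sres["sre_id"]))
    return AbundanceMatrix(values=mat, unit="RPKM")


# ---------------------------------------------------------------------------
# deciles


def partition_deciles(matrix: AbundanceMatrix, sres: pd.DataFrame | None = None
                      ) -> tuple[pd.Series, pd.Series]:
    """Decile label (1 = most abundant) per SRE plus per-decile mass share.

    SREs are ranked by mean abundance, descending; ties break by (chrom,
    start) when coordinates are supplied, else by feature id, so the
    labelling is deterministic.  Decile of the ``r``-th ranked of ``n`` is
    ``ceil(10 r / n)``.  The second return value is each decile's share (%)
    of the total mean-abundance mass.
    """
    n = len(matrix.values)
    if n < 10:
        raise ValueError(f"need >= 10 features to form deciles, got {n}")
    means = matrix.values.mean(axis=1)
    key = pd.DataFrame({"mean": means})
    if sres is not None:
        coords = sres.set_index("sre_id").loc[key.index]
        key["chrom"], key["start"] = coords["chrom"], coords["start"]
        ordered = key.sort_values(["mean", "chrom", "start"],
                                  ascending=[False, True, True], kind="mergesort")
    else:
        ordered = key.sort_index(kind="mergesort").sort_values(
            "mean", ascending=False, kind="mergesort")
    ranks = np.arange(1, n + 1)
    dec = np.ceil(10 * ranks / n).astype(int)
    deciles = pd.Series(dec, index=ordered.index, name="decile").reindex(means.index)
    total = means.sum()
    share = pd.Series(0.0, index=range(1, 11), name="mass_share_pct")
    if total > 0:
        grouped = means.groupby(deciles).sum() / total * 100
        share.update(grouped)
    return deciles, share


# ---------------------------------------------------------------------------
# classification


def _gene_trees(annotation: GenomeAnnotation):
    exon_tree: dict[str, IntervalTree] = {}
    gene_tree: dict[str, IntervalTree] = {}
    tx_gene = dict(zip(annotation.transcripts["transcript_id"],
                       annotation.transcripts["gene_id"]))
    for e in annotation.exons.itertuples(index=False):
        exon_tree.setdefault(e.chrom, IntervalTree()).addi(
            e.start, e.end, tx_gene[e.transcript_id])
    for g in annotation.genes.itertuples(index=False):
        gene_tree.setdefault(g.chrom, IntervalTree()).addi(
            g.start, g.end, g.gene_id)
    return exon_tree, gene_tree


def _nearest_gene_distance(chrom: str, start: int, end: int,
                           genes: pd.DataFrame) -> float:
    sub = genes[genes["chrom"] == chrom]
    if not len(sub):
        return math.inf
    gap_left = start - sub["end"].to_numpy()   # gene upstream of SRE
    gap_right = sub["start"].to_numpy() - end  # gene downstream of SRE
    d = np.maximum(np.maximum(gap_left, gap_right), 0)
    return float(d.min())


def classify_sres(sres: pd.DataFrame, annotation: GenomeAnnotation,
                  window: int = 10_000) -> pd.DataFrame:
    """Assign each SRE a class and its linked genes.

    Precedence: EXON (>=1 bp exon overlap) > NOVEL_INTRONIC (gene-body
    overlap, no exon) > UPDOWN10K (within ``window`` bp of a gene span) >
    ORPHAN.  Every gene satisfying the winning rule is linked, so one SRE
    may link several genes.  Orphans get their distance to the nearest gene
    span (unstranded); other classes get distance 0 (or the gap for
    UPDOWN10K).
    """
    exon_tree, gene_tree = _gene_trees(annotation)
    out = sres.copy()
    classes, links, dists = [], [], []
    for s in sres.itertuples(index=False):
        etree = exon_tree.get(s.chrom)
        gtree = gene_tree.get(s.chrom)
        exon_hits = sorted({iv.data for iv in etree.overlap(s.start, s.end)}) if etree else []
        if exon_hits:
            classes.append("EXON")
            links.append(exon_hits)
            dists.append(0.0)
            continue
        body_hits = sorted({iv.data for iv in gtree.overlap(s.start, s.end)}) if gtree else []
        if body_hits:
            classes.append("NOVEL_INTRONIC")
            links.append(body_hits)
            dists.append(0.0)
            continue
        near = gtree.overlap(s.start - window - 1, s.end + window + 1) if gtree else []
        near_hits = sorted({
            iv.data for iv in near
            if max(iv.begin - s.end, s.start - iv.end, 0) <= window
        })
        dist = _nearest_gene_distance(s.chrom, s.start, s.end, annotation.genes)
        if near_hits and dist <= window:
            classes.append("UPDOWN10K")
            links.append(near_hits)
        else:
            classes.append("ORPHAN")
            links.append([])
        dists.append(dist)
    out["sre_class"] = classes
    out["linked_gene_ids"] = links
    out["distance_to_nearest_gene"] = dists
    return out


def orphan_proximity(classified: pd.DataFrame, annotation: GenomeAnnotation,
                     threshold: int = 30_000) -> tuple[pd.Series, float | None]:
    """Nearest-gene distance of each ORPHAN SRE and the fraction <= threshold.

    Returns ``(distances, fraction)``; the fraction is ``None`` when there
    are no orphans.
    """
    orphans = classified[classified["sre_class"] == "ORPHAN"]
    if not len(orphans):
        return pd.Series(dtype=float), None
    dists = pd.Series(
        [_nearest_gene_distance(s.chrom, s.start, s.end, annotation.genes)
         for s in orphans.itertuples(index=False)],
        index=list(orphans["sre_id"]), name="distance_to_nearest_gene",
    )
    frac = float((dists <= threshold).sum() / len(dists))
    return dists, frac


def abundant_gene_set(classified: pd.DataFrame, deciles: pd.Series) -> set[str]:
    """Genes linked by top-decile SREs of any class except ORPHAN.

    This is the "abundant transcriptome" gene set: the union of genes in or
    near which the most abundant tenth of SREs map.
    """
    idx = classified.set_index("sre_id")
    top = deciles[deciles == 1].index
    genes: set[str] = set()
    for sid in top:
        row = idx.loc[sid]
        if row["sre_class"] != "ORPHAN":
            genes.update(row["linked_gene_ids"])
    return genes


def plot_cumulative_abundance(matrix: AbundanceMatrix, ax=None):
    """Fig-1-style view: SREs sorted by decreasing mean abundance (log10)
    with the cumulative mass share overlaid."""
    import matplotlib.pyplot as plt

    means = matrix.values.mean(axis=1).sort_values(ascending=False)
    if ax is None:
        _, ax = plt.subplots()
    with np.errstate(divide="ignore"):
        ax.plot(np.arange(1, len(means) + 1), np.log10(means.to_numpy()),
                ".", ms=2, color="black", label="log10 abundance")
    ax2 = ax.twinx()
    cum = means.cumsum() / means.sum() * 100
    ax2.plot(np.arange(1, len(means) + 1), cum.to_numpy(), color="red",
             label="cumulative share (%)")
    ax.set_xlabel("SRE rank (most abundant first)")
    ax.set_ylabel(f"log10 mean {matrix.unit}")
    ax2.set_ylabel("cumulative mass share (%)")
    return ax
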