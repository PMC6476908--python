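"""Short non-coding RNA processing: CPM normalization, detection filters,
de novo piRNA-cluster calling, cross-sample reproducibility and repeat
overlap.

piRNAs are 26-33 nt PIWI-interacting RNAs; a cluster is a genomic region
producing them densely.  The caller filters reads to the piRNA length
range, merges reads separated by at most ``max_gap`` bp, and keeps merged
intervals at least ``min_cluster_length`` bp long with at least
``min_reads`` supporting reads.  Calling is per sample; a consensus step
keeps clusters seen in a minimum number of samples.
"""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

from .io import ReadIntervalSet, RepeatTrack

__all__ = [
    "normalize_cpm",
    "filter_ubiquitous",
    "call_pirna_clusters",
    "reproducible_clusters",
    "cluster_re_overlap",
]


def normalize_cpm(counts: pd.DataFrame, depth: pd.Series) -> pd.DataFrame:
    """Counts-per-million: ``count * 1e6 / depth`` per sample column."""
    missing = [s for s in counts.columns if s not in depth.index]
    if missing:
        raise ValueError(f"no depth for samples: {missing}")
    if (depth[counts.columns] <= 0).any():
        raise ValueError("sample depth must be > 0")
    return counts * 1e6 / depth[counts.columns]


def filter_ubiquitous(counts: pd.DataFrame) -> pd.DataFrame:
    """Keep features with a raw count > 0 in every sample (the
    detected-in-all-samples rule used for miRNAs)."""
    return counts[(counts > 0).all(axis=1)].copy()


def call_pirna_clusters(reads: ReadIntervalSet,
                        len_min: int = 26, len_max: int = 33,
                        min_cluster_length: int = 5_000,
                        max_gap: int = 1_000,
                        min_reads: int = 10) -> pd.DataFrame:
    """De novo piRNA clusters of one sample.

    Reads with interval length in ``[len_min, len_max]`` nt are merged when
    separated by at most ``max_gap`` bp; a merged interval is a cluster iff
    its span is >= ``min_cluster_length`` bp and it contains >=
    ``min_reads`` reads.  Returns chrom, start, end, read_count sorted by
    position.
    """
    rl = reads.read_lengths
    sub = reads.records[(rl >= len_min) & (rl <= len_max)]
    rows = []
    for chrom in sorted(sub["chrom"].unique()):
        csub = sub[sub["chrom"] == chrom].sort_values(["start", "end"])
        cur_start = cur_end = None
        cur_n = 0
        for r in csub.itertuples(index=False):
            if cur_end is not None and r.start - cur_end <= max_gap:
                cur_end = max(cur_end, r.end)
                cur_n += 1
            else:
                if cur_end is not None and cur_end - cur_start >= min_cluster_length \
                        and cur_n >= min_reads:
                    rows.append((chrom, cur_start, cur_end, cur_n))
                cur_start, cur_end, cur_n = r.start, r.end, 1
        if cur_end is not None and cur_end - cur_start >= min_cluster_length \
                and cur_n >= min_reads:
            rows.append((chrom, cur_start, cur_end, cur_n))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "read_count"])


def reproducible_clusters(per_sample: dict[str, pd.DataFrame],
                          min_samples: int = 3) -> pd.DataFrame:
    """Consensus clusters supported by >= ``min_samples`` distinct samples.

    Per-sample clusters that overlap by >= 1 bp are grouped transitively;
    each group whose members come from enough distinct samples yields one
    consensus cluster spanning the union of its members.  The result is
    invariant to sample ordering.
    """
    rows = []
    for sid in sorted(per_sample):
        for c in per_sample[sid].itertuples(index=False):
            rows.append((c.chrom, int(c.start), int(c.end), sid))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end",
                                     "n_samples_supporting", "samples"])
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample"])
    out = []
    for chrom in sorted(df["chrom"].unique()):
        sub = df[df["chrom"] == chrom].sort_values(["start", "end"])
        g_start = g_end = None
        g_samples: set[str] = set()
        for r in sub.itertuples(index=False):
            if g_end is not None and r.start < g_end:  # >= 1 bp overlap
                g_end = max(g_end, r.end)
                g_samples.add(r.sample)
            else:
                if g_end is not None and len(g_samples) >= min_samples:
                    out.append((chrom, g_start, g_end, len(g_samples),
                                ",".join(sorted(g_samples))))
                g_start, g_end, g_samples = r.start, r.end, {r.sample}
        if g_end is not None and len(g_samples) >= min_samples:
            out.append((chrom, g_start, g_end, len(g_samples),
                        ",".join(sorted(g_samples))))
    return pd.DataFrame(out, columns=["chrom", "start", "end",
                                      "n_samples_supporting", "samples"])


def cluster_re_overlap(clusters: pd.DataFrame, track: RepeatTrack
                       ) -> tuple[pd.DataFrame, pd.Series]:
    """Flag clusters intersecting any repeat (>= 1 bp) and tally the repeat
    classes hit.

    Returns the clusters with added ``re_overlap`` (bool) and
    ``re_classes`` (comma-joined) columns, plus a Series counting, over the
    overlapping clusters, how many hit each repeat class.
    """
    trees: dict[str, IntervalTree] = {}
    for r in track.records.itertuples(index=False):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r.re_class)
    flags, classes = [], []
    tally: dict[str, int] = {}
    for c in clusters.itertuples(index=False):
        tree = trees.get(c.chrom)
        hits = sorted({iv.data for iv in tree.overlap(c.start, c.end)}) if tree else []
        flags.append(bool(hits))
        classes.append(",".join(hits))
        for cls in hits:
            tally[cls] = tally.get(cls, 0) + 1
    out = clusters.copy()
    out["re_overlap"] = flags
    out["re_classes"] = classes
    return out, pd.Series(tally, dtype=int).sort_index()
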