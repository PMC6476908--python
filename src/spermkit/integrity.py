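"""Transcript integrity (TIN) profiling.

TIN scores how uniformly and completely a transcript's exonic span is
covered by reads, on a 0-100 scale.  With per-base depths ``c_i`` over the
``L`` exonic bases and ``p_i = c_i / sum(c)`` restricted to covered bases,
the score is the entropy-effective support relative to the length::

    H = -sum p_i ln p_i          TIN = 100 * exp(H) / L

so uniform coverage of the whole span gives exactly 100, uniform coverage
of a fraction ``f`` of the span gives exactly ``100 * f``, and an
uncovered transcript gives 0.  Every exonic base enters the computation
(no position subsampling), which makes the score deterministic and scale
invariant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GenomeAnnotation, ReadIntervalSet, merge_intervals

__all__ = [
    "compute_tin",
    "transcript_coverage",
    "tin_table",
    "classify_fragmentation",
    "tin_correlations",
]

FRAGMENTED_MAX = 25.0   # TIN <= 25 -> fragmented
INTACT_MIN = 75.0       # TIN >  75 -> intact


def compute_tin(coverage: np.ndarray) -> float:
    """TIN of one per-base coverage vector (entries >= 0, length >= 1)."""
    c = np.asarray(coverage, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise ValueError("coverage must be a non-empty 1-D vector")
    if (c < 0).any():
        raise ValueError("coverage depths must be >= 0")
    total = c.sum()
    if total == 0:
        return 0.0
    pos = c[c > 0]
    if (pos == pos[0]).all():
        # exactly uniform over the support: entropy is ln(n) analytically,
        # so the score is the covered fraction with no round-off
        return float(100.0 * len(pos) / len(c))
    p = pos / total
    h = float(-(p * np.log(p)).sum())
    return float(100.0 * np.exp(h) / len(c))


def transcript_coverage(transcript_id: str, annotation: GenomeAnnotation,
                        reads: ReadIntervalSet) -> np.ndarray:
    """Per-base read depth over the union of a transcript's exons.

    The vector is laid out in exonic coordinates (intron bases excluded);
    a read contributes to each exonic base it overlaps.
    """
    ex = annotation.transcript_exons(transcript_id)
    if not len(ex):
        raise KeyError(f"transcript {transcript_id!r} has no exons")
    chrom = ex["chrom"].iloc[0]
    merged = merge_intervals(list(zip(ex["start"], ex["end"])))
    lengths = merged[:, 1] - merged[:, 0]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    cov = np.zeros(int(offsets[-1]), dtype=float)
    sub = reads.records[reads.records["chrom"] == chrom]
    if not len(sub):
        return cov
    a = sub["start"].to_numpy()
    b = sub["end"].to_numpy()
    for k in range(len(merged)):
        lo = np.maximum(a, merged[k, 0])
        hi = np.minimum(b, merged[k, 1])
        hit = lo < hi
        if not hit.any():
            continue
        starts = (lo[hit] - merged[k, 0] + offsets[k]).astype(int)
        ends = (hi[hit] - merged[k, 0] + offsets[k]).astype(int)
        # difference-array increments; one cumsum at the end realizes depth
        np.add.at(cov, starts, 1.0)
        inside = ends[ends < len(cov)]
        np.add.at(cov, inside, -1.0)
    return np.cumsum(cov)


def tin_table(annotation: GenomeAnnotation,
              reads_by_sample: dict[str, ReadIntervalSet]) -> pd.DataFrame:
    """TIN for every transcript in every sample (transcripts x samples).

    Transcripts with no coverage in a sample are kept at TIN = 0; any
    abundance filter is applied downstream.
    """
    tids = list(annotation.transcripts["transcript_id"])
    out = pd.DataFrame(index=tids, columns=list(reads_by_sample), dtype=float)
    for sid, reads in reads_by_sample.items():
        for tid in tids:
            out.loc[tid, sid] = compute_tin(
                transcript_coverage(tid, annotation, reads))
    return out


def classify_fragmentation(tin: float) -> str:
    """Fragmentation class: fragmented (TIN <= 25), intact (TIN > 75),
    else intermediate."""
    if not (0 <= tin <= 100):
        raise ValueError(f"TIN must be in [0, 100], got {tin}")
    if tin <= FRAGMENTED_MAX:
        return "fragmented"
    if tin > INTACT_MIN:
        return "intact"
    return "intermediate"


def tin_correlations(tins: pd.DataFrame,
                     length: pd.Series | None = None,
                     abundance: pd.DataFrame | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise sample Pearson correlations of TIN, plus per-sample
    correlations of TIN with transcript covariates.

    ``length`` is one value per transcript (CDS length where annotated,
    exonic length otherwise); ``abundance`` is transcripts x samples FPKM.
    Pairs involving a zero-variance vector are NaN.
    """
    if len(tins) < 3:
        raise ValueError("need >= 3 transcripts for correlations")
    sample_corr = tins.corr(method="pearson")
    cov_rows = {}
    if length is not None:
        cov_rows["length"] = {
            s: tins[s].corr(length.reindex(tins.index)) for s in tins.columns}
    if abundance is not None:
        cov_rows["abundance"] = {
            s: tins[s].corr(abundance.reindex(tins.index)[s])
            for s in tins.columns}
    covariates = pd.DataFrame(cov_rows).T if cov_rows else pd.DataFrame()
    return sample_corr, covariates
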