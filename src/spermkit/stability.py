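"""Cross-sample abundance statistics.

Covers the variability analysis of the sperm transcriptome: coefficient-of-
variation stability classes, gene-level stability assignment, the
testes/sperm/seminal-fluid enrichment partition, the across-fraction
variability comparison (one-way ANOVA + Tukey HSD), generic hypergeometric
over-representation with Bonferroni correction, and the de novo contig
retention filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import GeneSetCollection
from .sre import AbundanceMatrix

__all__ = [
    "compute_cv",
    "gene_stability",
    "partition_enrichment",
    "compare_fraction_variability",
    "overrepresentation_test",
    "filter_denovo_contigs",
    "STABILITY_BOUNDS",
]

#: CV class boundaries: stable below, unstable above, moderate in between
#: (both boundary values inclusive to moderate).
STABILITY_BOUNDS = (0.25, 0.75)


def _classify_cv(cv: float) -> str:
    lo, hi = STABILITY_BOUNDS
    if cv < lo:
        return "stable"
    if cv > hi:
        return "unstable"
    return "moderate"


def compute_cv(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Per-feature CV (sample SD / mean) and stability class.

    Features with mean 0 have no defined CV; they are returned with
    ``cv = NaN`` and class ``undefined`` and should be excluded from
    class tallies.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("need >= 2 samples to compute a CV")
    mean = matrix.values.mean(axis=1)
    sd = matrix.values.std(axis=1, ddof=1)
    cv = sd / mean.where(mean > 0)
    cls = cv.map(lambda v: "undefined" if pd.isna(v) else _classify_cv(float(v)))
    return pd.DataFrame({"cv": cv, "stability_class": cls})


def gene_stability(sre_stability: pd.DataFrame,
                   linked_genes: pd.Series) -> pd.Series:
    """Gene-level stability: a gene gets a class iff every one of its SREs
    falls in that class, otherwise ``unassigned``.

    ``sre_stability`` is the output of :func:`compute_cv` indexed by SRE id;
    ``linked_genes`` maps SRE id -> list of linked gene ids.  Genes with no
    SREs are absent from the output; SREs with undefined CV do not vote.
    """
    votes: dict[str, set[str]] = {}
    for sid, genes in linked_genes.items():
        if sid not in sre_stability.index:
            continue
        cls = sre_stability.loc[sid, "stability_class"]
        if cls == "undefined":
            continue
        for g in genes:
            votes.setdefault(g, set()).add(cls)
    out = {g: (next(iter(cset)) if len(cset) == 1 else "unassigned")
           for g, cset in votes.items()}
    return pd.Series(out, name="stability_class", dtype=object).sort_index()


@dataclass
class EnrichmentThresholds:
    high: float = 40.0  # FPKM a fraction must exceed in its own tissue
    low: float = 10.0   # FPKM it must stay under in the other two


def partition_enrichment(fpkm: pd.DataFrame,
                         high: float = 40.0, low: float = 10.0) -> pd.Series:
    """Tissue-enrichment partition of features.

    ``fpkm`` has columns ``testes, sperm, seminal_fluid`` (FPKM per
    feature).  A feature is X-enriched iff its FPKM in X exceeds ``high``
    and both other tissues are below ``low``; otherwise it is unassigned.
    Exactly one label per feature by construction.
    """
    cols = ["testes", "sperm", "seminal_fluid"]
    missing = [c for c in cols if c not in fpkm.columns]
    if missing:
        raise ValueError(f"missing FPKM columns: {missing}")
    if (fpkm[cols].to_numpy() < 0).any():
        raise ValueError("negative FPKM")
    out = pd.Series("unassigned", index=fpkm.index, name="fraction")
    for c in cols:
        others = [o for o in cols if o != c]
        hit = (fpkm[c] > high) & (fpkm[others] < low).all(axis=1)
        out[hit] = f"{c}_enriched"
    return out


def compare_fraction_variability(cv: pd.Series, fraction: pd.Series,
                                 min_group: int = 2
                                 ) -> tuple[float, pd.DataFrame, pd.Series]:
    """One-way ANOVA plus all-pairs Tukey HSD on CV grouped by fraction.

    Groups with fewer than ``min_group`` members are excluded with a
    warning; ``unassigned`` features are ignored.  Returns the ANOVA
    p-value, a DataFrame of pairwise Tukey results (group1, group2,
    meandiff, p_adj) and the per-group mean CV.
    """
    df = pd.DataFrame({"cv": cv, "group": fraction}).dropna()
    df = df[df["group"] != "unassigned"]
    sizes = df.groupby("group").size()
    small = sizes[sizes < min_group].index
    if len(small):
        warnings.warn(f"excluding groups with < {min_group} members: {list(small)}")
        df = df[~df["group"].isin(small)]
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 usable groups")
    arrays = [df.loc[df["group"] == g, "cv"].to_numpy() for g in groups]
    anova_p = float(stats.f_oneway(*arrays).pvalue)
    tk = pairwise_tukeyhsd(df["cv"].to_numpy(), df["group"].to_numpy())
    pairs = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    pairs = pairs.rename(columns={"p-adj": "p_adj"})[
        ["group1", "group2", "meandiff", "p_adj"]]
    pairs[["meandiff", "p_adj"]] = pairs[["meandiff", "p_adj"]].astype(float)
    means = df.groupby("group")["cv"].mean()
    return anova_p, pairs, means


def overrepresentation_test(query: set[str], collection: GeneSetCollection,
                            universe: set[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each
    set, Bonferroni-corrected over the number of sets tested.

    Sets are intersected with the universe before testing; the query must
    be a subset of the universe.  Returns one row per set with overlap,
    set_size, p and p_bonferroni.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set(query) <= set(universe):
        raise ValueError("query is not a subset of the universe")
    n_univ, n_query = len(universe), len(query)
    rows = []
    for sid, members in collection.sets.items():
        in_univ = set(members) & universe
        k = len(in_univ & set(query))
        m = len(in_univ)
        # P(X >= k) for X ~ Hypergeom(N=n_univ, K=m, n=n_query)
        p = float(stats.hypergeom.sf(k - 1, n_univ, m, n_query))
        rows.append((sid, k, m, n_univ, n_query, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_id", "overlap", "set_size",
                                      "universe_size", "query_size", "p"])
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def filter_denovo_contigs(table: pd.DataFrame,
                          min_identity: float = 85.0,
                          min_fpkm: float = 50.0,
                          min_samples: int = 5) -> pd.DataFrame:
    """Retention filter for de novo assembled contigs.

    Keeps contigs with identity strictly above ``min_identity`` (%), FPKM
    strictly above ``min_fpkm``, and detection in at least ``min_samples``
    samples.
    """
    needed = ["identity", "fpkm", "n_samples_detected"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"contig table is missing columns: {missing}")
    keep = ((table["identity"] > min_identity)
            & (table["fpkm"] > min_fpkm)
            & (table["n_samples_detected"] >= min_samples))
    return table[keep].copy()
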