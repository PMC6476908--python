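"""Seasonal differential abundance for count matrices.

Two-group (summer vs winter) negative-binomial testing with batch
adjustment, in the usual count-based RNA-seq skeleton:

1. median-of-ratios size factors;
2. per-feature method-of-moments NB dispersion, shrunk halfway toward the
   median dispersion of the feature's abundance decile;
3. per feature, a log-linear NB model ``log mu = log(sf) + intercept +
   batch + season`` fitted by iteratively reweighted least squares at
   fixed dispersion, with a Wald test of the season coefficient against
   the standard normal;
4. Benjamini-Hochberg FDR adjustment and the significance rule
   ``q < 0.05 and |FC| > 1.5`` (the fold-change bound applies to the
   absolute fold change, so strong effects in either direction qualify).

The entry point is :class:`SeasonalCountModel`, whose :meth:`fit` returns a
:class:`SeasonalDEResults` carrying estimates, standard errors, p/q-values
and a ``summary()`` table.  The individual steps are importable functions
so each can be tested against independent oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SeasonalCountModel",
    "SeasonalDEResults",
    "DesignError",
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "filter_de",
]

LN2 = np.log(2.0)


class DesignError(ValueError):
    pass


def _validate_design(design: pd.DataFrame) -> pd.DataFrame:
    design = design.copy()
    for col in ("sample_id", "season", "batch"):
        if col not in design.columns:
            raise DesignError(f"design needs a {col!r} column")
    bad = set(design["season"]) - {"summer", "winter"}
    if bad:
        raise DesignError(f"unknown season labels: {sorted(bad)}")
    counts = design["season"].value_counts()
    if counts.get("summer", 0) < 2 or counts.get("winter", 0) < 2:
        raise DesignError("need >= 2 samples per season")
    X = _design_matrix(design)[0]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("batch is perfectly confounded with season")
    return design


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + batch indicator(s) + season indicator (summer = 1)."""
    batches = sorted(design["batch"].unique())
    cols = [np.ones(len(design))]
    names = ["intercept"]
    for b in batches[1:]:
        cols.append((design["batch"] == b).to_numpy(float))
        names.append(f"batch[{b}]")
    cols.append((design["season"] == "summer").to_numpy(float))
    names.append("season[summer]")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# step functions


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, scaled to geometric mean 1.

    The pseudo-reference is the per-feature geometric mean over samples,
    using only features with no zero count; if no such feature exists the
    factors fall back to total-count scaling (with a warning).
    """
    mat = counts.to_numpy(float)
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns, name="size_factor")
    if (mat.sum(axis=0) == 0).any():
        raise ValueError("a sample has no nonzero count")
    allpos = (mat > 0).all(axis=1)
    if allpos.sum() == 0:
        warnings.warn("no feature free of zeros; falling back to total-count scaling")
        f = mat.sum(axis=0)
    else:
        sub = mat[allpos]
        logref = np.log(sub).mean(axis=1)
        f = np.exp(np.median(np.log(sub) - logref[:, None], axis=0))
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="size_factor")


def estimate_dispersion(counts: pd.DataFrame, factors: pd.Series,
                        alpha_min: float = 1e-4,
                        design: pd.DataFrame | None = None) -> pd.Series:
    """Per-feature NB dispersion ``alpha`` (variance = mu + alpha mu^2).

    Method of moments on size-factor-normalized counts,
    ``alpha = (s^2 - mu) / mu^2`` floored at ``alpha_min``, then shrunk 50%
    toward the median raw estimate within the feature's abundance decile.
    When a design is supplied the moments are computed within each season
    group and pooled by degrees of freedom, so a real between-group shift
    does not masquerade as biological dispersion.  All-zero features get
    NaN (excluded from testing).
    """
    if counts.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate dispersion")
    q = counts.to_numpy(float) / factors[counts.columns].to_numpy(float)
    mu = q.mean(axis=1)
    if design is None:
        s2 = q.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(mu > 0, np.maximum(alpha_min, (s2 - mu) / mu**2), np.nan)
    else:
        design = design.set_index("sample_id").loc[list(counts.columns)]
        raw_acc = np.zeros(len(mu))
        df_tot = 0
        for _, idx in design.groupby("season").groups.items():
            cols = [list(counts.columns).index(s) for s in idx]
            if len(cols) < 2:
                continue
            qg = q[:, cols]
            mg = qg.mean(axis=1)
            s2g = qg.var(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ag = np.where(mg > 0, (s2g - mg) / mg**2, 0.0)
            raw_acc += (len(cols) - 1) * np.nan_to_num(ag)
            df_tot += len(cols) - 1
        raw = np.where(mu > 0, np.maximum(alpha_min, raw_acc / max(df_tot, 1)),
                       np.nan)
    ok = mu > 0
    alpha = np.full(len(mu), np.nan)
    if ok.sum():
        ranks = pd.Series(mu[ok]).rank(method="first")
        dec = np.ceil(10 * ranks / ok.sum()).astype(int)
        trend = pd.Series(raw[ok]).groupby(dec.to_numpy()).transform("median")
        alpha[ok] = np.maximum(alpha_min, 0.5 * raw[ok] + 0.5 * trend.to_numpy())
    return pd.Series(alpha, index=counts.index, name="dispersion")


def nb_wald_test(counts: pd.DataFrame, factors: pd.Series,
                 dispersions: pd.Series, design: pd.DataFrame,
                 max_iter: int = 50, tol: float = 1e-6) -> pd.DataFrame:
    """Per-feature NB log-linear fit and Wald test of the season effect.

    IRLS at fixed dispersion, batched across features (the design matrix is
    shared, so the per-iteration solve is a stacked batch of small normal
    equations).  Non-converged features are flagged and given p = 1.
    Features with NaN dispersion (all-zero counts) get NaN estimates.

    Returns columns log2fc, se_log2fc, stat, p, converged.
    """
    design = _validate_design(design)
    X, names = _design_matrix(design)
    order = list(design["sample_id"])
    Y = counts[order].to_numpy(float)
    sf = factors[order].to_numpy(float)
    alpha = dispersions[counts.index].to_numpy(float)
    n_f, n_s = Y.shape
    p_dim = X.shape[1]
    offset = np.log(sf)[None, :]

    tested = ~np.isnan(alpha)
    beta = np.zeros((n_f, p_dim))
    with np.errstate(divide="ignore"):
        beta[:, 0] = np.log(np.maximum((Y / sf).mean(axis=1), 1e-8))
    converged = np.zeros(n_f, dtype=bool)
    active = tested.copy()
    a = np.where(np.isnan(alpha), 1.0, alpha)
    se_all = np.full((n_f, p_dim), np.nan)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = offset + beta @ X.T
        mu = np.maximum(np.exp(eta), 1e-10)
        W = mu / (1.0 + a[:, None] * mu)          # NB working weights
        z = (eta - offset) + (Y - mu) / mu         # working response
        XtWX = np.einsum("ni,fn,nj->fij", X, W, X)
        XtWz = np.einsum("ni,fn,fn->fi", X, W, z)
        idx = np.where(active)[0]
        try:
            new = np.linalg.solve(XtWX[idx], XtWz[idx][..., None])[..., 0]
        except np.linalg.LinAlgError:
            new = np.stack([np.linalg.lstsq(XtWX[i], XtWz[i], rcond=None)[0]
                            for i in idx])
        delta = np.abs(new - beta[idx]).max(axis=1)
        beta[idx] = new
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    # covariance at the final fit for every tested feature
    eta = offset + beta @ X.T
    mu = np.maximum(np.exp(eta), 1e-10)
    W = mu / (1.0 + a[:, None] * mu)
    XtWX = np.einsum("ni,fn,nj->fij", X, W, X)
    tidx = np.where(tested)[0]
    for i in tidx:
        try:
            se_all[i] = np.sqrt(np.diag(np.linalg.inv(XtWX[i])))
        except np.linalg.LinAlgError:
            se_all[i] = np.nan
    k = names.index("season[summer]")
    log2fc = np.where(tested, beta[:, k] / LN2, np.nan)
    se = np.where(tested, se_all[:, k] / LN2, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = beta[:, k] / se_all[:, k]
    pvals = 2.0 * stats.norm.sf(np.abs(stat))
    pvals = np.where(tested & ~converged, 1.0, pvals)
    pvals = np.where(tested, pvals, np.nan)
    if (tested & ~converged).any():
        warnings.warn(f"{int((tested & ~converged).sum())} features did not "
                      "converge; their p-values are set to 1")
    return pd.DataFrame({
        "log2fc": log2fc, "se_log2fc": se, "stat": np.where(tested, stat, np.nan),
        "p": pvals, "converged": converged,
    }, index=counts.index)


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    NaN entries stay NaN and do not count toward the number of tests.
    """
    arr = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(arr)
    if ((arr[ok] < 0) | (arr[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(arr, np.nan)
    if ok.sum():
        q[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(q, index=pvalues.index, name="q")
    return q


def filter_de(results: pd.DataFrame, fdr: float = 0.05,
              fc: float = 1.5) -> pd.DataFrame:
    """Significant features: ``q < fdr`` (strict) and ``2**|log2fc| > fc``.

    Adds a ``direction`` column (``up_in_summer`` / ``down_in_summer``)
    keyed on the sign of log2fc.
    """
    keep = (results["q"] < fdr) & (np.power(2.0, results["log2fc"].abs()) > fc)
    out = results[keep.fillna(False)].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up_in_summer", "down_in_summer")
    return out


# ---------------------------------------------------------------------------
# model / results objects


@dataclass
class SeasonalCountModel:
    """NB count model of a two-season, batched design.

    Parameters
    ----------
    counts : features x samples raw count matrix
    design : sample sheet with sample_id, season (summer/winter), batch

    ``fit()`` runs normalization, dispersion estimation, the per-feature
    Wald test and BH adjustment, and returns :class:`SeasonalDEResults`.
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    alpha_min: float = 1e-4
    max_iter: int = 50
    tol: float = 1e-6

    def __post_init__(self) -> None:
        self.design = _validate_design(self.design)
        missing = set(self.design["sample_id"]) - set(self.counts.columns)
        if missing:
            raise DesignError(f"counts lack design samples: {sorted(missing)}")

    @classmethod
    def from_files(cls, counts_path: str, design_path: str, **kw) -> "SeasonalCountModel":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t")
        return cls(counts=counts, design=design, **kw)

    def fit(self) -> "SeasonalDEResults":
        sf = size_factors(self.counts)
        disp = estimate_dispersion(self.counts, sf, alpha_min=self.alpha_min,
                                   design=self.design)
        wald = nb_wald_test(self.counts, sf, disp, self.design,
                            max_iter=self.max_iter, tol=self.tol)
        wald["q"] = bh_adjust(wald["p"])
        return SeasonalDEResults(model=self, table=wald, size_factors_=sf,
                                 dispersions_=disp)


@dataclass
class SeasonalDEResults:
    """Fitted seasonal differential-abundance results.

    ``table`` has one row per feature: log2fc (summer relative to winter),
    se_log2fc, Wald stat, p, q, converged.
    """

    model: SeasonalCountModel
    table: pd.DataFrame
    size_factors_: pd.Series
    dispersions_: pd.Series
    fdr: float = 0.05
    fc: float = 1.5
    _sig: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def pvalues(self) -> pd.Series:
        return self.table["p"]

    @property
    def qvalues(self) -> pd.Series:
        return self.table["q"]

    def significant(self, fdr: float | None = None,
                    fc: float | None = None) -> pd.DataFrame:
        """Features passing ``q < fdr`` and ``|FC| > fc``, with direction."""
        return filter_de(self.table, fdr=self.fdr if fdr is None else fdr,
                         fc=self.fc if fc is None else fc)

    def summary(self, top: int = 20) -> str:
        sig = self.significant()
        up = int((sig["direction"] == "up_in_summer").sum())
        down = int((sig["direction"] == "down_in_summer").sum())
        lines = [
            "Seasonal differential abundance (NB Wald, summer vs winter)",
            "=" * 60,
            f"features tested:      {int(self.table['p'].notna().sum())}",
            f"samples:              {len(self.model.design)} "
            f"({(self.model.design['season'] == 'summer').sum()} summer / "
            f"{(self.model.design['season'] == 'winter').sum()} winter)",
            f"significant (q < {self.fdr:g}, |FC| > {self.fc:g}): {len(sig)} "
            f"({up} up, {down} down in summer)",
            "",
            sig.sort_values("q")[["log2fc", "p", "q", "direction"]]
               .head(top).to_string(),
        ]
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t")
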