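"""Seasonal NB differential testing: normalization, dispersion, Wald fit
against an independent GLM oracle, BH against brute force, filters."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from spermkit import differential as de
from spermkit.simulate import SimulationConfig, simulate_counts


def design_5v5(n_batches=2):
    rows = []
    for season in ("summer", "winter"):
        for i in range(5):
            rows.append((f"{season[0]}{i + 1}", season, f"batch{(i % n_batches) + 1}"))
    return pd.DataFrame(rows, columns=["sample_id", "season", "batch"])


class TestSizeFactors:
    def test_identical_columns_all_one(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(de.size_factors(counts), 1.0)

    def test_doubled_column_ratio_two(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, 500) + 1
        counts = pd.DataFrame({"a": base, "b": 2 * base})
        f = de.size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0, rel=1e-12)

    def test_single_sample_factor_one(self):
        counts = pd.DataFrame({"a": [5, 10]})
        assert de.size_factors(counts).iloc[0] == 1.0

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, (300, 6)) + 1,
                              columns=list("abcdef"))
        f = de.size_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_no_zero_free_feature_falls_back(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 5]})
        with pytest.warns(UserWarning):
            f = de.size_factors(counts)
        assert np.allclose(f, 1.0)


class TestDispersion:
    def test_poisson_features_hit_floor(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(200, (400, 50)))
        f = de.size_factors(counts)
        alpha = de.estimate_dispersion(counts, f)
        # Poisson variance = mean -> raw alpha near 0, floored for most features
        assert alpha.median() < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(3)
        n, mu, a = 50, 200.0, 0.5
        lam = rng.gamma(1 / a, mu * a, size=(300, n))
        counts = pd.DataFrame(rng.poisson(lam))
        f = de.size_factors(counts)
        alpha = de.estimate_dispersion(counts, f)
        inside = ((alpha > 0.25) & (alpha < 0.9)).mean()
        assert inside >= 0.9

    def test_constant_counts_floor(self):
        counts = pd.DataFrame(np.full((5, 10), 7))
        alpha = de.estimate_dispersion(counts, de.size_factors(counts))
        assert (alpha == 1e-4).all()

    def test_all_zero_feature_nan(self):
        counts = pd.DataFrame(np.vstack([np.zeros(10), np.full(10, 5)]).astype(int))
        alpha = de.estimate_dispersion(counts, pd.Series(1.0, index=counts.columns))
        assert np.isnan(alpha.iloc[0]) and not np.isnan(alpha.iloc[1])


class TestNbWald:
    def test_matches_statsmodels_glm(self):
        """The batched IRLS agrees with an independent per-feature GLM fit
        (statsmodels, NB family with the same fixed dispersion)."""
        rng = np.random.default_rng(4)
        design = design_5v5()
        counts = pd.DataFrame(rng.poisson(rng.gamma(5, 40, (30, 10))),
                              index=[f"F{i}" for i in range(30)],
                              columns=design["sample_id"])
        sf = de.size_factors(counts)
        disp = de.estimate_dispersion(counts, sf)
        got = de.nb_wald_test(counts, sf, disp, design)
        X, names = de._design_matrix(design)
        k = names.index("season[summer]")
        offset = np.log(sf.to_numpy())
        for i, fid in enumerate(counts.index[:10]):
            y = counts.loc[fid].to_numpy(float)
            glm = sm.GLM(y, X, family=sm.families.NegativeBinomial(
                alpha=float(disp[fid])), offset=offset).fit()
            assert got.loc[fid, "log2fc"] == pytest.approx(
                glm.params[k] / np.log(2), rel=1e-4, abs=1e-6)
            assert got.loc[fid, "se_log2fc"] == pytest.approx(
                glm.bse[k] / np.log(2), rel=1e-3)

    def test_identical_groups_null_result(self):
        design = design_5v5()
        row = [40, 50, 60, 45, 55] * 2   # same counts in both seasons
        counts = pd.DataFrame([row] * 12, index=[f"F{i}" for i in range(12)],
                              columns=design["sample_id"])
        sf = pd.Series(1.0, index=design["sample_id"])
        disp = pd.Series(0.1, index=counts.index)
        out = de.nb_wald_test(counts, sf, disp, design)
        assert np.allclose(out["log2fc"], 0.0, atol=1e-8)
        assert (out["p"] > 0.999).all()

    def test_sample_reordering_invariance(self):
        rng = np.random.default_rng(5)
        design = design_5v5()
        counts = pd.DataFrame(rng.poisson(80, (20, 10)),
                              index=[f"F{i}" for i in range(20)],
                              columns=design["sample_id"])
        sf = de.size_factors(counts)
        disp = de.estimate_dispersion(counts, sf)
        a = de.nb_wald_test(counts, sf, disp, design)
        perm = rng.permutation(10)
        design_p = design.iloc[perm].reset_index(drop=True)
        b = de.nb_wald_test(counts, sf, disp, design_p)
        assert np.allclose(a["log2fc"], b["log2fc"], atol=1e-8)
        assert np.allclose(a["p"], b["p"], atol=1e-8)

    def test_season_swap_flips_sign(self):
        rng = np.random.default_rng(6)
        design = design_5v5()
        counts = pd.DataFrame(rng.poisson(80, (20, 10)),
                              index=[f"F{i}" for i in range(20)],
                              columns=design["sample_id"])
        sf = de.size_factors(counts)
        disp = de.estimate_dispersion(counts, sf)
        a = de.nb_wald_test(counts, sf, disp, design)
        swapped = design.assign(
            season=design["season"].map({"summer": "winter", "winter": "summer"}))
        b = de.nb_wald_test(counts, sf, disp, swapped)
        assert np.allclose(a["log2fc"], -b["log2fc"], atol=1e-6)
        assert np.allclose(a["p"], b["p"], atol=1e-6)

    def test_confounded_design_rejected(self):
        design = design_5v5()
        design["batch"] = np.where(design["season"] == "summer", "b1", "b2")
        counts = pd.DataFrame(np.ones((3, 10), dtype=int),
                              columns=design["sample_id"])
        with pytest.raises(de.DesignError):
            de.nb_wald_test(counts, pd.Series(1.0, index=design["sample_id"]),
                            pd.Series(0.1, index=counts.index), design)

    def test_planted_strong_effect_recovered(self):
        cfg = SimulationConfig(seed=8, n_features=500, planted_log2fc={0: 5.0})
        counts, truth = simulate_counts(cfg)
        res = de.SeasonalCountModel(counts, cfg.design()).fit()
        planted = truth.de_log2fc[truth.de_log2fc != 0].index[0]
        assert res.qvalues[planted] < 0.05
        assert res.log2fc[planted] == pytest.approx(5.0, abs=1.0)

    def test_batch_covariate_reduces_false_positives(self):
        """With a planted batch effect and no season effect, modelling the
        batch yields no more false positives than ignoring it."""
        fp_with, fp_without = 0, 0
        for seed in range(4):
            cfg = SimulationConfig(seed=100 + seed, n_features=400,
                                   planted_log2fc={}, batch_log2_effect=2.0)
            counts, _ = simulate_counts(cfg)
            design = cfg.design()
            res = de.SeasonalCountModel(counts, design).fit()
            fp_with += len(res.significant())
            no_batch = design.assign(batch="batch1")
            res2 = de.SeasonalCountModel(counts, no_batch).fit()
            fp_without += len(res2.significant())
        assert fp_with <= fp_without


def bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Step-up definition evaluated literally."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        q[idx] = min(min(1.0, m * p[j] / (list(order).index(j) + 1))
                     for j in order[rank_pos - 1:])
    return q


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert de.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_textbook_example(self):
        q = de.bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(de.bh_adjust(np.ones(5)), 1.0)

    def test_matches_bruteforce_up_to_length_12(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            m = int(rng.integers(1, 13))
            p = np.round(rng.uniform(0, 1, m), 3)
            assert np.allclose(de.bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust(np.array([1.5]))

    def test_monotone_in_ranked_order(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 100)
        q = de.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=12))
    def test_bruteforce_property(self, plist):
        p = np.asarray(plist)
        assert np.allclose(de.bh_adjust(p), bh_bruteforce(p), atol=1e-12)


class TestFilterDe:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "p", "q"],
                            index=[f"F{i}" for i in range(len(rows))])

    def test_strong_up_effect_kept(self):
        # the kind of entry a seasonal comparison reports at its top
        out = de.filter_de(self._results([(5.15, 1.68e-20, 3.13e-16)]))
        assert len(out) == 1 and out.iloc[0]["direction"] == "up_in_summer"

    def test_small_fold_change_dropped(self):
        out = de.filter_de(self._results([(0.3, 1e-5, 0.001)]))
        assert len(out) == 0  # FC = 1.23 < 1.5

    def test_high_q_dropped(self):
        assert len(de.filter_de(self._results([(-2.0, 0.01, 0.2)]))) == 0

    def test_q_exactly_at_threshold_not_significant(self):
        assert len(de.filter_de(self._results([(3.0, 1e-4, 0.05)]))) == 0

    def test_negative_fold_change_passes_absolute_rule(self):
        out = de.filter_de(self._results([(-2.0, 1e-5, 0.001)]))
        assert len(out) == 1 and out.iloc[0]["direction"] == "down_in_summer"

    def test_fc_boundary_strict(self):
        lfc = np.log2(1.5)
        assert len(de.filter_de(self._results([(lfc, 1e-5, 1e-4)]))) == 0
        assert len(de.filter_de(self._results([(lfc + 1e-6, 1e-5, 1e-4)]))) == 1


class TestModelObjects:
    def test_fit_returns_results_with_summary(self):
        cfg = SimulationConfig(seed=15, n_features=300)
        counts, _ = simulate_counts(cfg)
        res = de.SeasonalCountModel(counts, cfg.design()).fit()
        text = res.summary()
        assert "features tested" in text and "significant" in text
        assert len(res.table) == 300
        assert set(["log2fc", "p", "q"]) <= set(res.table.columns)

    def test_missing_sample_rejected(self):
        cfg = SimulationConfig(seed=16, n_features=10, planted_log2fc={})
        counts, _ = simulate_counts(cfg)
        with pytest.raises(de.DesignError):
            de.SeasonalCountModel(counts.drop(columns=["s1"]), cfg.design())
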