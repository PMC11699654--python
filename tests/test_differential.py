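"""Differential statistics: TMM, moderated t, BH, confect, msd, gene scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from epinteg import (
    CountMatrix,
    SimulationConfig,
    bh_adjust,
    confident_effect,
    filter_low_expression,
    log_cpm,
    moderated_t_test,
    msd_rank,
    signed_quantile_score,
    simulate_paired_experiment,
    tmm_factors,
)
from epinteg.differential import _treat_p


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30, 40], "b": [10, 20, 30, 40]})
        assert tmm_factors(df) == pytest.approx([1.0, 1.0])

    def test_pure_depth_difference_gives_unit_factors(self):
        rng = np.random.default_rng(0)
        a = rng.integers(10, 1000, size=200)
        df = pd.DataFrame({"a": a, "b": 2 * a})
        assert tmm_factors(df) == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_composition_bias_shrinks_factor(self):
        # one gene absorbs half of B's reads; B's remaining genes look
        # depleted, so TMM must scale B's effective library down
        rng = np.random.default_rng(1)
        a = rng.integers(50, 500, size=300)
        b = a.copy()
        b[0] = a.sum()  # gene 0 takes ~50% of B
        df = pd.DataFrame({"a": a, "b": b})
        f = tmm_factors(df, ref=0)
        assert f[1] < 1.0

    def test_all_zero_sample_rejected(self):
        df = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError, match="b"):
            tmm_factors(df)


class TestLogCpm:
    def test_plug_in_value(self):
        # one gene with count 0 out of a 1e6 library: log2(0.5) exactly
        df = pd.DataFrame({"s": [0, 999_999 + 1]})
        vals = log_cpm(df, np.array([1.0]), prior=0.5)
        expected = np.log2(0.5 / 1e6 * 1e6)
        assert vals.iloc[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.integers(100, 1000, size=(100, 3)))
        a = log_cpm(df, np.ones(3))
        b = log_cpm(df * 2, np.ones(3))
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 0.01

    def test_zero_prior_rejected(self):
        with pytest.raises(ValueError):
            log_cpm(pd.DataFrame({"s": [0]}), np.array([1.0]), prior=0.0)


class TestFilter:
    def test_all_zero_gene_removed_and_expressed_kept(self, toy_counts):
        kept = filter_low_expression(toy_counts, min_count=3, min_samples=2)
        assert "g2" not in kept and "g3" in kept

    def test_zero_threshold_keeps_everything(self, toy_counts):
        assert filter_low_expression(toy_counts, min_count=0) == ["g1", "g2", "g3"]


class TestModeratedT:
    def test_identical_groups_give_zero_lfc_p_one(self):
        rng = np.random.default_rng(3)
        base = rng.normal(5, 1, size=(50, 3))
        x = pd.DataFrame(np.hstack([base, base]),
                         columns=[f"s{i}" for i in range(6)])
        res = moderated_t_test(x, ["c"] * 3 + ["t"] * 3)
        assert np.allclose(res["log2fc"], 0)
        assert np.allclose(res["p"], 1)

    def test_infinite_prior_df_limit(self):
        # when log-variances have no excess spread, every gene shares s0
        rng = np.random.default_rng(4)
        x = pd.DataFrame(rng.normal(0, 1, size=(2000, 6)))
        res = moderated_t_test(x, ["c"] * 3 + ["t"] * 3)
        if np.isinf(res.attrs["d0"]):
            s0 = res.attrs["s0_sq"]
            t_expected = res["log2fc"] / np.sqrt(s0 * (2 / 3))
            t_actual = res["log2fc"] / res["se"]
            assert np.allclose(t_actual, t_expected)

    def test_null_calibration_nominal_alpha(self):
        """Fraction p < 0.05 on 10,000 null NB genes is 0.05 +- 0.01."""
        cfg = SimulationConfig(n_genes=10_000, de_fraction=0.0, seed=42,
                               enhancer_fraction=0.0, distal_fraction=0.0,
                               n_conditions=2)
        rna, _, _ = simulate_paired_experiment(cfg)
        expr = log_cpm(rna.counts, tmm_factors(rna.counts))
        groups = [rna.conditions[s] for s in rna.samples]
        res = moderated_t_test(expr, groups)
        frac = float((res["p"] < 0.05).mean())
        assert abs(frac - 0.05) <= 0.01

    def test_degenerate_zero_variance_rejected(self):
        x = pd.DataFrame(np.ones((10, 6)))
        with pytest.raises(ValueError, match="degenerate"):
            moderated_t_test(x, ["c"] * 3 + ["t"] * 3)


class TestBh:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_degenerate(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_monotone_and_order_preserving(self, p):
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1 + 1e-12).all()


def _toy_results(lfc, se, df=10.0):
    n = len(lfc)
    lfc, se = np.asarray(lfc, float), np.asarray(se, float)
    t = lfc / se
    p = 2 * stats.t.sf(np.abs(t), df)
    crit = stats.t.ppf(0.975, df)
    return pd.DataFrame(
        {"log2fc": lfc, "ci_low": lfc - crit * se, "ci_high": lfc + crit * se,
         "p": p, "q": bh_adjust(p), "se": se, "df": df},
        index=[f"f{i:02d}" for i in range(n)],
    )


def _confect_grid_oracle(results, fdr_level=0.05, step=1e-3):
    """Grid search over c applying the interval-null p + BH at each step."""
    lfc = results["log2fc"].to_numpy()
    se = results["se"].to_numpy()
    df = float(results["df"].iloc[0])
    out = np.full(len(lfc), np.nan)
    grid = np.arange(0.0, np.abs(lfc).max() + step, step)
    best = np.full(len(lfc), -1.0)
    for c in grid:
        tau, delta = np.abs(lfc) / se, c / se
        p = np.minimum(stats.t.sf(tau - delta, df) + stats.t.sf(tau + delta, df), 1.0)
        rejected = bh_adjust(p) < fdr_level
        best[rejected & (best < c)] = c
    ok = best >= 0
    out[ok] = np.sign(lfc[ok]) * best[ok]
    return out


class TestConfect:
    def test_non_significant_feature_is_null(self):
        res = _toy_results([0.1, 3.0], [0.5, 0.2])
        conf = confident_effect(res)
        assert np.isnan(conf.iloc[0])
        assert conf.iloc[1] > 0

    def test_sign_and_bound_property(self):
        res = _toy_results([3.0, -2.5, 0.05], [0.1, 0.1, 0.5])
        conf = confident_effect(res)
        assert 0 < conf.iloc[0] < 3.0
        assert -2.5 < conf.iloc[1] < 0
        # |confect| <= |log2fc| wherever non-null
        ok = conf.notna()
        assert (conf[ok].abs() <= res.loc[ok, "log2fc"].abs() + 1e-9).all()

    def test_matches_grid_search_oracle(self):
        """Bisection agrees with the brute-force grid (step 1e-3) on 20 features."""
        rng = np.random.default_rng(7)
        lfc = rng.normal(0, 2, size=20)
        se = rng.uniform(0.1, 0.8, size=20)
        res = _toy_results(lfc, se)
        conf = confident_effect(res, tol=1e-4).to_numpy()
        oracle = _confect_grid_oracle(res, step=1e-3)
        assert np.isnan(conf).tolist() == np.isnan(oracle).tolist()
        ok = ~np.isnan(conf)
        assert np.abs(conf[ok] - oracle[ok]).max() < 2e-3

    def test_interval_null_p_is_monotone_in_c(self):
        lfc, se = np.array([2.0]), np.array([0.3])
        cs = np.linspace(0, 2, 50)
        ps = [_treat_p(lfc, se, 10.0, c)[0] for c in cs]
        assert (np.diff(ps) >= -1e-12).all()


class TestMsd:
    @pytest.mark.parametrize(
        "lfc,lo,hi,expected",
        [(1.0, 0.5, 1.5, 0.5), (1.0, -0.2, 1.5, -0.2), (-1.0, -1.5, -0.5, 0.5)],
    )
    def test_formula(self, lfc, lo, hi, expected):
        res = pd.DataFrame({"log2fc": [lfc], "ci_low": [lo], "ci_high": [hi]})
        assert msd_rank(res)["msd"].iloc[0] == pytest.approx(expected)

    def test_negative_msd_ranks_below_positive(self):
        res = pd.DataFrame(
            {"log2fc": [1.0, 1.0, -1.0], "ci_low": [-0.2, 0.5, -1.5],
             "ci_high": [1.5, 1.5, -0.5]},
            index=["cross", "strong_up", "strong_down"],
        )
        ranked = msd_rank(res)
        assert list(ranked.index)[-1] == "cross"


class TestSignedQuantileScore:
    def test_reference_value(self):
        z = signed_quantile_score([0.05], [2.0])
        assert z[0] == pytest.approx(1.95996, abs=1e-4)

    def test_q_one_maps_to_zero(self):
        assert signed_quantile_score([1.0], [-3.0])[0] == 0.0

    @given(st.floats(1e-10, 1.0), st.floats(0.01, 10))
    def test_odd_symmetry(self, q, lfc):
        up = signed_quantile_score([q], [lfc])[0]
        down = signed_quantile_score([q], [-lfc])[0]
        assert up == pytest.approx(-down)

    def test_zero_q_rejected(self):
        with pytest.raises(ValueError):
            signed_quantile_score([0.0], [1.0])


def test_confect_and_msd_orderings_agree_on_significant_features():
    """Both are CI-bound rankings; restricted to q<0.05 they sort alike."""
    rng = np.random.default_rng(11)
    lfc = rng.normal(0, 2, size=60)
    se = rng.uniform(0.1, 0.4, size=60)
    res = _toy_results(lfc, se)
    res["confect"] = confident_effect(res)
    ranked = msd_rank(res)
    sig = ranked[(ranked["q"] < 0.05) & ranked["confect"].notna()]
    # compare orderings by |confect| vs msd among positive-effect features
    pos = sig[sig["log2fc"] > 0]
    if len(pos) > 2:
        rho = stats.spearmanr(pos["confect"], pos["msd"]).statistic
        assert rho > 0.95
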