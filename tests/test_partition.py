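"""Variance shares and treatment predictions on known-answer draws."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st
from scipy.special import expit

from hostassay import treatment_predictions, variance_shares, summarize_model

from conftest import cell_effects, make_draws


class TestVarianceShares:
    def test_single_draw_hand_arithmetic(self):
        # components at the survival-model posterior means; the host share
        # of the summed link-scale variance is 2.09 / 4.0065
        d = make_draws(
            intercept=[0.0],
            variances={"host": [2.09], "population": [0.046],
                       "population:host": [0.87], "culture": [0.0005]},
            effects={},
            var_residual=1.0,
        )
        shares = variance_shares(d)
        total = 2.09 + 0.046 + 0.87 + 0.0005 + 1.0
        assert shares.table.loc["host", "share_mean"] == pytest.approx(
            2.09 / total, abs=1e-12)
        assert shares.table.loc["host", "share_mean"] == pytest.approx(
            0.522, abs=0.001)

    def test_equal_components_split_evenly(self):
        d = make_draws(
            intercept=np.zeros(10),
            variances={"host": np.full(10, 3.0),
                       "population": np.full(10, 3.0)},
            effects={},
            var_residual=3.0,
        )
        shares = variance_shares(d)
        assert np.allclose(shares.table["share_mean"], 1.0 / 3.0)

    @given(seed=st.integers(0, 10_000))
    @hsettings(max_examples=40, deadline=None)
    def test_shares_sum_to_one_in_every_draw(self, seed):
        rng = np.random.default_rng(seed)
        d = make_draws(
            intercept=np.zeros(20),
            variances={"host": rng.gamma(1.0, size=20),
                       "culture": rng.gamma(0.1, size=20)},
            effects={},
            var_residual=rng.gamma(1.0, size=20) + 1e-6,
        )
        shares = variance_shares(d)
        assert np.allclose(shares.share_draws.sum(axis=1), 1.0, atol=1e-12)

    def test_draw_order_permutation_invariance(self):
        rng = np.random.default_rng(7)
        v = rng.gamma(1.0, size=50)
        d1 = make_draws(np.zeros(50), {"host": v}, {}, var_residual=1.0)
        d2 = make_draws(np.zeros(50), {"host": v[::-1]}, {}, var_residual=1.0)
        t1, t2 = variance_shares(d1).table, variance_shares(d2).table
        assert np.allclose(t1.to_numpy(), t2.to_numpy(), rtol=1e-12)

    def test_mean_share_not_ratio_of_mean_variances(self):
        # draw-wise shares vs the plug-in ratio: they differ for varying draws
        v = np.array([0.1, 10.0])
        d = make_draws(np.zeros(2), {"host": v}, {}, var_residual=1.0)
        share = variance_shares(d).table.loc["host", "share_mean"]
        plug_in = v.mean() / (v.mean() + 1.0)
        assert abs(share - plug_in) > 0.05


class TestTreatmentPredictions:
    def test_identity_link_zero_effects(self):
        hosts = ["oak", "willow"]
        d = make_draws(
            intercept=np.full(5, 33.9),
            variances={"host": np.ones(5)},
            effects={"host": (hosts, np.zeros((5, 2)))},
        )
        pred = treatment_predictions(d, "host")
        assert np.allclose(pred.draws, 33.9)

    def test_logit_link_midpoint(self):
        d = make_draws(
            intercept=np.zeros(1),
            variances={"host": np.ones(1)},
            effects={"host": (["oak"], np.zeros((1, 1)))},
            family="binary-logit", response="survival",
        )
        d.levels["host"] = ("oak",)  # single-level ok for prediction math
        pred = treatment_predictions(d, "host")
        assert pred.draws[0, 0] == pytest.approx(0.5)

    def test_predictions_monotone_in_linear_predictor(self):
        rng = np.random.default_rng(1)
        hosts = [f"h{i}" for i in range(6)]
        eff = rng.standard_normal((40, 6))
        d = make_draws(
            intercept=rng.standard_normal(40),
            variances={"host": np.ones(40)},
            effects={"host": (hosts, eff)},
            family="binary-logit", response="survival",
        )
        pred = treatment_predictions(d, "host")
        eta = d.intercept()[:, None] + eff
        order_eta = np.argsort(eta, axis=1)
        order_pred = np.argsort(pred.draws, axis=1)
        assert (order_eta == order_pred).all()

    def test_survival_predictions_within_unit_interval(self, strong_fit):
        for level in ("host", "cell"):
            pred = treatment_predictions(strong_fit, level)
            assert (pred.draws >= 0.0).all() and (pred.draws <= 1.0).all()
            s = pred.summary()
            assert (s["lower"] <= s["mean"]).all()
            assert (s["mean"] <= s["upper"]).all()

    def test_cell_level_adds_population_terms(self):
        rng = np.random.default_rng(2)
        pops, hosts = ["A", "B"], ["x", "y"]
        eff = cell_effects(pops, hosts, rng, S=30)
        d = make_draws(
            intercept=np.zeros(30),
            variances={t: np.ones(30) for t in eff},
            effects=eff,
        )
        cell = treatment_predictions(d, "cell")
        j = cell.labels.index(("A", "y"))
        expected = (eff["population"][1][:, 0] + eff["host"][1][:, 1]
                    + eff["population:host"][1][:, 1])
        assert np.allclose(cell.draws[:, j], expected)

    def test_population_average_mode(self):
        rng = np.random.default_rng(3)
        pops, hosts = ["A", "B"], ["x", "y"]
        eff = cell_effects(pops, hosts, rng, S=30)
        d = make_draws(
            intercept=np.zeros(30),
            variances={t: np.ones(30) for t in eff},
            effects=eff,
        )
        marg = treatment_predictions(d, "host", population_mode="average")
        cell = treatment_predictions(d, "cell")
        jx = [cell.labels.index((p, "x")) for p in pops]
        assert np.allclose(marg.draws[:, 0], cell.draws[:, jx].mean(axis=1))

    def test_unknown_level_rejected(self, strong_fit):
        with pytest.raises(ValueError, match="level"):
            treatment_predictions(strong_fit, "brood")


class TestSummarizeModel:
    def test_constant_chain_summary(self):
        d = make_draws(np.full(30, 2.5), {"host": np.full(30, 1.0)}, {})
        s = summarize_model(d).set_index("term")
        assert s.loc["intercept", "mean"] == 2.5
        assert s.loc["intercept", "lower"] == s.loc["intercept", "upper"] == 2.5

    def test_one_row_per_term(self, strong_fit):
        s = summarize_model(strong_fit)
        assert set(s["term"]) == {"intercept", "var_host", "var_population",
                                  "var_population:host", "var_culture",
                                  "var_residual"}
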