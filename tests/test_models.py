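import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import consensus_arena as ca
from consensus_arena.models import ModelSpec, anova_type2, bh_adjust


def logistic_data(seed=0, n_groups=25, per=40, b0=-1.0, b1=0.7, sd_u=0.8):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), per)
    u = rng.normal(0, sd_u, n_groups)
    x = rng.normal(size=n_groups * per)
    y = (rng.uniform(size=len(x)) < expit(b0 + b1 * x + u[g])).astype(int)
    return pd.DataFrame({"y": y, "x": x, "g": [f"g{i}" for i in g]})


class TestFitModel:
    def test_exact_linear_recovery(self):
        x = np.arange(20.0)
        df = pd.DataFrame({"y": 2 * x + 1, "x": x})
        fit = ca.fit_model(df, ModelSpec("y", ("x",), (),
                                         family="gaussian_identity"))
        assert fit.params["Intercept"] == pytest.approx(1.0, abs=1e-8)
        assert fit.params["x"] == pytest.approx(2.0, abs=1e-10)
        assert fit.scale == pytest.approx(0.0, abs=1e-12)

    def test_intercept_only_logit_of_half(self):
        df = pd.DataFrame({"y": [0, 1] * 50})
        fit = ca.fit_model(df, ModelSpec("y", ()))
        assert fit.params["Intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_zero_variance_groups_match_plain_glm(self):
        # response independent of the grouping: estimated variance ~ 0 and
        # coefficients equal to the ordinary GLM fit
        df = logistic_data(seed=2, sd_u=0.0)
        mixed = ca.fit_model(df, ModelSpec("y", ("x",), ("g",)))
        plain = ca.fit_model(df, ModelSpec("y", ("x",)))
        assert mixed.vc["g"] < 1e-3
        assert np.allclose(mixed.params, plain.params, rtol=1e-4, atol=1e-5)

    def test_binomial_requires_01_response(self):
        df = pd.DataFrame({"y": [0.0, 0.5, 1.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="0/1"):
            ca.fit_model(df, ModelSpec("y", ("x",)))

    def test_singular_design_rejected(self):
        df = pd.DataFrame({"y": [0, 1, 0, 1], "x": [1.0, 2.0, 3.0, 4.0]})
        df["x2"] = 2 * df["x"]
        with pytest.raises(ValueError, match="singular"):
            ca.fit_model(df, ModelSpec("y", ("x", "x2")))

    def test_incomplete_rows_dropped(self):
        df = logistic_data(seed=3)
        df.loc[:9, "x"] = np.nan
        fit = ca.fit_model(df, ModelSpec("y", ("x",), ("g",)))
        assert fit.n_dropped == 10

    def test_gaussian_mixed_recovers_group_variance(self):
        rng = np.random.default_rng(5)
        g = np.repeat(np.arange(40), 10)
        u = rng.normal(0, 2.0, 40)
        x = rng.normal(size=400)
        y = 1.0 + 0.5 * x + u[g] + rng.normal(0, 1.0, 400)
        df = pd.DataFrame({"y": y, "x": x, "g": [f"g{i}" for i in g]})
        fit = ca.fit_model(df, ModelSpec("y", ("x",), ("g",),
                                         family="gaussian_identity"))
        assert fit.converged and not fit.fallback
        assert fit.params["x"] == pytest.approx(0.5, abs=0.15)
        assert fit.vc["g"] == pytest.approx(4.0, rel=0.5)


def test_glmm_matches_lme4_glmer(tmp_path):
    """The Laplace logistic mixed fit reproduces lme4::glmer (nAGQ=1)."""
    df = logistic_data(seed=3)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- glmer(y ~ x + (1|g), data=d, family=binomial)
        co <- summary(m)$coefficients
        cat(co[,1], co[,2], as.data.frame(VarCorr(m))$vcov,
            as.numeric(logLik(m)), sep="\\n")
    """)
    res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert res.returncode == 0, res.stderr
    b0, b1, se0, se1, vc, ll = (float(v) for v in res.stdout.split())
    fit = ca.fit_model(df, ModelSpec("y", ("x",), ("g",)))
    assert fit.params["Intercept"] == pytest.approx(b0, rel=6e-3)
    assert fit.params["x"] == pytest.approx(b1, rel=6e-3)
    assert fit.vc["g"] == pytest.approx(vc, rel=0.02)
    assert fit.loglike == pytest.approx(ll, abs=0.01)
    assert fit.bse["x"] == pytest.approx(se1, rel=0.02)


class TestAnovaType2:
    def test_wald_identity_single_predictor(self):
        df = logistic_data(seed=4)
        fit = ca.fit_model(df, ModelSpec("y", ("x",), ("g",)))
        an = anova_type2(fit)
        z = fit.params["x"] / fit.bse["x"]
        assert an.loc[an.term == "x", "df"].iloc[0] == 1
        assert an.loc[an.term == "x", "chi2"].iloc[0] == \
            pytest.approx(z ** 2, rel=1e-3)

    def test_balanced_design_type2_equals_type3(self):
        # one 3-level factor, balanced: the Type II refit equals the Wald
        # test on the sum-coded full model (Type III convention)
        rng = np.random.default_rng(6)
        lev = np.repeat(["a", "b", "c"], 40)
        y = rng.normal(0, 1, 120) + np.repeat([0.0, 0.5, 1.0], 40)
        df = pd.DataFrame({"y": y, "f": lev})
        spec = ModelSpec("y", ("f",), (), family="gaussian_identity")
        an = anova_type2(ca.fit_model(df, spec))
        fit3 = ca.fit_model(df, spec, coding="sum")
        sl = slice(1, 3)
        b = fit3.params.to_numpy()[sl]
        V = fit3.cov_params.to_numpy()[sl, sl]
        chi3 = b @ np.linalg.solve(V, b)
        assert an["chi2"].iloc[0] == pytest.approx(chi3, rel=1e-8)

    def test_matches_car_anova_type2_wald(self, tmp_path):
        """Cross-check against car::Anova on a fixed-effects GLM."""
        rng = np.random.default_rng(8)
        n = 300
        f = rng.choice(["a", "b", "c"], n)
        x = rng.normal(size=n)
        eta = -0.5 + 0.8 * x + (f == "b") * 0.5 + (f == "c") * 1.0
        y = (rng.uniform(size=n) < expit(eta)).astype(int)
        df = pd.DataFrame({"y": y, "x": x, "f": f})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        # main effects are tested in the model without the interaction
        # (the Type II refit convention); the interaction in the full model
        script = textwrap.dedent(f"""
            suppressMessages(library(car))
            d <- read.csv("{csv}")
            m2 <- glm(y ~ x + f, data=d, family=binomial)
            m <- glm(y ~ x + f + x:f, data=d, family=binomial)
            a2 <- Anova(m2, type=2, test.statistic="Wald")
            a <- Anova(m, type=2, test.statistic="Wald")
            cat(a2["x","Chisq"], a2["f","Chisq"], a["x:f","Chisq"], sep="\\n")
        """)
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        ref = dict(zip(["x", "f", "x:f"],
                       (float(v) for v in res.stdout.split())))
        spec = ModelSpec("y", ("x", "f", "x:f"))
        an = anova_type2(ca.fit_model(df, spec)).set_index("term")
        for term in ["x", "f", "x:f"]:
            assert an.loc[term, "chi2"] == pytest.approx(ref[term], rel=1e-4)


class TestBHAdjust:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.04], [0.03, 0.03, 0.04]),
        ([0.2], [0.2]),
        ([0.3, 0.3, 0.3], [0.3, 0.3, 0.3]),
    ])
    def test_hand_computations(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    def test_order_preserving_and_bounds(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=25)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in the order stats
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEmmPairwise:
    def test_balanced_two_level_equals_cell_mean_difference(self):
        rng = np.random.default_rng(10)
        f = np.repeat(["a", "b"], 50)
        y = rng.normal(0, 1, 100) + (f == "b") * 1.5
        df = pd.DataFrame({"y": y, "f": f})
        fit = ca.fit_model(df, ModelSpec("y", ("f",), (),
                                         family="gaussian_identity"))
        out = ca.emm_pairwise(fit, "f")
        diff = df[df.f == "a"].y.mean() - df[df.f == "b"].y.mean()
        assert out["estimate"].iloc[0] == pytest.approx(diff, abs=1e-10)

    def test_three_levels_three_contrasts(self):
        rng = np.random.default_rng(11)
        f = np.repeat(["a", "b", "c"], 30)
        df = pd.DataFrame({"y": rng.normal(size=90), "f": f})
        fit = ca.fit_model(df, ModelSpec("y", ("f",), (),
                                         family="gaussian_identity"))
        out = ca.emm_pairwise(fit, "f")
        assert len(out) == 3
        assert (out["p_adj"] >= out["p"] - 1e-12).all()

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "f": ["a", "a"]})
        fit = ca.fit_model(df, ModelSpec("y", (), (),
                                         family="gaussian_identity"))
        with pytest.raises(ValueError):
            ca.emm_pairwise(fit, "f")


class TestPredictedCurve:
    def make_fit(self):
        rng = np.random.default_rng(12)
        ds = rng.integers(-7, 8, 4000).astype(float)
        y = (rng.uniform(size=4000) < expit(-2.0 + 0.4 * ds)).astype(int)
        df = pd.DataFrame({"switch": y, "delta_social": ds,
                           "participant_id": rng.integers(0, 40, 4000)})
        return ca.fit_model(df, ModelSpec("switch", ("delta_social",),
                                          ("participant_id",)))

    def test_positive_coefficient_strictly_increasing(self):
        fit = self.make_fit()
        curve = ca.predicted_switch_curve(fit, np.arange(-10, 11))
        assert (np.diff(curve["probability"]) > 0).all()

    def test_value_at_zero_is_logistic_intercept(self):
        fit = self.make_fit()
        curve = ca.predicted_switch_curve(fit, [0.0])
        assert curve["probability"].iloc[0] == \
            pytest.approx(expit(fit.params["Intercept"]), rel=1e-9)

    def test_curve_tracks_generating_logistic(self):
        fit = self.make_fit()
        grid = np.arange(-7, 8)
        curve = ca.predicted_switch_curve(fit, grid)
        truth = expit(-2.0 + 0.4 * grid)
        assert np.abs(curve["probability"] - truth).max() < 0.05

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ca.predicted_switch_curve(self.make_fit(), [])
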