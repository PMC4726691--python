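import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ventdose import LMMData, aic_of, fit_lmm, predict, wald_inference
from conftest import toy_lmm_dataset

LOG2PI = np.log(2 * np.pi)


def dense_reml_m2l(X, y, groups, tau2, sigma2):
    """-2 REML log-likelihood from explicit dense matrices (oracle path)."""
    n, p = X.shape
    Z = pd.get_dummies(groups).to_numpy(float)
    V = sigma2 * np.eye(n) + tau2 * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_V = np.linalg.slogdet(V)
    _, ld_X = np.linalg.slogdet(XtViX)
    return ld_V + ld_X + r @ Vi @ r + (n - p) * LOG2PI, beta


def dense_reml_oracle(df, response="y", predictor="x"):
    """Maximize the dense REML criterion over (tau2, sigma2) from a grid."""
    X = np.column_stack([np.ones(len(df)), df[predictor]])
    y = df[response].to_numpy(float)
    groups = df["subject_id"]

    def m2l(params):
        t2, s2 = np.exp(params)
        return dense_reml_m2l(X, y, groups, t2, s2)[0]

    grid = [(lt, ls) for lt in np.linspace(-12, 3, 24) for ls in np.linspace(-6, 3, 16)]
    start = min(grid, key=lambda g: m2l(g))
    res = optimize.minimize(m2l, start, method="Nelder-Mead",
                            options=dict(xatol=1e-12, fatol=1e-14, maxiter=4000))
    tau2, sigma2 = np.exp(res.x)
    _, beta = dense_reml_m2l(X, y, groups, tau2, sigma2)
    return dict(tau2=tau2, sigma2=sigma2, beta=beta, m2l=res.fun)


class TestREMLAgainstOracles:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_grid_gls_oracle_on_toy_tables(self, seed):
        df = toy_lmm_dataset(seed)
        fit = fit_lmm(df, ["x"], response="y")
        oracle = dense_reml_oracle(df)
        assert fit.params.to_numpy() == pytest.approx(oracle["beta"], abs=1e-6)
        assert fit.sigma2 == pytest.approx(oracle["sigma2"], rel=1e-5, abs=1e-8)
        assert fit.tau2 == pytest.approx(oracle["tau2"], rel=1e-4, abs=1e-6)
        assert -2 * fit.reml_loglik == pytest.approx(oracle["m2l"], abs=1e-8)

    def test_matches_statsmodels_mixedlm(self, study):
        sm = pytest.importorskip("statsmodels.formula.api")
        table = study["table"]
        ours = fit_lmm(table, ["hr", "fb"])
        theirs = sm.mixedlm("ve_norm ~ hr + fb", table, groups=table["subject_id"]).fit(reml=True)
        assert ours.params.to_numpy() == pytest.approx(theirs.params.to_numpy()[:3], rel=1e-4)
        assert ours.sigma2 == pytest.approx(theirs.scale, rel=1e-3)
        assert ours.tau2 == pytest.approx(float(theirs.cov_re.iloc[0, 0]), rel=1e-2)

    def test_no_subject_effect_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            dict(
                subject_id=np.repeat([f"s{i}" for i in range(10)], 30),
                x=rng.normal(0, 1, 300),
            )
        )
        df["y"] = 2.0 + 0.8 * df["x"] + rng.normal(0, 0.5, 300)  # tau = 0 truth
        fit = fit_lmm(df, ["x"], response="y")
        X = np.column_stack([np.ones(300), df["x"]])
        ols = np.linalg.lstsq(X, df["y"], rcond=None)[0]
        assert fit.params.to_numpy() == pytest.approx(ols, abs=1e-6)


class TestAIC:
    def test_hand_computed_criterion_on_tiny_table(self):
        df = toy_lmm_dataset(3)
        fit = fit_lmm(df, ["x"], response="y")
        X = np.column_stack([np.ones(len(df)), df["x"]])
        m2l, _ = dense_reml_m2l(X, df["y"].to_numpy(), df["subject_id"], fit.tau2, fit.sigma2)
        assert fit.aic == pytest.approx(m2l + 2 * 2, abs=1e-8)
        assert aic_of(fit, "all") == pytest.approx(m2l + 2 * (2 + 2), abs=1e-8)

    def test_refit_is_deterministic(self):
        df = toy_lmm_dataset(4)
        assert fit_lmm(df, ["x"], response="y").aic == fit_lmm(df, ["x"], response="y").aic

    def test_pure_noise_predictor_changes_aic_little(self):
        """Under the null, adding a noise predictor moves AIC by < 4 almost always."""
        rng = np.random.default_rng(12)
        small_changes = 0
        for _ in range(100):
            df = pd.DataFrame(
                dict(
                    subject_id=np.repeat([f"s{i}" for i in range(15)], 20),
                    x1=rng.normal(0, 1, 300),
                    x2=rng.normal(0, 1, 300),
                )
            )
            b = np.repeat(rng.normal(0, 0.5, 15), 20)
            df["y"] = 1.0 + 0.5 * df["x1"] + b + rng.normal(0, 1.0, 300)
            data = LMMData(df, ["x1", "x2"], "y")
            delta = data.fit(["x1", "x2"]).aic - data.fit(["x1"]).aic
            small_changes += abs(delta) < 4.0
        assert small_changes >= 90


class TestInference:
    def test_zero_coefficient_gives_p_one(self):
        df = toy_lmm_dataset(6)
        fit = fit_lmm(df, ["x"], response="y")
        fit.params["x"] = 0.0
        out = wald_inference(fit)
        assert out.loc["x", "pvalue"] == pytest.approx(1.0)

    def test_pvalues_fall_as_noise_shrinks(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 120)
        b = np.repeat(rng.normal(0, 0.3, 6), 20)
        eps = rng.normal(0, 1, 120)
        pvals = []
        for sigma in (1.0, 0.5, 0.25):
            df = pd.DataFrame(
                dict(subject_id=np.repeat([f"s{i}" for i in range(6)], 20), x=x)
            )
            df["y"] = 1.0 + 0.3 * x + b + sigma * eps
            pvals.append(fit_lmm(df, ["x"], response="y").pvalues["x"])
        assert pvals[0] > pvals[1] > pvals[2]

    def test_confidence_intervals_bracket_estimates(self):
        df = toy_lmm_dataset(8)
        fit = fit_lmm(df, ["x"], response="y")
        assert (fit.ci_lower <= fit.params).all() and (fit.params <= fit.ci_upper).all()


class TestFitProperties:
    def test_response_scaling(self):
        df = toy_lmm_dataset(10, n_subjects=5, n_per=8)
        base = fit_lmm(df, ["x"], response="y")
        doubled = fit_lmm(df.assign(y=2 * df["y"]), ["x"], response="y")
        assert doubled.params.to_numpy() == pytest.approx(2 * base.params.to_numpy(), rel=1e-6)
        assert doubled.sigma2 == pytest.approx(4 * base.sigma2, rel=1e-6)

    def test_invariant_to_row_order_and_relabeling(self):
        df = toy_lmm_dataset(11, n_subjects=6, n_per=6)
        base = fit_lmm(df, ["x"], response="y")
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["subject_id"] = shuffled["subject_id"].map(lambda s: "subj_" + s[::-1])
        again = fit_lmm(shuffled, ["x"], response="y")
        assert again.params.to_numpy() == pytest.approx(base.params.to_numpy(), abs=1e-8)
        assert again.tau2 == pytest.approx(base.tau2, abs=1e-8)

    def test_fev1_normalized_response_variant(self, study):
        """V̇E/FEV1 fits give slopes scaled up by roughly 1/(FEV1/FVC)."""
        fvc_fit = fit_lmm(study["table"], ["hr", "fb"], response="ve_norm")
        fev1_fit = fit_lmm(study["table"], ["hr", "fb"], response="ve_over_fev1")
        ratio = fev1_fit.params["hr"] / fvc_fit.params["hr"]
        assert 1.0 < ratio < 1.0 / 0.75  # mean FEV1/FVC is ~0.88

    def test_prediction_uses_fixed_effects_only(self):
        df = toy_lmm_dataset(12)
        fit = fit_lmm(df, ["x"], response="y")
        new = pd.DataFrame(dict(x=[0.0, 1.0]))
        got = predict(fit, new)
        want = fit.params["intercept"] + fit.params["x"] * new["x"].to_numpy()
        assert got == pytest.approx(want)


class TestErrors:
    def test_single_subject_rejected(self):
        df = toy_lmm_dataset(1, n_subjects=1)
        with pytest.raises(ValueError, match="two subjects"):
            fit_lmm(df, ["x"], response="y")

    def test_rank_deficient_design_names_columns(self):
        df = toy_lmm_dataset(2)
        df["x_dup"] = df["x"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_lmm(df, ["x", "x_dup"], response="y")

    def test_subject_with_single_observation_rejected(self):
        df = toy_lmm_dataset(2)
        extra = pd.DataFrame([dict(subject_id="lone", x=0.1, y=1.0)])
        with pytest.raises(ValueError, match="2 observations"):
            fit_lmm(pd.concat([df, extra], ignore_index=True), ["x"], response="y")
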