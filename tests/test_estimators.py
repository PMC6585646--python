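import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from simulelast import ModelSpec, PanelDataset, fe_2sls, fe_ols
from simulelast.estimators import EstimationError
from conftest import random_panel


def dummy_ols_oracle(frame, dep, regressors):
    """Independent oracle: OLS with explicit entity+period indicator columns."""
    rhs = " + ".join(regressors)
    fit = smf.ols(f"{dep} ~ {rhs} + C(entity) + C(period)", data=frame).fit()
    return {r: fit.params[r] for r in regressors}


def iv_ratio_oracle(frame):
    """Exactly-identified IV as a ratio of within-covariances."""
    f = frame.copy()
    for c in ("y", "x", "z"):
        fit = smf.ols(f"{c} ~ C(entity) + C(period)", data=f).fit()
        f[c + "_t"] = fit.resid
    return float(np.cov(f.y_t, f.z_t)[0, 1] / np.cov(f.x_t, f.z_t)[0, 1])


def projection_oracle(frame):
    """Generic 2SLS sandwich (R'PzR)^-1 R'Pz y with dummy-expanded design."""
    d_ent = pd.get_dummies(frame.entity, drop_first=True, dtype=float).to_numpy()
    d_per = pd.get_dummies(frame.period, drop_first=True, dtype=float).to_numpy()
    ones = np.ones((len(frame), 1))
    R = np.column_stack([frame.x, ones, d_ent, d_per])
    Z = np.column_stack([frame.z, ones, d_ent, d_per])
    y = frame.y.to_numpy()
    Pz = Z @ np.linalg.solve(Z.T @ Z, Z.T)
    b = np.linalg.solve(R.T @ Pz @ R, R.T @ Pz @ y)
    return float(b[0])


def test_exact_fit_zero_residuals(small_panel):
    frame = small_panel.frame.copy()
    frame["y"] = 2.0 * frame["x"]
    res = fe_ols(ModelSpec("y", controls=("x",)), small_panel.with_frame(frame))
    assert np.isclose(res.params["x"], 2.0, atol=1e-10)
    assert np.max(np.abs(res.residuals)) < 1e-10
    assert abs(res.residuals.mean()) < 1e-8


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_fe_ols_matches_dummy_oracle(seed):
    data = random_panel(seed, n_ent=6, n_per=5, missing=0.15)
    res = fe_ols(ModelSpec("y", controls=("x", "z")), data)
    oracle = dummy_ols_oracle(data.frame, "y", ["x", "z"])
    for k in oracle:
        assert abs(res.params[k] - oracle[k]) < 1e-8


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_fe_2sls_matches_both_oracles(seed):
    data = random_panel(seed, n_ent=8, n_per=6, missing=0.1)
    res = fe_2sls(ModelSpec("y", endogenous=("x",), instruments=("z",)), data)
    assert abs(res.params["x"] - iv_ratio_oracle(data.frame)) < 1e-8
    assert abs(res.params["x"] - projection_oracle(data.frame)) < 1e-8


def test_self_instrumented_2sls_equals_ols(small_panel):
    frame = small_panel.frame.copy()
    frame["x2"] = frame["x"]
    data = small_panel.with_frame(frame)
    iv = fe_2sls(ModelSpec("y", endogenous=("x",), instruments=("x2",)), data)
    ols = fe_ols(ModelSpec("y", controls=("x",)), data)
    assert abs(iv.params["x"] - ols.params["x"]) < 1e-10


def test_2sls_invariant_to_instrument_rescaling(small_panel):
    frame = small_panel.frame.copy()
    base = fe_2sls(ModelSpec("y", endogenous=("x",), instruments=("z",)), small_panel)
    frame["z"] = -73.5 * frame["z"]
    scaled = fe_2sls(
        ModelSpec("y", endogenous=("x",), instruments=("z",)), small_panel.with_frame(frame)
    )
    assert np.isclose(base.params["x"], scaled.params["x"], atol=1e-10)


def test_reduced_form_equals_first_stage_times_2sls(small_panel):
    res = fe_2sls(ModelSpec("y", endogenous=("x",), instruments=("z",)), small_panel)
    lhs = res.reduced_form.params["z"]
    rhs = res.first_stage.params["z"] * res.params["x"]
    assert abs(lhs - rhs) < 1e-8


def test_rank_deficiency_names_collinear_column(small_panel):
    frame = small_panel.frame.copy()
    frame["x_dup"] = 2.0 * frame["x"]
    with pytest.raises(EstimationError, match="collinear"):
        fe_ols(ModelSpec("y", controls=("x", "x_dup")), small_panel.with_frame(frame))


def test_zero_within_variance_instrument_errors(small_panel):
    frame = small_panel.frame.copy()
    frame["zc"] = frame.groupby("entity")["z"].transform("mean")  # entity-constant
    with pytest.raises(EstimationError, match="within-variance|collinear"):
        fe_2sls(ModelSpec("y", endogenous=("x",), instruments=("zc",)),
                small_panel.with_frame(frame))


def test_role_overlap_and_order_condition_rejected():
    with pytest.raises(EstimationError, match="two roles"):
        ModelSpec("y", endogenous=("x",), instruments=("x",))
    with pytest.raises(EstimationError, match="under-identified"):
        ModelSpec("y", endogenous=("x", "w"), instruments=("z",))


class TestVcov:
    def test_single_cluster_errors(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({
            "entity": ["A"] * 8 + ["B"] * 8,
            "period": list(range(8)) * 2,
            "y": rng.standard_normal(16),
            "x": rng.standard_normal(16),
        })
        from simulelast.estimators import estimate_vcov

        X = frame[["x"]].to_numpy()
        with pytest.raises(EstimationError, match="2 clusters"):
            estimate_vcov(X, frame.y.to_numpy(), np.zeros(16, dtype=int),
                          "cluster_entity", n_absorbed=1)

    def test_cluster_matches_score_sum_oracle(self):
        data = random_panel(seed=40, n_ent=4, n_per=6)
        res = fe_ols(ModelSpec("y", controls=("x",), vcov="cluster_entity"), data)
        # brute force: within-transform by dummy regression, sum scores per entity
        frame = data.frame.copy()
        xt = smf.ols("x ~ C(entity) + C(period)", data=frame).fit().resid.to_numpy()
        e = res.residuals.to_numpy()
        bread = 1.0 / float(xt @ xt)
        scores = pd.Series(xt * e).groupby(frame.entity.to_numpy()).sum().to_numpy()
        G = 4
        meat = float(scores @ scores)
        V = (G / (G - 1)) * bread * meat * bread
        assert np.isclose(res.vcov.loc["x", "x"], V, rtol=1e-6)

    def test_robust_close_to_classical_under_homoskedasticity(self):
        data = random_panel(seed=50, n_ent=500, n_per=10)
        rob = fe_ols(ModelSpec("y", controls=("x",), vcov="robust"), data)
        cla = fe_ols(ModelSpec("y", controls=("x",), vcov="classical"), data)
        se_r, se_c = rob.std_errors["x"], cla.std_errors["x"]
        assert abs(se_r - se_c) / se_c < 0.15

    def test_vcov_psd_and_se_consistency(self, sim_panel):
        res = fe_2sls(
            ModelSpec("log_pharma", endogenous=("log_gdp",), instruments=("log_tourism",)),
            sim_panel,
        )
        eigs = np.linalg.eigvalsh(res.vcov.to_numpy())
        assert eigs.min() > -1e-12
        for k, se in res.std_errors.items():
            assert np.isclose(se, np.sqrt(res.vcov.loc[k, k]))


def test_iv_within_r2_can_be_negative():
    # weak instrument + endogeneity can drive the IV within-R^2 negative;
    # the fit must report it unclipped
    rng = np.random.default_rng(8)
    rows = []
    for i in range(30):
        for t in range(6):
            e = rng.standard_normal()
            z = rng.standard_normal()
            x = 0.6 * z + e + 0.3 * rng.standard_normal()
            y = 0.5 * x - 2.0 * e
            rows.append({"entity": f"E{i}", "period": t, "y": y, "x": x, "z": z})
    data = PanelDataset(pd.DataFrame(rows))
    res = fe_2sls(ModelSpec("y", endogenous=("x",), instruments=("z",)), data)
    assert res.r_squared < 0
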