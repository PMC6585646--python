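"""Instrument and specification diagnostics.

The four statistics reported alongside every IV fit in applied panel work:

* first-stage F — Wald test that the excluded instruments jointly predict the
  endogenous regressor (weak-instrument screen, rule-of-thumb threshold 10);
* rank LM — score test of underidentification: is the partial correlation
  between the within-partialled endogenous regressor and the instruments
  zero?  With the classical flavor it reduces to the Anderson
  canonical-correlation LM = n * r^2; with robust/clustered weighting it is
  the heteroskedasticity-consistent score form in the Kleibergen-Paap
  tradition;
* Hausman FE-vs-RE — contrast of the fixed-effects and feasible-GLS
  random-effects slope estimates;
* Durbin-Wu-Hausman endogeneity test — control-function form: significance of
  the first-stage residual added to the structural equation.

Scope: one endogenous regressor, k >= 1 instruments (every specification in
the motivating application is exactly identified, so no overidentification
J test exists here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EstimationError,
    EstimationResult,
    ModelSpec,
    _absorbed_count,
    _estimation_frame,
    estimate_vcov,
)
from .panel import PanelDataset
from .transforms import FixedEffectsStructure, demean_matrix


@dataclass
class TestResult:
    statistic: float
    p_value: float
    dof: int
    name: str
    note: str = ""

    def to_dict(self) -> dict:
        d = {"statistic": float(self.statistic), "p_value": float(self.p_value), "dof": self.dof}
        if self.note:
            d["note"] = self.note
        return d


@dataclass
class DiagnosticsReport:
    first_stage_F: TestResult
    rank_LM: TestResult
    hausman: TestResult | None
    endogeneity: TestResult

    def to_dict(self) -> dict:
        out = {
            "First stage F-stat": self.first_stage_F.to_dict(),
            "Rank LM statistic": self.rank_LM.to_dict(),
            "Endogeneity test": self.endogeneity.to_dict(),
        }
        if self.hausman is not None:
            out["Hausman test statistic"] = self.hausman.to_dict()
        return out


# ------------------------------------------------------------------ helpers


def _partial_out(M: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Residualize columns of M on W (both already demeaned)."""
    if W.size == 0 or W.shape[1] == 0:
        return M
    coef, *_ = np.linalg.lstsq(W, M, rcond=None)
    return M - W @ coef


def _spec_arrays(spec: ModelSpec, data: PanelDataset):
    frame = _estimation_frame(spec, data)
    sub = PanelDataset(frame, entity_col=data.entity_col, period_col=data.period_col)
    ent, ent_lab = sub.entity_codes()
    per, per_lab = sub.period_codes()
    cols = [spec.dependent, *spec.endogenous, *spec.instruments, *spec.controls]
    dm = demean_matrix(frame[cols].to_numpy(dtype=float), ent, per, fe=spec.fe)
    k_en, k_z = len(spec.endogenous), len(spec.instruments)
    y = dm[:, 0]
    X = dm[:, 1 : 1 + k_en]
    Z = dm[:, 1 + k_en : 1 + k_en + k_z]
    W = dm[:, 1 + k_en + k_z :]
    n_abs = _absorbed_count(spec.fe, len(ent_lab), len(per_lab))
    return frame, ent, per, y, X, Z, W, n_abs, len(ent_lab), len(per_lab)


# --------------------------------------------------------------- statistics


def first_stage_F(first_stage: EstimationResult, instruments: list[str] | tuple[str, ...]) -> TestResult:
    """Wald F that all excluded-instrument coefficients are zero.

    Uses the first stage's own variance flavor; with a single instrument the
    statistic is exactly the squared t-statistic of that instrument.
    """
    instruments = list(instruments)
    b = np.array([first_stage.params[z] for z in instruments])
    V = first_stage.vcov.loc[instruments, instruments].to_numpy()
    q = len(instruments)
    F = float(b @ np.linalg.solve(V, b)) / q
    p = float(stats.f.sf(F, q, first_stage.df_resid))
    return TestResult(F, p, q, "first_stage_F")


def rank_LM_test(spec: ModelSpec, data: PanelDataset, flavor: str | None = None) -> TestResult:
    """Underidentification score test.

    After partialling controls (and absorbed effects) out of the endogenous
    regressor x and the instruments z, the moment vector g_i = z_i * x_i has
    zero mean iff the model is unidentified.  The statistic is
    n * gbar' S^{-1} gbar with S the flavor-matched covariance of g; under
    the classical flavor this equals n * R^2 of x on z (Anderson LM,
    n * r^2 for a single instrument).  dof = #instruments - #endogenous + 1.
    """
    if len(spec.endogenous) != 1:
        raise NotImplementedError("rank LM implemented for exactly one endogenous regressor")
    flavor = flavor or spec.vcov
    frame, ent, per, y, X, Z, W, n_abs, n_ent, n_per = _spec_arrays(spec, data)
    n = len(y)
    x = _partial_out(X, W)[:, 0]
    Zp = _partial_out(Z, W)
    dof = Z.shape[1] - 1 + 1

    if flavor == "classical":
        # R^2 of x on partialled instruments
        coef, *_ = np.linalg.lstsq(Zp, x, rcond=None)
        resid = x - Zp @ coef
        r2 = 1.0 - float(resid @ resid) / float(x @ x)
        lm = n * r2
    else:
        g = Zp * x[:, None]  # n x k moment contributions
        gbar = g.mean(axis=0)
        if flavor == "cluster_entity":
            _, inv = np.unique(ent, return_inverse=True)
            G = inv.max() + 1
            sums = np.zeros((G, g.shape[1]))
            for j in range(g.shape[1]):
                sums[:, j] = np.bincount(inv, weights=g[:, j], minlength=G)
            S = sums.T @ sums / n
        else:  # robust
            S = g.T @ g / n
        # Var(gbar) ~ S/n, so the score statistic is gbar' (S/n)^{-1} gbar
        lm = float(gbar @ np.linalg.solve(S / n, gbar))
    p = float(stats.chi2.sf(lm, dof))
    return TestResult(float(lm), p, dof, "rank_LM", note=flavor)


def hausman_fe_re(spec: ModelSpec, data: PanelDataset) -> TestResult:
    """Hausman contrast of fixed-effects vs random-effects slopes.

    Both models include time indicator regressors when the spec absorbs time
    effects; the random-effects side is fitted by Swamy-Arora feasible GLS
    quasi-demeaning with the entity variance component truncated at zero.
    The contrast runs over the time-varying slopes (endogenous + controls)
    only, with classical variance matrices as the test requires an efficient
    estimator under the null.  A non-invertible variance difference falls
    back to a pseudo-inverse, flagged in the note.
    """
    frame = _estimation_frame(spec, data)
    sub = PanelDataset(frame, entity_col=data.entity_col, period_col=data.period_col)
    ent, ent_lab = sub.entity_codes()
    per, per_lab = sub.period_codes()
    names = [*spec.endogenous, *spec.controls]
    if not names:
        raise EstimationError("hausman test needs at least one slope regressor")
    y_raw = frame[spec.dependent].to_numpy(dtype=float)
    X_raw = frame[list(names)].to_numpy(dtype=float)
    n = len(y_raw)
    n_ent, n_per = len(ent_lab), len(per_lab)

    # time indicators (drop first) if the spec has time effects
    if spec.fe.time_effects and n_per > 1:
        D = np.zeros((n, n_per - 1))
        for t in range(1, n_per):
            D[:, t - 1] = (per == t).astype(float)
    else:
        D = np.zeros((n, 0))

    # ---- FE: within (entity) transform of y, X, D
    def ent_demean(M):
        out = M.astype(float).copy()
        counts = np.bincount(ent, minlength=n_ent).astype(float)
        for j in range(out.shape[1]):
            mm = np.bincount(ent, weights=out[:, j], minlength=n_ent) / counts
            out[:, j] -= mm[ent]
        return out

    yw = ent_demean(y_raw[:, None])[:, 0]
    Xw = ent_demean(np.column_stack([X_raw, D]))
    k_all = Xw.shape[1]
    XtX = Xw.T @ Xw
    b_fe = np.linalg.solve(XtX, Xw.T @ yw)
    e_fe = yw - Xw @ b_fe
    df_fe = n - n_ent - k_all
    s2_e = float(e_fe @ e_fe) / df_fe
    V_fe = s2_e * np.linalg.inv(XtX)

    # ---- variance components (Swamy-Arora flavor)
    counts = np.bincount(ent, minlength=n_ent).astype(float)
    ybar = np.bincount(ent, weights=y_raw, minlength=n_ent) / counts
    Xbar = np.column_stack(
        [np.bincount(ent, weights=c, minlength=n_ent) / counts
         for c in np.column_stack([X_raw, D]).T]
    )
    Xb1 = np.column_stack([np.ones(n_ent), Xbar])
    bb, *_ = np.linalg.lstsq(Xb1, ybar, rcond=None)
    eb = ybar - Xb1 @ bb
    df_b = max(n_ent - Xb1.shape[1], 1)
    Tbar = stats.hmean(counts)
    s2_between = float(eb @ eb) / df_b
    s2_alpha = max(s2_between - s2_e / Tbar, 0.0)

    # ---- RE: quasi-demeaning with entity-specific theta
    theta = 1.0 - np.sqrt(s2_e / (counts * s2_alpha + s2_e))
    th = theta[ent]
    ones = np.ones((n, 1))
    Xfull = np.column_stack([ones, X_raw, D])

    def quasi(M):
        out = M.astype(float).copy()
        for j in range(out.shape[1]):
            mm = np.bincount(ent, weights=out[:, j], minlength=n_ent) / counts
            out[:, j] -= th * mm[ent]
        return out

    yq = quasi(y_raw[:, None])[:, 0]
    Xq = quasi(Xfull)
    XtXq = Xq.T @ Xq
    b_re = np.linalg.solve(XtXq, Xq.T @ yq)
    e_re = yq - Xq @ b_re
    df_re = n - Xq.shape[1]
    s2_re = float(e_re @ e_re) / df_re
    V_re = s2_re * np.linalg.inv(XtXq)

    # contrast over the named slopes only
    k = len(names)
    idx_fe = np.arange(k)           # FE design: [slopes, time dummies]
    idx_re = np.arange(1, k + 1)    # RE design: [const, slopes, time dummies]
    d = b_fe[idx_fe] - b_re[idx_re]
    Vd = V_fe[np.ix_(idx_fe, idx_fe)] - V_re[np.ix_(idx_re, idx_re)]
    note = ""
    try:
        H = float(d @ np.linalg.solve(Vd, d))
        if H < 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        H = float(d @ np.linalg.pinv(Vd) @ d)
        H = abs(H)
        note = "pseudo-inverse used (variance difference not positive definite)"
    p = float(stats.chi2.sf(H, k))
    return TestResult(H, p, k, "hausman_fe_re", note=note)


def endogeneity_test(spec: ModelSpec, data: PanelDataset, flavor: str | None = None) -> TestResult:
    """Durbin-Wu-Hausman regressor-exogeneity test, control-function form.

    The first-stage residual of the endogenous regressor (on instruments and
    controls, effects absorbed) is added to the structural equation estimated
    by FE-OLS; the statistic is the flavor-matched Wald test of its
    coefficient, chi-square with 1 dof.  Insignificance says least squares
    and IV estimate the same parameter.
    """
    if len(spec.endogenous) != 1:
        raise NotImplementedError("endogeneity test implemented for one endogenous regressor")
    flavor = flavor or spec.vcov
    frame, ent, per, y, X, Z, W, n_abs, n_ent, n_per = _spec_arrays(spec, data)
    x = X[:, 0]
    ZW = np.column_stack([Z, W]) if W.shape[1] else Z
    coef, *_ = np.linalg.lstsq(ZW, x, rcond=None)
    vhat = x - ZW @ coef

    design = np.column_stack([x, W, vhat]) if W.shape[1] else np.column_stack([x, vhat])
    XtX = design.T @ design
    b = np.linalg.solve(XtX, design.T @ y)
    resid = y - design @ b
    V = estimate_vcov(design, resid, ent, flavor, n_abs, bread=np.linalg.inv(XtX))
    j = design.shape[1] - 1  # vhat column
    stat = float(b[j] ** 2 / V[j, j])
    p = float(stats.chi2.sf(stat, 1))
    return TestResult(stat, p, 1, "endogeneity_DWH", note=flavor)


def full_diagnostics(
    spec: ModelSpec,
    data: PanelDataset,
    result: EstimationResult | None = None,
    hausman: bool = True,
) -> DiagnosticsReport:
    """Compute the standard four-test report for an IV specification."""
    from .estimators import fe_2sls

    if result is None or result.first_stage is None:
        result = fe_2sls(spec, data)
    fsf = first_stage_F(result.first_stage, list(spec.instruments))
    lm = rank_LM_test(spec, data)
    dwh = endogeneity_test(spec, data)
    hm = None
    if hausman:
        try:
            hm = hausman_fe_re(spec, data)
        except EstimationError:
            hm = None
    return DiagnosticsReport(first_stage_F=fsf, rank_LM=lm, hausman=hm, endogeneity=dwh)
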