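"""Fixed-effects regression engines.

Two-way fixed-effects OLS and fixed-effects two-stage least squares (2SLS)
with first-stage and reduced-form byproducts, plus classical, HC1-robust and
entity-clustered variance estimation.  All fits absorb entity/time effects by
within-transformation (iterated demeaning on unbalanced panels) and count the
absorbed effects in the degrees of freedom.

The 2SLS estimator is the generic projection form: with regressors R (the
endogenous variable plus exogenous controls) and full instrument set
Z = (excluded instruments, controls), all within-transformed,

    b = (R' Pz R)^{-1} R' Pz y,   Pz = Z (Z'Z)^{-1} Z',

with residuals e = y - R b computed from the ACTUAL endogenous values so that
variance estimates are consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .panel import PanelDataset, PanelError
from .transforms import TWO_WAY, FixedEffectsStructure, demean_matrix

VCOV_FLAVORS = ("classical", "robust", "cluster_entity")


class EstimationError(ValueError):
    pass


@dataclass
class ModelSpec:
    """Declarative description of one regression.

    ``dependent`` is the outcome; ``endogenous`` regressors are instrumented
    by ``instruments`` (order condition: at least as many instruments as
    endogenous regressors); ``controls`` enter both stages as exogenous
    regressors.  For a plain FE-OLS fit leave ``endogenous`` empty and put
    every regressor in ``controls``.
    """

    dependent: str
    endogenous: tuple[str, ...] = ()
    instruments: tuple[str, ...] = ()
    controls: tuple[str, ...] = ()
    fe: FixedEffectsStructure = TWO_WAY
    vcov: str = "cluster_entity"

    def __post_init__(self) -> None:
        self.endogenous = tuple(self.endogenous)
        self.instruments = tuple(self.instruments)
        self.controls = tuple(self.controls)
        if self.vcov not in VCOV_FLAVORS:
            raise EstimationError(f"unknown vcov flavor {self.vcov!r}; expected {VCOV_FLAVORS}")
        if self.endogenous and len(self.instruments) < len(self.endogenous):
            raise EstimationError(
                "under-identified: need at least as many instruments as endogenous regressors"
            )
        roles: list[str] = [self.dependent, *self.endogenous, *self.instruments, *self.controls]
        seen: set[str] = set()
        for name in roles:
            if name in seen:
                raise EstimationError(f"variable {name!r} appears in two roles")
            seen.add(name)

    @property
    def all_columns(self) -> tuple[str, ...]:
        return (self.dependent, *self.endogenous, *self.instruments, *self.controls)

    def validate(self, data: PanelDataset) -> None:
        data.require_columns(self.all_columns)


@dataclass
class EstimationResult:
    """Coefficients, variance matrix, residuals and sample bookkeeping."""

    params: dict[str, float]
    vcov: pd.DataFrame
    residuals: pd.Series  # indexed like the estimation sample rows
    fitted: pd.Series
    n_obs: int
    n_entities: int
    n_periods: int
    df_resid: int
    r_squared: float  # within-R^2 (on demeaned data); negative allowed for IV
    r_squared_overall: float
    vcov_flavor: str = "cluster_entity"
    first_stage: "EstimationResult | None" = None
    reduced_form: "EstimationResult | None" = None
    sample_index: pd.Index | None = None
    diagnostics: object | None = None

    @property
    def std_errors(self) -> dict[str, float]:
        return {k: float(np.sqrt(self.vcov.loc[k, k])) for k in self.params}

    @property
    def tstats(self) -> dict[str, float]:
        se = self.std_errors
        return {k: self.params[k] / se[k] for k in self.params}

    def conf_int(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2)
        se = self.std_errors
        return {k: (self.params[k] - z * se[k], self.params[k] + z * se[k]) for k in self.params}

    def to_dict(self) -> dict:
        out = {
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "std_errors": {k: float(v) for k, v in self.std_errors.items()},
            "n_obs": self.n_obs,
            "n_entities": self.n_entities,
            "r_squared_within": float(self.r_squared),
            "r_squared_overall": float(self.r_squared_overall),
            "vcov_flavor": self.vcov_flavor,
        }
        if self.diagnostics is not None and hasattr(self.diagnostics, "to_dict"):
            out["diagnostics"] = self.diagnostics.to_dict()
        return out


# --------------------------------------------------------------------- guts


def _estimation_frame(spec: ModelSpec, data: PanelDataset) -> pd.DataFrame:
    """Listwise-complete sample over every column the spec references."""
    spec.validate(data)
    cols = [data.entity_col, data.period_col, *spec.all_columns]
    frame = data.frame[cols].dropna(subset=list(spec.all_columns)).reset_index(drop=True)
    return frame


def _absorbed_count(fe: FixedEffectsStructure, n_ent: int, n_per: int) -> int:
    if fe.entity_effects and fe.time_effects:
        return (n_ent - 1) + (n_per - 1) + 1
    if fe.entity_effects:
        return n_ent
    if fe.time_effects:
        return n_per
    return 1  # grand mean


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[1] == 0:
        return
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # QR with pivoting to point at the culprit columns
        _, _, piv = linalg.qr(X, pivoting=True, mode="economic")
        bad = [names[j] for j in piv[r:]]
        raise EstimationError(f"rank-deficient design after demeaning; collinear: {bad}")


def estimate_vcov(
    design: np.ndarray,
    residuals: np.ndarray,
    entity_codes: np.ndarray,
    flavor: str,
    n_absorbed: int,
    bread: np.ndarray | None = None,
) -> np.ndarray:
    """Variance matrix for a (possibly instrumented) least-squares fit.

    ``design`` is the effective regressor matrix (fitted values for 2SLS),
    ``residuals`` the structural residuals.  ``bread`` defaults to
    (design'design)^{-1}.  Flavors: ``classical`` sigma^2 * bread with
    absorbed-effects dof; ``robust`` HC1 sandwich; ``cluster_entity``
    entity-clustered sandwich with the G/(G-1) small-sample correction.
    """
    n, k = design.shape
    k_eff = k + n_absorbed
    df = n - k_eff
    if df <= 0:
        raise EstimationError(f"non-positive residual dof ({n} obs, {k_eff} parameters)")
    if bread is None:
        bread = np.linalg.inv(design.T @ design)

    if flavor == "classical":
        sigma2 = float(residuals @ residuals) / df
        return sigma2 * bread
    if flavor == "robust":
        Xe = design * residuals[:, None]
        meat = Xe.T @ Xe
        return (n / df) * bread @ meat @ bread
    if flavor == "cluster_entity":
        G = len(np.unique(entity_codes))
        if G < 2:
            raise EstimationError("entity-clustered vcov needs at least 2 clusters")
        Xe = design * residuals[:, None]
        scores = np.zeros((G, k))
        _, inv = np.unique(entity_codes, return_inverse=True)
        for j in range(k):
            scores[:, j] = np.bincount(inv, weights=Xe[:, j], minlength=G)
        meat = scores.T @ scores
        c = G / (G - 1)
        return c * bread @ meat @ bread
    raise EstimationError(f"unknown vcov flavor {flavor!r}")


def _wrap_result(
    names: Sequence[str],
    beta: np.ndarray,
    V: np.ndarray,
    resid: np.ndarray,
    fitted: np.ndarray,
    y_dm: np.ndarray,
    y_raw: np.ndarray,
    frame: pd.DataFrame,
    n_ent: int,
    n_per: int,
    df_resid: int,
    flavor: str,
) -> EstimationResult:
    rss = float(resid @ resid)
    tss_within = float(y_dm @ y_dm)
    tss_overall = float(((y_raw - y_raw.mean()) ** 2).sum())
    return EstimationResult(
        params={nm: float(b) for nm, b in zip(names, beta)},
        vcov=pd.DataFrame(V, index=list(names), columns=list(names)),
        residuals=pd.Series(resid, index=frame.index),
        fitted=pd.Series(fitted, index=frame.index),
        n_obs=len(frame),
        n_entities=n_ent,
        n_periods=n_per,
        df_resid=df_resid,
        r_squared=1.0 - rss / tss_within if tss_within > 0 else np.nan,
        r_squared_overall=1.0 - rss / tss_overall if tss_overall > 0 else np.nan,
        vcov_flavor=flavor,
        sample_index=frame.index,
    )


def fe_ols(spec: ModelSpec, data: PanelDataset) -> EstimationResult:
    """Fixed-effects OLS (no instrumenting): regress dependent on controls."""
    if spec.endogenous:
        raise EstimationError("fe_ols requires a spec with no endogenous regressors")
    frame = _estimation_frame(spec, data)
    names = list(spec.controls)
    if not names:
        raise EstimationError("fe_ols needs at least one regressor in controls")
    sub = PanelDataset(frame, entity_col=data.entity_col, period_col=data.period_col)
    ent, ent_lab = sub.entity_codes()
    per, per_lab = sub.period_codes()

    raw = frame[[spec.dependent, *names]].to_numpy(dtype=float)
    dm = demean_matrix(raw, ent, per, fe=spec.fe)
    y_dm, X = dm[:, 0], dm[:, 1:]
    _check_rank(X, names)

    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y_dm)
    fitted = X @ beta
    resid = y_dm - fitted
    n_abs = _absorbed_count(spec.fe, len(ent_lab), len(per_lab))
    df = len(frame) - len(names) - n_abs
    V = estimate_vcov(X, resid, ent, spec.vcov, n_abs, bread=np.linalg.inv(XtX))
    return _wrap_result(
        names, beta, V, resid, fitted, y_dm, raw[:, 0], frame,
        len(ent_lab), len(per_lab), df, spec.vcov,
    )


def _ols_on_demeaned(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
    y_raw: np.ndarray,
    frame: pd.DataFrame,
    ent: np.ndarray,
    n_ent: int,
    n_per: int,
    n_abs: int,
    flavor: str,
) -> EstimationResult:
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    fitted = X @ beta
    resid = y - fitted
    df = len(y) - X.shape[1] - n_abs
    V = estimate_vcov(X, resid, ent, flavor, n_abs, bread=np.linalg.inv(XtX))
    return _wrap_result(
        names, beta, V, resid, fitted, y, y_raw, frame, n_ent, n_per, df, flavor
    )


def fe_2sls(spec: ModelSpec, data: PanelDataset) -> EstimationResult:
    """Fixed-effects 2SLS with stored first-stage and reduced-form fits."""
    if not spec.endogenous:
        raise EstimationError("fe_2sls requires at least one endogenous regressor")
    frame = _estimation_frame(spec, data)
    sub = PanelDataset(frame, entity_col=data.entity_col, period_col=data.period_col)
    ent, ent_lab = sub.entity_codes()
    per, per_lab = sub.period_codes()

    endog = list(spec.endogenous)
    instr = list(spec.instruments)
    ctrl = list(spec.controls)
    cols = [spec.dependent, *endog, *instr, *ctrl]
    raw = frame[cols].to_numpy(dtype=float)
    dm = demean_matrix(raw, ent, per, fe=spec.fe)

    y = dm[:, 0]
    Xen = dm[:, 1 : 1 + len(endog)]
    Zex = dm[:, 1 + len(endog) : 1 + len(endog) + len(instr)]
    W = dm[:, 1 + len(endog) + len(instr) :]

    for j, nm in enumerate(instr):
        if float(Zex[:, j] @ Zex[:, j]) <= 1e-14 * len(y):
            raise EstimationError(f"instrument {nm!r} has zero within-variance")

    R = np.column_stack([Xen, W]) if ctrl else Xen
    Z = np.column_stack([Zex, W]) if ctrl else Zex
    r_names = endog + ctrl
    z_names = instr + ctrl
    _check_rank(Z, z_names)

    # projection of R on the instrument space
    ZtZ_inv = np.linalg.inv(Z.T @ Z)
    Rhat = Z @ (ZtZ_inv @ (Z.T @ R))
    A = R.T @ Rhat  # == Rhat'Rhat
    _check_rank(Rhat, r_names)
    beta = np.linalg.solve(A, Rhat.T @ y)
    fitted = R @ beta  # actual regressors
    resid = y - fitted

    n_abs = _absorbed_count(spec.fe, len(ent_lab), len(per_lab))
    df = len(frame) - len(r_names) - n_abs
    bread = np.linalg.inv(A)
    V = estimate_vcov(Rhat, resid, ent, spec.vcov, n_abs, bread=bread)

    result = _wrap_result(
        r_names, beta, V, resid, fitted, y, raw[:, 0], frame,
        len(ent_lab), len(per_lab), df, spec.vcov,
    )
    # byproducts on the identical sample: first stage (per endogenous) and
    # reduced form, both OLS of the demeaned variable on excluded
    # instruments + controls
    first = _ols_on_demeaned(
        Xen[:, 0], Z, z_names, raw[:, 1], frame, ent,
        len(ent_lab), len(per_lab), n_abs, spec.vcov,
    )
    reduced = _ols_on_demeaned(
        y, Z, z_names, raw[:, 0], frame, ent,
        len(ent_lab), len(per_lab), n_abs, spec.vcov,
    )
    result.first_stage = first
    result.reduced_form = reduced
    return result
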