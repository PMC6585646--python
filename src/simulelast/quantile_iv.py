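"""Instrumental-variable quantile regression by inverse-quantile grid search.

For each candidate value b of the endogenous regressor's coefficient, a
standard quantile regression of (y - b * x) on the instrument, controls and
entity/time indicator regressors is fitted at quantile tau; the chosen b is
the grid point that makes the instrument most irrelevant (smallest absolute
t-ratio of the instrument coefficient).  Under correct specification the true
coefficient renders the instrument uninformative about the partialled
outcome, which is what the search exploits.

Fixed effects enter as indicator regressors (not within-demeaning, which is
invalid for quantiles); with short panels this carries the usual
incidental-parameter caveat, warned about when T < 15.

The inner quantile regressions are delegated to statsmodels' QuantReg
(interior-point / IRLS solution of the check-loss problem).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import EstimationError, ModelSpec, fe_2sls
from .panel import PanelDataset

log = logging.getLogger(__name__)


class GridBoundaryError(ValueError):
    """The objective is minimized at a grid endpoint; widen the grid."""


@dataclass
class QuantileResult:
    tau: float
    coefficient: float
    std_error: float
    grid: np.ndarray
    objective: np.ndarray  # squared instrument t-ratio per grid point

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "coefficient": float(self.coefficient),
            "std_error": float(self.std_error),
        }


def _design(spec: ModelSpec, data: PanelDataset) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    cols = list(spec.all_columns)
    frame = data.frame.dropna(subset=cols).reset_index(drop=True)
    y = frame[spec.dependent].to_numpy(float)
    x = frame[spec.endogenous[0]].to_numpy(float)
    z = frame[spec.instruments[0]].to_numpy(float)
    parts = [np.ones((len(frame), 1)), z[:, None]]
    names = ["const", spec.instruments[0]]
    for c in spec.controls:
        parts.append(frame[[c]].to_numpy(float))
        names.append(c)
    if spec.fe.entity_effects:
        d = pd.get_dummies(frame[data.entity_col], drop_first=True, dtype=float)
        parts.append(d.to_numpy())
        names += [f"ent_{c}" for c in d.columns]
    if spec.fe.time_effects:
        d = pd.get_dummies(frame[data.period_col], drop_first=True, dtype=float)
        parts.append(d.to_numpy())
        names += [f"per_{c}" for c in d.columns]
    X = np.column_stack(parts)
    return frame, y, x, z, X


def iv_quantile(
    spec: ModelSpec,
    data: PanelDataset,
    taus: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9),
    grid: np.ndarray | None = None,
    grid_halfwidth_se: float = 3.0,
    grid_points: int = 121,
) -> list[QuantileResult]:
    """IV quantile regression of the endogenous coefficient at each tau.

    ``grid`` defaults to the fixed-effects 2SLS point estimate +/- 3 of its
    standard errors, 121 points.  Raises :class:`GridBoundaryError` when the
    minimizer for any tau sits on the grid edge.
    """
    from statsmodels.regression.quantile_regression import QuantReg

    if len(spec.endogenous) != 1 or len(spec.instruments) != 1:
        raise EstimationError("iv_quantile needs exactly one endogenous regressor and one instrument")
    for t in taus:
        if not 0 < t < 1:
            raise ValueError(f"tau must lie in (0,1), got {t}")

    frame, y, x, z, X = _design(spec, data)
    n_periods = frame[data.period_col].nunique()
    if spec.fe.entity_effects and n_periods < 15:
        log.warning(
            "entity indicators with T=%d < 15 periods: quantile fixed-effects "
            "estimates carry incidental-parameter bias", n_periods,
        )

    if grid is None:
        anchor = fe_2sls(spec, data)
        b0 = anchor.params[spec.endogenous[0]]
        se0 = anchor.std_errors[spec.endogenous[0]]
        grid = np.linspace(b0 - grid_halfwidth_se * se0, b0 + grid_halfwidth_se * se0, grid_points)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3:
        raise ValueError("grid needs at least 3 points")

    zcol = 1  # instrument column index in X
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # QuantReg convergence chatter on dummies
        for tau in taus:
            tstats = np.empty(grid.size)
            gammas = np.empty(grid.size)
            gse = np.empty(grid.size)
            for i, b in enumerate(grid):
                fit = QuantReg(y - b * x, X).fit(q=tau)
                gammas[i] = fit.params[zcol]
                gse[i] = fit.bse[zcol]
                tstats[i] = (fit.params[zcol] / fit.bse[zcol]) ** 2
            j = int(np.argmin(tstats))
            if j in (0, grid.size - 1):
                raise GridBoundaryError(
                    f"tau={tau}: objective minimized at grid boundary b={grid[j]:.4g}; "
                    "widen the coefficient grid"
                )
            # delta-method SE: se(b) = se(gamma) / |d gamma / d b| at the solution
            dgdb = (gammas[j + 1] - gammas[j - 1]) / (grid[j + 1] - grid[j - 1])
            se_b = float(gse[j] / abs(dgdb)) if abs(dgdb) > 1e-12 else np.inf
            results.append(
                QuantileResult(
                    tau=tau, coefficient=float(grid[j]), std_error=se_b,
                    grid=grid.copy(), objective=tstats,
                )
            )
    return results
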