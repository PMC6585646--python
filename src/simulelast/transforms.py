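"""Deterministic panel transformations.

Natural-log transforms, two-way within-demeaning (the fixed-effects
"within transformation"), lag creation that never crosses entity boundaries,
and balanced-panel extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import PanelDataset, PanelError


class ConvergenceError(RuntimeError):
    """Iterated demeaning failed to reach tolerance; carries the residual."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"two-way demeaning did not converge after {iterations} iterations "
            f"(max abs change {residual:.3e})"
        )


@dataclass(frozen=True)
class FixedEffectsStructure:
    """Which additive effects are absorbed: entity (country) and/or time.

    Both flags false means a pooled model (only the grand mean is removed).
    """

    entity_effects: bool = True
    time_effects: bool = True

    @property
    def label(self) -> str:
        if self.entity_effects and self.time_effects:
            return "two-way"
        if self.entity_effects:
            return "entity"
        if self.time_effects:
            return "time"
        return "pooled"


TWO_WAY = FixedEffectsStructure(True, True)


def _group_demean_once(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Subtract group means in place; return max abs mean removed."""
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    worst = 0.0
    for j in range(values.shape[1]):
        sums = np.bincount(codes, weights=values[:, j], minlength=n_groups)
        means = sums / counts
        values[:, j] -= means[codes]
        worst = max(worst, float(np.max(np.abs(means))) if means.size else 0.0)
    return worst


def demean_matrix(
    values: np.ndarray,
    entity_codes: np.ndarray,
    period_codes: np.ndarray,
    fe: FixedEffectsStructure = TWO_WAY,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Within-transform a dense (n, k) matrix of complete cells.

    For two-way effects on an unbalanced panel the entity/period demeaning is
    alternated until the largest mean removed in a sweep falls below ``tol``
    (on a balanced panel a single sweep is exact).  Scale-aware: tolerance is
    relative to the initial column scale.
    """
    out = np.array(values, dtype=float, copy=True)
    if out.ndim == 1:
        out = out[:, None]
    scale = max(1.0, float(np.max(np.abs(out))) if out.size else 1.0)

    if not fe.entity_effects and not fe.time_effects:
        out -= out.mean(axis=0, keepdims=True)
        return out

    n_ent = int(entity_codes.max()) + 1 if fe.entity_effects else 0
    n_per = int(period_codes.max()) + 1 if fe.time_effects else 0

    if fe.entity_effects and not fe.time_effects:
        _group_demean_once(out, entity_codes, n_ent)
        return out
    if fe.time_effects and not fe.entity_effects:
        _group_demean_once(out, period_codes, n_per)
        return out

    for it in range(max_iter):
        w1 = _group_demean_once(out, entity_codes, n_ent)
        w2 = _group_demean_once(out, period_codes, n_per)
        if max(w1, w2) <= tol * scale:
            return out
    raise ConvergenceError(residual=max(w1, w2), iterations=max_iter)


def log_transform(data: PanelDataset, columns: Sequence[str]) -> PanelDataset:
    """Apply the natural logarithm to the given columns (missing propagates).

    Any nonpositive value is a hard error naming the offending (entity,
    period) cells: expenditure and income series must be strictly positive
    before logging, and silently coercing zeros would fabricate data.
    """
    data.require_columns(columns)
    frame = data.frame.copy()
    for c in columns:
        col = pd.to_numeric(frame[c], errors="coerce")
        bad = col.notna() & (col <= 0)
        if bad.any():
            cells = frame.loc[bad, [data.entity_col, data.period_col]].itertuples(
                index=False, name=None
            )
            raise PanelError(f"nonpositive values in {c!r} at cells {sorted(cells)}; cannot log")
        frame[c] = np.log(col)
    out = data.with_frame(frame)
    for c in columns:
        out.metadata[c] = f"log({data.metadata.get(c, c)})"
    return out


def within_transform(
    data: PanelDataset,
    columns: Sequence[str],
    fe: FixedEffectsStructure = TWO_WAY,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> PanelDataset:
    """Within-transform columns, absorbing entity and/or time effects.

    Each column is demeaned over its own non-missing cells, so missing values
    propagate untouched.  After the transform, entity means and period means
    of every column are below tolerance on its observed cells.
    """
    data.require_columns(columns)
    frame = data.frame.copy()
    ent, _ = data.entity_codes()
    per, _ = data.period_codes()
    for c in columns:
        col = pd.to_numeric(frame[c], errors="coerce").to_numpy(dtype=float)
        mask = np.isfinite(col)
        if mask.sum() == 0:
            continue
        sub_ent, _ = pd.factorize(ent[mask])
        sub_per, _ = pd.factorize(per[mask])
        col[mask] = demean_matrix(
            col[mask][:, None], sub_ent, sub_per, fe=fe, tol=tol, max_iter=max_iter
        )[:, 0]
        frame[c] = col
    return data.with_frame(frame)


def make_lags(data: PanelDataset, column: str, orders: Sequence[int]) -> PanelDataset:
    """Add calendar lags ``column_lag{k}`` shifted within entity.

    The lag at period t is the value at period t-k of the same entity; a gap
    year therefore breaks the lag chain (no interpolation), and lags never
    cross entity boundaries.  An order exceeding an entity's span simply
    yields all-missing cells for that entity.
    """
    data.require_columns([column])
    if any(k < 1 for k in orders):
        raise ValueError("lag orders must be >= 1")
    frame = data.frame.copy()
    for k in orders:
        shifted = frame[[data.entity_col, data.period_col, column]].copy()
        shifted[data.period_col] = shifted[data.period_col] + k
        shifted = shifted.rename(columns={column: f"{column}_lag{k}"})
        frame = frame.merge(shifted, on=[data.entity_col, data.period_col], how="left")
    return data.with_frame(frame)


def balance_panel(
    data: PanelDataset,
    first: int,
    last: int,
    columns: Sequence[str] | None = None,
) -> PanelDataset:
    """Keep entities observed (non-missing on ``columns``) in every period.

    ``columns`` defaults to all variable columns; a fitted specification
    should pass exactly the columns it references, since requiring balance on
    unused controls would discard information for no reason.
    """
    if first > last:
        raise ValueError("first period must not exceed last")
    cols = list(columns) if columns is not None else data.variables
    data.require_columns(cols)
    span = set(range(int(first), int(last) + 1))
    frame = data.frame
    in_span = frame[data.period_col].between(first, last)
    sub = frame.loc[in_span]
    complete = sub[cols].notna().all(axis=1) if cols else pd.Series(True, index=sub.index)
    good = sub.loc[complete]
    cover = good.groupby(data.entity_col)[data.period_col].agg(lambda s: set(s) >= span)
    keep = set(cover.index[cover])
    result = frame.loc[in_span & frame[data.entity_col].isin(keep)]
    if result.empty or len(keep) == 0:
        raise PanelError(f"no entity is fully observed over [{first}, {last}]")
    return data.with_frame(result.reset_index(drop=True))
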