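"""Long-format country-year panel container and delimited-text I/O.

The central object is :class:`PanelDataset`, a thin validated wrapper around a
:class:`pandas.DataFrame` in long format: one row per (entity, period) cell,
one column per variable.  Entities are country-like categorical labels and
periods are integer years.  Everything downstream (transforms, estimators,
the simulator) consumes and produces this type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ENTITY = "entity"
PERIOD = "period"


class PanelError(ValueError):
    """Raised when a panel violates a structural invariant."""


@dataclass
class VariableRole:
    """Binds a column name to the role it plays in a model."""

    name: str
    role: str  # dependent | endogenous | instrument | control | group | weight

    _ROLES = frozenset(
        {"dependent", "endogenous", "instrument", "control", "group", "weight"}
    )

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(self._ROLES)}")


class PanelDataset:
    """Validated long-format entity x period panel.

    Parameters
    ----------
    frame
        Long-format table with an entity column, an integer period column and
        any number of numeric variable columns.  Missing values are allowed in
        variable columns and are represented as NaN.
    metadata
        Optional map variable name -> free-text unit / description, carried
        along through transforms.

    Invariants enforced at construction: (entity, period) keys are unique,
    periods are integers, and at least two entities and two periods exist.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        metadata: Mapping[str, str] | None = None,
        entity_col: str = ENTITY,
        period_col: str = PERIOD,
    ) -> None:
        if entity_col not in frame.columns or period_col not in frame.columns:
            raise PanelError(
                f"frame must contain {entity_col!r} and {period_col!r} columns; "
                f"got {list(frame.columns)}"
            )
        frame = frame.copy()
        frame[entity_col] = frame[entity_col].astype(str)
        periods = pd.to_numeric(frame[period_col], errors="coerce")
        if periods.isna().any():
            bad = frame.index[periods.isna()].tolist()
            raise PanelError(f"non-numeric periods at rows {bad}")
        if not np.allclose(periods, np.round(periods)):
            raise PanelError("periods must be integers (annual panel)")
        frame[period_col] = periods.astype(np.int64)

        dup = frame.duplicated(subset=[entity_col, period_col], keep=False)
        if dup.any():
            keys = (
                frame.loc[dup, [entity_col, period_col]]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise PanelError(f"duplicate (entity, period) keys: {sorted(keys)}")

        frame = frame.sort_values([entity_col, period_col], kind="stable").reset_index(drop=True)
        if frame[entity_col].nunique() < 2:
            raise PanelError("panel needs at least 2 entities")
        if frame[period_col].nunique() < 2:
            raise PanelError("panel needs at least 2 periods")

        self._frame = frame
        self.entity_col = entity_col
        self.period_col = period_col
        self.metadata: dict[str, str] = dict(metadata or {})

    # ------------------------------------------------------------------ basic
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def variables(self) -> list[str]:
        return [c for c in self._frame.columns if c not in (self.entity_col, self.period_col)]

    @property
    def n_obs(self) -> int:
        return len(self._frame)

    @property
    def n_entities(self) -> int:
        return self._frame[self.entity_col].nunique()

    @property
    def n_periods(self) -> int:
        return self._frame[self.period_col].nunique()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PanelDataset({self.n_entities} entities x {self.n_periods} periods, "
            f"{self.n_obs} rows, variables={self.variables})"
        )

    def copy(self) -> "PanelDataset":
        return PanelDataset(
            self._frame.copy(),
            metadata=self.metadata,
            entity_col=self.entity_col,
            period_col=self.period_col,
        )

    def with_frame(self, frame: pd.DataFrame) -> "PanelDataset":
        """Re-wrap a derived frame, preserving metadata and column naming."""
        return PanelDataset(
            frame, metadata=self.metadata, entity_col=self.entity_col, period_col=self.period_col
        )

    def require_columns(self, columns: Iterable[str]) -> None:
        missing = [c for c in columns if c not in self._frame.columns]
        if missing:
            raise PanelError(f"columns not in panel: {missing}")

    def entity_codes(self) -> tuple[np.ndarray, pd.Index]:
        codes, uniques = pd.factorize(self._frame[self.entity_col], sort=True)
        return codes.astype(np.int64), uniques

    def period_codes(self) -> tuple[np.ndarray, pd.Index]:
        codes, uniques = pd.factorize(self._frame[self.period_col], sort=True)
        return codes.astype(np.int64), uniques

    # --------------------------------------------------------------------- io
    def to_csv(self, path: str | Path, delimiter: str = ",") -> None:
        self._frame.to_csv(path, sep=delimiter, index=False)


def read_panel(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    delimiter: str = ",",
    entity_col: str = ENTITY,
    period_col: str = PERIOD,
) -> PanelDataset:
    """Read a delimited long-format panel file.

    ``schema`` optionally maps column names to roles (dependent, endogenous,
    instrument, control, group, weight); every mapped column must exist.  Rows
    whose period fails to parse as an integer are dropped with their 1-based
    data row numbers reported via logging.

    Raises :class:`PanelError` on duplicate (entity, period) keys or missing
    mandatory columns.
    """
    frame = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    for col in (entity_col, period_col):
        if col not in frame.columns:
            raise PanelError(f"mandatory column {col!r} missing from {path}")
    if schema:
        for col, role in schema.items():
            VariableRole(col, role)  # validates the role label
            if col not in frame.columns:
                raise PanelError(f"schema column {col!r} (role {role}) missing from {path}")

    periods = pd.to_numeric(frame[period_col], errors="coerce")
    bad = periods.isna() | (periods != np.round(periods.fillna(0)))
    if bad.any():
        rows = (frame.index[bad] + 1).tolist()
        log.warning("dropping %d rows with unparseable periods (data rows %s)", bad.sum(), rows)
        frame = frame.loc[~bad]
    return PanelDataset(frame, entity_col=entity_col, period_col=period_col)


def write_panel(data: PanelDataset, path: str | Path, delimiter: str = ",") -> None:
    """Write a panel back to delimited text (header row, '.' decimals)."""
    data.to_csv(path, delimiter=delimiter)


def summarize_panel(data: PanelDataset, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-variable summary table: n (non-missing), mean, sd, min, max.

    Mirrors the descriptive-statistics table of a typical panel study; ``n``
    counts non-missing cells, never rows.
    """
    cols = list(columns) if columns is not None else data.variables
    data.require_columns(cols)
    rows = []
    for c in cols:
        s = pd.to_numeric(data.frame[c], errors="coerce")
        rows.append(
            {
                "variable": c,
                "n": int(s.notna().sum()),
                "mean": float(s.mean()),
                "sd": float(s.std(ddof=1)),
                "min": float(s.min()),
                "max": float(s.max()),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
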