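"""Two-step IV correction for simultaneity between income and expenditure.

Step 1 estimates the income elasticity beta of (log) expenditure y with
respect to (log) income x by fixed-effects 2SLS, instrumenting x with an
exogenous shifter z (tourist receipts in the motivating application).

Step 2 targets the reverse effect delta of expenditure on income.  Naive
least squares of x on y is contaminated by the very feedback Step 1
estimated, so an endogeneity-adjusted expenditure series

    y*_it = y_it - beta_hat * x_it

is constructed: the residual variation in expenditure not driven by income.
Using y* as the instrument for y in the income equation purges the
simultaneity and yields a consistent delta.

Because y* depends on the estimated beta_hat (a generated instrument), the
analytic step-2 standard errors ignore first-step sampling noise; a
pairs-cluster bootstrap that resamples entities and reruns the whole
procedure end-to-end is provided and reported alongside.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import DiagnosticsReport, full_diagnostics
from .estimators import EstimationError, EstimationResult, ModelSpec, fe_2sls
from .panel import PanelDataset
from .transforms import TWO_WAY, FixedEffectsStructure


class BootstrapError(RuntimeError):
    pass


@dataclass
class AdjustedSeries:
    """The endogeneity-adjusted expenditure series y* = y - beta_hat * x.

    Defined exactly on rows where both y and x are observed; carries the
    beta used and a fingerprint of the specification that produced it.
    """

    values: pd.Series
    beta_used: float
    source_fingerprint: str
    name: str = "adjusted_expenditure"

    @classmethod
    def fingerprint_of(cls, spec: ModelSpec, n_obs: int) -> str:
        payload = json.dumps(
            {
                "dependent": spec.dependent,
                "endogenous": spec.endogenous,
                "instruments": spec.instruments,
                "controls": spec.controls,
                "fe": spec.fe.label,
                "n_obs": n_obs,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class TwoStepResult:
    step1: EstimationResult
    adjusted: AdjustedSeries
    step2: EstimationResult
    bootstrap_se: dict[str, float] | None = None
    n_boot: int = 0
    n_boot_failed: int = 0
    seed: int | None = None
    diagnostics_step1: DiagnosticsReport | None = None
    diagnostics_step2: DiagnosticsReport | None = None

    def to_dict(self) -> dict:
        out = {
            "step1": self.step1.to_dict(),
            "step2": self.step2.to_dict(),
            "beta_used": float(self.adjusted.beta_used),
            "n_boot": self.n_boot,
            "n_boot_failed": self.n_boot_failed,
        }
        if self.bootstrap_se:
            out["bootstrap_se"] = {k: float(v) for k, v in self.bootstrap_se.items()}
        if self.diagnostics_step1:
            out["step1"]["diagnostics"] = self.diagnostics_step1.to_dict()
        if self.diagnostics_step2:
            out["step2"]["diagnostics"] = self.diagnostics_step2.to_dict()
        return out


def construct_adjusted_series(
    data: PanelDataset, beta: float, y: str, x: str, fingerprint: str = ""
) -> AdjustedSeries:
    """Compute y* = y - beta * x row-wise (missing in either input -> missing)."""
    data.require_columns([y, x])
    vals = data.frame[y].astype(float) - float(beta) * data.frame[x].astype(float)
    return AdjustedSeries(values=vals, beta_used=float(beta), source_fingerprint=fingerprint)


def run_step1(
    spec_eq1: ModelSpec, data: PanelDataset, diagnostics: bool = True
) -> EstimationResult:
    """Step-1 fixed-effects 2SLS of expenditure on instrumented income."""
    result = fe_2sls(spec_eq1, data)
    if diagnostics:
        result.diagnostics = full_diagnostics(spec_eq1, data, result=result)
    return result


def run_step2(
    spec_eq2: ModelSpec,
    data: PanelDataset,
    adjusted: AdjustedSeries,
    diagnostics: bool = False,
) -> EstimationResult:
    """Step-2 fixed-effects 2SLS of income on expenditure, instrumented by y*.

    ``spec_eq2.instruments`` must name a single placeholder column which is
    overwritten with the adjusted values, guaranteeing the invariant that the
    instrument column IS the adjusted series.
    """
    if len(spec_eq2.instruments) != 1:
        raise EstimationError("step 2 uses exactly one instrument: the adjusted series")
    iname = spec_eq2.instruments[0]
    frame = data.frame.copy()
    frame[iname] = adjusted.values.reindex(frame.index).to_numpy()
    data2 = data.with_frame(frame)
    result = fe_2sls(spec_eq2, data2)
    if diagnostics:
        result.diagnostics = full_diagnostics(spec_eq2, data2, result=result, hausman=False)
    return result


def two_step(
    data: PanelDataset,
    y: str,
    x: str,
    z: str,
    controls: tuple[str, ...] = (),
    fe: FixedEffectsStructure = TWO_WAY,
    vcov: str = "cluster_entity",
    n_boot: int = 0,
    seed: int | None = None,
    diagnostics: bool = False,
) -> TwoStepResult:
    """Run the full two-step procedure on one panel.

    beta_hat is estimated on the same listwise-complete sample that Step 2
    uses (rows observed on y, x, z and all controls), so the adjusted series
    and the step-2 fit share one sample by construction.
    """
    spec1 = ModelSpec(
        dependent=y, endogenous=(x,), instruments=(z,), controls=controls, fe=fe, vcov=vcov
    )
    step1 = run_step1(spec1, data, diagnostics=diagnostics)
    beta_hat = step1.params[x]
    fp = AdjustedSeries.fingerprint_of(spec1, step1.n_obs)
    adjusted = construct_adjusted_series(data, beta_hat, y=y, x=x, fingerprint=fp)

    iname = "_adjusted_expenditure"
    spec2 = ModelSpec(
        dependent=x, endogenous=(y,), instruments=(iname,), controls=controls, fe=fe, vcov=vcov
    )
    step2 = run_step2(spec2, data, adjusted, diagnostics=diagnostics)

    result = TwoStepResult(step1=step1, adjusted=adjusted, step2=step2, seed=seed)
    if diagnostics:
        result.diagnostics_step1 = step1.diagnostics
        result.diagnostics_step2 = step2.diagnostics
    if n_boot:
        if seed is None:
            raise ValueError("bootstrap requires an explicit seed")
        boot = bootstrap_twostep(
            data, y=y, x=x, z=z, controls=controls, fe=fe, vcov=vcov,
            n_boot=n_boot, seed=seed,
        )
        result.bootstrap_se = boot["se"]
        result.n_boot = n_boot
        result.n_boot_failed = boot["n_failed"]
    return result


def bootstrap_twostep(
    data: PanelDataset,
    y: str,
    x: str,
    z: str,
    controls: tuple[str, ...] = (),
    fe: FixedEffectsStructure = TWO_WAY,
    vcov: str = "cluster_entity",
    n_boot: int = 999,
    seed: int = 0,
) -> dict:
    """Pairs-cluster bootstrap of the two-step procedure.

    Entities are resampled with replacement (respecting within-country
    dependence); every replicate reruns Step 1, the adjusted-series
    construction and Step 2 end-to-end, so the generated-instrument noise is
    propagated into the reported SEs.  Replicates where either stage fails
    (rank deficiency, degenerate instrument) are dropped and counted; more
    than 20% failures aborts.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    frame = data.frame
    entities = np.sort(frame[data.entity_col].unique())
    groups = {e: g for e, g in frame.groupby(data.entity_col)}
    betas, deltas = [], []
    n_failed = 0
    for b in range(n_boot):
        draw = rng.choice(entities, size=len(entities), replace=True)
        parts = []
        for j, e in enumerate(draw):
            gpart = groups[e].copy()
            gpart[data.entity_col] = f"B{j:04d}"  # clones become distinct entities
            parts.append(gpart)
        bframe = pd.concat(parts, ignore_index=True)
        try:
            bdata = data.with_frame(bframe)
            res = two_step(
                bdata, y=y, x=x, z=z, controls=controls, fe=fe, vcov=vcov,
                n_boot=0, diagnostics=False,
            )
            betas.append(res.step1.params[x])
            deltas.append(res.step2.params[y])
        except (EstimationError, np.linalg.LinAlgError, ValueError):
            n_failed += 1
    if n_failed > 0.2 * n_boot:
        raise BootstrapError(
            f"{n_failed}/{n_boot} bootstrap replicates failed; sample too fragile"
        )
    betas = np.asarray(betas)
    deltas = np.asarray(deltas)
    se = {
        "beta": float(betas.std(ddof=1)),
        "delta": float(deltas.std(ddof=1)),
    }
    return {"se": se, "n_failed": n_failed, "betas": betas, "deltas": deltas}
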