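"""Counterfactual post-stratified effects (MRP-ATE) per covariate level.

For a focal covariate level, the contrast is fully counterfactual: the
post-stratified prevalence when every member of the target population is
assigned that level, minus the prevalence when everyone is assigned the
reference level, holding the joint distribution of all other covariates
fixed.  Computed per posterior draw, it yields a full posterior for each
contrast.  With the outcome coded as probability of *not* being health
literate, negative values are improvements.  These are predictive
comparisons — summaries of the fitted model's structure over the target
population — not identified causal effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError, SchemaError
from .frame import PostStratFrame
from .model import CellPredictions, poststratify
from .schema import CovariateSchema, IMD_VARIABLE

__all__ = [
    "InterventionSpec",
    "AteDraws",
    "AteSummary",
    "counterfactual_frame",
    "mrp_ate",
    "summarize_ate",
    "ate_table",
    "analytic_ate",
]


@dataclass(frozen=True)
class InterventionSpec:
    """A focal (variable, level) assignment contrasted with its reference."""

    variable: str
    level: str
    reference: str

    def __post_init__(self) -> None:
        if self.level == self.reference:
            raise SchemaError("treated level must differ from the reference")

    @classmethod
    def for_level(
        cls, schema: CovariateSchema, variable: str, level: str
    ) -> "InterventionSpec":
        var = schema[variable]
        var.code(level)  # validates membership
        return cls(variable=variable, level=level, reference=var.reference)


@dataclass(frozen=True)
class AteDraws:
    """Posterior draws of one contrast's difference in prevalence."""

    intervention: InterventionSpec
    outcome: str
    draws: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class AteSummary:
    mean: float
    lower95: float
    upper95: float

    def __post_init__(self) -> None:
        # tiny slack: the mean of identical draws can differ from the
        # quantiles in the last ulp
        eps = 1e-9 * max(1.0, abs(self.mean))
        if not (self.lower95 - eps <= self.mean <= self.upper95 + eps):
            raise DataError("summary must satisfy lower <= mean <= upper")


def counterfactual_frame(
    frame: PostStratFrame, variable: str, level: str
) -> PostStratFrame:
    """Move every stratum's weight onto ``variable = level``.

    Within each combination of the remaining covariates, all mass is
    transferred to the cell with the focal level, so total weight and the
    joint of the non-focal covariates are conserved exactly.
    """
    schema = frame.schema
    var = schema[variable]
    level_code = var.code(level)
    axis = schema.names.index(variable)
    arr = frame.as_array()
    collapsed = arr.sum(axis=axis, keepdims=True)
    new = np.zeros_like(arr)
    index = [slice(None)] * arr.ndim
    index[axis] = slice(level_code, level_code + 1)
    new[tuple(index)] = collapsed
    return PostStratFrame(frame.cell_index, new.reshape(-1))


def mrp_ate(
    preds: CellPredictions, frame: PostStratFrame, spec: InterventionSpec
) -> AteDraws:
    """Per-draw difference of the two counterfactual post-stratified prevalences.

    Computed in stratum-difference form — for each stratum of the non-focal
    covariates, weight times (prediction at the focal level minus prediction
    at the reference) — which is algebraically identical to differencing the
    two counterfactual :func:`poststratify` calls and returns an exact zero
    whenever the focal coefficient is zero in every draw.
    """
    schema = frame.schema
    if not preds.cell_index.same_as(frame.cell_index):
        raise AlignmentError("predictions and frame use different cell indexes")
    var = schema[spec.variable]
    axis = schema.names.index(spec.variable)
    shape = schema.level_counts()
    strata_w = frame.as_array().sum(axis=axis).reshape(-1)
    mat = preds.matrix.reshape(preds.matrix.shape[0], *shape)
    treated = np.take(mat, var.code(spec.level), axis=1 + axis)
    control = np.take(mat, var.code(spec.reference), axis=1 + axis)
    diff = (treated - control).reshape(preds.matrix.shape[0], -1)
    return AteDraws(intervention=spec, outcome="", draws=diff @ strata_w)


def summarize_ate(d: AteDraws, round_dp: int | None = None) -> AteSummary:
    """Posterior mean and equal-tailed 95% interval (linear-interpolation quantiles)."""
    if d.draws.size < 2:
        raise DataError("need at least two draws to summarise")
    mean = float(np.mean(d.draws))
    lo, hi = np.quantile(d.draws, [0.025, 0.975], method="linear")
    s = AteSummary(mean=mean, lower95=float(lo), upper95=float(hi))
    if round_dp is not None:
        s = AteSummary(
            mean=round(s.mean, round_dp),
            lower95=round(s.lower95, round_dp),
            upper95=round(s.upper95, round_dp),
        )
    return s


def ate_table(
    preds: CellPredictions,
    frame: PostStratFrame,
    outcome: str,
    round_dp: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All non-reference contrasts for one outcome.

    Returns ``(summary, draws)``: the reporting table (outcome, variable,
    level, mean, lower95, upper95) and a long per-draw table for ranking and
    forest plots.  IMD quintiles are contrasted against quintile 1 like any
    other covariate.
    """
    schema = frame.schema
    rows, draw_cols = [], {}
    for variable, level in schema.non_reference_pairs():
        spec = InterventionSpec.for_level(schema, variable, level)
        d = mrp_ate(preds, frame, spec)
        s = summarize_ate(d, round_dp=round_dp)
        rows.append(
            {
                "outcome": outcome,
                "variable": variable,
                "level": level,
                "mean": s.mean,
                "lower95": s.lower95,
                "upper95": s.upper95,
            }
        )
        draw_cols[(variable, level)] = d.draws
    summary = pd.DataFrame(rows)
    draws = pd.DataFrame(
        {f"{v}[{l}]": col for (v, l), col in draw_cols.items()}
    )
    return summary, draws


def analytic_ate(
    true_params,
    frame: PostStratFrame,
    spec: InterventionSpec,
) -> float:
    """Exact MRP-ATE under known generator parameters, by cell enumeration.

    Serves as the oracle for recovery tests: evaluates the true-parameter cell
    probabilities over both counterfactual frames and differences them.
    """
    schema = frame.schema

    def prevalence(f: PostStratFrame) -> float:
        eta = true_params.linear_predictor(f.cell_index.codes, schema)
        return float((1.0 / (1.0 + np.exp(-eta))) @ f.weights)

    return prevalence(
        counterfactual_frame(frame, spec.variable, spec.level)
    ) - prevalence(counterfactual_frame(frame, spec.variable, spec.reference))
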