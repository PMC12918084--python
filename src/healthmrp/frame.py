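"""Post-stratification frame construction for the target population.

The target frame assigns a population share ``w_c`` to every covariate cell
``c`` so that model predictions can be averaged as ``sum_c w_c * pi_c``.  No
single local source covers all covariates, so the frame is assembled from
blocks: a joint estimated directly from local microdata, a second joint from
national microdata raked (iterative proportional fitting) to local margins,
and an area-deprivation margin aggregated from an LSOA population table.
Blocks are combined under mutual independence, which is the frame-construction
assumption documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConvergenceError,
    DataError,
    InfeasibleMarginsError,
    SchemaError,
)
from .schema import IMD_VARIABLE, CellIndex, CovariateSchema, enumerate_cells

__all__ = [
    "JointTable",
    "MarginalTable",
    "PostStratFrame",
    "estimate_joint_from_microdata",
    "ipf_rake",
    "aggregate_imd",
    "combine_blocks",
]


@dataclass(frozen=True)
class JointTable:
    """Joint probability table over a subset of schema covariates.

    ``probs`` is an ndarray whose axes follow ``variables`` order, with axis
    sizes equal to the schema level counts; entries are nonnegative and sum
    to one.
    """

    schema: CovariateSchema
    variables: tuple[str, ...]
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        expected = tuple(self.schema[v].n_levels for v in self.variables)
        if self.probs.shape != expected:
            raise SchemaError(
                f"joint shape {self.probs.shape} does not match levels {expected}"
            )
        if np.any(self.probs < 0):
            raise DataError("joint probabilities must be nonnegative")
        if abs(float(self.probs.sum()) - 1.0) > 1e-9:
            raise DataError("joint probabilities must sum to 1 (tol 1e-9)")

    def margin(self, variable: str) -> "MarginalTable":
        """Marginal distribution of one of the joint's variables."""
        if variable not in self.variables:
            raise SchemaError(f"{variable!r} is not a dimension of this joint")
        axis = self.variables.index(variable)
        other = tuple(i for i in range(self.probs.ndim) if i != axis)
        return MarginalTable(
            schema=self.schema,
            variable=variable,
            proportions=self.probs.sum(axis=other),
        )

    def marginalise(self, variables: Sequence[str]) -> "JointTable":
        """Joint over a subset of this joint's variables."""
        keep = [self.variables.index(v) for v in variables]
        drop = tuple(i for i in range(self.probs.ndim) if i not in keep)
        probs = self.probs.sum(axis=drop)
        # reorder remaining axes to the requested order
        remaining = [v for v in self.variables if v in set(variables)]
        perm = [remaining.index(v) for v in variables]
        return JointTable(self.schema, tuple(variables), np.transpose(probs, perm))


@dataclass(frozen=True)
class MarginalTable:
    """Marginal distribution of a single covariate."""

    schema: CovariateSchema
    variable: str
    proportions: np.ndarray

    def __post_init__(self) -> None:
        var = self.schema[self.variable]
        if self.proportions.shape != (var.n_levels,):
            raise SchemaError(
                f"marginal for {self.variable!r} has wrong length "
                f"{self.proportions.shape}"
            )
        if np.any(self.proportions < 0):
            raise DataError("marginal proportions must be nonnegative")
        if abs(float(self.proportions.sum()) - 1.0) > 1e-9:
            raise DataError("marginal proportions must sum to 1 (tol 1e-9)")


@dataclass(frozen=True)
class PostStratFrame:
    """Cell weights over the full schema: ``w_c = N_c / N``, summing to one."""

    cell_index: CellIndex
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.weights.shape != (self.cell_index.n_cells,):
            raise AlignmentError("weight vector length must equal cell count")
        if np.any(self.weights < 0):
            raise DataError("frame weights must be nonnegative")
        if abs(float(self.weights.sum()) - 1.0) > 1e-12:
            raise DataError("frame weights must sum to 1 (tol 1e-12)")

    @property
    def schema(self) -> CovariateSchema:
        return self.cell_index.schema

    def as_array(self) -> np.ndarray:
        """Weights reshaped to one axis per covariate (declared order)."""
        return self.weights.reshape(self.schema.level_counts())

    def margin(self, variable: str) -> MarginalTable:
        axis = self.schema.names.index(variable)
        other = tuple(i for i in range(len(self.schema.names)) if i != axis)
        return MarginalTable(self.schema, variable, self.as_array().sum(axis=other))

    def joint(self, variables: Sequence[str]) -> JointTable:
        """Joint distribution of a covariate subset implied by the frame."""
        full = JointTable(self.schema, self.schema.names, self.as_array())
        return full.marginalise(variables)

    # ---- CSV interface -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cell_index.assignments(), columns=self.schema.names)
        df["weight"] = self.weights
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, schema: CovariateSchema) -> "PostStratFrame":
        df = pd.read_csv(path, dtype={n: str for n in schema.names},
                         float_precision="round_trip")
        index = enumerate_cells(schema)
        expected = pd.DataFrame(index.assignments(), columns=schema.names)
        if len(df) != index.n_cells or not df[list(schema.names)].equals(expected):
            raise SchemaError(f"{path}: rows do not enumerate the schema cells")
        return cls(index, df["weight"].to_numpy(dtype=float))


def estimate_joint_from_microdata(
    records: pd.DataFrame,
    schema: CovariateSchema,
    variables: Sequence[str],
    record_weights: np.ndarray | None = None,
) -> JointTable:
    """Estimate a joint distribution as (weighted) relative cell frequencies.

    Combinations absent from the microdata receive probability zero; such
    structural zeros are preserved by subsequent raking.

    Raises :class:`SchemaError` naming the record and variable on any value
    outside the schema.
    """
    variables = tuple(variables)
    if len(records) == 0:
        raise DataError("microdata table is empty")
    shape = tuple(schema[v].n_levels for v in variables)
    codes = np.empty((len(records), len(variables)), dtype=np.int64)
    for j, v in enumerate(variables):
        if v not in records.columns:
            raise SchemaError(f"microdata lacks column {v!r}")
        cat = pd.Categorical(
            records[v].astype(str), categories=list(schema[v].levels)
        )
        bad = np.flatnonzero(cat.codes == -1)
        if bad.size:
            raise SchemaError(
                f"record {records.index[bad[0]]}: value "
                f"{records[v].iloc[bad[0]]!r} is not a level of {v!r}"
            )
        codes[:, j] = cat.codes
    if record_weights is None:
        w = np.ones(len(records))
    else:
        w = np.asarray(record_weights, dtype=float)
        if w.shape != (len(records),) or np.any(w < 0):
            raise DataError("record_weights must be nonnegative, one per record")
    counts = np.zeros(shape)
    np.add.at(counts, tuple(codes.T), w)
    total = counts.sum()
    if total <= 0:
        raise DataError("total record weight is zero")
    return JointTable(schema, variables, counts / total)


def ipf_rake(
    seed: JointTable,
    targets: Sequence[MarginalTable],
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> JointTable:
    """Iterative proportional fitting (raking) of a seed joint to target margins.

    Cycles proportional adjustments over the targets, in the given order, until
    every fitted margin matches its target within ``tol`` (max absolute
    deviation, checked after each full cycle).  IPF preserves the seed's
    interaction structure: every conditional odds ratio of the seed carries
    over to the fitted table, and structural zeros remain zero.

    Raises :class:`InfeasibleMarginsError` when a target puts mass on a level
    whose seed margin is zero, and :class:`ConvergenceError` (reporting the
    final deviation) if ``max_iter`` cycles do not reach ``tol``.
    """
    axes = []
    for t in targets:
        if t.variable not in seed.variables:
            raise SchemaError(f"target {t.variable!r} is not a dimension of the seed")
        axes.append(seed.variables.index(t.variable))

    probs = seed.probs.astype(float).copy()
    ndim = probs.ndim
    for t, axis in zip(targets, axes):
        other = tuple(i for i in range(ndim) if i != axis)
        margin = probs.sum(axis=other)
        if np.any((t.proportions > 0) & (margin == 0)):
            raise InfeasibleMarginsError(
                f"target for {t.variable!r} puts mass on a level with zero seed margin"
            )

    def max_deviation(p: np.ndarray) -> float:
        dev = 0.0
        for t, axis in zip(targets, axes):
            other = tuple(i for i in range(ndim) if i != axis)
            dev = max(dev, float(np.abs(p.sum(axis=other) - t.proportions).max()))
        return dev

    for _ in range(max_iter):
        for t, axis in zip(targets, axes):
            other = tuple(i for i in range(ndim) if i != axis)
            margin = probs.sum(axis=other)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(margin > 0, t.proportions / np.maximum(margin, 1e-300), 0.0)
            shape = [1] * ndim
            shape[axis] = probs.shape[axis]
            probs = probs * ratio.reshape(shape)
        if max_deviation(probs) <= tol:
            probs = probs / probs.sum()
            return JointTable(seed.schema, seed.variables, probs)
    raise ConvergenceError(
        f"IPF did not converge in {max_iter} cycles "
        f"(final max margin deviation {max_deviation(probs):.3e})"
    )


def aggregate_imd(lsoa: pd.DataFrame, schema: CovariateSchema) -> MarginalTable:
    """Pool an LSOA decile population table into an IMD quintile margin.

    Quintile ``q`` pools deciles ``2q-1`` and ``2q`` (1 = most deprived);
    proportions are pooled population over total population.
    """
    required = {"lsoa_id", "imd_decile", "population"}
    if not required.issubset(lsoa.columns):
        raise DataError(f"LSOA table needs columns {sorted(required)}")
    if len(lsoa) == 0:
        raise DataError("LSOA table is empty")
    deciles = lsoa["imd_decile"].to_numpy(dtype=int)
    pops = lsoa["population"].to_numpy(dtype=float)
    if deciles.min() < 1 or deciles.max() > 10:
        raise DataError("imd_decile must lie in 1..10")
    if np.any(pops < 0):
        raise DataError("population must be nonnegative")
    total = pops.sum()
    if total <= 0:
        raise DataError("total LSOA population is zero")
    quintiles = (deciles + 1) // 2  # deciles {1,2}->1, ..., {9,10}->5
    pooled = np.bincount(quintiles - 1, weights=pops, minlength=5)[:5]
    return MarginalTable(schema, IMD_VARIABLE, pooled / total)


def combine_blocks(
    blocks: Sequence[JointTable | MarginalTable],
    schema: CovariateSchema,
) -> PostStratFrame:
    """Combine disjoint covariate blocks into a full frame under independence.

    Each cell's weight is the product of its block probabilities; marginalising
    the frame back to any block recovers that block exactly.  Blocks must
    partition the schema's covariates.
    """
    covered: list[str] = []
    joints: list[JointTable] = []
    for b in blocks:
        if isinstance(b, MarginalTable):
            b = JointTable(schema, (b.variable,), b.proportions)
        joints.append(b)
        covered.extend(b.variables)
    if len(set(covered)) != len(covered):
        dupes = sorted({v for v in covered if covered.count(v) > 1})
        raise SchemaError(f"blocks overlap on covariates {dupes}")
    missing = set(schema.names) - set(covered)
    if missing:
        raise SchemaError(f"blocks do not cover covariates {sorted(missing)}")

    names = list(schema.names)
    shape = schema.level_counts()
    arr = np.ones(shape)
    for b in joints:
        axes = [names.index(v) for v in b.variables]
        order = np.argsort(axes)
        probs = np.transpose(b.probs, order)
        sorted_axes = set(np.sort(axes))
        expand_shape = [shape[i] if i in sorted_axes else 1 for i in range(len(names))]
        arr = arr * probs.reshape(expand_shape)
    weights = arr.reshape(-1)
    weights = weights / weights.sum()
    return PostStratFrame(enumerate_cells(schema), weights)
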