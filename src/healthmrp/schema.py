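"""Categorical covariate schema and post-stratification cell enumeration.

Every stage of the pipeline (frame construction, model fitting, counterfactual
effects) is expressed over a shared :class:`CovariateSchema`: an ordered list
of named categorical covariates, each with ordered levels and a designated
reference level.  Reference levels are pinned to zero in the regression, so
every reported effect is a contrast against them.

The default schema mirrors the adult-skills survey covariates used for
health-literacy modelling in the UK: ten individual-level covariates plus an
area-deprivation quintile (IMD), giving 2^8 * 3 * 3 * 5 = 11,520 cells.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import SchemaError

__all__ = [
    "Covariate",
    "CovariateSchema",
    "CellIndex",
    "enumerate_cells",
    "default_schema",
    "IMD_VARIABLE",
    "RESIDENTS_BLOCK",
    "LFS_BLOCK",
]

#: Name of the area-deprivation covariate modelled as a random effect.
IMD_VARIABLE = "imd_quintile"

#: Covariates whose target-area joint distribution comes from resident-survey microdata.
RESIDENTS_BLOCK = ("age", "sex", "ethnicity", "working", "own_home")

#: Covariates whose joint comes from labour-force microdata raked to local margins.
LFS_BLOCK = ("english", "ukborn", "qualification", "income", "job")


@dataclass(frozen=True)
class Covariate:
    """One categorical covariate: ordered levels plus a reference level."""

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise SchemaError(f"covariate {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"covariate {self.name!r} has duplicate levels")
        if self.reference not in self.levels:
            raise SchemaError(
                f"reference {self.reference!r} not among levels of {self.name!r}"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def non_reference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)

    def code(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise SchemaError(
                f"{level!r} is not a level of covariate {self.name!r}"
            ) from None


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered collection of covariates defining the cell space."""

    variables: tuple[Covariate, ...]

    def __post_init__(self) -> None:
        if not self.variables:
            raise SchemaError("schema must contain at least one covariate")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("covariate names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def __getitem__(self, name: str) -> Covariate:
        for v in self.variables:
            if v.name == name:
                return v
        raise SchemaError(f"unknown covariate {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self.names

    @property
    def n_cells(self) -> int:
        return int(np.prod([v.n_levels for v in self.variables]))

    def level_counts(self) -> tuple[int, ...]:
        return tuple(v.n_levels for v in self.variables)

    def non_reference_pairs(
        self, exclude: Iterable[str] = ()
    ) -> list[tuple[str, str]]:
        """All (variable, level) contrasts against the reference, in order."""
        skip = set(exclude)
        return [
            (v.name, l)
            for v in self.variables
            if v.name not in skip
            for l in v.non_reference_levels()
        ]

    def subset(self, names: Sequence[str]) -> "CovariateSchema":
        return CovariateSchema(tuple(self[n] for n in names))

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variables": [
                {"name": v.name, "levels": list(v.levels), "reference": v.reference}
                for v in self.variables
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateSchema":
        try:
            variables = tuple(
                Covariate(e["name"], tuple(e["levels"]), e["reference"])
                for e in d["variables"]
            )
        except (KeyError, TypeError) as exc:
            raise SchemaError(f"malformed schema document: {exc}") from exc
        return cls(variables)

    @classmethod
    def from_file(cls, path: str | Path) -> "CovariateSchema":
        """Load from a YAML or JSON schema document."""
        text = Path(path).read_text()
        doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(doc)

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass(frozen=True)
class CellIndex:
    """Enumeration of all covariate-level combinations in a fixed order.

    Cells are ordered lexicographically by declared covariate order (row-major
    over the level codes), which matches a C-order flatten of any array shaped
    by :meth:`CovariateSchema.level_counts`.
    """

    schema: CovariateSchema
    codes: np.ndarray = field(repr=False)  # (n_cells, n_vars) int level codes

    @property
    def n_cells(self) -> int:
        return self.codes.shape[0]

    def assignments(self) -> list[tuple[str, ...]]:
        """Cell assignments as tuples of level labels, in cell order."""
        levels = [v.levels for v in self.schema.variables]
        return [
            tuple(levels[j][c] for j, c in enumerate(row)) for row in self.codes
        ]

    def ordinal(self, assignment: Sequence[str]) -> int:
        """Cell ordinal of one full assignment of level labels."""
        if len(assignment) != len(self.schema.variables):
            raise SchemaError("assignment length does not match schema")
        counts = self.schema.level_counts()
        idx = 0
        for j, (var, level) in enumerate(zip(self.schema.variables, assignment)):
            idx = idx * counts[j] + var.code(level)
        return idx

    def column(self, name: str) -> np.ndarray:
        """Level codes of one covariate across all cells."""
        j = self.schema.names.index(name) if name in self.schema else None
        if j is None:
            raise SchemaError(f"unknown covariate {name!r}")
        return self.codes[:, j]

    def same_as(self, other: "CellIndex") -> bool:
        return self.schema == other.schema and np.array_equal(self.codes, other.codes)


def enumerate_cells(schema: CovariateSchema) -> CellIndex:
    """Enumerate the full cartesian product of covariate levels.

    Ordering is deterministic: lexicographic in declared covariate order, with
    each covariate's declared level order.  The product over an 11-covariate
    schema with level counts (2,...,2,3,3,5) yields 11,520 cells.
    """
    counts = schema.level_counts()
    codes = np.array(
        list(itertools.product(*[range(c) for c in counts])), dtype=np.int64
    )
    return CellIndex(schema=schema, codes=codes)


def default_schema() -> CovariateSchema:
    """The 11-covariate schema used for the health-literacy analysis.

    Reference levels are the contrasts' baselines: age 16-44, female, non-white
    ethnicity, English not first language, not UK born, not owning home, not
    working, qualification at level 1 or below, income under 10k, higher
    (managerial/professional) job status, and most-deprived IMD quintile.
    """
    return CovariateSchema(
        (
            Covariate("age", ("16-44", "45+"), "16-44"),
            Covariate("sex", ("female", "male"), "female"),
            Covariate("ethnicity", ("non-white", "white"), "non-white"),
            Covariate("english", ("no", "yes"), "no"),
            Covariate("ukborn", ("no", "yes"), "no"),
            Covariate("own_home", ("no", "yes"), "no"),
            Covariate("working", ("no", "yes"), "no"),
            Covariate("qualification", ("<=level1", ">=level2"), "<=level1"),
            Covariate("income", ("<10k", ">=10k", "other"), "<10k"),
            Covariate("job", ("higher", "intermediate", "lower"), "higher"),
            Covariate(IMD_VARIABLE, ("1", "2", "3", "4", "5"), "1"),
        )
    )
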