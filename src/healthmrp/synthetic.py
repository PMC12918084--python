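"""Synthetic inputs drawn from a known multilevel logistic ground truth.

Real inputs to this pipeline are license-restricted (local resident-survey
microdata) or need a data-service download (national skills and labour-force
surveys), so every input has a synthetic counterpart generated here from a
known process:

* a source survey with 11 categorical covariates and three binary skill
  outcomes (literacy, numeracy, ICT) observed on nested subsamples, with each
  outcome generated from its own multilevel logistic parameters;
* target-area microdata over the resident-survey covariate block;
* labour-force-style microdata over the remaining covariate block, drawn from
  a deliberately non-local joint, together with the local margins that raking
  must reproduce;
* an LSOA table of deprivation deciles and population counts.

Default level frequencies mirror the source-vs-target contrast that motivates
post-stratification: the source population is mostly UK-born, white and
English-first-language, while the target population is young, diverse, mostly
renting, and concentrated in deprived-but-not-most-deprived IMD deciles.
All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import json
import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, SchemaError
from .frame import JointTable, MarginalTable
from .schema import (
    IMD_VARIABLE,
    LFS_BLOCK,
    RESIDENTS_BLOCK,
    CovariateSchema,
    default_schema,
)

__all__ = [
    "OUTCOMES",
    "GRADE_LADDER",
    "BINARY_THRESHOLDS",
    "TrueParams",
    "SourceSurvey",
    "SyntheticBundle",
    "tilted_joint",
    "grade_to_binary",
    "generate_source_survey",
    "generate_target_microdata",
    "generate_lfs_inputs",
    "generate_lsoa_table",
    "make_default_bundle",
    "default_true_params",
]

#: Outcome order also fixes subsample nesting (later outcomes are subsets).
OUTCOMES = ("literacy", "numeracy", "ict")

#: The five lowest national qualification-framework grades, ascending.
GRADE_LADDER = ("EL1", "EL2", "EL3", "L1", "L2plus")

#: Minimum grade counting as health literate, per outcome.
BINARY_THRESHOLDS = {"literacy": "L2plus", "numeracy": "L1", "ict": "EL3"}

#: Share of the source sample assessed for each outcome (nested subsets),
#: matching the 5818/4396/2274 of 7230 split of the source skills survey.
DEFAULT_SUBSAMPLE_FRACTIONS = {
    "literacy": 5818 / 7230,
    "numeracy": 4396 / 7230,
    "ict": 2274 / 7230,
}

#: Marginal level probabilities for the source survey (national-like).
SOURCE_LEVEL_PROBS: dict[str, tuple[float, ...]] = {
    "age": (0.54, 0.46),
    "sex": (0.57, 0.43),
    "ethnicity": (0.11, 0.89),
    "english": (0.08, 0.92),
    "ukborn": (0.12, 0.88),
    "own_home": (0.41, 0.59),
    "working": (0.32, 0.68),
    "qualification": (0.31, 0.69),
    "income": (0.14, 0.39, 0.47),
    "job": (0.38, 0.10, 0.52),
    IMD_VARIABLE: (0.21, 0.22, 0.20, 0.19, 0.18),
}

#: Marginal level probabilities for the target borough population.
TARGET_LEVEL_PROBS: dict[str, tuple[float, ...]] = {
    "age": (0.64, 0.36),
    "sex": (0.46, 0.54),
    "ethnicity": (0.70, 0.30),
    "english": (0.35, 0.65),
    "ukborn": (0.54, 0.46),
    "own_home": (0.65, 0.35),
    "working": (0.35, 0.65),
    "qualification": (0.43, 0.57),
    "income": (0.10, 0.85, 0.05),
    "job": (0.17, 0.28, 0.55),
}

#: Decile mix for the target borough's LSOAs: mass concentrated in deciles 2-4.
TARGET_DECILE_PROBS = (0.04, 0.34, 0.30, 0.20, 0.06, 0.03, 0.015, 0.01, 0.004, 0.001)


def tilted_joint(
    schema: CovariateSchema,
    variables: Sequence[str],
    margins: Mapping[str, Sequence[float]],
    tilt: float = 0.0,
) -> JointTable:
    """Build a block joint from margins with an optional pairwise association.

    ``tilt = 0`` gives the independence product of the margins.  A nonzero
    tilt multiplies each cell by ``exp(tilt * sum_{j<k} s_j s_k)`` where
    ``s`` is the level code rescaled to [-0.5, 0.5], then renormalises — a
    simple log-odds association knob that leaves structural support intact.
    (The resulting margins differ slightly from the inputs when tilted; they
    are the generator's truth, not a raking target.)
    """
    variables = tuple(variables)
    mats = []
    for v in variables:
        p = np.asarray(margins[v], dtype=float)
        if p.shape != (schema[v].n_levels,) or np.any(p < 0):
            raise ConfigError(f"bad margin for {v!r}")
        mats.append(p / p.sum())
    probs = mats[0]
    for p in mats[1:]:
        probs = np.multiply.outer(probs, p)
    if tilt != 0.0:
        scores = [
            np.arange(schema[v].n_levels) / (schema[v].n_levels - 1) - 0.5
            for v in variables
        ]
        grids = np.meshgrid(*scores, indexing="ij")
        inter = np.zeros_like(probs)
        for j in range(len(grids)):
            for k in range(j + 1, len(grids)):
                inter = inter + grids[j] * grids[k]
        probs = probs * np.exp(tilt * inter)
    probs = probs / probs.sum()
    return JointTable(schema, variables, probs)


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth multilevel logistic parameters for one outcome.

    The linear predictor for an individual is
    ``intercept + sum_x beta_x[level_x] + imd_effects[quintile]`` with
    reference levels fixed at zero; ``imd_effects`` are the five total
    quintile effects, nominally drawn from N(imd_mu, imd_sigma^2).
    """

    intercept: float
    fixed_effects: Mapping[tuple[str, str], float]
    imd_mu: float = 0.0
    imd_sigma: float = 0.2
    imd_effects: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.imd_sigma < 0:
            raise ConfigError("imd_sigma must be nonnegative")
        if len(self.imd_effects) != 5:
            raise ConfigError("imd_effects must cover 5 quintiles")

    def effect(self, variable: str, level: str, schema: CovariateSchema) -> float:
        if level == schema[variable].reference:
            return 0.0
        return float(self.fixed_effects.get((variable, level), 0.0))

    def linear_predictor(
        self, codes: np.ndarray, schema: CovariateSchema
    ) -> np.ndarray:
        """Vectorised eta for rows of level codes aligned to schema order."""
        eta = np.full(codes.shape[0], self.intercept)
        for j, var in enumerate(schema.variables):
            if var.name == IMD_VARIABLE:
                eta += np.asarray(self.imd_effects)[codes[:, j]]
            else:
                per_level = np.array(
                    [self.effect(var.name, l, schema) for l in var.levels]
                )
                eta += per_level[codes[:, j]]
        return eta

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "fixed_effects": {f"{v}={l}": b for (v, l), b in self.fixed_effects.items()},
            "imd_mu": self.imd_mu,
            "imd_sigma": self.imd_sigma,
            "imd_effects": list(self.imd_effects),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueParams":
        fe = {
            tuple(k.split("=", 1)): float(v) for k, v in d["fixed_effects"].items()
        }
        return cls(
            intercept=float(d["intercept"]),
            fixed_effects=fe,
            imd_mu=float(d["imd_mu"]),
            imd_sigma=float(d["imd_sigma"]),
            imd_effects=tuple(d["imd_effects"]),
        )


def default_true_params() -> dict[str, TrueParams]:
    """Ground-truth parameters per outcome (logit scale).

    Signs and rough magnitudes echo the field's recurring findings: higher
    qualification, English as first language (for literacy), home ownership
    and white ethnicity reduce the probability of *not* being health literate;
    older age sharply worsens ICT; lower job status worsens all outcomes.
    Working status carries an exactly-zero effect everywhere, providing a
    known-null covariate for calibration checks.
    """
    lit = TrueParams(
        intercept=0.8,
        fixed_effects={
            ("age", "45+"): 0.45,
            ("sex", "male"): 0.18,
            ("ethnicity", "white"): -0.35,
            ("english", "yes"): -0.95,
            ("ukborn", "yes"): -0.10,
            ("own_home", "yes"): -0.40,
            ("working", "yes"): 0.0,
            ("qualification", ">=level2"): -1.20,
            ("income", ">=10k"): -0.08,
            ("income", "other"): 0.35,
            ("job", "intermediate"): 0.22,
            ("job", "lower"): 0.80,
        },
        imd_mu=0.0,
        imd_sigma=0.2,
        imd_effects=(0.10, 0.05, 0.15, -0.05, -0.25),
    )
    num = TrueParams(
        intercept=0.6,
        fixed_effects={
            ("age", "45+"): 0.12,
            ("sex", "male"): -0.40,
            ("ethnicity", "white"): -0.60,
            ("english", "yes"): 0.15,
            ("ukborn", "yes"): -0.05,
            ("own_home", "yes"): -0.35,
            ("working", "yes"): 0.0,
            ("qualification", ">=level2"): -0.70,
            ("income", ">=10k"): -0.12,
            ("income", "other"): 0.15,
            ("job", "intermediate"): 0.25,
            ("job", "lower"): 0.65,
        },
        imd_mu=0.0,
        imd_sigma=0.25,
        imd_effects=(0.10, 0.05, 0.00, -0.15, -0.45),
    )
    ict = TrueParams(
        intercept=0.3,
        fixed_effects={
            ("age", "45+"): 1.20,
            ("sex", "male"): 0.10,
            ("ethnicity", "white"): -0.20,
            ("english", "yes"): 0.04,
            ("ukborn", "yes"): -0.35,
            ("own_home", "yes"): -0.12,
            ("working", "yes"): 0.0,
            ("qualification", ">=level2"): -0.75,
            ("income", ">=10k"): -0.30,
            ("income", "other"): 0.20,
            ("job", "intermediate"): -0.02,
            ("job", "lower"): 0.60,
        },
        imd_mu=0.0,
        imd_sigma=0.15,
        imd_effects=(0.05, 0.10, 0.00, -0.08, -0.15),
    )
    return {"literacy": lit, "numeracy": num, "ict": ict}


@dataclass(frozen=True)
class SourceSurvey:
    """Individual-level source survey: covariates plus per-outcome flags.

    ``data`` holds one string column per covariate, a nullable-integer column
    per outcome (1 = not health literate, NaN outside the subsample), and a
    boolean ``in_<outcome>`` membership column per outcome.
    """

    schema: CovariateSchema
    data: pd.DataFrame = field(repr=False)
    outcomes: tuple[str, ...] = OUTCOMES

    def subsample(self, outcome: str) -> pd.DataFrame:
        if outcome not in self.outcomes:
            raise DataError(f"unknown outcome {outcome!r}")
        return self.data.loc[self.data[f"in_{outcome}"]]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, schema: CovariateSchema,
        outcomes: Sequence[str] = OUTCOMES,
    ) -> "SourceSurvey":
        df = pd.read_csv(path, dtype={n: str for n in schema.names})
        for o in outcomes:
            df[f"in_{o}"] = df[f"in_{o}"].astype(bool)
        return cls(schema, df, tuple(outcomes))


def grade_to_binary(outcome: str, grade: str) -> int:
    """Map a five-level skill grade to the binary health-literate flag.

    The flag is 1 when the grade meets or exceeds the outcome's threshold on
    the ladder EL1 < EL2 < EL3 < L1 < L2plus (L2plus for literacy, L1 for
    numeracy, EL3 for ICT).
    """
    if outcome not in BINARY_THRESHOLDS:
        raise DataError(f"unknown outcome {outcome!r}")
    if grade not in GRADE_LADDER:
        raise DataError(f"unknown grade {grade!r}")
    return int(GRADE_LADDER.index(grade) >= GRADE_LADDER.index(BINARY_THRESHOLDS[outcome]))


def _draw_covariates(
    schema: CovariateSchema,
    n: int,
    level_probs: Mapping[str, Sequence[float]],
    association: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n rows of level codes, independent or from a tilted full joint."""
    if association == 0.0:
        codes = np.empty((n, len(schema.variables)), dtype=np.int64)
        for j, var in enumerate(schema.variables):
            p = np.asarray(level_probs[var.name], dtype=float)
            codes[:, j] = rng.choice(var.n_levels, size=n, p=p / p.sum())
        return codes
    joint = tilted_joint(schema, schema.names, level_probs, tilt=association)
    flat = joint.probs.reshape(-1)
    cells = rng.choice(flat.size, size=n, p=flat)
    return np.array(np.unravel_index(cells, joint.probs.shape)).T.astype(np.int64)


def generate_source_survey(
    schema: CovariateSchema,
    true_params: Mapping[str, TrueParams],
    n: int,
    subsample_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
    level_probs: Mapping[str, Sequence[float]] | None = None,
    association: float = 0.0,
) -> SourceSurvey:
    """Simulate the source survey from the ground-truth logistic process.

    Covariates are drawn from the (optionally tilted) source joint; each
    outcome's binary response is Bernoulli(inv-logit(eta)) under that
    outcome's :class:`TrueParams`, observed only on its subsample.  Subsamples
    are nested heads of one seeded permutation, sized ``round(n * fraction)``.
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    fractions = dict(subsample_fractions or DEFAULT_SUBSAMPLE_FRACTIONS)
    outcomes = tuple(true_params)
    for o in outcomes:
        f = fractions.get(o)
        if f is None or not (0.0 < f <= 1.0):
            raise ConfigError(f"subsample fraction for {o!r} must be in (0, 1]")
    probs = dict(SOURCE_LEVEL_PROBS)
    if level_probs:
        probs.update(level_probs)

    rng = np.random.default_rng(seed)
    codes = _draw_covariates(schema, n, probs, association, rng)
    levels = [v.levels for v in schema.variables]
    data = pd.DataFrame(
        {name: np.array(levels[j], dtype=object)[codes[:, j]]
         for j, name in enumerate(schema.names)}
    )

    perm = rng.permutation(n)
    for o in outcomes:
        size = int(round(n * fractions[o]))
        member = np.zeros(n, dtype=bool)
        member[perm[:size]] = True
        eta = true_params[o].linear_predictor(codes, schema)
        y = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))
        col = np.where(member, y.astype(float), np.nan)
        data[o] = col
        data[f"in_{o}"] = member
    return SourceSurvey(schema, data, outcomes)


def generate_target_microdata(
    schema: CovariateSchema,
    target_joint: JointTable,
    variables: Sequence[str],
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw n iid records from the target joint over the named covariates."""
    if n <= 0:
        raise ConfigError("n must be positive")
    for v in variables:
        if v not in schema:
            raise ConfigError(f"{v!r} is not a schema covariate")
    joint = (
        target_joint
        if tuple(variables) == target_joint.variables
        else target_joint.marginalise(variables)
    )
    rng = np.random.default_rng(seed)
    flat = joint.probs.reshape(-1)
    cells = rng.choice(flat.size, size=n, p=flat)
    codes = np.array(np.unravel_index(cells, joint.probs.shape)).T
    return pd.DataFrame(
        {v: np.array(schema[v].levels, dtype=object)[codes[:, j]]
         for j, v in enumerate(variables)}
    )


def generate_lfs_inputs(
    schema: CovariateSchema,
    joint: JointTable,
    variables: Sequence[str],
    n: int,
    seed: int = 0,
    target_margins: Mapping[str, Sequence[float]] | None = None,
) -> tuple[pd.DataFrame, list[MarginalTable]]:
    """Labour-force-style microdata plus the local margins raking must hit.

    The microdata are drawn from ``joint`` (a national-like distribution,
    deliberately different from the local margins so raking is non-trivial);
    the returned :class:`MarginalTable` list is the local truth for each of
    the block's covariates.
    """
    if set(variables) != set(LFS_BLOCK):
        raise ConfigError(f"LFS block must cover exactly {sorted(LFS_BLOCK)}")
    micro = generate_target_microdata(schema, joint, variables, n, seed)
    margins_src = dict(target_margins) if target_margins else {
        v: TARGET_LEVEL_PROBS[v] for v in LFS_BLOCK
    }
    margins = [
        MarginalTable(
            schema, v,
            np.asarray(margins_src[v], dtype=float)
            / np.asarray(margins_src[v], dtype=float).sum(),
        )
        for v in variables
    ]
    return micro, margins


def generate_lsoa_table(
    n_lsoa: int = 164,
    seed: int = 0,
    decile_probs: Sequence[float] = TARGET_DECILE_PROBS,
    mean_population: float = 2100.0,
) -> pd.DataFrame:
    """LSOA-level table of deprivation decile and mid-year population."""
    if n_lsoa <= 0:
        raise ConfigError("n_lsoa must be positive")
    rng = np.random.default_rng(seed)
    p = np.asarray(decile_probs, dtype=float)
    deciles = rng.choice(np.arange(1, 11), size=n_lsoa, p=p / p.sum())
    pops = rng.poisson(mean_population, size=n_lsoa)
    return pd.DataFrame(
        {
            "lsoa_id": [f"E0100{i:04d}" for i in range(n_lsoa)],
            "imd_decile": deciles,
            "population": pops,
        }
    )


@dataclass(frozen=True)
class SyntheticBundle:
    """Complete, mutually consistent synthetic input set from one seed."""

    schema: CovariateSchema
    source_survey: SourceSurvey
    target_microdata: pd.DataFrame = field(repr=False)
    lfs_microdata: pd.DataFrame = field(repr=False)
    lfs_margins: list[MarginalTable] = field(repr=False)
    lsoa_table: pd.DataFrame = field(repr=False)
    true_params: dict[str, TrueParams] = field(repr=False)
    residents_joint_truth: JointTable = field(repr=False)
    lfs_joint_truth: JointTable = field(repr=False)
    seed: int = 0

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every component as CSV (plus TrueParams JSON); returns paths."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "schema": out / "schema.yaml",
            "source_survey": out / "source_survey.csv",
            "target_microdata": out / "target_microdata.csv",
            "lfs_microdata": out / "lfs_microdata.csv",
            "lfs_margins": out / "lfs_margins.csv",
            "lsoa_table": out / "lsoa_imd.csv",
            "true_params": out / "true_params.json",
        }
        self.schema.to_file(paths["schema"])
        self.source_survey.to_csv(paths["source_survey"])
        self.target_microdata.to_csv(paths["target_microdata"], index=False)
        self.lfs_microdata.to_csv(paths["lfs_microdata"], index=False)
        rows = [
            {"variable": m.variable, "level": l, "proportion": p}
            for m in self.lfs_margins
            for l, p in zip(self.schema[m.variable].levels, m.proportions)
        ]
        pd.DataFrame(rows).to_csv(paths["lfs_margins"], index=False)
        self.lsoa_table.to_csv(paths["lsoa_table"], index=False)
        paths["true_params"].write_text(
            json.dumps({o: tp.to_dict() for o, tp in self.true_params.items()},
                       indent=2)
        )
        return paths


def make_default_bundle(
    seed: int,
    n_source: int = 4000,
    n_target: int = 3000,
    n_lfs: int = 3000,
    n_lsoa: int = 164,
    schema: CovariateSchema | None = None,
    true_params: Mapping[str, TrueParams] | None = None,
    block_tilt: float = 0.5,
) -> SyntheticBundle:
    """One call yielding the complete desk-scale input set for the pipeline.

    Block joints for the target population carry a within-block association
    (``block_tilt``) so the microdata joints are not simple margin products;
    blocks are mutually independent, matching the frame-construction
    assumption, so the analytic prevalence is exactly enumerable.
    """
    schema = schema or default_schema()
    params = dict(true_params or default_true_params())
    ss = np.random.SeedSequence(seed)
    s_src, s_tgt, s_lfs, s_lsoa = (int(c.generate_state(1)[0] % 2**31)
                                   for c in ss.spawn(4))

    residents_truth = tilted_joint(schema, RESIDENTS_BLOCK, TARGET_LEVEL_PROBS, tilt=block_tilt)
    # national-like joint for the labour-force block, tilted the other way so
    # its margins genuinely differ from the local targets
    lfs_national = tilted_joint(schema, LFS_BLOCK, SOURCE_LEVEL_PROBS, tilt=-block_tilt)

    survey = generate_source_survey(schema, params, n_source, seed=s_src)
    target_micro = generate_target_microdata(schema, residents_truth, RESIDENTS_BLOCK,
                                             n_target, seed=s_tgt)
    lfs_micro, lfs_margins = generate_lfs_inputs(schema, lfs_national, LFS_BLOCK,
                                                 n_lfs, seed=s_lfs)
    lsoa = generate_lsoa_table(n_lsoa, seed=s_lsoa)
    return SyntheticBundle(
        schema=schema,
        source_survey=survey,
        target_microdata=target_micro,
        lfs_microdata=lfs_micro,
        lfs_margins=lfs_margins,
        lsoa_table=lsoa,
        true_params=params,
        residents_joint_truth=residents_truth,
        lfs_joint_truth=lfs_national,
        seed=seed,
    )
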