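"""Bayesian multilevel logistic regression, cell prediction, post-stratification.

The model for a binary response (1 = not health literate) is

    y_i ~ Bernoulli(pi_i),   logit(pi_i) = b0 + sum_x b_x[level_x(i)] + u[q(i)]

with reference levels of every fixed categorical covariate pinned at zero and
partially pooled area-deprivation effects u_q ~ N(mu, sigma^2) over the five
IMD quintiles.  Priors are weakly informative by default: N(0, 2.5) on the
intercept, fixed effects and mu, HalfNormal(1) on sigma.

Sampling uses an affine-invariant ensemble MCMC (differential-evolution
moves) over the 20-dimensional posterior, with the random-effect block in a
non-centred parameterisation, walkers initialised near the penalised mode,
and multiple independent ensembles treated as chains for R-hat / ESS
diagnostics.  The likelihood is evaluated on collapsed covariate patterns
(binomial form), which keeps a fit at n in the thousands to a few seconds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import emcee
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .errors import AlignmentError, ConfigError, DataError, SchemaError
from .frame import PostStratFrame
from .schema import IMD_VARIABLE, CellIndex, CovariateSchema
from .synthetic import SourceSurvey

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "PosteriorDraws",
    "CellPredictions",
    "fit_mrp",
    "predict_cells",
    "poststratify",
]

N_QUINTILES = 5


@dataclass(frozen=True)
class PriorSpec:
    """Prior scales (all normal/half-normal, centred at zero)."""

    fixed_effect_sd: float = 2.5
    intercept_sd: float = 2.5
    imd_mu_sd: float = 2.5
    imd_sigma_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("fixed_effect_sd", "intercept_sd", "imd_mu_sd", "imd_sigma_scale"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def vague(cls) -> "PriorSpec":
        """Near-flat priors (scales inflated 100x); sigma keeps a proper prior."""
        return cls(fixed_effect_sd=250.0, intercept_sd=250.0,
                   imd_mu_sd=250.0, imd_sigma_scale=10.0)


@dataclass(frozen=True)
class McmcSettings:
    """Ensemble-MCMC settings; ``draws`` is retained draws per chain."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.01
    walkers: int = 64

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 1 or self.draws < 1:
            raise ConfigError("chains, warmup and draws must be positive")

    @classmethod
    def test_profile(cls, seed: int = 0) -> "McmcSettings":
        """Desk-scale profile: 2 chains x 500 warmup x 500 retained draws."""
        return cls(chains=2, warmup=500, draws=500, seed=seed)


@dataclass(frozen=True)
class PosteriorDraws:
    """Posterior draws on the natural scale, plus convergence diagnostics.

    ``params`` has chains*draws rows and one column per parameter:
    ``intercept``, one ``<variable>[<level>]`` per non-reference fixed-effect
    level, ``imd_mu``, ``imd_sigma``, and ``imd[q]`` for the five total
    quintile effects (mu + sigma * z).
    """

    schema: CovariateSchema
    outcome: str
    params: pd.DataFrame = field(repr=False)
    chains: int = 1
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.params)

    def fixed_effect_columns(self) -> list[str]:
        return [
            f"{v}[{l}]"
            for v, l in self.schema.non_reference_pairs(exclude=(IMD_VARIABLE,))
        ]

    def imd_columns(self) -> list[str]:
        return [f"imd[{q}]" for q in range(1, N_QUINTILES + 1)]

    def max_rhat(self) -> float:
        vals = [d["rhat"] for d in self.diagnostics.get("params", {}).values()]
        return max(vals) if vals else math.nan

    # ---- persistence ---------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        df = self.params.copy()
        df.insert(0, "chain", np.repeat(np.arange(self.chains), len(df) // self.chains))
        df.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".diagnostics.json")
        sidecar.write_text(json.dumps(
            {"outcome": self.outcome, **self.diagnostics}, indent=2, sort_keys=True))

    @classmethod
    def from_csv(
        cls, path: str | Path, schema: CovariateSchema, outcome: str
    ) -> "PosteriorDraws":
        df = pd.read_csv(path, float_precision="round_trip")
        chains = int(df["chain"].nunique())
        params = df.drop(columns=["chain"])
        sidecar = Path(path).with_suffix(".diagnostics.json")
        diags = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        diags.pop("outcome", None)
        return cls(schema=schema, outcome=outcome, params=params,
                   chains=chains, diagnostics=diags)


@dataclass(frozen=True)
class CellPredictions:
    """Per-draw probability for every post-stratification cell."""

    cell_index: CellIndex
    matrix: np.ndarray = field(repr=False)  # (n_draws, n_cells)

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.cell_index.n_cells:
            raise AlignmentError("prediction matrix does not match cell index")


# ---------------------------------------------------------------------------
# internal design construction
# ---------------------------------------------------------------------------

def _fixed_design(codes: np.ndarray, schema: CovariateSchema) -> np.ndarray:
    """One-hot design for non-reference levels of all non-IMD covariates."""
    cols = []
    for j, var in enumerate(schema.variables):
        if var.name == IMD_VARIABLE:
            continue
        ref_code = var.code(var.reference)
        for code in range(var.n_levels):
            if code != ref_code:
                cols.append((codes[:, j] == code).astype(float))
    return np.column_stack(cols) if cols else np.empty((codes.shape[0], 0))


def _codes_from_records(
    records: pd.DataFrame, schema: CovariateSchema
) -> np.ndarray:
    codes = np.empty((len(records), len(schema.variables)), dtype=np.int64)
    for j, var in enumerate(schema.variables):
        if var.name not in records.columns:
            raise DataError(f"survey lacks covariate column {var.name!r}")
        cat = pd.Categorical(records[var.name].astype(str), categories=list(var.levels))
        if (cat.codes == -1).any():
            bad = records[var.name][np.asarray(cat.codes) == -1].iloc[0]
            raise SchemaError(f"value {bad!r} is not a level of {var.name!r}")
        codes[:, j] = cat.codes
    return codes


class _LogPosterior:
    """Vectorised log posterior over collapsed covariate patterns.

    Parameter vector (dimension 1 + K + 2 + 5):
    [b0, beta_1..K, imd_mu, log_imd_sigma, z_1..z_5], non-centred random
    effects u_q = mu + exp(log_sigma) * z_q.
    """

    def __init__(self, Xf: np.ndarray, imd_idx: np.ndarray,
                 successes: np.ndarray, trials: np.ndarray, priors: PriorSpec):
        self.Xf, self.imd_idx = Xf, imd_idx
        self.succ, self.trials = successes, trials
        self.priors = priors
        self.K = Xf.shape[1]
        self.ndim = 1 + self.K + 2 + N_QUINTILES

    def unpack(self, theta: np.ndarray):
        K = self.K
        return (theta[..., 0], theta[..., 1:1 + K], theta[..., 1 + K],
                theta[..., 2 + K], theta[..., 3 + K:])

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        """theta: (W, ndim) -> (W,) log posterior."""
        theta = np.atleast_2d(theta)
        b0, beta, mu, log_sigma, z = self.unpack(theta)
        sigma = np.exp(log_sigma)
        u = mu[:, None] + sigma[:, None] * z          # (W, 5)
        eta = b0[None, :] + self.Xf @ beta.T + u[:, self.imd_idx].T  # (P, W)
        ll = self.succ @ eta - self.trials @ np.logaddexp(0.0, eta)
        p = self.priors
        lp = (
            -0.5 * b0**2 / p.intercept_sd**2
            - 0.5 * (beta**2).sum(axis=1) / p.fixed_effect_sd**2
            - 0.5 * mu**2 / p.imd_mu_sd**2
            - 0.5 * sigma**2 / p.imd_sigma_scale**2 + log_sigma  # HalfNormal + Jacobian
            - 0.5 * (z**2).sum(axis=1)
        )
        return ll + lp

    def negative(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Scalar -log posterior and its gradient, for mode finding."""
        b0, beta, mu, log_sigma, z = self.unpack(theta)
        sigma = math.exp(log_sigma)
        u = mu + sigma * z
        eta = b0 + self.Xf @ beta + u[self.imd_idx]
        ll = float(self.succ @ eta - self.trials @ np.logaddexp(0.0, eta))
        resid = self.succ - self.trials * expit(eta)
        g_u = np.bincount(self.imd_idx, weights=resid, minlength=N_QUINTILES)
        p = self.priors
        lp = (
            -0.5 * b0**2 / p.intercept_sd**2
            - 0.5 * float(beta @ beta) / p.fixed_effect_sd**2
            - 0.5 * mu**2 / p.imd_mu_sd**2
            - 0.5 * sigma**2 / p.imd_sigma_scale**2 + log_sigma
            - 0.5 * float(z @ z)
        )
        grad = np.empty(self.ndim)
        grad[0] = resid.sum() - b0 / p.intercept_sd**2
        grad[1:1 + self.K] = self.Xf.T @ resid - beta / p.fixed_effect_sd**2
        grad[1 + self.K] = g_u.sum() - mu / p.imd_mu_sd**2
        grad[2 + self.K] = (
            float(g_u @ z) * sigma - sigma**2 / p.imd_sigma_scale**2 + 1.0
        )
        grad[3 + self.K:] = g_u * sigma - z
        return -(ll + lp), -grad


def fit_mrp(
    survey: SourceSurvey,
    outcome: str,
    schema: CovariateSchema,
    priors: PriorSpec | None = None,
    settings: McmcSettings | None = None,
) -> PosteriorDraws:
    """Fit the multilevel logistic model to one outcome's subsample.

    Returns posterior draws on the natural scale and per-parameter R-hat /
    effective sample size; a :class:`UserWarning` is emitted when any R-hat
    exceeds ``settings.rhat_threshold``.
    """
    priors = priors or PriorSpec()
    settings = settings or McmcSettings()

    rows = survey.subsample(outcome)
    y_raw = rows[outcome].to_numpy(dtype=float)
    if len(rows) == 0 or np.isnan(y_raw).all():
        raise DataError(f"outcome {outcome!r} has an empty subsample")
    if np.isnan(y_raw).any():
        raise DataError(f"outcome {outcome!r} has missing responses inside its subsample")
    y = y_raw.astype(np.int64)
    if y.min() == y.max():
        raise DataError(
            f"outcome {outcome!r} is single-class (all {y[0]}); model is separable"
        )

    codes = _codes_from_records(rows, schema)
    # collapse to unique covariate patterns -> binomial likelihood
    patterns, inverse = np.unique(codes, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    successes = np.bincount(inverse, weights=y.astype(float))
    trials = np.bincount(inverse).astype(float)
    Xf = _fixed_design(patterns, schema)
    imd_idx = patterns[:, schema.names.index(IMD_VARIABLE)]

    logpost = _LogPosterior(Xf, imd_idx, successes, trials, priors)

    # penalised mode for walker initialisation
    x0 = np.zeros(logpost.ndim)
    opt = minimize(logpost.negative, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500})
    mode = opt.x

    nw = max(settings.walkers, 2 * logpost.ndim + 2)
    steps = max(2 * math.ceil(settings.draws / nw), 256)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]

    ss = np.random.SeedSequence(settings.seed)
    chain_draws = []
    for child in ss.spawn(settings.chains):
        chain_seed = int(child.generate_state(1)[0] % 2**31)
        rng = np.random.RandomState(chain_seed)
        sampler = emcee.EnsembleSampler(nw, logpost.ndim, logpost,
                                        vectorize=True, moves=moves)
        sampler.random_state = rng.get_state()
        p0 = mode + 0.05 * rng.standard_normal((nw, logpost.ndim))
        state = sampler.run_mcmc(p0, settings.warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, steps, progress=False)
        flat = sampler.get_chain().reshape(steps * nw, logpost.ndim)  # step-major
        keep = np.round(np.linspace(0, len(flat) - 1, settings.draws)).astype(int)
        chain_draws.append(flat[keep])
    raw = np.stack(chain_draws)  # (chains, draws, ndim)

    # transform to the natural scale
    K = logpost.K
    b0 = raw[..., 0]
    beta = raw[..., 1:1 + K]
    mu = raw[..., 1 + K]
    sigma = np.exp(raw[..., 2 + K])
    u = mu[..., None] + sigma[..., None] * raw[..., 3 + K:]
    names = (
        ["intercept"]
        + [f"{v}[{l}]" for v, l in schema.non_reference_pairs(exclude=(IMD_VARIABLE,))]
        + ["imd_mu", "imd_sigma"]
        + [f"imd[{q}]" for q in range(1, N_QUINTILES + 1)]
    )
    natural = np.concatenate(
        [b0[..., None], beta, mu[..., None], sigma[..., None], u], axis=-1
    )

    diagnostics = _diagnose(natural, names)
    params = pd.DataFrame(natural.reshape(-1, natural.shape[-1]), columns=names)
    draws = PosteriorDraws(schema=schema, outcome=outcome, params=params,
                           chains=settings.chains, diagnostics=diagnostics)
    worst = draws.max_rhat()
    if settings.chains > 1 and worst > settings.rhat_threshold:
        warnings.warn(
            f"fit for {outcome!r}: max R-hat {worst:.4f} exceeds "
            f"threshold {settings.rhat_threshold}", UserWarning, stacklevel=2)
    return draws


def _diagnose(natural: np.ndarray, names: list[str]) -> dict:
    """Split-R-hat and bulk ESS per parameter via arviz."""
    import arviz as az

    ds = az.convert_to_dataset(
        {n: natural[..., i] for i, n in enumerate(names)}
    )
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    per_param = {
        n: {"rhat": float(rhat[n].values), "ess": float(ess[n].values)}
        for n in names
    }
    return {"params": per_param}


def predict_cells(draws: PosteriorDraws, cells: CellIndex) -> CellPredictions:
    """Inverse-logit linear predictor for every (draw, cell) pair."""
    schema = cells.schema
    if schema != draws.schema:
        raise AlignmentError("cell index schema differs from the fitted schema")
    Xf = _fixed_design(cells.codes, schema)
    fixed_cols = draws.fixed_effect_columns()
    missing = [c for c in fixed_cols if c not in draws.params.columns]
    if missing:
        raise AlignmentError(f"draws lack coefficients {missing}")
    beta = draws.params[fixed_cols].to_numpy()
    b0 = draws.params["intercept"].to_numpy()
    u = draws.params[draws.imd_columns()].to_numpy()
    imd_idx = cells.column(IMD_VARIABLE)
    eta = b0[:, None] + beta @ Xf.T + u[:, imd_idx]
    return CellPredictions(cell_index=cells, matrix=expit(eta))


def poststratify(preds: CellPredictions, frame: PostStratFrame) -> np.ndarray:
    """Per-draw post-stratified prevalence: ``sum_c w_c * pi_c``."""
    if not preds.cell_index.same_as(frame.cell_index):
        raise AlignmentError("predictions and frame use different cell indexes")
    return preds.matrix @ frame.weights
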