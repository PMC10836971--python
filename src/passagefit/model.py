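"""Bayesian relative-fitness model for serial-transfer competitions.

The model
---------
Two genotypes compete over serial passages. Writing ``p_t`` for the focal
genotype's frequency at sampled timepoint ``t`` and ``dg_t`` for the
generations elapsed since the previous sample, the frequency follows

    p_t = p_{t-1} * w_eff ** dg_t                      ("as_printed")

with the effective per-generation relative fitness decomposed additively
into a baseline and condition effects:

    w_eff = w_base + b_mat * mat + b_cocl2 * cocl2
            + b_glucose * (glucose_pct - 2) + b_tf_null * is_tf_null

The multiplicative recursion is a first-order description valid while
``p_t`` stays in [0, 1]; the "normalized" variant
``p * w**dg / (p * w**dg + (1 - p))`` is the exact haploid-selection
update and agrees with it to < 1e-4 in the near-neutral regime
(|w - 1| <= 0.005, dg <= 10, p in [0.2, 0.8]).

Sequenced counts are modelled as ``count_tf0 ~ Binomial(n, p_t)`` with
``n = count_tf0 + count_wt`` (a beta-binomial option handles
overdispersed data). The initial frequency ``p0`` is a free parameter per
replicate. Posteriors are drawn with an affine-invariant ensemble MCMC
sampler initialized at the posterior mode; parameters are summarized by
the posterior median and the 89% highest-posterior-density interval
(HPDI), and a parameter is called consistent with neutrality when its
HPDI contains the null value (1 for fitness, 0 for the offsets).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import CovariateSetting
from .errors import (
    ConvergenceError,
    InvalidInputError,
    RecursionOverflowError,
    UndefinedFrequencyError,
)

__all__ = [
    "CompetitionDataset",
    "ModelSpec",
    "PosteriorSummary",
    "ParameterSummary",
    "FitnessDecision",
    "effective_fitness",
    "propagate_frequency",
    "log_likelihood",
    "sample_posterior",
    "hpdi",
    "decide_neutrality",
    "selection_coefficients",
]

BETA_NAMES = ("mat", "cocl2", "glucose", "tf_null")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def effective_fitness(
    w_base: float, betas: dict[str, float], covariates: CovariateSetting
) -> float:
    """Per-generation relative fitness under a covariate setting.

    ``betas`` maps covariate names (a subset of ``mat``, ``cocl2``,
    ``glucose``, ``tf_null``) to additive offsets; the glucose offset is
    per g/100 mL above 2%.
    """
    w = w_base
    for name, beta in betas.items():
        if name not in BETA_NAMES:
            raise InvalidInputError(f"unknown covariate effect {name!r}")
        w += beta * covariates.value(name)
    if w <= 0:
        raise InvalidInputError(f"effective fitness {w} is not positive")
    return w


def propagate_frequency(
    p_prev: float, w_eff: float, delta_g: float, variant: str = "as_printed"
) -> float:
    """Advance a genotype frequency by ``delta_g`` generations.

    ``as_printed`` applies the multiplicative recursion
    ``p * w**dg`` and raises :class:`RecursionOverflowError` if the result
    exceeds 1; ``normalized`` renormalizes against the competitor
    (``(1-p)`` growing at rate 1) and is always a valid frequency.
    """
    if not 0.0 <= p_prev <= 1.0:
        raise InvalidInputError("p_prev must lie in [0, 1]")
    if delta_g < 0:
        raise InvalidInputError("delta_g must be >= 0")
    if w_eff <= 0:
        raise InvalidInputError("w_eff must be positive")
    grown = p_prev * w_eff**delta_g
    if variant == "as_printed":
        if grown > 1.0:
            raise RecursionOverflowError(
                f"as_printed recursion produced frequency {grown:.6g} > 1; "
                "use variant='normalized' for strong selection or long intervals"
            )
        return grown
    if variant == "normalized":
        return grown / (grown + (1.0 - p_prev))
    raise InvalidInputError(f"unknown recursion variant {variant!r}")


def selection_coefficients(w: float, n_insertions: int = 13) -> tuple[float, float]:
    """Total and per-insertion selection coefficients implied by ``w``.

    The focal strain lacks ``n_insertions`` transposon copies; assuming
    purely additive effects, ``s_total = w - 1`` is the combined
    coefficient of all insertions and ``s_total / n_insertions`` the
    average per copy.
    """
    if n_insertions < 1:
        raise InvalidInputError("n_insertions must be >= 1")
    s_total = w - 1.0
    return s_total, s_total / n_insertions


def hpdi(draws, prob: float = 0.89) -> tuple[float, float]:
    """Highest posterior density interval of a scalar sample.

    The narrowest contiguous interval over the sorted draws containing
    ``ceil(prob * n)`` of them; ties go to the leftmost window.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 1:
        raise InvalidInputError("hpdi requires at least one draw")
    if not 0.0 < prob < 1.0:
        raise InvalidInputError("prob must lie in (0, 1)")
    m = int(math.ceil(prob * n))
    m = max(m, 1)
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first (leftmost) minimum
    return float(x[i]), float(x[i + m - 1])


# ---------------------------------------------------------------------------
# Dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Replicate:
    """One culture's time series: generations and genotype counts."""

    rep_id: str
    covariates: CovariateSetting
    delta_g: np.ndarray      # generations since previous sample; 0 at t=0
    count_tf0: np.ndarray
    count_wt: np.ndarray

    def __post_init__(self):
        dg = np.asarray(self.delta_g, float)
        tf0 = np.asarray(self.count_tf0, int)
        wt = np.asarray(self.count_wt, int)
        if not (len(dg) == len(tf0) == len(wt)):
            raise InvalidInputError("replicate arrays must have equal length")
        if np.any(dg[1:] <= 0):
            raise InvalidInputError("delta_g must be > 0 after the first timepoint")
        if np.any(tf0 < 0) or np.any(wt < 0):
            raise InvalidInputError("counts must be non-negative")
        if np.any(tf0 + wt == 0):
            raise UndefinedFrequencyError(
                f"replicate {self.rep_id}: timepoint with zero informative reads"
            )
        object.__setattr__(self, "delta_g", dg)
        object.__setattr__(self, "count_tf0", tf0)
        object.__setattr__(self, "count_wt", wt)

    @property
    def n_obs(self) -> int:
        return len(self.delta_g)

    @property
    def frequencies(self) -> np.ndarray:
        return self.count_tf0 / (self.count_tf0 + self.count_wt)


class CompetitionDataset:
    """Replicate time series of genotype counts with condition covariates."""

    def __init__(self, replicates: list[Replicate]):
        # an empty dataset is legal (its likelihood is 0) but cannot be fitted
        self.replicates = list(replicates)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "CompetitionDataset":
        """Build from a genotype count table.

        Expects columns ``replicate``, ``timepoint``, ``cum_generations``,
        ``count_tf0``, ``count_wt`` and the covariates ``mat``, ``cocl2``,
        ``glucose_pct`` (and optionally ``condition``, ``is_tf_null``).
        """
        required = {"replicate", "timepoint", "cum_generations", "count_tf0", "count_wt"}
        missing = required - set(table.columns)
        if missing:
            raise InvalidInputError(f"count table missing columns: {sorted(missing)}")
        keys = [c for c in ("condition", "mat", "cocl2", "glucose_pct", "is_tf_null")
                if c in table.columns]
        reps = []
        for group_key, grp in table.groupby(keys + ["replicate"], sort=True):
            grp = grp.sort_values("timepoint")
            cum = grp["cum_generations"].to_numpy(float)
            dg = np.diff(cum, prepend=cum[0])
            cov = CovariateSetting(
                mat=int(grp["mat"].iloc[0]) if "mat" in grp else 0,
                cocl2=int(grp["cocl2"].iloc[0]) if "cocl2" in grp else 0,
                glucose_pct=float(grp["glucose_pct"].iloc[0]) if "glucose_pct" in grp else 2.0,
                is_tf_null=int(grp["is_tf_null"].iloc[0]) if "is_tf_null" in grp else 0,
            )
            rep_id = "_".join(str(k) for k in np.atleast_1d(np.asarray(group_key, dtype=object)))
            reps.append(
                Replicate(
                    rep_id=rep_id,
                    covariates=cov,
                    delta_g=dg,
                    count_tf0=grp["count_tf0"].to_numpy(int),
                    count_wt=grp["count_wt"].to_numpy(int),
                )
            )
        return cls(reps)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CompetitionDataset":
        return cls.from_table(pd.read_csv(path, sep="\t"))

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def _padded_arrays(self):
        """Stack replicates into (R, T) arrays padded with a mask."""
        R = len(self.replicates)
        T = max(r.n_obs for r in self.replicates)
        dg = np.zeros((R, T))
        tf0 = np.zeros((R, T), dtype=int)
        n = np.zeros((R, T), dtype=int)
        mask = np.zeros((R, T), dtype=bool)
        for i, r in enumerate(self.replicates):
            t = r.n_obs
            dg[i, :t] = r.delta_g
            tf0[i, :t] = r.count_tf0
            n[i, :t] = r.count_tf0 + r.count_wt
            mask[i, :t] = True
        return dg, tf0, n, mask

    def covariate_matrix(self, active: tuple[str, ...]) -> np.ndarray:
        """(R, len(active)) design matrix of covariate values."""
        return np.array(
            [[r.covariates.value(name) for name in active] for r in self.replicates]
        )


# ---------------------------------------------------------------------------
# Model specification and priors
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Prior scales; all weakly informative relative to the data.

    ``w_base ~ Normal(1, w_scale)`` truncated to (0, inf);
    ``beta ~ Normal(0, beta_scale)``; ``p0 ~ Beta(p0_a, p0_b)`` per
    replicate; overdispersion (beta-binomial only) ~ HalfNormal(od_scale).
    """

    w_loc: float = 1.0
    w_scale: float = 0.05
    beta_scale: float = 0.01
    p0_a: float = 2.0
    p0_b: float = 2.0
    od_scale: float = 0.02

    def scaled(self, factor: float) -> "PriorSpec":
        return PriorSpec(
            w_loc=self.w_loc,
            w_scale=self.w_scale * factor,
            beta_scale=self.beta_scale * factor,
            p0_a=self.p0_a,
            p0_b=self.p0_b,
            od_scale=self.od_scale * factor,
        )


@dataclass
class ModelSpec:
    """Configuration of one model fit."""

    recursion_variant: str = "as_printed"
    likelihood: str = "binomial"
    active_betas: tuple[str, ...] = ("mat", "cocl2")
    priors: PriorSpec = field(default_factory=PriorSpec)
    fixed_p0: float | None = None
    walkers: int = 64
    warmup: int = 1000
    steps: int = 2000
    seed: int = 0
    hpdi_prob: float = 0.89
    rhat_max: float = 1.01
    ess_min: float = 400.0

    def __post_init__(self):
        if not 0.0 < self.hpdi_prob < 1.0:
            raise InvalidInputError("hpdi_prob must lie in (0, 1)")
        if self.walkers < 4:
            raise InvalidInputError("need at least 4 walkers")
        if self.recursion_variant not in ("as_printed", "normalized"):
            raise InvalidInputError(f"unknown recursion variant {self.recursion_variant!r}")
        if self.likelihood not in ("binomial", "beta_binomial"):
            raise InvalidInputError(f"unknown likelihood {self.likelihood!r}")
        for b in self.active_betas:
            if b not in BETA_NAMES:
                raise InvalidInputError(f"unknown covariate effect {b!r}")

    def parameter_names(self, dataset: CompetitionDataset) -> list[str]:
        names = ["w_base"] + [f"beta_{b}" for b in self.active_betas]
        if self.fixed_p0 is None:
            names += [f"p0[{r.rep_id}]" for r in dataset.replicates]
        if self.likelihood == "beta_binomial":
            names.append("overdispersion")
        return names


# ---------------------------------------------------------------------------
# Likelihood and posterior
# ---------------------------------------------------------------------------

def _trajectories(w_eff, p0, dg, variant):
    """Propagate frequencies for a batch of parameter vectors.

    w_eff: (W, R); p0: (W, R); dg: (R, T). Returns p: (W, R, T) and a
    validity flag (W,) that is False where the as_printed recursion left
    [0, 1].
    """
    W, R = w_eff.shape
    T = dg.shape[1]
    p = np.empty((W, R, T))
    p[:, :, 0] = p0
    valid = np.ones(W, dtype=bool)
    for t in range(1, T):
        grown = p[:, :, t - 1] * w_eff ** dg[:, t]
        if variant == "as_printed":
            bad = np.any(grown > 1.0, axis=1)
            valid &= ~bad
            p[:, :, t] = np.clip(grown, 0.0, 1.0)
        else:
            prev = p[:, :, t - 1]
            p[:, :, t] = grown / (grown + (1.0 - prev))
    return p, valid


def _count_loglik(tf0, n, p, mask, likelihood, overdispersion=None):
    """Sum of count log-probabilities over masked (R, T) cells.

    tf0, n, mask: (R, T); p: (W, R, T). Returns (W,).
    """
    eps = 1e-12
    p_c = np.clip(p, eps, 1.0 - eps)
    if likelihood == "binomial":
        ll = stats.binom.logpmf(tf0[None], n[None], p_c)
    else:
        kappa = 1.0 / np.maximum(np.asarray(overdispersion)[:, None, None], 1e-8)
        a = p_c * kappa
        b = (1.0 - p_c) * kappa
        ll = stats.betabinom.logpmf(tf0[None], n[None], a, b)
    # exact boundary handling: p=0 demands tf0=0, p=1 demands tf0=n
    at0 = p <= 0.0
    at1 = p >= 1.0
    if np.any(at0):
        ll = np.where(at0, np.where(tf0[None] == 0, 0.0, -np.inf), ll)
    if np.any(at1):
        ll = np.where(at1, np.where(tf0[None] == n[None], 0.0, -np.inf), ll)
    return np.where(mask[None], ll, 0.0).sum(axis=(1, 2))


def log_likelihood(dataset: CompetitionDataset, parameters: dict, spec: ModelSpec) -> float:
    """Log-likelihood of the counts under one parameter setting.

    ``parameters`` holds ``w_base``, ``beta_<name>`` for each active
    covariate, ``p0`` (scalar or one value per replicate) and, for the
    beta-binomial likelihood, ``overdispersion``.
    """
    if not dataset.replicates or all(r.n_obs == 0 for r in dataset.replicates):
        return 0.0
    dg, tf0, n, mask = dataset._padded_arrays()
    X = dataset.covariate_matrix(spec.active_betas)
    beta = np.array([parameters.get(f"beta_{b}", 0.0) for b in spec.active_betas])
    w_eff = (parameters["w_base"] + X @ beta)[None, :]
    if np.any(w_eff <= 0):
        return -np.inf
    p0 = np.broadcast_to(
        np.asarray(parameters["p0"], dtype=float), (len(dataset.replicates),)
    )[None, :]
    p, valid = _trajectories(w_eff, p0, dg, spec.recursion_variant)
    od = None
    if spec.likelihood == "beta_binomial":
        od = np.atleast_1d(parameters["overdispersion"])
    ll = _count_loglik(tf0, n, p, mask, spec.likelihood, od)
    return float(np.where(valid, ll, -np.inf)[0])


class _Posterior:
    """Vectorized log-posterior over the flat parameter vector."""

    def __init__(self, dataset: CompetitionDataset, spec: ModelSpec):
        self.spec = spec
        self.dg, self.tf0, self.n, self.mask = dataset._padded_arrays()
        self.X = dataset.covariate_matrix(spec.active_betas)
        self.R = dataset.n_replicates
        self.nb = len(spec.active_betas)
        self.free_p0 = spec.fixed_p0 is None
        self.has_od = spec.likelihood == "beta_binomial"
        self.ndim = 1 + self.nb + (self.R if self.free_p0 else 0) + (1 if self.has_od else 0)

    def unpack(self, theta):
        theta = np.atleast_2d(theta)
        w = theta[:, 0]
        beta = theta[:, 1 : 1 + self.nb]
        i = 1 + self.nb
        if self.free_p0:
            p0 = theta[:, i : i + self.R]
            i += self.R
        else:
            p0 = np.full((theta.shape[0], self.R), self.spec.fixed_p0)
        od = theta[:, i] if self.has_od else None
        return w, beta, p0, od

    def __call__(self, theta):
        theta = np.atleast_2d(theta)
        w, beta, p0, od = self.unpack(theta)
        pr = self.spec.priors
        lp = np.zeros(theta.shape[0])

        ok = w > 0
        # truncated-normal prior on w (truncation constant is parameter-free)
        lp += np.where(ok, -0.5 * ((w - pr.w_loc) / pr.w_scale) ** 2, -np.inf)
        lp += np.sum(-0.5 * (beta / pr.beta_scale) ** 2, axis=1)
        if self.free_p0:
            in_unit = np.all((p0 > 0) & (p0 < 1), axis=1)
            p0_safe = np.clip(p0, 1e-12, 1 - 1e-12)
            lp += np.where(
                in_unit,
                np.sum(
                    (pr.p0_a - 1) * np.log(p0_safe) + (pr.p0_b - 1) * np.log1p(-p0_safe),
                    axis=1,
                ),
                -np.inf,
            )
        if self.has_od:
            lp += np.where(od > 0, -0.5 * (od / pr.od_scale) ** 2, -np.inf)

        finite = np.isfinite(lp)
        if np.any(finite):
            w_eff = w[finite, None] + (beta[finite] @ self.X.T if self.nb else 0.0)
            w_eff = np.broadcast_to(w_eff, (int(finite.sum()), self.R)).copy()
            pos = np.all(w_eff > 0, axis=1)
            p, valid = _trajectories(
                np.clip(w_eff, 1e-9, None),
                np.clip(p0[finite], 1e-12, 1 - 1e-12),
                self.dg,
                self.spec.recursion_variant,
            )
            ll = _count_loglik(
                self.tf0, self.n, p, self.mask, self.spec.likelihood,
                od[finite] if self.has_od else None,
            )
            ll = np.where(pos & valid, ll, -np.inf)
            lp[finite] += ll
        return lp if theta.shape[0] > 1 else lp


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

@dataclass
class ParameterSummary:
    name: str
    draws: np.ndarray        # (chains, draws)
    median: float
    hpdi_low: float
    hpdi_high: float
    rhat: float
    ess: float

    @property
    def flat(self) -> np.ndarray:
        return self.draws.ravel()


@dataclass
class FitnessDecision:
    parameter: str
    null_value: float
    verdict: str             # "consistent_with_null" | "non_null"
    interval: tuple[float, float]


@dataclass
class PosteriorSummary:
    parameters: dict[str, ParameterSummary]
    hpdi_prob: float
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> ParameterSummary:
        return self.parameters[name]

    @property
    def converged(self) -> bool:
        return not self.warnings

    def to_frame(self, null_values: dict[str, float] | None = None) -> pd.DataFrame:
        rows = []
        for p in self.parameters.values():
            null = _default_null(p.name) if null_values is None else null_values.get(p.name)
            decision = ""
            if null is not None:
                decision = decide_neutrality(self, p.name, null).verdict
            rows.append(
                {
                    "parameter": p.name,
                    "median": p.median,
                    "hpdi_low": p.hpdi_low,
                    "hpdi_high": p.hpdi_high,
                    "rhat": p.rhat,
                    "ess": p.ess,
                    "decision": decision,
                }
            )
        return pd.DataFrame(rows)

    def save(self, outdir: str | Path) -> None:
        """Write summary TSV and a plain-text draws matrix."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(outdir / "posterior_summary.tsv", sep="\t", index=False)
        draws = pd.DataFrame({k: v.flat for k, v in self.parameters.items()})
        draws.to_csv(outdir / "posterior_draws.tsv", sep="\t", index=False)


def _default_null(name: str) -> float | None:
    if name.startswith("w"):
        return 1.0
    if name.startswith("beta") or name == "overdispersion":
        return 0.0
    return None


def decide_neutrality(
    summary: PosteriorSummary, parameter: str, null_value: float | None = None
) -> FitnessDecision:
    """Classify a parameter against its null via the HPDI rule.

    The parameter is consistent with the null hypothesis iff the HPDI at
    the summary's probability level contains the null value (boundary
    inclusive — a conservative choice).
    """
    p = summary[parameter]
    if null_value is None:
        null_value = _default_null(parameter)
        if null_value is None:
            raise InvalidInputError(f"no default null value for {parameter!r}")
    inside = p.hpdi_low <= null_value <= p.hpdi_high
    return FitnessDecision(
        parameter=parameter,
        null_value=null_value,
        verdict="consistent_with_null" if inside else "non_null",
        interval=(p.hpdi_low, p.hpdi_high),
    )


def interval_decision(
    interval: tuple[float, float], null_value: float
) -> str:
    """HPDI decision rule applied to a bare interval."""
    lo, hi = interval
    return "consistent_with_null" if lo <= null_value <= hi else "non_null"


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _map_estimate(post: _Posterior, dataset: CompetitionDataset, spec: ModelSpec):
    """Posterior mode, used to initialize the walker ensemble."""
    x0 = [1.0] + [0.0] * post.nb
    if post.free_p0:
        x0 += [float(np.clip(r.frequencies[0], 0.02, 0.98)) for r in dataset.replicates]
    if post.has_od:
        x0 += [spec.priors.od_scale / 2]
    x0 = np.array(x0)

    def neg(theta):
        v = post(theta[None])[0]
        return -v if np.isfinite(v) else 1e12

    bounds = [(1e-3, None)] + [(None, None)] * post.nb
    if post.free_p0:
        bounds += [(1e-6, 1 - 1e-6)] * post.R
    if post.has_od:
        bounds += [(1e-8, None)]
    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-10})
    res2 = optimize.minimize(neg, res.x, method="Powell", bounds=bounds,
                             options={"maxiter": 20000, "xtol": 1e-12, "ftol": 1e-12})
    return res2.x if res2.fun <= res.fun else res.x


def sample_posterior(dataset: CompetitionDataset, spec: ModelSpec) -> PosteriorSummary:
    """Draw from the posterior and summarize every free parameter.

    Runs an affine-invariant ensemble sampler (walkers initialized in a
    tight ball around the posterior mode), discards ``spec.warmup`` steps,
    and keeps ``spec.steps`` steps from each of ``spec.walkers`` walkers.
    Walkers are treated as chains for split-R-hat and effective sample
    size; a convergence warning is attached when R-hat > ``rhat_max`` or
    ESS < ``ess_min`` for any parameter. Fully reproducible given
    ``spec.seed``.
    """
    import arviz as az
    import emcee

    if not dataset.replicates:
        raise InvalidInputError("cannot fit an empty dataset")
    post = _Posterior(dataset, spec)
    names = spec.parameter_names(dataset)
    if len(names) != post.ndim:
        raise InvalidInputError("parameter bookkeeping mismatch")

    rstate = np.random.RandomState(spec.seed % (2**31))
    center = _map_estimate(post, dataset, spec)
    scales = np.full(post.ndim, 1e-4)
    if post.free_p0:
        scales[1 + post.nb : 1 + post.nb + post.R] = 1e-3
    init = center[None] + rstate.randn(spec.walkers, post.ndim) * scales[None]
    if post.free_p0:
        sl = slice(1 + post.nb, 1 + post.nb + post.R)
        init[:, sl] = np.clip(init[:, sl], 1e-6, 1 - 1e-6)
    if post.has_od:
        init[:, -1] = np.abs(init[:, -1]) + 1e-8

    # differential-evolution moves mix far better than the default stretch
    # move on this posterior (narrow, correlated, ~15 dimensions)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(
        spec.walkers, post.ndim, post, vectorize=True, moves=moves
    )
    sampler._random = rstate
    state = sampler.run_mcmc(init, spec.warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, spec.steps, progress=False)

    chain = sampler.get_chain()              # (steps, walkers, ndim)
    if not np.all(np.isfinite(sampler.get_log_prob())):
        raise ConvergenceError(
            "sampler visited non-finite posterior density",
            {"acceptance": sampler.acceptance_fraction.tolist()},
        )

    msgs = []
    params: dict[str, ParameterSummary] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(names):
            draws = chain[:, :, j].T         # (walkers, steps) = (chain, draw)
            rhat = float(az.rhat(draws))
            ess = float(az.ess(draws))
            lo, hi = hpdi(draws, spec.hpdi_prob)
            params[name] = ParameterSummary(
                name=name,
                draws=draws,
                median=float(np.median(draws)),
                hpdi_low=lo,
                hpdi_high=hi,
                rhat=rhat,
                ess=ess,
            )
            if rhat > spec.rhat_max:
                msgs.append(f"{name}: R-hat {rhat:.4f} > {spec.rhat_max}")
            if ess < spec.ess_min:
                msgs.append(f"{name}: ESS {ess:.0f} < {spec.ess_min:.0f}")
    mean_accept = float(np.mean(sampler.acceptance_fraction))
    if mean_accept < 0.05:
        raise ConvergenceError(
            f"mean acceptance fraction {mean_accept:.3f} too low",
            {"acceptance": mean_accept},
        )
    return PosteriorSummary(parameters=params, hpdi_prob=spec.hpdi_prob, warnings=msgs)
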