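"""Generalized fiducial inference for the random-intercept mixed model.

The fiducial distribution arises from inverting the data-generating equation

    Y = A(U, theta) = X beta + (sigma2_a S_a + sigma2_e I_n)^{1/2} U,
    U ~ N(0, I_n),

yielding the (unnormalized) fiducial density

    r_y(theta)  proportional to  f(y | theta) * J(y, theta),

where f is the marginal Gaussian likelihood and the Jacobian factor is
J = D(M) with

    M = [ X,  S_a V^{-1}(y - X beta),  V^{-1}(y - X beta) ],
    V = sigma2_a S_a + sigma2_e I_n.

``D(M) = sqrt(det(M'M))`` by default (the square-root convention of the
generalized fiducial literature); ``sqrt_jacobian=False`` selects the
plain-determinant variant.  Unlike a Bayesian posterior there is no prior:
the Jacobian plays its role and is determined by the model equation alone.

Sampling uses an adaptive Gaussian random-walk Metropolis chain on
(beta, log sigma2_a, log sigma2_e); the log transform keeps the variance
boundary unreachable and contributes the usual + log sigma2_a + log sigma2_e
change-of-variables term to the target.  Equal-tailed quantile intervals of
the draws are the fiducial confidence intervals; by construction they are
available for the variance components as well as for the fixed effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import (
    DesignRealization,
    DomainError,
    Theta,
    log_marginal_likelihood,
    marginal_covariance,
)

logger = logging.getLogger("fidlmm")

__all__ = [
    "SamplerConfig",
    "FiducialDraws",
    "IntervalSummary",
    "jacobian_matrix",
    "log_jacobian",
    "log_fiducial_density",
    "sample_fiducial",
    "summarize",
    "null_effect_decision",
]


# ---------------------------------------------------------------------------
# Jacobian and fiducial density
# ---------------------------------------------------------------------------


def jacobian_matrix(theta: Theta, design: DesignRealization) -> np.ndarray:
    """The n x (p+2) matrix M = [X, S_a V^{-1} r, V^{-1} r] with r = y - X beta."""
    V = marginal_covariance(theta, design.group_index)
    r = design.y - design.X @ theta.beta
    vinv_r = V.solve(r)
    return np.column_stack([design.X, V.sa_apply(vinv_r), vinv_r])


def log_jacobian(theta: Theta, design: DesignRealization, sqrt_jacobian: bool = True) -> float:
    """log D(M) for the Jacobian matrix M.

    Returns ``0.5 * logdet(M'M)`` (default square-root convention) or the
    full ``logdet(M'M)``.  A singular M'M (e.g. exact fit, r = 0) yields
    ``-inf`` — a rejectable log-density value, not an exception.
    """
    M = jacobian_matrix(theta, design)
    sign, logdet = np.linalg.slogdet(M.T @ M)
    if sign <= 0 or not np.isfinite(logdet):
        return -np.inf
    return 0.5 * logdet if sqrt_jacobian else logdet


def log_fiducial_density(theta, design: DesignRealization,
                         sqrt_jacobian: bool = True) -> float:
    """Unnormalized log fiducial density log f(y|theta) + log J(y,theta).

    ``theta`` may be a :class:`Theta` or a raw ``(beta, var_subject,
    var_resid)`` triple; values outside the parameter space (sigma2_e <= 0,
    sigma2_a < 0) score ``-inf`` by convention rather than raising, so
    samplers can reject them.  Only log-density differences are meaningful:
    the normalizing integral is never computed.
    """
    if not isinstance(theta, Theta):
        beta, s2a, s2e = theta
        try:
            theta = Theta(beta=np.atleast_1d(beta), var_subject=s2a, var_resid=s2e)
        except DomainError:
            return -np.inf
    ll = log_marginal_likelihood(theta, design)
    return ll + log_jacobian(theta, design, sqrt_jacobian=sqrt_jacobian)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SamplerConfig:
    """Adaptive random-walk Metropolis settings.

    Defaults (4 chains, 2000 warmup, 5000 kept draws per chain) are sized
    for a final analysis; simulation studies use lighter schedules.
    ``sample_var_subject=False`` pins sigma2_a at 0 and drops its dimension
    (and the corresponding Jacobian column) — the classical one-sample
    configuration.
    """

    n_chains: int = 4
    n_warmup: int = 2000
    n_keep: int = 5000
    seed: int = 0
    target_accept: float = 0.30
    init_step_scale: float = 0.7
    thin: int = 2
    sample_var_subject: bool = True
    sqrt_jacobian: bool = True
    compute_diagnostics: bool = True

    def __post_init__(self):
        if self.n_chains < 2:
            raise DomainError("need at least 2 chains")
        if self.n_warmup <= 0 or self.n_keep <= 0:
            raise DomainError("warmup and keep must be positive")
        if self.thin < 1:
            raise DomainError("thin must be >= 1")


@dataclass
class FiducialDraws:
    """MCMC draws from the fiducial distribution, natural scale.

    ``draws`` has one column per fixed effect followed by sigma2_a (tau00)
    and sigma2_e; ``chain_id`` maps rows to chains.
    """

    draws: np.ndarray
    chain_id: np.ndarray
    param_names: list
    config: SamplerConfig
    rhat: np.ndarray | None = None
    ess: np.ndarray | None = None
    accept_rate: float = np.nan
    warnings: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def by_chain(self) -> np.ndarray:
        """Draws reshaped to (n_chains, n_keep, n_params)."""
        c = self.config
        return self.draws.reshape(c.n_chains, c.n_keep, -1)


class _FastTarget:
    """Vectorized evaluator of the log fiducial density on the transformed
    scale (beta, log sigma2_a, log sigma2_e), including the log-transform
    Jacobian term log sigma2_a + log sigma2_e."""

    def __init__(self, design: DesignRealization, sample_var_subject: bool,
                 sqrt_jacobian: bool):
        self.X = design.X
        self.y = design.y
        self.g = design.group_index
        self.n, self.p = design.X.shape
        self.n_groups = int(self.g.max()) + 1
        self.sizes = np.bincount(self.g, minlength=self.n_groups).astype(float)
        self.sample_var_subject = sample_var_subject
        self.jfac = 0.5 if sqrt_jacobian else 1.0
        self.log2pi = np.log(2.0 * np.pi)

    def __call__(self, z: np.ndarray) -> float:
        p = self.p
        beta = z[:p]
        if self.sample_var_subject:
            la, le = z[p], z[p + 1]
            s2a, s2e = np.exp(la), np.exp(le)
        else:
            le = z[p]
            s2a, s2e = 0.0, np.exp(le)
        if not np.isfinite(s2e) or s2e <= 0:
            return -np.inf

        r = self.y - self.X @ beta
        s = np.bincount(self.g, weights=r, minlength=self.n_groups)
        denom = s2e + self.sizes * s2a
        shrink = s2a / (s2e * denom)
        vinv_r = r / s2e - (shrink * s)[self.g]
        quad = r @ vinv_r
        logdet = np.sum((self.sizes - 1.0)) * np.log(s2e) + np.sum(np.log(denom))
        ll = -0.5 * (self.n * self.log2pi + logdet + quad)

        if self.sample_var_subject:
            sa_vr = np.bincount(self.g, weights=vinv_r, minlength=self.n_groups)[self.g]
            M = np.column_stack([self.X, sa_vr, vinv_r])
        else:
            M = np.column_stack([self.X, vinv_r])
        sign, mlogdet = np.linalg.slogdet(M.T @ M)
        if sign <= 0 or not np.isfinite(mlogdet):
            return -np.inf

        # + la + le: change of variables for the log-variance parameterization
        extra = (z[p] + z[p + 1]) if self.sample_var_subject else z[p]
        return ll + self.jfac * mlogdet + extra


def _init_states(design: DesignRealization, config: SamplerConfig, rngs):
    """REML-centred, per-chain jittered starting points and a proposal scale.

    With the random-intercept dimension disabled the model is plain
    regression, so OLS initializes instead of REML."""
    p = design.p
    if config.sample_var_subject:
        from .frequentist import fit_reml  # local import: avoids a cycle

        fit = fit_reml(design)
        th = fit.theta_hat
        s2e = th.var_resid
        s2a = th.var_subject if th.var_subject > 0 else s2e / 10.0
        beta, se = th.beta, fit.se_beta
        center = np.concatenate([beta, [np.log(s2a), np.log(s2e)]])
        base_sd = np.concatenate([np.maximum(se, 1e-8), [0.5, 0.5]])
    else:
        beta, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        resid = design.y - design.X @ beta
        s2e = float(resid @ resid) / max(design.n - p, 1)
        XtX_inv = np.linalg.inv(design.X.T @ design.X)
        se = np.sqrt(s2e * np.diag(XtX_inv))
        center = np.concatenate([beta, [np.log(s2e)]])
        base_sd = np.concatenate([np.maximum(se, 1e-8), [0.5]])
    states = [center + 0.3 * base_sd * rng.standard_normal(center.shape) for rng in rngs]
    return states, base_sd


def sample_fiducial(design: DesignRealization, config: SamplerConfig) -> FiducialDraws:
    """Sample the generalized fiducial distribution by adaptive random-walk
    Metropolis on (beta, log sigma2_a, log sigma2_e).

    The global step scale is tuned toward ``target_accept`` during warmup
    only (Robbins–Monro); at the warmup midpoint the proposal covariance is
    re-estimated from the first warmup half.  Draws are back-transformed to
    the natural scale.  Same seed and config give identical draws.
    """
    target = _FastTarget(design, config.sample_var_subject, config.sqrt_jacobian)
    d = design.p + (2 if config.sample_var_subject else 1)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    rngs = [np.random.default_rng(s) for s in seeds]
    states, base_sd = _init_states(design, config, rngs)

    n_iter = config.n_warmup + config.n_keep * config.thin
    all_draws = np.empty((config.n_chains, config.n_keep, d))
    accepted_total = 0

    for c in range(config.n_chains):
        rng = rngs[c]
        z = states[c].copy()
        lp = target(z)
        tries = 0
        while not np.isfinite(lp) and tries < 50:
            z = states[c] + 0.1 * base_sd * rng.standard_normal(d)
            lp = target(z)
            tries += 1
        if not np.isfinite(lp):
            raise RuntimeError("could not find a finite-density starting point")

        L = np.diag(base_sd)
        log_scale = np.log(config.init_step_scale / np.sqrt(d))
        half = config.n_warmup // 2
        warm_hist = np.empty((half, d))
        n_acc_chain = 0

        for t in range(n_iter):
            prop = z + np.exp(log_scale) * (L @ rng.standard_normal(d))
            lp_prop = target(prop)
            accept = np.log(rng.random()) < lp_prop - lp
            if accept:
                z, lp = prop, lp_prop
                n_acc_chain += 1
            if t < config.n_warmup:
                gamma = (t + 1.0) ** (-0.6)
                log_scale += gamma * ((1.0 if accept else 0.0) - config.target_accept)
                if t < half:
                    warm_hist[t] = z
                if t == half - 1 and half >= 2 * d:
                    cov = np.cov(warm_hist.T) + 1e-10 * np.eye(d)
                    try:
                        L = np.linalg.cholesky(cov)
                        log_scale = np.log(2.38 / np.sqrt(d))
                    except np.linalg.LinAlgError:
                        pass
            else:
                k = t - config.n_warmup
                if k % config.thin == config.thin - 1:
                    all_draws[c, k // config.thin] = z
        accepted_total += n_acc_chain

    if accepted_total == 0:
        raise RuntimeError("sampler failure: all proposals were rejected")

    # back-transform to the natural scale, padding sigma2_a = 0 if disabled
    p = design.p
    nat = np.empty((config.n_chains, config.n_keep, p + 2))
    nat[:, :, :p] = all_draws[:, :, :p]
    if config.sample_var_subject:
        nat[:, :, p] = np.exp(all_draws[:, :, p])
        nat[:, :, p + 1] = np.exp(all_draws[:, :, p + 1])
    else:
        nat[:, :, p] = 0.0
        nat[:, :, p + 1] = np.exp(all_draws[:, :, p])

    names = list(design.column_names) + ["tau00", "sigma2"]
    chain_id = np.repeat(np.arange(config.n_chains), config.n_keep)
    out = FiducialDraws(
        draws=nat.reshape(-1, p + 2),
        chain_id=chain_id,
        param_names=names,
        config=config,
        accept_rate=accepted_total / (config.n_chains * n_iter),
    )

    if config.compute_diagnostics:
        import arviz as az

        rhat = np.empty(p + 2)
        ess = np.empty(p + 2)
        for j in range(p + 2):
            col = nat[:, :, j]
            if np.allclose(col, col.flat[0]):
                rhat[j], ess[j] = 1.0, float(col.size)
                continue
            rhat[j] = float(az.rhat(col))
            ess[j] = float(az.ess(col))
        out.rhat, out.ess = rhat, ess
        if np.nanmax(rhat) > 1.05:
            msg = f"possible non-convergence: max R-hat = {np.nanmax(rhat):.3f}"
            out.warnings.append(msg)
            logger.warning(msg)
    return out


# ---------------------------------------------------------------------------
# Summaries and decisions
# ---------------------------------------------------------------------------


@dataclass
class IntervalSummary:
    """Per-parameter fiducial point estimates and equal-tailed intervals."""

    param_names: list
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.param_names,
            "estimate": self.estimate,
            "lower": self.lower,
            "upper": self.upper,
        })

    def interval_of(self, parameter: str) -> tuple[float, float]:
        j = self.param_names.index(parameter)
        return float(self.lower[j]), float(self.upper[j])


def summarize(draws: FiducialDraws, level: float = 0.95) -> IntervalSummary:
    """Means and equal-tailed quantile intervals of the fiducial draws —
    available for the variance components as well as the fixed effects."""
    if not 0.0 < level < 1.0:
        raise DomainError("level must lie in (0, 1)")
    if draws.n_draws == 0:
        raise DomainError("no draws to summarize")
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(draws.draws, alpha, axis=0)
    hi = np.quantile(draws.draws, 1.0 - alpha, axis=0)
    return IntervalSummary(
        param_names=list(draws.param_names),
        estimate=draws.draws.mean(axis=0),
        lower=lo,
        upper=hi,
        level=level,
    )


def null_effect_decision(interval: IntervalSummary | tuple[float, float],
                         parameter: str | None = None,
                         equivalence_bound: float = None) -> str:
    """Equivalence-style call on one parameter's fiducial interval.

    ``nonnull`` if the interval excludes 0; ``null`` if it contains 0 and
    lies inside (-bound, +bound) — i.e. contains no values far from 0; else
    ``inconclusive``.  The bound is analyst-supplied; there is no default.
    """
    if equivalence_bound is None or equivalence_bound <= 0:
        raise DomainError("equivalence_bound must be a positive number")
    if isinstance(interval, IntervalSummary):
        if parameter is None:
            raise DomainError("parameter name required with an IntervalSummary")
        lo, hi = interval.interval_of(parameter)
    else:
        lo, hi = float(interval[0]), float(interval[1])
    if lo > 0 or hi < 0:
        return "nonnull"
    if -equivalence_bound < lo and hi < equivalence_bound:
        return "null"
    return "inconclusive"
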