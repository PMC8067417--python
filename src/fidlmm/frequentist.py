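"""REML estimation of the random-intercept model with Satterthwaite t-tests,
the unconditional variance partition, and simple-slopes probing of
cross-level interactions.

The restricted likelihood is profiled over the fixed effects: for given
variance components (sigma2_a, sigma2_e),

    l_R = -1/2 [ (n-p) log 2pi + log|V| + log|X'V^{-1}X| + r'V^{-1}r ],

with ``r = y - X beta_hat`` and ``beta_hat`` the GLS solution.  The
optimizer works on log variances (multi-start) and the sigma2_a = 0 boundary
is checked explicitly, so a zero random-intercept variance estimate is
permitted here (unlike the fiducial sampler, which stays interior).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model_core import (
    BlockCovariance,
    ConfigurationError,
    DesignRealization,
    DomainError,
    ModelSpec,
    ModelTerm,
    Theta,
    build_design,
)

logger = logging.getLogger("fidlmm")

__all__ = [
    "FitResult",
    "reml_criterion",
    "fit_reml",
    "satterthwaite_tests",
    "variance_partition",
    "simple_slopes",
]


@dataclass
class FitResult:
    """REML fit: parameter estimates plus Wald/Satterthwaite inference."""

    theta_hat: Theta
    cov_beta: np.ndarray
    se_beta: np.ndarray
    reml_criterion: float
    converged: bool
    column_names: list
    satterthwaite_df: np.ndarray | None = None
    t_values: np.ndarray | None = None
    p_values: np.ndarray | None = None
    varcomp_cov: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy coefficient table (parameter, estimate, se, df, t, p)."""
        d = {
            "parameter": list(self.column_names),
            "estimate": self.theta_hat.beta,
            "se": self.se_beta,
        }
        if self.satterthwaite_df is not None:
            d["df"] = self.satterthwaite_df
            d["t"] = self.t_values
            d["p"] = self.p_values
        return pd.DataFrame(d)


# ---------------------------------------------------------------------------
# REML criterion and optimization
# ---------------------------------------------------------------------------


def _profile_pieces(var_subject: float, var_resid: float, design: DesignRealization):
    """GLS beta-hat and the quantities entering the restricted likelihood."""
    if not (np.isfinite(var_subject) and np.isfinite(var_resid)):
        return None
    V = BlockCovariance(var_subject, var_resid, design.group_index)
    X, y = design.X, design.y
    VinvX = V.solve(X)
    XtVinvX = X.T @ VinvX
    XtVinvy = VinvX.T @ y
    if not np.all(np.isfinite(XtVinvX)):
        return None
    try:
        beta = np.linalg.solve(XtVinvX, XtVinvy)
    except np.linalg.LinAlgError:
        return None
    quad = float(y @ V.solve(y) - beta @ XtVinvy)
    sign, logdet_xvx = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        return None
    return beta, XtVinvX, quad, V.logdet() + logdet_xvx


def reml_criterion(var_subject: float, var_resid: float, design: DesignRealization) -> float:
    """Restricted log-likelihood, profiled over the fixed effects."""
    if var_resid <= 0 or var_subject < 0:
        return -np.inf
    pieces = _profile_pieces(var_subject, var_resid, design)
    if pieces is None:
        return -np.inf
    _, _, quad, logdets = pieces
    n, p = design.n, design.p
    return -0.5 * ((n - p) * np.log(2.0 * np.pi) + logdets + quad)


def _mom_start(design: DesignRealization) -> tuple[float, float]:
    """Method-of-moments starting values from OLS residuals."""
    X, y, g = design.X, design.y, design.group_index
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sizes = np.bincount(g).astype(float)
    means = np.bincount(g, weights=resid) / sizes
    within = resid - means[g]
    dof_w = max(design.n - len(sizes) - design.p + 1, 1)
    s2e = float(within @ within) / dof_w
    s2a = max(float(np.var(means, ddof=1)) - s2e / float(np.mean(sizes)), 1e-3 * s2e)
    return s2a, max(s2e, 1e-12)


def fit_reml(design: DesignRealization) -> FitResult:
    """Maximize the profiled REML criterion over (sigma2_a, sigma2_e).

    Optimization runs on log variances from a method-of-moments start plus
    two jittered restarts; the sigma2_a = 0 boundary is evaluated separately
    and wins if it matches or beats the interior optimum.
    """
    if design.n_groups < 2:
        raise ConfigurationError("need at least 2 groups for REML")
    if design.n <= design.p + 2:
        raise ConfigurationError("too few observations")

    def neg(z):
        return -reml_criterion(np.exp(z[0]), np.exp(z[1]), design)

    s2a0, s2e0 = _mom_start(design)
    starts = [np.log([s2a0, s2e0])]
    rng = np.random.default_rng(0)  # fixed jitters: fit is deterministic
    for _ in range(2):
        starts.append(starts[0] + rng.normal(scale=1.0, size=2))

    best = None
    ok = False
    for z0 in starts:
        res = optimize.minimize(neg, z0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("REML optimization failed to produce a finite criterion")

    s2a, s2e = np.exp(best.x)
    crit = -best.fun

    # explicit sigma2_a = 0 boundary: 1-D profile over log sigma2_e
    bres = optimize.minimize_scalar(
        lambda le: -reml_criterion(0.0, np.exp(le), design),
        bracket=(np.log(s2e0) - 2, np.log(s2e0) + 2),
    )
    if np.isfinite(bres.fun) and -bres.fun >= crit - 1e-7:
        s2a, s2e, crit = 0.0, float(np.exp(bres.x)), -bres.fun
        ok = True

    pieces = _profile_pieces(s2a, s2e, design)
    if pieces is None:
        raise RuntimeError("REML solution yields a singular GLS system")
    beta, XtVinvX, _, _ = pieces
    cov_beta = np.linalg.inv(XtVinvX)
    theta = Theta(beta=beta, var_subject=float(s2a), var_resid=float(s2e))
    if not ok:
        logger.warning("REML optimizer did not report convergence (criterion %.6g)", crit)
    return FitResult(
        theta_hat=theta,
        cov_beta=cov_beta,
        se_beta=np.sqrt(np.diag(cov_beta)),
        reml_criterion=float(crit),
        converged=ok,
        column_names=list(design.column_names),
    )


# ---------------------------------------------------------------------------
# Satterthwaite degrees of freedom
# ---------------------------------------------------------------------------


def _varcomp_cov(fit: FitResult, design: DesignRealization) -> np.ndarray | None:
    """Asymptotic covariance of (sigma2_a_hat, sigma2_e_hat): inverse of the
    negative Hessian of the restricted likelihood on the variance scale."""
    s2a, s2e = fit.theta_hat.var_subject, fit.theta_hat.var_resid
    h = np.array([max(s2a, 1e-4 * s2e) * 1e-4, s2e * 1e-4])

    def f(v):
        return reml_criterion(max(v[0], 0.0), v[1], design)

    x0 = np.array([s2a, s2e])
    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            H[i, j] = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or cov[0, 0] < 0 or cov[1, 1] < 0:
        return None
    return cov


def _coef_variance(l: np.ndarray, var_subject: float, var_resid: float,
                   design: DesignRealization) -> float:
    """l' (X'V^{-1}X)^{-1} l at the given variance components."""
    V = BlockCovariance(max(var_subject, 0.0), var_resid, design.group_index)
    XtVinvX = design.X.T @ V.solve(design.X)
    return float(l @ np.linalg.solve(XtVinvX, l))


def _satterthwaite_df_for(l: np.ndarray, fit: FitResult, design: DesignRealization,
                          varcomp_cov: np.ndarray | None) -> float:
    """Moment-matched df for the variance of the contrast l'beta_hat."""
    n, p = design.n, design.p
    fallback = float(n - p)
    if varcomp_cov is None:
        return fallback
    s2a, s2e = fit.theta_hat.var_subject, fit.theta_hat.var_resid
    h = np.array([max(s2a, 1e-3 * s2e) * 1e-3, s2e * 1e-3])
    c0 = _coef_variance(l, s2a, s2e, design)
    grad = np.empty(2)
    for i in range(2):
        e = np.eye(2)[i] * h[i]
        lo = max(s2a - e[0], 0.0) if i == 0 else s2a
        hi_a = s2a + e[0] if i == 0 else s2a
        if i == 0:
            cp = _coef_variance(l, hi_a, s2e, design)
            cm = _coef_variance(l, lo, s2e, design)
            grad[i] = (cp - cm) / (hi_a - lo) if hi_a > lo else 0.0
        else:
            cp = _coef_variance(l, s2a, s2e + h[1], design)
            cm = _coef_variance(l, s2a, s2e - h[1], design)
            grad[i] = (cp - cm) / (2 * h[1])
    denom = float(grad @ varcomp_cov @ grad)
    if denom <= 0:
        return fallback
    df = 2.0 * c0 * c0 / denom
    if not np.isfinite(df) or df <= 0:
        logger.warning("non-positive Satterthwaite df; falling back to n - p")
        return fallback
    # a flat variance-component ridge (e.g. boundary tau00 = 0) sends the
    # moment-matched df to infinity; the regression df is the usable cap
    return float(min(df, fallback))


def satterthwaite_tests(fit: FitResult, design: DesignRealization) -> FitResult:
    """Attach Satterthwaite-df t-tests for every fixed effect."""
    if not fit.converged:
        logger.warning("satterthwaite_tests on a fit that did not report convergence")
    vc = _varcomp_cov(fit, design)
    p = design.p
    df = np.empty(p)
    for j in range(p):
        l = np.zeros(p)
        l[j] = 1.0
        df[j] = _satterthwaite_df_for(l, fit, design, vc)
    t = fit.theta_hat.beta / fit.se_beta
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return replace(fit, satterthwaite_df=df, t_values=t, p_values=pvals, varcomp_cov=vc)


# ---------------------------------------------------------------------------
# Unconditional variance partition
# ---------------------------------------------------------------------------


def variance_partition(table: pd.DataFrame, response: str = "sbp_r",
                       grouping: str = "subject_id"):
    """Fit the unconditional (intercept-only) model and split the variance.

    Returns ``(within_share, between_share, sigma2, tau00)`` with the shares
    as percentages of the total sigma2 + tau00.
    """
    spec = ModelSpec(response=response, fixed_terms=(), grouping=grouping)
    design = build_design(table, spec)
    sizes = np.bincount(design.group_index)
    if (sizes >= 2).sum() < 2:
        raise ConfigurationError("need >= 2 subjects with >= 2 observations")
    fit = fit_reml(design)
    s2, t00 = fit.theta_hat.var_resid, fit.theta_hat.var_subject
    total = s2 + t00
    if total <= 0:
        raise DomainError("degenerate variance: sigma2 + tau00 <= 0")
    return 100.0 * s2 / total, 100.0 * t00 / total, s2, t00


# ---------------------------------------------------------------------------
# Simple slopes
# ---------------------------------------------------------------------------


def simple_slopes(fit: FitResult, design: DesignRealization, focal: ModelTerm,
                  moderator: ModelTerm, at: tuple[float, ...] = (-1.0, 1.0)) -> pd.DataFrame:
    """Conditional slopes of ``focal`` at moderator mean + a*SD.

    The moderator SD is computed between persons (one value per subject,
    moderators being person-level).  SEs come from the delta method on the
    GLS coefficient covariance; df and p are Satterthwaite for the contrast.
    """
    if isinstance(focal, str):
        focal = ModelTerm.parse(focal)
    if isinstance(moderator, str):
        moderator = ModelTerm.parse(moderator)
    interaction = ModelTerm(tuple(focal.factors) + tuple(moderator.factors))
    j_f = design.column_of(focal)
    j_m = design.column_of(moderator)
    try:
        j_i = design.column_of(interaction)
    except ConfigurationError:
        # factor order in the stored term may differ
        matches = [t for t in design.term_map
                   if set(t.factors) == set(interaction.factors)]
        if not matches:
            raise ConfigurationError(
                f"model lacks the {interaction.name!r} interaction") from None
        j_i = design.column_of(matches[0])

    # between-person moderator distribution
    mvals = design.X[:, j_m]
    first = np.full(design.n_groups, np.nan)
    for g in range(design.n_groups):
        first[g] = mvals[design.group_index == g][0]
    m_mean, m_sd = float(np.mean(first)), float(np.std(first, ddof=1))

    vc = fit.varcomp_cov if fit.varcomp_cov is not None else _varcomp_cov(fit, design)
    rows = []
    for a in at:
        x = m_mean + a * m_sd
        l = np.zeros(design.p)
        l[j_f] = 1.0
        l[j_i] = x
        slope = float(l @ fit.theta_hat.beta)
        se = float(np.sqrt(l @ fit.cov_beta @ l))
        df = _satterthwaite_df_for(l, fit, design, vc)
        t = slope / se
        rows.append({
            "at_sd": a,
            "moderator_value": x,
            "slope": slope,
            "se": se,
            "df": df,
            "t": t,
            "p": float(2.0 * stats.t.sf(abs(t), df)),
        })
    return pd.DataFrame(rows)
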