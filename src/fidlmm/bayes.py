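"""Default-prior (Jeffreys–Zellner–Siow) Bayes factors and all-subsets model
comparison against the intercept-only null.

Each candidate model keeps the random intercept as a nuisance term (the null
is itself a multilevel model).  Effects are standardized and given
g-priors: conditional on a vector of g parameters, effects are
N(0, sigma2 g) on their standardized columns, the grand mean and sigma2
carry Jeffreys priors, and each g has the scaled inverse-chi^2(1) mixing
density implied by a half-Cauchy scale — so integrating over g produces the
Cauchy-tailed JZS marginal.  The conditional-on-g marginal of the data is
available in closed form; the g integral is evaluated by adaptive
quadrature (<= 2 g dimensions) or Laplace-guided importance sampling.

By default the continuous fixed-effect columns share one g (scale
sqrt(2)/4), binary columns share one g (scale 0.5) and the random intercept
has its own g (scale 1); ``per_term_g=True`` gives every term its own g.
Bayes factors K are reported against the intercept-only null, so the null's
K is identically 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special

from .model_core import (
    ConfigurationError,
    DesignRealization,
    DomainError,
    ModelSpec,
    ModelTerm,
)

__all__ = [
    "PriorScales",
    "BayesComparison",
    "enumerate_models",
    "jzs_log_marginal",
    "compare_all",
    "interpret_ratio",
]


@dataclass(frozen=True)
class PriorScales:
    """Half-Cauchy scales of the g-prior mixing densities."""

    fixed: float = 0.5                      # binary / factor-like effects ("medium")
    continuous: float = math.sqrt(2.0) / 4  # continuous covariates
    random: float = 1.0                     # random-intercept block ("nuisance")


# ---------------------------------------------------------------------------
# Model enumeration under marginality
# ---------------------------------------------------------------------------


def _respects_marginality(subset: frozenset, candidates: list[ModelTerm]) -> bool:
    """Every interaction in ``subset`` has all its lower-order candidate
    terms (terms whose factor set is a proper subset of its own) present."""
    for t in subset:
        if t.order < 2:
            continue
        tf = set(t.factors)
        for u in candidates:
            if u is not t and set(u.factors) < tf and u not in subset:
                return False
    return True


def enumerate_models(candidate_terms, always_include=(), response: str = "sbp_r",
                     grouping: str = "subject_id",
                     random_intercept: bool = True) -> list[ModelSpec]:
    """All subsets of ``candidate_terms`` that contain ``always_include`` and
    respect marginality; the intercept (and random intercept) is implicit in
    every model, so the empty subset is the intercept-only null.

    Ordering is canonical: by model size, then by candidate-term positions.
    """
    cands = [t if isinstance(t, ModelTerm) else ModelTerm.parse(t) for t in candidate_terms]
    if len(set(cands)) != len(cands):
        raise ConfigurationError("duplicate candidate terms")
    forced = [t if isinstance(t, ModelTerm) else ModelTerm.parse(t) for t in always_include]
    for t in forced:
        if t not in cands:
            raise ConfigurationError(f"always_include term {t.name!r} not a candidate")

    pos = {t: i for i, t in enumerate(cands)}
    specs = []
    for subset in chain.from_iterable(combinations(cands, k) for k in range(len(cands) + 1)):
        sset = frozenset(subset)
        if not all(t in sset for t in forced):
            continue
        if not _respects_marginality(sset, cands):
            continue
        ordered = tuple(sorted(subset, key=pos.__getitem__))
        specs.append(ModelSpec(response=response, fixed_terms=ordered,
                               grouping=grouping, random_intercept=random_intercept))
    specs.sort(key=lambda s: (len(s.fixed_terms), tuple(pos[t] for t in s.fixed_terms)))
    return specs


# ---------------------------------------------------------------------------
# JZS marginal likelihood engine
# ---------------------------------------------------------------------------


def _log_invgamma_half(g: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """log density of g ~ InverseGamma(1/2, r^2/2) (sqrt(g) half-Cauchy(r))."""
    return 0.5 * np.log(r2 / 2.0) - special.gammaln(0.5) - 1.5 * np.log(g) - r2 / (2.0 * g)


class _JzsEngine:
    """Closed-form conditional marginal m(y|g) for one design, shared across
    candidate sub-models (columns are selected per model)."""

    def __init__(self, design: DesignRealization, scales: PriorScales,
                 per_term_g: bool = False):
        self.design = design
        self.scales = scales
        self.per_term_g = per_term_g
        y = design.y.astype(float)
        self.n = y.shape[0]
        # response standardization: affects only model-independent constants
        y = (y - y.mean()) / y.std(ddof=1)
        self.y = y
        self.yty = float(y @ y)
        self.oty = float(y.sum())  # = 0 after centering, kept for clarity

        # standardized fixed-effect columns (skip the intercept column)
        self.cols = {}
        self.col_scale = {}
        for term, j in design.term_map.items():
            c = design.X[:, j].astype(float)
            sd = c.std(ddof=1)
            if sd <= 0:
                raise DomainError(f"zero-variance column for term {term.name!r}")
            self.cols[term] = (c - c.mean()) / sd
            nuniq = len(np.unique(design.X[:, j]))
            self.col_scale[term] = scales.fixed if nuniq <= 2 else scales.continuous

        self.random = bool(design.spec.random_intercept) if design.spec else True
        if self.random:
            g = design.group_index
            q = int(g.max()) + 1
            Z = np.zeros((self.n, q))
            Z[np.arange(self.n), g] = 1.0
            self.Z = Z
        else:
            self.Z = None

    # -- g structure per candidate -------------------------------------------

    def g_structure(self, terms: tuple[ModelTerm, ...]):
        """Columns W, per-column g-group index, and per-group Cauchy scale."""
        Wcols, gidx, group_of = [], [], {}
        scales_list = []

        def group_for(key, scale):
            if key not in group_of:
                group_of[key] = len(scales_list)
                scales_list.append(scale)
            return group_of[key]

        for t in terms:
            key = ("term", t) if self.per_term_g else ("class", self.col_scale[t])
            k = group_for(key, self.col_scale[t])
            Wcols.append(self.cols[t])
            gidx.append(k)
        if self.random:
            k = group_for(("random",), self.scales.random)
            for j in range(self.Z.shape[1]):
                Wcols.append(self.Z[:, j])
                gidx.append(k)
        W = np.column_stack(Wcols) if Wcols else np.zeros((self.n, 0))
        return W, np.asarray(gidx, dtype=int), np.asarray(scales_list, dtype=float)

    # -- conditional marginal --------------------------------------------------

    def log_marginal_given_g(self, pre, g: np.ndarray) -> float:
        """log m(y | g): Jeffreys on (mu, sigma2), effects integrated out."""
        WtW, Wty, Wt1, gidx = pre
        n = self.n
        const = (special.gammaln((n - 1) / 2.0)
                 - ((n - 1) / 2.0) * np.log(np.pi))
        if WtW.shape[0] == 0:
            Q = self.yty - self.oty ** 2 / n
            return const - 0.5 * np.log(n) - ((n - 1) / 2.0) * np.log(Q)
        dvec = np.sqrt(g[gidx])
        B = np.eye(WtW.shape[0]) + (dvec[:, None] * WtW) * dvec[None, :]
        try:
            L = np.linalg.cholesky(B)
        except np.linalg.LinAlgError:
            return -np.inf
        logdetB = 2.0 * np.sum(np.log(np.diag(L)))
        ay = dvec * Wty
        a1 = dvec * Wt1
        sy = np.linalg.solve(L, ay)
        s1 = np.linalg.solve(L, a1)
        yPy = self.yty - sy @ sy
        oPo = float(n - s1 @ s1)
        if oPo <= 0:
            return -np.inf
        oPy = self.oty - s1 @ sy
        Q = yPy - oPy ** 2 / oPo
        if Q <= 0:
            return -np.inf
        return const - 0.5 * logdetB - 0.5 * np.log(oPo) - ((n - 1) / 2.0) * np.log(Q)

    def precompute(self, terms: tuple[ModelTerm, ...]):
        W, gidx, gscales = self.g_structure(terms)
        return (W.T @ W, W.T @ self.y, W.T @ np.ones(self.n), gidx), gscales

    # -- the g integral --------------------------------------------------------

    def log_marginal(self, terms: tuple[ModelTerm, ...], method: str = "auto",
                     n_importance: int = 4000, seed: int = 0) -> tuple[float, float]:
        """Integrate m(y|g) over the g mixing densities.

        Returns (log marginal, error estimate on the log scale).
        """
        pre, gscales = self.precompute(terms)
        m = gscales.shape[0]
        if m == 0:
            return self.log_marginal_given_g(pre, np.empty(0)), 0.0
        r2 = gscales ** 2

        def log_f(z):
            z = np.asarray(z, dtype=float)
            g = np.exp(z)
            return (self.log_marginal_given_g(pre, g)
                    + float(np.sum(_log_invgamma_half(g, r2) + z)))

        # Laplace fit in z = log g
        res = optimize.minimize(lambda z: -log_f(z), np.zeros(m), method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
        zhat, shift = res.x, -res.fun
        hdiag = np.empty(m)
        h = 1e-3
        for i in range(m):
            e = np.zeros(m)
            e[i] = h
            hdiag[i] = -(log_f(zhat + e) - 2.0 * shift + log_f(zhat - e)) / h ** 2
        sd = 1.0 / np.sqrt(np.maximum(hdiag, 1e-4))

        if method == "auto":
            method = "quadrature" if m <= 2 else "importance"

        if method == "quadrature":
            if m > 2:
                raise DomainError("quadrature path supports at most 2 g dimensions")
            # the right tail in z = log g decays only exponentially (Cauchy
            # mixing), so pad the Laplace-width window generously
            los = zhat - 10 * sd - 5.0
            his = zhat + 10 * sd + 30.0
            if m == 1:
                val, err = integrate.quad(
                    lambda z: math.exp(log_f([z]) - shift), los[0], his[0], limit=300)
            else:
                val, err = integrate.dblquad(
                    lambda z1, z0: math.exp(log_f([z0, z1]) - shift),
                    los[0], his[0], los[1], his[1], epsabs=1e-10, epsrel=1e-8)
            if val <= 0:
                raise RuntimeError("quadrature produced a non-positive integral")
            return shift + math.log(val), err / val

        # importance sampling from a multivariate-t(4) Laplace proposal
        rng = np.random.default_rng(seed)
        nu = 4.0
        zs = zhat + sd * (rng.standard_normal((n_importance, m))
                          / np.sqrt(rng.chisquare(nu, size=(n_importance, m)) / nu))
        log_q = np.sum(
            special.gammaln((nu + 1) / 2) - special.gammaln(nu / 2)
            - 0.5 * np.log(nu * np.pi) - np.log(sd)
            - ((nu + 1) / 2) * np.log1p(((zs - zhat) / sd) ** 2 / nu),
            axis=1,
        )
        log_w = np.array([log_f(z) for z in zs]) - log_q
        mx = np.max(log_w)
        w = np.exp(log_w - mx)
        mean_w = float(np.mean(w))
        err = float(np.std(w, ddof=1) / math.sqrt(n_importance) / mean_w)
        return mx + math.log(mean_w), err


def jzs_log_marginal(design: DesignRealization, spec: ModelSpec | None = None,
                     scales: PriorScales = PriorScales(), method: str = "auto",
                     per_term_g: bool = False, n_importance: int = 4000,
                     seed: int = 0) -> tuple[float, float]:
    """JZS log marginal likelihood of one model (up to a y-standardization
    constant that cancels in Bayes factors) and its error estimate.

    On an error estimate above 0.02 (log scale) the integral is retried with
    a quadrupled budget before raising.
    """
    terms = spec.fixed_terms if spec is not None else (design.spec.fixed_terms
                                                       if design.spec else ())
    engine = _JzsEngine(design, scales, per_term_g=per_term_g)
    val, err = engine.log_marginal(terms, method=method,
                                   n_importance=n_importance, seed=seed)
    if err > 0.02:
        val, err = engine.log_marginal(terms, method=method,
                                       n_importance=4 * n_importance, seed=seed + 1)
        if err > 0.05:
            raise RuntimeError(f"g-integration error too large: {err:.3g}")
    return val, err


# ---------------------------------------------------------------------------
# All-subsets comparison
# ---------------------------------------------------------------------------


@dataclass
class BayesComparison:
    """Per-candidate Bayes factors K against the intercept-only null."""

    candidates: list
    log_K: np.ndarray
    mc_error: np.ndarray
    prior_scales: PriorScales
    best_index: int = field(init=False)

    def __post_init__(self):
        self.log_K = np.asarray(self.log_K, dtype=float)
        self.best_index = int(np.argmax(self.log_K))

    def ratio(self, i: int, j: int) -> float:
        """K_i / K_j."""
        return float(np.exp(self.log_K[i] - self.log_K[j]))

    def ratios_to_best(self) -> np.ndarray:
        return np.exp(self.log_K - self.log_K[self.best_index])

    def to_frame(self) -> pd.DataFrame:
        labels = [" + ".join(t.name for t in s.fixed_terms) or "(intercept only)"
                  for s in self.candidates]
        df = pd.DataFrame({
            "model": labels,
            "n_terms": [len(s.fixed_terms) for s in self.candidates],
            "log10_K": self.log_K / np.log(10.0),
            "K_ratio_to_best": self.ratios_to_best(),
            "mc_error": self.mc_error,
        })
        df["label"] = [interpret_ratio(r) if r > 0 else "anecdotal"
                       for r in df["K_ratio_to_best"]]
        return df.sort_values("log10_K", ascending=False).reset_index(drop=True)


def compare_all(design: DesignRealization, candidate_terms, scales: PriorScales = PriorScales(),
                always_include=(), method: str = "auto", per_term_g: bool = False,
                n_importance: int = 4000, seed: int = 0) -> BayesComparison:
    """K for every marginality-respecting subset of ``candidate_terms``
    versus the intercept-only null (random intercept retained throughout).

    ``design`` must realize all candidate terms (their columns are selected
    per sub-model).
    """
    spec0 = design.spec
    specs = enumerate_models(
        candidate_terms, always_include,
        response=spec0.response if spec0 else "y",
        grouping=spec0.grouping if spec0 else "subject_id",
        random_intercept=spec0.random_intercept if spec0 else True)
    for s in specs:
        for t in s.fixed_terms:
            if t not in design.term_map:
                raise ConfigurationError(f"design lacks candidate term {t.name!r}")

    engine = _JzsEngine(design, scales, per_term_g=per_term_g)
    lm0, err0 = engine.log_marginal((), method=method, n_importance=n_importance, seed=seed)
    log_K = np.empty(len(specs))
    errs = np.empty(len(specs))
    for i, s in enumerate(specs):
        if s.fixed_terms:
            lm, err = engine.log_marginal(s.fixed_terms, method=method,
                                          n_importance=n_importance, seed=seed + i + 1)
        else:
            lm, err = lm0, err0
        log_K[i] = lm - lm0
        errs[i] = math.hypot(err, err0)
    return BayesComparison(candidates=specs, log_K=log_K, mc_error=errs,
                           prior_scales=scales)


def interpret_ratio(ratio: float) -> str:
    """Heuristic evidence label for a K ratio; symmetric under reciprocals."""
    if not ratio > 0:
        raise DomainError("ratio must be positive")
    r = ratio if ratio >= 1.0 else 1.0 / ratio
    if r >= 20.0:
        return "strong"
    if r >= 10.0:
        return "substantial"
    return "anecdotal"
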