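"""Random-intercept linear mixed model: terms, design matrices and the
marginal Gaussian likelihood.

The model analysed throughout this package is the two-level multilevel model

    y_ti = x_ti' beta + u_i + e_ti,   u_i ~ N(0, sigma2_a),  e_ti ~ N(0, sigma2_e),

for repeated observations t nested in subjects i.  Marginally,

    y ~ N(X beta, V),   V = sigma2_a * S_a + sigma2_e * I_n,

where ``S_a`` is the same-subject indicator matrix.  ``V`` is block diagonal
by subject with blocks ``sigma2_e I + sigma2_a 11'``, which this module
exploits for O(n) solves and log-determinants (Sherman–Morrison within each
block).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("fidlmm")

__all__ = [
    "ConfigurationError",
    "DomainError",
    "SingularDesignError",
    "ModelTerm",
    "ModelSpec",
    "DesignRealization",
    "Theta",
    "BlockCovariance",
    "validate_table",
    "build_design",
    "marginal_covariance",
    "log_marginal_likelihood",
]


class ConfigurationError(ValueError):
    """A model specification refers to something the data do not provide."""


class SingularDesignError(ValueError):
    """The fixed-effects design matrix is rank deficient."""


class DomainError(ValueError):
    """A parameter value lies outside the parameter space."""


# ---------------------------------------------------------------------------
# Terms and model specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelTerm:
    """A fixed-effect term: one covariate name for a main effect, several for
    an interaction (the design column is the elementwise product)."""

    factors: tuple[str, ...]

    def __init__(self, factors):
        if isinstance(factors, str):
            factors = (factors,)
        factors = tuple(factors)
        if not factors:
            raise ConfigurationError("a term needs at least one factor")
        if len(set(factors)) != len(factors):
            raise ConfigurationError(f"duplicate factor in term {factors}")
        object.__setattr__(self, "factors", factors)

    @property
    def order(self) -> int:
        return len(self.factors)

    @property
    def name(self) -> str:
        return ":".join(self.factors)

    @classmethod
    def parse(cls, text: str) -> "ModelTerm":
        """Parse ``"a"`` or ``"a:b"`` / ``"a*b"`` / ``"a×b"`` into a term."""
        for sep in (":", "*", "×"):
            text = text.replace(sep, ":")
        return cls(tuple(p.strip() for p in text.split(":") if p.strip()))

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model: response, fixed terms (intercept implicit) and the
    subject grouping carrying the random intercept."""

    response: str
    fixed_terms: tuple[ModelTerm, ...] = ()
    grouping: str = "subject_id"
    random_intercept: bool = True

    def __post_init__(self):
        terms = tuple(
            t if isinstance(t, ModelTerm) else ModelTerm.parse(t) for t in self.fixed_terms
        )
        if len(set(terms)) != len(terms):
            raise ConfigurationError("duplicate fixed terms in model spec")
        object.__setattr__(self, "fixed_terms", terms)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "fixed_terms": [t.name for t in self.fixed_terms],
            "grouping": self.grouping,
            "random_intercept": self.random_intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            response=d["response"],
            fixed_terms=tuple(ModelTerm.parse(t) for t in d.get("fixed_terms", [])),
            grouping=d.get("grouping", "subject_id"),
            random_intercept=bool(d.get("random_intercept", True)),
        )


@dataclass(frozen=True)
class Theta:
    """Model parameters: fixed effects, random-intercept variance tau00 and
    residual variance sigma2."""

    beta: np.ndarray
    var_subject: float
    var_resid: float

    def __post_init__(self):
        object.__setattr__(self, "beta", np.atleast_1d(np.asarray(self.beta, dtype=float)))
        if not np.all(np.isfinite(self.beta)):
            raise DomainError("beta must be finite")
        if not np.isfinite(self.var_subject) or self.var_subject < 0:
            raise DomainError("var_subject must be finite and >= 0")
        if not np.isfinite(self.var_resid) or self.var_resid <= 0:
            raise DomainError("var_resid must be finite and > 0")

    @property
    def p(self) -> int:
        return self.beta.shape[0]


@dataclass
class DesignRealization:
    """Realized response vector, design matrix and grouping for one model."""

    y: np.ndarray
    X: np.ndarray
    group_index: np.ndarray
    term_map: dict = field(default_factory=dict)
    column_names: list = field(default_factory=list)
    spec: ModelSpec | None = None

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_groups(self) -> int:
        return int(self.group_index.max()) + 1 if self.n else 0

    def column_of(self, term: ModelTerm) -> int:
        try:
            return self.term_map[term]
        except KeyError:
            raise ConfigurationError(f"term {term.name!r} is not in the design") from None


# ---------------------------------------------------------------------------
# Table validation and design construction
# ---------------------------------------------------------------------------

PERSON_LEVEL_PREFIXES = (
    "sbp_baseline",
    "cognition",
    "physical",
    "mental",
    "log_cortisol",
)


def validate_table(table: pd.DataFrame, subject_col: str = "subject_id") -> pd.DataFrame:
    """Basic structural checks on a long-format repeated-measures table.

    Checks the tertile index range, the per-subject row cap of 24
    (2 waves x 12 tertiles) and that person-level covariates are constant
    within subject.  Returns the table unchanged.
    """
    if subject_col not in table.columns:
        raise ConfigurationError(f"missing column {subject_col!r}")
    if "tertile" in table.columns:
        t = pd.to_numeric(table["tertile"])
        if not ((t >= 1) & (t <= 12)).all():
            raise ConfigurationError("tertile must lie in 1..12")
    counts = table.groupby(subject_col, observed=True).size()
    if (counts > 24).any():
        bad = counts[counts > 24].index.tolist()
        raise ConfigurationError(f"subjects with more than 24 rows: {bad}")
    person_cols = [
        c
        for c in table.columns
        if any(c.startswith(p) for p in PERSON_LEVEL_PREFIXES)
    ]
    for col in person_cols:
        nun = table.dropna(subset=[col]).groupby(subject_col, observed=True)[col].nunique()
        if (nun > 1).any():
            raise ConfigurationError(f"person-level column {col!r} varies within subject")
    return table


def _term_column(table: pd.DataFrame, term: ModelTerm) -> np.ndarray:
    col = np.ones(len(table))
    for f in term.factors:
        col = col * pd.to_numeric(table[f]).to_numpy(dtype=float)
    return col


def build_design(table: pd.DataFrame, spec: ModelSpec) -> DesignRealization:
    """Realize a :class:`ModelSpec` against a table.

    Rows with missing values in any referenced column are dropped (the count
    is logged).  The design matrix has an all-ones intercept first, then one
    column per fixed term in spec order; interaction columns are raw
    elementwise products of their factors' columns.
    """
    referenced = {spec.response, spec.grouping}
    for t in spec.fixed_terms:
        referenced.update(t.factors)
    missing_cols = sorted(c for c in referenced if c not in table.columns)
    if missing_cols:
        raise ConfigurationError(f"unknown column(s): {missing_cols}")

    kept = table.dropna(subset=sorted(referenced))
    n_dropped = len(table) - len(kept)
    if n_dropped:
        logger.info("build_design: dropped %d rows with missing values", n_dropped)

    groups, _ = pd.factorize(kept[spec.grouping], use_na_sentinel=False)
    n_groups = int(groups.max()) + 1 if len(groups) else 0
    if n_groups < 2:
        raise ConfigurationError("need at least 2 subjects")

    y = pd.to_numeric(kept[spec.response]).to_numpy(dtype=float)
    cols = [np.ones(len(kept))]
    names = ["intercept"]
    term_map: dict[ModelTerm, int] = {}
    for j, term in enumerate(spec.fixed_terms, start=1):
        cols.append(_term_column(kept, term))
        names.append(term.name)
        term_map[term] = j
    X = np.column_stack(cols)
    n, p = X.shape
    if n < p + 2:
        raise ConfigurationError(f"too few rows after dropping missing values (n={n}, p={p})")

    if np.linalg.matrix_rank(X) < p:
        # name the offending terms: a column lying (numerically) in the span
        # of the preceding columns
        bad = []
        for j in range(1, p):
            sub = X[:, :j]
            coef, *_ = np.linalg.lstsq(sub, X[:, j], rcond=None)
            resid = X[:, j] - sub @ coef
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
                bad.append(names[j])
        raise SingularDesignError(f"design matrix is rank deficient; collinear terms: {bad}")

    return DesignRealization(
        y=y,
        X=X,
        group_index=np.asarray(groups, dtype=np.intp),
        term_map=term_map,
        column_names=names,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Block-structured marginal covariance
# ---------------------------------------------------------------------------


class BlockCovariance:
    """Handle for V = sigma2_a S_a + sigma2_e I_n with per-subject blocks.

    Within subject i of size n_i the block is ``sigma2_e I + sigma2_a 11'``;
    Sherman–Morrison gives the O(n) solve

        V^{-1} v = v / sigma2_e - sigma2_a / (sigma2_e (sigma2_e + n_i sigma2_a)) (1'v) 1

    and the log determinant is ``sum_i [(n_i-1) log sigma2_e +
    log(sigma2_e + n_i sigma2_a)]``.
    """

    def __init__(self, var_subject: float, var_resid: float, group_index: np.ndarray):
        if not np.isfinite(var_resid) or var_resid <= 0:
            raise DomainError("var_resid must be > 0")
        if not np.isfinite(var_subject) or var_subject < 0:
            raise DomainError("var_subject must be >= 0")
        self.var_subject = float(var_subject)
        self.var_resid = float(var_resid)
        self.group_index = np.asarray(group_index, dtype=np.intp)
        self.n = self.group_index.shape[0]
        self.n_groups = int(self.group_index.max()) + 1 if self.n else 0
        self.group_sizes = np.bincount(self.group_index, minlength=self.n_groups).astype(float)

    # -- group machinery -----------------------------------------------------

    def group_sums(self, v: np.ndarray) -> np.ndarray:
        """Per-group sums of v; columns handled independently for matrices."""
        v = np.asarray(v, dtype=float)
        if v.ndim == 1:
            return np.bincount(self.group_index, weights=v, minlength=self.n_groups)
        out = np.empty((self.n_groups, v.shape[1]))
        for k in range(v.shape[1]):
            out[:, k] = np.bincount(self.group_index, weights=v[:, k], minlength=self.n_groups)
        return out

    def sa_apply(self, v: np.ndarray) -> np.ndarray:
        """S_a v: broadcast the within-group sum back to rows."""
        return self.group_sums(v)[self.group_index]

    # -- covariance operations ------------------------------------------------

    def solve(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        s = self.group_sums(r)
        shrink = self.var_subject / (self.var_resid * (self.var_resid + self.group_sizes * self.var_subject))
        if r.ndim == 2:
            shrink = shrink[:, None]
        return r / self.var_resid - (shrink * s)[self.group_index]

    def logdet(self) -> float:
        return float(
            np.sum((self.group_sizes - 1.0) * np.log(self.var_resid))
            + np.sum(np.log(self.var_resid + self.group_sizes * self.var_subject))
        )

    def quad_form(self, r: np.ndarray) -> float:
        """r' V^{-1} r."""
        return float(r @ self.solve(r))

    def dense(self) -> np.ndarray:
        """Materialize V (testing / tiny n only)."""
        same = self.group_index[:, None] == self.group_index[None, :]
        return self.var_subject * same + self.var_resid * np.eye(self.n)


def marginal_covariance(theta: Theta, group_index: np.ndarray) -> BlockCovariance:
    """The marginal covariance V implied by ``theta`` and the grouping."""
    return BlockCovariance(theta.var_subject, theta.var_resid, group_index)


def log_marginal_likelihood(theta: Theta, design: DesignRealization) -> float:
    """log N(y; X beta, V) via the block structure."""
    if theta.p != design.p:
        raise DomainError(f"beta has length {theta.p}, design has p={design.p}")
    V = marginal_covariance(theta, design.group_index)
    r = design.y - design.X @ theta.beta
    return -0.5 * (design.n * np.log(2.0 * np.pi) + V.logdet() + V.quad_form(r))
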