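"""Synthetic data with the statistical structure of the study design: a
random-intercept two-level model over 2 waves x 12 tertiles per subject,
person-level moderators and cross-level interactions.

Defaults mirror the study conditions: 28 subjects, up to 24 rows each with
~25% completely-at-random missingness (so roughly 504 of 672 rows remain),
generating variances tau00 = 125.97 and sigma2 = 131.22 (the published
unconditional variance partition), fixed effects from the published Model 1
estimates, and covariate moments from the descriptive table (e.g.
log-cortisol mean 2.35, SD 1.47).  Wave-2 covariates are correlated
perturbations of wave 1 so change-moderator models are estimable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model_core import ConfigurationError, ModelSpec, ModelTerm, Theta
from .dataprep import SbpTrace

__all__ = [
    "SyntheticConfig",
    "TraceConfig",
    "simulate_dataset",
    "simulate_trace",
    "coverage_study",
]

# study-condition defaults: published Model 1 estimates as generating truth
DEFAULT_BETA = {
    "intercept": 5.82,
    "tertile": -0.33,
    "sbp_baseline": 0.22,
    "cognition": -11.82,
    "physical_challenges_w1": -6.59,
    "cognition:tertile": 0.32,
    "physical_challenges_w1:tertile": 0.13,
}

# descriptive-table moments (mean, SD) for person-level covariates
DEFAULT_COVARIATES = {
    "sbp_baseline": (130.92, 21.31),
    "cognition": (-0.03, 0.90),
    "physical_challenges_w1": (-0.04, 0.67),
    "mental_challenges_w1": (0.01, 0.68),
    "log_cortisol_w1": (2.35, 1.47),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the study conditions."""

    seed: int
    n_subjects: int = 28
    n_waves: int = 2
    tertiles_per_wave: int = 12
    missing_rate: float = 0.25
    beta: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    tau00: float = 125.97
    sigma2: float = 131.22
    covariates: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    wave_correlation: float = 0.6

    def __post_init__(self):
        if self.tau00 < 0 or self.sigma2 < 0:
            raise ConfigurationError("variances must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.n_subjects < 2:
            raise ConfigurationError("need at least 2 subjects")
        if "intercept" not in self.beta:
            raise ConfigurationError("beta must include an 'intercept' entry")

    def model_spec(self, response: str = "sbp_r") -> ModelSpec:
        """The ModelSpec matching the generating fixed effects."""
        terms = tuple(ModelTerm.parse(k) for k in self.beta if k != "intercept")
        return ModelSpec(response=response, fixed_terms=terms, grouping="subject_id")

    def true_theta(self) -> Theta:
        beta = np.array([self.beta["intercept"]]
                        + [v for k, v in self.beta.items() if k != "intercept"])
        return Theta(beta=beta, var_subject=self.tau00,
                     var_resid=max(self.sigma2, 1e-12))


def _draw_covariates(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.n_subjects
    cov = {"subject_id": [f"s{i:03d}" for i in range(m)]}
    rho = config.wave_correlation
    for name, (mean, sd) in config.covariates.items():
        z1 = rng.standard_normal(m)
        cov[name] = mean + sd * z1
        if name.endswith("_w1"):
            z2 = rho * z1 + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(m)
            cov[name[:-3] + "_w2"] = mean + sd * z2
    return pd.DataFrame(cov)


def simulate_dataset(config: SyntheticConfig) -> tuple[pd.DataFrame, Theta]:
    """Draw one long-format dataset plus its generating parameters.

    The response follows the two-level algebra exactly: X beta from the
    configured terms, plus a subject random intercept u0_i ~ N(0, tau00)
    and residual e ~ N(0, sigma2).  Missingness is completely at random,
    with two rows per subject exempted so every subject stays estimable.
    Byte-identical under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    persons = _draw_covariates(config, rng)

    frames = []
    for wave in range(1, config.n_waves + 1):
        for tert in range(1, config.tertiles_per_wave + 1):
            f = persons.copy()
            f["wave"] = wave
            f["tertile"] = tert
            f["level"] = (tert - 1) // 3 + 1
            frames.append(f)
    table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["subject_id", "wave", "tertile"]).reset_index(drop=True)

    eta = np.full(len(table), config.beta["intercept"], dtype=float)
    for key, b in config.beta.items():
        if key == "intercept":
            continue
        term = ModelTerm.parse(key)
        col = np.ones(len(table))
        for f in term.factors:
            if f not in table.columns:
                raise ConfigurationError(f"beta refers to unknown column {f!r}")
            col = col * table[f].to_numpy(float)
        eta += b * col

    codes, _ = pd.factorize(table["subject_id"])
    u0 = np.sqrt(config.tau00) * rng.standard_normal(config.n_subjects)
    resid = np.sqrt(config.sigma2) * rng.standard_normal(len(table))
    table["sbp_r"] = eta + u0[codes] + resid

    if config.missing_rate > 0:
        drop = rng.random(len(table)) < config.missing_rate
        for i in range(config.n_subjects):
            rows = np.flatnonzero(codes == i)
            keep2 = rng.choice(rows, size=min(2, rows.size), replace=False)
            drop[keep2] = False
        table = table.loc[~drop].reset_index(drop=True)

    ordered = ["subject_id", "wave", "level", "tertile", "sbp_r"]
    ordered += [c for c in table.columns if c not in ordered]
    return table[ordered], config.true_theta()


# ---------------------------------------------------------------------------
# Trace simulation (exercises the preprocessing end to end)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraceConfig:
    """1 Hz trace generator: a rest window then four task levels whose mean
    SBP follows ``baseline + engagement[tertile]`` within each tertile."""

    seed: int
    n_subjects: int = 5
    wave: int = 1
    rest_duration: int = 600
    level_durations: tuple = (60, 90, 120, 150)
    baseline: float = 130.0
    engagement: tuple = (2, 3, 4, 3, 4, 5, 4, 5, 6, 5, 6, 7)
    noise_sd: float = 0.0

    def __post_init__(self):
        if any(d < 3 for d in self.level_durations):
            raise ConfigurationError("each level needs >= 3 s")
        if len(self.engagement) != 12:
            raise ConfigurationError("engagement profile must have 12 values")


def simulate_trace(config: TraceConfig) -> list[SbpTrace]:
    """Generate one trace per subject under ``config``."""
    rng = np.random.default_rng(config.seed)
    traces = []
    for i in range(config.n_subjects):
        segs, markers, t0 = [], {}, 0
        markers["rest"] = (0.0, float(config.rest_duration))
        segs.append(np.full(config.rest_duration, config.baseline))
        t0 = config.rest_duration
        for lev, dur in enumerate(config.level_durations, start=1):
            base, extra = divmod(dur, 3)
            lens = [base + (1 if j < extra else 0) for j in range(3)]
            vals = np.concatenate([
                np.full(ln, config.baseline + config.engagement[3 * (lev - 1) + j])
                for j, ln in enumerate(lens)
            ])
            segs.append(vals)
            markers[f"level{lev}"] = (float(t0), float(t0 + dur))
            t0 += dur
        sbp = np.concatenate(segs)
        if config.noise_sd > 0:
            sbp = sbp + config.noise_sd * rng.standard_normal(sbp.size)
        traces.append(SbpTrace(subject_id=f"s{i:03d}", wave=config.wave,
                               times=np.arange(sbp.size, dtype=float), sbp=sbp,
                               markers=markers))
    return traces


# ---------------------------------------------------------------------------
# Coverage study
# ---------------------------------------------------------------------------


def coverage_study(config: SyntheticConfig, n_reps: int, level: float = 0.95,
                   method: str = "fiducial", sampler_config=None,
                   fixed_effects_only: bool = True) -> pd.DataFrame:
    """Simulate -> fit -> record interval coverage of the generating values.

    Per parameter: empirical coverage with a binomial Monte-Carlo SE.
    Replications whose fit fails are excluded and counted in ``n_failed``.
    ``method`` is ``"fiducial"`` (quantile intervals of the fiducial draws)
    or ``"reml"`` (Wald-Satterthwaite t intervals, fixed effects only).
    """
    from . import fiducial as fid
    from . import frequentist as freq
    from scipy import stats

    if n_reps < 1:
        raise ConfigurationError("n_reps must be positive")
    truth = config.true_theta()
    spec = config.model_spec()
    p = truth.p
    names = None
    hits, n_ok, n_failed = None, 0, 0

    for rep in range(n_reps):
        rep_seed = int((config.seed * 100003 + rep) % (2 ** 31 - 1))
        table, _ = simulate_dataset(replace(config, seed=rep_seed))
        try:
            from .model_core import build_design

            design = build_design(table, spec)
            if names is None:
                names = (list(design.column_names)
                         + ([] if fixed_effects_only else ["tau00", "sigma2"]))
                hits = np.zeros(len(names))
            if method == "fiducial":
                scfg = sampler_config or fid.SamplerConfig(
                    n_chains=2, n_warmup=1000, n_keep=1200, thin=2, seed=rep_seed,
                    compute_diagnostics=False)
                scfg = replace(scfg, seed=rep_seed)
                summ = fid.summarize(fid.sample_fiducial(design, scfg), level=level)
                lo, hi = summ.lower, summ.upper
            elif method == "reml":
                fit = freq.satterthwaite_tests(freq.fit_reml(design), design)
                half = stats.t.ppf(1 - (1 - level) / 2, fit.satterthwaite_df) * fit.se_beta
                lo = np.concatenate([fit.theta_hat.beta - half, [np.nan, np.nan]])
                hi = np.concatenate([fit.theta_hat.beta + half, [np.nan, np.nan]])
            else:
                raise ConfigurationError(f"unknown method {method!r}")
        except (np.linalg.LinAlgError, RuntimeError, ConfigurationError) as exc:
            n_failed += 1
            import logging

            logging.getLogger("fidlmm").warning("coverage rep %d failed: %s", rep, exc)
            continue
        true_vals = np.concatenate(
            [truth.beta, [truth.var_subject, truth.var_resid]])[:len(names)]
        hits += ((lo[:len(names)] <= true_vals) & (true_vals <= hi[:len(names)]))
        n_ok += 1

    if n_ok == 0:
        raise RuntimeError("all coverage replications failed")
    cov = hits / n_ok
    return pd.DataFrame({
        "parameter": names,
        "coverage": cov,
        "mc_se": np.sqrt(cov * (1 - cov) / n_ok),
        "n_reps": n_ok,
        "n_failed": n_failed,
        "level": level,
    })
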