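"""Preprocessing of second-by-second systolic blood pressure traces into the
long-format analysis table.

Pipeline: a 10-minute rest window gives baseline SBP (mean over its final
5 minutes); each of the four task levels is split into three contiguous
tertiles of near-equal duration; per-tertile means minus baseline give
SBP-R, the responsivity index (mmHg above resting baseline).  Hair-cortisol
concentrations are natural-log transformed, and person-level composites
(cognition, physical/mental health challenges) are transparent z-score
means of their indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ConfigurationError

logger = logging.getLogger("fidlmm")

__all__ = [
    "SbpTrace",
    "baseline_sbp",
    "tertile_means",
    "to_sbp_r",
    "log_cortisol",
    "composite_score",
    "read_traces",
    "prepare_table",
]

LEVELS = ("level1", "level2", "level3", "level4")


@dataclass
class SbpTrace:
    """One subject-wave 1 Hz SBP recording with rest/level markers.

    ``markers`` maps segment names (``rest``, ``level1``..``level4``) to
    half-open [start_s, end_s) intervals on the 0-based ``times`` axis.
    """

    subject_id: str
    wave: int
    times: np.ndarray
    sbp: np.ndarray
    markers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        if self.times.shape != self.sbp.shape:
            raise ConfigurationError("times and sbp must have equal length")
        ivals = sorted(self.markers.values())
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            if a1 > b0:
                raise ConfigurationError("marker intervals overlap")
        for name, (s, e) in self.markers.items():
            if e <= s:
                raise ConfigurationError(f"empty marker interval {name!r}")

    def segment(self, name: str) -> np.ndarray:
        """SBP samples with time in [start, end) of the named segment."""
        if name not in self.markers:
            raise ConfigurationError(f"trace has no {name!r} marker")
        s, e = self.markers[name]
        return self.sbp[(self.times >= s) & (self.times < e)]


def baseline_sbp(trace: SbpTrace) -> float:
    """Mean SBP over the final 300 s of the rest window.

    A rest window shorter than 300 s is used in full (logged warning).
    """
    s, e = trace.markers.get("rest", (None, None))
    if s is None:
        raise ConfigurationError("trace has no rest window")
    if e - s < 300.0:
        logger.warning("rest window of %.0f s < 300 s for subject %s; using all of it",
                       e - s, trace.subject_id)
        lo = s
    else:
        lo = e - 300.0
    vals = trace.sbp[(trace.times >= lo) & (trace.times < e)]
    return float(vals.mean())


def _span_lengths(n: int, remainder: str = "earliest") -> tuple[int, int, int]:
    """Split n samples into 3 contiguous spans differing by at most 1;
    leftover seconds go to the earliest (default) or latest tertiles."""
    base, extra = divmod(n, 3)
    lens = [base, base, base]
    idx = range(extra) if remainder == "earliest" else range(2, 2 - extra, -1)
    for i in idx:
        lens[i] += 1
    return tuple(lens)


def tertile_means(trace: SbpTrace, remainder: str = "earliest") -> np.ndarray:
    """12 per-tertile SBP means: level 1 tertiles 1-3 through level 4
    tertiles 10-12.  Spans exactly tile each level (no sample dropped or
    reused)."""
    if remainder not in ("earliest", "latest"):
        raise ConfigurationError("remainder must be 'earliest' or 'latest'")
    out = []
    for name in LEVELS:
        vals = trace.segment(name)
        if vals.size < 3:
            raise ConfigurationError(
                f"{name} has {vals.size} samples (< 3) for subject {trace.subject_id}")
        lens = _span_lengths(vals.size, remainder)
        i = 0
        for ln in lens:
            out.append(float(vals[i:i + ln].mean()))
            i += ln
    return np.asarray(out)


def to_sbp_r(tertile_means: np.ndarray, baseline: float) -> np.ndarray:
    """Responsivity: tertile means minus baseline SBP (elementwise)."""
    tm = np.asarray(tertile_means, dtype=float)
    if not (np.all(np.isfinite(tm)) and np.isfinite(baseline)):
        raise ConfigurationError("non-finite inputs to to_sbp_r")
    return tm - float(baseline)


def log_cortisol(hcc) -> np.ndarray | float:
    """Natural log of hair cortisol concentration (pg/mg); non-positive
    values become missing (count logged)."""
    arr = np.asarray(hcc, dtype=float)
    bad = ~(arr > 0)
    if bad.any():
        logger.warning("log_cortisol: %d non-positive value(s) set to missing", int(bad.sum()))
    out = np.where(bad, np.nan, np.log(np.where(bad, 1.0, arr)))
    return float(out) if np.isscalar(hcc) or arr.ndim == 0 else out


def composite_score(indicators: pd.DataFrame, signs: dict | None = None) -> pd.Series:
    """Transparent z-score composite of person-level indicators.

    Each indicator is z-scored across persons, oriented by its declared
    sign, averaged, and the average is re-centred to mean 0.  This is a
    documented stand-in for latent factor scoring: it preserves ordering
    and near-zero means but not factor-score variances.
    """
    signs = signs or {}
    cols = []
    for name in indicators.columns:
        v = pd.to_numeric(indicators[name])
        sd = v.std(ddof=1)
        if not sd > 0:
            logger.warning("composite_score: excluding zero-variance indicator %r", name)
            continue
        cols.append(signs.get(name, 1.0) * (v - v.mean()) / sd)
    if len(cols) < 2:
        raise ConfigurationError("a composite needs >= 2 usable indicators")
    comp = sum(cols) / len(cols)
    return comp - comp.mean()


# ---------------------------------------------------------------------------
# File I/O and table assembly
# ---------------------------------------------------------------------------


def read_traces(samples_path, markers_path) -> list[SbpTrace]:
    """Read traces from delimited text: samples (subject, wave, time_s, sbp)
    and markers (subject, wave, segment, start_s, end_s)."""
    samples = pd.read_csv(samples_path)
    markers = pd.read_csv(markers_path)
    traces = []
    for (subj, wave), grp in samples.groupby(["subject", "wave"], sort=True):
        mk = markers[(markers["subject"] == subj) & (markers["wave"] == wave)]
        mdict = {r["segment"]: (float(r["start_s"]), float(r["end_s"]))
                 for _, r in mk.iterrows()}
        traces.append(SbpTrace(subject_id=str(subj), wave=int(wave),
                               times=grp["time_s"].to_numpy(float),
                               sbp=grp["sbp"].to_numpy(float), markers=mdict))
    return traces


def prepare_table(traces: list[SbpTrace], covariates: pd.DataFrame | None = None,
                  remainder: str = "earliest") -> pd.DataFrame:
    """Full preprocessing: traces -> long AnalysisTable (one row per
    subject x wave x tertile) with sbp_r and sbp_baseline, merged with
    person-level covariates on subject_id when supplied."""
    rows = []
    for tr in traces:
        base = baseline_sbp(tr)
        resp = to_sbp_r(tertile_means(tr, remainder=remainder), base)
        for t, val in enumerate(resp, start=1):
            rows.append({
                "subject_id": tr.subject_id,
                "wave": tr.wave,
                "level": (t - 1) // 3 + 1,
                "tertile": t,
                "sbp_r": val,
                "sbp_baseline": base,
            })
    table = pd.DataFrame(rows)
    if covariates is not None:
        cov = covariates.copy()
        cov["subject_id"] = cov["subject_id"].astype(str)
        table = table.merge(cov, on="subject_id", how="left")
    return table
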