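"""Cardiorespiratory-fitness phenotypes from submaximal cycle-ramp traces.

Two phenotypes are derived per participant from the exercise phase of the
test:

* **CRF-vo2max** (W/kg): the workload extrapolated to the age-predicted
  maximum heart rate (208 − 0.7·age), divided by body weight — a submaximal
  proxy for maximal oxygen uptake expressed as relative power.
* **CRF-slope** (bpm per trend unit): the OLS slope of the low-pass-filtered
  heart rate on the ordinal measurement index ("trend"); sessions with a
  negative slope are excluded from this phenotype.

QC mirrors the derivation protocol: only minimal/small/medium risk
categories on the bicycle method are eligible; the modelled window is the
4-min workload ramp (minimal/small) or the full constant-workload exercise
phase (medium); observations with cadence outside 35–125 RPM are dropped;
at least 20 observations must survive; heart rate is smoothed with a
zero-phase low-pass Butterworth filter before fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

log = logging.getLogger(__name__)

__all__ = [
    "ErgoSession", "CRFRecord", "select_exercise_window", "apply_qc_filters",
    "lowpass_filter", "age_predicted_max_hr", "derive_vo2max", "derive_slope",
    "derive_crf_phenotypes", "sessions_from_traces",
]

ELIGIBLE_RISK = ("minimal", "small", "medium")


@dataclass
class ErgoSession:
    """One participant's ramp-test trace plus the metadata QC needs."""

    participant_id: str
    risk_category: str
    age: float
    weight: float
    observations: pd.DataFrame     # phase, trend, heart_rate, workload, cadence
    method: str = "Bicycle"


@dataclass
class CRFRecord:
    """Derived phenotypes and QC provenance for one session."""

    participant_id: str
    vo2max: float = np.nan
    slope: float = np.nan
    intercept: float = np.nan
    hr_age_max: float = np.nan
    wl_hr_max: float = np.nan
    n_trend: int = 0
    hr_start: float = np.nan
    hr_end: float = np.nan
    qc_flags: set = field(default_factory=set)

    @property
    def emitted(self) -> bool:
        return not self.qc_flags & {"bad_risk", "bad_method", "low_cadence_n"}


class SessionExcluded(Exception):
    """Session fails an eligibility rule; carries the QC flag."""

    def __init__(self, flag: str, message: str = ""):
        self.flag = flag
        super().__init__(message or flag)


def sessions_from_traces(traces: pd.DataFrame, cohort: pd.DataFrame,
                         method: str = "Bicycle") -> list[ErgoSession]:
    """Join a long-format trace table with the cohort table into sessions."""
    meta = cohort.set_index("participant_id")
    sessions = []
    for pid, obs in traces.groupby("participant_id", sort=True):
        row = meta.loc[pid]
        sessions.append(ErgoSession(
            participant_id=str(pid), risk_category=row["risk_category"],
            age=float(row["age"]), weight=float(row["weight"]),
            observations=obs.reset_index(drop=True), method=method))
    return sessions


# ----------------------------------------------------------------- selection
def select_exercise_window(session: ErgoSession) -> pd.DataFrame:
    """Pick the observations to model: the workload ramp for minimal/small
    risk, the whole exercise phase for medium risk.

    The ramp is located as the longest contiguous exercise-phase run of
    non-decreasing workload with an overall increase, trimmed of its
    constant lead-in (points still at the run's starting workload).
    Raises :class:`SessionExcluded` for high-risk or non-bicycle sessions.
    """
    if session.method != "Bicycle":
        raise SessionExcluded("bad_method",
                              f"method {session.method!r} is not 'Bicycle'")
    if session.risk_category not in ELIGIBLE_RISK:
        raise SessionExcluded("bad_risk",
                              f"risk category {session.risk_category!r}")

    ex = session.observations[session.observations["phase"] == "exercise"]
    ex = ex.sort_values("trend").reset_index(drop=True)
    if len(ex) == 0:
        raise SessionExcluded("low_cadence_n", "no exercise-phase observations")
    if session.risk_category == "medium":
        return ex

    wl = ex["workload"].to_numpy()
    # maximal non-decreasing runs; keep the best (longest, then largest rise)
    best = (0, 0)
    start = 0
    for i in range(1, len(wl) + 1):
        if i == len(wl) or wl[i] < wl[i - 1]:
            if wl[i - 1] > wl[start] and (i - start) > (best[1] - best[0]):
                best = (start, i)
            start = i
    a, b = best
    if b == a:
        raise SessionExcluded("degenerate_workload",
                              "no workload ramp found for ramped protocol")
    run = ex.iloc[a:b]
    return run[run["workload"] > wl[a]].reset_index(drop=True)


def apply_qc_filters(observations: pd.DataFrame, cadence_min: float = 35.0,
                     cadence_max: float = 125.0, min_observations: int = 20
                     ) -> pd.DataFrame:
    """Drop rows with cadence outside [cadence_min, cadence_max] (inclusive
    bounds retained) and require at least ``min_observations`` survivors."""
    kept = observations[(observations["cadence"] >= cadence_min)
                        & (observations["cadence"] <= cadence_max)]
    if len(kept) < min_observations:
        raise SessionExcluded(
            "low_cadence_n",
            f"{len(kept)} observations after cadence filter (< {min_observations})")
    return kept.reset_index(drop=True)


# ------------------------------------------------------------------ filtering
def lowpass_filter(heart_rate: np.ndarray, order: int = 4,
                   cutoff_fraction: float = 0.1) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter of a heart-rate sequence.

    Applied forward and backward (``filtfilt``) so the smoothed trend is not
    phase-lagged; ``cutoff_fraction`` is relative to Nyquist.  Odd-reflection
    padding extends the signal point-symmetrically, which keeps a linear
    trend exactly linear through the ends.  Sequences too short to pad are
    returned unfiltered (degraded mode, logged).
    """
    hr = np.asarray(heart_rate, dtype=float)
    if not 0.0 < cutoff_fraction < 1.0:
        raise ValueError("cutoff_fraction must be in (0, 1)")
    if hr.size < max(20, 3 * order):
        log.warning("sequence of length %d too short to filter; "
                    "returning raw signal", hr.size)
        return hr.copy()
    b, a = signal.butter(order, cutoff_fraction)
    # pad until the slowest pole has decayed below 1e-13 so edge transients
    # cannot reach the window; np.pad repeats the odd reflection as needed
    pole_max = np.abs(np.roots(a)).max()
    pad = max(3 * max(len(a), len(b)),
              int(np.ceil(np.log(1e-13) / np.log(pole_max))))
    ext = np.pad(hr, pad, mode="reflect", reflect_type="odd")
    return signal.filtfilt(b, a, ext, padlen=0)[pad:-pad]


# ----------------------------------------------------------------- phenotypes
def age_predicted_max_hr(age: float) -> float:
    """Age-predicted maximum heart rate, 208 − 0.7·age (bpm)."""
    if age <= 0:
        raise ValueError("age must be positive")
    return 208.0 - 0.7 * age


def derive_vo2max(observations: pd.DataFrame, age: float, weight: float,
                  mode: str = "regression",
                  filtered_hr: np.ndarray | None = None
                  ) -> tuple[float, float, float, float, set]:
    """Extrapolate workload to the age-predicted maximum heart rate and
    scale by body weight.

    ``mode="regression"`` (default) fits workload ~ heart rate by least
    squares over the window and evaluates the line at the age-predicted
    maximum; ``mode="endpoints"`` draws the line through the first and last
    (filtered) points.  A constant-workload window (medium-risk protocol)
    has no usable slope: the constant workload itself is emitted with the
    ``degenerate_workload`` flag.

    Returns ``(vo2max, wl_hr_max, hr_start, hr_end, flags)``.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if len(observations) < 2:
        raise SessionExcluded("low_cadence_n", "fewer than 2 observations")
    hr = np.asarray(filtered_hr if filtered_hr is not None
                    else observations["heart_rate"], dtype=float)
    wl = observations["workload"].to_numpy(dtype=float)
    hr_max = age_predicted_max_hr(age)
    hr_start, hr_end = float(hr[0]), float(hr[-1])
    flags: set = set()

    if np.ptp(wl) == 0.0:
        flags.add("degenerate_workload")
        wl_hr_max = float(wl[0])
    elif mode == "regression":
        slope, intercept = np.polyfit(hr, wl, 1)
        wl_hr_max = float(intercept + slope * hr_max)
    elif mode == "endpoints":
        if hr_end == hr_start:
            raise SessionExcluded("degenerate_workload",
                                  "identical endpoint heart rates")
        slope = (wl[-1] - wl[0]) / (hr_end - hr_start)
        wl_hr_max = float(wl[0] + slope * (hr_max - hr_start))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return wl_hr_max / weight, wl_hr_max, hr_start, hr_end, flags


def derive_slope(observations: pd.DataFrame,
                 filtered_hr: np.ndarray | None = None
                 ) -> tuple[float, float, set]:
    """OLS fit of (filtered) heart rate on the trend index.

    Returns ``(intercept, slope, flags)``; a strictly negative slope gets
    the ``negative_slope`` flag (excluded from the slope phenotype; zero is
    retained).
    """
    hr = np.asarray(filtered_hr if filtered_hr is not None
                    else observations["heart_rate"], dtype=float)
    trend = observations["trend"].to_numpy(dtype=float)
    if len(hr) < 2 or np.ptp(trend) == 0.0:
        raise SessionExcluded("degenerate_workload",
                              "cannot fit slope without distinct trend values")
    if np.ptp(hr) == 0.0:     # constant signal: slope exactly zero, retained
        return float(hr[0]), 0.0, set()
    beta1, beta0 = np.polyfit(trend, hr, 1)
    flags = {"negative_slope"} if beta1 < 0 else set()
    return float(beta0), float(beta1), flags


# -------------------------------------------------------------- orchestration
def derive_crf_phenotypes(sessions, butter_order: int = 4,
                          butter_cutoff: float = 0.1,
                          cadence_min: float = 35.0, cadence_max: float = 125.0,
                          min_observations: int = 20,
                          mode: str = "regression"
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full derivation over an iterable of sessions.

    Returns ``(records, exclusion_log)``: one record per eligible session
    (vo2max and slope with flags; the slope column is NaN for negative-slope
    sessions) and a per-reason exclusion count table.  Exclusions partition
    the input: n_sessions = n_emitted + sum of exclusion counts.
    """
    records: list[CRFRecord] = []
    exclusions: dict[str, int] = {}
    for session in sessions:
        rec = CRFRecord(participant_id=session.participant_id)
        try:
            window = select_exercise_window(session)
            window = apply_qc_filters(window, cadence_min, cadence_max,
                                      min_observations)
            filt = lowpass_filter(window["heart_rate"].to_numpy(),
                                  butter_order, butter_cutoff)
            vo2, wlmax, h0, h1, vflags = derive_vo2max(
                window, session.age, session.weight, mode, filtered_hr=filt)
            b0, b1, sflags = derive_slope(window, filtered_hr=filt)
        except SessionExcluded as exc:
            exclusions[exc.flag] = exclusions.get(exc.flag, 0) + 1
            continue
        rec.vo2max, rec.wl_hr_max = vo2, wlmax
        rec.hr_start, rec.hr_end = h0, h1
        rec.hr_age_max = age_predicted_max_hr(session.age)
        rec.intercept, rec.slope = b0, b1
        rec.n_trend = len(window)
        rec.qc_flags = vflags | sflags
        records.append(rec)

    columns = ["participant_id", "crf_vo2max", "crf_slope", "intercept",
               "wl_hr_max", "hr_age_max", "hr_start", "hr_end", "n_trend",
               "qc_flags"]
    if not records:
        return (pd.DataFrame(columns=columns),
                pd.DataFrame(sorted(exclusions.items()), columns=["reason", "n"]))
    table = pd.DataFrame([{
        "participant_id": r.participant_id,
        "crf_vo2max": r.vo2max,
        "crf_slope": np.nan if "negative_slope" in r.qc_flags else r.slope,
        "intercept": r.intercept, "wl_hr_max": r.wl_hr_max,
        "hr_age_max": r.hr_age_max, "hr_start": r.hr_start, "hr_end": r.hr_end,
        "n_trend": r.n_trend, "qc_flags": ";".join(sorted(r.qc_flags)),
    } for r in records])
    excl = pd.DataFrame(sorted(exclusions.items()), columns=["reason", "n"])
    return table, excl
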