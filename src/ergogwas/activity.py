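"""Physical-activity QC for wrist-worn accelerometer summaries.

A record enters the analysis only if the device reported good wear time and
good calibration, no data-problem indicator is present, and the wear-time
adjusted 7-day average acceleration is at most 100 milligravities (the
exclusion is strictly "> 100 mg", so exactly 100 is retained).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["qc_pa"]

REQUIRED = ["participant_id", "pa_accel_mg", "good_wear_time",
            "good_calibration", "problem_indicators"]


def qc_pa(records: pd.DataFrame, accel_threshold_mg: float = 100.0
          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the accelerometer inclusion filters.

    Returns ``(records, exclusion_log)`` where ``records`` gains an
    ``included`` column and ``exclusion_log`` counts failures per rule
    (a record failing several rules is counted under each).  Records with a
    negative acceleration are malformed and rejected with reason
    ``malformed``.
    """
    missing = [c for c in REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"PA table missing columns: {missing}")
    out = records.copy()
    problems = out["problem_indicators"].fillna("").astype(str).str.strip()
    malformed = out["pa_accel_mg"] < 0
    fail_wear = ~out["good_wear_time"].astype(bool)
    fail_cal = ~out["good_calibration"].astype(bool)
    fail_prob = problems != ""
    fail_accel = out["pa_accel_mg"] > accel_threshold_mg

    out["included"] = ~(malformed | fail_wear | fail_cal | fail_prob | fail_accel)
    log = pd.DataFrame({
        "reason": ["malformed", "bad_wear_time", "bad_calibration",
                   "problem_indicator", f"accel_gt_{accel_threshold_mg:g}mg"],
        "n": [int(malformed.sum()), int(fail_wear.sum()), int(fail_cal.sum()),
              int(fail_prob.sum()), int(fail_accel.sum())],
    })
    return out, log
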