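"""Tabular I/O helpers.

All tabular exchange uses TSV.  Tables written by pipeline stages carry a
leading comment header naming the producing stage and the config hash, e.g.::

    # ergogwas stage=crf config=0123456789ab

Readers skip any leading ``#`` comment lines, so files round-trip.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["write_table", "read_table", "TRACE_COLUMNS"]

TRACE_COLUMNS = ["participant_id", "phase", "trend", "heart_rate", "workload", "cadence"]


def write_table(df: pd.DataFrame, path: str | Path, stage: str | None = None,
                config_hash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if stage is not None:
            tag = f"# ergogwas stage={stage}"
            if config_hash:
                tag += f" config={config_hash}"
            fh.write(tag + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_traces(traces: pd.DataFrame, path: str | Path, **kw) -> None:
    """Write a long-format ramp-test trace table (one row per observation)."""
    missing = [c for c in TRACE_COLUMNS if c not in traces.columns]
    if missing:
        raise ValueError(f"trace table missing columns: {missing}")
    write_table(traces[TRACE_COLUMNS], path, **kw)


def read_traces(path: str | Path) -> pd.DataFrame:
    df = read_table(path, dtype={"participant_id": str, "phase": str})
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing columns: {missing}")
    return df
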