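"""Optional QC and result figures (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_session_qc", "plot_decile_frequency"]


def plot_session_qc(window: pd.DataFrame, filtered_hr: np.ndarray, path) -> None:
    """Per-participant signal-processing plot: raw heart rate, the low-pass
    filtered signal, and the fitted linear trend over the modelled window."""
    trend = window["trend"].to_numpy(dtype=float)
    raw = window["heart_rate"].to_numpy(dtype=float)
    b1, b0 = np.polyfit(trend, filtered_hr, 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(trend, raw, ".", ms=3, alpha=0.6, label="raw")
    ax.plot(trend, filtered_hr, "-", lw=1.5, label="Butterworth filtered")
    ax.plot(trend, b0 + b1 * trend, "--", lw=1.5, label="linear model")
    ax.set_xlabel("trend (measurement index)")
    ax.set_ylabel("heart rate (bpm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_decile_frequency(table: pd.DataFrame, path) -> None:
    """Faceted diagnosis-frequency-by-decile plot, one panel per disease
    group, lines by sex."""
    groups = sorted(table["disease_group"].unique())
    ncol = min(5, len(groups))
    nrow = int(np.ceil(len(groups) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.5 * nrow),
                             sharex=True, squeeze=False)
    for ax, group in zip(axes.ravel(), groups):
        sub = table[table["disease_group"] == group]
        for sex_level, s in sub.groupby("sex"):
            ax.plot(s["decile"], 100 * s["frequency"], marker="o", ms=3,
                    label=sex_level)
        ax.set_title(group, fontsize=9)
    for ax in axes[-1]:
        ax.set_xlabel("phenotype decile")
    for ax in axes[:, 0]:
        ax.set_ylabel("frequency (%)")
    axes[0, 0].legend(frameon=False, fontsize=8)
    for ax in axes.ravel()[len(groups):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
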