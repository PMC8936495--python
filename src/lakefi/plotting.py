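"""Plot export: FI maps, summary scatters and cvFI time series.

Maps are plain lon/lat scatters — low FI plotted blue and small, high FI red
and large — with the window mean and standard deviation annotated. No basemap
rendering is attempted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless export only

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .fisher import FI_MAX

__all__ = ["export_fi_map", "summary_scatter", "cv_timeseries"]


def export_fi_map(
    windows: pd.DataFrame, path: str | Path, title: str = ""
) -> Path | None:
    """Scatter window FI at anchor coordinates; colour and size encode FI."""
    if len(windows) == 0:
        warnings.warn("no windows to plot", UserWarning, stacklevel=2)
        return None
    path = Path(path)
    fi = windows["fi"].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(5, 6))
    sc = ax.scatter(
        windows["lon"],
        windows["lat"],
        c=fi,
        s=20 + 180 * fi / FI_MAX,
        cmap="coolwarm",
        vmin=0,
        vmax=FI_MAX,
        edgecolors="k",
        linewidths=0.3,
    )
    fig.colorbar(sc, ax=ax, label="FI")
    ax.set_xlabel("longitude (deg)")
    ax.set_ylabel("latitude (deg)")
    ax.set_title(title)
    ax.text(
        0.02,
        0.98,
        f"mu = {fi.mean():.2f}\nsigma = {fi.std(ddof=1):.2f}",
        transform=ax.transAxes,
        va="top",
        fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def summary_scatter(summaries: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    """muFI vs sdFI scatter, one point per year (stable years ringed)."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(summaries["mean_fi"], summaries["sd_fi"], c="tab:blue", s=30)
    if "stable" in summaries.columns:
        st = summaries[summaries["stable"]]
        ax.scatter(
            st["mean_fi"], st["sd_fi"], facecolors="none", edgecolors="red", s=90
        )
    for _, row in summaries.iterrows():
        ax.annotate(
            str(int(row["year"])),
            (row["mean_fi"], row["sd_fi"]),
            fontsize=6,
            xytext=(2, 2),
            textcoords="offset points",
        )
    ax.set_xlabel("muFI")
    ax.set_ylabel("sdFI")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def cv_timeseries(summaries: pd.DataFrame, path: str | Path) -> Path:
    """cvFI against year, one line per dataset."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 4))
    for tag, grp in summaries.groupby("dataset"):
        grp = grp.sort_values("year")
        ax.plot(grp["year"], grp["cv_fi"], marker="o", label=str(tag))
    ax.set_xlabel("year")
    ax.set_ylabel("cvFI")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
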