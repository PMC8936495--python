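"""Yearly summaries, stability classification and Kendall tau-b analyses.

A windowed FI series is reduced per year to its mean (muFI), sample standard
deviation (sdFI) and coefficient of variation (cvFI = sdFI/muFI). A year counts
as *stable* when all three criteria hold relative to the study-period averages:
above-average muFI, below-average sdFI and below-average cvFI. Kendall tau-b
(tie-corrected rank correlation) measures abiotic-biotic congruence between two
datasets' window FI series within each year, and monotone trends of yearly
statistics against calendar year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fisher import DataError, WindowFI

__all__ = [
    "AlignmentError",
    "TauResult",
    "kendall_tau_b",
    "yearly_summary",
    "classify_stable_years",
    "correlate_datasets",
    "trend_over_years",
    "partition_by_boundary",
    "boundary_window_zones",
]


class AlignmentError(ValueError):
    """Paired series do not line up one-to-one."""


@dataclass(frozen=True)
class TauResult:
    """Kendall tau-b with its tie-corrected p-value and pair count."""

    tau: float
    p_value: float
    n: int

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.tau))


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> TauResult:
    """Kendall tau-b between paired sequences, dropping incomplete pairs.

    Tie correction is applied in both margins; the p-value comes from the
    tie-corrected normal approximation of the concordance statistic. A margin
    that is entirely tied leaves tau undefined, signalled with a warning and
    NaN fields.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AlignmentError("x and y must be paired 1-d sequences")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise DataError(f"need at least 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn(
            "tau-b undefined: one margin is entirely tied", UserWarning, stacklevel=2
        )
        return TauResult(tau=float("nan"), p_value=float("nan"), n=n)
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return TauResult(tau=float(res.statistic), p_value=float(res.pvalue), n=n)


def _fi_by_year(windows) -> dict[int, np.ndarray]:
    """Normalise {year: [WindowFI | float]} or a (year, fi) DataFrame."""
    if isinstance(windows, pd.DataFrame):
        if not {"year", "fi"} <= set(windows.columns):
            raise DataError("window frame needs 'year' and 'fi' columns")
        return {
            int(yr): grp["fi"].to_numpy(dtype=float)
            for yr, grp in windows.groupby("year")
        }
    out: dict[int, np.ndarray] = {}
    for yr, vals in windows.items():
        arr = np.asarray(
            [v.fi if isinstance(v, WindowFI) else float(v) for v in vals], dtype=float
        )
        out[int(yr)] = arr
    return out


def yearly_summary(windows, dataset: str) -> pd.DataFrame:
    """Per-year muFI, sdFI (sample, n-1) and cvFI for one dataset's windows.

    ``windows`` is either a mapping year -> sequence of WindowFI (or plain FI
    values) or a DataFrame with ``year`` and ``fi`` columns. cvFI is reported
    missing (NaN) with a warning when muFI is 0.
    """
    by_year = _fi_by_year(windows)
    rows = []
    for yr in sorted(by_year):
        fi = by_year[yr]
        if fi.size < 2:
            raise DataError(f"year {yr} has {fi.size} window(s); need at least 2")
        mu = float(fi.mean())
        sd = float(fi.std(ddof=1))
        if mu > 0:
            cv = sd / mu
        else:
            warnings.warn(
                f"year {yr}: muFI = 0, cvFI undefined", UserWarning, stacklevel=2
            )
            cv = float("nan")
        rows.append(
            {
                "dataset": dataset,
                "year": yr,
                "n_windows": int(fi.size),
                "mean_fi": mu,
                "sd_fi": sd,
                "cv_fi": cv,
            }
        )
    return pd.DataFrame(rows)


def classify_stable_years(summaries: pd.DataFrame) -> pd.DataFrame:
    """Flag stable years: muFI above, sdFI and cvFI below their period means.

    Comparisons are strict, per dataset, against the unweighted mean of the
    yearly statistics over the whole period. ``stable`` is the conjunction of
    the three flags.
    """
    needed = {"dataset", "year", "mean_fi", "sd_fi", "cv_fi"}
    if not needed <= set(summaries.columns):
        raise DataError(f"summary frame needs columns {sorted(needed)}")
    out = summaries.copy()
    if out.groupby("dataset")["year"].count().min() < 2:
        raise DataError("need at least 2 years per dataset to classify stability")
    grand = out.groupby("dataset")[["mean_fi", "sd_fi", "cv_fi"]].transform("mean")
    out["high_mean"] = out["mean_fi"] > grand["mean_fi"]
    out["low_sd"] = out["sd_fi"] < grand["sd_fi"]
    out["low_cv"] = out["cv_fi"] < grand["cv_fi"]
    out["stable"] = out["high_mean"] & out["low_sd"] & out["low_cv"]
    return out


def correlate_datasets(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Per-year tau-b between two datasets' paired window FI series.

    Both frames need ``year``, ``window`` and ``fi`` columns and must share the
    station ordering so windows pair one-to-one within each year; mismatched
    window counts raise :class:`AlignmentError`.
    """
    for name, df in (("a", a), ("b", b)):
        if not {"year", "window", "fi"} <= set(df.columns):
            raise DataError(f"frame {name} needs year/window/fi columns")
    rows = []
    years = sorted(set(a["year"]) & set(b["year"]))
    for yr in years:
        fa = a.loc[a["year"] == yr].sort_values("window")
        fb = b.loc[b["year"] == yr].sort_values("window")
        if len(fa) != len(fb) or not np.array_equal(
            fa["window"].to_numpy(), fb["window"].to_numpy()
        ):
            raise AlignmentError(
                f"year {yr}: window sequences do not align "
                f"({len(fa)} vs {len(fb)} windows)"
            )
        res = kendall_tau_b(fa["fi"].to_numpy(), fb["fi"].to_numpy())
        rows.append(
            {"year": int(yr), "tau": res.tau, "p_value": res.p_value, "n": res.n}
        )
    return pd.DataFrame(rows)


def trend_over_years(values: Sequence[float], years: Sequence[int]) -> TauResult:
    """Kendall tau-b of a yearly scalar against calendar year.

    Negative tau indicates a monotone decline (e.g., shrinking spatial
    variability when applied to cvFI).
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    if years.size != values.size:
        raise AlignmentError("years and values must pair one-to-one")
    if years.size < 3:
        raise DataError("need at least 3 years for a trend test")
    return kendall_tau_b(years, values)


def partition_by_boundary(
    stations: pd.DataFrame,
    *,
    boundary_latitude: float | None = None,
    labels: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split stations into (above, below) a regime boundary.

    Either pass ``labels`` naming a column with values 'above'/'below', or a
    ``boundary_latitude`` threshold (stations strictly above the latitude go to
    the 'above' set). A station resolvable to neither side raises; an empty
    side is legal but flagged with a warning (degenerate partition).
    """
    if (labels is None) == (boundary_latitude is None):
        raise ValueError("pass exactly one of labels= or boundary_latitude=")
    if labels is not None:
        if labels not in stations.columns:
            raise DataError(f"label column {labels!r} not in stations table")
        vals = stations[labels].astype(str)
        bad = stations.loc[~vals.isin(["above", "below"]), "station_id"]
        if len(bad):
            raise DataError(
                f"stations not resolvable to a side: {sorted(map(str, bad))[:5]}"
            )
        above = stations.loc[vals == "above"].reset_index(drop=True)
        below = stations.loc[vals == "below"].reset_index(drop=True)
    else:
        lat = stations["lat"].astype(float)
        if lat.isna().any():
            raise DataError("stations with missing latitude cannot be partitioned")
        above = stations.loc[lat > boundary_latitude].reset_index(drop=True)
        below = stations.loc[lat <= boundary_latitude].reset_index(drop=True)
    if len(above) == 0 or len(below) == 0:
        warnings.warn(
            "degenerate partition: one side is empty", UserWarning, stacklevel=2
        )
    return above, below


def boundary_window_zones(
    windows: pd.DataFrame,
    stations: pd.DataFrame,
    boundary_latitude: float,
    zone_width_deg: float,
) -> pd.Series:
    """Classify windows relative to an ecotone boundary zone.

    A window is 'boundary' when its anchor station lies within
    ``zone_width_deg`` of the boundary latitude, 'interior' when *every*
    member station lies farther than that (so no member sits in the elevated-
    variability zone), and 'shoulder' otherwise. ``windows`` needs
    ``anchor_station`` and ``members`` (';'-joined station ids) columns.
    """
    if not {"anchor_station", "members"} <= set(windows.columns):
        raise DataError("windows frame needs anchor_station and members columns")
    lat = stations.set_index(stations["station_id"].astype(str))["lat"].astype(float)

    def zone(row) -> str:
        if abs(lat[str(row["anchor_station"])] - boundary_latitude) <= zone_width_deg:
            return "boundary"
        d_min = min(
            abs(lat[m] - boundary_latitude) for m in str(row["members"]).split(";")
        )
        return "interior" if d_min > zone_width_deg else "shoulder"

    return windows.apply(zone, axis=1)
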