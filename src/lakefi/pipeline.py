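"""End-to-end driver: ordering → sost → windowed FI → summaries → trends.

`analyze_landscape` composes the whole analysis in memory for two datasets
sharing one station network (canonically the physicochemical table, tag "PC",
and the community table, tag "PHYTO"); `run_pipeline` wraps it with file I/O,
plotting and a run manifest.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fisher import (
    DataError,
    SizingError,
    SostVector,
    estimate_sost,
    windowed_fi,
    windows_to_frame,
)
from .io import (
    matrix_for_year,
    read_csv_with_schema,
    read_dataset,
    read_stations,
    write_csv_with_schema,
)
from .spatial import EARTH_RADIUS_KM, OrderedLandscape, order_stations
from .summary import (
    TauResult,
    classify_stable_years,
    correlate_datasets,
    kendall_tau_b,
    partition_by_boundary,
    trend_over_years,
    yearly_summary,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "LandscapeResult", "analyze_landscape", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (CLI > config file > defaults)."""

    abiotic_path: str = ""
    community_path: str = ""
    stations_path: str = ""
    out_dir: str = "lakefi_out"
    window_size: int = 10
    step: int = 1
    sost_mode: str = "estimate"  # {"estimate", "file"}
    sost_path: str = ""
    sost_multiplier: float = 2.0
    sost_reference: str = "first"  # {"first", "pooled"} or a year as string
    radius_km: float = EARTH_RADIUS_KM
    boundary_latitude: float | None = None
    boundary_labels: str | None = "region"  # station-table column with above/below
    alpha: float = 0.05
    reestimate_sost_per_regime: bool = False
    make_plots: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.sost_multiplier <= 0:
            raise ValueError("sost multiplier must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load YAML or JSON config; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class DatasetResult:
    """Windowed FI of one dataset over all years, plus the sost used."""

    tag: str
    sost: SostVector
    windows: pd.DataFrame  # dataset, year, window, anchor_station, lat, lon, n_states, fi


@dataclass
class PartitionResult:
    """Per-regime re-run of the pipeline on one side of the boundary."""

    side: str
    n_stations: int
    window_size: int
    summaries: pd.DataFrame
    trends: pd.DataFrame  # dataset, metric, tau, p_value, n


@dataclass
class LandscapeResult:
    """Everything `analyze_landscape` computes."""

    ordering: OrderedLandscape
    datasets: dict[str, DatasetResult]
    summaries: pd.DataFrame  # per dataset-year, with stability flags
    cross_tau: pd.DataFrame  # per-year tau between the two datasets' FI series
    cross_tau_trend: TauResult | None
    trends: pd.DataFrame  # cvFI-vs-year tau per dataset and scope
    partitions: dict[str, PartitionResult]


def _sost_for(
    long_df: pd.DataFrame,
    order: list[str],
    years: list[int],
    window_size: int,
    multiplier: float,
    reference: str,
) -> SostVector:
    """Estimate sost from a fixed reference period of the ordered data."""
    if reference == "pooled":
        mats = [matrix_for_year(long_df, y, order) for y in years]
        mats = [m for m in mats if len(m) >= window_size]
        if not mats:
            raise SizingError("no year has enough rows to estimate sost")
        data = pd.concat(mats)
    else:
        year = years[0] if reference == "first" else int(reference)
        data = matrix_for_year(long_df, year, order)
    return estimate_sost(data, window_size, multiplier)


def _windows_for(
    long_df: pd.DataFrame,
    tag: str,
    ordering: OrderedLandscape,
    sost: SostVector,
    window_size: int,
    step: int,
) -> pd.DataFrame:
    """Windowed FI per year, skipping years with too few complete rows."""
    coords = ordering.frame.set_index("station_id")[["lat", "lon"]]
    order = ordering.station_ids
    years = sorted(long_df["year"].unique())
    frames = []
    for year in years:
        mat = matrix_for_year(long_df, year, order)
        if len(mat) < window_size:
            warnings.warn(
                f"{tag} {year}: {len(mat)} usable rows < window {window_size}; "
                "year skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        wins = windowed_fi(mat, sost, window_size, step, coords=coords)
        frame = windows_to_frame(wins)
        frame.insert(0, "year", int(year))
        frame.insert(0, "dataset", tag)
        frames.append(frame)
    if not frames:
        raise SizingError(f"{tag}: no year has enough rows for window {window_size}")
    return pd.concat(frames, ignore_index=True)


def _trend_row(windows: pd.DataFrame, tag: str, scope: str) -> dict:
    summ = yearly_summary(windows, tag)
    res = trend_over_years(summ["cv_fi"].to_numpy(), summ["year"].to_numpy())
    return {
        "dataset": tag,
        "scope": scope,
        "metric": "cv_fi",
        "tau": res.tau,
        "p_value": res.p_value,
        "n": res.n,
    }


def analyze_landscape(
    datasets: Mapping[str, pd.DataFrame],
    stations: pd.DataFrame,
    *,
    window_size: int = 10,
    step: int = 1,
    sost: Mapping[str, SostVector] | None = None,
    sost_multiplier: float = 2.0,
    sost_reference: str = "first",
    radius_km: float = EARTH_RADIUS_KM,
    boundary_latitude: float | None = None,
    boundary_labels: str | None = "region",
    reestimate_sost_per_regime: bool = False,
) -> LandscapeResult:
    """Run the full FI analysis on one or two datasets sharing a station set.

    ``datasets`` maps a tag (e.g. "PC", "PHYTO") to a long-format table. One
    spatial ordering is computed from the station table and reused for every
    dataset so window k covers the same lakes throughout; sost is estimated
    once per dataset from the reference period unless supplied.
    """
    ordering = order_stations(stations, radius_km)
    order = ordering.station_ids

    results: dict[str, DatasetResult] = {}
    for tag, long_df in datasets.items():
        years = sorted(long_df["year"].unique())
        if sost and tag in sost:
            sv = sost[tag]
        else:
            sv = _sost_for(
                long_df, order, years, window_size, sost_multiplier, sost_reference
            )
        windows = _windows_for(long_df, tag, ordering, sv, window_size, step)
        results[tag] = DatasetResult(tag=tag, sost=sv, windows=windows)

    summaries = pd.concat(
        [yearly_summary(r.windows, r.tag) for r in results.values()],
        ignore_index=True,
    )
    summaries = classify_stable_years(summaries)

    tags = list(results)
    if len(tags) == 2:
        cross = correlate_datasets(results[tags[0]].windows, results[tags[1]].windows)
        finite = cross.dropna(subset=["tau"])
        cross_trend = (
            trend_over_years(finite["tau"].to_numpy(), finite["year"].to_numpy())
            if len(finite) >= 3
            else None
        )
    else:
        cross = pd.DataFrame(columns=["year", "tau", "p_value", "n"])
        cross_trend = None

    trends = pd.DataFrame([_trend_row(r.windows, r.tag, "all") for r in results.values()])

    # per-regime re-run (ordering and windows recomputed within each side)
    partitions: dict[str, PartitionResult] = {}
    if boundary_labels and boundary_labels in stations.columns:
        above, below = partition_by_boundary(stations, labels=boundary_labels)
    elif boundary_latitude is not None:
        above, below = partition_by_boundary(
            stations, boundary_latitude=boundary_latitude
        )
    else:
        above = below = None
    if above is not None:
        for side, side_stations in (("above", above), ("below", below)):
            if len(side_stations) < 3:
                warnings.warn(
                    f"partition side {side!r} has <3 stations; skipped",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            # cap below the side size so each year still yields >= 2 windows
            w_side = min(window_size, len(side_stations) - 1)
            if w_side < window_size:
                warnings.warn(
                    f"partition side {side!r}: window shrunk to {w_side}",
                    UserWarning,
                    stacklevel=2,
                )
            side_ordering = order_stations(side_stations, radius_km)
            side_summaries = []
            side_trends = []
            for tag, long_df in datasets.items():
                side_ids = set(side_ordering.station_ids)
                side_df = long_df[long_df["station_id"].astype(str).isin(side_ids)]
                if reestimate_sost_per_regime:
                    sv = _sost_for(
                        side_df,
                        side_ordering.station_ids,
                        sorted(side_df["year"].unique()),
                        w_side,
                        sost_multiplier,
                        sost_reference,
                    )
                else:
                    sv = results[tag].sost
                wins = _windows_for(side_df, tag, side_ordering, sv, w_side, step)
                side_summaries.append(yearly_summary(wins, tag))
                side_trends.append(_trend_row(wins, tag, side))
            partitions[side] = PartitionResult(
                side=side,
                n_stations=len(side_stations),
                window_size=w_side,
                summaries=pd.concat(side_summaries, ignore_index=True),
                trends=pd.DataFrame(side_trends),
            )
        if partitions:
            trends = pd.concat(
                [trends, *(p.trends for p in partitions.values())], ignore_index=True
            )

    return LandscapeResult(
        ordering=ordering,
        datasets=results,
        summaries=summaries,
        cross_tau=cross,
        cross_tau_trend=cross_trend,
        trends=trends,
        partitions=partitions,
    )


def run_pipeline(config: RunConfig) -> Path:
    """File-level pipeline: read inputs, analyse, write the result bundle.

    Writes into ``config.out_dir``: the station ordering, per-window FI tables
    per dataset, yearly summaries with stability flags, the tau tables
    (dataset-vs-dataset per year; cvFI-vs-year trends overall and per regime),
    plots, and a JSON manifest recording the configuration and version.
    Outputs are deterministic given identical config and inputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    datasets: dict[str, pd.DataFrame] = {}
    if config.abiotic_path:
        datasets["PC"], _ = read_dataset(config.abiotic_path)
    if config.community_path:
        datasets["PHYTO"], _ = read_dataset(config.community_path)
    if not datasets:
        raise DataError("no input datasets configured")
    if config.stations_path:
        stations = read_stations(config.stations_path)
    else:
        first = next(iter(datasets.values()))
        stations = first.drop_duplicates("station_id")[
            ["station_id", "lat", "lon"]
        ].reset_index(drop=True)

    supplied_sost: dict[str, SostVector] | None = None
    if config.sost_mode == "file":
        tol = read_csv_with_schema(config.sost_path)
        supplied_sost = {}
        for tag, df in datasets.items():
            sub = tol[tol["dataset"] == tag] if "dataset" in tol.columns else tol
            supplied_sost[tag] = SostVector(
                tolerances=sub["tolerance"].to_numpy(dtype=float),
                variables=tuple(sub["variable"].astype(str)),
                source="supplied",
            )

    result = analyze_landscape(
        datasets,
        stations,
        window_size=config.window_size,
        step=config.step,
        sost=supplied_sost,
        sost_multiplier=config.sost_multiplier,
        sost_reference=config.sost_reference,
        radius_km=config.radius_km,
        boundary_latitude=config.boundary_latitude,
        boundary_labels=config.boundary_labels,
        reestimate_sost_per_regime=config.reestimate_sost_per_regime,
    )

    write_csv_with_schema(result.ordering.frame, out / "ordering.csv")
    for tag, ds in result.datasets.items():
        write_csv_with_schema(ds.windows, out / f"windows_{tag}.csv")
        sost_frame = pd.DataFrame(
            {
                "dataset": tag,
                "variable": ds.sost.variables,
                "tolerance": ds.sost.tolerances,
            }
        )
        write_csv_with_schema(sost_frame, out / f"sost_{tag}.csv")
    write_csv_with_schema(result.summaries, out / "year_summaries.csv")
    write_csv_with_schema(result.cross_tau, out / "tau_cross_datasets.csv")
    write_csv_with_schema(result.trends, out / "trends.csv")
    for side, part in result.partitions.items():
        write_csv_with_schema(part.summaries, out / f"summaries_{side}.csv")

    if config.make_plots:
        from . import plotting

        for tag, ds in result.datasets.items():
            first_year = int(ds.windows["year"].min())
            plotting.export_fi_map(
                ds.windows[ds.windows["year"] == first_year],
                out / f"fi_map_{tag}_{first_year}.png",
                title=f"{tag} FI, {first_year}",
            )
            plotting.summary_scatter(
                result.summaries[result.summaries["dataset"] == tag],
                out / f"summary_scatter_{tag}.png",
                title=f"{tag}: muFI vs sdFI by year",
            )
        plotting.cv_timeseries(result.summaries, out / "cv_fi_timeseries.png")

    manifest = {
        "package": "lakefi",
        "version": __version__,
        "config": asdict(config),
        "n_stations": int(len(stations)),
        "datasets": {
            tag: {
                "years": sorted(map(int, ds.windows["year"].unique())),
                "windows_per_year": int(
                    ds.windows.groupby("year")["window"].count().iloc[0]
                ),
            }
            for tag, ds in result.datasets.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
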