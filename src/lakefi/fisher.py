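"""Discrete Fisher Information over moving windows of multivariate observations.

Fisher Information (FI) is used here as an index of dynamic order: multivariate
observations (one row per monitoring station, ordered in space) are grouped into
discrete *states*, two observations belonging to the same state when they differ
by no more than a per-variable tolerance — the "size of states" (sost) — on every
variable. From the state occupation probabilities ``p(s)`` the index is

    FI = 4 * sum_s (q(s) - q(s+1))**2,     q(s) = sqrt(p(s)),

with the amplitude sequence taken in state first-appearance order and padded with
a single zero at each end. Under this convention FI ranges over [0, 8]: FI = 8
when all observations fall into one state (perfect order) and FI declines toward
0.8·(something small) as observations disperse over many states.

The moving-window driver slides a fixed-size window along a spatially ordered
station sequence and reports one FI value per window, anchored at the window's
first station.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

FI_MAX = 8.0

__all__ = [
    "FI_MAX",
    "SizingError",
    "DataError",
    "NormalizationError",
    "SostVector",
    "StateAssignment",
    "WindowFI",
    "estimate_sost",
    "bin_states",
    "compute_fi",
    "windowed_fi",
    "windows_to_frame",
]


class SizingError(ValueError):
    """Window/step sizes incompatible with the data."""


class DataError(ValueError):
    """Invalid observation data (missing values, shape mismatch, duplicates)."""


class NormalizationError(ValueError):
    """State probabilities do not form a probability distribution."""


# ---------------------------------------------------------------------------
# Types


@dataclass(frozen=True)
class SostVector:
    """Per-variable indistinguishability tolerance (size of states).

    Two observations co-bin into one state when they are within ``tolerances[k]``
    of each other on *every* variable k. Tolerances carry the units of their
    variables; ``multiplier`` records the dimensionless factor applied to the
    stable-window standard deviations when the vector was estimated.
    """

    tolerances: np.ndarray
    variables: tuple[str, ...] = ()
    multiplier: float = 1.0
    source: str = "supplied"  # {"supplied", "estimated"}

    def __post_init__(self) -> None:
        tol = np.asarray(self.tolerances, dtype=float)
        if tol.ndim != 1:
            raise DataError("sost tolerances must be one-dimensional")
        if np.any(np.isnan(tol)) or np.any(tol < 0):
            raise DataError("sost tolerances must be non-negative and finite")
        object.__setattr__(self, "tolerances", tol)
        if self.variables and len(self.variables) != tol.size:
            raise DataError(
                f"{len(self.variables)} variable names for {tol.size} tolerances"
            )
        if self.source not in ("supplied", "estimated"):
            raise DataError(f"unknown sost source {self.source!r}")

    def __len__(self) -> int:
        return int(self.tolerances.size)


@dataclass(frozen=True)
class StateAssignment:
    """Result of binning one window of observations into discrete states.

    ``labels`` holds the 1-based state index of each observation; ``counts``
    the state occupancies in first-appearance order.
    """

    labels: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        counts = np.asarray(self.counts, dtype=int)
        if labels.size == 0:
            raise SizingError("empty window: no observations to bin")
        if np.any(counts <= 0) or counts.sum() != labels.size:
            raise DataError("state counts must be positive and sum to window size")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "counts", counts)

    @property
    def window_size(self) -> int:
        return int(self.labels.size)

    @property
    def n_states(self) -> int:
        return int(self.counts.size)

    @property
    def p(self) -> np.ndarray:
        """State probabilities p(s), first-appearance order."""
        return self.counts / self.labels.size

    @property
    def q(self) -> np.ndarray:
        """Probability amplitudes q(s) = sqrt(p(s))."""
        return np.sqrt(self.p)


@dataclass(frozen=True)
class WindowFI:
    """FI of one spatial window along the ordered station sequence."""

    index: int  # 1-based window index
    members: tuple[str, ...]  # ordered member station ids
    anchor: str  # station at which the value is reported (window start)
    fi: float
    n_states: int
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fi <= FI_MAX + 1e-12):
            raise NormalizationError(f"FI {self.fi} outside [0, {FI_MAX}]")


# ---------------------------------------------------------------------------
# Helpers


def _as_matrix(data) -> tuple[np.ndarray, tuple[str, ...], list[str]]:
    """Coerce a DataFrame/array to (values, variable names, row ids)."""
    if isinstance(data, pd.DataFrame):
        values = data.to_numpy(dtype=float)
        variables = tuple(str(c) for c in data.columns)
        ids = [str(i) for i in data.index]
    else:
        values = np.asarray(data, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        variables = tuple(f"var_{k + 1}" for k in range(values.shape[1]))
        ids = [str(i) for i in range(values.shape[0])]
    return values, variables, ids


def _check_finite(values: np.ndarray) -> None:
    if not np.all(np.isfinite(values)):
        raise DataError(
            "observation matrix contains missing/non-finite values; apply the "
            "missing-data policy (listwise row drop per year) before binning"
        )


def _cobin_matrix(values: np.ndarray, tol: np.ndarray) -> np.ndarray:
    """Boolean n×n matrix: True where two rows are within sost on every variable."""
    n, v = values.shape
    ok = np.ones((n, n), dtype=bool)
    # chunk over variables to bound the n*n*v temporary
    chunk = max(1, int(4_000_000 // max(n * n, 1)))
    for lo in range(0, v, chunk):
        hi = min(v, lo + chunk)
        block = values[:, lo:hi]
        diff = np.abs(block[:, None, :] - block[None, :, :])
        ok &= np.all(diff <= tol[lo:hi], axis=-1)
    return ok


def _greedy_assign(cobin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy first-fit state assignment from a pairwise co-binning matrix.

    The first observation founds state 1 and is its reference point; each later
    observation joins the earliest-founded state whose *reference* it matches,
    otherwise founds a new state. Ties (a point matching several states) go to
    the earliest-founded state, which makes the rule deterministic.
    """
    n = cobin.shape[0]
    labels = np.zeros(n, dtype=int)
    refs: list[int] = []
    counts: list[int] = []
    for i in range(n):
        for s, r in enumerate(refs):
            if cobin[i, r]:
                labels[i] = s + 1
                counts[s] += 1
                break
        else:
            refs.append(i)
            counts.append(1)
            labels[i] = len(refs)
    return labels, np.asarray(counts, dtype=int)


# ---------------------------------------------------------------------------
# Operations


def estimate_sost(
    data,
    window_size: int,
    multiplier: float = 2.0,
    *,
    scale_by_overall_sd: bool = True,
) -> SostVector:
    """Estimate per-variable tolerances from the least-variable window.

    The rows are split into consecutive *disjoint* windows of ``window_size``;
    for each window the per-variable sample standard deviation is computed, and
    the "least variation" window is the one minimising the mean of those
    standard deviations. With ``scale_by_overall_sd`` (default) each variable's
    window sd is first divided by that variable's overall sd so that no single
    large-magnitude variable dominates the selection; set it False for a raw
    mean. The returned tolerances are ``multiplier`` times the selected
    window's (unscaled) per-variable standard deviations.

    Variables that are constant everywhere get tolerance 0 (identical values
    still co-bin) with a warning.
    """
    values, variables, _ = _as_matrix(data)
    _check_finite(values)
    n, v = values.shape
    if window_size < 2:
        raise SizingError("window_size must be at least 2")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    if n < window_size:
        raise SizingError(f"{n} rows is fewer than window_size={window_size}")

    n_windows = n // window_size
    blocks = values[: n_windows * window_size].reshape(n_windows, window_size, v)
    window_sds = blocks.std(axis=1, ddof=1)

    if scale_by_overall_sd:
        overall = values.std(axis=0, ddof=1)
        constant = overall == 0
        if np.any(constant):
            names = [variables[k] for k in np.flatnonzero(constant)]
            warnings.warn(
                f"variables constant everywhere (tolerance will be 0): {names}",
                UserWarning,
                stacklevel=2,
            )
        scaled = np.divide(
            window_sds,
            overall,
            out=np.zeros_like(window_sds),
            where=~constant,
        )
        criterion = scaled.mean(axis=1)
    else:
        criterion = window_sds.mean(axis=1)

    best = int(np.argmin(criterion))
    return SostVector(
        tolerances=multiplier * window_sds[best],
        variables=variables,
        multiplier=float(multiplier),
        source="estimated",
    )


def bin_states(window, sost: SostVector | Sequence[float]) -> StateAssignment:
    """Group a window's observations into states under the sost rule.

    Greedy sequential grouping: the first observation founds state 1 and becomes
    its reference point; each subsequent observation joins the first existing
    state (in founding order) whose reference point is within sost on every
    variable, otherwise it founds a new state.
    """
    values, variables, _ = _as_matrix(window)
    if values.shape[0] == 0:
        raise SizingError("empty window: no observations to bin")
    _check_finite(values)
    tol = (
        sost.tolerances
        if isinstance(sost, SostVector)
        else np.asarray(sost, dtype=float)
    )
    if tol.size != values.shape[1]:
        raise DataError(
            f"sost length {tol.size} does not match {values.shape[1]} variables"
        )
    labels, counts = _greedy_assign(_cobin_matrix(values, tol))
    return StateAssignment(labels=labels, counts=counts)


def compute_fi(assignment) -> float:
    """Discrete Fisher Information from a state assignment or a p(s) vector.

    The amplitudes q(s) = sqrt(p(s)), in state first-appearance order, are
    padded with a single zero at each end and the index is
    ``4 * sum (q(s) - q(s+1))**2``, which lies in [0, 8] and equals 8 exactly
    when there is a single state.
    """
    if isinstance(assignment, StateAssignment):
        p = assignment.p
    else:
        p = np.asarray(assignment, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise NormalizationError("p(s) must be a non-empty 1-d vector")
    if np.any(p < 0):
        raise NormalizationError("p(s) must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise NormalizationError(f"p(s) sums to {p.sum():.12g}, not 1")
    q = np.concatenate(([0.0], np.sqrt(p), [0.0]))
    return float(4.0 * np.sum(np.diff(q) ** 2))


def windowed_fi(
    data,
    sost: SostVector | Sequence[float],
    window_size: int = 10,
    step: int = 1,
    coords: Mapping[str, tuple[float, float]] | pd.DataFrame | None = None,
) -> list[WindowFI]:
    """Compute FI in a moving window along a spatially ordered observation matrix.

    Window k (1-based) covers rows k .. k+window_size-1 of the ordered matrix
    and its FI value is anchored at the k-th station. With n rows, window size
    w and step 1 this yields n - w + 1 windows (85 stations, window 10 → 76).

    Parameters
    ----------
    data : pandas.DataFrame or array
        Rows are station observations in spatial order; the index holds
        station ids.
    sost : SostVector or sequence of float
        Per-variable tolerances.
    coords : optional
        Mapping or DataFrame (indexed by station id, columns lat/lon) giving
        each anchor's coordinates for plotting/export.
    """
    values, variables, ids = _as_matrix(data)
    _check_finite(values)
    n = values.shape[0]
    if window_size < 2:
        raise SizingError("window_size must be at least 2")
    if step < 1:
        raise SizingError("step must be at least 1")
    if window_size > n:
        raise SizingError(f"window_size={window_size} exceeds {n} rows")
    tol = (
        sost.tolerances
        if isinstance(sost, SostVector)
        else np.asarray(sost, dtype=float)
    )
    if tol.size != values.shape[1]:
        raise DataError(
            f"sost length {tol.size} does not match {values.shape[1]} variables"
        )

    if isinstance(coords, pd.DataFrame):
        coord_map = {
            str(i): (float(r["lat"]), float(r["lon"])) for i, r in coords.iterrows()
        }
    else:
        coord_map = {str(k): v for k, v in coords.items()} if coords else {}

    cobin = _cobin_matrix(values, tol)
    out: list[WindowFI] = []
    for widx, start in enumerate(range(0, n - window_size + 1, step), start=1):
        stop = start + window_size
        labels, counts = _greedy_assign(cobin[start:stop, start:stop])
        assignment = StateAssignment(labels=labels, counts=counts)
        anchor = ids[start]
        lat, lon = coord_map.get(anchor, (None, None))
        out.append(
            WindowFI(
                index=widx,
                members=tuple(ids[start:stop]),
                anchor=anchor,
                fi=compute_fi(assignment),
                n_states=assignment.n_states,
                lat=lat,
                lon=lon,
            )
        )
    return out


def windows_to_frame(windows: Iterable[WindowFI]) -> pd.DataFrame:
    """Tabulate WindowFI records (members joined with ';') for CSV export."""
    rows = [
        {
            "window": w.index,
            "anchor_station": w.anchor,
            "lat": w.lat,
            "lon": w.lon,
            "n_states": w.n_states,
            "fi": w.fi,
            "members": ";".join(w.members),
        }
        for w in windows
    ]
    return pd.DataFrame(
        rows,
        columns=["window", "anchor_station", "lat", "lon", "n_states", "fi", "members"],
    )
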