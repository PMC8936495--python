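"""Synthetic lake-landscape generator.

Emulates the statistical structure the FI pipeline is designed to detect in a
boreal lake monitoring network: two latitudinal regimes separated by a hard
ecotone boundary, ~10 physicochemical variables driven by a small number of
latent spatial factors, and a sparse many-taxon community whose abundances
respond to the abiotic field. Three headline features are built in:

* **boundary variance** — observation noise is inflated near the regime
  boundary, decaying exponentially with latitude distance from it;
* **declining spatial variance** — the noise scale shrinks by a constant
  multiplicative factor per year;
* **abiotic–biotic decoupling** — the community's response coefficient to the
  abiotic field interpolates from a strong initial coupling to a weak final
  one across the study years.

All randomness flows from a single integer seed, so the same configuration
always yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SyntheticConfig", "generate_landscape", "ABIOTIC_VARIABLES"]


class ConfigError(ValueError):
    """Invalid synthetic-landscape configuration."""


#: default physicochemical variables as (name, mean level, natural scale)
ABIOTIC_VARIABLES: list[tuple[str, float, float]] = [
    ("water_temp", 16.0, 1.5),  # degC, August surface water
    ("ph", 6.5, 0.4),
    ("alkalinity", 0.15, 0.05),  # meq/L
    ("conductivity", 8.0, 2.0),  # mS/m
    ("sulphate", 2.5, 0.8),  # mg/L
    ("ammonium", 15.0, 5.0),  # ug/L
    ("phosphate", 8.0, 3.0),  # ug/L
    ("toc", 9.0, 2.0),  # mg/L
    ("total_p", 12.0, 4.0),  # ug/L
    ("water_colour", 0.15, 0.05),  # abs 420nm
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterisation of the simulated lake landscape.

    Defaults mirror the monitoring design the pipeline targets: 85 lakes
    (31 above / 54 below the boundary), 23 annual August surveys, 10 abiotic
    variables and a 200-taxon sparse community. Effect sizes are in units of
    the latent-factor standard deviation (``base_noise_sd``).
    """

    n_stations_north: int = 31
    n_stations_south: int = 54
    boundary_latitude: float = 60.0
    north_lat_range: tuple[float, float] = (60.1, 66.5)
    south_lat_range: tuple[float, float] = (56.0, 59.9)
    lon_range: tuple[float, float] = (12.5, 18.5)
    year_start: int = 1996
    year_end: int = 2018
    n_abiotic_vars: int = 10
    n_taxa: int = 200
    n_common_taxa: int = 40
    regime_offset: float = 1.0  # north-south abiotic mean shift, alternating sign
    base_noise_sd: float = 1.0
    n_factors: int = 2
    idiosyncratic_sd: float = 0.2  # per-variable noise on top of the factors
    regional_field_sd: float = 0.3  # shared year x regime x variable intercept
    outlier_prob: float = 0.08  # chance of an episodic large excursion per draw
    outlier_scale: float = 4.0  # excursion sd relative to the quiet sd
    boundary_inflation: float = 0.7  # peak multiplicative noise excess at boundary
    boundary_decay_deg: float = 0.75  # e-folding scale of the excess, degrees lat
    variance_trend: float = 0.93  # per-year multiplicative decline of noise sd
    coupling_initial: float = 0.8  # community response to the abiotic field ...
    coupling_final: float = 0.1  # ... at the first and last survey year
    community_log_sd: float = 0.25  # log10 spread of common-taxon biovolumes
    community_noise_sd: float = 0.15  # taxon-level residual, relative units
    specialist_edge_jitter_deg: float = 0.1  # spread of range edges round boundary
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations_north <= 0 or self.n_stations_south <= 0:
            raise ConfigError("station counts must be positive")
        if self.year_end - self.year_start + 1 < 3:
            raise ConfigError("need at least 3 survey years")
        for lo, hi in (self.north_lat_range, self.south_lat_range, self.lon_range):
            if not hi > lo:
                raise ConfigError("degenerate coordinate extent")
        if not (0.0 <= self.coupling_final <= 1.0 and 0.0 <= self.coupling_initial <= 1.0):
            raise ConfigError("coupling values must lie in [0, 1]")
        if self.boundary_decay_deg <= 0:
            raise ConfigError("boundary decay length must be positive")
        if self.variance_trend <= 0:
            raise ConfigError("variance_trend must be positive")
        if not 0 < self.n_common_taxa <= self.n_taxa:
            raise ConfigError("n_common_taxa must be in (0, n_taxa]")
        if self.n_abiotic_vars < 1 or self.n_factors < 1:
            raise ConfigError("need at least one abiotic variable and factor")
        if self.boundary_inflation < 0:
            raise ConfigError("boundary_inflation must be non-negative")
        if not 0.0 <= self.outlier_prob < 1.0 or self.outlier_scale < 1.0:
            raise ConfigError("outlier_prob must be in [0,1) and outlier_scale >= 1")

    @property
    def years(self) -> list[int]:
        return list(range(self.year_start, self.year_end + 1))

    @property
    def n_stations(self) -> int:
        return self.n_stations_north + self.n_stations_south


def _variable_table(n: int) -> list[tuple[str, float, float]]:
    out = list(ABIOTIC_VARIABLES[:n])
    for k in range(len(out), n):
        out.append((f"chem_{k + 1:02d}", 10.0, 2.0))
    return out


def _place_stations(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    lat_n = rng.uniform(*cfg.north_lat_range, cfg.n_stations_north)
    lon_n = rng.uniform(*cfg.lon_range, cfg.n_stations_north)
    lat_s = rng.uniform(*cfg.south_lat_range, cfg.n_stations_south)
    lon_s = rng.uniform(*cfg.lon_range, cfg.n_stations_south)
    lat = np.concatenate([lat_n, lat_s])
    lon = np.concatenate([lon_n, lon_s])
    region = ["above"] * cfg.n_stations_north + ["below"] * cfg.n_stations_south
    ids = [f"L{i + 1:03d}" for i in range(cfg.n_stations)]
    return pd.DataFrame(
        {"station_id": ids, "lat": lat, "lon": lon, "region": region}
    )


def generate_landscape(
    config: SyntheticConfig | None = None, **overrides
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (abiotic table, community table, station table).

    Both data tables are long format with columns ``station_id, lat, lon,
    year`` followed by one column per variable/taxon — the same CSV schema the
    readers consume. The station table adds the regime label
    (``region`` = 'above'/'below' the boundary).

    Model sketch (station i, year t with index k):

    * latent factors ``F[f,i,t] ~ N(0, (base_sd * infl_i * trend**k)**2)``
      where ``infl_i = 1 + boundary_inflation * exp(-|lat_i - boundary| /
      decay)``;
    * abiotic variable v: plausible mean + regime offset (alternating sign)
      + shared year-by-regime field + factor loadings @ F + idiosyncratic
      noise, then mapped onto each variable's natural scale;
    * common taxa (present everywhere): log10 biovolume responds to the first
      abiotic factor with coefficient ``c_t`` interpolating from
      coupling_initial to coupling_final, plus an independent community factor
      and taxon-level noise;
    * specialist taxa: range-limited to one regime with a range edge jittered
      around the boundary, fixed detection-level biovolume where present and
      structural zeros elsewhere (the source of the matrix's sparsity).
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    stations = _place_stations(cfg, rng)
    n = cfg.n_stations
    years = cfg.years
    n_years = len(years)

    dist = np.abs(stations["lat"].to_numpy() - cfg.boundary_latitude)
    infl = 1.0 + cfg.boundary_inflation * np.exp(-dist / cfg.boundary_decay_deg)
    is_north = (stations["region"] == "above").to_numpy()

    varinfo = _variable_table(cfg.n_abiotic_vars)
    var_names = [v[0] for v in varinfo]
    var_mean = np.array([v[1] for v in varinfo])
    var_scale = np.array([v[2] for v in varinfo])

    # structured loadings: each variable loads mainly on one factor
    loadings = np.full((cfg.n_abiotic_vars, cfg.n_factors), 0.25)
    for v in range(cfg.n_abiotic_vars):
        loadings[v, v % cfg.n_factors] = 1.0
    offsets = cfg.regime_offset * np.where(
        np.arange(cfg.n_abiotic_vars) % 2 == 0, 1.0, -1.0
    )

    # community parameters, drawn once
    n_common = cfg.n_common_taxa
    n_spec = cfg.n_taxa - n_common
    mu_common = rng.uniform(0.5, 2.5, n_common)  # log10 biovolume level
    beta = rng.uniform(0.8, 1.2, n_common) * rng.choice([-1.0, 1.0], n_common)
    gamma = rng.uniform(0.3, 0.55, n_common)
    taxon_factor = np.arange(n_common) % cfg.n_factors  # abiotic factor each tracks
    spec_home_north = np.arange(n_spec) % 2 == 0
    spec_edge = cfg.boundary_latitude + rng.uniform(
        -cfg.specialist_edge_jitter_deg, cfg.specialist_edge_jitter_deg, n_spec
    )
    spec_value = 10.0 ** rng.uniform(-0.5, 1.5, n_spec)
    taxa_names = [f"taxon_{j + 1:03d}" for j in range(cfg.n_taxa)]

    lat = stations["lat"].to_numpy()
    spec_present = np.where(
        spec_home_north[None, :], lat[:, None] >= spec_edge[None, :],
        lat[:, None] <= spec_edge[None, :],
    )  # (n stations, n specialists), time-invariant range limits

    abio_blocks = []
    comm_blocks = []
    if n_years > 1:
        coupling = np.linspace(cfg.coupling_initial, cfg.coupling_final, n_years)
    else:
        coupling = np.array([cfg.coupling_initial])

    def episodic(shape, rng):
        """Gaussian scale mixture: quiet noise with occasional large excursions."""
        z = rng.normal(size=shape)
        big = rng.random(shape) < cfg.outlier_prob
        return np.where(big, z * cfg.outlier_scale, z)

    for k, year in enumerate(years):
        scale_t = cfg.base_noise_sd * cfg.variance_trend**k * infl  # per station
        factors = episodic((cfg.n_factors, n), rng) * scale_t[None, :]
        idio = rng.normal(size=(cfg.n_abiotic_vars, n)) * (
            cfg.idiosyncratic_sd / cfg.base_noise_sd
        ) * scale_t[None, :]
        regional = rng.normal(size=(cfg.n_abiotic_vars, 2)) * cfg.regional_field_sd
        anomaly = (
            loadings @ factors
            + idio
            + np.where(is_north[None, :], regional[:, :1], regional[:, 1:])
            + 0.5 * offsets[:, None] * np.where(is_north[None, :], 1.0, -1.0)
        )
        abio = var_mean[:, None] + var_scale[:, None] * anomaly

        g_comm = rng.normal(size=n)  # independent community-wide latent factor
        eps = rng.normal(size=(n_common, n)) * cfg.community_noise_sd
        driver = coupling[k] * factors[taxon_factor]  # realized abiotic field
        log10_bio = mu_common[:, None] + cfg.community_log_sd * (
            beta[:, None] * driver + gamma[:, None] * g_comm[None, :] + eps
        )
        common = 10.0**log10_bio  # (n_common, n)
        spec = np.where(spec_present.T, spec_value[:, None], 0.0)  # (n_spec, n)

        base = stations[["station_id", "lat", "lon"]].copy()
        base.insert(3, "year", year)
        abio_blocks.append(
            pd.concat(
                [base, pd.DataFrame(abio.T, columns=var_names)], axis=1
            )
        )
        comm_blocks.append(
            pd.concat(
                [
                    base.copy(),
                    pd.DataFrame(
                        np.vstack([common, spec]).T, columns=taxa_names
                    ),
                ],
                axis=1,
            )
        )

    abiotic = pd.concat(abio_blocks, ignore_index=True)
    community = pd.concat(comm_blocks, ignore_index=True)
    return abiotic, community, stations
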