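"""Synthetic generators for the four input streams of the planning analysis.

Real inputs (station weather, soil-salinity surveys, salinity-yield trials,
household production surveys) are not redistributable, so every stream can be
emulated with the statistical structure the downstream analysis assumes:

* weather — seasonal sinusoid + AR(1) daily anomalies for temperature,
  Bernoulli-gamma occurrence/amount for precipitation, calibrated to a
  warm-temperate coastal-delta climate (annual mean 12.4 degC, 551.6 mm);
* soil salinity — a belt-shaped linear gradient rising toward the coast plus
  Gaussian patches, spanning all four suitability classes;
* salinity-yield trials — a negative linear response with Gaussian noise,
  truncated at zero;
* surveys — concave quadratic fertilizer responses per cropping system, with
  economics and nitrogen-recovery fields drawn around configured per-class
  targets.

All draws come from one explicitly passed seeded generator; a fixed seed
regenerates every stream byte-identically. A 365-day (no leap) calendar is
used throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import day_length
from .economics import SALINITY_CLASSES

__all__ = [
    "SyntheticConfig",
    "CroppingSystem",
    "DEFAULT_SYSTEMS",
    "DEFAULT_ECON_TARGETS",
    "generate_weather",
    "generate_salinity_field",
    "generate_yield_trial",
    "generate_surveys",
    "write_stream_csv",
    "points_to_geojson",
]

ANNUAL_MEAN_T = 12.4  # degC
ANNUAL_PRECIP = 551.6  # mm
T_AMPLITUDE = 14.3  # degC, winter-summer half-range
PEAK_DOY = 197  # mid-July


@dataclass(frozen=True)
class CroppingSystem:
    """Configured truth for one cropping system's survey records."""

    name: str
    crop: str
    b0: float  # control (zero-fertilizer) yield, Mg/ha
    x_at_max: float  # total-fertilizer rate at maximum yield, Mg/ha
    y_max: float  # maximum yield, Mg/ha
    npk_split: tuple[float, float, float]  # N / P2O5 / K2O fractions of total
    classes: tuple[str, ...]  # salinity classes where the system is practiced
    re_n_targets: tuple[float, ...]  # mean apparent N recovery (%) per class
    n_records: int

    @property
    def b1(self) -> float:
        return 2.0 * (self.y_max - self.b0) / self.x_at_max

    @property
    def b2(self) -> float:
        b2 = -(self.y_max - self.b0) / self.x_at_max**2
        if b2 >= 0:
            raise ValueError(f"system {self.name!r}: configured response must be concave (b2 < 0)")
        return b2


# Control yields and rates-at-maximum follow the regional survey pattern for
# the five systems; maximum yields are plausible regional ceilings. N recovery
# targets decline with salinity (wheat 33.0/27.1/11.8%, summer maize
# 38.2/34.4/17.8%); other systems use field-typical levels.
DEFAULT_SYSTEMS: tuple[CroppingSystem, ...] = (
    CroppingSystem(
        "double-season wheat", "Wheat", 4.294, 0.995, 9.0,
        (0.444 / 0.995, 0.515 / 0.995, 0.036 / 0.995),
        SALINITY_CLASSES[:3], (33.0, 27.1, 11.8), 38,
    ),
    CroppingSystem(
        "double-season maize", "Maize", 5.800, 0.447, 11.0,
        (0.220 / 0.447, 0.208 / 0.447, 0.019 / 0.447),
        SALINITY_CLASSES[:3], (38.2, 34.4, 17.8), 38,
    ),
    CroppingSystem(
        "one-season cotton", "Cotton", 2.106, 0.342, 4.2,
        (0.139 / 0.342, 0.153 / 0.342, 0.049 / 0.342),
        SALINITY_CLASSES[2:], (21.0, 19.5), 23,
    ),
    CroppingSystem(
        "one-season rice", "Rice", 6.440, 0.540, 10.0,
        (0.279 / 0.540, 0.208 / 0.540, 0.019 / 0.540),
        SALINITY_CLASSES[2:], (22.0, 18.5), 10,
    ),
    CroppingSystem(
        "one-season maize", "Maize (one-season)", 6.366, 0.829, 10.5,
        (0.383 / 0.829, 0.337 / 0.829, 0.109 / 0.829),
        SALINITY_CLASSES[1:], (35.4, 24.0, 15.0), 23,
    ),
    # experimental-plot forage records (fresh weight); grown across all four
    # classes, with the strongest N recovery under moderate/heavy salinity
    CroppingSystem(
        "sweet sorghum plots", "Sweet sorghum", 40.0, 0.30, 55.0,
        (0.60, 0.30, 0.10),
        SALINITY_CLASSES, (34.0, 28.0, 20.9, 19.6), 20,
    ),
)

# (ratio %, economic output CNY/ha) targets per crop and salinity class; None
# marks combinations not planted. Mirrors the regional comparison pattern.
DEFAULT_ECON_TARGETS: dict[str, tuple[tuple[float, float] | None, ...]] = {
    "Soybean": ((82.78, 8400.0), (71.73, 7278.0), None, None),
    "Cotton": ((67.55, 23265.0), (71.72, 24703.5), (57.92, 19950.0), (43.11, 14850.0)),
    "Rice": (None, None, (137.46, 17598.0), (128.87, 16500.0)),
    "Wheat": ((161.52, 19407.0), (136.03, 16041.0), (95.17, 11223.0), None),
    "Maize": ((178.06, 18859.5), (161.65, 17121.0), (158.59, 16797.0), None),
    "Sweet sorghum": ((215.80, 17712.0), (147.32, 9723.0), (90.41, 5967.0), (74.4, 4911.0)),
}


@dataclass
class SyntheticConfig:
    """Knobs for all four generators; defaults are the study conditions."""

    seed: int = 0
    n_stations: int = 5
    years: tuple[int, int] = (2000, 2009)
    domain_bbox: tuple[float, float, float, float] = (117.5, 36.9, 119.5, 38.2)  # W, S, E, N
    n_soil_points: int = 121
    n_trial_points: int = 58
    n_survey_records_per_system: int | None = None  # None -> per-system survey counts
    salinity_gradient_direction: tuple[float, float] = (0.7071067811865476, 0.7071067811865476)
    trial_salinity_max: float = 8.0  # permil
    noise_sd_yield: float = 1.52  # trial yield noise, calibrated to R^2 ~ 0.38 at n = 58
    true_yield_intercept: float = 5.3384
    true_yield_slope: float = -0.5077
    survey_noise_sd_yield: float = 0.6  # Mg/ha around the quadratic response
    survey_noise_rel_econ: float = 0.05  # relative sd on economics fields
    survey_noise_rel_re: float = 0.15  # relative sd on the N-uptake increment
    systems: tuple[CroppingSystem, ...] = DEFAULT_SYSTEMS
    econ_targets: dict = field(default_factory=lambda: dict(DEFAULT_ECON_TARGETS))

    def __post_init__(self) -> None:
        if self.years[1] < self.years[0]:
            raise ValueError("empty year range")
        w, s, e, n = self.domain_bbox
        if e <= w or n <= s:
            raise ValueError("degenerate domain bounding box")
        if self.noise_sd_yield < 0:
            raise ValueError("noise_sd_yield must be nonnegative")
        gx, gy = self.salinity_gradient_direction
        norm = float(np.hypot(gx, gy))
        if norm == 0:
            raise ValueError("salinity gradient direction must be a nonzero vector")
        self.salinity_gradient_direction = (gx / norm, gy / norm)

    def rng(self, stream: str) -> np.random.Generator:
        """Independent, reproducible generator per stream."""
        return np.random.default_rng([self.seed, _STREAM_IDS[stream]])


_STREAM_IDS = {"weather": 1, "soil": 2, "trial": 3, "survey": 4}


def _noleap_dates(year_start: int, year_end: int) -> pd.DatetimeIndex:
    dates = pd.date_range(f"{year_start}-01-01", f"{year_end}-12-31", freq="D")
    return dates[~((dates.month == 2) & (dates.day == 29))]


def generate_weather(config: SyntheticConfig) -> pd.DataFrame:
    """Daily station weather for all calendar years in the configured range.

    Columns: station, date, lon, lat, elevation, t_mean, t_min, t_max,
    precip (mm), sunshine (h), u2 (m/s), rh (fraction).
    """
    if config.n_stations < 1:
        raise ValueError("need at least one station")
    rng = config.rng("weather")
    w, s, e, n = config.domain_bbox
    lons = rng.uniform(w, e, config.n_stations)
    lats = rng.uniform(s, n, config.n_stations)
    elevs = rng.uniform(2.0, 25.0, config.n_stations)

    dates = _noleap_dates(*config.years)
    doy = dates.dayofyear.to_numpy().astype(float)
    # re-map doys after Feb 28 in leap years onto the 365-day cycle
    leap = dates.year.to_numpy() % 4 == 0
    doy = np.where(leap & (doy > 59), doy - 1, doy)
    seasonal = np.cos(2.0 * np.pi * (doy - PEAK_DOY) / 365.0)

    # precipitation climatology: summer-concentrated expected daily totals
    shape_w = 1.0 + 0.9 * seasonal
    cycle_doy = np.arange(1, 366)
    cycle_w = 1.0 + 0.9 * np.cos(2.0 * np.pi * (cycle_doy - PEAK_DOY) / 365.0)
    expected_daily = ANNUAL_PRECIP * shape_w / cycle_w.sum()
    p_wet = np.clip(0.32 * shape_w, 0.05, 0.60)

    frames = []
    for i in range(config.n_stations):
        t_base = ANNUAL_MEAN_T + T_AMPLITUDE * seasonal
        anom = np.empty(len(dates))
        anom[0] = rng.normal(0.0, 2.0)
        eps = rng.normal(0.0, 2.0 * np.sqrt(1 - 0.7**2), len(dates))
        for j in range(1, len(dates)):
            anom[j] = 0.7 * anom[j - 1] + eps[j]
        t_mean = t_base + anom
        spread_hi = 4.0 + np.abs(rng.normal(0.0, 0.8, len(dates)))
        spread_lo = 4.0 + np.abs(rng.normal(0.0, 0.8, len(dates)))
        t_max = t_mean + spread_hi
        t_min = t_mean - spread_lo

        wet = rng.uniform(size=len(dates)) < p_wet
        gamma_shape = 0.8
        amounts = rng.gamma(gamma_shape, (expected_daily / p_wet) / gamma_shape)
        precip = np.where(wet, amounts, 0.0)

        n_day = np.array([day_length(lats[i], int(d)) for d in doy])
        sun_frac = rng.beta(3.0, 2.0, len(dates))
        sunshine = sun_frac * n_day

        rh = np.clip(rng.normal(0.66, 0.08, len(dates)), 0.30, 0.98)
        u2 = rng.gamma(4.0, 0.65, len(dates))

        frames.append(
            pd.DataFrame(
                {
                    "station": f"S{i + 1:02d}",
                    "date": dates,
                    "lon": lons[i],
                    "lat": lats[i],
                    "elevation": elevs[i],
                    "t_mean": t_mean,
                    "t_min": t_min,
                    "t_max": t_max,
                    "precip": precip,
                    "sunshine": sunshine,
                    "u2": u2,
                    "rh": rh,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_salinity_field(config: SyntheticConfig) -> pd.DataFrame:
    """Soil sample points with a coastward salinity gradient plus patches.

    Columns: point_id, lon, lat, depth_layer (0-10 / 10-20 / 20-40 cm),
    salinity (permil). Salinity rises along the configured gradient
    direction (toward the coast) from ~0 to >10 permil.
    """
    if config.n_soil_points < 4:
        raise ValueError("need at least 4 soil points")
    rng = config.rng("soil")
    w, s, e, n = config.domain_bbox
    lon = rng.uniform(w, e, config.n_soil_points)
    lat = rng.uniform(s, n, config.n_soil_points)
    gx, gy = config.salinity_gradient_direction

    proj = (lon - w) * gx + (lat - s) * gy
    pmin, pmax = proj.min(), proj.max()
    t = (proj - pmin) / (pmax - pmin)  # 0 inland, 1 at the coast edge

    n_bumps = 6
    bx = rng.uniform(w, e, n_bumps)
    by = rng.uniform(s, n, n_bumps)
    bamp = rng.normal(0.0, 1.2, n_bumps)
    bscale = rng.uniform(0.15, 0.4, n_bumps)
    bumps = sum(
        a * np.exp(-((lon - x0) ** 2 + (lat - y0) ** 2) / (2 * sc**2))
        for a, x0, y0, sc in zip(bamp, bx, by, bscale)
    )

    surface = 0.3 + 11.2 * t + bumps
    layer_offsets = {"0-10": 0.0, "10-20": -0.3, "20-40": -0.8}
    rows = []
    for layer, off in layer_offsets.items():
        sal = np.maximum(surface + off + rng.normal(0.0, 0.25, config.n_soil_points), 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "point_id": np.arange(config.n_soil_points),
                    "lon": lon,
                    "lat": lat,
                    "depth_layer": layer,
                    "salinity": sal,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_yield_trial(config: SyntheticConfig) -> pd.DataFrame:
    """Paired (salinity, yield) trial observations around the configured line.

    yield = max(0, intercept + slope*salinity + N(0, noise_sd)).
    """
    if config.n_trial_points < 10:
        raise ValueError("need at least 10 trial points")
    rng = config.rng("trial")
    sal = rng.uniform(0.0, config.trial_salinity_max, config.n_trial_points)
    noise = rng.normal(0.0, config.noise_sd_yield, config.n_trial_points) if config.noise_sd_yield > 0 else 0.0
    y = np.maximum(config.true_yield_intercept + config.true_yield_slope * sal + noise, 0.0)
    return pd.DataFrame({"salinity": sal, "yield": y})


def _class_index(cls: str) -> int:
    return SALINITY_CLASSES.index(cls)


def generate_surveys(config: SyntheticConfig) -> pd.DataFrame:
    """Household survey records for the five cropping systems.

    Per record: fertilizer rates (total and N/P2O5/K2O split), a yield drawn
    from the system's concave quadratic response, previous-year yield,
    economics fields around the configured (ratio, output) targets, and
    above-ground N uptake with/without fertilizer embedding the configured
    per-class apparent-recovery targets.
    """
    rng = config.rng("survey")
    rows = []
    for sys_ in config.systems:
        if len(sys_.re_n_targets) != len(sys_.classes):
            raise ValueError(f"system {sys_.name!r}: one RE target per class required")
        _ = sys_.b2  # validates concavity
        n_rec = config.n_survey_records_per_system or sys_.n_records
        if n_rec < 5:
            raise ValueError("need at least 5 survey records per cropping system")
        targets = config.econ_targets.get(sys_.crop)
        for cls, re_target in zip(sys_.classes, sys_.re_n_targets):
            ci = _class_index(cls)
            econ = targets[ci] if targets is not None and targets[ci] is not None else None
            for _k in range(n_rec):
                x_total = rng.uniform(0.3 * sys_.x_at_max, 1.5 * sys_.x_at_max)
                y_noise = (
                    rng.normal(0.0, config.survey_noise_sd_yield)
                    if config.survey_noise_sd_yield > 0
                    else 0.0
                )
                yld = max(sys_.b0 + sys_.b1 * x_total + sys_.b2 * x_total**2 + y_noise, 0.0)
                y_prev = max(yld + (rng.normal(0.0, config.survey_noise_sd_yield)
                                    if config.survey_noise_sd_yield > 0 else 0.0), 0.0)
                # nutrient components are shares of the total rate
                split_sum = sum(sys_.npk_split)
                fn, fp, fk = (x_total * f / split_sum for f in sys_.npk_split)

                if econ is not None:
                    ratio_t, output_t = econ
                    e1 = rng.normal(0.0, config.survey_noise_rel_econ) if config.survey_noise_rel_econ > 0 else 0.0
                    e2 = rng.normal(0.0, config.survey_noise_rel_econ) if config.survey_noise_rel_econ > 0 else 0.0
                    output_value = output_t * (1.0 + e1)
                    input_cost = output_value / (ratio_t / 100.0) * (1.0 + e2)
                else:
                    output_value = np.nan
                    input_cost = np.nan

                re_eps = rng.normal(0.0, config.survey_noise_rel_re) if config.survey_noise_rel_re > 0 else 0.0
                du = (re_target / 100.0) * fn * (1.0 + re_eps)
                u0 = 0.015 * sys_.b0  # control above-ground N uptake, Mg/ha
                rows.append(
                    {
                        "system": sys_.name,
                        "crop": sys_.crop,
                        "salinity_class": cls,
                        "fert_total": x_total,
                        "fert_N": fn,
                        "fert_P2O5": fp,
                        "fert_K2O": fk,
                        "yield": yld,
                        "yield_prev": y_prev,
                        "input_cost": input_cost,
                        "output_value": output_value,
                        "uptake_N": u0 + max(du, 0.0),
                        "uptake_N_control": u0,
                        "area_ha": float(rng.uniform(0.2, 3.0)),
                    }
                )
    return pd.DataFrame(rows)


def write_stream_csv(df: pd.DataFrame, path) -> Path:
    """Write a generated stream as CSV with header; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def points_to_geojson(df: pd.DataFrame, value_col: str, path) -> Path:
    """Write (lon, lat, value) points as a GeoJSON FeatureCollection."""
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [round(r.lon, 8), round(r.lat, 8)]},
            "properties": {value_col: getattr(r, value_col)},
        }
        for r in df.itertuples()
    ]
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": feats}, sort_keys=True))
    return path
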