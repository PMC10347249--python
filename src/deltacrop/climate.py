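"""Per-growth-stage climate suitability indices for a summer forage crop.

Three daily-weather-driven indices are combined per growth stage:

* temperature suitability ``F(T)`` — a beta-type unimodal response between
  cardinal temperatures (lower limit ``T_l``, optimum ``T_o``, upper limit
  ``T_h``) with shape exponent ``B = (T_h - T_o) / (T_o - T_l)``;
* water suitability ``F(R)`` — stage precipitation judged against a band
  around the stage crop water requirement ``ET_c = K_c * sum(ET_0)``, with
  ``ET_0`` the FAO-56 daily Penman-Monteith reference evapotranspiration;
* sunshine suitability ``F(S)`` — actual sunshine relative to an optimal
  duration, applied only in the photoperiod-sensitive stage.

The per-stage comprehensive index is the geometric mean of the three, and a
season value aggregates the stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StageParams",
    "DEFAULT_STAGES",
    "SuitabilityResult",
    "beta_exponent",
    "temperature_suitability",
    "saturation_vapor_pressure",
    "reference_et0",
    "crop_water_requirement",
    "water_suitability",
    "day_length",
    "sunshine_suitability",
    "comprehensive_index",
    "season_suitability",
    "period_means",
]

# FAO-56 constants (daily time step)
SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1
STEFAN_BOLTZMANN = 4.903e-9  # MJ K-4 m-2 d-1
ALBEDO = 0.23
ANGSTROM_A = 0.25
ANGSTROM_B = 0.50


@dataclass(frozen=True)
class StageParams:
    """Cardinal temperatures and coefficients for one growth stage.

    ``date_window`` is an inclusive (start, end) day-of-year pair. ``s_opt``
    is the most suitable sunshine duration in hours; when ``None`` the
    photoperiod threshold defaults to 0.7 x astronomical day length.
    """

    name: str
    date_window: tuple[int, int]
    t_l: float
    t_o: float
    t_h: float
    k_c: float
    photoperiod_sensitive: bool = False
    s_opt: float | None = None

    def __post_init__(self) -> None:
        if not (self.t_l < self.t_o < self.t_h):
            raise ValueError(
                f"stage {self.name!r}: cardinal temperatures must satisfy "
                f"T_l < T_o < T_h, got ({self.t_l}, {self.t_o}, {self.t_h})"
            )
        if self.k_c <= 0:
            raise ValueError(f"stage {self.name!r}: K_c must be positive")
        lo, hi = self.date_window
        if not (1 <= lo <= hi <= 366):
            raise ValueError(f"stage {self.name!r}: invalid date window {self.date_window}")

    @property
    def beta(self) -> float:
        return beta_exponent(self.t_l, self.t_o, self.t_h)

    @property
    def n_days(self) -> int:
        return self.date_window[1] - self.date_window[0] + 1


# Sweet-sorghum calendar for a warm-temperate coastal delta (~37.5 N):
# emergence-heading mid-May to mid-July, heading-flowering mid-July to late
# August (the sole photoperiod-sensitive stage, optimal sunshine 11 h/d),
# flowering-maturity late August to early October.
DEFAULT_STAGES: tuple[StageParams, ...] = (
    StageParams("emergence-heading", (135, 196), t_l=11.0, t_o=30.0, t_h=42.0, k_c=0.45),
    StageParams(
        "heading-flowering",
        (197, 238),
        t_l=11.0,
        t_o=30.0,
        t_h=42.0,
        k_c=1.15,
        photoperiod_sensitive=True,
        s_opt=11.0,
    ),
    StageParams("flowering-maturity", (239, 280), t_l=5.7, t_o=22.5, t_h=42.0, k_c=1.05),
)


@dataclass
class SuitabilityResult:
    """Per-stage and season-aggregated suitability indices for one season."""

    stage_names: list[str]
    f_t: np.ndarray
    f_r: np.ndarray
    f_s: np.ndarray
    f_trs: np.ndarray
    et_c: np.ndarray
    season: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.stage_names,
                "F_T": self.f_t,
                "F_R": self.f_r,
                "F_S": self.f_s,
                "F_TRS": self.f_trs,
                "ET_c_mm": self.et_c,
            }
        )


def beta_exponent(t_l: float, t_o: float, t_h: float) -> float:
    """Shape exponent B = (T_h - T_o) / (T_o - T_l) of the beta response."""
    if not (t_l < t_o < t_h):
        raise ValueError(f"cardinal temperatures must satisfy T_l < T_o < T_h, got ({t_l}, {t_o}, {t_h})")
    return (t_h - t_o) / (t_o - t_l)


def temperature_suitability(t, params: StageParams):
    """Beta-function temperature suitability in [0, 1].

    ``F(T) = [(T - T_l) (T_h - T)^B] / [(T_o - T_l) (T_h - T_o)^B]`` on
    ``(T_l, T_h)``, zero at and outside the cardinal limits, one at ``T_o``.
    Accepts scalars or arrays.
    """
    t = np.asarray(t, dtype=float)
    b = params.beta
    inside = (t > params.t_l) & (t < params.t_h)
    ft = np.zeros_like(t)
    tt = np.where(inside, t, params.t_o)
    num = (tt - params.t_l) * (params.t_h - tt) ** b
    den = (params.t_o - params.t_l) * (params.t_h - params.t_o) ** b
    ft = np.where(inside, num / den, 0.0)
    return float(ft) if ft.ndim == 0 else ft


def saturation_vapor_pressure(t: float) -> float:
    """Saturation vapor pressure e0(T) in kPa (FAO-56 Tetens form)."""
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


def _solar_geometry(lat_deg: float, doy: int) -> tuple[float, float, float]:
    """Return (sunset hour angle rad, extraterrestrial radiation MJ/m2/d, inverse rel. distance)."""
    phi = math.radians(lat_deg)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi / 365.0 * doy)
    delta = 0.409 * math.sin(2.0 * math.pi / 365.0 * doy - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    if not (-1.0 < x < 1.0):
        raise ValueError(f"polar day/night at lat={lat_deg}, doy={doy}: out of scope")
    ws = math.acos(x)
    ra = (
        24.0 * 60.0 / math.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * math.sin(phi) * math.sin(delta) + math.cos(phi) * math.cos(delta) * math.sin(ws))
    )
    return ws, ra, dr


def day_length(lat: float, doy: int) -> float:
    """Astronomical day length in hours from solar declination geometry."""
    if abs(lat) >= 66.5:
        raise ValueError("polar latitudes are out of scope")
    ws, _, _ = _solar_geometry(lat, doy)
    return 24.0 / math.pi * ws


def reference_et0(
    t_mean: float,
    t_min: float,
    t_max: float,
    rh: float,
    u2: float,
    sunshine_hours: float,
    lat: float,
    doy: int,
    elevation: float = 0.0,
) -> float:
    """FAO-56 daily Penman-Monteith reference evapotranspiration (mm/d).

    Net radiation is derived from actual sunshine duration through the
    Angstrom relation (a=0.25, b=0.50); soil heat flux G = 0 at the daily
    step; actual vapor pressure from mean relative humidity (fraction).
    """
    for name, v in (("rh", rh), ("u2", u2), ("sunshine_hours", sunshine_hours)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing meteorological input {name!r}; no silent default")
    if not 0.0 < rh <= 1.0:
        raise ValueError(f"relative humidity must be a fraction in (0, 1], got {rh}")
    if u2 < 0 or sunshine_hours < 0:
        raise ValueError("wind speed and sunshine duration must be nonnegative")

    ws, ra, _ = _solar_geometry(lat, doy)
    n_max = 24.0 / math.pi * ws
    rs = (ANGSTROM_A + ANGSTROM_B * min(sunshine_hours, n_max) / n_max) * ra
    rso = (0.75 + 2e-5 * elevation) * ra
    rns = (1.0 - ALBEDO) * rs

    es = 0.5 * (saturation_vapor_pressure(t_max) + saturation_vapor_pressure(t_min))
    ea = rh * es
    tkmax, tkmin = t_max + 273.16, t_min + 273.16
    cloud = 1.35 * min(rs / rso, 1.0) - 0.35
    rnl = (
        STEFAN_BOLTZMANN
        * 0.5 * (tkmax**4 + tkmin**4)
        * (0.34 - 0.14 * math.sqrt(ea))
        * cloud
    )
    rn = rns - rnl

    pressure = 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    delta = 4098.0 * saturation_vapor_pressure(t_mean) / (t_mean + 237.3) ** 2

    g = 0.0  # negligible at the daily step
    num = 0.408 * delta * (rn - g) + gamma * (900.0 / (t_mean + 273.0)) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return max(num / den, 0.0)


def crop_water_requirement(et0_series: Sequence[float], k_c: float) -> float:
    """Stage crop water requirement ET_c = K_c * sum(ET_0) in mm."""
    et0 = np.asarray(et0_series, dtype=float)
    if et0.size == 0:
        raise ValueError("empty ET_0 series: stage window not covered")
    if k_c < 0:
        raise ValueError("K_c must be nonnegative")
    return float(k_c * et0.sum())


def water_suitability(r: float, et_c: float) -> float:
    """Precipitation suitability against the [0.7, 1.3] x ET_c band.

    1 inside the band; R/R_b below it (mild drought); R_m/R above it (mild
    waterlogging), with R_b = 0.7*ET_c and R_m = 1.3*ET_c.
    """
    if r < 0:
        raise ValueError("precipitation must be nonnegative")
    if et_c <= 0:
        raise ValueError("ET_c must be positive: the precipitation band is undefined at 0")
    r_b, r_m = 0.7 * et_c, 1.3 * et_c
    if r < r_b:
        return r / r_b
    if r > r_m:
        return r_m / r
    return 1.0


def sunshine_suitability(s: float, s_o: float) -> float:
    """min(S/S_o, 1): linear below the optimal duration, saturating at 1."""
    if s_o <= 0:
        raise ValueError("optimal sunshine duration must be positive")
    if s < 0:
        raise ValueError("sunshine duration must be nonnegative")
    return min(s / s_o, 1.0)


def comprehensive_index(f_t: float, f_r: float, f_s: float) -> float:
    """Geometric mean (cube root of the product) of the three indices."""
    for name, v in (("F_T", f_t), ("F_R", f_r), ("F_S", f_s)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return float((f_t * f_r * f_s) ** (1.0 / 3.0))


_REQUIRED_WEATHER = ("date", "t_mean", "t_min", "t_max", "precip", "sunshine", "u2", "rh")


def season_suitability(
    daily: pd.DataFrame,
    stages: Sequence[StageParams] = DEFAULT_STAGES,
    *,
    lat: float | None = None,
    elevation: float | None = None,
    sunshine_threshold: Literal["fixed", "daylength"] = "fixed",
    temperature_input: Literal["stage_mean", "daily_mean"] = "stage_mean",
    aggregation: Literal["length_weighted", "unweighted"] = "length_weighted",
) -> SuitabilityResult:
    """Per-stage and season suitability from one season of daily weather.

    ``daily`` needs columns date (datetime-like), t_mean, t_min, t_max,
    precip (mm), sunshine (h), u2 (m/s), rh (fraction), and either ``lat`` /
    ``elevation`` columns or the keyword overrides.

    ``sunshine_threshold='fixed'`` uses each sensitive stage's configured
    ``s_opt`` hours; ``'daylength'`` uses 0.7 x astronomical day length.
    Photoperiod-insensitive stages score F_S = 1 regardless of sunshine.
    """
    missing = [c for c in _REQUIRED_WEATHER if c not in daily.columns]
    if missing:
        raise ValueError(f"daily weather is missing columns: {missing}")
    df = daily.copy()
    df["doy"] = pd.to_datetime(df["date"]).dt.dayofyear
    lat = float(df["lat"].iloc[0]) if lat is None and "lat" in df else (lat if lat is not None else 37.5)
    elevation = (
        float(df["elevation"].iloc[0])
        if elevation is None and "elevation" in df
        else (elevation if elevation is not None else 0.0)
    )

    names: list[str] = []
    f_t = np.empty(len(stages))
    f_r = np.empty(len(stages))
    f_s = np.empty(len(stages))
    f_trs = np.empty(len(stages))
    et_c = np.empty(len(stages))
    weights = np.array([s.n_days for s in stages], dtype=float)

    for i, stage in enumerate(stages):
        lo, hi = stage.date_window
        win = df[(df["doy"] >= lo) & (df["doy"] <= hi)]
        covered = set(win["doy"])
        gaps = [d for d in range(lo, hi + 1) if d not in covered]
        if gaps:
            raise ValueError(
                f"stage {stage.name!r} window {stage.date_window} has weather gaps "
                f"(first missing doy {gaps[0]}, {len(gaps)} missing)"
            )

        if temperature_input == "stage_mean":
            f_t[i] = temperature_suitability(float(win["t_mean"].mean()), stage)
        else:
            f_t[i] = float(np.mean(temperature_suitability(win["t_mean"].to_numpy(), stage)))

        et0 = [
            reference_et0(
                row.t_mean, row.t_min, row.t_max, row.rh, row.u2, row.sunshine, lat, int(row.doy), elevation
            )
            for row in win.itertuples()
        ]
        et_c[i] = crop_water_requirement(et0, stage.k_c)
        f_r[i] = water_suitability(float(win["precip"].sum()), et_c[i])

        if not stage.photoperiod_sensitive:
            f_s[i] = 1.0
        else:
            if sunshine_threshold == "fixed" and stage.s_opt is not None:
                s_o = stage.s_opt
            else:
                s_o = 0.7 * float(np.mean([day_length(lat, int(d)) for d in win["doy"]]))
            f_s[i] = sunshine_suitability(float(win["sunshine"].mean()), s_o)

        f_trs[i] = comprehensive_index(f_t[i], f_r[i], f_s[i])
        names.append(stage.name)

    if aggregation == "length_weighted":
        season = float(np.average(f_trs, weights=weights))
    else:
        season = float(f_trs.mean())
    return SuitabilityResult(names, f_t, f_r, f_s, f_trs, et_c, season)


def period_means(yearly: pd.DataFrame, periods: Iterable[tuple[int, int]]) -> pd.DataFrame:
    """Mean of per-year season values over multi-year periods, per station.

    ``yearly`` has columns station, year, and one or more index columns;
    each (start, end) period is averaged inclusively.
    """
    out = []
    value_cols = [c for c in yearly.columns if c not in ("station", "year")]
    for start, end in periods:
        sel = yearly[(yearly["year"] >= start) & (yearly["year"] <= end)]
        if sel.empty:
            continue
        g = sel.groupby("station", as_index=False)[value_cols].mean()
        g.insert(1, "period", f"{start}-{end}")
        out.append(g)
    if not out:
        raise ValueError("no years fall inside the requested periods")
    return pd.concat(out, ignore_index=True)
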