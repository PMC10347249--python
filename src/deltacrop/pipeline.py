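"""End-to-end orchestration: synthesize/load inputs, compute suitability,
interpolate, zone by salinity, summarize economics and fertilizer efficiency.

Every run writes plain-text artifacts (CSV, ESRI ASCII grid, JSON) into an
output directory plus a manifest listing each artifact with its SHA-256
hash; a fixed config and seed reproduce the manifest hash-for-hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import climate, economics, fertilizer, salinity, spatial, synthetic

__all__ = ["RunConfig", "Violation", "validate_inputs", "run_pipeline", "load_config"]

log = logging.getLogger("deltacrop")

DECADES = ((1980, 1989), (1990, 1999), (2000, 2014))


@dataclass
class RunConfig:
    """One pipeline run: input sources, method settings, output location.

    Each input stream is either a CSV path or None (synthesized from
    ``synthetic`` settings). ``periods`` are inclusive year ranges averaged
    for the suitability maps.
    """

    out_dir: str = "deltacrop_out"
    seed: int = 0
    weather_csv: str | None = None
    soil_csv: str | None = None
    trial_csv: str | None = None
    survey_csv: str | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    idw_power: float = 2.0
    idw_k_neighbors: int | None = None
    grid_cell_size: float = 0.01
    threshold_fractions: tuple[float, float, float] = (0.75, 0.50, 0.25)
    sunshine_threshold: str = "fixed"
    aggregation: str = "length_weighted"
    periods: tuple[tuple[int, int], ...] | None = None
    nutrient_content: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in fertilizer.DEFAULT_NUTRIENT_CONTENT.items()}
    )
    enabled_streams: tuple[str, ...] = ("weather", "soil", "trial", "survey")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        f = self.threshold_fractions
        if not (len(f) == 3 and all(0 < x < 1 for x in f) and f[0] > f[1] > f[2]):
            raise ValueError("threshold fractions must be three strictly decreasing values in (0,1)")
        if self.synthetic is None and None in (
            self.weather_csv, self.soil_csv, self.trial_csv, self.survey_csv,
        ):
            # default to synthesizing whatever is not supplied as a file
            self.synthetic = synthetic.SyntheticConfig(seed=self.seed)


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file; nested `synthetic:` keys map onto
    SyntheticConfig fields."""
    raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
    syn = raw.pop("synthetic", None)
    cfg = RunConfig(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()})
    if syn is not None:
        syn = {k: (tuple(v) if isinstance(v, list) else v) for k, v in syn.items()}
        cfg.synthetic = synthetic.SyntheticConfig(**syn)
    return cfg


@dataclass
class Violation:
    stream: str
    row: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = f" (row {self.row})" if self.row is not None else ""
        return f"[{self.stream}]{loc} {self.message}"


def _load_streams(cfg: RunConfig) -> dict[str, pd.DataFrame | None]:
    """Resolve each stream from file or the synthetic generators."""
    syn = cfg.synthetic
    streams: dict[str, pd.DataFrame | None] = {}
    loaders = {
        "weather": (cfg.weather_csv, synthetic.generate_weather),
        "soil": (cfg.soil_csv, synthetic.generate_salinity_field),
        "trial": (cfg.trial_csv, synthetic.generate_yield_trial),
        "survey": (cfg.survey_csv, synthetic.generate_surveys),
    }
    for name, (path, gen) in loaders.items():
        if name not in cfg.enabled_streams:
            streams[name] = None
            log.info("stream %s disabled; dependent stages will be skipped", name)
        elif path is not None:
            df = pd.read_csv(path)
            if name == "weather":
                df["date"] = pd.to_datetime(df["date"])
            streams[name] = df
            log.info("loaded %s from %s: %d records", name, path, len(df))
        elif syn is not None:
            streams[name] = gen(syn)
            log.info("synthesized %s: %d records", name, len(streams[name]))
        else:
            streams[name] = None
            log.info("stream %s absent; dependent stages will be skipped", name)
    return streams


def validate_inputs(cfg: RunConfig) -> list[Violation]:
    """Schema/range checks per stream; returns every violation found."""
    streams = _load_streams(cfg)
    out: list[Violation] = []

    wx = streams["weather"]
    if wx is not None:
        for col in ("t_mean", "t_min", "t_max", "precip", "sunshine", "u2", "rh"):
            if col not in wx.columns:
                out.append(Violation("weather", None, f"missing column {col!r}"))
        if not out:
            bad = wx.index[(wx["t_min"] > wx["t_mean"]) | (wx["t_mean"] > wx["t_max"])]
            out += [Violation("weather", int(i), "t_min <= t_mean <= t_max violated") for i in bad]
            for col, lo, hi in (("precip", 0, None), ("sunshine", 0, 24), ("u2", 0, None), ("rh", 0, 1)):
                v = wx[col]
                bad = v.index[(v < lo) | ((v > hi) if hi is not None else False)]
                out += [Violation("weather", int(i), f"{col} out of range") for i in bad]
            # stage coverage per station-year
            doy = pd.to_datetime(wx["date"]).dt.dayofyear
            for (st, yr), grp in wx.groupby([wx["station"], pd.to_datetime(wx["date"]).dt.year]):
                days = set(pd.to_datetime(grp["date"]).dt.dayofyear)
                for stage in climate.DEFAULT_STAGES:
                    lo_, hi_ = stage.date_window
                    missing = [d for d in range(lo_, hi_ + 1) if d not in days]
                    if missing:
                        out.append(
                            Violation(
                                "weather", None,
                                f"stage coverage: station {st} year {yr} stage {stage.name!r} "
                                f"missing {len(missing)} days",
                            )
                        )

    soil = streams["soil"]
    if soil is not None:
        bad = soil.index[soil["salinity"] < 0]
        out += [Violation("soil", int(i), "negative salinity") for i in bad]

    trial = streams["trial"]
    if trial is not None:
        for col in ("salinity", "yield"):
            bad = trial.index[trial[col] < 0]
            out += [Violation("trial", int(i), f"negative {col}") for i in bad]

    survey = streams["survey"]
    if survey is not None:
        bad = survey.index[~survey["salinity_class"].isin(economics.SALINITY_CLASSES)]
        out += [Violation("survey", int(i), "unknown salinity class") for i in bad]
        for col in ("fert_total", "fert_N"):
            bad = survey.index[survey[col] <= 0]
            out += [Violation("survey", int(i), f"nonpositive {col}") for i in bad]
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _combine_topsoil(soil: pd.DataFrame) -> pd.DataFrame:
    """0-20 cm salinity per point: depth-weighted mean of 0-10 and 10-20 cm."""
    top = soil[soil["depth_layer"].isin(["0-10", "10-20"])]
    g = top.groupby("point_id").agg(lon=("lon", "first"), lat=("lat", "first"), value=("salinity", "mean"))
    return g.reset_index()


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute all available stages; returns the manifest dict."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    streams = _load_streams(cfg)
    notes: list[str] = []

    def save_df(df: pd.DataFrame, name: str) -> None:
        p = out_dir / name
        df.to_csv(p, index=False, float_format="%.10g")
        artifacts.append(p)

    # --- stage 1: synthesized inputs are themselves artifacts ---------------
    for name, df in streams.items():
        if df is not None:
            save_df(df, f"input_{name}.csv")

    # --- stage 2: per-station, per-year climate suitability -----------------
    yearly = None
    wx = streams["weather"]
    if wx is not None:
        log.info("suitability: %d station-days", len(wx))
        rows = []
        wxx = wx.copy()
        wxx["year"] = pd.to_datetime(wxx["date"]).dt.year
        for (st, yr), grp in wxx.groupby(["station", "year"]):
            res = climate.season_suitability(
                grp,
                sunshine_threshold=cfg.sunshine_threshold,  # type: ignore[arg-type]
                aggregation=cfg.aggregation,  # type: ignore[arg-type]
            )
            rows.append(
                {
                    "station": st,
                    "year": yr,
                    "lon": grp["lon"].iloc[0],
                    "lat": grp["lat"].iloc[0],
                    "F_T": float(np.mean(res.f_t)),
                    "F_R": float(np.mean(res.f_r)),
                    "F_S": float(np.mean(res.f_s)),
                    "season": res.season,
                }
            )
        yearly = pd.DataFrame(rows)
        save_df(yearly, "suitability_yearly.csv")

        periods = cfg.periods
        if periods is None:
            y0, y1 = int(yearly["year"].min()), int(yearly["year"].max())
            periods = tuple((a, b) for a, b in DECADES if a <= y1 and b >= y0) or ((y0, y1),)
        pm = climate.period_means(yearly[["station", "year", "F_T", "F_R", "F_S", "season"]], periods)
        save_df(pm, "suitability_periods.csv")

    # --- stage 3: spatial interpolation --------------------------------------
    w, s, e, n = (cfg.synthetic.domain_bbox if cfg.synthetic is not None else (117.5, 36.9, 119.5, 38.2))
    geom = spatial.Grid(
        lon0=w, lat0=s, cell_size=cfg.grid_cell_size,
        n_rows=int(round((n - s) / cfg.grid_cell_size)) + 1,
        n_cols=int(round((e - w) / cfg.grid_cell_size)) + 1,
    )
    if yearly is not None:
        pts = yearly.groupby("station").agg(lon=("lon", "first"), lat=("lat", "first"), value=("season", "mean")).reset_index()
        suit_grid = spatial.idw_interpolate(pts, geom, power=cfg.idw_power, k_neighbors=cfg.idw_k_neighbors)
        p = out_dir / "suitability_grid.asc"
        suit_grid.write_ascii(p)
        artifacts.append(p)

    sal_grid = None
    if streams["soil"] is not None:
        topsoil = _combine_topsoil(streams["soil"])
        save_df(topsoil, "soil_topsoil_points.csv")
        sal_grid = spatial.idw_interpolate(topsoil, geom, power=cfg.idw_power, k_neighbors=cfg.idw_k_neighbors)
        p = out_dir / "salinity_grid.asc"
        sal_grid.write_ascii(p)
        artifacts.append(p)

    # --- stage 4: salinity-yield fit and zoning ------------------------------
    fit = None
    if streams["trial"] is not None:
        trial = streams["trial"]
        fit = salinity.SalinityYieldModel(degree=1, fractions=cfg.threshold_fractions).fit(
            trial["salinity"], trial["yield"]
        ).to_fit()
        quad = salinity.fit_quadratic(trial["salinity"], trial["yield"])
        report = {
            "linear": {
                "intercept": fit.intercept, "slope": fit.slope,
                "r_squared": fit.r_squared, "p_value": fit.p_value,
                "max_yield": fit.max_yield, "thresholds_permil": list(fit.thresholds or ()),
            },
            "quadratic": {
                "intercept": quad.intercept, "slope": quad.slope, "curvature": quad.curvature,
                "r_squared": quad.r_squared, "p_value": quad.p_value,
            },
        }
        p = out_dir / "salinity_yield_fit.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True))
        artifacts.append(p)
        if fit.thresholds is not None:
            save_df(
                pd.DataFrame(
                    {
                        "fraction_of_max_yield": list(cfg.threshold_fractions),
                        "salinity_breakpoint_permil": list(fit.thresholds),
                    }
                ),
                "thresholds.csv",
            )
        if sal_grid is not None and fit.thresholds is not None:
            classes = spatial.classify_grid(sal_grid, fit.thresholds)
            p = out_dir / "salinity_classes.asc"
            classes.write_ascii(p)
            artifacts.append(p)
            cdf = classes.to_frame("class_index").dropna()
            cdf["class_label"] = [spatial.CLASS_LABELS[int(i)] for i in cdf["class_index"]]
            save_df(cdf, "salinity_classes.csv")
    else:
        notes.append("trial stream absent: zoning skipped")
        log.info("trial stream absent: zoning skipped")

    # --- stage 5: economics ---------------------------------------------------
    survey = streams["survey"]
    if survey is not None and survey["output_value"].notna().any():
        econ = economics.summarize_economics(survey.dropna(subset=["output_value", "input_cost"]))
        save_df(econ, "economics_summary.csv")
        table = economics.to_comparison_table(econ)
        p = out_dir / "economics_table.csv"
        table.to_csv(p)
        artifacts.append(p)
    else:
        notes.append("survey stream absent: economics skipped")
        log.info("survey stream absent: economics skipped")

    # --- stage 6: fertilizer response + N recovery ---------------------------
    if survey is not None:
        fits, res = [], []
        for sys_name, grp in survey.groupby("system"):
            rf = fertilizer.fit_response(grp["fert_total"], grp["yield"])
            fits.append(
                {
                    "system": sys_name, "b0": rf.b0, "b1": rf.b1, "b2": rf.b2,
                    "x_at_max": rf.x_at_max, "y_max": rf.y_max, "r_squared": rf.r_squared,
                }
            )
            for cls, cgrp in grp.groupby("salinity_class"):
                re_vals = [
                    fertilizer.recovery_efficiency(r.uptake_N, r.uptake_N_control, r.fert_N)
                    for r in cgrp.itertuples()
                ]
                res.append(
                    {
                        "system": sys_name, "salinity_class": cls,
                        "mean_re_n_pct": float(np.mean(re_vals)), "n": len(re_vals),
                    }
                )
        save_df(pd.DataFrame(fits).sort_values("system"), "fertilizer_response_fits.csv")
        save_df(
            pd.DataFrame(res).sort_values(["system", "salinity_class"]), "recovery_efficiency.csv"
        )
    else:
        notes.append("survey stream absent: fertilizer efficiency skipped")

    manifest = {
        "seed": cfg.seed,
        "notes": notes,
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("wrote %d artifacts to %s", len(artifacts), out_dir)
    return manifest
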