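"""Study bundles: CSV schemas, validation, and the end-to-end pipeline.

A *study bundle* is a directory of five plain-CSV input tables plus an
optional ground-truth sidecar:

  bursts.csv      individual, timestamp, sample_index, ax, ay, az   (g)
  calib.csv       individual, axis, offset, gain
  gps.csv         individual, timestamp, lon, lat                   (WGS84)
  thread.csv      individual, day, seq, distance_m, bearing_deg,
                  start_lon, start_lat
  body_temp.csv   individual, timestamp, body_temp_c
  weather.csv     date, hour, ambient_temp_c, abs_humidity_gm3,
                  cloud_cover (0-5), precipitation (0/1)
  truth.json      generating parameters (+ pointers to hidden-label CSVs)

Every table written by this package carries ``#``-prefixed metadata
header lines (config hash, stage, package version); readers skip them.
All timestamps are ISO-8601 local clock time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, accel, activity, envstats, geo, paths, synth, thermal

__all__ = [
    "AnalysisConfig",
    "ValidationReport",
    "write_study",
    "load_config",
    "validate_bundle",
    "run_all",
]

SCHEMAS = {
    "bursts.csv": ["individual", "timestamp", "sample_index", "ax", "ay", "az"],
    "calib.csv": ["individual", "axis", "offset", "gain"],
    "gps.csv": ["individual", "timestamp", "lon", "lat"],
    "thread.csv": [
        "individual", "day", "seq", "distance_m", "bearing_deg",
        "start_lon", "start_lat",
    ],
    "body_temp.csv": ["individual", "timestamp", "body_temp_c"],
    "weather.csv": [
        "date", "hour", "ambient_temp_c", "abs_humidity_gm3",
        "cloud_cover", "precipitation",
    ],
}

MOVEMENT_TERMS = ["ambient_temp_c", "abs_humidity_gm3", "precipitation",
                  "cloud_cover", "hour"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the analysis stages (one YAML file covers all)."""

    static_window_s: float | None = None  # None = full-burst mean
    mixture_mode: str = "weighted"
    mixture_min_n: int = 50
    breadth_level: float = 0.8
    cluster_method: str = "kmeans"
    day_start: int = 7
    day_end: int = 19
    utm_zone: int | None = None
    seed: int = 0


def _config_hash(cfg) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def _read_csv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kw)


def write_study(study: synth.SynthStudy, outdir) -> Path:
    """Write a SynthStudy as a validated bundle (five CSVs + truth
    sidecar).  Planar simulation coordinates are anchored at the
    configured lon/lat and exported as WGS84 degrees."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    meta = {"config_hash": _config_hash(cfg), "version": __version__}

    rows = []
    for b in study.bursts:
        n = b.samples.shape[0]
        rows.append(
            pd.DataFrame(
                {
                    "individual": b.individual,
                    "timestamp": b.timestamp.isoformat(),
                    "sample_index": np.arange(n),
                    "ax": b.samples[:, 0],
                    "ay": b.samples[:, 1],
                    "az": b.samples[:, 2],
                }
            )
        )
    _write_csv(pd.concat(rows, ignore_index=True), outdir / "bursts.csv",
               {**meta, "stage": "simulate/bursts"})

    individuals = sorted({b.individual for b in study.bursts})
    calib = pd.DataFrame(
        [(ind, ax, 0.0, 1.0) for ind in individuals for ax in ("x", "y", "z")],
        columns=SCHEMAS["calib.csv"],
    )
    _write_csv(calib, outdir / "calib.csv", {**meta, "stage": "simulate/calib"})

    zone = geo.utm_zone(cfg.anchor_lon)
    e0, n0, _ = geo.to_utm(cfg.anchor_lon, cfg.anchor_lat, zone)
    gps = study.gps.copy()
    lon, lat = geo.to_wgs84(e0 + gps["x"].to_numpy(), n0 + gps["y"].to_numpy(), zone)
    gps_out = pd.DataFrame(
        {
            "individual": gps["individual"],
            "timestamp": gps["timestamp"].map(pd.Timestamp.isoformat),
            "lon": lon,
            "lat": lat,
        }
    )
    _write_csv(gps_out, outdir / "gps.csv", {**meta, "stage": "simulate/gps"})

    thread_rows = []
    for ind, grp in study.fine_paths.groupby("individual", sort=True):
        for day, dgrp in grp.groupby(grp["timestamp"].dt.date, sort=True):
            xy = dgrp[["x", "y"]].to_numpy()
            if len(xy) < 2:
                continue
            d = np.diff(xy, axis=0)
            dist = np.hypot(d[:, 0], d[:, 1])
            bearing = np.degrees(np.arctan2(d[:, 0], d[:, 1])) % 360.0
            slon, slat = geo.to_wgs84(e0 + xy[0, 0], n0 + xy[0, 1], zone)
            thread_rows.append(
                pd.DataFrame(
                    {
                        "individual": ind,
                        "day": str(day),
                        "seq": np.arange(len(dist)),
                        "distance_m": dist,
                        "bearing_deg": bearing,
                        "start_lon": float(slon),
                        "start_lat": float(slat),
                    }
                )
            )
    _write_csv(pd.concat(thread_rows, ignore_index=True), outdir / "thread.csv",
               {**meta, "stage": "simulate/thread"})

    bt = study.body_temps.copy()
    bt["timestamp"] = bt["timestamp"].map(pd.Timestamp.isoformat)
    _write_csv(bt, outdir / "body_temp.csv", {**meta, "stage": "simulate/body_temp"})
    _write_csv(study.weather, outdir / "weather.csv",
               {**meta, "stage": "simulate/weather"})

    labels = study.burst_labels.copy()
    labels["timestamp"] = labels["timestamp"].map(pd.Timestamp.isoformat)
    _write_csv(labels, outdir / "truth_burst_labels.csv",
               {**meta, "stage": "simulate/truth"})
    modes = study.fine_paths[["individual", "timestamp", "true_mode"]].copy()
    modes["timestamp"] = modes["timestamp"].map(pd.Timestamp.isoformat)
    _write_csv(modes, outdir / "truth_step_modes.csv",
               {**meta, "stage": "simulate/truth"})
    truth = dict(study.truth)
    truth["hidden_label_files"] = ["truth_burst_labels.csv", "truth_step_modes.csv"]
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=str)
    return outdir


def read_bursts(bundle: Path) -> list[accel.AccBurst]:
    df = _read_csv(Path(bundle) / "bursts.csv")
    calib_path = Path(bundle) / "calib.csv"
    calibs = {}
    if calib_path.exists():
        cdf = _read_csv(calib_path)
        for ind, grp in cdf.groupby("individual"):
            g = grp.set_index("axis")
            calibs[ind] = accel.Calibration(
                offset=g.loc[["x", "y", "z"], "offset"].to_numpy(),
                gain=g.loc[["x", "y", "z"], "gain"].to_numpy(),
            )
    bursts = []
    for (ind, ts), grp in df.groupby(["individual", "timestamp"], sort=True):
        grp = grp.sort_values("sample_index")
        samples = grp[["ax", "ay", "az"]].to_numpy()
        n = samples.shape[0]
        # infer the rate from the bundle-wide convention: 30-s bursts
        bursts.append(
            accel.AccBurst(
                individual=ind,
                timestamp=pd.Timestamp(ts),
                samples=samples,
                rate=n / 30.0,
                calibration=calibs.get(ind),
            )
        )
    return bursts


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_bundle(bundle) -> ValidationReport:
    """Schema- and range-check every table of a bundle.

    Violations are itemised with table and row; cross-table individual
    mismatches are warnings (partial data is tolerated)."""
    bundle = Path(bundle)
    rep = ValidationReport()
    tables = {}
    for name, cols in SCHEMAS.items():
        p = bundle / name
        if not p.exists():
            (rep.warnings if name == "weather.csv" else rep.errors).append(
                f"{name}: file missing"
            )
            continue
        df = _read_csv(p)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            rep.errors.append(f"{name}: missing columns {missing}")
            continue
        tables[name] = df

    w = tables.get("weather.csv")
    if w is not None:
        bad = ~w["cloud_cover"].isin(range(6))
        for i in w.index[bad]:
            rep.errors.append(f"weather.csv row {i}: cloud_cover outside 0-5")
        bad = ~w["hour"].between(0, 23)
        for i in w.index[bad]:
            rep.errors.append(f"weather.csv row {i}: hour outside 0-23")

    t = tables.get("thread.csv")
    if t is not None:
        bad = (t["bearing_deg"] < 0) | (t["bearing_deg"] >= 360)
        for i in t.index[bad]:
            rep.errors.append(
                f"thread.csv row {i}: bearing {t.loc[i, 'bearing_deg']} "
                "outside [0, 360)"
            )
        bad = t["distance_m"] < 0
        for i in t.index[bad]:
            rep.errors.append(f"thread.csv row {i}: negative distance")

    g = tables.get("gps.csv")
    if g is not None:
        if not np.isfinite(g[["lon", "lat"]].to_numpy()).all():
            rep.errors.append("gps.csv: non-finite coordinates")

    b = tables.get("bursts.csv")
    if b is not None and g is not None:
        gps_ind = set(g["individual"])
        burst_ind = set(b["individual"])
        for ind in sorted(gps_ind - burst_ind):
            rep.warnings.append(
                f"individual {ind} present in gps.csv but absent from bursts.csv"
            )
        for ind in sorted(burst_ind - gps_ind):
            rep.warnings.append(
                f"individual {ind} present in bursts.csv but absent from gps.csv"
            )
    return rep


def _steps_from_gps(gps: pd.DataFrame, acfg: AnalysisConfig) -> pd.DataFrame:
    zone = acfg.utm_zone or geo.utm_zone(float(gps["lon"].mean()))
    e, n, _ = geo.to_utm(gps["lon"].to_numpy(), gps["lat"].to_numpy(), zone)
    pts = gps.copy()
    pts["x"], pts["y"] = e, n
    pts["timestamp"] = pd.to_datetime(pts["timestamp"])
    steps = paths.compute_steps_by_individual(
        pts[["individual", "timestamp", "x", "y"]]
    )
    return paths.exclude_overnight(steps, (acfg.day_start, acfg.day_end))


def _steps_from_thread(thread: pd.DataFrame, acfg: AnalysisConfig) -> pd.DataFrame:
    zone = acfg.utm_zone or geo.utm_zone(float(thread["start_lon"].mean()))
    parts = []
    for (ind, day), grp in thread.groupby(["individual", "day"], sort=True):
        grp = grp.sort_values("seq")
        e0, n0, _ = geo.to_utm(
            float(grp["start_lon"].iloc[0]), float(grp["start_lat"].iloc[0]), zone
        )
        pts = paths.thread_to_path(
            (e0, n0), grp["distance_m"].to_numpy(), grp["bearing_deg"].to_numpy()
        )
        df = pd.DataFrame(pts, columns=["x", "y"])
        df["individual"] = ind
        s = paths.compute_steps(df)
        parts.append(s)
    return pd.concat(parts, ignore_index=True)


def load_config(path) -> tuple[synth.SynthConfig, AnalysisConfig]:
    """Load the single YAML config covering simulation and analysis."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.get("simulate", {})
    for key, cls in (
        ("mixture", synth.MixtureTruth),
        ("weather", synth.WeatherEffects),
    ):
        if key in sim:
            sim[key] = cls(**sim[key])
    if "crw" in sim:
        crw = sim["crw"]
        for mk in ("extensive", "intensive"):
            if mk in crw:
                crw[mk] = synth.ModeTruth(**crw[mk])
        sim["crw"] = synth.CrwTruth(**crw)
    scfg = synth.SynthConfig(**sim)
    acfg = AnalysisConfig(**raw.get("analysis", {}))
    return scfg, acfg


def run_all(bundle, outdir, acfg: AnalysisConfig | None = None) -> dict:
    """Run the full pipeline on a validated bundle.

    Stages: ODBA -> activity classification -> path segmentation ->
    thermal performance curve -> environmental models (skipped with a
    notice when weather.csv is absent).  Outputs are deterministic for
    a fixed config; a ``truth.json`` sidecar triggers recovery
    diagnostics (estimated vs generating parameters) in the report.
    """
    bundle, outdir = Path(bundle), Path(outdir)
    acfg = acfg or AnalysisConfig()
    rep = validate_bundle(bundle)
    if not rep.ok:
        raise ValueError("bundle failed validation:\n" + "\n".join(rep.errors))
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": _config_hash(acfg), "version": __version__}
    report: dict = {"config": asdict(acfg), "notices": list(rep.warnings)}

    # --- stage: ODBA
    try:
        bursts = read_bursts(bundle)
        bursts = [
            accel.apply_calibration(b) if b.calibration is not None else b
            for b in bursts
        ]
        bt_path = bundle / "body_temp.csv"
        body = _read_csv(bt_path) if bt_path.exists() else None
        if body is not None:
            body["timestamp"] = pd.to_datetime(body["timestamp"])
        records = accel.odba_records(bursts, body, window=acfg.static_window_s)
        _write_csv(records, outdir / "odba.csv", {**meta, "stage": "odba"})
    except Exception as exc:
        raise RuntimeError(f"stage 'odba' failed: {exc}") from exc

    # --- stage: activity classification
    try:
        fits, label_parts = [], []
        for ind, grp in records.groupby("individual", sort=True):
            x = activity.transform_odba(
                activity.floor_positive(grp["odba"].to_numpy())
            )
            fit = activity.fit_mixture(
                x, individual=ind, mode=acfg.mixture_mode,
                min_n=acfg.mixture_min_n, seed=acfg.seed,
            )
            fits.append(fit)
            label_parts.append(activity.classify_bursts(fit, grp))
        labels = pd.concat(label_parts, ignore_index=True)
        hourly = activity.activity_proportion(labels)
        fits_df = pd.DataFrame([asdict(f) for f in fits])
        _write_csv(fits_df, outdir / "mixture_fits.csv", {**meta, "stage": "classify"})
        _write_csv(labels, outdir / "labels.csv", {**meta, "stage": "classify"})
        _write_csv(hourly, outdir / "hourly_activity.csv",
                   {**meta, "stage": "classify"})
        pooled_act = labels.loc[labels["state"] == "active", "odba"]
        pooled_inact = labels.loc[labels["state"] == "inactive", "odba"]
        report["activity"] = {
            "individuals": len(fits),
            "pooled_active_range_g": [float(pooled_act.min()), float(pooled_act.max())]
            if len(pooled_act) else None,
            "pooled_inactive_range_g": [
                float(pooled_inact.min()), float(pooled_inact.max())
            ] if len(pooled_inact) else None,
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    # --- stage: path segmentation (per-method mode-count table)
    try:
        gps = _read_csv(bundle / "gps.csv")
        gsteps = _steps_from_gps(gps, acfg)
        gsteps, gsum = paths.classify_modes(
            gsteps, seed=acfg.seed, method=acfg.cluster_method, source="gps"
        )
        thread = _read_csv(bundle / "thread.csv")
        tsteps = _steps_from_thread(thread, acfg)
        tsteps, tsum = paths.classify_modes(
            tsteps, seed=acfg.seed, method=acfg.cluster_method, source="thread"
        )
        _write_csv(gsteps, outdir / "steps_gps.csv", {**meta, "stage": "segment"})
        _write_csv(tsteps, outdir / "steps_thread.csv", {**meta, "stage": "segment"})
        mode_summary = pd.concat(
            [gsum.as_frame(), tsum.as_frame()], ignore_index=True
        )
        _write_csv(mode_summary, outdir / "mode_summary.csv",
                   {**meta, "stage": "segment"})
        hourly_odba = accel.hourly_mean_odba(records)
        report["segment"] = mode_summary.to_dict(orient="records")
        try:
            report["mode_odba_ttest"] = paths.mode_odba_compare(gsteps, hourly_odba)
        except ValueError as exc:
            report["mode_odba_ttest"] = {"skipped": str(exc)}
    except Exception as exc:
        raise RuntimeError(f"stage 'segment' failed: {exc}") from exc

    # --- stage: thermal performance curve
    try:
        if records["body_temp"].notna().any():
            bins = accel.bin_by_temperature(records)
            tfit = thermal.fit_tpc(bins)
            breadth = thermal.performance_breadth(tfit, acfg.breadth_level)
            _write_csv(tfit.candidates, outdir / "tpc_candidates.csv",
                       {**meta, "stage": "tpc"})
            grid = np.round(np.arange(tfit.temp_range[0], tfit.temp_range[1] + 1e-9,
                                      0.1), 6)
            curve = pd.DataFrame(
                {"temp_c": grid, "predicted_odba": tfit.predict(grid)}
            )
            _write_csv(curve, outdir / "tpc_curve.csv", {**meta, "stage": "tpc"})
            report["tpc"] = {
                "best_model": tfit.name,
                "t_opt": breadth.t_opt,
                "breadth_level": breadth.level,
                "breadth_interval_c": [breadth.lo, breadth.hi],
            }
        else:
            report["tpc"] = {"skipped": "no body temperatures in bundle"}
    except Exception as exc:
        raise RuntimeError(f"stage 'tpc' failed: {exc}") from exc

    # --- stage: environmental models
    wpath = bundle / "weather.csv"
    if not wpath.exists():
        report["models"] = {
            "skipped": "weather.csv absent; environmental models not fitted"
        }
    else:
        try:
            weather = _read_csv(wpath)
            weather["date"] = pd.to_datetime(weather["date"]).dt.date

            move = gsteps.copy()
            t0 = pd.to_datetime(move["t_start"])
            move["date"], move["hour"] = t0.dt.date, t0.dt.hour
            move = move.merge(weather, on=["date", "hour"], how="inner")
            move["log_distance"] = np.log(move["step_length"] + 1.0)
            mv_terms, mv_res = envstats.backward_stepwise(
                move, "log_distance", MOVEMENT_TERMS
            )
            report["models"] = {
                "movement": _model_json(mv_res),
                "movement_terms_retained": mv_terms,
            }
            _dump_json(outdir / "model_movement.json",
                       report["models"]["movement"])

            act = hourly_odba.merge(weather, on=["date", "hour"], how="inner")
            od_terms, od_res = envstats.backward_stepwise(
                act, "mean_odba", MOVEMENT_TERMS
            )
            report["models"]["activity_odba"] = _model_json(od_res)
            report["models"]["activity_terms_retained"] = od_terms
            _dump_json(outdir / "model_activity.json",
                       report["models"]["activity_odba"])

            hl = hourly.merge(weather, on=["date", "hour"], how="inner")
            lg_res = envstats.fit_activity_logistic(hl, MOVEMENT_TERMS)
            report["models"]["activity_likelihood"] = _model_json(lg_res)
            _dump_json(outdir / "model_activity_likelihood.json",
                       report["models"]["activity_likelihood"])

            contrast = envstats.precip_contrast(
                move["step_length"].to_numpy(),
                move["precipitation"].to_numpy(),
            )
            report["models"]["precip_contrast_distance"] = contrast
            _write_csv(pd.DataFrame([contrast]), outdir / "contrasts.csv",
                       {**meta, "stage": "models"})
        except Exception as exc:
            raise RuntimeError(f"stage 'models' failed: {exc}") from exc

    # --- recovery diagnostics when the truth sidecar is present
    tpath = bundle / "truth.json"
    if tpath.exists():
        with open(tpath) as fh:
            truth = json.load(fh)
        diag = {}
        mix = truth.get("config", {}).get("mixture")
        if mix:
            est = fits_df[["mu_a", "sigma_a", "mu_b", "sigma_b", "weight"]].mean()
            diag["mixture"] = {
                k: {"true": float(mix[k]), "estimated_mean": float(est[k])}
                for k in ("mu_a", "sigma_a", "mu_b", "sigma_b", "weight")
            }
        lab_file = bundle / "truth_burst_labels.csv"
        if lab_file.exists():
            tl = _read_csv(lab_file)
            tl["timestamp"] = pd.to_datetime(tl["timestamp"])
            merged = labels.merge(
                tl[["individual", "timestamp", "state"]],
                on=["individual", "timestamp"],
                suffixes=("", "_true"),
            )
            if len(merged):
                diag["label_accuracy"] = float(
                    (merged["state"] == merged["state_true"]).mean()
                )
        report["recovery"] = diag

    _dump_json(outdir / "report.json", report)
    return report


def _model_json(res: envstats.ModelResult) -> dict:
    return {
        "response": res.response,
        "terms": list(res.terms),
        "fixed_effects": res.fixed_effects.to_dict(orient="records"),
        "re_var": res.re_var,
        "resid_var": res.resid_var,
        "lrt": {"stat": res.lrt_stat, "df": res.lrt_df, "p": res.lrt_p},
        "r2_marginal": res.r2_marginal,
        "r2_conditional": res.r2_conditional,
        "n": res.n,
        "aic": res.aic,
        "singular": res.singular,
        "flags": list(res.flags),
    }


def _dump_json(path: Path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
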