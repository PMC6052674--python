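"""Synthetic biologging studies with known ground truth.

Emulates the five data streams a field study of free-ranging box
turtles produces — tri-axial accelerometer bursts, hourly daytime GPS
fixes, fine-scale thread-trailing paths, internal body temperature, and
hourly weather-station records — with every generating parameter
configurable and recorded, so each downstream analysis stage can be
validated against hidden truth.

Generating model, in outline:

* Bursts: each burst has a hidden active/inactive state; per state the
  transformed ODBA x = ODBA^(-1/3) is Gaussian, so pooled transformed
  values follow a two-Gaussian mixture.  The tri-axial signal is built
  by inverting the ODBA operator exactly (gravity offset + zero-mean
  alternating dynamic component), not by simulating biomechanics: the
  pipeline only ever consumes ODBA.
* Fine paths: a two-mode correlated random walk.  Following the study
  convention, the "extensive" mode takes short steps with large
  absolute turning angles (direction reversals) and the "intensive"
  mode long, straight steps; per-mode log-normal step lengths and
  wrapped-normal turning angles about a per-mode centre with a random
  sign; Markov mode switching.
* Hourly GPS: per-hour displacement follows a log-linear model in the
  weather covariates plus an individual random intercept, which is what
  the mixed-model stage is meant to recover.
* Body temperature: thermoconformer — ambient temperature interpolated
  to 5-min resolution plus AR(1) noise.
* Weather: diurnal + day-to-day ambient temperature, absolute humidity
  coupled to temperature, ordinal cloud cover 0-5, and a precipitation
  flag concentrated in the cloudiest hours.

All randomness flows from a single integer seed; identical seed and
configuration give bitwise-identical tables.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .accel import AccBurst

__all__ = [
    "MixtureTruth",
    "ModeTruth",
    "CrwTruth",
    "WeatherEffects",
    "SynthConfig",
    "SynthStudy",
    "simulate_bursts",
    "simulate_track",
    "simulate_weather",
    "simulate_study",
]


@dataclass(frozen=True)
class MixtureTruth:
    """True mixture on the transformed ODBA scale (x = ODBA^(-1/3)).

    Component a is active (lower transformed mean = higher ODBA).
    Defaults put the active component around 0.037 g and the inactive
    component around 0.003 g, comfortably inside the ranges field
    studies report for box turtles, with roughly a third of bursts
    active.
    """

    mu_a: float = 3.0
    sigma_a: float = 0.5
    mu_b: float = 7.0
    sigma_b: float = 0.8
    weight: float = 0.3  # mixing proportion of the active component


@dataclass(frozen=True)
class ModeTruth:
    """One movement mode of the fine-scale correlated random walk."""

    step_median_m: float
    step_sdlog: float
    turn_center_deg: float  # centre of |turning angle|
    turn_sd_deg: float


@dataclass(frozen=True)
class CrwTruth:
    extensive: ModeTruth = field(
        default_factory=lambda: ModeTruth(0.7, 0.6, 150.0, 30.0)
    )
    intensive: ModeTruth = field(
        default_factory=lambda: ModeTruth(4.0, 0.5, 15.0, 20.0)
    )
    p_ext_to_int: float = 0.1
    p_int_to_ext: float = 0.1
    start_mode: str = "intensive"


@dataclass(frozen=True)
class WeatherEffects:
    """Coefficients of the weather covariates on the two responses.

    ``distance``: effects on natural-log hourly displacement (m).
    ``activity``: effects on the log-odds of a burst being in the
    active state.  Because the mean hourly ODBA is (mean active ODBA -
    mean inactive ODBA) times the active fraction plus a constant, an
    activity-probability effect induces the corresponding effect on
    mean ODBA while leaving the two mixture components themselves
    untouched — matching the field observation that mean-ODBA
    differences arise mainly from a changed likelihood of activity.
    Keys: temp (degC), humidity (g/m3), cloud (ordinal 0-5),
    precip (0/1), hour (hour of day, 7-19).
    """

    distance: dict = field(
        default_factory=lambda: {
            "temp": 0.0,
            "humidity": 0.0,
            "cloud": 0.0,
            "precip": -0.27,
            "hour": -0.02,
        }
    )
    activity: dict = field(
        default_factory=lambda: {
            "temp": 0.02,
            "humidity": 0.04,
            "cloud": 0.08,
            "precip": 0.0,
            "hour": -0.08,
        }
    )

    @classmethod
    def null(cls) -> "WeatherEffects":
        zero = {"temp": 0.0, "humidity": 0.0, "cloud": 0.0, "precip": 0.0, "hour": 0.0}
        return cls(distance=dict(zero), activity=dict(zero))


@dataclass(frozen=True)
class SynthConfig:
    n_individuals: int = 12
    days: int = 14
    burst_interval_min: float = 10.0
    burst_duration_s: float = 30.0
    acc_rate_hz: float = 10.0
    gps_interval_min: float = 60.0
    fine_interval_min: float = 5.0
    day_start: int = 7
    day_end: int = 19
    start_date: str = "2015-06-01"
    mixture: MixtureTruth = field(default_factory=MixtureTruth)
    crw: CrwTruth = field(default_factory=CrwTruth)
    weather: WeatherEffects = field(default_factory=WeatherEffects)
    # ln(17) - (0.7^2 + 0.3^2)/2 + 0.02*12.5: log-normal variance terms
    # and the mean of the default time-of-day effect are recentred so the
    # day-averaged arithmetic dry-hour displacement is ~17 m
    log_distance_intercept: float = 2.79
    indiv_sd_distance: float = 0.3
    resid_sd_distance: float = 0.7
    indiv_sd_odba: float = 0.1
    body_temp_ar1: float = 0.9
    body_temp_noise_sd: float = 0.3
    anchor_lon: float = -84.7
    anchor_lat: float = 39.5
    seed: int = 0

    def validate(self) -> None:
        if min(
            self.burst_interval_min,
            self.burst_duration_s,
            self.acc_rate_hz,
            self.gps_interval_min,
            self.fine_interval_min,
        ) <= 0:
            raise ValueError("all rates and intervals must be strictly positive")
        if self.n_individuals < 1 or self.days < 1:
            raise ValueError("need at least one individual and one day")
        if not 0 <= self.day_start < self.day_end <= 24:
            raise ValueError("day window must satisfy 0 <= start < end <= 24")
        m = self.mixture
        if not (0.0 < m.weight < 1.0):
            raise ValueError("mixing weight must lie strictly in (0, 1)")
        if m.sigma_a <= 0 or m.sigma_b <= 0:
            raise ValueError("mixture SDs must be positive")
        if m.mu_a == m.mu_b and m.sigma_a == m.sigma_b:
            raise ValueError("degenerate mixture: identical components")
        # the transform x -> x^-3 needs strictly positive transformed values
        for mu, sd, name in ((m.mu_a, m.sigma_a, "a"), (m.mu_b, m.sigma_b, "b")):
            if mu - 5.0 * sd <= 0:
                raise ValueError(
                    f"component {name}: transformed support reaches non-positive "
                    "values (mu - 5*sigma <= 0); the ODBA transform is undefined "
                    "there (the residual <3e-7 tail is redrawn at sampling time)"
                )
        for p in (self.crw.p_ext_to_int, self.crw.p_int_to_ext):
            if not 0.0 <= p <= 1.0:
                raise ValueError("mode-switch probabilities must lie in [0, 1]")


def _burst_times(cfg: SynthConfig, rng=None) -> pd.DatetimeIndex:
    start = pd.Timestamp(cfg.start_date)
    times = []
    for d in range(cfg.days):
        day = start + pd.Timedelta(days=d)
        t = day + pd.Timedelta(hours=cfg.day_start)
        end = day + pd.Timedelta(hours=cfg.day_end)
        while t < end:
            times.append(t)
            t += pd.Timedelta(minutes=cfg.burst_interval_min)
    return pd.DatetimeIndex(times)


def _build_burst(individual, ts, odba_target, n_samples, rate, rng) -> AccBurst:
    """Tri-axial signal realising ``odba_target`` exactly under the
    full-burst-window ODBA operator: constant gravity per axis plus a
    zero-mean alternating (+d, -d) dynamic component whose per-axis
    amplitudes sum to the target."""
    gravity = np.array([0.05, -0.03, 0.98]) + rng.normal(0.0, 0.02, 3)
    share = rng.dirichlet(np.ones(3))
    n_even = n_samples - (n_samples % 2)
    samples = np.tile(gravity, (n_samples, 1))
    if n_even > 0:
        sign = np.zeros(n_samples)
        sign[:n_even] = np.where(np.arange(n_even) % 2 == 0, 1.0, -1.0)
        # with any trailing zero sample the mean |dyn| shrinks by n_even/n
        amp = share * odba_target * (n_samples / n_even)
        samples = samples + sign[:, None] * amp[None, :]
    return AccBurst(individual=individual, timestamp=ts, samples=samples, rate=rate)


def simulate_bursts(
    cfg: SynthConfig,
    individual: str = "T01",
    n_bursts: int | None = None,
    rng: np.random.Generator | None = None,
    p_active=None,
):
    """Generate bursts for one individual.

    ``p_active`` optionally overrides the mixture weight with a
    per-burst active-state probability (scalar or array matched to the
    burst schedule) — this is how weather effects on activity enter.
    Returns (bursts, labels) where labels is a DataFrame with the
    hidden state and the exact target ODBA per burst.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    m = cfg.mixture
    times = _burst_times(cfg)
    if n_bursts is not None:
        reps = int(np.ceil(n_bursts / len(times)))
        times = pd.DatetimeIndex(
            np.concatenate(
                [times + pd.Timedelta(days=cfg.days * r) for r in range(reps)]
            )
        )[:n_bursts]
    n = len(times)
    p = np.broadcast_to(
        np.asarray(m.weight if p_active is None else p_active, dtype=float), (n,)
    )
    active = rng.random(n) < p
    x = np.where(
        active,
        rng.normal(m.mu_a, m.sigma_a, n),
        rng.normal(m.mu_b, m.sigma_b, n),
    )
    # resample the (astronomically rare, config guards 6 sigma) non-positives
    while np.any(x <= 0):
        bad = x <= 0
        x[bad] = np.where(
            active[bad],
            rng.normal(m.mu_a, m.sigma_a, bad.sum()),
            rng.normal(m.mu_b, m.sigma_b, bad.sum()),
        )
    odba = x**-3.0
    n_samples = int(round(cfg.burst_duration_s * cfg.acc_rate_hz))
    bursts = [
        _build_burst(individual, ts, o, n_samples, cfg.acc_rate_hz, rng)
        for ts, o in zip(times, odba)
    ]
    labels = pd.DataFrame(
        {
            "individual": individual,
            "timestamp": times,
            "state": np.where(active, "active", "inactive"),
            "odba_true": odba,
            "transformed_true": x,
        }
    )
    return bursts, labels


def _wrap180(a):
    return -((-a + 180.0) % 360.0 - 180.0)


def simulate_track(
    cfg: SynthConfig,
    individual: str = "T01",
    rng: np.random.Generator | None = None,
):
    """Two-mode correlated random walk for one individual.

    Returns (fine, hourly): the continuous path sampled every
    ``fine_interval_min`` during the day window with the true mode of
    the step INTO each point attached, and the same path subsampled at
    ``gps_interval_min``.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    modes = {"extensive": cfg.crw.extensive, "intensive": cfg.crw.intensive}
    switch = {
        "extensive": ("intensive", cfg.crw.p_ext_to_int),
        "intensive": ("extensive", cfg.crw.p_int_to_ext),
    }

    start = pd.Timestamp(cfg.start_date)
    times = []
    for d in range(cfg.days):
        day = start + pd.Timedelta(days=d)
        t = day + pd.Timedelta(hours=cfg.day_start)
        end = day + pd.Timedelta(hours=cfg.day_end)
        while t <= end:
            times.append(t)
            t += pd.Timedelta(minutes=cfg.fine_interval_min)
    times = pd.DatetimeIndex(times)

    n_steps = len(times) - 1
    mode = cfg.crw.start_mode
    heading = rng.uniform(0.0, 360.0)
    xy = np.zeros((len(times), 2))
    step_modes = ["start"]
    for i in range(n_steps):
        other, p = switch[mode]
        if rng.random() < p:
            mode = other
        mt = modes[mode]
        turn = _wrap180(
            rng.choice([-1.0, 1.0]) * (mt.turn_center_deg + rng.normal(0.0, mt.turn_sd_deg))
        )
        heading = (heading + turn) % 360.0
        length = np.exp(np.log(mt.step_median_m) + rng.normal(0.0, mt.step_sdlog))
        rad = np.radians(heading)
        xy[i + 1] = xy[i] + [length * np.sin(rad), length * np.cos(rad)]
        step_modes.append(mode)

    fine = pd.DataFrame(
        {
            "individual": individual,
            "timestamp": times,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "true_mode": step_modes,  # mode of the step INTO this point
        }
    )
    mins = (
        times - times.normalize()
    ).total_seconds() / 60.0 - cfg.day_start * 60.0
    keep = np.isclose(np.mod(mins, cfg.gps_interval_min), 0.0)
    hourly = fine.loc[keep].reset_index(drop=True)
    return fine, hourly


def simulate_weather(cfg: SynthConfig, rng: np.random.Generator | None = None):
    """Hourly weather-station records over the study period."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    start = pd.Timestamp(cfg.start_date)
    rows = []
    base = 20.0
    cloud_latent = 0.0
    for d in range(cfg.days):
        base = 20.0 + 0.8 * (base - 20.0) + rng.normal(0.0, 1.5)
        day = (start + pd.Timedelta(days=d)).date()
        for h in range(24):
            temp = base + 5.0 * np.sin(np.pi * (h - 9.0) / 12.0) + rng.normal(0.0, 0.5)
            humidity = max(1.0, 10.0 + 0.4 * (temp - 20.0) + rng.normal(0.0, 1.5))
            cloud_latent = 0.7 * cloud_latent + rng.normal(0.0, 1.0)
            cloud = int(np.clip(np.floor(2.5 + 1.4 * cloud_latent), 0, 5))
            precip = bool(cloud == 5 and rng.random() < 0.75)
            rows.append((day, h, temp, humidity, cloud, int(precip)))
    return pd.DataFrame(
        rows,
        columns=["date", "hour", "ambient_temp_c", "abs_humidity_gm3",
                 "cloud_cover", "precipitation"],
    )


def simulate_tpc_records(
    n: int = 5000,
    *,
    curve: str = "gaussian",
    t_opt: float = 21.0,
    width: float = 5.0,
    amplitude: float = 0.04,
    baseline: float = 0.005,
    noise_sd: float = 0.008,
    t_range: tuple[float, float] = (11.0, 36.0),
    seed: int = 0,
) -> pd.DataFrame:
    """ODBA-record table whose expected ODBA given body temperature follows
    a known thermal performance curve ("gaussian" peaked at ``t_opt``,
    or "flat" = temperature-independent activity, the thermoconformer
    generalist case).  For validating the TPC fitting stage.
    """
    rng = np.random.default_rng(seed)
    temps = rng.uniform(t_range[0], t_range[1], n)
    if curve == "gaussian":
        mean = baseline + amplitude * np.exp(-((temps - t_opt) ** 2) / (2 * width**2))
    elif curve == "flat":
        mean = np.full(n, baseline + amplitude)
    else:
        raise ValueError(f"unknown curve {curve!r}")
    odba = np.clip(mean + rng.normal(0.0, noise_sd, n), 1e-4, None)
    ts = pd.Timestamp("2015-06-01 07:00") + pd.to_timedelta(
        rng.integers(0, 12 * 60, n), unit="min"
    )
    return pd.DataFrame(
        {
            "individual": "T01",
            "timestamp": ts,
            "odba": odba,
            "body_temp": temps,
            "hour": pd.DatetimeIndex(ts).hour,
        }
    )


@dataclass(frozen=True)
class SynthStudy:
    config: SynthConfig
    bursts: list  # of AccBurst
    burst_labels: pd.DataFrame
    gps: pd.DataFrame  # individual, timestamp, x, y (m, planar)
    fine_paths: pd.DataFrame  # thread-trailing analogue with true_mode
    body_temps: pd.DataFrame  # individual, timestamp, body_temp_c
    weather: pd.DataFrame
    truth: dict


def simulate_study(cfg: SynthConfig) -> SynthStudy:
    """Compose a full synthetic study for ``cfg.n_individuals`` animals.

    Hourly GPS displacement is drawn from the log-linear weather model
    ln L = intercept + X*beta_distance + b_i + eps; burst ODBA is
    multiplied by exp(X*beta_odba + c_i), so zero configured effects
    leave the pure mixture/CRW untouched.
    """
    cfg.validate()
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(cfg.n_individuals + 1)
    rng_w = np.random.default_rng(streams[0])
    weather = simulate_weather(cfg, rng_w)
    wkey = weather.set_index(["date", "hour"])

    eff_d, eff_a = cfg.weather.distance, cfg.weather.activity
    all_bursts: list[AccBurst] = []
    labels_parts, gps_parts, fine_parts, temp_parts = [], [], [], []
    b_dist, b_act = {}, {}

    for i in range(cfg.n_individuals):
        ind = f"T{i + 1:02d}"
        rng = np.random.default_rng(streams[i + 1])
        b_dist[ind] = rng.normal(0.0, cfg.indiv_sd_distance)
        b_act[ind] = rng.normal(0.0, cfg.indiv_sd_odba)

        # --- bursts: weather shifts the log-odds of the active state
        times = _burst_times(cfg)
        base_logit = np.log(cfg.mixture.weight / (1.0 - cfg.mixture.weight))
        eta = np.empty(len(times))
        for j, ts in enumerate(times):
            row = wkey.loc[(ts.date(), ts.hour)]
            eta[j] = (
                eff_a["temp"] * row["ambient_temp_c"]
                + eff_a["humidity"] * row["abs_humidity_gm3"]
                + eff_a["cloud"] * row["cloud_cover"]
                + eff_a["precip"] * row["precipitation"]
                + eff_a["hour"] * ts.hour
            )
        if np.any(eta != 0.0):
            eta = eta - eta.mean()  # keep the average activity level
        p = 1.0 / (1.0 + np.exp(-(base_logit + eta + b_act[ind])))
        bursts, labels = simulate_bursts(cfg, individual=ind, rng=rng, p_active=p)
        all_bursts.extend(bursts)
        labels_parts.append(labels)

        # --- fine (thread-trailing analogue) path
        fine, _ = simulate_track(cfg, individual=ind, rng=rng)
        fine_parts.append(fine)

        # --- hourly GPS track from the log-linear displacement model
        start = pd.Timestamp(cfg.start_date)
        rows = []
        x = y = 0.0
        heading = rng.uniform(0.0, 360.0)
        for d in range(cfg.days):
            day = start + pd.Timedelta(days=d)
            for h in range(cfg.day_start, cfg.day_end + 1):
                ts = day + pd.Timedelta(hours=h)
                rows.append((ind, ts, x, y))
                if h == cfg.day_end:
                    break
                row = wkey.loc[(day.date(), h)]
                eta = (
                    eff_d["temp"] * row["ambient_temp_c"]
                    + eff_d["humidity"] * row["abs_humidity_gm3"]
                    + eff_d["cloud"] * row["cloud_cover"]
                    + eff_d["precip"] * row["precipitation"]
                    + eff_d["hour"] * h
                )
                length = np.exp(
                    cfg.log_distance_intercept
                    + eta
                    + b_dist[ind]
                    + rng.normal(0.0, cfg.resid_sd_distance)
                )
                heading = (heading + rng.normal(0.0, 60.0)) % 360.0
                rad = np.radians(heading)
                x += length * np.sin(rad)
                y += length * np.cos(rad)
        gps_parts.append(pd.DataFrame(rows, columns=["individual", "timestamp", "x", "y"]))

        # --- body temperature: thermoconformer, ambient + AR(1) noise
        amb = weather.copy()
        amb["timestamp"] = pd.to_datetime(amb["date"].astype(str)) + pd.to_timedelta(
            amb["hour"], unit="h"
        )
        amb = amb.set_index("timestamp")["ambient_temp_c"]
        t5 = pd.date_range(
            amb.index[0], amb.index[-1], freq=f"{5}min"
        )
        ambient_5 = np.interp(
            t5.astype(np.int64), amb.index.astype(np.int64), amb.to_numpy()
        )
        noise = np.zeros(len(t5))
        eps = rng.normal(0.0, cfg.body_temp_noise_sd, len(t5))
        for j in range(1, len(t5)):
            noise[j] = cfg.body_temp_ar1 * noise[j - 1] + eps[j]
        temp_parts.append(
            pd.DataFrame(
                {"individual": ind, "timestamp": t5, "body_temp_c": ambient_5 + noise}
            )
        )

    truth = {
        "config": asdict(cfg),
        "individual_intercepts_distance": b_dist,
        "individual_intercepts_activity": b_act,
    }
    return SynthStudy(
        config=cfg,
        bursts=all_bursts,
        burst_labels=pd.concat(labels_parts, ignore_index=True),
        gps=pd.concat(gps_parts, ignore_index=True),
        fine_paths=pd.concat(fine_parts, ignore_index=True),
        body_temps=pd.concat(temp_parts, ignore_index=True),
        weather=weather,
        truth=truth,
    )
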