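"""Movement-path reconstruction and extensive/intensive segmentation.

A path is a sequence of projected (x, y) points in metres.  A path of
n points yields n-1 steps (Euclidean lengths) and n-2 turning angles:
the absolute change of heading at each interior point, in [0, 180]
degrees.  Steps are clustered (k-means, k=2, on standardised
log step length and turning angle) into two movement modes; following
the operational convention of the box-turtle study this package
accompanies, the cluster with the LARGER mean turning angle is called
"extensive" (exploratory) and the other "intensive" (foraging) — note
this inverts much of the area-restricted-search literature, where
high-turning movement is the intensive mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans

__all__ = [
    "thread_to_path",
    "compute_steps",
    "classify_modes",
    "subsample",
    "exclude_overnight",
    "mode_odba_compare",
]


def thread_to_path(start, distances, bearings) -> np.ndarray:
    """Dead-reckon a thread-trailing record into planar coordinates.

    Compass convention: 0 deg = north (+y), angles increase clockwise,
    so each segment advances (d*sin(b), d*cos(b)).  Returns an
    (n+1, 2) array of points for n (distance, bearing) records,
    starting at ``start``.
    """
    d = np.asarray(distances, dtype=float)
    b = np.asarray(bearings, dtype=float)
    if np.any(d < 0):
        raise ValueError("segment distances must be non-negative")
    if np.any((b < 0) | (b >= 360)):
        raise ValueError("bearings must lie in [0, 360)")
    rad = np.radians(b)
    dx = d * np.sin(rad)
    dy = d * np.cos(rad)
    pts = np.zeros((d.size + 1, 2))
    pts[0] = np.asarray(start, dtype=float)
    pts[1:, 0] = pts[0, 0] + np.cumsum(dx)
    pts[1:, 1] = pts[0, 1] + np.cumsum(dy)
    return pts


def _wrap_angle(a):
    """Wrap degrees to (-180, 180]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


def compute_steps(points: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Step lengths and absolute turning angles along one path.

    ``points`` is either an (n, 2) array of x/y metres or a DataFrame
    with columns x, y and optionally individual/timestamp columns that
    are carried through (timestamps of the terminal fix of each step).

    Returns one row per step: step_length (m), heading (deg, compass),
    turn_angle (absolute deg in [0, 180]; missing for the first step
    and wherever a zero-length step makes the heading undefined).
    """
    if isinstance(points, pd.DataFrame):
        xy = points[["x", "y"]].to_numpy(dtype=float)
        meta = points
    else:
        xy = np.asarray(points, dtype=float)
        meta = None
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if xy.shape[0] < 2:
        raise ValueError("need at least 2 points to form a step")
    if not np.all(np.isfinite(xy)):
        raise ValueError("coordinates must be finite")

    d = np.diff(xy, axis=0)
    lengths = np.hypot(d[:, 0], d[:, 1])
    heading = np.degrees(np.arctan2(d[:, 0], d[:, 1]))  # compass
    heading = np.where(lengths > 0, heading, np.nan)

    turn = np.full(lengths.shape, np.nan)
    if lengths.size >= 2:
        dh = _wrap_angle(heading[1:] - heading[:-1])
        turn[1:] = np.abs(dh)  # NaN propagates from undefined headings

    out = pd.DataFrame(
        {"step_length": lengths, "heading": heading, "turn_angle": turn}
    )
    if meta is not None:
        for col in meta.columns:
            if col in ("x", "y"):
                continue
            out[col] = meta[col].to_numpy()[1:]  # terminal fix of each step
        if "timestamp" in meta.columns:
            out["t_start"] = meta["timestamp"].to_numpy()[:-1]
    return out


def compute_steps_by_individual(points: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`compute_steps` per individual and concatenate."""
    parts = []
    for _, grp in points.groupby("individual", sort=True):
        if len(grp) < 2:
            continue
        parts.append(compute_steps(grp.reset_index(drop=True)))
    if not parts:
        raise ValueError("no individual has 2 or more points")
    return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class ModeSummary:
    source: str
    total_steps: int
    n_extensive: int
    n_intensive: int
    n_unassigned: int
    mean_angle_extensive: float
    se_angle_extensive: float
    mean_angle_intensive: float
    se_angle_intensive: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [self.source],
                "total_steps": [self.total_steps],
                "n_extensive": [self.n_extensive],
                "n_intensive": [self.n_intensive],
                "n_unassigned": [self.n_unassigned],
                "mean_angle_extensive": [self.mean_angle_extensive],
                "se_angle_extensive": [self.se_angle_extensive],
                "mean_angle_intensive": [self.mean_angle_intensive],
                "se_angle_intensive": [self.se_angle_intensive],
            }
        )


def classify_modes(
    steps: pd.DataFrame,
    seed: int = 0,
    *,
    method: str = "kmeans",
    eps: float = 0.01,
    source: str = "",
):
    """Cluster steps into extensive/intensive movement modes.

    Features are standardised (log(step_length + eps), turn_angle);
    k-means with k=2 and 10 seeded restarts by default (``method=
    "hierarchical"`` switches to Ward agglomeration).  Steps without a
    defined turning angle stay "unassigned".  Whatever the cluster
    indices, the cluster with the larger mean turning angle is labelled
    extensive.
    """
    ok = steps["turn_angle"].notna().to_numpy()
    if ok.sum() < 2:
        raise ValueError("need at least 2 steps with a defined turning angle")
    feats = np.column_stack(
        [
            np.log(steps.loc[ok, "step_length"].to_numpy() + eps),
            steps.loc[ok, "turn_angle"].to_numpy(),
        ]
    )
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd

    if method == "kmeans":
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        lab = km.fit_predict(z)
    elif method == "hierarchical":
        lab = AgglomerativeClustering(n_clusters=2, linkage="ward").fit_predict(z)
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    angles = steps.loc[ok, "turn_angle"].to_numpy()
    mean0 = angles[lab == 0].mean() if np.any(lab == 0) else -np.inf
    mean1 = angles[lab == 1].mean() if np.any(lab == 1) else -np.inf
    ext_cluster = 0 if mean0 >= mean1 else 1

    mode = np.full(len(steps), "unassigned", dtype=object)
    mode[np.flatnonzero(ok)] = np.where(
        lab == ext_cluster, "extensive", "intensive"
    )
    out = steps.copy()
    out["mode"] = mode

    def _stats(name):
        a = out.loc[out["mode"] == name, "turn_angle"].to_numpy()
        if a.size == 0:
            return 0, np.nan, np.nan
        se = a.std(ddof=1) / np.sqrt(a.size) if a.size > 1 else 0.0
        return a.size, float(a.mean()), float(se)

    ne, me, see = _stats("extensive")
    ni, mi, sei = _stats("intensive")
    summary = ModeSummary(
        source=source,
        total_steps=len(out),
        n_extensive=ne,
        n_intensive=ni,
        n_unassigned=int((out["mode"] == "unassigned").sum()),
        mean_angle_extensive=me,
        se_angle_extensive=see,
        mean_angle_intensive=mi,
        se_angle_intensive=sei,
    )
    return out, summary


def subsample(points: pd.DataFrame, interval: pd.Timedelta | int) -> pd.DataFrame:
    """Thin a fine path to a coarser sampling interval, keeping endpoints.

    ``interval`` is a Timedelta (requires a ``timestamp`` column;
    points at whole multiples of the interval from the first fix are
    retained) or an integer decimation factor (every k-th point).
    """
    if isinstance(interval, (int, np.integer)):
        if interval <= 0:
            raise ValueError("interval must be positive")
        idx = np.arange(0, len(points), int(interval))
    else:
        if interval <= pd.Timedelta(0):
            raise ValueError("interval must be positive")
        t = pd.to_datetime(points["timestamp"])
        elapsed = (t - t.iloc[0]).to_numpy()
        step = interval.to_numpy()
        idx = np.flatnonzero(elapsed % step == np.timedelta64(0))
    idx = np.union1d(idx, [len(points) - 1])
    return points.iloc[idx].reset_index(drop=True)


def exclude_overnight(steps: pd.DataFrame, day_window=(7, 19)) -> pd.DataFrame:
    """Drop steps whose start and terminal fixes fall on different dates
    (the overnight interval between the last evening fix and the first
    morning fix), since animals may move before recording resumes."""
    if "t_start" not in steps.columns or "timestamp" not in steps.columns:
        return steps
    t0 = pd.to_datetime(steps["t_start"])
    t1 = pd.to_datetime(steps["timestamp"])
    keep = t0.dt.date == t1.dt.date
    return steps.loc[keep].reset_index(drop=True)


def mode_odba_compare(steps: pd.DataFrame, hourly_odba: pd.DataFrame) -> dict:
    """Compare mean ODBA between movement modes with a Student's t-test.

    Each step is paired with the mean ODBA of the hour ending at its
    terminal fix (join on individual x date x hour).  Returns per-mode
    means, the t statistic, degrees of freedom and p-value.
    """
    df = steps.loc[steps["mode"].isin(["extensive", "intensive"])].copy()
    ts = pd.to_datetime(df["timestamp"])
    df["date"] = ts.dt.date
    df["hour"] = ts.dt.hour
    joined = df.merge(
        hourly_odba[["individual", "date", "hour", "mean_odba"]],
        on=["individual", "date", "hour"],
        how="inner",
    )
    ext = joined.loc[joined["mode"] == "extensive", "mean_odba"].to_numpy()
    inten = joined.loc[joined["mode"] == "intensive", "mean_odba"].to_numpy()
    if ext.size < 2 or inten.size < 2:
        raise ValueError("each mode needs at least 2 joined observations")
    if np.var(ext) == 0 and np.var(inten) == 0 and ext.mean() == inten.mean():
        t, p = 0.0, 1.0  # degenerate: no variance, no difference
    else:
        t, p = stats.ttest_ind(ext, inten, equal_var=True)
    return {
        "mean_extensive": float(ext.mean()),
        "mean_intensive": float(inten.mean()),
        "n_extensive": int(ext.size),
        "n_intensive": int(inten.size),
        "t": float(t),
        "df": int(ext.size + inten.size - 2),
        "p": float(p),
    }
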