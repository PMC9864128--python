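"""Quality filtering, movement metrics and discretization of biologging streams.

The raw inputs are a GPS fix table (7-min nominal schedule, projected metric
coordinates, satellite counts) and an accelerometer table (activity counts in
[0, 300] per 5-min window: the number of one-second epochs with any
above-zero acceleration).  The filtering cascade is:

1. drop GPS fixes with low satellite coverage (<= 4 satellites);
2. drop activity counts recorded as zero (the animal was in its burrow);
3. segment tracks into bursts of consecutive fixes at 7 +/- 1 min intervals,
   compute step length / speed / turning angle, and drop biologically
   implausible steps (> 800 m per step);
4. pair each movement observation with the nearest accelerometer record
   within 60 s (each record used at most once).

Finally the three streams are discretized into the fixed bins the mixture
model consumes: 6 equal-width activity bins on (0, 300], 6 equal-width speed
bins on (0, 1] m/s plus an overflow 7th bin above 1 m/s, and 10 equal-width
turning-angle bins on (-pi, pi].  All intervals are right-closed; the
minimum possible value falls in bin 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GPS_COLUMNS = ["individual_id", "timestamp", "x", "y", "n_satellites"]
ACTIVITY_COLUMNS = ["individual_id", "timestamp", "activity_count"]

#: movement-observation columns written by :func:`preprocess`
OBS_COLUMNS = [
    "individual_id",
    "timestamp",
    "x",
    "y",
    "step_length",
    "dt",
    "speed",
    "turning_angle",
    "burst_id",
    "activity_count",
    "activity_bin",
    "speed_bin",
    "turn_bin",
]


@dataclass(frozen=True)
class BinningScheme:
    """Fixed, data-independent bin edges for the three data streams.

    Edges are anchored on the natural ranges of each metric (activity
    counts 0-300, speed 0-1 m/s with an overflow bin, angle -pi..pi) so
    that binned results are comparable across datasets.
    """

    n_activity_bins: int = 6
    activity_max: float = 300.0
    n_speed_bins: int = 6  # regular bins on (0, speed_max]; +1 overflow bin
    speed_max: float = 1.0
    n_turn_bins: int = 10

    @property
    def activity_edges(self) -> np.ndarray:
        return np.arange(1, self.n_activity_bins + 1) * (
            self.activity_max / self.n_activity_bins
        )

    @property
    def speed_edges(self) -> np.ndarray:
        return np.arange(1, self.n_speed_bins + 1) * (self.speed_max / self.n_speed_bins)

    @property
    def turn_edges(self) -> np.ndarray:
        return -np.pi + np.arange(1, self.n_turn_bins + 1) * (2 * np.pi / self.n_turn_bins)

    @property
    def n_bins(self) -> dict[str, int]:
        return {
            "activity": self.n_activity_bins,
            "speed": self.n_speed_bins + 1,
            "turn": self.n_turn_bins,
        }


def _check_sorted(df: pd.DataFrame, what: str) -> None:
    """Reject input not sorted by (individual, time), naming the first
    out-of-order row."""
    for ind, grp in df.groupby("individual_id", sort=False):
        ts = pd.DatetimeIndex(grp["timestamp"]).asi8
        bad = np.nonzero(ts[1:] < ts[:-1])[0]
        if bad.size:
            row = grp.index[bad[0] + 1]
            raise ValueError(
                f"{what} not time-sorted for individual {ind!r}: row {row} "
                f"precedes its predecessor"
            )


def filter_gps(fixes: pd.DataFrame, min_satellites: int = 5) -> pd.DataFrame:
    """Remove fixes with low satellite coverage (fewer than ``min_satellites``).

    Input must be sorted by (individual, time); order is preserved.
    """
    if fixes.empty:
        return fixes.copy()
    _check_sorted(fixes, "GPS fixes")
    kept = fixes[fixes["n_satellites"] >= min_satellites].copy()
    logger.info("satellite filter: %d -> %d fixes", len(fixes), len(kept))
    return kept


def filter_activity(records: pd.DataFrame, max_count: int = 300) -> pd.DataFrame:
    """Remove zero activity counts; reject out-of-range counts.

    Counts outside [0, ``max_count``] are physically impossible (the count
    is a number of seconds within the recording window) and are dropped
    with a data-quality warning.
    """
    if records.empty:
        return records.copy()
    counts = records["activity_count"]
    bad = (counts < 0) | (counts > max_count)
    if bad.any():
        logger.warning(
            "dropping %d activity records with counts outside [0, %d]",
            int(bad.sum()),
            max_count,
        )
    kept = records[~bad & (counts >= 1)].copy()
    logger.info("activity filter: %d -> %d records", len(records), len(kept))
    return kept


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi], counter-clockwise positive."""
    m = np.mod(a, 2 * np.pi)
    return np.where(m > np.pi, m - 2 * np.pi, m)


def segment_and_metrics(
    fixes: pd.DataFrame,
    max_step: float = 800.0,
    interval: tuple[float, float] = (360.0, 480.0),
) -> pd.DataFrame:
    """Segment filtered fixes into bursts and compute movement metrics.

    A *step* joins two consecutive fixes of the same individual.  Steps
    whose duration falls outside ``interval`` (seconds; default 7 +/- 1
    min) or whose length exceeds ``max_step`` meters are discarded and
    break the burst: no metric ever spans a break.  Each retained step
    yields one movement observation stamped at the step's end fix, with
    ``speed = step_length / dt`` and the turning angle relative to the
    previous step of the same burst (missing for the first step of a
    burst, and for steps adjacent to a zero-length step whose heading is
    undefined).
    """
    if fixes.empty:
        return pd.DataFrame(
            columns=[
                "individual_id", "timestamp", "x", "y", "step_length",
                "dt", "speed", "turning_angle", "burst_id",
            ]
        )
    _check_sorted(fixes, "GPS fixes")
    xy = fixes[["x", "y"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        raise ValueError("non-finite coordinates in GPS fixes")

    lo, hi = interval
    frames = []
    burst_counter = 0
    for ind, grp in fixes.groupby("individual_id", sort=False):
        t = pd.DatetimeIndex(grp["timestamp"]).asi8
        if np.any(t[1:] == t[:-1]):
            raise ValueError(f"duplicate timestamps for individual {ind!r}")
        x = grp["x"].to_numpy(dtype=float)
        y = grp["y"].to_numpy(dtype=float)
        dt = (t[1:] - t[:-1]) / 1e9
        dx = np.diff(x)
        dy = np.diff(y)
        step = np.hypot(dx, dy)
        ok = (dt >= lo) & (dt <= hi) & (step <= max_step)
        if not ok.any():
            continue
        heading = np.arctan2(dy, dx)
        heading[step == 0] = np.nan  # undefined heading for zero-length steps

        # burst ids: a new burst starts wherever the previous step is absent
        new_burst = np.empty(ok.size, dtype=bool)
        new_burst[0] = ok[0]
        new_burst[1:] = ok[1:] & ~ok[:-1]
        burst_id = burst_counter + np.cumsum(new_burst) - 1
        burst_counter = int(burst_id.max()) + 1 if ok.any() else burst_counter

        turn = np.full(ok.size, np.nan)
        both = ok[1:] & ok[:-1]
        turn[1:][both] = _wrap_angle(heading[1:][both] - heading[:-1][both])

        frames.append(
            pd.DataFrame(
                {
                    "individual_id": ind,
                    "timestamp": pd.DatetimeIndex(grp["timestamp"])[1:][ok],
                    "x": x[1:][ok],
                    "y": y[1:][ok],
                    "step_length": step[ok],
                    "dt": dt[ok],
                    "speed": step[ok] / dt[ok],
                    "turning_angle": turn[ok],
                    "burst_id": burst_id[ok],
                }
            )
        )
    if not frames:
        return segment_and_metrics(fixes.iloc[0:0])
    out = pd.concat(frames, ignore_index=True)
    logger.info(
        "interval/step filter: %d fixes -> %d movement observations",
        len(fixes),
        len(out),
    )
    return out


def match_streams(
    moves: pd.DataFrame,
    acts: pd.DataFrame,
    window: float = 60.0,
) -> pd.DataFrame:
    """Pair movement observations with accelerometer records.

    Greedy nearest-first matching per individual: candidate (observation,
    record) pairs within ``window`` seconds are taken in order of
    increasing |dt|, each observation and each record used at most once.
    Unmatched observations are dropped.
    """
    if moves.empty or acts.empty:
        return moves.iloc[0:0].assign(activity_count=pd.Series(dtype=int))
    _check_sorted(moves, "movement observations")
    _check_sorted(acts, "activity records")

    matched = []
    for ind, grp in moves.groupby("individual_id", sort=False):
        a = acts[acts["individual_id"] == ind]
        if a.empty:
            continue
        at = pd.DatetimeIndex(a["timestamp"]).asi8
        mt = pd.DatetimeIndex(grp["timestamp"]).asi8
        win_ns = int(window * 1e9)

        # candidate pairs: for each observation, activity records within the window
        lo = np.searchsorted(at, mt - win_ns, side="left")
        hi = np.searchsorted(at, mt + win_ns, side="right")
        pair_m, pair_a, pair_d = [], [], []
        for i, (l, h) in enumerate(zip(lo, hi)):
            for j in range(l, h):
                pair_m.append(i)
                pair_a.append(j)
                pair_d.append(abs(mt[i] - at[j]))
        if not pair_m:
            continue
        order = np.lexsort((np.asarray(pair_m), np.asarray(pair_d)))
        used_m = np.zeros(len(mt), dtype=bool)
        used_a = np.zeros(len(at), dtype=bool)
        take_m, take_a = [], []
        for k in order:
            i, j = pair_m[k], pair_a[k]
            if used_m[i] or used_a[j]:
                continue
            used_m[i] = used_a[j] = True
            take_m.append(i)
            take_a.append(j)
        sel = grp.iloc[sorted(take_m)].copy()
        counts = a["activity_count"].to_numpy()
        sel["activity_count"] = counts[[x for _, x in sorted(zip(take_m, take_a))]]
        matched.append(sel)
    if not matched:
        return moves.iloc[0:0].assign(activity_count=pd.Series(dtype=int))
    out = pd.concat(matched).reset_index(drop=True)
    logger.info("stream matching: %d -> %d observations", len(moves), len(out))
    return out


def discretize(
    obs: pd.DataFrame,
    scheme: BinningScheme | None = None,
) -> pd.DataFrame:
    """Attach ``activity_bin``, ``speed_bin`` and ``turn_bin`` columns.

    All intervals are right-closed, left-open; the left edge of bin 1 is
    closed so the minimum possible value of each metric falls in bin 1.
    Speeds above the top regular edge go to the overflow bin (bin 7 under
    the default scheme).  Turning-angle bins are missing wherever the
    angle itself is missing (first step of a burst).
    """
    scheme = scheme or BinningScheme()
    counts = obs["activity_count"].to_numpy()
    if np.any(counts < 1):
        raise ValueError("activity_count < 1 present; zero counts must be filtered first")
    out = obs.copy()
    out["activity_bin"] = (
        np.searchsorted(scheme.activity_edges, counts, side="left") + 1
    ).astype(np.int64)
    if out["activity_bin"].max() > scheme.n_activity_bins:
        raise ValueError("activity_count above the binning range")

    speed = obs["speed"].to_numpy(dtype=float)
    if np.any(speed < 0):
        raise ValueError("negative speed")
    out["speed_bin"] = (
        np.searchsorted(scheme.speed_edges, speed, side="left") + 1
    ).astype(np.int64)  # values > speed_max land in the overflow bin

    turn = obs["turning_angle"].to_numpy(dtype=float)
    tb = np.searchsorted(scheme.turn_edges, turn, side="left") + 1.0
    tb[~np.isfinite(turn)] = np.nan
    if np.nanmax(tb, initial=1) > scheme.n_turn_bins:
        raise ValueError("turning angle outside (-pi, pi]")
    out["turn_bin"] = tb
    return out


def preprocess(
    gps: pd.DataFrame,
    acts: pd.DataFrame,
    min_satellites: int = 5,
    max_step: float = 800.0,
    interval: tuple[float, float] = (360.0, 480.0),
    match_window: float = 60.0,
    scheme: BinningScheme | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full filtering cascade and discretization.

    Returns the processed observation table plus a per-stage report of row
    counts (input = retained + removed at each stage).
    """
    report: dict[str, int] = {"gps_in": len(gps), "activity_in": len(acts)}
    g = filter_gps(gps, min_satellites=min_satellites)
    report["gps_satellite_kept"] = len(g)
    a = filter_activity(acts)
    report["activity_nonzero_kept"] = len(a)
    moves = segment_and_metrics(g, max_step=max_step, interval=interval)
    report["movement_observations"] = len(moves)
    matched = match_streams(moves, a, window=match_window)
    report["matched_observations"] = len(matched)
    binned = discretize(matched, scheme=scheme)
    report["final_observations"] = len(binned)
    return binned, report


# -- table I/O ------------------------------------------------------------


def read_gps_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = set(GPS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"GPS table missing columns {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df[GPS_COLUMNS]


def read_activity_csv(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = set(ACTIVITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"activity table missing columns {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df[ACTIVITY_COLUMNS]


def write_observations(obs: pd.DataFrame, path) -> None:
    out = obs.copy()
    out["timestamp"] = pd.DatetimeIndex(
        pd.to_datetime(out["timestamp"], utc=True)
    ).astype(str)  # full (nanosecond) precision ISO strings
    out.to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
    return df
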