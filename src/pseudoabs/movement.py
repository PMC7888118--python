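"""Telemetry tracks, study domains, and empirical movement statistics.

A :class:`Track` is one animal's time-ordered sequence of fixes. Tracks are
regularized to a fixed sampling interval by linear interpolation in time, and
the regularized tracks yield the paired empirical (step length, turn angle)
distribution that parameterizes buffer-radius selection and correlated
random-walk simulation.

Sign convention: turn angles are counterclockwise positive and wrapped to
(-pi, pi], so a 90-degree right turn is -pi/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .geodesy import haversine_km, initial_bearing, turn_angle

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["animal_id", "timestamp", "lon", "lat"]


@dataclass
class Track:
    """One animal's time-ordered telemetry fixes (the presence data).

    Parameters
    ----------
    animal_id : str
        Tag / individual identifier.
    fixes : pandas.DataFrame
        Columns ``timestamp`` (UTC datetimes, strictly increasing within a
        segment), ``lon``, ``lat`` in decimal degrees, and optionally
        ``segment`` (int) marking contiguous regularized segments separated
        by data gaps. Without a ``segment`` column the whole track is one
        segment.
    """

    animal_id: str
    fixes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.fixes.reset_index(drop=True).copy()
        if "segment" not in df.columns:
            df["segment"] = 0
        missing = [c for c in ("timestamp", "lon", "lat") if c not in df.columns]
        if missing:
            raise ValueError(f"track {self.animal_id!r}: missing columns {missing}")
        if len(df) < 2:
            raise ValueError(f"track {self.animal_id!r}: needs >= 2 fixes, has {len(df)}")
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
        if not ((df["lon"] >= -180).all() and (df["lon"] <= 180).all()):
            raise ValueError(f"track {self.animal_id!r}: lon outside [-180, 180]")
        if not ((df["lat"] >= -90).all() and (df["lat"] <= 90).all()):
            raise ValueError(f"track {self.animal_id!r}: lat outside [-90, 90]")
        for _, seg in df.groupby("segment"):
            if not seg["timestamp"].is_monotonic_increasing or seg["timestamp"].duplicated().any():
                raise ValueError(
                    f"track {self.animal_id!r}: timestamps not strictly increasing"
                )
        self.fixes = df

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def lon(self) -> np.ndarray:
        return self.fixes["lon"].to_numpy()

    @property
    def lat(self) -> np.ndarray:
        return self.fixes["lat"].to_numpy()

    @property
    def timestamps(self) -> pd.Series:
        return self.fixes["timestamp"]

    def segments(self) -> Iterable["Track"]:
        """Yield each contiguous segment as its own Track (segments of < 2 fixes are dropped)."""
        for _, seg in self.fixes.groupby("segment"):
            if len(seg) >= 2:
                yield Track(self.animal_id, seg.reset_index(drop=True))


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    """Concatenate tracks into one tidy frame (animal_id, timestamp, lon, lat)."""
    rows = []
    for t in tracks:
        df = t.fixes[["timestamp", "lon", "lat"]].copy()
        df.insert(0, "animal_id", t.animal_id)
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def tracks_to_csv(tracks: Sequence[Track], path) -> None:
    df = tracks_to_frame(tracks)
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df.to_csv(path, index=False)


def tracks_from_csv(path) -> list[Track]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    return [
        Track(str(aid), g[["timestamp", "lon", "lat"]].reset_index(drop=True))
        for aid, g in df.groupby("animal_id", sort=True)
    ]


# ---------------------------------------------------------------------------
# Domains


class Domain:
    """A study domain with a point-containment predicate and area-uniform sampling."""

    def contains(self, lon, lat):  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, n: int):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class BoxDomain(Domain):
    """Longitude/latitude bounding box, e.g. 32-45 N x -140 to -115 E.

    Area-uniform sampling draws longitude uniformly and latitude with density
    proportional to cos(lat) (uniform in sin(lat)).
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float

    def __post_init__(self) -> None:
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("box bounds must satisfy lon_min < lon_max and lat_min < lat_max")

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon_min)
            & (lon <= self.lon_max)
            & (lat >= self.lat_min)
            & (lat <= self.lat_max)
        )

    def sample(self, rng: np.random.Generator, n: int):
        lon = rng.uniform(self.lon_min, self.lon_max, n)
        s = rng.uniform(np.sin(np.radians(self.lat_min)), np.sin(np.radians(self.lat_max)), n)
        lat = np.degrees(np.arcsin(s))
        return lon, lat


@dataclass(frozen=True)
class PolygonDomain(Domain):
    """Polygon (or multipolygon) domain, e.g. a fenced park boundary.

    Sampling is by area-uniform rejection from the bounding box; the retry cap
    guards against degenerate slivers.
    """

    polygon: Polygon
    max_rejection_rounds: int = 1000

    def __post_init__(self) -> None:
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise ValueError("polygon domain must have positive area")

    @property
    def _box(self) -> BoxDomain:
        lon_min, lat_min, lon_max, lat_max = self.polygon.bounds
        return BoxDomain(lon_min, lon_max, lat_min, lat_max)

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        pts = shapely.points(lon, lat)
        return shapely.contains(self.polygon, pts) | shapely.touches(self.polygon, pts)

    def sample(self, rng: np.random.Generator, n: int):
        box = self._box
        out_lon = np.empty(0)
        out_lat = np.empty(0)
        for _ in range(self.max_rejection_rounds):
            need = n - len(out_lon)
            if need <= 0:
                break
            lon, lat = box.sample(rng, max(need * 2, 16))
            keep = self.contains(lon, lat)
            out_lon = np.concatenate([out_lon, lon[keep]])
            out_lat = np.concatenate([out_lat, lat[keep]])
        if len(out_lon) < n:
            raise RuntimeError("rejection sampling failed: polygon too small within its bounds")
        return out_lon[:n], out_lat[:n]


# ---------------------------------------------------------------------------
# Regularization


def regularize_track(track: Track, interval: pd.Timedelta, max_gap: pd.Timedelta | None = None) -> Track:
    """Resample a track to fixes at exact multiples of ``interval``.

    Positions are interpolated linearly in time between bracketing observed
    fixes; nothing is extrapolated beyond the first or last observation.
    Observed gaps longer than ``max_gap`` are never interpolated across: the
    output is split into segments (``segment`` column) and the gap interior
    contains no fixes.
    """
    interval = pd.Timedelta(interval)
    if interval <= pd.Timedelta(0):
        raise ValueError("interval must be positive")
    if max_gap is None:
        max_gap = pd.Timedelta.max
    else:
        max_gap = pd.Timedelta(max_gap)

    obs = track.fixes
    t_obs = obs["timestamp"]
    span = t_obs.iloc[-1] - t_obs.iloc[0]
    if span < interval:
        raise ValueError(f"track {track.animal_id!r} spans less than one interval")

    # break observed record into blocks at long gaps
    gaps = t_obs.diff() > max_gap
    block_id = gaps.cumsum()

    out = []
    seg_counter = 0
    t0 = t_obs.iloc[0]
    for _, block in obs.groupby(block_id):
        tb = block["timestamp"]
        if tb.iloc[-1] - tb.iloc[0] < interval:
            continue
        # grid times: multiples of interval from the track's first fix,
        # clipped to this block's observed span
        k_start = int(np.ceil((tb.iloc[0] - t0) / interval))
        k_end = int(np.floor((tb.iloc[-1] - t0) / interval))
        if k_end < k_start + 1:
            continue
        times = pd.DatetimeIndex(t0 + interval * np.arange(k_start, k_end + 1))
        tsec = (tb - t0).dt.total_seconds().to_numpy()
        gsec = (times - t0).total_seconds()
        lon = np.interp(gsec, tsec, block["lon"].to_numpy())
        lat = np.interp(gsec, tsec, block["lat"].to_numpy())
        out.append(
            pd.DataFrame(
                {"timestamp": times, "lon": lon, "lat": lat, "segment": seg_counter}
            )
        )
        seg_counter += 1
    if not out:
        raise ValueError(f"track {track.animal_id!r}: no segment spans one interval")
    return Track(track.animal_id, pd.concat(out, ignore_index=True))


# ---------------------------------------------------------------------------
# Empirical move distributions


@dataclass
class MoveDistribution:
    """Paired empirical (step length, turn angle) samples.

    The pairing is preserved: a draw always returns a (step, turn) pair that
    occurred together in a real displacement, mirroring how correlated
    random walks resample the joint movement distribution.
    """

    step_km: np.ndarray
    turn_rad: np.ndarray
    source: str = "pooled"
    interval: pd.Timedelta | None = None
    animal_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.step_km = np.asarray(self.step_km, dtype=float)
        self.turn_rad = np.asarray(self.turn_rad, dtype=float)
        if self.step_km.shape != self.turn_rad.shape:
            raise ValueError("step and turn sample vectors must have equal length")
        if not np.all(np.isfinite(self.step_km)) or np.any(self.step_km < 0):
            raise ValueError("step lengths must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.step_km)

    def sample(self, rng: np.random.Generator, n: int):
        """Draw n paired (step, turn) samples with replacement."""
        if len(self) == 0:
            raise ValueError("empty move distribution")
        idx = rng.integers(0, len(self), n)
        return self.step_km[idx], self.turn_rad[idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"step_km": self.step_km, "turn_rad": self.turn_rad})
        if self.animal_id is not None:
            df["animal_id"] = self.animal_id
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "MoveDistribution":
        return cls(
            df["step_km"].to_numpy(),
            df["turn_rad"].to_numpy(),
            animal_id=df["animal_id"].to_numpy() if "animal_id" in df else None,
            **kw,
        )


def _segment_moves(lon: np.ndarray, lat: np.ndarray):
    """Paired (step, turn) samples from one regular segment.

    Each interior fix contributes one pair: the outgoing step length and the
    signed bearing change from the incoming to the outgoing displacement.
    The first fix has no incoming bearing and contributes nothing.
    """
    d = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    b = initial_bearing(lon[:-1], lat[:-1], lon[1:], lat[1:])
    steps = d[1:]
    turns = turn_angle(b[:-1], b[1:])
    return steps, np.atleast_1d(turns)


def empirical_moves(
    tracks: Sequence[Track],
    pooling: Literal["pooled", "per-animal"] = "pooled",
) -> MoveDistribution | dict[str, MoveDistribution]:
    """Extract the paired (step length, turn angle) distribution from tracks.

    With ``pooling="pooled"`` all animals contribute to a single
    :class:`MoveDistribution`; with ``"per-animal"`` a dict keyed by animal id
    is returned. Requires segments of >= 3 fixes (a turn angle needs two
    consecutive displacements).
    """
    per: dict[str, list] = {}
    for track in tracks:
        acc = per.setdefault(track.animal_id, [])
        for seg in track.segments():
            if len(seg) < 3:
                continue
            steps, turns = _segment_moves(seg.lon, seg.lat)
            acc.append((steps, turns))

    def build(pairs: list, source: str) -> MoveDistribution:
        if not pairs:
            raise ValueError("no segment has >= 3 fixes; cannot form move distribution")
        steps = np.concatenate([p[0] for p in pairs])
        turns = np.concatenate([p[1] for p in pairs])
        return MoveDistribution(steps, turns, source=source)

    if pooling == "pooled":
        all_pairs = [p for acc in per.values() for p in acc]
        md = build(all_pairs, "pooled")
        md.animal_id = np.concatenate(
            [np.repeat(aid, sum(len(p[0]) for p in acc)) for aid, acc in per.items() if acc]
        ) if any(per.values()) else None
        return md
    if pooling == "per-animal":
        return {aid: build(acc, f"animal:{aid}") for aid, acc in per.items() if acc}
    raise ValueError(f"unknown pooling {pooling!r}; use 'pooled' or 'per-animal'")


def mode_step_length(moves: MoveDistribution, bin_width: float | None = None) -> float:
    """Histogram mode of the step-length distribution, km.

    Bins are equal-width over [0, max step]. Ties between equally populated
    bins break toward the smaller bin. The default bin width is 5% of the
    95th-percentile step, a reproducible stand-in for the mode of a
    continuous sample. The returned value (the modal bin center) is the
    buffer radius used by buffer pseudo-absence sampling.
    """
    if len(moves) == 0:
        raise ValueError("empty move distribution")
    steps = moves.step_km
    if bin_width is None:
        p95 = float(np.percentile(steps, 95))
        bin_width = 0.05 * p95 if p95 > 0 else 1.0
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    hi = float(steps.max())
    if hi == 0:
        return 0.0 + bin_width / 2.0
    edges = np.arange(0.0, hi + bin_width, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(steps, bins=edges)
    best = int(np.argmax(counts))  # argmax takes the first = smallest bin on ties
    return float((edges[best] + edges[best + 1]) / 2.0)
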