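"""The four pseudo-absence generation methods for telemetry-based SDMs.

Each method emits exactly one pseudo-absence per presence (a 1:1 ratio),
inside the study domain, with a timestamp so dynamic (monthly) covariates
can be sampled:

``background``
    Points drawn uniformly by area across the whole domain; incorporates no
    movement information. Each point inherits the timestamp of its
    index-matched presence.
``buffer``
    One point per presence, uniform by area on the geodesic disc of a fixed
    radius around that presence; the radius comes from the mode of the
    empirical step-length distribution. The step-selection-style method.
``crw`` / ``reverse_crw``
    A correlated random walk resampling paired (step length, turn angle)
    draws from the empirical movement distribution: forward from the tagging
    location and first timestamp, or backward in time from the last recorded
    position. Preserves the autocorrelation structure of real tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .geodesy import destination, initial_bearing
from .movement import Domain, MoveDistribution, Track

logger = logging.getLogger(__name__)

METHODS = ("background", "buffer", "crw", "reverse_crw")
RETRY_CAP = 20

PA_COLUMNS = ["animal_id", "timestamp", "lon", "lat", "label", "method", "matched_presence_index"]


@dataclass
class PseudoAbsenceSet:
    """Labeled pseudo-absence records for one generation method."""

    method: str
    records: pd.DataFrame  # PA_COLUMNS
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; valid: {METHODS}")
        df = self.records.reset_index(drop=True).copy()
        df["label"] = 0
        df["method"] = self.method
        if "matched_presence_index" not in df.columns:
            df["matched_presence_index"] = pd.NA
        self.records = df[PA_COLUMNS]

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        df = self.records.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.strftime(
            "%Y-%m-%dT%H:%M:%SZ"
        )
        df.to_csv(path, index=False)


def _as_points_frame(presences) -> pd.DataFrame:
    """Accept a DataFrame or a list of Tracks; return tidy presence points."""
    if isinstance(presences, pd.DataFrame):
        return presences.reset_index(drop=True)
    from .movement import tracks_to_frame

    return tracks_to_frame(list(presences))


# ---------------------------------------------------------------------------


def background_sample(presences, domain: Domain, seed: int) -> PseudoAbsenceSet:
    """Uniform-by-area random sampling across the whole domain.

    Point i inherits the timestamp (and animal id) of presence i, so monthly
    covariates are sampled at the same times as the matched presences.
    """
    pres = _as_points_frame(presences)
    rng = np.random.default_rng(seed)
    lon, lat = domain.sample(rng, len(pres))
    records = pd.DataFrame(
        {
            "animal_id": pres["animal_id"].to_numpy(),
            "timestamp": pres["timestamp"].to_numpy(),
            "lon": lon,
            "lat": lat,
            "matched_presence_index": np.arange(len(pres)),
        }
    )
    return PseudoAbsenceSet("background", records, {"seed": seed})


def _disc_point(rng: np.random.Generator, lon: float, lat: float, radius_km: float):
    """One point uniform by area on the geodesic disc around (lon, lat)."""
    bearing = rng.uniform(0.0, 2.0 * np.pi)
    dist = radius_km * np.sqrt(rng.uniform())
    return destination(lon, lat, bearing, dist)


def buffer_sample(presences, radius_km: float, domain: Domain, seed: int) -> PseudoAbsenceSet:
    """One pseudo-absence uniform on the radius-km disc around each presence.

    Out-of-domain draws are retried; if a presence sits on the domain edge
    with almost no in-domain disc, it is skipped with a warning and the
    replacement drawn around a randomly chosen other presence so the 1:1
    count is preserved.
    """
    if radius_km <= 0:
        raise ValueError("buffer radius must be > 0")
    pres = _as_points_frame(presences)
    rng = np.random.default_rng(seed)
    plon = pres["lon"].to_numpy()
    plat = pres["lat"].to_numpy()

    out_lon = np.empty(len(pres))
    out_lat = np.empty(len(pres))
    matched = np.arange(len(pres))
    for i in range(len(pres)):
        center = i
        placed = False
        for round_ in range(RETRY_CAP):
            for _ in range(RETRY_CAP):
                lo, la = _disc_point(rng, plon[center], plat[center], radius_km)
                if bool(np.asarray(domain.contains(lo, la)).all()):
                    out_lon[i], out_lat[i] = lo, la
                    matched[i] = center
                    placed = True
                    break
            if placed:
                break
            logger.warning(
                "buffer_sample: presence %d has no in-domain disc point after %d draws; "
                "redrawing around a random other presence",
                center,
                RETRY_CAP,
            )
            center = int(rng.integers(0, len(pres)))
        if not placed:
            raise RuntimeError(f"buffer_sample: could not place a point for presence {i}")
    records = pd.DataFrame(
        {
            "animal_id": pres["animal_id"].to_numpy(),
            "timestamp": pres["timestamp"].to_numpy(),
            "lon": out_lon,
            "lat": out_lat,
            "matched_presence_index": matched,
        }
    )
    return PseudoAbsenceSet("buffer", records, {"radius_km": radius_km, "seed": seed})


# ---------------------------------------------------------------------------


def crw_simulate(
    track: Track,
    moves: MoveDistribution,
    domain: Domain,
    seed: int,
    direction: Literal["forward", "reverse"] = "forward",
) -> PseudoAbsenceSet:
    """Correlated-random-walk pseudo-absences paired to one track.

    Forward walks start at the track's first fix and timestamp (the tagging
    location); reverse walks start at the last fix and assign timestamps
    backwards to the tagging date. Each step resamples a paired (step
    length, turn angle) with replacement from ``moves`` and turns the
    current heading by it (counterclockwise positive). The walk emits
    exactly as many points as the track has fixes, starting with the start
    fix itself. Steps leaving the domain are redrawn up to a cap, then the
    heading is reflected (reversed) and the turn redrawn.
    """
    if len(moves) == 0:
        raise ValueError("empty move distribution")
    if direction not in ("forward", "reverse"):
        raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")
    rng = np.random.default_rng(seed)
    lon = track.lon
    lat = track.lat
    times = track.timestamps.reset_index(drop=True)
    n = len(track)

    if direction == "forward":
        start = (lon[0], lat[0])
        heading = float(initial_bearing(lon[0], lat[0], lon[1], lat[1]))
        out_times = times
    else:
        start = (lon[-1], lat[-1])
        heading = float(initial_bearing(lon[-1], lat[-1], lon[-2], lat[-2]))
        out_times = times[::-1].reset_index(drop=True)

    cur_lon, cur_lat = float(start[0]), float(start[1])
    sim_lon = [cur_lon]
    sim_lat = [cur_lat]
    for step in range(1, n):
        placed = False
        for reflect in range(2):
            for _ in range(RETRY_CAP):
                d, th = moves.sample(rng, 1)
                new_head = float(np.mod(heading - th[0], 2.0 * np.pi))
                nlon, nlat = destination(cur_lon, cur_lat, new_head, float(d[0]))
                if bool(np.asarray(domain.contains(nlon, nlat)).all()):
                    cur_lon, cur_lat = float(nlon), float(nlat)
                    heading = new_head
                    placed = True
                    break
            if placed:
                break
            heading = float(np.mod(heading + np.pi, 2.0 * np.pi))  # reflect and retry
        if not placed:
            raise RuntimeError(
                f"crw_simulate ({track.animal_id}, {direction}): no in-domain step at fix {step}"
            )
        sim_lon.append(cur_lon)
        sim_lat.append(cur_lat)

    records = pd.DataFrame(
        {
            "animal_id": track.animal_id,
            "timestamp": out_times.to_numpy(),
            "lon": sim_lon,
            "lat": sim_lat,
            "matched_presence_index": np.arange(n),
        }
    )
    method = "crw" if direction == "forward" else "reverse_crw"
    return PseudoAbsenceSet(method, records, {"seed": seed, "direction": direction})


# ---------------------------------------------------------------------------


def generate(
    method: str,
    tracks: Sequence[Track],
    domain: Domain,
    seed: int,
    radius_km: float | None = None,
    moves: MoveDistribution | None = None,
) -> PseudoAbsenceSet:
    """Dispatch over the four methods; per-animal sets concatenated 1:1.

    buffer requires ``radius_km``; crw / reverse_crw require ``moves``.
    Per-animal sub-seeds are derived deterministically from ``seed``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid methods: {', '.join(METHODS)}")
    tracks = list(tracks)
    if method == "background":
        return background_sample(tracks, domain, seed)
    if method == "buffer":
        if radius_km is None:
            raise ValueError("buffer method requires radius_km")
        return buffer_sample(tracks, radius_km, domain, seed)
    if moves is None:
        raise ValueError(f"{method} requires a move distribution")
    direction = "forward" if method == "crw" else "reverse"
    child_seeds = np.random.SeedSequence(seed).generate_state(len(tracks)) % (2**31)
    parts = [
        crw_simulate(t, moves, domain, int(s), direction=direction).records
        for t, s in zip(tracks, child_seeds)
    ]
    out = PseudoAbsenceSet(method, pd.concat(parts, ignore_index=True), {"seed": seed})
    return out
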