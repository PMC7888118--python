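"""The four pseudo-absence generators: 1:1 counts, containment, distributions."""

import logging

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pseudoabs as pa
from pseudoabs.geodesy import haversine_km

from conftest import straight_track


# ---------------------------------------------------------------------------
# shared contracts


@pytest.mark.parametrize("method", pa.METHODS)
def test_one_to_one_count_and_containment(method, small_study, small_moves):
    """Every method emits exactly one in-domain point per presence."""
    pa_set = pa.generate(
        method, small_study.tracks, small_study.domain, seed=7,
        radius_km=15.0, moves=small_moves,
    )
    n_presences = len(small_study.presences)
    assert len(pa_set) == n_presences
    rec = pa_set.records
    assert (rec["label"] == 0).all()
    assert small_study.domain.contains(rec["lon"].to_numpy(), rec["lat"].to_numpy()).all()


@pytest.mark.parametrize("method", pa.METHODS)
def test_deterministic_under_seed(method, small_study, small_moves):
    kw = dict(radius_km=15.0, moves=small_moves)
    a = pa.generate(method, small_study.tracks, small_study.domain, seed=3, **kw)
    b = pa.generate(method, small_study.tracks, small_study.domain, seed=3, **kw)
    pd.testing.assert_frame_equal(a.records, b.records)


def test_unknown_method_lists_valid_names(small_study):
    with pytest.raises(ValueError, match="background"):
        pa.generate("maxent", small_study.tracks, small_study.domain, seed=0)


# ---------------------------------------------------------------------------
# background


def test_background_latitude_density_follows_cosine():
    """Area-uniform box sampling: latitude counts proportional to cos(lat)."""
    domain = pa.BoxDomain(-140, -115, 32, 60)
    pres = pd.DataFrame(
        {
            "animal_id": "a",
            "timestamp": pd.date_range("2006-01-01", periods=20000, freq="1h", tz="UTC"),
            "lon": -120.0,
            "lat": 40.0,
        }
    )
    out = pa.background_sample(pres, domain, seed=2).records
    lats = out["lat"].to_numpy()
    edges = np.linspace(32, 60, 15)
    counts, _ = np.histogram(lats, bins=edges)
    # expected mass per bin from integrating cos(lat)
    upper = np.radians(edges[1:])
    lower = np.radians(edges[:-1])
    mass = np.sin(upper) - np.sin(lower)
    expected = mass / mass.sum() * counts.sum()
    assert stats.chisquare(counts, expected).pvalue > 0.01


def test_background_inherits_matched_timestamps(small_study):
    pres = small_study.presences
    out = pa.background_sample(pres, small_study.domain, seed=1).records
    assert (out["timestamp"].to_numpy() == pres["timestamp"].to_numpy()).all()
    assert (out["matched_presence_index"].to_numpy() == np.arange(len(pres))).all()


# ---------------------------------------------------------------------------
# buffer


def test_buffer_max_distance_leq_radius(small_study):
    radius = 25.0
    pres = small_study.presences
    out = pa.buffer_sample(pres, radius, small_study.domain, seed=9).records
    d = haversine_km(
        pres["lon"].to_numpy()[out["matched_presence_index"].to_numpy().astype(int)],
        pres["lat"].to_numpy()[out["matched_presence_index"].to_numpy().astype(int)],
        out["lon"].to_numpy(),
        out["lat"].to_numpy(),
    )
    assert (d <= radius + 1e-6).all()


def test_buffer_distances_uniform_in_area():
    """Uniform-by-area disc sampling: median distance = radius / sqrt(2)."""
    radius = 10.0
    domain = pa.BoxDomain(-130, -110, 30, 50)  # presences far from edges
    pres = pd.DataFrame(
        {
            "animal_id": "a",
            "timestamp": pd.Timestamp("2006-06-01", tz="UTC"),
            "lon": np.full(2000, -120.0),
            "lat": np.full(2000, 40.0),
        }
    )
    out = pa.buffer_sample(pres, radius, domain, seed=4).records
    d = haversine_km(-120.0, 40.0, out["lon"].to_numpy(), out["lat"].to_numpy())
    assert np.median(d) == pytest.approx(radius / np.sqrt(2), rel=0.10)


def test_buffer_edge_presence_keeps_one_to_one(caplog):
    """A presence on the domain corner with a tiny in-domain sliver still
    yields a 1:1 set, redrawing around another presence with a warning."""
    domain = pa.BoxDomain(0, 1, 0, 1)
    pres = pd.DataFrame(
        {
            "animal_id": "a",
            "timestamp": pd.Timestamp("2006-01-01", tz="UTC"),
            # first presence far outside-ish corner; others comfortably inside
            "lon": [0.0005, 0.5, 0.5, 0.5],
            "lat": [0.0005, 0.5, 0.5, 0.5],
        }
    )
    with caplog.at_level(logging.WARNING):
        out = pa.buffer_sample(pres, 50.0, domain, seed=6)
    assert len(out) == 4
    assert domain.contains(out.records["lon"].to_numpy(), out.records["lat"].to_numpy()).all()


def test_buffer_rejects_nonpositive_radius(small_study):
    with pytest.raises(ValueError, match="radius"):
        pa.buffer_sample(small_study.presences, 0.0, small_study.domain, seed=0)


# ---------------------------------------------------------------------------
# CRW / reverse CRW


def test_crw_degenerate_moves_straight_line(small_study):
    track = small_study.tracks[0]
    moves = pa.MoveDistribution(np.array([1.0]), np.array([0.0]))
    domain = pa.BoxDomain(-180, 180, -89, 89)
    out = pa.crw_simulate(track, moves, domain, seed=0).records
    assert len(out) == len(track)
    d = haversine_km(
        out["lon"].to_numpy()[:-1], out["lat"].to_numpy()[:-1],
        out["lon"].to_numpy()[1:], out["lat"].to_numpy()[1:],
    )
    np.testing.assert_allclose(d, 1.0, rtol=1e-6)


def test_crw_starts_at_first_fix(small_study, small_moves):
    track = small_study.tracks[0]
    out = pa.crw_simulate(track, small_moves, small_study.domain, seed=1).records
    assert out["lon"].iloc[0] == track.lon[0]
    assert out["lat"].iloc[0] == track.lat[0]
    assert out["timestamp"].iloc[0] == track.timestamps.iloc[0]


def test_reverse_crw_starts_at_last_fix_with_decreasing_timestamps(small_study, small_moves):
    track = small_study.tracks[0]
    out = pa.crw_simulate(
        track, small_moves, small_study.domain, seed=1, direction="reverse"
    ).records
    assert out["lon"].iloc[0] == track.lon[-1]
    assert out["lat"].iloc[0] == track.lat[-1]
    ts = pd.to_datetime(out["timestamp"])
    assert ts.is_monotonic_decreasing
    assert ts.iloc[0] == track.timestamps.iloc[-1]
    assert ts.iloc[-1] == track.timestamps.iloc[0]


def test_crw_preserves_step_length_marginal(small_moves):
    """Resampling with replacement reproduces the marginal step distribution."""
    times = pd.date_range("2006-01-01", periods=1001, freq="1D", tz="UTC")
    track = pa.Track(
        "long",
        pd.DataFrame({"timestamp": times, "lon": np.linspace(-120, -119, 1001), "lat": 40.0}),
    )
    domain = pa.BoxDomain(-170, -60, 0, 80)  # wide: essentially no boundary rejection
    out = pa.crw_simulate(track, small_moves, domain, seed=12).records
    sim_steps = haversine_km(
        out["lon"].to_numpy()[:-1], out["lat"].to_numpy()[:-1],
        out["lon"].to_numpy()[1:], out["lat"].to_numpy()[1:],
    )
    assert stats.ks_2samp(sim_steps, small_moves.step_km).pvalue > 0.01


def test_crw_rejects_empty_moves(small_study):
    md = pa.MoveDistribution(np.array([1.0]), np.array([0.0]))
    md.step_km = np.empty(0)
    md.turn_rad = np.empty(0)
    with pytest.raises(ValueError, match="empty"):
        pa.crw_simulate(small_study.tracks[0], md, small_study.domain, seed=0)


# ---------------------------------------------------------------------------
# spatial / environmental contrast ordering


def test_spatial_contrast_ordering_majority():
    """On a gradient world with presences clustered on one side (clustered tag
    deployments, movement diffusive relative to the domain), background
    sampling separates environments most and buffer least, with CRWs
    intermediate — checked as a majority property over 10 seeds."""
    spec = pa.EnvironmentSpec(
        origin_lon=-125.0, origin_lat=45.0, cell_size=0.1, n_cols=60, n_rows=60,
        layers=(pa.LayerSpec("grad", kind="gradient", direction="east"),), seed=2,
    )
    sel = pa.SelectionParams(
        coefficients={"grad": 4.0},
        moves=pa.ParametricMoves(mean_step_km=3.0, turn_kappa=1.0),
    )
    wins_bg = wins_buffer = 0
    n_seeds = 10
    for seed in range(n_seeds):
        study = pa.generate_study(
            spec, sel, n_animals=3, n_steps=150, seed=200 + seed, clustered_starts=True
        )
        moves = pa.empirical_moves(study.tracks)
        pres = study.presences
        pres_vals = study.env.extract(pres)["grad"]
        sep = {}
        for method in pa.METHODS:
            out = pa.generate(
                method, study.tracks, study.domain, seed=300 + seed,
                radius_km=pa.mode_step_length(moves), moves=moves,
            )
            abs_vals = study.env.extract(out.records)["grad"]
            sep[method] = 1.0 - pa.bhattacharyya(pres_vals, abs_vals)
        crw_mean = (sep["crw"] + sep["reverse_crw"]) / 2
        if sep["background"] >= crw_mean:
            wins_bg += 1
        if sep["buffer"] <= crw_mean:
            wins_buffer += 1
    assert wins_bg > n_seeds / 2
    assert wins_buffer > n_seeds / 2


def test_background_farther_from_presences_than_buffer(small_study, small_moves):
    """Background points sit farther from their matched presences than buffer points."""
    pres = small_study.presences
    radius = pa.mode_step_length(small_moves)
    bg = pa.generate("background", small_study.tracks, small_study.domain, seed=5)
    bf = pa.generate(
        "buffer", small_study.tracks, small_study.domain, seed=5, radius_km=radius
    )

    def mean_dist(out):
        idx = out.records["matched_presence_index"].to_numpy().astype(int)
        return haversine_km(
            pres["lon"].to_numpy()[idx], pres["lat"].to_numpy()[idx],
            out.records["lon"].to_numpy(), out.records["lat"].to_numpy(),
        ).mean()

    assert mean_dist(bg) > mean_dist(bf)
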