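import numpy as np
import pandas as pd
import pytest

import pseudoabs as pa


@pytest.fixture(scope="session")
def small_env_spec():
    """Three-layer 60x60 grid: one east gradient, two smoothed-noise fields."""
    return pa.EnvironmentSpec(
        origin_lon=-125.0,
        origin_lat=45.0,
        cell_size=0.1,
        n_cols=60,
        n_rows=60,
        layers=(
            pa.LayerSpec("grad", kind="gradient", direction="east"),
            pa.LayerSpec("noise1", kind="smoothed-noise", correlation_length=4.0),
            pa.LayerSpec("noise2", kind="smoothed-noise", correlation_length=8.0),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_env_spec):
    """Gradient-biased study: 5 animals x 100 daily steps, beta=3 on the gradient."""
    sel = pa.SelectionParams(
        coefficients={"grad": 3.0}, moves=pa.ParametricMoves(mean_step_km=8.0)
    )
    return pa.generate_study(small_env_spec, sel, n_animals=5, n_steps=100, seed=11)


@pytest.fixture(scope="session")
def small_moves(small_study):
    return pa.empirical_moves(small_study.tracks, pooling="pooled")


@pytest.fixture(scope="session")
def background_table(small_study):
    absences = pa.background_sample(small_study.presences, small_study.domain, seed=5)
    return pa.build_table(small_study.presences, absences.records, small_study.env)


def straight_track(n=5, step_deg=0.5, animal_id="t0"):
    """Fixes marching due north along a meridian at equal spacing."""
    times = pd.date_range("2006-01-01", periods=n, freq="1D", tz="UTC")
    return pa.Track(
        animal_id,
        pd.DataFrame({"timestamp": times, "lon": 0.0, "lat": np.arange(n) * step_deg}),
    )
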