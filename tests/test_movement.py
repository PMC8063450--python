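"""Movement kernel, path simulation, thinning and measurement error."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from movebench.habitat import HabitatParams, HabitatRaster, generate_habitat
from movebench.movement import (
    NEIGHBOUR_ANGLES,
    NEIGHBOUR_DISTS,
    NEIGHBOUR_OFFSETS,
    BoundaryError,
    MovementParams,
    TripConfig,
    draw_trip,
    observe_track,
    simulate_path,
    step_kernel,
    track_from_csv,
    track_to_csv,
)


def flat_raster(size=64, value=0.5):
    return HabitatRaster(
        values=np.full((size, size), value), params=HabitatParams(0.0, 0.0)
    )


@pytest.mark.parametrize(
    "kwargs,field",
    [
        ({"sigma_sd": 2.6}, "sigma_sd"),
        ({"sigma_omega": -0.1}, "sigma_omega"),
        ({"sigma_alpha": 0.2}, "sigma_alpha"),
        ({"sigma_ran": 3.0}, "sigma_ran"),
        ({"error_spat": 3.5}, "error_spat"),
    ],
)
def test_out_of_range_movement_params_rejected(kwargs, field):
    with pytest.raises(ValueError, match=field):
        MovementParams(**kwargs)


def test_distance_penalty_only_kernel_matches_hand_evaluation():
    """With all sigmas zero only the mu*distance term acts: the hand-evaluated
    probabilities are exp(-1.8)/Z for rook and exp(-1.8*sqrt(2))/Z for
    diagonal neighbours."""
    r = flat_raster(value=0.0)
    p = step_kernel((32, 32), None, r, MovementParams(), (40, 32), eps=np.zeros(8))
    expected = np.exp(-1.8 * NEIGHBOUR_DISTS)
    expected /= expected.sum()
    np.testing.assert_allclose(p, expected, atol=1e-12)
    rook = NEIGHBOUR_DISTS == 1.0
    assert p[rook][0] == pytest.approx(0.1696, abs=1e-4)
    assert p[~rook][0] == pytest.approx(0.0805, abs=1e-4)


def test_kernel_symmetry_on_uniform_habitat():
    r = flat_raster(value=0.7)
    p = step_kernel(
        (20, 20), None, r,
        MovementParams(sigma_omega=0.9), (30, 20), eps=np.zeros(8),
    )
    rook = NEIGHBOUR_DISTS == 1.0
    # attraction off (sigma_alpha=0): all rook equal, all diagonal equal
    assert np.ptp(p[rook]) < 1e-12
    assert np.ptp(p[~rook]) < 1e-12
    assert p[rook][0] > p[~rook][0]


def test_single_good_neighbour_attracts_matching_hand_evaluation():
    r = flat_raster(value=0.0)
    r.values[33, 32] = 1.0  # one rook neighbour of (32, 32)
    p = step_kernel(
        (32, 32), None, r, MovementParams(sigma_omega=1.0), (32, 40), eps=np.zeros(8)
    )
    k = int(np.flatnonzero((NEIGHBOUR_OFFSETS == [1, 0]).all(axis=1))[0])
    # exp(1 - 1.8) over exp(1-1.8) + 3 exp(-1.8) + 4 exp(-1.8 sqrt 2)
    z = np.exp(1 - 1.8) + 3 * np.exp(-1.8) + 4 * np.exp(-1.8 * np.sqrt(2))
    assert p[k] == pytest.approx(np.exp(1 - 1.8) / z, abs=1e-12)
    assert p[k] == pytest.approx(0.357, abs=1e-3)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    sd=st.floats(0, 2.5), om=st.floats(0, 1), al=st.floats(0, 0.1),
    ra=st.floats(0, 2.5), ra2=st.floats(0, 1), heading=st.floats(-np.pi, np.pi),
)
def test_kernel_is_a_probability_vector(sd, om, al, ra, ra2, heading):
    r = flat_raster()
    rng = np.random.default_rng(0)
    p = step_kernel(
        (30, 30), heading, r,
        MovementParams(sigma_sd=sd, sigma_omega=om, sigma_alpha=al,
                       sigma_ran=ra, sigma_ran2=ra2),
        (10, 50), rng=rng,
    )
    assert np.all(p >= 0)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_zero_turn_maximizes_persistent_kernel():
    """The persistence penalty is minimized (F maximized) at zero angular
    deviation from the previous heading, so a strongly persistent walker keeps
    going straight."""
    r = flat_raster(128)
    heading = NEIGHBOUR_ANGLES[0]  # east
    p = step_kernel(
        (64, 64), heading, r, MovementParams(sigma_ran=2.5), (64, 64 + 30),
        eps=np.zeros(8),
    )
    assert np.argmax(p) == 0
    # and a simulated path is predominantly straight at the range maximum
    trip = TripConfig(start=(64, 64), centre=(80, 80), n_steps=120, n_obs=10)
    path = simulate_path(r, MovementParams(sigma_ran=2.5), trip, np.random.default_rng(5))
    steps = np.diff(path.positions, axis=0)
    straight = (steps[1:] == steps[:-1]).all(axis=1).mean()
    assert straight > 0.7


def test_attraction_pulls_paths_towards_centre():
    r = flat_raster(300)
    trip = TripConfig(start=(150, 150), centre=(90, 90), n_steps=800, n_obs=50)
    pulled, free = [], []
    for seed in range(20):
        pa = simulate_path(r, MovementParams(sigma_alpha=0.1), trip,
                           np.random.default_rng(seed))
        pf = simulate_path(r, MovementParams(), trip, np.random.default_rng(seed))
        pulled.append(np.hypot(*(pa.positions - [90, 90]).T).mean())
        free.append(np.hypot(*(pf.positions - [90, 90]).T).mean())
    pulled, free = np.array(pulled), np.array(free)
    assert (pulled < free).mean() >= 0.9
    assert pulled.mean() < free.mean()


def test_habitat_selection_concentrates_use_in_good_habitat():
    """Paired against a sigma_omega = 0 control on the same fine-grained,
    high-contrast landscape, selection raises the habitat value at occupied
    pixels."""
    raster = generate_habitat(HabitatParams(0.15, 0.0, "sharp"), 300, seed=2)
    trip = TripConfig(start=(150, 150), centre=(150, 150), n_steps=2000, n_obs=50)
    sel, ctl = [], []
    for seed in range(10):
        ps = simulate_path(raster, MovementParams(sigma_omega=1.0), trip,
                           np.random.default_rng(seed))
        pc = simulate_path(raster, MovementParams(), trip, np.random.default_rng(seed))
        sel.append(raster.values[ps.positions[:, 0], ps.positions[:, 1]].mean())
        ctl.append(raster.values[pc.positions[:, 0], pc.positions[:, 1]].mean())
    assert np.mean(sel) > np.mean(ctl)
    assert np.mean(sel) > raster.values.mean()


def test_path_determinism_and_length():
    r = flat_raster(200)
    trip = TripConfig(start=(100, 100), centre=(80, 120), n_steps=500, n_obs=50)
    mp = MovementParams(sigma_sd=1.5, sigma_ran=1.0)
    a = simulate_path(r, mp, trip, np.random.default_rng(9))
    b = simulate_path(r, mp, trip, np.random.default_rng(9))
    np.testing.assert_array_equal(a.positions, b.positions)
    assert len(a.positions) == trip.n_steps + 1
    steps = np.abs(np.diff(a.positions, axis=0))
    assert steps.max() == 1  # consecutive positions are 8-neighbours


def test_boundary_hit_raises():
    r = flat_raster(64)
    trip = TripConfig(start=(32, 32), centre=(50, 32), n_steps=3000, n_obs=10)
    with pytest.raises(BoundaryError):
        simulate_path(r, MovementParams(sigma_ran=2.5), trip, np.random.default_rng(0))


def test_jitted_walk_matches_python_kernel_stepping():
    """The compiled inner loop reproduces, draw for draw, a pure-Python walk
    that evaluates step_kernel with the same pre-drawn noise."""
    raster = generate_habitat(HabitatParams(0.5, 0.3, "medium"), 200, seed=6)
    mp = MovementParams(sigma_sd=1.2, sigma_omega=0.8, sigma_alpha=0.05,
                        sigma_ran=1.5, sigma_ran2=0.6)
    trip = TripConfig(start=(100, 100), centre=(60, 140), n_steps=80, n_obs=10)
    rng = np.random.default_rng(17)
    path = simulate_path(raster, mp, trip, rng)

    rng2 = np.random.default_rng(17)
    eps = rng2.standard_normal((trip.n_steps, 8)) * mp.sigma_sd
    uni = rng2.random(trip.n_steps)
    pos = np.array(trip.start)
    heading = None
    for t in range(trip.n_steps):
        p = step_kernel(pos, heading, raster, mp, trip.centre, eps=eps[t])
        k = int(np.searchsorted(np.cumsum(p), uni[t]))
        pos = pos + NEIGHBOUR_OFFSETS[k]
        heading = NEIGHBOUR_ANGLES[k]
        np.testing.assert_array_equal(path.positions[t + 1], pos)


def test_observation_thinning_and_error():
    r = flat_raster(300)
    trip = TripConfig(start=(150, 150), centre=(100, 100), n_steps=1000, n_obs=60)
    path = simulate_path(r, MovementParams(sigma_sd=1.0), trip, np.random.default_rng(1))

    exact = observe_track(path, 60, 0.0, np.random.default_rng(0))
    idx = np.rint(np.linspace(0, 1000, 60)).astype(int)
    np.testing.assert_array_equal(
        exact.points[["x", "y"]].to_numpy(), path.positions[idx].astype(float)
    )
    dt = np.diff(exact.points["t_min"].to_numpy())
    assert np.all(dt > 0) and np.ptp(dt) <= 1.0  # equidistant up to index rounding
    # metric bookkeeping: n-1 step lengths, n-2 turning angles
    assert exact.points["d_x"].notna().sum() <= 59
    assert exact.points["ta"].isna().sum() >= 2

    # measurement error: residual SD per coordinate ~ error_spat
    resid = []
    for s in range(400):
        noisy = observe_track(path, 60, 3.0, np.random.default_rng(s))
        resid.append(noisy.points[["x", "y"]].to_numpy() - path.positions[idx])
    sd = np.concatenate(resid).ravel().std()
    assert sd == pytest.approx(3.0, rel=0.05)


def test_draw_trip_respects_ranges_and_null_flag():
    rng = np.random.default_rng(0)
    null_params = [draw_trip(rng, with_effects=False)[0] for _ in range(50)]
    assert all(p.sigma_omega == 0.0 and p.sigma_alpha == 0.0 for p in null_params)
    assert any(p.sigma_sd > 0 for p in null_params)
    eff = [draw_trip(rng, with_effects=True)[0] for _ in range(2000)]
    assert max(p.sigma_alpha for p in eff) <= 0.1
    assert max(p.sigma_sd for p in eff) <= 2.5
    assert all(p.mu == 1.8 for p in eff)
    for _, trip in (draw_trip(rng, True, 1000) for _ in range(20)):
        assert 250 <= trip.start[0] <= 750 and 250 <= trip.start[1] <= 750
        assert 75 <= trip.centre[0] <= 925 and 75 <= trip.centre[1] <= 925


def test_track_csv_roundtrip(tmp_path, sim_track):
    f = tmp_path / "track.csv"
    track_to_csv(sim_track, f, trip_id=3)
    back = track_from_csv(f)
    pd.testing.assert_frame_equal(back.points, sim_track.points)
    assert back.centre == sim_track.centre
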