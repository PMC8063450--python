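"""Stepping-stone movement simulation and device-like tracking data.

An animal moves on the pixel grid of a habitat raster. At each 1-minute step it
chooses one of the 8 neighbouring pixels Y of its current pixel X_t with
probability proportional to

    F(Y) = exp( eps_Y + sigma_omega * hab(Y) - mu * ||Y - X_t||
                - sigma_alpha * a_att(Y) - f * a_pers(Y) ),

where eps_Y ~ N(0, sigma_sd) is drawn independently for every neighbour at
every step, ``a_att`` is the absolute angle (radians, in [0, pi]) between the
candidate step direction and the direction from X_t to a fixed attraction
centre, ``a_pers`` the same against the previous realized step direction, and

    f = sigma_ran / (1 + sigma_ran2 * mean_neighbour_hab)

modulates directional persistence: high local habitat (averaged over the 8
neighbours) weakens persistence, giving more tortuous search in good habitat.
``mu = 1.8`` penalizes the longer diagonal moves. The first step has no
previous heading, so the persistence term is dropped there.

A simulated path of ``n_steps`` pixel moves is thinned to ``n_obs`` tracking
points at equidistant indices, and iid N(0, error_spat) noise is added to each
coordinate, mimicking device measurement error. Derived per-point step metrics
(step length ``d_x``, turning angle ``ta``, distance to the attraction centre
``attrac_dist``, and ``attrac_ang`` — the cosine of the angular deviation of
the realized step from the straight line previous-point -> centre) feed the
downstream model fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .habitat import HabitatRaster

__all__ = [
    "MovementParams",
    "TripConfig",
    "Path",
    "Track",
    "BoundaryError",
    "PARAM_RANGES",
    "step_kernel",
    "simulate_path",
    "observe_track",
    "draw_trip",
    "draw_movement_params",
    "draw_trip_config",
    "compute_step_metrics",
    "track_to_csv",
    "track_from_csv",
]

# 8-neighbour offsets, their headings and Euclidean lengths (fixed geometry).
NEIGHBOUR_OFFSETS = np.array(
    [[1, 0], [1, 1], [0, 1], [-1, 1], [-1, 0], [-1, -1], [0, -1], [1, -1]],
    dtype=np.int64,
)
NEIGHBOUR_ANGLES = np.arctan2(
    NEIGHBOUR_OFFSETS[:, 1].astype(float), NEIGHBOUR_OFFSETS[:, 0].astype(float)
)
NEIGHBOUR_DISTS = np.hypot(*NEIGHBOUR_OFFSETS.astype(float).T)

#: Closed parameter ranges of the movement generator.
PARAM_RANGES = {
    "sigma_sd": (0.0, 2.5),
    "sigma_omega": (0.0, 1.0),
    "sigma_alpha": (0.0, 0.1),
    "sigma_ran": (0.0, 2.5),
    "sigma_ran2": (0.0, 1.0),
    "error_spat": (0.0, 3.0),
}

MU_DEFAULT = 1.8


class BoundaryError(RuntimeError):
    """Raised when a simulated path would leave the raster."""


@dataclass(frozen=True)
class MovementParams:
    """Movement-kernel parameters for one trip.

    ``mu`` is the distance penalty and stays at 1.8 unless explicitly
    overridden; all other parameters live in the closed ranges of
    :data:`PARAM_RANGES`.
    """

    sigma_sd: float = 0.0
    sigma_omega: float = 0.0
    sigma_alpha: float = 0.0
    sigma_ran: float = 0.0
    sigma_ran2: float = 0.0
    error_spat: float = 0.0
    mu: float = MU_DEFAULT

    def __post_init__(self) -> None:
        for name, (lo, hi) in PARAM_RANGES.items():
            v = getattr(self, name)
            if not (np.isfinite(v) and lo <= v <= hi):
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {v!r}")
        if not np.isfinite(self.mu):
            raise ValueError(f"mu must be finite, got {self.mu!r}")


@dataclass(frozen=True)
class TripConfig:
    """Start point, attraction centre and observation settings of one trip."""

    start: tuple[int, int]
    centre: tuple[int, int]
    n_steps: int = 5000
    n_obs: int = 300
    dt_minutes: float = 1.0

    def __post_init__(self) -> None:
        if self.n_obs > self.n_steps + 1:
            raise ValueError("n_obs cannot exceed the number of path positions")
        if self.n_steps < 1 or self.n_obs < 3:
            raise ValueError("need n_steps >= 1 and n_obs >= 3")

    def validate_for(self, size: int) -> None:
        """Check start/centre lie in their central squares of the raster."""
        sx, sy = self.start
        cx, cy = self.centre
        s_lo, s_hi = 0.25 * size, 0.75 * size
        c_lo, c_hi = 0.075 * size, 0.925 * size
        if not (s_lo <= sx <= s_hi and s_lo <= sy <= s_hi):
            raise ValueError(f"start {self.start} outside the central square of a {size} raster")
        if not (c_lo <= cx <= c_hi and c_lo <= cy <= c_hi):
            raise ValueError(f"centre {self.centre} outside its allowed square")


@dataclass
class Path:
    """Raw pixel-scale movement path (one position per minute)."""

    positions: np.ndarray  # (n_steps+1, 2) int pixel coordinates
    times: np.ndarray  # minutes
    centre: tuple[int, int]

    @property
    def n_steps(self) -> int:
        return len(self.positions) - 1


@dataclass
class Track:
    """Observed tracking points with derived step metrics.

    ``points`` has columns t_min, x, y, d_x, ta, attrac_dist, attrac_ang.
    ``d_x``/``attrac_ang`` are NaN on the first point and ``ta`` on the first
    two (undefined), and wherever a zero-length step leaves the angle
    undefined.
    """

    points: pd.DataFrame
    centre: tuple[int, int]

    @property
    def n_obs(self) -> int:
        return len(self.points)


def _abs_angdiff(a, b):
    d = np.mod(a - b + np.pi, 2.0 * np.pi) - np.pi
    return np.abs(d)


def step_kernel(
    current,
    prev_heading,
    raster: HabitatRaster,
    params: MovementParams,
    centre,
    rng: np.random.Generator | None = None,
    eps: np.ndarray | None = None,
) -> np.ndarray:
    """Probabilities of the 8 neighbouring pixels for the next move.

    ``eps`` may inject the 8 Gaussian noise values (already scaled by
    sigma_sd); otherwise they are drawn from ``rng``. The first step of a path
    passes ``prev_heading=None``, dropping the persistence term.
    """
    x, y = int(current[0]), int(current[1])
    n = raster.size
    nx = x + NEIGHBOUR_OFFSETS[:, 0]
    ny = y + NEIGHBOUR_OFFSETS[:, 1]
    if nx.min() < 0 or ny.min() < 0 or nx.max() >= n or ny.max() >= n:
        raise BoundaryError(f"neighbour of pixel ({x}, {y}) lies outside the raster")
    if eps is None:
        if params.sigma_sd > 0.0:
            if rng is None:
                raise ValueError("rng required when sigma_sd > 0 and eps not given")
            eps = rng.normal(0.0, params.sigma_sd, size=8)
        else:
            eps = np.zeros(8)
    hab = raster.values[nx, ny]
    f_pers = params.sigma_ran / (1.0 + params.sigma_ran2 * hab.mean())
    ang_centre = np.arctan2(centre[1] - y, centre[0] - x)
    a_att = _abs_angdiff(NEIGHBOUR_ANGLES, ang_centre)
    logf = (
        eps
        + params.sigma_omega * hab
        - params.mu * NEIGHBOUR_DISTS
        - params.sigma_alpha * a_att
    )
    if prev_heading is not None:
        logf = logf - f_pers * _abs_angdiff(NEIGHBOUR_ANGLES, prev_heading)
    w = np.exp(logf - logf.max())
    return w / w.sum()


@njit(cache=False)
def _walk(values, x0, y0, cx, cy, eps, uni, mu, s_om, s_al, s_ran, s_ran2):  # pragma: no cover
    n_steps = eps.shape[0]
    n = values.shape[0]
    xs = np.empty(n_steps + 1, dtype=np.int64)
    ys = np.empty(n_steps + 1, dtype=np.int64)
    xs[0] = x0
    ys[0] = y0
    offx = np.array([1, 1, 0, -1, -1, -1, 0, 1], dtype=np.int64)
    offy = np.array([0, 1, 1, 1, 0, -1, -1, -1], dtype=np.int64)
    angs = np.empty(8)
    dists = np.empty(8)
    for k in range(8):
        angs[k] = np.arctan2(float(offy[k]), float(offx[k]))
        dists[k] = np.sqrt(float(offx[k] * offx[k] + offy[k] * offy[k]))
    two_pi = 2.0 * np.pi
    prev_head = 0.0
    have_head = False
    w = np.empty(8)
    for t in range(n_steps):
        x = xs[t]
        y = ys[t]
        if x <= 0 or y <= 0 or x >= n - 1 or y >= n - 1:
            return xs, ys, t  # boundary reached before step t
        habsum = 0.0
        for k in range(8):
            habsum += values[x + offx[k], y + offy[k]]
        f_pers = s_ran / (1.0 + s_ran2 * habsum / 8.0)
        ang_c = np.arctan2(float(cy - y), float(cx - x))
        mx = -1e300
        for k in range(8):
            d = angs[k] - ang_c
            d = d - two_pi * np.floor((d + np.pi) / two_pi)
            a_att = abs(d)
            v = (
                eps[t, k]
                + s_om * values[x + offx[k], y + offy[k]]
                - mu * dists[k]
                - s_al * a_att
            )
            if have_head:
                d2 = angs[k] - prev_head
                d2 = d2 - two_pi * np.floor((d2 + np.pi) / two_pi)
                v -= f_pers * abs(d2)
            w[k] = v
            if v > mx:
                mx = v
        tot = 0.0
        for k in range(8):
            w[k] = np.exp(w[k] - mx)
            tot += w[k]
        u = uni[t] * tot
        acc = 0.0
        pick = 7
        for k in range(8):
            acc += w[k]
            if u <= acc:
                pick = k
                break
        xs[t + 1] = x + offx[pick]
        ys[t + 1] = y + offy[pick]
        prev_head = angs[pick]
        have_head = True
    return xs, ys, -1


def simulate_path(
    raster: HabitatRaster,
    params: MovementParams,
    trip: TripConfig,
    rng: np.random.Generator,
) -> Path:
    """Simulate a pixel-scale path of ``trip.n_steps`` kernel draws.

    Deterministic for a fixed generator state. Raises :class:`BoundaryError`
    if the walk reaches the raster border (the generator assumes it never
    does; callers may retry with a fresh seed).
    """
    trip.validate_for(raster.size)
    n = trip.n_steps
    eps = rng.standard_normal((n, 8)) * params.sigma_sd
    uni = rng.random(n)
    xs, ys, status = _walk(
        raster.values,
        int(trip.start[0]),
        int(trip.start[1]),
        int(trip.centre[0]),
        int(trip.centre[1]),
        eps,
        uni,
        params.mu,
        params.sigma_omega,
        params.sigma_alpha,
        params.sigma_ran,
        params.sigma_ran2,
    )
    if status >= 0:
        raise BoundaryError(f"path reached the raster border at step {status}")
    positions = np.stack([xs, ys], axis=1)
    times = np.arange(n + 1, dtype=float) * trip.dt_minutes
    return Path(positions=positions, times=times, centre=tuple(trip.centre))


def compute_step_metrics(x, y, centre) -> pd.DataFrame:
    """Per-point step metrics for an ordered sequence of coordinates.

    Returns columns d_x, ta, attrac_dist, attrac_ang aligned with the input
    points; undefined entries (first point(s), zero-length steps) are NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    dx = np.diff(x)
    dy = np.diff(y)
    d = np.hypot(dx, dy)
    head = np.arctan2(dy, dx)
    head[d == 0.0] = np.nan

    d_x = np.full(n, np.nan)
    d_x[1:] = d
    ta = np.full(n, np.nan)
    if n >= 3:
        ta[2:] = np.mod(head[1:] - head[:-1] + np.pi, 2.0 * np.pi) - np.pi
    attrac_dist = np.hypot(x - centre[0], y - centre[1])
    attrac_ang = np.full(n, np.nan)
    ang_c = np.arctan2(centre[1] - y[:-1], centre[0] - x[:-1])
    attrac_ang[1:] = np.cos(head - ang_c)
    return pd.DataFrame(
        {"d_x": d_x, "ta": ta, "attrac_dist": attrac_dist, "attrac_ang": attrac_ang}
    )


def observe_track(
    path: Path,
    n_obs: int,
    error_spat: float,
    rng: np.random.Generator,
) -> Track:
    """Thin a path to ``n_obs`` equidistant points and add measurement error.

    Indices are ``round(linspace(0, n_steps, n_obs))``; iid N(0, error_spat)
    noise is added to each coordinate of each point, after which the step
    metrics are recomputed on the observed (noisy) points.
    """
    if n_obs > len(path.positions):
        raise ValueError("n_obs exceeds the number of path positions")
    idx = np.rint(np.linspace(0, path.n_steps, n_obs)).astype(int)
    pts = path.positions[idx].astype(float)
    if error_spat > 0.0:
        pts = pts + rng.normal(0.0, error_spat, size=pts.shape)
    df = pd.DataFrame({"t_min": path.times[idx], "x": pts[:, 0], "y": pts[:, 1]})
    metrics = compute_step_metrics(df["x"].to_numpy(), df["y"].to_numpy(), path.centre)
    df = pd.concat([df, metrics], axis=1)
    return Track(points=df, centre=path.centre)


def draw_movement_params(
    rng: np.random.Generator, with_effects: bool
) -> MovementParams:
    """Uniform draw over the stated ranges; null trips zero the two effects."""
    draws = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in PARAM_RANGES.items()}
    if not with_effects:
        draws["sigma_omega"] = 0.0
        draws["sigma_alpha"] = 0.0
    return MovementParams(**draws)


def draw_trip_config(
    rng: np.random.Generator,
    size: int = 1000,
    n_steps: int = 5000,
    n_obs: int = 300,
) -> TripConfig:
    """Random start (central 50% square) and centre (central 85% square)."""
    s_lo, s_hi = int(np.ceil(0.25 * size)), int(np.floor(0.75 * size))
    c_lo, c_hi = int(np.ceil(0.075 * size)), int(np.floor(0.925 * size))
    start = (int(rng.integers(s_lo, s_hi + 1)), int(rng.integers(s_lo, s_hi + 1)))
    centre = (int(rng.integers(c_lo, c_hi + 1)), int(rng.integers(c_lo, c_hi + 1)))
    return TripConfig(start=start, centre=centre, n_steps=n_steps, n_obs=n_obs)


def draw_trip(
    rng: np.random.Generator,
    with_effects: bool,
    raster: HabitatRaster | int = 1000,
    n_steps: int = 5000,
    n_obs: int = 300,
) -> tuple[MovementParams, TripConfig]:
    """Draw movement parameters and a trip layout for one simulated trip."""
    size = raster.size if isinstance(raster, HabitatRaster) else int(raster)
    params = draw_movement_params(rng, with_effects)
    trip = draw_trip_config(rng, size=size, n_steps=n_steps, n_obs=n_obs)
    return params, trip


def track_to_csv(track: Track, path, trip_id: int = 0) -> None:
    df = track.points.copy()
    df.insert(0, "trip_id", trip_id)
    df["centre_x"] = track.centre[0]
    df["centre_y"] = track.centre[1]
    df.to_csv(path, index=False)


def track_from_csv(path) -> Track:
    df = pd.read_csv(path)
    centre = (float(df["centre_x"].iloc[0]), float(df["centre_y"].iloc[0]))
    cols = ["t_min", "x", "y", "d_x", "ta", "attrac_dist", "attrac_ang"]
    return Track(points=df[cols].reset_index(drop=True), centre=centre)
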