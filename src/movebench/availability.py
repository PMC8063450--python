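"""Used/dummy-point design tables for the four model families.

All families share one table schema so that coefficients are comparable
like-for-like: rows carry ``stratum`` (time index; -1 for the unstratified
SLRM scheme), ``point_id``, ``used`` flag, coordinates, a response ``u`` and
quadrature weight ``w`` (u*w = 1 on used rows and u = 0 on dummies for the
point-process scheme; u = used flag, w = 1 elsewhere), and the covariates
``hab``, ``attrac_dist``, ``attrac_ang``, ``log_dx``, ``cos_ta``.

Dummy-point schemes:

* SLRM — uniform dummy points inside the minimum convex polygon (MCP) of the
  track, generated once per trip (the model is unstratified).
* SSM / iSSM — per used step, "available" steps anchored at the previous
  tracking point with lengths from a maximum-likelihood gamma fit and turning
  angles from a von Mises fit to the observed steps.
* ST-PPM — per used point, a regular sqrt(n) x sqrt(n) quadrature grid of side
  ``l`` centred on the previous tracking point, independently randomly
  rotated, with rectangle-rule weights w = l^2/(n+1) shared by the used point.
  The grid extent is chosen per trip by stepping l = 2.5, 5.0, ... until the
  relative likelihood change of a probe fit is <= 1% or changes sign.

Strata are the tracking-point indices at which both the step length and the
turning angle are defined (points 3..n of the track), so all model-selection
candidates of a family see identical data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import shapely
from shapely.geometry import MultiPoint, Polygon

from .habitat import HabitatRaster
from .movement import Track

__all__ = [
    "DesignError",
    "StepDistributions",
    "GridSpec",
    "DESIGN_COLUMNS",
    "grid_points_for",
    "compute_mcp",
    "sample_mcp_dummies",
    "build_slrm_table",
    "fit_step_distributions",
    "sample_available_steps",
    "build_quadrature_grid",
    "select_grid_extent",
]

DESIGN_COLUMNS = [
    "stratum", "point_id", "used", "x", "y", "u", "w",
    "hab", "attrac_dist", "attrac_ang", "log_dx", "cos_ta", "family",
]

#: floor for step lengths before taking logs (zero-length guard)
DX_FLOOR = 1e-6

#: nominal dummy-point levels -> nearest perfect-square quadrature grid counts
GRID_COUNTS = {8: 9, 80: 81, 230: 225}


class DesignError(ValueError):
    """Degenerate geometry or invalid design specification."""


@dataclass(frozen=True)
class StepDistributions:
    """Fitted empirical step distributions of one track."""

    gamma_shape: float
    gamma_scale: float
    vonmises_mu: float
    vonmises_kappa: float

    def __post_init__(self) -> None:
        if not (self.gamma_shape > 0 and self.gamma_scale > 0 and self.vonmises_kappa > 0):
            raise ValueError("shape, scale and concentration must be positive")


@dataclass(frozen=True)
class GridSpec:
    """Quadrature grid specification for the point-process scheme.

    ``rotation=None`` draws an independent Uniform(0, 2*pi) angle per stratum.
    """

    l: float
    n_points: int
    rotation: float | None = None

    def __post_init__(self) -> None:
        if not self.l > 0:
            raise ValueError(f"side length l must be positive, got {self.l!r}")
        m = int(round(np.sqrt(self.n_points)))
        if m * m != self.n_points:
            raise DesignError(
                f"n_points must be a perfect square for a regular grid, got {self.n_points}"
            )


def grid_points_for(n_dummy: int) -> int:
    """Perfect-square grid count realizing a nominal dummy-point level."""
    if n_dummy in GRID_COUNTS:
        return GRID_COUNTS[n_dummy]
    m = max(int(round(np.sqrt(n_dummy))), 1)
    return m * m


# ---------------------------------------------------------------------------
# SLRM scheme: MCP + uniform dummies


def compute_mcp(track: Track) -> Polygon:
    """Minimum convex polygon (convex hull) of the observed points."""
    pts = track.points[["x", "y"]].to_numpy()
    if len(pts) < 3:
        raise DesignError("need at least 3 points for a convex polygon")
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0.0:
        raise DesignError("tracking points are collinear; convex polygon is degenerate")
    return hull


def sample_mcp_dummies(polygon: Polygon, n_total: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygon by rejection from its bounding box."""
    minx, miny, maxx, maxy = polygon.bounds
    out = np.empty((n_total, 2))
    got = 0
    frac = max(polygon.area / ((maxx - minx) * (maxy - miny)), 1e-3)
    while got < n_total:
        m = int((n_total - got) / frac * 1.2) + 16
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(polygon, xs, ys)
        take = min(int(keep.sum()), n_total - got)
        out[got : got + take, 0] = xs[keep][:take]
        out[got : got + take, 1] = ys[keep][:take]
        got += take
    return out


def _finish_table(df: pd.DataFrame, family: str) -> pd.DataFrame:
    df["family"] = family
    return df[DESIGN_COLUMNS].reset_index(drop=True)


def build_slrm_table(
    track: Track,
    raster: HabitatRaster,
    n_dummy: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Unstratified presence/dummy table: track points vs MCP-uniform dummies.

    ``n_dummy`` is per tracking point, so the table has
    ``n_obs * (1 + n_dummy)`` rows. Angle-dependent covariates are undefined
    for dummy rows of a purely spatial scheme and set to NaN.
    """
    poly = compute_mcp(track)
    pts = track.points
    dummies = sample_mcp_dummies(poly, n_dummy * len(pts), rng)
    used = pd.DataFrame(
        {
            "stratum": -1,
            "point_id": np.arange(len(pts)),
            "used": 1,
            "x": pts["x"].to_numpy(),
            "y": pts["y"].to_numpy(),
        }
    )
    dum = pd.DataFrame(
        {
            "stratum": -1,
            "point_id": np.arange(len(dummies)) + len(pts),
            "used": 0,
            "x": dummies[:, 0],
            "y": dummies[:, 1],
        }
    )
    df = pd.concat([used, dum], ignore_index=True)
    df["u"] = df["used"].astype(float)
    df["w"] = 1.0
    df["hab"] = raster.hab_at(df["x"].to_numpy(), df["y"].to_numpy())
    df["attrac_dist"] = np.hypot(df["x"] - track.centre[0], df["y"] - track.centre[1])
    df["attrac_ang"] = np.nan
    df["log_dx"] = np.nan
    df["cos_ta"] = np.nan
    return _finish_table(df, "SLRM")


# ---------------------------------------------------------------------------
# SSM/iSSM scheme: distribution-matched available steps


def fit_step_distributions(track: Track) -> StepDistributions:
    """ML gamma fit to observed step lengths, von Mises fit to turning angles."""
    d = track.points["d_x"].to_numpy()
    ta = track.points["ta"].to_numpy()
    d = d[np.isfinite(d) & (d > 0)]
    ta = ta[np.isfinite(ta)]
    if len(d) < 20 or len(ta) < 20:
        raise DesignError("need at least 20 defined steps to fit step distributions")
    if np.ptp(d) < 1e-12:
        raise DesignError("step lengths are all equal; gamma fit is degenerate")
    shape, _, scale = scipy.stats.gamma.fit(d, floc=0.0)
    kappa, mu, _ = scipy.stats.vonmises.fit(ta, fscale=1.0)
    kappa = max(float(kappa), 1e-8)
    return StepDistributions(
        gamma_shape=float(shape),
        gamma_scale=float(scale),
        vonmises_mu=float(mu),
        vonmises_kappa=kappa,
    )


def _stratum_frame(track: Track):
    """Indices i (0-based tracking points) usable as strata: metrics defined.

    A stratum at point i needs a defined current step (d_x[i] > 0), a defined
    turning angle (finite ta[i]) and a defined previous heading (d_x[i-1] > 0).
    """
    pts = track.points
    d = pts["d_x"].to_numpy()
    ta = pts["ta"].to_numpy()
    idx = np.arange(len(pts))
    prev_d = np.r_[np.nan, d[:-1]]
    ok = (
        (idx >= 2)
        & np.isfinite(d)
        & (d > 0)
        & np.isfinite(ta)
        & np.isfinite(prev_d)
        & (prev_d > 0)
    )
    return idx[ok]


def _step_covariates(ax, ay, px, py, centre, raster, prev_head):
    """Covariates of candidate endpoints (px, py) anchored at (ax, ay)."""
    dx = px - ax
    dy = py - ay
    d = np.hypot(dx, dy)
    head = np.arctan2(dy, dx)
    ang_c = np.arctan2(centre[1] - ay, centre[0] - ax)
    return {
        "hab": raster.hab_at(px, py),
        "attrac_dist": np.hypot(px - centre[0], py - centre[1]),
        "attrac_ang": np.cos(head - ang_c),
        "log_dx": np.log(np.maximum(d, DX_FLOOR)),
        "cos_ta": np.cos(head - prev_head),
    }


def sample_available_steps(
    track: Track,
    dists: StepDistributions,
    n_dummy: int,
    rng: np.random.Generator,
    raster: HabitatRaster,
) -> pd.DataFrame:
    """Stratified used/available-step table for (i)SSM fitting.

    One stratum per tracking point with defined step length and turning angle;
    each stratum holds the used step plus ``n_dummy`` available steps anchored
    at the previous tracking point, with gamma lengths and von Mises turning
    angles relative to the previous observed heading.
    """
    pts = track.points
    x = pts["x"].to_numpy()
    y = pts["y"].to_numpy()
    strata = _stratum_frame(track)
    if len(strata) == 0:
        raise DesignError("no usable strata in track")
    ax, ay = x[strata - 1], y[strata - 1]
    prev_head = np.arctan2(y[strata - 1] - y[strata - 2], x[strata - 1] - x[strata - 2])

    S = len(strata)
    lengths = rng.gamma(dists.gamma_shape, dists.gamma_scale, size=(S, n_dummy))
    turns = scipy.stats.vonmises.rvs(
        dists.vonmises_kappa, loc=dists.vonmises_mu, size=(S, n_dummy), random_state=rng
    )
    heads = prev_head[:, None] + turns
    px = ax[:, None] + lengths * np.cos(heads)
    py = ay[:, None] + lengths * np.sin(heads)

    rows = []
    used_cov = _step_covariates(
        ax, ay, x[strata], y[strata], track.centre, raster, prev_head
    )
    used = pd.DataFrame(
        {"stratum": strata, "point_id": 0, "used": 1, "x": x[strata], "y": y[strata], **used_cov}
    )
    rows.append(used)
    avail_cov = _step_covariates(
        np.repeat(ax, n_dummy),
        np.repeat(ay, n_dummy),
        px.ravel(),
        py.ravel(),
        track.centre,
        raster,
        np.repeat(prev_head, n_dummy),
    )
    avail = pd.DataFrame(
        {
            "stratum": np.repeat(strata, n_dummy),
            "point_id": np.tile(np.arange(1, n_dummy + 1), S),
            "used": 0,
            "x": px.ravel(),
            "y": py.ravel(),
            **avail_cov,
        }
    )
    rows.append(avail)
    df = pd.concat(rows, ignore_index=True).sort_values(["stratum", "point_id"])
    df["u"] = df["used"].astype(float)
    df["w"] = 1.0
    return _finish_table(df, "SSM")


# ---------------------------------------------------------------------------
# ST-PPM scheme: rotated quadrature grids, rectangle-rule weights


def build_quadrature_grid(
    track: Track,
    spec: GridSpec,
    rng: np.random.Generator,
    raster: HabitatRaster,
) -> pd.DataFrame:
    """Per-stratum rotated quadrature grid with rectangle-rule weights.

    Each stratum holds the used tracking point plus ``spec.n_points`` grid
    points (cell centres of an l x l square partition) centred on the previous
    tracking point and rotated by an independent Uniform(0, 2*pi) angle. Every
    row of a stratum carries weight w = l^2/(n+1); used rows have u = 1/w.
    """
    pts = track.points
    x = pts["x"].to_numpy()
    y = pts["y"].to_numpy()
    strata = _stratum_frame(track)
    if len(strata) == 0:
        raise DesignError("no usable strata in track")
    ax, ay = x[strata - 1], y[strata - 1]
    prev_head = np.arctan2(y[strata - 1] - y[strata - 2], x[strata - 1] - x[strata - 2])

    m = int(round(np.sqrt(spec.n_points)))
    g = (np.arange(m) + 0.5) / m * spec.l - spec.l / 2.0
    gx, gy = np.meshgrid(g, g, indexing="ij")
    base = np.stack([gx.ravel(), gy.ravel()], axis=1)  # (n, 2)

    S = len(strata)
    if spec.rotation is None:
        theta = rng.uniform(0.0, 2.0 * np.pi, size=S)
    else:
        theta = np.full(S, float(spec.rotation))
    c, s = np.cos(theta), np.sin(theta)
    # rotate base offsets per stratum: (S, n, 2)
    rx = base[None, :, 0] * c[:, None] - base[None, :, 1] * s[:, None]
    ry = base[None, :, 0] * s[:, None] + base[None, :, 1] * c[:, None]
    px = ax[:, None] + rx
    py = ay[:, None] + ry

    n = spec.n_points
    w = spec.l**2 / (n + 1)
    used_cov = _step_covariates(ax, ay, x[strata], y[strata], track.centre, raster, prev_head)
    used = pd.DataFrame(
        {
            "stratum": strata,
            "point_id": 0,
            "used": 1,
            "x": x[strata],
            "y": y[strata],
            "u": 1.0 / w,
            "w": w,
            **used_cov,
        }
    )
    dum_cov = _step_covariates(
        np.repeat(ax, n),
        np.repeat(ay, n),
        px.ravel(),
        py.ravel(),
        track.centre,
        raster,
        np.repeat(prev_head, n),
    )
    dum = pd.DataFrame(
        {
            "stratum": np.repeat(strata, n),
            "point_id": np.tile(np.arange(1, n + 1), S),
            "used": 0,
            "x": px.ravel(),
            "y": py.ravel(),
            "u": 0.0,
            "w": w,
            **dum_cov,
        }
    )
    df = pd.concat([used, dum], ignore_index=True).sort_values(["stratum", "point_id"])
    return _finish_table(df, "STPPM")


def select_grid_extent(
    track: Track,
    raster: HabitatRaster,
    n_probe: int = 8,
    tol: float = 0.01,
    l_start: float = 2.5,
    l_step: float = 2.5,
    l_max: float = 50.0,
    rng: np.random.Generator | None = None,
    loglik_fn=None,
) -> float:
    """Choose the quadrature-grid extent by likelihood convergence.

    Fits a habitat-only point-process probe model (``n_probe`` dummies per
    point) at l = 2.5, 5.0, 7.5, ... and stops as soon as the relative
    likelihood change from the previous extent is <= ``tol`` or switches
    sign, returning the previous (converged) extent. If the cap ``l_max`` is
    reached without convergence it is returned with a warning.

    The monitored quantity is the habitat model's log-likelihood gain over
    the intercept-only fit at the same extent: the raw quadrature likelihood
    shrinks like -2 log(l) per stratum as the grid dilutes (a pure intercept
    rescaling with no information about convergence), whereas the gain is
    scale-invariant and stabilises once the grid covers the locally available
    area.

    ``loglik_fn(l) -> float`` may replace the probe quantity (used in testing
    and for custom probe models).
    """
    if loglik_fn is None:
        if rng is None:
            rng = np.random.default_rng(0)
        from .inference import fit_weighted_poisson, ppm_loglik  # local: avoid cycle

        n_pts = grid_points_for(n_probe)

        def loglik_fn(l: float) -> float:
            table = build_quadrature_grid(
                track, GridSpec(l=l, n_points=n_pts), rng, raster
            )
            u = table["u"].to_numpy()
            w = table["w"].to_numpy()
            X = np.column_stack([np.ones(len(table)), table["hab"].to_numpy()])
            try:
                _, lam = fit_weighted_poisson(X, u, w)
            except np.linalg.LinAlgError:  # e.g. constant hab in the window
                X = X[:, :1]
                _, lam = fit_weighted_poisson(X, u, w)
            _, lam0 = fit_weighted_poisson(X[:, :1], u, w)
            return ppm_loglik(u, w, lam) - ppm_loglik(u, w, lam0)

    prev_ll = None
    prev_change = None
    prev_l = None
    l = l_start
    while l <= l_max + 1e-9:
        ll = float(loglik_fn(l))
        if prev_ll is not None:
            change = (ll - prev_ll) / max(abs(prev_ll), 1e-8)
            sign_flip = prev_change is not None and np.sign(change) != np.sign(prev_change)
            if abs(change) <= tol or sign_flip:
                return float(prev_l)
            prev_change = change
        prev_ll = ll
        prev_l = l
        l += l_step
    warnings.warn(
        f"grid-extent search did not converge below l={l_max}; returning the cap",
        RuntimeWarning,
        stacklevel=2,
    )
    return float(l_max)
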