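"""Synthetic habitat landscapes with controlled spatial structure.

Landscapes are square rasters of habitat values ``hab`` in [0, 1], generated by
smoothing an iid Uniform(0, 1) field with a moving-window (Gaussian) kernel.
Four knobs control the result:

* ``hab_auto`` in [0, 1] — strength of spatial autocorrelation. 0 means the raw
  iid field is returned untouched; larger values widen the smoothing window.
* ``hab_anis`` in [0, 1] — anisotropy of the autocorrelation. 0 is isotropic;
  1 stretches habitat patches along the x-axis.
* ``hab_smooth`` — sharpness of transitions between habitat patches:
  ``sharp`` (smooth, then histogram-equalize so the full value range is used,
  giving crisp patch boundaries after thresholding), ``medium`` (single
  smoothing pass) or ``blurry`` (two passes).
* ``hab_type`` — ``continuous`` keeps values in [0, 1]; ``categorical``
  thresholds them at 0.5 into {0, 1}.

Rasters are indexed ``values[x, y]`` with pixel coordinates starting at 0 in
the grid corner. Moran's I (rook contiguity, optionally restricted to the x or
y direction) is provided as the autocorrelation diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import rankdata

SMOOTH_LEVELS = ("sharp", "medium", "blurry")
HAB_TYPES = ("continuous", "categorical")

#: Window scale (pixels, y direction) per unit of hab_auto. The maximum patch
#: correlation length (~2 sigma = 12 px) is of the same order as the observed
#: step lengths of a thinned track, so habitat varies detectably — but not
#: trivially — within each step's availability neighbourhood.
AUTO_SCALE = 6.0
#: Multiplier applied to the x-direction window scale per unit of hab_anis.
ANIS_SCALE = 9.0


@dataclass(frozen=True)
class HabitatParams:
    """Generating parameters of a habitat raster."""

    hab_auto: float
    hab_anis: float
    hab_smooth: str = "medium"
    hab_type: str = "continuous"

    def __post_init__(self) -> None:
        for name in ("hab_auto", "hab_anis"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.hab_smooth not in SMOOTH_LEVELS:
            raise ValueError(
                f"hab_smooth must be one of {SMOOTH_LEVELS}, got {self.hab_smooth!r}"
            )
        if self.hab_type not in HAB_TYPES:
            raise ValueError(
                f"hab_type must be one of {HAB_TYPES}, got {self.hab_type!r}"
            )


@dataclass
class HabitatRaster:
    """A square habitat raster plus the parameters that generated it.

    ``values[x, y]`` holds the habitat value at pixel (x, y).
    """

    values: np.ndarray
    params: HabitatParams
    seed: int | None = None

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def hab_at(self, x, y):
        """Habitat value at real-valued coordinates, nearest cell, clamped.

        Points that fall outside the raster (e.g. after measurement error) are
        clamped to the nearest edge cell.
        """
        n = self.size
        ix = np.clip(np.rint(np.asarray(x)).astype(np.int64), 0, n - 1)
        iy = np.clip(np.rint(np.asarray(y)).astype(np.int64), 0, n - 1)
        return self.values[ix, iy]


def smooth_field(
    values: np.ndarray, hab_auto: float, hab_anis: float, hab_smooth: str = "medium"
) -> np.ndarray:
    """Moving-window smoothing of a 2-D field, rescaled to span [0, 1].

    The window is a Gaussian with standard deviation ``AUTO_SCALE * hab_auto``
    pixels along y and ``(1 + ANIS_SCALE * hab_anis)`` times that along x, with
    reflect padding at the edges. ``hab_auto = 0`` is exactly the identity
    window (the input is only min-max rescaled).

    Smoothed fields are rank-equalized back to a Uniform(0, 1) marginal:
    convolution alone concentrates values near the mid-range (the more so the
    wider the window), which would make the habitat contrast seen along a
    track shrink with ``hab_auto`` instead of reflecting the declared U(0, 1)
    habitat values. ``hab_smooth`` then shapes the patch transitions:
    ``sharp`` applies a sigmoid contrast curve pushing values towards 0/1
    (crisp boundaries), ``medium`` keeps the equalized field, ``blurry`` uses
    two convolution passes before equalizing.
    """
    if hab_smooth not in SMOOTH_LEVELS:
        raise ValueError(f"hab_smooth must be one of {SMOOTH_LEVELS}, got {hab_smooth!r}")
    if not 0.0 <= hab_auto <= 1.0:
        raise ValueError(f"hab_auto must lie in [0, 1], got {hab_auto!r}")
    if not 0.0 <= hab_anis <= 1.0:
        raise ValueError(f"hab_anis must lie in [0, 1], got {hab_anis!r}")
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("values must be a non-empty 2-D grid")

    sigma_y = AUTO_SCALE * hab_auto
    sigma_x = sigma_y * (1.0 + ANIS_SCALE * hab_anis)
    out = arr
    if sigma_y > 0.0:
        n_pass = 2 if hab_smooth == "blurry" else 1
        for _ in range(n_pass):
            # axis 0 is x, axis 1 is y: anisotropy stretches along x
            out = gaussian_filter(out, sigma=(sigma_x, sigma_y), mode="reflect")
        # rank transform -> exact Uniform(0, 1) marginal at any window width
        out = (rankdata(out.ravel()) - 1).reshape(out.shape) / max(out.size - 1, 1)
        if hab_smooth == "sharp":
            out = 0.5 + 0.5 * np.tanh(3.0 * (out - 0.5)) / np.tanh(1.5)
    lo, hi = out.min(), out.max()
    if hi > lo:
        out = (out - lo) / (hi - lo)
    else:  # constant field: map to mid-range rather than dividing by zero
        out = np.full_like(out, 0.5)
    return out


def generate_habitat(params: HabitatParams, size: int = 1000, seed: int = 0) -> HabitatRaster:
    """Generate a habitat raster: iid U(0,1) noise, smoothed, optionally binarized.

    Deterministic for fixed ``(params, size, seed)``.
    """
    if size < 32:
        raise ValueError(f"size must be >= 32, got {size}")
    rng = np.random.default_rng(seed)
    base = rng.random((size, size))
    vals = smooth_field(base, params.hab_auto, params.hab_anis, params.hab_smooth)
    if params.hab_type == "categorical":
        vals = (vals >= 0.5).astype(float)
    return HabitatRaster(values=vals, params=params, seed=seed)


def random_params(rng: np.random.Generator) -> HabitatParams:
    """Draw habitat parameters: uniform knobs, hab_type Bernoulli(0.5)."""
    return HabitatParams(
        hab_auto=float(rng.uniform(0.0, 1.0)),
        hab_anis=float(rng.uniform(0.0, 1.0)),
        hab_smooth=str(rng.choice(SMOOTH_LEVELS)),
        hab_type="categorical" if rng.random() < 0.5 else "continuous",
    )


def morans_i(values: np.ndarray, direction: str = "all") -> float:
    """Moran's I with rook contiguity, optionally restricted to one axis.

    ``direction`` is ``all`` (both rook axes), ``x`` (neighbours along axis 0)
    or ``y`` (neighbours along axis 1). Raises on constant rasters, where the
    statistic is undefined.
    """
    z = np.asarray(values, dtype=float)
    if z.ndim != 2 or min(z.shape) < 3:
        raise ValueError("values must be a 2-D grid of at least 3x3")
    if direction not in ("all", "x", "y"):
        raise ValueError(f"direction must be 'all', 'x' or 'y', got {direction!r}")
    z = z - z.mean()
    denom = float((z**2).sum())
    if denom == 0.0:
        raise ValueError("Moran's I is undefined for a constant raster")
    num = 0.0
    w = 0.0
    if direction in ("all", "x"):
        num += 2.0 * float((z[1:, :] * z[:-1, :]).sum())
        w += 2.0 * z[1:, :].size
    if direction in ("all", "y"):
        num += 2.0 * float((z[:, 1:] * z[:, :-1]).sum())
        w += 2.0 * z[:, 1:].size
    n = z.size
    return float(n / w * num / denom)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(values: np.ndarray, path, cellsize: float = 1.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid (.asc).

    Row 1 of the file is the top of the map (largest y); ``values`` is indexed
    ``[x, y]`` with the origin at the grid corner.
    """
    arr = np.asarray(values, dtype=float)
    nx, ny = arr.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write("NODATA_value -9999\n")
        # rows top-down: y = ny-1 .. 0; columns left-right: x = 0 .. nx-1
        np.savetxt(fh, arr.T[::-1, :], fmt="%.17g")


def read_ascii_grid(path) -> np.ndarray:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        header = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            key, _, val = line.partition(" ")
            if key.lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[key.lower()] = float(val)
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)
    return body[::-1, :].T


def save_raster(raster: HabitatRaster, path) -> None:
    """Write a raster as .asc plus a JSON sidecar with its parameters/seed."""
    path = Path(path)
    write_ascii_grid(raster.values, path)
    meta = {"seed": raster.seed, "size": raster.size, "params": asdict(raster.params)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_raster(path) -> HabitatRaster:
    path = Path(path)
    values = read_ascii_grid(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return HabitatRaster(
        values=values, params=HabitatParams(**meta["params"]), seed=meta["seed"]
    )
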