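"""Shared helper: simulate a spatial Poisson point pattern as a design table."""

import numpy as np
import pandas as pd


def simulate_spatial_ppm(rng, beta_hab=1.0, beta0=-3.0, n_cells=40):
    """Poisson point pattern on a grid with log-linear intensity in a smooth
    habitat field; returns a quadrature design table (cells as dummies,
    events as used points, cell area shared by the rectangle rule)."""
    gx, gy = np.meshgrid(*(np.arange(n_cells) + 0.5,) * 2, indexing="ij")
    hab = 0.5 + 0.5 * np.sin(2 * np.pi * gx / n_cells) * np.cos(2 * np.pi * gy / n_cells)
    area = 1.0  # per cell
    lam = np.exp(beta0 + beta_hab * hab) * area
    counts = rng.poisson(lam)
    rows = []
    for (cx, cy, h, c) in zip(gx.ravel(), gy.ravel(), hab.ravel(), counts.ravel()):
        w = area / (c + 1)
        rows.append((0.0, h, w, 0, cx, cy))
        for _ in range(c):
            rows.append((1.0 / w, h, w, 1, cx, cy))
    u, hab_col, w, used, xs, ys = map(np.asarray, zip(*rows))
    return pd.DataFrame(
        {
            "stratum": 0, "point_id": np.arange(len(u)), "used": used.astype(int),
            "x": xs, "y": ys, "u": u, "w": w, "hab": hab_col,
            "attrac_dist": np.hypot(xs, ys), "attrac_ang": np.nan,
            "log_dx": np.nan, "cos_ta": np.nan,
        }
    )
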