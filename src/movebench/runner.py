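"""Study orchestration: landscapes x trips x methods x dummy levels.

The full design simulates ``n_landscapes`` habitats; each landscape draws one
set of movement parameters and carries ``trips_with`` trips whose habitat and
attraction effects are active plus ``trips_without`` null trips (sigma_omega =
sigma_alpha = 0, all other parameters shared). Every trip is fitted by the
requested model families at every dummy-point level and focal measure,
producing one evaluation record per (trip, family, focal, n_dummy).

Reproducibility contract: every random stream is derived from
``(master_seed, landscape_id, trip_id, stage)`` via ``numpy.SeedSequence``
spawn keys, so results are identical regardless of worker count or execution
order. Trips that reach the raster border (the movement generator's error
path) are retried with a deterministically derived attempt sub-seed.

``iid_trip_records`` provides the flat single-trip design used by the
benchmark batches: every trip gets its own landscape and parameter draw.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import availability as av
from . import inference as inf
from .evaluation import aggregate_rates, single_trip_effect
from .habitat import HabitatParams, HabitatRaster, generate_habitat, random_params
from .movement import (
    BoundaryError,
    MovementParams,
    Track,
    TripConfig,
    draw_movement_params,
    draw_trip_config,
    observe_track,
    simulate_path,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "derive_rng",
    "simulate_observed_trip",
    "evaluate_track",
    "run_study",
    "iid_trip_records",
    "timing_probe",
    "preset_desk",
    "preset_fig2a_mini",
]

logger = logging.getLogger("movebench")

_STAGE = {"habitat": 0, "params": 1, "trip": 2, "path": 3, "observe": 4, "design": 5}


def derive_rng(master_seed: int, *keys: int) -> np.random.Generator:
    """Independent generator keyed on (master seed, ids...) — order-stable."""
    ss = np.random.SeedSequence(entropy=int(master_seed),
                                spawn_key=tuple(int(k) for k in keys))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class StudyConfig:
    """Scale and scope of one simulation study."""

    n_landscapes: int = 40
    trips_with: int = 5
    trips_without: int = 5
    n_dummy: tuple[int, ...] = (8, 80)
    families: tuple[str, ...] = ("SLRM", "SLRM_s", "SLRM_w", "SSM", "iSSM", "STPPM")
    focals: tuple[str, ...] = ("hab", "attrac_dist", "attrac_ang")
    size: int = 1000
    n_steps: int = 5000
    n_obs: int = 300
    master_seed: int = 0
    workers: int = 1
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for f in self.families:
            if f not in inf.FAMILIES:
                raise ValueError(f"unknown family {f!r}")
        for f in self.focals:
            if f not in inf.FOCALS:
                raise ValueError(f"unknown focal {f!r}")


@dataclass
class StudyResult:
    records: pd.DataFrame
    rates: pd.DataFrame
    config: StudyConfig


def preset_desk() -> StudyConfig:
    """Desk-scale version of the full design (40 landscapes x 10 trips)."""
    return StudyConfig()


def preset_fig2a_mini() -> StudyConfig:
    """Habitat-selection rate panel at reduced scale: >=100 null and >=100
    effect trips for the two methods with nominal type-I control."""
    return StudyConfig(
        n_landscapes=20,
        trips_with=5,
        trips_without=5,
        n_dummy=(80,),
        families=("iSSM", "STPPM"),
        focals=("hab",),
    )


def simulate_observed_trip(
    raster: HabitatRaster,
    params: MovementParams,
    trip: TripConfig,
    master_seed: int,
    landscape_id: int,
    trip_id: int,
    max_attempts: int = 20,
) -> Track:
    """Simulate a path and its observed track, retrying border hits.

    Each attempt draws from a fresh (seed, attempt) stream, so a retried trip
    is still fully reproducible.
    """
    for attempt in range(max_attempts):
        rng = derive_rng(master_seed, landscape_id, trip_id, _STAGE["path"], attempt)
        try:
            path = simulate_path(raster, params, trip, rng)
        except BoundaryError:
            logger.info(
                "landscape %d trip %d attempt %d hit the border; retrying",
                landscape_id, trip_id, attempt,
            )
            continue
        rng_obs = derive_rng(master_seed, landscape_id, trip_id, _STAGE["observe"], attempt)
        return observe_track(path, trip.n_obs, params.error_spat, rng_obs)
    raise BoundaryError(
        f"trip ({landscape_id}, {trip_id}) hit the raster border in all "
        f"{max_attempts} attempts"
    )


def evaluate_track(
    track: Track,
    raster: HabitatRaster,
    families: tuple[str, ...],
    focals: tuple[str, ...],
    n_dummies: tuple[int, ...],
    rng_design: np.random.Generator,
) -> list[dict]:
    """Fit the requested model families to one track.

    Returns one dict per (family, focal, n_dummy) with the focal inference.
    Availability structures are built once per family class and dummy level
    and shared across focal measures.
    """
    out: list[dict] = []

    def push(fit: inf.FitResult, n_dummy: int, **extra):
        out.append(
            {
                "family": fit.family,
                "focal": fit.focal,
                "n_dummy": n_dummy,
                "estimate": fit.estimate,
                "se": fit.se,
                "p": fit.p,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "converged": fit.converged,
                "selected_formula": fit.selected_formula,
                "effect": single_trip_effect(fit),
                **extra,
            }
        )

    slrm_variants = [f for f in families if f.startswith("SLRM")]
    if slrm_variants:
        for nd in n_dummies:
            table = av.build_slrm_table(track, raster, nd, rng_design)
            for fam in slrm_variants:
                variant = {"SLRM": "plain", "SLRM_s": "smooth", "SLRM_w": "weighted"}[fam]
                for focal in focals:
                    if focal == "attrac_ang":
                        continue
                    push(inf.fit_slrm(table, variant, focal), nd)

    if "SSM" in families or "iSSM" in families:
        dists = av.fit_step_distributions(track)
        for nd in n_dummies:
            table = av.sample_available_steps(track, dists, nd, rng_design, raster)
            for focal in focals:
                if "SSM" in families:
                    push(inf.fit_ssm(table, focal), nd)
                if "iSSM" in families:
                    push(inf.fit_issm(table, focal), nd)

    if "STPPM" in families:
        l_opt = av.select_grid_extent(track, raster, rng=rng_design)
        for nd in n_dummies:
            spec = av.GridSpec(l=l_opt, n_points=av.grid_points_for(nd))
            table = av.build_quadrature_grid(track, spec, rng_design, raster)
            for focal in focals:
                push(inf.fit_stppm(table, focal), nd, l_opt=l_opt)

    return out


def _param_record(hp: HabitatParams, mp: MovementParams) -> dict:
    rec = asdict(hp) | asdict(mp)
    rec.pop("mu", None)
    return rec


def _landscape_job(cfg: StudyConfig, lid: int) -> list[dict]:
    rng_h = derive_rng(cfg.master_seed, lid, 0, _STAGE["habitat"])
    hp = random_params(rng_h)
    raster = generate_habitat(hp, cfg.size, seed=int(rng_h.integers(2**31)))
    rng_p = derive_rng(cfg.master_seed, lid, 0, _STAGE["params"])
    mp_effect = draw_movement_params(rng_p, with_effects=True)
    mp_null = replace(mp_effect, sigma_omega=0.0, sigma_alpha=0.0)

    records: list[dict] = []
    n_trips = cfg.trips_with + cfg.trips_without
    for tid in range(n_trips):
        with_effects = tid < cfg.trips_with
        mp = mp_effect if with_effects else mp_null
        rng_t = derive_rng(cfg.master_seed, lid, tid, _STAGE["trip"])
        trip = draw_trip_config(rng_t, size=cfg.size, n_steps=cfg.n_steps, n_obs=cfg.n_obs)
        try:
            track = simulate_observed_trip(raster, mp, trip, cfg.master_seed, lid, tid)
            rng_d = derive_rng(cfg.master_seed, lid, tid, _STAGE["design"])
            fits = evaluate_track(track, raster, cfg.families, cfg.focals,
                                  cfg.n_dummy, rng_d)
        except Exception as exc:  # failed trip: log and continue the run
            logger.warning("landscape %d trip %d skipped: %s", lid, tid, exc)
            continue
        base = {
            "landscape_id": lid,
            "trip_id": tid,
            "with_effects": with_effects,
            **_param_record(hp, mp),
        }
        records.extend(base | f for f in fits)
    return records


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full habitat -> trips -> designs -> fits -> rates pipeline.

    Deterministic for a fixed master seed, independent of ``workers``.
    """
    t0 = time.perf_counter()
    jobs = (delayed(_landscape_job)(config, lid) for lid in range(config.n_landscapes))
    if config.workers > 1:
        chunks = Parallel(n_jobs=config.workers)(jobs)
    else:
        chunks = [_landscape_job(config, lid) for lid in range(config.n_landscapes)]
    records = pd.DataFrame([r for chunk in chunks for r in chunk])
    rates = aggregate_rates(records, rng=derive_rng(config.master_seed, 2**20)) \
        if len(records) else pd.DataFrame()
    logger.info("study finished in %.1f s (%d records)",
                time.perf_counter() - t0, len(records))
    if config.out_dir is not None:
        from pathlib import Path

        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "records.csv", index=False)
        rates.to_csv(out / "rates.csv", index=False)
    return StudyResult(records=records, rates=rates, config=config)


# ---------------------------------------------------------------------------
# Flat single-trip batches (one landscape per trip)


def _iid_trip_job(
    master_seed: int,
    tid: int,
    with_effects: bool,
    families: tuple[str, ...],
    focals: tuple[str, ...],
    n_dummies: tuple[int, ...],
    hab_type: str | None,
    sigma_ran_range: tuple[float, float] | None,
    size: int,
    n_steps: int,
    n_obs: int,
) -> list[dict]:
    rng_h = derive_rng(master_seed, tid, 0, _STAGE["habitat"])
    hp = random_params(rng_h)
    if hab_type is not None:
        hp = replace(hp, hab_type=hab_type)
    raster = generate_habitat(hp, size, seed=int(rng_h.integers(2**31)))
    rng_p = derive_rng(master_seed, tid, 0, _STAGE["params"])
    mp = draw_movement_params(rng_p, with_effects=with_effects)
    if sigma_ran_range is not None:
        mp = replace(mp, sigma_ran=float(rng_p.uniform(*sigma_ran_range)))
    trip = draw_trip_config(
        derive_rng(master_seed, tid, 0, _STAGE["trip"]),
        size=size, n_steps=n_steps, n_obs=n_obs,
    )
    track = simulate_observed_trip(raster, mp, trip, master_seed, tid, 0)
    rng_d = derive_rng(master_seed, tid, 0, _STAGE["design"])
    fits = evaluate_track(track, raster, families, focals, n_dummies, rng_d)
    base = {
        "landscape_id": tid,
        "trip_id": tid,
        "with_effects": with_effects,
        **_param_record(hp, mp),
    }
    return [base | f for f in fits]


def iid_trip_records(
    n_trips: int,
    master_seed: int,
    with_effects: bool,
    families: tuple[str, ...],
    focals: tuple[str, ...] = ("hab",),
    n_dummies: tuple[int, ...] = (80,),
    hab_type: str | None = None,
    sigma_ran_range: tuple[float, float] | None = None,
    size: int = 1000,
    n_steps: int = 5000,
    n_obs: int = 300,
    workers: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Independent single-trip records: one fresh landscape per trip.

    All habitat and movement parameters are drawn uniformly over their stated
    ranges per trip; ``with_effects=False`` zeroes sigma_omega and sigma_alpha
    (type-I batches), ``hab_type`` restricts the landscape type, and
    ``sigma_ran_range`` narrows the directional-persistence draw.
    """
    args = dict(
        with_effects=with_effects, families=tuple(families), focals=tuple(focals),
        n_dummies=tuple(n_dummies), hab_type=hab_type,
        sigma_ran_range=sigma_ran_range, size=size, n_steps=n_steps, n_obs=n_obs,
    )
    chunks = []
    if workers > 1:
        chunks = Parallel(n_jobs=workers)(
            delayed(_iid_trip_job)(master_seed, tid, **args) for tid in range(n_trips)
        )
    else:
        for tid in range(n_trips):
            chunks.append(_iid_trip_job(master_seed, tid, **args))
            if progress and (tid + 1) % 25 == 0:
                print(f"  .. {tid + 1}/{n_trips} trips", file=sys.stderr, flush=True)
    return pd.DataFrame([r for chunk in chunks for r in chunk])


def timing_probe(
    track_sizes: tuple[int, ...] = (50, 100, 300),
    families: tuple[str, ...] = ("SLRM", "SLRM_w", "SSM", "iSSM", "STPPM"),
    n_dummy: int = 80,
    master_seed: int = 0,
    size: int = 1000,
) -> pd.DataFrame:
    """Wall-clock time of dummy generation + fit per family and track size.

    Informational only; no model selection is applied (each family is fitted
    with its fullest formula).
    """
    rows = []
    for i, n_obs in enumerate(track_sizes):
        n_steps = max(n_obs * 10, n_obs + 1)
        rng_h = derive_rng(master_seed, i, 0, _STAGE["habitat"])
        hp = random_params(rng_h)
        raster = generate_habitat(hp, size, seed=int(rng_h.integers(2**31)))
        mp = draw_movement_params(derive_rng(master_seed, i, 0, _STAGE["params"]), True)
        trip = draw_trip_config(derive_rng(master_seed, i, 0, _STAGE["trip"]),
                                size=size, n_steps=n_steps, n_obs=n_obs)
        track = simulate_observed_trip(raster, mp, trip, master_seed, i, 0)
        rng_d = derive_rng(master_seed, i, 0, _STAGE["design"])
        for fam in families:
            t0 = time.perf_counter()
            evaluate_track(track, raster, (fam,), ("hab",), (n_dummy,), rng_d)
            rows.append({"family": fam, "n_obs": n_obs,
                         "seconds": time.perf_counter() - t0})
    return pd.DataFrame(rows)
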