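"""Model fitting: conditional logit, point-process likelihood, SLRM variants.

The conditional-logit and weighted-Poisson solvers are checked against
independent oracles: grid search over a hand-written likelihood, closed-form
stationarity conditions, statsmodels re-fits, and the weighted-logistic /
Poisson point-process equivalence.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm
from statsmodels.discrete.conditional_models import ConditionalLogit

from movebench.inference import (
    ISSM_CANDIDATES,
    ModelSpec,
    fit_conditional_logit,
    fit_issm,
    fit_slrm,
    fit_ssm,
    fit_stppm,
    fit_weighted_poisson,
    ppm_loglik,
)


def make_strata(x, used, strata):
    """Design table from plain arrays (one covariate named hab)."""
    df = pd.DataFrame(
        {
            "stratum": strata,
            "used": used,
            "hab": np.asarray(x, float),
            "u": used,
            "w": 1.0,
        }
    )
    df["point_id"] = df.groupby("stratum").cumcount()
    for c in ("x", "y", "attrac_dist", "attrac_ang", "log_dx", "cos_ta"):
        df[c] = 0.0
    return df


def simulate_clogit(rng, beta, n_strata, n_avail, extra_cols=()):
    """Data generated from a conditional-logit model with given slope."""
    rows = []
    for s in range(n_strata):
        x = rng.normal(size=n_avail + 1)
        p = np.exp(beta * x)
        p /= p.sum()
        chosen = rng.choice(n_avail + 1, p=p)
        used = np.zeros(n_avail + 1, int)
        used[chosen] = 1
        rows.append(pd.DataFrame({"stratum": s, "used": used, "hab": x}))
    df = pd.concat(rows, ignore_index=True)
    df["point_id"] = df.groupby("stratum").cumcount()
    for c in ("x", "y", "attrac_dist", "attrac_ang", "log_dx", "cos_ta"):
        df[c] = 0.0
    return df


class TestConditionalLogit:
    def test_two_stratum_example_matches_grid_search_oracle(self):
        # stratum A: used x=1 vs available {0, 0}; B: used x=0 vs {1, 0}
        tab = make_strata(
            x=[1, 0, 0, 0, 1, 0],
            used=[1, 0, 0, 1, 0, 0],
            strata=[0, 0, 0, 1, 1, 1],
        )

        def neg_ll(b):  # hand-written conditional likelihood
            return -(
                np.log(np.exp(b) / (np.exp(b) + 2)) + np.log(1 / (2 + np.exp(b)))
            )

        grid = np.linspace(-3, 3, 60001)
        oracle = grid[np.argmin([neg_ll(b) for b in grid])]
        fit = fit_conditional_logit(tab, (), "hab")
        assert fit.converged
        assert fit.estimate == pytest.approx(oracle, abs=1e-3)
        assert fit.estimate == pytest.approx(np.log(2.0), abs=1e-6)

    def test_exchangeable_strata_give_zero_coefficient(self):
        # mirror-image strata: used x=1 vs {0} and used x=0 vs {1}
        tab = make_strata(
            x=[1, 0, 0, 1], used=[1, 0, 1, 0], strata=[0, 0, 1, 1]
        )
        fit = fit_conditional_logit(tab, (), "hab")
        assert fit.estimate == pytest.approx(0.0, abs=1e-8)

    def test_parameter_recovery_beta_1p5(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            tab = simulate_clogit(rng, 1.5, n_strata=300, n_avail=20)
            fit = fit_conditional_logit(tab, (), "hab")
            hits += fit.converged and 1.3 <= fit.estimate <= 1.7
        assert hits >= 90

    def test_agrees_with_statsmodels_conditional_logit(self):
        rng = np.random.default_rng(5)
        tab = simulate_clogit(rng, 0.8, n_strata=80, n_avail=8)
        ours = fit_conditional_logit(tab, (), "hab")
        ref = ConditionalLogit(
            tab["used"].to_numpy(), tab[["hab"]].to_numpy(),
            groups=tab["stratum"].to_numpy(),
        ).fit(disp=0)
        assert ours.estimate == pytest.approx(ref.params[0], abs=1e-5)
        assert ours.se == pytest.approx(ref.bse[0], rel=1e-3)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_invariant_to_stratum_constant_offsets(self):
        rng = np.random.default_rng(6)
        tab = simulate_clogit(rng, 1.0, n_strata=60, n_avail=6)
        base = fit_conditional_logit(tab, (), "hab")
        shifted = tab.copy()
        offsets = shifted["stratum"].map(
            dict(enumerate(rng.normal(0, 5, shifted["stratum"].nunique())))
        )
        shifted["hab"] = shifted["hab"] + offsets
        out = fit_conditional_logit(shifted, (), "hab")
        assert out.estimate == pytest.approx(base.estimate, abs=1e-6)

    def test_within_stratum_constant_covariate_is_inestimable(self):
        tab = make_strata(
            x=[1, 1, 1, 2, 2, 2], used=[1, 0, 0, 1, 0, 0], strata=[0, 0, 0, 1, 1, 1]
        )
        fit = fit_conditional_logit(tab, (), "hab")
        assert not fit.converged
        assert np.isnan(fit.p)

    def test_null_pvalues_uniform(self):
        pvals = []
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            tab = simulate_clogit(rng, 0.0, n_strata=50, n_avail=5)
            fit = fit_ssm(tab, "hab")
            if fit.converged:
                pvals.append(fit.p)
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestISSM:
    def test_aic_definition_and_nesting(self, sim_track, medium_raster):
        from movebench.availability import fit_step_distributions, sample_available_steps

        dists = fit_step_distributions(sim_track)
        tab = sample_available_steps(
            sim_track, dists, 20, np.random.default_rng(0), medium_raster
        )
        fits = [fit_conditional_logit(tab, t, "hab") for t in ISSM_CANDIDATES]
        for f, terms in zip(fits, ISSM_CANDIDATES):
            assert f.aic == pytest.approx(2 * (1 + len(terms)) - 2 * f.loglik)
        ssm = fit_ssm(tab, "hab")
        issm = fit_issm(tab, "hab")
        assert ssm.loglik <= issm.loglik + 1e-9  # nesting
        if issm.selected_formula == "hab":
            assert issm.loglik == pytest.approx(ssm.loglik, abs=1e-9)

    def test_selects_simplest_model_under_null_movement_terms(self):
        wins = 0
        for rep in range(50):
            rng = np.random.default_rng(2000 + rep)
            tab = simulate_clogit(rng, 1.0, n_strata=60, n_avail=8)
            tab["log_dx"] = rng.normal(size=len(tab))
            tab["cos_ta"] = rng.normal(size=len(tab))
            fit = fit_issm(tab, "hab")
            wins += fit.selected_formula == "hab"
        assert wins > 25

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec("SLRM", "attrac_ang")
        spec = ModelSpec("iSSM", "hab")
        assert len(spec.candidate_formulas) == 5
        assert spec.candidate_formulas[-1] == "hab + log_dx + cos_ta + log_dx:cos_ta"


class TestPPMLoglik:
    def test_single_point_closed_form(self):
        u = np.array([2.0, 0.0])
        w = np.array([0.5, 0.5])
        lams = np.linspace(0.05, 4, 200)
        vals = [ppm_loglik(u, w, np.full(2, lam)) for lam in lams]
        np.testing.assert_allclose(vals, np.log(lams) - lams, atol=1e-12)
        assert lams[np.argmax(vals)] == pytest.approx(1.0, abs=0.02)

    def test_intercept_only_mle_equals_count_over_weight(self):
        rng = np.random.default_rng(0)
        n = 500
        u = np.zeros(n)
        u[:40] = 7.0
        w = rng.uniform(0.05, 0.4, n)
        u[:40] = 1.0 / w[:40]
        X = np.ones((n, 1))
        beta, lam = fit_weighted_poisson(X, u, w)
        assert lam[0] == pytest.approx(40.0 / w.sum(), rel=1e-8)

    def test_empty_pattern_and_domain_errors(self):
        u = np.zeros(4)
        w = np.full(4, 0.25)
        lam = np.full(4, 2.0)
        assert ppm_loglik(u, w, lam) == pytest.approx(-(w * lam).sum())
        with pytest.raises(ValueError):
            ppm_loglik(u, w, np.array([1.0, -1.0, 1.0, 1.0]))


def simulate_spatial_ppm(rng, beta_hab=1.0, beta0=-3.0, n_cells=40):
    """Poisson point pattern on a unit square with log-linear intensity in a
    smooth habitat field; returns a quadrature design table (cells as dummies,
    events as used points, total area shared by rectangle rule)."""
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


class TestPPMFitting:
    def test_weighted_poisson_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        tab = simulate_spatial_ppm(rng)
        X = np.column_stack([np.ones(len(tab)), tab["hab"]])
        beta, _ = fit_weighted_poisson(X, tab["u"].to_numpy(), tab["w"].to_numpy())
        ref = sm.GLM(
            tab["u"].to_numpy(), X, family=sm.families.Poisson(),
            var_weights=tab["w"].to_numpy(),
        ).fit()
        np.testing.assert_allclose(beta, ref.params, atol=1e-6)

    def test_ppm_coefficient_recovery(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(4000 + rep)
            tab = simulate_spatial_ppm(rng, beta_hab=0.8, beta0=-1.0, n_cells=50)
            X = np.column_stack([np.ones(len(tab)), tab["hab"]])
            beta, _ = fit_weighted_poisson(X, tab["u"].to_numpy(), tab["w"].to_numpy())
            hits += 0.6 <= beta[1] <= 1.0
        assert hits >= 90

    def test_infinitely_weighted_logistic_equals_ppm(self):
        """Weighted logistic regression (W=1000 on dummies) recovers the
        Poisson point-process slope on the same points (Fithian-Hastie limit)."""
        rng = np.random.default_rng(2)
        tab = simulate_spatial_ppm(rng, beta_hab=1.0, beta0=-2.0)
        X = np.column_stack([np.ones(len(tab)), tab["hab"]])
        beta_ppm, _ = fit_weighted_poisson(X, tab["u"].to_numpy(), tab["w"].to_numpy())
        slrm_w = fit_slrm(tab, "weighted", "hab")
        assert slrm_w.converged
        assert slrm_w.estimate == pytest.approx(beta_ppm[1], rel=0.01)

    def test_stppm_selection_on_spatial_only_problem(self, sim_track, medium_raster):
        from movebench.availability import GridSpec, build_quadrature_grid

        tab = build_quadrature_grid(
            sim_track, GridSpec(l=10.0, n_points=81), np.random.default_rng(3),
            medium_raster,
        )
        fit = fit_stppm(tab, "hab")
        assert fit.converged
        assert np.isfinite(fit.aic) and np.isfinite(fit.p)
        # PPM AIC is consistent with its own likelihood and edf
        assert fit.aic == pytest.approx(2 * fit.edf - 2 * fit.loglik, rel=1e-9)


class TestSLRM:
    def _null_table(self, rng, n=2500):
        used = np.r_[np.ones(n // 5, int), np.zeros(n - n // 5, int)]
        return pd.DataFrame(
            {
                "stratum": -1, "point_id": np.arange(n), "used": used,
                "x": rng.uniform(0, 100, n), "y": rng.uniform(0, 100, n),
                "u": used.astype(float), "w": 1.0,
                "hab": rng.random(n),
                "attrac_dist": rng.uniform(0, 50, n),
                "attrac_ang": np.nan, "log_dx": np.nan, "cos_ta": np.nan,
            }
        )

    def test_null_coefficient_within_three_se(self):
        fit = fit_slrm(self._null_table(np.random.default_rng(0)), "plain", "hab")
        assert fit.converged
        assert abs(fit.estimate) < 3 * fit.se

    def test_separation_flagged(self):
        tab = self._null_table(np.random.default_rng(1), n=500)
        tab["hab"] = tab["used"].astype(float)
        fit = fit_slrm(tab, "plain", "hab")
        assert not fit.converged
        assert np.isnan(fit.p)

    def test_smooth_variant_fits_with_spatial_spline(self):
        rng = np.random.default_rng(2)
        tab = self._null_table(rng, n=2000)
        # spatially clustered used points: the 2-D smooth should absorb this
        tab.loc[tab["used"] == 1, ["x", "y"]] = rng.normal(50, 8, (400, 2))
        fit = fit_slrm(tab, "smooth", "hab")
        assert fit.converged
        assert fit.edf > 3.0
        assert np.isfinite(fit.p)

    def test_attrac_ang_rejected(self):
        with pytest.raises(ValueError):
            fit_slrm(self._null_table(np.random.default_rng(3)), "plain", "attrac_ang")
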