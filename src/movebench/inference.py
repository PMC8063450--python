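"""Model fitting: SLRM variants, conditional logit (SSM/iSSM), and ST-PPM.

Six models are fitted to the shared design-table schema, each returning a
:class:`FitResult` with the focal-coefficient estimate, its standard error, a
two-sided Wald z-test p-value, the model log-likelihood and AIC.

* ``SLRM`` — logistic regression of used vs dummy points (binomial GLM);
  ``SLRM_s`` adds a penalized 2-D spline over the coordinates (tensor-product
  B-splines, smoothing by GCV); ``SLRM_w`` gives dummy points prior weight
  W = 1000 ("infinitely weighted" logistic regression, whose likelihood
  approaches that of an inhomogeneous Poisson process).
* ``SSM`` — conditional (per-stratum multinomial) logistic regression with the
  focal covariate only.
* ``iSSM`` — conditional logit with AIC selection over five candidate
  formulas adding log step length, cosine turning angle and their interaction.
* ``STPPM`` — weighted Poisson regression approximating the spatio-temporal
  point-process likelihood sum_jk w_jk (u_jk log lambda_jk - lambda_jk), with
  smooth terms s(.) as penalized B-splines and te(.) as a tensor product,
  smoothing by GCV, and AIC computed from the point-process likelihood with
  effective degrees of freedom = trace of the influence matrix.

The conditional-logit and penalized-IRLS solvers are implemented here as
vectorised Newton/IRLS routines (the study fits thousands of models per
batch); statsmodels provides the unpenalized GLM fits and serves as the
independent cross-check in the test-suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
import statsmodels.api as sm
from statsmodels.gam.smooth_basis import BSplines

__all__ = [
    "FAMILIES",
    "FOCALS",
    "ISSM_CANDIDATES",
    "STPPM_CANDIDATES",
    "ModelSpec",
    "FitResult",
    "fit_conditional_logit",
    "fit_ssm",
    "fit_issm",
    "ppm_loglik",
    "fit_weighted_poisson",
    "fit_stppm",
    "fit_slrm",
]

FAMILIES = ("SLRM", "SLRM_s", "SLRM_w", "SSM", "iSSM", "STPPM")
FOCALS = ("hab", "attrac_dist", "attrac_ang")

#: iSSM candidate movement terms (the focal covariate is always included).
ISSM_CANDIDATES: tuple[tuple[str, ...], ...] = (
    (),
    ("log_dx",),
    ("cos_ta",),
    ("log_dx", "cos_ta"),
    ("log_dx", "cos_ta", "log_dx:cos_ta"),
)

#: ST-PPM candidate movement terms; ``s(.)`` penalized spline, ``te(.)`` tensor.
STPPM_CANDIDATES: tuple[tuple[str, ...], ...] = (
    (),
    ("s(log_dx)",),
    ("s(cos_ta)",),
    ("s(log_dx)", "s(cos_ta)"),
    ("te(log_dx,cos_ta)",),
)

#: GCV grid of smoothing penalties.
ALPHA_GRID = np.logspace(-2.0, 6.0, 5)

_SLRM_DUMMY_WEIGHT = 1000.0


@dataclass(frozen=True)
class ModelSpec:
    """Family + focal covariate + the family's candidate formula list."""

    family: str
    focal: str = "hab"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.focal not in FOCALS:
            raise ValueError(f"focal must be one of {FOCALS}, got {self.focal!r}")
        if self.focal == "attrac_ang" and self.family.startswith("SLRM"):
            raise ValueError(
                "attrac_ang requires the temporal order of points and cannot be "
                "used with the purely spatial SLRM family"
            )

    @property
    def candidate_formulas(self) -> list[str]:
        if self.family == "iSSM":
            return [_formula_str(self.focal, t) for t in ISSM_CANDIDATES]
        if self.family == "STPPM":
            return [_formula_str(self.focal, t) for t in STPPM_CANDIDATES]
        return [self.focal]


@dataclass
class FitResult:
    """Focal-coefficient inference from one model fit."""

    family: str
    focal: str
    estimate: float = np.nan
    se: float = np.nan
    p: float = np.nan
    loglik: float = np.nan
    aic: float = np.nan
    edf: float = np.nan
    converged: bool = False
    selected_formula: str = ""
    n_dummy: int | None = None


def _formula_str(focal: str, terms: tuple[str, ...]) -> str:
    return " + ".join([focal, *terms])


def _wald_p(est: float, se: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return np.nan
    return float(2.0 * scipy.stats.norm.sf(abs(est / se)))


# ---------------------------------------------------------------------------
# Conditional logistic regression (vectorised Newton)


def _term_column(df: pd.DataFrame, term: str) -> np.ndarray:
    if ":" in term:
        a, b = term.split(":")
        return df[a].to_numpy(float) * df[b].to_numpy(float)
    return df[term].to_numpy(float)


def _clogit_core(X: np.ndarray, used: np.ndarray, stratum: np.ndarray):
    """Newton maximization of the per-stratum multinomial likelihood.

    Rows must be sorted by stratum. Returns (beta, cov, loglik, converged).
    """
    n, p = X.shape
    starts = np.r_[0, np.flatnonzero(np.diff(stratum)) + 1]
    counts = np.diff(np.r_[starts, n])
    gidx = np.repeat(np.arange(len(starts)), counts)

    def loglik(beta):
        eta = X @ beta
        gmax = np.maximum.reduceat(eta, starts)
        pex = np.exp(eta - gmax[gidx])
        denom = np.add.reduceat(pex, starts)
        return float(eta[used].sum() - (gmax + np.log(denom)).sum()), pex / denom[gidx]

    beta = np.zeros(p)
    ll, pr = loglik(beta)
    converged = False
    H = np.eye(p)
    for _ in range(60):
        grad = X[used].sum(axis=0) - X.T @ pr
        XW = X * pr[:, None]
        M = np.add.reduceat(XW, starts, axis=0)
        H = X.T @ XW - M.T @ M
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            return beta, None, ll, False
        t = 1.0
        for _ in range(12):  # step halving
            ll_new, pr_new = loglik(beta + t * step)
            if ll_new >= ll - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        ll, pr = ll_new, pr_new
        if np.max(np.abs(grad)) < 1e-8 and np.max(np.abs(t * step)) < 1e-8:
            converged = True
            break
    if np.max(np.abs(beta)) > 25.0:  # separation / divergence guard
        converged = False
    try:
        cov = np.linalg.inv(H + 1e-10 * np.eye(p))
    except np.linalg.LinAlgError:
        cov = None
        converged = False
    return beta, cov, ll, converged


def fit_conditional_logit(
    table: pd.DataFrame,
    terms: tuple[str, ...] = (),
    focal: str = "hab",
    family_label: str = "SSM",
) -> FitResult:
    """Conditional logit of used vs available rows within strata.

    ``terms`` are extra covariates (``a:b`` denotes an interaction); the focal
    covariate always enters first. Strata with missing covariate values or
    without exactly one used row are dropped.
    """
    cols = [focal] + [t for term in terms for t in term.split(":")]
    df = table.copy()
    keep = np.ones(len(df), bool)
    for c in dict.fromkeys(cols):
        keep &= np.isfinite(df[c].to_numpy(float))
    df = df[keep]
    n_used = df.groupby("stratum")["used"].sum()
    ok = n_used[n_used == 1].index
    df = df[df["stratum"].isin(ok)].sort_values(["stratum", "point_id"], kind="stable")
    res = FitResult(family=family_label, focal=focal,
                    selected_formula=_formula_str(focal, terms))
    if df.empty or df["stratum"].nunique() < 2:
        return res
    X = np.column_stack([_term_column(df, t) for t in (focal, *terms)])
    # inestimable when a covariate is constant within every stratum
    gmean = pd.DataFrame(X).groupby(df["stratum"].to_numpy()).transform("mean").to_numpy()
    if np.any(np.max(np.abs(X - gmean), axis=0) < 1e-12):
        return res
    beta, cov, ll, converged = _clogit_core(
        X, df["used"].to_numpy() == 1, df["stratum"].to_numpy()
    )
    k = X.shape[1]
    res.loglik = ll
    res.aic = 2.0 * k - 2.0 * ll
    res.edf = float(k)
    res.converged = bool(converged and cov is not None)
    if cov is not None:
        res.estimate = float(beta[0])
        res.se = float(np.sqrt(max(cov[0, 0], 0.0)))
        if res.converged:
            res.p = _wald_p(res.estimate, res.se)
    return res


def fit_ssm(table: pd.DataFrame, focal: str = "hab") -> FitResult:
    """Step selection model: conditional logit with the focal covariate only."""
    return fit_conditional_logit(table, (), focal, family_label="SSM")


def fit_issm(table: pd.DataFrame, focal: str = "hab") -> FitResult:
    """Integrated SSM: AIC selection over the five candidate formulas.

    Ties in AIC (within 1e-9) go to the candidate with fewer parameters; the
    focal inference is taken from the selected model.
    """
    fits = [
        fit_conditional_logit(table, terms, focal, family_label="iSSM")
        for terms in ISSM_CANDIDATES
    ]
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        out = fits[0]
        out.family = "iSSM"
        return out
    best = min(ok, key=lambda f: (round(f.aic / 1e-9) * 1e-9, f.edf))
    best.family = "iSSM"
    return best


# ---------------------------------------------------------------------------
# Weighted-Poisson point-process machinery


def ppm_loglik(u: np.ndarray, w: np.ndarray, lam: np.ndarray) -> float:
    """Quadrature approximation sum_jk w_jk (u_jk log lambda_jk - lambda_jk)."""
    u = np.asarray(u, float)
    w = np.asarray(w, float)
    lam = np.asarray(lam, float)
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise ValueError("intensity values must be positive and finite")
    term = np.where(u > 0, u * np.log(lam), 0.0) - lam
    return float((w * term).sum())


def _family_funcs(family: str):
    if family == "poisson":

        def mu_of(eta):
            return np.exp(np.clip(eta, -30.0, 30.0))

        def irls_wz(y, mu, eta):
            return mu, eta + (y - mu) / mu

        def deviance(y, mu, w):
            t = scipy.special.xlogy(y, y / mu) - (y - mu)
            return 2.0 * float((w * t).sum())

    elif family == "binomial":

        def mu_of(eta):
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -30.0, 30.0)))

        def irls_wz(y, mu, eta):
            v = mu * (1.0 - mu)
            v = np.maximum(v, 1e-10)
            return v, eta + (y - mu) / v

        def deviance(y, mu, w):
            t = scipy.special.xlogy(y, y / mu) + scipy.special.xlogy(
                1.0 - y, (1.0 - y) / (1.0 - mu)
            )
            return 2.0 * float((w * t).sum())

    else:  # pragma: no cover
        raise ValueError(family)
    return mu_of, irls_wz, deviance


def _pirls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    family: str,
    S: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    n_unpen: int | None = None,
):
    """Penalized IRLS for a weighted GLM with optional quadratic penalty S.

    Returns a dict with beta, cov (Bayesian (X'WX+S)^-1), edf (trace of the
    influence matrix), deviance and a convergence flag.
    """
    mu_of, irls_wz, deviance = _family_funcs(family)
    n, p = X.shape
    Sfull = np.zeros((p, p)) if S is None else S
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    dev = np.inf
    converged = False
    XtWX = None
    for _ in range(max_iter):
        eta = X @ beta
        mu = mu_of(eta)
        v, z = irls_wz(y, mu, eta)
        Wd = w * v
        XtW = X.T * Wd
        XtWX = XtW @ X
        try:
            beta_new = np.linalg.solve(XtWX + Sfull + 1e-9 * np.eye(p), XtW @ z)
        except np.linalg.LinAlgError:
            return None
        dev_new = deviance(y, mu_of(X @ beta_new), w)
        if not np.isfinite(dev_new):
            return None
        if abs(dev_new - dev) < tol * (abs(dev_new) + 0.1):
            beta = beta_new
            dev = dev_new
            converged = True
            break
        beta = beta_new
        dev = dev_new
    eta = X @ beta
    mu = mu_of(eta)
    v, _ = irls_wz(y, mu, eta)
    XtW = X.T * (w * v)
    XtWX = XtW @ X
    A = XtWX + Sfull + 1e-9 * np.eye(p)
    Ainv = np.linalg.inv(A)
    edf = float(np.trace(Ainv @ XtWX))
    return {
        "beta": beta,
        "cov": Ainv,
        "edf": edf,
        "deviance": deviance(y, mu, w),
        "mu": mu,
        "converged": converged
        and bool(np.max(np.abs(beta[: (n_unpen if n_unpen is not None else p)])) < 30.0),
    }


def fit_weighted_poisson(X: np.ndarray, u: np.ndarray, w: np.ndarray):
    """Plain (unpenalized) weighted-Poisson fit; returns (beta, lambda_hat)."""
    out = _pirls(X, np.asarray(u, float), np.asarray(w, float), "poisson")
    if out is None:
        raise np.linalg.LinAlgError("weighted Poisson fit failed")
    return out["beta"], np.exp(np.clip(X @ out["beta"], -30.0, 30.0))


def _spline_block(x: np.ndarray, df: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Centred B-spline basis and its curvature penalty for one covariate.

    The basis is built on values clipped to the [1%, 99%] quantile range so
    isolated extremes (e.g. the log of a near-zero step length) do not consume
    the basis; clipped rows re-use the boundary basis functions.
    """
    lo, hi = np.quantile(x, [0.01, 0.99])
    if hi - lo < 1e-9:
        hi = lo + 1e-9
    xc = np.clip(x, lo, hi)
    bs = BSplines(xc, df=[df], degree=[3], include_intercept=False)
    B = np.asarray(bs.basis, float)
    S = np.asarray(bs.penalty_matrices[0], float)
    B = B - B.mean(axis=0, keepdims=True)  # centring: intercept stays identifiable
    return B, S


def _tensor_block(x1: np.ndarray, x2: np.ndarray, df: int = 5):
    """Row-wise tensor product of two marginal B-spline bases."""
    B1, S1 = _spline_block(x1, df=df + 1)  # df+1 -> df columns after constraint
    B2, S2 = _spline_block(x2, df=df + 1)
    k1, k2 = B1.shape[1], B2.shape[1]
    T = (B1[:, :, None] * B2[:, None, :]).reshape(len(x1), k1 * k2)
    S = np.kron(S1, np.eye(k2)) + np.kron(np.eye(k1), S2)
    T = T - T.mean(axis=0, keepdims=True)
    return T, S


def _assemble(X0: np.ndarray, blocks: list[tuple[np.ndarray, np.ndarray]]):
    """Stack a linear part and smooth blocks; return X and per-block slices."""
    mats = [X0]
    slices = []
    p = X0.shape[1]
    for B, _ in blocks:
        slices.append(slice(p, p + B.shape[1]))
        mats.append(B)
        p += B.shape[1]
    return np.column_stack(mats), slices


def _penalty_for(p: int, blocks, slices, alphas) -> np.ndarray:
    S = np.zeros((p, p))
    for (B, Sj), sl, a in zip(blocks, slices, alphas):
        S[sl, sl] = a * Sj
    return S


def _fit_penalized(X0, blocks, y, w, family, gcv_n=None):
    """Fit a GLM with smooth blocks, choosing penalties by GCV on a log-grid.

    With two blocks the grid is scanned coordinate-wise (one sweep each),
    warm-starting each fit from the previous solution.
    """
    X, slices = _assemble(X0, blocks)
    n = len(y) if gcv_n is None else gcv_n
    n_unpen = X0.shape[1]
    if not blocks:
        out = _pirls(X, y, w, family, n_unpen=n_unpen)
        return out, X, slices, ()
    n_b = len(blocks)
    alphas = [ALPHA_GRID[len(ALPHA_GRID) // 2]] * n_b
    best = None
    beta0 = None
    for bi in range(n_b):
        best_a, best_gcv = None, np.inf
        for a in ALPHA_GRID:
            trial = list(alphas)
            trial[bi] = a
            S = _penalty_for(X.shape[1], blocks, slices, trial)
            out = _pirls(X, y, w, family, S=S, beta0=beta0, n_unpen=n_unpen)
            if out is None:
                continue
            beta0 = out["beta"]
            gcv = n * out["deviance"] / max(n - out["edf"], 1.0) ** 2
            if gcv < best_gcv:
                best_gcv, best_a, best = gcv, a, out
        if best_a is not None:
            alphas[bi] = best_a
    if best is None:
        return None, X, slices, tuple(alphas)
    # final fit at the selected penalties
    S = _penalty_for(X.shape[1], blocks, slices, alphas)
    out = _pirls(X, y, w, family, S=S, beta0=best["beta"], n_unpen=n_unpen)
    return out, X, slices, tuple(alphas)


def fit_stppm(table: pd.DataFrame, focal: str = "hab") -> FitResult:
    """Spatio-temporal point-process model via weighted Poisson regression.

    Fits the five candidate formulas (linear focal term plus none/smooth
    movement terms), computes AIC from the point-process likelihood
    approximation with edf = trace of the influence matrix, and reports
    the focal Wald test from the minimum-AIC candidate.
    """
    u = table["u"].to_numpy(float)
    w = table["w"].to_numpy(float)
    fvals = table[focal].to_numpy(float)
    X0 = np.column_stack([np.ones(len(table)), fvals])
    log_dx = table["log_dx"].to_numpy(float)
    cos_ta = table["cos_ta"].to_numpy(float)

    results = []
    for terms in STPPM_CANDIDATES:
        blocks = []
        for t in terms:
            if t == "s(log_dx)":
                blocks.append(_spline_block(log_dx))
            elif t == "s(cos_ta)":
                blocks.append(_spline_block(cos_ta))
            elif t == "te(log_dx,cos_ta)":
                blocks.append(_tensor_block(log_dx, cos_ta))
        out, X, slices, alphas = _fit_penalized(X0, blocks, u, w, "poisson")
        if out is None:
            continue
        lam = np.exp(np.clip(X @ out["beta"], -30.0, 30.0))
        ll = ppm_loglik(u, w, lam)
        aic = 2.0 * out["edf"] - 2.0 * ll
        results.append((terms, out, ll, aic))

    res = FitResult(family="STPPM", focal=focal)
    if not results:
        return res
    ok = [r for r in results if r[1]["converged"]]
    pool = ok if ok else results
    terms, out, ll, aic = min(pool, key=lambda r: (round(r[3] / 1e-9) * 1e-9, r[1]["edf"]))
    res.estimate = float(out["beta"][1])
    res.se = float(np.sqrt(max(out["cov"][1, 1], 0.0)))
    res.loglik = ll
    res.aic = aic
    res.edf = out["edf"]
    res.converged = bool(out["converged"])
    res.selected_formula = _formula_str(focal, terms)
    if res.converged:
        res.p = _wald_p(res.estimate, res.se)
    return res


# ---------------------------------------------------------------------------
# Spatial logistic regression models


def fit_slrm(table: pd.DataFrame, variant: str = "plain", focal: str = "hab") -> FitResult:
    """Spatial logistic regression of used vs dummy points.

    ``variant`` is ``plain`` (focal covariate only), ``smooth`` (adds a
    penalized 2-D tensor-product spline over the coordinates, smoothing by
    GCV) or ``weighted`` (dummy points carry prior weight 1000).
    """
    if variant not in ("plain", "smooth", "weighted"):
        raise ValueError(f"unknown SLRM variant {variant!r}")
    if focal == "attrac_ang":
        raise ValueError("attrac_ang cannot be used with the spatial SLRM family")
    label = {"plain": "SLRM", "smooth": "SLRM_s", "weighted": "SLRM_w"}[variant]
    y = table["used"].to_numpy(float)
    X0 = np.column_stack([np.ones(len(table)), table[focal].to_numpy(float)])
    wts = np.ones(len(table))
    if variant == "weighted":
        wts = np.where(y > 0, 1.0, _SLRM_DUMMY_WEIGHT)
    res = FitResult(family=label, focal=focal, selected_formula=focal)

    if variant == "smooth":
        xs = table["x"].to_numpy(float)
        ys_ = table["y"].to_numpy(float)
        blocks = [_tensor_block(xs, ys_, df=5)]  # 36 tensor columns max
        out, X, slices, _ = _fit_penalized(X0, blocks, y, wts, "binomial")
        if out is None:
            return res
        res.estimate = float(out["beta"][1])
        res.se = float(np.sqrt(max(out["cov"][1, 1], 0.0)))
        mu = out["mu"]
        ll = float(np.sum(np.where(y > 0, np.log(mu), np.log1p(-mu))))
        res.loglik = ll
        res.edf = out["edf"]
        res.aic = 2.0 * out["edf"] - 2.0 * ll
        res.converged = bool(out["converged"])
        if res.converged:
            res.p = _wald_p(res.estimate, res.se)
        return res

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(y, X0, family=sm.families.Binomial(), var_weights=wts)
            fit = glm.fit(maxiter=100)
    except Exception:
        return res
    beta = np.asarray(fit.params)
    res.estimate = float(beta[1])
    res.se = float(np.asarray(fit.bse)[1])
    res.loglik = float(fit.llf)
    res.edf = float(X0.shape[1])
    res.aic = 2.0 * X0.shape[1] - 2.0 * res.loglik
    res.converged = bool(
        fit.converged and np.all(np.isfinite(beta)) and np.max(np.abs(beta)) < 30.0
        and np.isfinite(res.se) and res.se > 0
    )
    if res.converged:
        res.p = _wald_p(res.estimate, res.se)
    return res
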