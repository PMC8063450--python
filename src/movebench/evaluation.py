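"""Power / type-I aggregation and the LASSO + GEE meta-analysis.

Every model fit on a simulated trip is condensed into one evaluation record:
the binary outcome ``effect`` (focal coefficient significant at alpha = 0.05,
strict inequality) together with the habitat and movement parameters that
generated the trip. Aggregation follows the hierarchical design: the binary
outcome is first averaged within each block of trips sharing covariates (a
landscape), then across blocks, with 95% bootstrap percentile intervals over
block means.

The meta-analysis regresses ``effect`` on habitat/movement/method predictors:
an L1-penalized (LASSO) logistic regression with 10-fold cross-validation
pre-selects predictors, and a binomial GEE with an exchangeable working
correlation (clustered on the landscape id, robust sandwich errors) provides
the final tests at the Bonferroni level alpha/m, where m is the number of
candidate predictors entering the LASSO.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .inference import FitResult

__all__ = [
    "HABITAT_PREDICTORS",
    "MOVEMENT_PREDICTORS",
    "MetaAnalysisResult",
    "single_trip_effect",
    "multi_trip_effect",
    "multi_trip_records",
    "aggregate_rates",
    "build_meta_design",
    "lasso_preselect",
    "gee_analysis",
]

HABITAT_PREDICTORS = ("hab_auto", "hab_anis", "hab_smooth", "hab_type")
MOVEMENT_PREDICTORS = (
    "sigma_sd", "sigma_alpha", "sigma_omega", "sigma_ran", "sigma_ran2", "error_spat",
)


@dataclass
class MetaAnalysisResult:
    """GEE estimates after LASSO pre-selection, tested at alpha/m."""

    params: pd.Series
    se: pd.Series
    p: pd.Series
    m: int
    alpha: float = 0.05
    selected: list[str] = field(default_factory=list)
    working_correlation: float = np.nan

    @property
    def alpha_bonferroni(self) -> float:
        return self.alpha / max(self.m, 1)

    @property
    def significant(self) -> list[str]:
        thr = self.alpha_bonferroni
        return [k for k in self.p.index if k != "const" and self.p[k] < thr]


def single_trip_effect(fit: FitResult, alpha: float = 0.05):
    """Binary outcome of one fit: 1 iff p < alpha (strict).

    Returns None for non-converged fits or missing p-values; such records are
    excluded from rate aggregation.
    """
    if not fit.converged or not np.isfinite(fit.p):
        return None
    return int(fit.p < alpha)


def multi_trip_effect(coefficients, alpha: float = 0.05) -> int:
    """Multi-trip outcome: is the mean of 5 per-trip coefficients nonzero?

    Implemented as the intercept-only linear model, i.e. a two-sided one-sample
    t-test with 4 degrees of freedom. Zero-variance inputs are resolved by
    convention: all equal and nonzero -> significant; all zero -> not.
    """
    c = np.asarray(list(coefficients), float)
    if c.shape != (5,) or not np.all(np.isfinite(c)):
        raise ValueError("need exactly 5 finite coefficients")
    if np.ptp(c) == 0.0:
        if c[0] == 0.0:
            return 0
        warnings.warn("zero-variance coefficients with nonzero mean: significant "
                      "by convention", RuntimeWarning, stacklevel=2)
        return 1
    t = scipy.stats.ttest_1samp(c, 0.0)
    return int(t.pvalue < alpha)


def multi_trip_records(
    records: pd.DataFrame,
    group_cols: tuple[str, ...] = ("family", "focal", "n_dummy", "with_effects"),
    block_col: str = "landscape_id",
    n_trips: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Multi-trip outcomes: one record per block of trips sharing covariates.

    For every (group, block) with exactly ``n_trips`` converged coefficient
    estimates, tests whether their mean differs from zero
    (:func:`multi_trip_effect`); blocks with missing or non-converged fits are
    dropped with a warning. The result feeds :func:`aggregate_rates` with
    ``block_col`` as its own block (each row is already one block).
    """
    rows = []
    dropped = 0
    recs = records[records["converged"].fillna(False).astype(bool)]
    for key, grp in recs.groupby(list(group_cols) + [block_col], observed=True):
        est = grp["estimate"].to_numpy(float)
        if len(est) != n_trips or not np.all(np.isfinite(est)):
            dropped += 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eff = multi_trip_effect(est, alpha=alpha)
        rows.append(dict(zip(list(group_cols) + [block_col], key)) | {"effect": eff})
    if dropped:
        warnings.warn(f"{dropped} trip blocks dropped (incomplete or non-finite "
                      "coefficients)", RuntimeWarning, stacklevel=2)
    return pd.DataFrame(rows)


def aggregate_rates(
    records: pd.DataFrame,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    block_col: str = "landscape_id",
    group_cols: tuple[str, ...] = ("family", "focal", "n_dummy", "with_effects"),
) -> pd.DataFrame:
    """Average detection rates with bootstrap CIs, respecting the hierarchy.

    Within each group, ``effect`` is first averaged per block (trips sharing
    covariates), then across blocks; 95% intervals come from resampling block
    means with replacement (percentile method).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    recs = records.dropna(subset=["effect"])
    rows = []
    for key, grp in recs.groupby(list(group_cols), observed=True, dropna=False):
        blocks = grp.groupby(block_col)["effect"].mean().to_numpy(float)
        if len(blocks) == 0:
            warnings.warn(f"group {key} has no usable records", RuntimeWarning,
                          stacklevel=2)
            continue
        rate = float(blocks.mean())
        idx = rng.integers(0, len(blocks), size=(n_boot, len(blocks)))
        boot = blocks[idx].mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append(
            dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
            | {"rate": rate, "ci_lo": float(lo), "ci_hi": float(hi),
               "n_blocks": len(blocks), "n_trips": len(grp)}
        )
    return pd.DataFrame(rows)


def build_meta_design(
    records: pd.DataFrame,
    candidates: tuple[str, ...] = HABITAT_PREDICTORS + MOVEMENT_PREDICTORS,
    interactions: bool = False,
) -> pd.DataFrame:
    """Numeric design matrix for the meta-analysis.

    Categorical habitat predictors become dummies (``hab_smooth`` baseline
    "sharp"; ``hab_type`` coded 1 for categorical); the method enters as
    ``Meth_<family>`` dummies with the ST-PPM as baseline when present. With
    ``interactions=True``, products of the method dummies with every
    habitat/movement predictor are appended.
    """
    cols = {}
    for c in candidates:
        if c == "hab_smooth":
            smooth = records["hab_smooth"].astype(str)
            for lvl in ("medium", "blurry"):
                cols[f"hab_smooth_{lvl}"] = (smooth == lvl).astype(float)
        elif c == "hab_type":
            cols["hab_type"] = (records["hab_type"].astype(str) == "categorical").astype(float)
        else:
            cols[c] = records[c].astype(float)
    fams = sorted(records["family"].astype(str).unique())
    baseline = "STPPM" if "STPPM" in fams else fams[0]
    meth_cols = []
    for fam in fams:
        if fam == baseline:
            continue
        name = f"Meth_{fam}"
        cols[name] = (records["family"].astype(str) == fam).astype(float)
        meth_cols.append(name)
    X = pd.DataFrame(cols, index=records.index)
    if interactions:
        enviro = [c for c in X.columns if not c.startswith("Meth_")]
        for m in meth_cols:
            for e in enviro:
                X[f"{m}:{e}"] = X[m] * X[e]
    return X


@dataclass
class LassoSelection:
    selected: list[str]
    coefficients: pd.Series
    C: float


def lasso_preselect(
    records: pd.DataFrame,
    candidates: tuple[str, ...] = HABITAT_PREDICTORS + MOVEMENT_PREDICTORS,
    interactions: bool = False,
    rng: np.random.Generator | None = None,
    cv: int = 10,
    fixed_C: float | None = None,
) -> LassoSelection:
    """L1-penalized logistic pre-selection of meta-analysis predictors.

    Predictors are standardized; the penalty is chosen by ``cv``-fold
    cross-validated prediction error (log-loss) under the one-standard-error
    rule — the strongest penalty whose mean CV loss is within one standard
    error of the minimum — which favours the parsimonious model among those
    predicting equally well. ``fixed_C`` skips the search and fits at one
    penalty; the limits C -> 0 / C -> inf give the all-zero and unpenalized
    solutions. Returns the predictors with nonzero coefficients.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    X = build_meta_design(records, candidates, interactions)
    names = list(X.columns)
    y = records["effect"].to_numpy(float)
    Xs = StandardScaler().fit_transform(X.to_numpy(float))
    seed = int(rng.integers(2**31))
    if fixed_C is None:
        Cs = np.logspace(-3, 2, 16)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv_model = LogisticRegressionCV(
                penalty="l1",
                solver="liblinear",
                Cs=Cs,
                cv=KFold(cv, shuffle=True, random_state=seed),
                scoring="neg_log_loss",
                max_iter=5000,
                random_state=seed,
            ).fit(Xs, y)
        scores = next(iter(cv_model.scores_.values()))  # (folds, n_Cs) neg log-loss
        mean = scores.mean(axis=0)
        best = int(np.argmax(mean))
        se_best = scores[:, best].std(ddof=1) / np.sqrt(scores.shape[0])
        within = np.flatnonzero(mean >= mean[best] - se_best)
        fixed_C = float(Cs[within[0]])  # smallest C = strongest penalty
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LogisticRegression(
            penalty="l1", C=fixed_C, solver="liblinear", max_iter=5000,
            random_state=seed,
        ).fit(Xs, y)
    coefs = pd.Series(model.coef_.ravel(), index=names)
    selected = [n for n in names if abs(coefs[n]) > 1e-8]
    return LassoSelection(selected=selected, coefficients=coefs, C=float(fixed_C))


def gee_analysis(
    records: pd.DataFrame,
    selected: list[str],
    m: int | None = None,
    alpha: float = 0.05,
    candidates: tuple[str, ...] = HABITAT_PREDICTORS + MOVEMENT_PREDICTORS,
    interactions: bool = False,
) -> MetaAnalysisResult:
    """Binomial GEE (logit link, exchangeable correlation, robust SEs).

    Records are clustered on ``landscape_id``; significance is judged at the
    Bonferroni level alpha/m. With clusters of size one the GEE reduces to an
    ordinary logistic regression with robust standard errors.
    """
    Xall = build_meta_design(records, candidates, interactions)
    if m is None:
        m = Xall.shape[1]
    X = Xall[selected] if selected else Xall[[]]
    X = sm.add_constant(X, has_constant="add")
    y = records["effect"].to_numpy(float)
    groups = records["landscape_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE(
            y, X, groups=groups,
            family=sm.families.Binomial(),
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        fit = model.fit()
    return MetaAnalysisResult(
        params=pd.Series(fit.params, index=X.columns),
        se=pd.Series(fit.bse, index=X.columns),
        p=pd.Series(fit.pvalues, index=X.columns),
        m=int(m),
        alpha=alpha,
        selected=list(selected),
        working_correlation=float(np.atleast_1d(model.cov_struct.dep_params)[0]),
    )


def plot_rates(rates: pd.DataFrame, ax=None):
    """Dot-and-interval chart of detection rates per method and dummy level."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    markers = {8: "o", 80: "^", 230: "s"}
    xpos = {}
    for _, row in rates.iterrows():
        key = (row["family"], row.get("focal", "hab"))
        x = xpos.setdefault(key, len(xpos))
        x = x + 0.1 * list(markers).index(int(row["n_dummy"])) if row["n_dummy"] in markers else x
        colour = "tab:green" if row.get("with_effects", True) else "tab:blue"
        ax.errorbar(
            x, row["rate"],
            yerr=[[row["rate"] - row["ci_lo"]], [row["ci_hi"] - row["rate"]]],
            fmt=markers.get(int(row["n_dummy"]), "o"), color=colour, capsize=3,
        )
    ax.set_xticks([v for v in xpos.values()])
    ax.set_xticklabels(["/".join(map(str, k)) for k in xpos], rotation=30, ha="right")
    ax.axhline(0.05, ls=":", color="grey")
    ax.set_ylabel("detection rate")
    return ax
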