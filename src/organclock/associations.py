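"""Association machinery: covariate-adjusted Cox and linear models over
age gaps, Benjamini-Hochberg correction, Gini dispersion of log hazard
ratios, penalized-Cox mortality-model comparison, and Kaplan-Meier
summaries.

Cox fits use lifelines' partial likelihood (Efron tie handling) with
time-on-study from the blood draw as the timescale and age-at-draw and
sex as default covariates, mirroring the standard organ-aging design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

DEFAULT_COVARIATES = ("age", "sex")


@dataclass
class AssociationResult:
    exposure: str
    model: str                      # "cox" | "linear"
    estimate: float                 # log HR or slope
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int | None = None
    q: float | None = None
    endpoint: str | None = None
    flagged: bool = False
    note: str = ""

    @property
    def hazard_ratio(self) -> float:
        if self.model != "cox":
            raise ValueError("hazard ratio is defined for Cox results only")
        return float(np.exp(self.estimate))

    def to_dict(self) -> dict:
        d = {
            "exposure": self.exposure,
            "endpoint": self.endpoint,
            "model": self.model,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "q": self.q,
            "n": self.n,
            "n_events": self.n_events,
            "flagged": self.flagged,
        }
        return d


def _assemble(
    exposure: pd.Series | pd.DataFrame,
    survival: pd.DataFrame,
    covariates: pd.DataFrame | None,
) -> pd.DataFrame:
    df = survival[["time", "event"]].copy()
    exp_df = exposure.to_frame() if isinstance(exposure, pd.Series) else exposure
    df = df.join(exp_df, how="inner")
    if covariates is not None:
        df = df.join(covariates, how="inner")
    df = df.dropna()
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    return df


def cox_association(
    exposure: pd.Series,
    survival: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    endpoint: str | None = None,
    reference: str = "normal",
) -> AssociationResult | list[AssociationResult]:
    """Cox PH association of one exposure with an endpoint.

    ``survival`` carries 'time' (years from draw) and 'event' columns,
    indexed by sample.  A numeric exposure yields a single result (per-SD
    log HR when the exposure is a z-gap); a categorical exposure is
    dummy-coded against ``reference`` and yields one result per level.
    Zero events or a degenerate fit come back flagged with no estimate.
    """
    categorical = exposure.dtype == object or isinstance(
        exposure.dtype, pd.CategoricalDtype
    )
    name = exposure.name or "exposure"
    if categorical:
        levels = [l for l in pd.unique(exposure.dropna()) if l != reference]
        dummies = pd.DataFrame(
            {f"{name}[{l}]": (exposure == l).astype(float) for l in levels},
            index=exposure.index,
        )
        df = _assemble(dummies, survival, covariates)
        exp_cols = list(dummies.columns)
    else:
        df = _assemble(exposure.rename(name), survival, covariates)
        exp_cols = [name]

    n = len(df)
    n_events = int(df["event"].sum())
    if n_events == 0 or df["time"].nunique() < 2:
        flagged = [
            AssociationResult(c, "cox", np.nan, np.nan, np.nan, np.nan, np.nan,
                              n, n_events, endpoint=endpoint, flagged=True,
                              note="no events or degenerate time distribution")
            for c in exp_cols
        ]
        return flagged if categorical else flagged[0]

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        flagged = [
            AssociationResult(c, "cox", np.nan, np.nan, np.nan, np.nan, np.nan,
                              n, n_events, endpoint=endpoint, flagged=True,
                              note=f"fit failure: {exc}")
            for c in exp_cols
        ]
        return flagged if categorical else flagged[0]

    out = []
    for c in exp_cols:
        s = cph.summary.loc[c]
        out.append(
            AssociationResult(
                exposure=c,
                model="cox",
                estimate=float(s["coef"]),
                se=float(s["se(coef)"]),
                ci_low=float(s["coef lower 95%"]),
                ci_high=float(s["coef upper 95%"]),
                p=float(s["p"]),
                n=n,
                n_events=n_events,
                endpoint=endpoint,
            )
        )
    return out if categorical else out[0]


def linear_association(
    outcome: pd.Series,
    exposures: pd.Series | pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> list[AssociationResult]:
    """OLS of an age gap (or any outcome) on one or more exposures with
    covariates; returns one result per exposure column."""
    exp_df = exposures.to_frame() if isinstance(exposures, pd.Series) else exposures
    X = exp_df.copy()
    if covariates is not None:
        X = X.join(covariates, how="inner")
    df = X.join(outcome.rename("_y"), how="inner").dropna()
    y = df.pop("_y")
    Xd = sm.add_constant(df, has_constant="add")
    rank = np.linalg.matrix_rank(Xd.to_numpy(float))
    if rank < Xd.shape[1]:
        corr = df.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax() if len(df.columns) > 1 else tuple(df.columns)
        raise ValueError(f"design matrix is rank deficient (collinear: {worst})")
    fit = sm.OLS(y, Xd).fit()
    ci = fit.conf_int()
    return [
        AssociationResult(
            exposure=c,
            model="linear",
            estimate=float(fit.params[c]),
            se=float(fit.bse[c]),
            ci_low=float(ci.loc[c, 0]),
            ci_high=float(ci.loc[c, 1]),
            p=float(fit.pvalues[c]),
            n=int(fit.nobs),
        )
        for c in exp_df.columns
    ]


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def attach_q(results: list[AssociationResult]) -> list[AssociationResult]:
    """BH-adjust one analysis family of results in place."""
    ok = [r for r in results if not r.flagged and np.isfinite(r.p)]
    if ok:
        q = adjust_bh([r.p for r in ok])
        for r, qi in zip(ok, q):
            r.q = float(qi)
    return results


@dataclass
class GiniResult:
    endpoint: str
    values: np.ndarray
    gini: float
    flagged: bool = False


def gini_of_log_hazards(
    log_hrs, endpoint: str = "", clip_negative: bool = True
) -> GiniResult:
    """Gini dispersion of per-organ log hazard ratios for one endpoint.

    G = sum_ij |x_i - x_j| / (2 n^2 xbar).  High G means the disease
    signal concentrates in few organs; G = 0 means a fully systemic
    (equal) signal.  Negative log HRs are clipped to zero first by
    default; an all-zero vector leaves the Gini undefined (NaN, flagged).
    """
    x = np.asarray(log_hrs, float)
    if x.size < 2:
        raise ValueError("need at least two log hazard ratios")
    if clip_negative:
        x = np.clip(x, 0.0, None)
    elif (x < 0).any():
        raise ValueError("negative inputs with clipping disabled")
    if np.all(x == 0):
        return GiniResult(endpoint, x, float("nan"), flagged=True)
    diff = np.abs(x[:, None] - x[None, :]).sum()
    g = float(diff / (2.0 * x.size**2 * x.mean()))
    return GiniResult(endpoint, x, g)


def association_grid(
    z_wide: pd.DataFrame,
    events: dict[str, pd.DataFrame],
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Cox grid of every z-gap model against every endpoint, BH-corrected
    within the grid (one analysis family)."""
    results: list[AssociationResult] = []
    for endpoint, table in events.items():
        surv = table.set_index("subject_id")[["time", "event"]]
        for model in z_wide.columns:
            res = cox_association(
                z_wide[model].rename(model), surv, covariates, endpoint=endpoint
            )
            results.append(res)
    attach_q(results)
    return pd.DataFrame([r.to_dict() for r in results])


def gini_per_endpoint(grid: pd.DataFrame, exclude=("conventional",)) -> pd.DataFrame:
    rows = []
    for endpoint, sub in grid.groupby("endpoint"):
        sub = sub[~sub["exposure"].isin(exclude) & ~sub["flagged"]]
        if len(sub) < 2:
            continue
        res = gini_of_log_hazards(sub["estimate"].to_numpy(), endpoint=endpoint)
        rows.append({"endpoint": endpoint, "gini": res.gini, "flagged": res.flagged,
                     "n_models": len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mortality model comparison
# ---------------------------------------------------------------------------

def _cv_penalty(
    df: pd.DataFrame, penalties, l1_ratio: float, seed: int = 0
) -> float:
    """Choose the Cox penalizer by 3-fold cross-validated partial
    log-likelihood on the training split."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(df))
    folds = np.array_split(idx, 3)
    best, best_ll = penalties[0], -np.inf
    for pen in penalties:
        ll = 0.0
        ok = True
        for i in range(3):
            va = folds[i]
            tr = np.concatenate([folds[j] for j in range(3) if j != i])
            cph = CoxPHFitter(penalizer=pen, l1_ratio=l1_ratio)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df.iloc[tr], "time", "event")
                    ll += cph.score(df.iloc[va], scoring_method="log_likelihood")
            except Exception:
                ok = False
                break
        if ok and ll > best_ll:
            best, best_ll = pen, ll
    return best


def compare_mortality_models(
    feature_sets: dict[str, list[str]],
    data: pd.DataFrame,
    train_ids,
    test_ids,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    penalties=(0.001, 0.01, 0.1),
    l1_ratio: float = 1.0,
    seed: int = 0,
) -> dict:
    """Concordance comparison of Lasso-regularized Cox models.

    ``data`` holds 'time', 'event', the covariates, and every feature
    column, indexed by sample.  Each feature set is fitted on the
    training samples (always together with age and sex); train and test
    concordance are reported, plus the coefficient vector of the last
    (typically combined) model.
    """
    out: dict = {"concordance": {}, "coefficients": {}, "penalty": {}}
    for name, feats in feature_sets.items():
        if not feats and not covariates:
            raise ValueError(f"feature set '{name}' is empty")
        cols = ["time", "event"] + list(covariates) + [
            f for f in feats if f not in covariates
        ]
        missing = set(cols) - set(data.columns)
        if missing:
            raise ValueError(f"feature set '{name}' names absent columns: {sorted(missing)}")
        train = data.loc[train_ids, cols].dropna()
        test = data.loc[test_ids, cols].dropna()
        pen = _cv_penalty(train, penalties, l1_ratio, seed)
        cph = CoxPHFitter(penalizer=pen, l1_ratio=l1_ratio)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(train, "time", "event")
        out["penalty"][name] = pen
        out["coefficients"][name] = cph.params_.to_dict()
        out["concordance"][name] = {
            "train": float(
                concordance_index(
                    train["time"],
                    -cph.predict_partial_hazard(train),
                    train["event"],
                )
            ),
            "test": float(
                concordance_index(
                    test["time"],
                    -cph.predict_partial_hazard(test),
                    test["event"],
                )
            ),
        }
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_curve(survival: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Product-limit survival per group, with cumulative incidence.

    Returns long-format rows (group, time, survival, cumulative_incidence,
    at_risk); censoring after the last event leaves S at event times
    unchanged, as the estimator requires.
    """
    paired = survival.index.intersection(groups.dropna().index)
    rows = []
    for g, ids in groups.loc[paired].groupby(groups.loc[paired]).groups.items():
        sub = survival.loc[ids]
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"])
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        for t, s in surv.items():
            rows.append(
                {
                    "group": g,
                    "time": float(t),
                    "survival": float(s),
                    "cumulative_incidence": float(1.0 - s),
                    "at_risk": int(at_risk.loc[t]) if pd.notna(at_risk.loc[t]) else None,
                }
            )
    return pd.DataFrame(rows)


def event_percentage(n_events: int, n_total: int) -> float:
    """Percent of subjects with an observed event (printed-table scale)."""
    if n_total <= 0 or n_events < 0 or n_events > n_total:
        raise ValueError("need 0 <= n_events <= n_total with n_total > 0")
    return 100.0 * n_events / n_total
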