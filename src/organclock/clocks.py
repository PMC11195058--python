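"""Sparse penalized aging clocks and age-gap machinery.

A clock is a LASSO regression of chronological age on a protein panel.
The penalty is chosen by 5-fold cross-validation, then deliberately
backed off to the *largest* (sparsest) penalty whose mean CV R-squared
still reaches a fraction (default 95%) of the best penalty's — trading a
sliver of accuracy for a much sparser, more interpretable model.

The clock's biological-age readout is the *age gap*: the residual of
predicted age after ordinary least squares on actual age, z-scored by
the training gap mean/SD.  Residualizer and z-scale are fitted on the
training cohort and frozen, so gaps are comparable across splits and
across permutation analyses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.feature_selection import RFECV
from sklearn.linear_model import Lasso, LassoCV, lasso_path
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted


def _as_frame(X) -> pd.DataFrame:
    return X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))


def _alpha_grid(X: np.ndarray, y: np.ndarray, n_alphas: int, eps: float = 1e-4) -> np.ndarray:
    n = len(y)
    alpha_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    alpha_max = max(alpha_max, 1e-12)
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * eps), n_alphas)


class OrganAgeClock(RegressorMixin, BaseEstimator):
    """LASSO chronological-age predictor for one protein panel.

    Parameters
    ----------
    panel : list of str, optional
        Protein columns the clock may use; defaults to every column of
        the training matrix.
    perf_fraction : float
        Fraction of the best mean CV R-squared a sparser penalty must
        retain to be chosen (0.95 for primary clocks, 0.90 for distilled
        ones).
    n_alphas, cv, random_state
        Penalty-path resolution, CV fold count (5, matching the study
        design), and the fold-shuffling seed.

    Fitted attributes
    -----------------
    coef_, intercept_ : sparse weights and intercept of the final refit.
    alpha_, alpha_best_ : chosen and CV-optimal penalties.
    cv_record_ : per-penalty mean CV R-squared and nonzero counts.
    non_predictive_ : True when the best mean CV R-squared is <= 0; age
        gaps are disabled on such a clock.
    slope_, res_intercept_, gap_mean_, gap_sd_ : residualizer and z-scale
        fitted on training predictions.
    """

    def __init__(
        self,
        panel: list[str] | None = None,
        name: str | None = None,
        perf_fraction: float = 0.95,
        n_alphas: int = 100,
        cv: int = 5,
        random_state: int = 0,
        max_iter: int = 5000,
    ):
        self.panel = panel
        self.name = name
        self.perf_fraction = perf_fraction
        self.n_alphas = n_alphas
        self.cv = cv
        self.random_state = random_state
        self.max_iter = max_iter

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "OrganAgeClock":
        if not 0.0 < self.perf_fraction <= 1.0:
            raise ValueError("perf_fraction must be in (0, 1]")
        Xf = _as_frame(X)
        feats = list(self.panel) if self.panel is not None else list(Xf.columns)
        missing = set(feats) - set(Xf.columns)
        if missing:
            raise ValueError(f"panel proteins absent from matrix: {sorted(missing)[:5]}")
        Xm = Xf[feats].to_numpy(float)
        y = np.asarray(y, float)
        if len(y) < 10:
            raise ValueError("need at least 10 training samples")
        if np.var(y) == 0:
            raise ValueError("zero age variance in training samples")

        alphas = _alpha_grid(Xm, y, self.n_alphas)
        folds = KFold(n_splits=self.cv, shuffle=True, random_state=self.random_state)
        r2_folds = np.zeros((self.cv, len(alphas)))
        for i, (tr, va) in enumerate(folds.split(Xm)):
            x_mu = Xm[tr].mean(axis=0)
            y_mu = y[tr].mean()
            # lasso_path fits without an intercept; center within the fold
            _, coefs, _ = lasso_path(
                Xm[tr] - x_mu, y[tr] - y_mu, alphas=alphas, max_iter=self.max_iter
            )
            pred = (Xm[va] - x_mu) @ coefs + y_mu
            resid = pred - y[va][:, None]
            fold_sse = np.sum(resid**2, axis=0)
            fold_sst = np.sum((y[va] - y[va].mean()) ** 2)
            r2_folds[i] = 1.0 - fold_sse / max(fold_sst, 1e-300)
        mean_r2 = r2_folds.mean(axis=0)

        best_idx = int(np.argmax(mean_r2))
        best_r2 = float(mean_r2[best_idx])
        self.alpha_best_ = float(alphas[best_idx])
        self.cv_r2_best_ = best_r2
        self.non_predictive_ = best_r2 <= 0.0
        if self.non_predictive_:
            chosen_idx = best_idx
        else:
            qualifying = np.nonzero(mean_r2 >= self.perf_fraction * best_r2)[0]
            chosen_idx = int(qualifying[0])  # alphas descend: first = sparsest
        self.alpha_ = float(alphas[chosen_idx])

        # nonzero counts along the full-data path, for the CV record
        _, full_coefs, _ = lasso_path(
            Xm - Xm.mean(axis=0), y - y.mean(), alphas=alphas, max_iter=self.max_iter
        )
        self.cv_record_ = pd.DataFrame(
            {
                "alpha": alphas,
                "mean_cv_r2": mean_r2,
                "n_nonzero": (full_coefs != 0).sum(axis=0),
            }
        )

        final = Lasso(alpha=self.alpha_, max_iter=self.max_iter)
        final.fit(Xm, y)
        self.feature_names_in_ = np.asarray(feats, dtype=object)
        self.n_features_in_ = len(feats)
        self.coef_ = final.coef_
        self.intercept_ = float(final.intercept_)

        pred_train = final.predict(Xm)
        self._fit_residualizer(pred_train, y)
        return self

    def _fit_residualizer(self, pred_train: np.ndarray, y: np.ndarray) -> None:
        if np.var(y) == 0:
            raise ValueError("degenerate residualizer: zero age variance")
        slope, intercept = np.polyfit(y, pred_train, 1)
        self.slope_ = float(slope)
        self.res_intercept_ = float(intercept)
        gaps = pred_train - (self.slope_ * y + self.res_intercept_)
        self.gap_mean_ = float(gaps.mean())
        sd = float(gaps.std(ddof=0))
        if sd <= 0 and not self.non_predictive_:
            self.non_predictive_ = True
        self.gap_sd_ = sd if sd > 0 else 1.0

    # ------------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        Xf = _as_frame(X)
        needed = [f for f, w in zip(self.feature_names_in_, self.coef_) if w != 0]
        absent = set(needed) - set(Xf.columns)
        if absent:
            raise ValueError(f"required proteins missing from matrix: {sorted(absent)[:5]}")
        # absent zero-weight columns contribute nothing; fill for alignment
        Xm = Xf.reindex(columns=list(self.feature_names_in_), fill_value=0.0)
        return Xm.to_numpy(float) @ self.coef_ + self.intercept_

    def age_gaps(self, X, age, cohort: str = "apply") -> pd.DataFrame:
        """Predicted age, raw gap (years) and z-gap for each sample."""
        check_is_fitted(self, "slope_")
        if self.non_predictive_:
            raise ValueError(
                f"clock '{self.name or 'unnamed'}' is flagged non-predictive; "
                "age gaps are disabled"
            )
        Xf = _as_frame(X)
        pred = self.predict(Xf)
        return compute_age_gaps(self, pred, np.asarray(age, float), index=Xf.index)

    @property
    def nonzero_proteins_(self) -> list[str]:
        check_is_fitted(self, "coef_")
        return [f for f, w in zip(self.feature_names_in_, self.coef_) if w != 0]

    # ---- serialization ----------------------------------------------
    def to_json(self, path: str | Path) -> None:
        check_is_fitted(self, "coef_")
        payload = {
            "name": self.name,
            "perf_fraction": self.perf_fraction,
            "alpha": self.alpha_,
            "alpha_best": self.alpha_best_,
            "cv_r2_best": self.cv_r2_best_,
            "non_predictive": bool(self.non_predictive_),
            "intercept": self.intercept_,
            "weights": {
                f: float(w)
                for f, w in zip(self.feature_names_in_, self.coef_)
                if w != 0
            },
            "panel": list(self.feature_names_in_),
            "residualizer": {"slope": self.slope_, "intercept": self.res_intercept_},
            "gap_scale": {"mean": self.gap_mean_, "sd": self.gap_sd_},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "OrganAgeClock":
        with open(path) as fh:
            d = json.load(fh)
        clock = cls(panel=d["panel"], name=d["name"], perf_fraction=d["perf_fraction"])
        clock.feature_names_in_ = np.asarray(d["panel"], dtype=object)
        clock.n_features_in_ = len(d["panel"])
        clock.coef_ = np.array([d["weights"].get(f, 0.0) for f in d["panel"]])
        clock.intercept_ = d["intercept"]
        clock.alpha_ = d["alpha"]
        clock.alpha_best_ = d["alpha_best"]
        clock.cv_r2_best_ = d["cv_r2_best"]
        clock.non_predictive_ = d["non_predictive"]
        clock.slope_ = d["residualizer"]["slope"]
        clock.res_intercept_ = d["residualizer"]["intercept"]
        clock.gap_mean_ = d["gap_scale"]["mean"]
        clock.gap_sd_ = d["gap_scale"]["sd"]
        return clock


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_clock(
    train_matrix: pd.DataFrame,
    ages,
    panel: list[str] | None = None,
    perf_fraction: float = 0.95,
    name: str | None = None,
    random_state: int = 0,
) -> OrganAgeClock:
    return OrganAgeClock(
        panel=panel, name=name, perf_fraction=perf_fraction, random_state=random_state
    ).fit(train_matrix, ages)


def predict_age(clock: OrganAgeClock, matrix) -> np.ndarray:
    return clock.predict(matrix)


def compute_age_gaps(
    clock: OrganAgeClock, predicted, actual, index=None
) -> pd.DataFrame:
    """Raw gap = predicted - (slope*actual + intercept); z by training scale."""
    check_is_fitted(clock, "slope_")
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    gap = predicted - (clock.slope_ * actual + clock.res_intercept_)
    z = (gap - clock.gap_mean_) / clock.gap_sd_
    return pd.DataFrame(
        {
            "model": clock.name or "clock",
            "predicted_age": predicted,
            "gap": gap,
            "z_gap": z,
        },
        index=index,
    )


def gap_table(
    clocks: dict[str, OrganAgeClock], matrix: pd.DataFrame, ages
) -> pd.DataFrame:
    """Long AgeGapTable over several clocks: sample_id, model, predicted_age,
    gap, z_gap.  Non-predictive clocks are skipped."""
    rows = []
    for name, clock in clocks.items():
        if getattr(clock, "non_predictive_", False):
            continue
        df = clock.age_gaps(matrix, ages)
        df = df.assign(model=name)
        df.index.name = "sample_id"
        rows.append(df.reset_index())
    return pd.concat(rows, ignore_index=True)


def gap_wide(table: pd.DataFrame, value: str = "z_gap") -> pd.DataFrame:
    return table.pivot(index="sample_id", columns="model", values=value)


# ---------------------------------------------------------------------------
# meta clock
# ---------------------------------------------------------------------------

@dataclass
class MetaClock:
    weights: pd.Series           # raw coefficients on organ predicted ages
    relative_weights: pd.Series  # |w| normalized to sum 1
    intercept: float
    r2: float


def fit_meta_clock(
    organ_ages: pd.DataFrame, conventional_age, random_state: int = 0
) -> MetaClock:
    """Sparse linear model predicting the conventional clock's age from
    organ predicted ages; reports variance explained and relative weights."""
    if organ_ages.shape[1] < 2:
        raise ValueError("need at least two organ age columns")
    y = np.asarray(conventional_age, float)
    model = LassoCV(cv=5, random_state=random_state, max_iter=5000)
    model.fit(organ_ages.to_numpy(float), y)
    w = pd.Series(model.coef_, index=organ_ages.columns)
    total = np.abs(w).sum()
    rel = np.abs(w) / total if total > 0 else w * 0.0
    r2 = float(model.score(organ_ages.to_numpy(float), y))
    return MetaClock(
        weights=w, relative_weights=rel, intercept=float(model.intercept_), r2=r2
    )


# ---------------------------------------------------------------------------
# distillation onto a reduced platform
# ---------------------------------------------------------------------------

@dataclass
class DistillationResult:
    clock: OrganAgeClock | None
    retained: bool
    holdout_r: float
    n_features: int
    record: dict


def distill_clock(
    parent: OrganAgeClock,
    train_matrix: pd.DataFrame,
    train_ages,
    reduced_panel: list[str],
    holdout_matrix: pd.DataFrame,
    holdout_ages,
    perf_fraction: float = 0.90,
    retention_r: float = 0.8,
    random_state: int = 0,
) -> DistillationResult:
    """Train a reduced-panel clock to mimic the parent clock's predictions.

    The target is the parent's predicted age on the training samples (so
    the child inherits the parent's notion of biological age, not raw
    chronology).  The penalty is chosen by the 90% rule; recursive
    feature elimination with CV then minimizes the feature count.  The
    child is retained only when its holdout predictions correlate with
    the parent's at r >= ``retention_r``; otherwise it is dropped with a
    record.  Holdout samples must be disjoint from training samples.
    """
    if not reduced_panel:
        raise ValueError("reduced panel is empty")
    target = parent.predict(train_matrix)
    child = OrganAgeClock(
        panel=list(reduced_panel),
        name=f"{parent.name or 'clock'}_distilled",
        perf_fraction=perf_fraction,
        random_state=random_state,
    ).fit(train_matrix, target)

    # RFECV at the chosen penalty to shrink the feature count further
    support = np.ones(len(reduced_panel), dtype=bool)
    nz = child.coef_ != 0
    if nz.sum() >= 2:
        Xr = train_matrix[list(reduced_panel)].to_numpy(float)
        rfe = RFECV(
            Lasso(alpha=child.alpha_, max_iter=5000),
            step=0.2,
            cv=KFold(5, shuffle=True, random_state=random_state),
            scoring="r2",
            min_features_to_select=1,
        )
        rfe.fit(Xr, target)
        support = rfe.support_
        kept = [p for p, s in zip(reduced_panel, support) if s]
        child = OrganAgeClock(
            panel=kept,
            name=child.name,
            perf_fraction=perf_fraction,
            random_state=random_state,
        ).fit(train_matrix, target)

    # gap machinery should refer to actual ages, not the distillation target
    child._fit_residualizer(child.predict(train_matrix), np.asarray(train_ages, float))

    parent_hold = parent.predict(holdout_matrix)
    child_hold = child.predict(holdout_matrix)
    if np.std(child_hold) == 0 or np.std(parent_hold) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(parent_hold, child_hold)[0, 1])
    retained = r >= retention_r
    record = {
        "parent": parent.name,
        "holdout_r": r,
        "retention_threshold": retention_r,
        "retained": retained,
        "n_features": len(child.nonzero_proteins_),
        "n_parent_features": len(parent.nonzero_proteins_),
        "retention_rule": "kept iff corr(child, parent) >= threshold on held-out "
                          "samples (equivalently r^2 >= threshold^2)",
    }
    return DistillationResult(
        clock=child if retained else None,
        retained=retained,
        holdout_r=r,
        n_features=record["n_features"],
        record=record,
    )
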