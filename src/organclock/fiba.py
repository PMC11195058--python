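"""Permutation Feature Importance for Biological Aging (FIBA).

FIBA asks how much of a clock's gap-outcome association each clock
protein carries: permute that protein's column across samples, recompute
predicted ages with the *fixed* clock (no refitting), recompute z-gaps
with the clock's frozen residualizer and z-scale, refit the outcome
association, and score the protein by the effect-size loss relative to
the unpermuted baseline.  Proteins the clock ignores (zero weight) score
exactly zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .associations import AssociationResult, cox_association, linear_association
from .clocks import OrganAgeClock, compute_age_gaps


@dataclass
class FibaResult:
    clock: str
    outcome: str
    effect_measure: str            # "cox" | "linear"
    baseline_effect: float
    scores: pd.DataFrame           # protein, weight, score, perm_mean, perm_sd, n_ok
    n_permutations: int
    seed: int


def _fit_effect(
    z: pd.Series,
    outcome,
    covariates: pd.DataFrame | None,
    measure: str,
) -> float | None:
    try:
        if measure == "cox":
            res = cox_association(z.rename("z_gap"), outcome, covariates)
            if isinstance(res, AssociationResult) and not res.flagged:
                return res.estimate
            return None
        res = linear_association(outcome, z.rename("z_gap"), covariates)
        return res[0].estimate
    except Exception:
        return None


def fiba_scores(
    clock: OrganAgeClock,
    matrix: pd.DataFrame,
    ages: pd.Series,
    outcome,
    covariates: pd.DataFrame | None = None,
    effect: str = "cox",
    n_perm: int = 10,
    seed: int = 0,
    outcome_name: str = "outcome",
) -> FibaResult:
    """Score each clock protein's contribution to the gap-outcome link.

    ``outcome`` is a survival frame (time/event, indexed by sample) for
    ``effect="cox"`` or a continuous Series for ``effect="linear"``.
    The permutation operates on the analysis-ready (imputed, scaled)
    matrix, so only the clock's use of the protein is ablated.
    """
    if effect not in ("cox", "linear"):
        raise ValueError("effect must be 'cox' or 'linear'")
    rng = np.random.default_rng(seed)
    ages_arr = np.asarray(ages.loc[matrix.index] if isinstance(ages, pd.Series) else ages,
                          float)
    pred0 = clock.predict(matrix)
    gaps0 = compute_age_gaps(clock, pred0, ages_arr, index=matrix.index)
    baseline = _fit_effect(gaps0["z_gap"], outcome, covariates, effect)
    if baseline is None:
        raise ValueError("baseline outcome association failed to fit")

    weights = dict(zip(clock.feature_names_in_, clock.coef_))
    rows = []
    for protein in clock.feature_names_in_:
        w = float(weights[protein])
        if w == 0.0:
            rows.append(
                {"protein": protein, "weight": 0.0, "score": 0.0,
                 "perm_mean": baseline, "perm_sd": 0.0, "n_ok": 0}
            )
            continue
        x = matrix[protein].to_numpy(float)
        effects = []
        for _ in range(n_perm):
            x_perm = rng.permutation(x)
            # clock is linear: permuted prediction = baseline + w * delta
            pred = pred0 + w * (x_perm - x)
            gaps = compute_age_gaps(clock, pred, ages_arr, index=matrix.index)
            est = _fit_effect(gaps["z_gap"], outcome, covariates, effect)
            if est is not None:
                effects.append(est)
        n_ok = len(effects)
        if n_ok == 0:
            rows.append(
                {"protein": protein, "weight": w, "score": np.nan,
                 "perm_mean": np.nan, "perm_sd": np.nan, "n_ok": 0}
            )
            continue
        perm_mean = float(np.mean(effects))
        rows.append(
            {
                "protein": protein,
                "weight": w,
                "score": baseline - perm_mean,
                "perm_mean": perm_mean,
                "perm_sd": float(np.std(effects, ddof=0)),
                "n_ok": n_ok,
            }
        )
    scores = pd.DataFrame(rows).set_index("protein")
    return FibaResult(
        clock=clock.name or "clock",
        outcome=outcome_name,
        effect_measure=effect,
        baseline_effect=float(baseline),
        scores=scores,
        n_permutations=n_perm,
        seed=seed,
    )


def permute_all_effect(
    clock: OrganAgeClock,
    matrix: pd.DataFrame,
    ages: pd.Series,
    outcome,
    covariates: pd.DataFrame | None = None,
    effect: str = "cox",
    seed: int = 0,
) -> float | None:
    """Outcome effect after permuting every clock protein simultaneously
    (each column independently) — the full-ablation null."""
    rng = np.random.default_rng(seed)
    shuffled = matrix.copy()
    for protein in clock.nonzero_proteins_:
        shuffled[protein] = rng.permutation(shuffled[protein].to_numpy())
    ages_arr = np.asarray(ages.loc[matrix.index] if isinstance(ages, pd.Series) else ages,
                          float)
    pred = clock.predict(shuffled)
    gaps = compute_age_gaps(clock, pred, ages_arr, index=matrix.index)
    return _fit_effect(gaps["z_gap"], outcome, covariates, effect)
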