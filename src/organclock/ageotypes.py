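"""Extreme-ager taxonomy, age-gap bins, and cross-visit transitions.

An "extreme ager" has at least one clock z-gap beyond +/-1.5 SD (top and
bottom ~6-7% of a standard-normal gap).  Samples are classified as
normal (no extreme gap), single-organ, multi-organ (two or more extreme
gaps of the same sign, binned 2-4 / 5-7 / 8+), or ambiguous (extreme
gaps of both signs).  The conventional clock is excluded from
eligibility because it duplicates the organismal signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 1.5
BIN_EDGES = (-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5)
MULTI_ORGAN_BINS = ((2, 4), (5, 7), (8, None))


@dataclass
class AgeotypeLabel:
    category: str                   # normal | single_organ | multi_organ | ambiguous
    direction: str                  # aged | youthful | mixed | none
    organs: list[str] = field(default_factory=list)
    multi_organ_bin: str | None = None  # "2-4" | "5-7" | "8+"


def _multi_bin(n: int) -> str:
    for lo, hi in MULTI_ORGAN_BINS:
        if n >= lo and (hi is None or n <= hi):
            return f"{lo}-{hi}" if hi is not None else f"{lo}+"
    raise ValueError(f"no multi-organ bin for count {n}")


def classify_ageotype(
    z_gaps: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
    eligible_models: list[str] | None = None,
) -> AgeotypeLabel:
    """Classify one sample from its per-model z-gaps.

    ``eligible_models`` defaults to every index entry except
    "conventional".  A missing z for an eligible model is an error.
    """
    if eligible_models is None:
        eligible_models = [m for m in z_gaps.index if m != "conventional"]
    missing = [m for m in eligible_models if m not in z_gaps.index or pd.isna(z_gaps[m])]
    if missing:
        raise ValueError(f"missing z-gap for eligible models: {missing}")
    z = z_gaps[eligible_models]
    extreme = z[np.abs(z) >= threshold]
    if extreme.empty:
        return AgeotypeLabel("normal", "none")
    organs = list(extreme.index)
    pos = (extreme > 0).any()
    neg = (extreme < 0).any()
    if pos and neg:
        return AgeotypeLabel("ambiguous", "mixed", organs)
    direction = "aged" if pos else "youthful"
    if len(extreme) == 1:
        return AgeotypeLabel("single_organ", direction, organs)
    return AgeotypeLabel("multi_organ", direction, organs, _multi_bin(len(extreme)))


def classify_cohort(
    z_wide: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    eligible_models: list[str] | None = None,
) -> pd.DataFrame:
    """Vectorized taxonomy over a samples x models z-gap matrix."""
    if eligible_models is None:
        eligible_models = [m for m in z_wide.columns if m != "conventional"]
    z = z_wide[eligible_models]
    if z.isna().any().any():
        bad = z.columns[z.isna().any()].tolist()
        raise ValueError(f"missing z-gaps for eligible models: {bad}")
    arr = z.to_numpy(float)
    n_pos = (arr >= threshold).sum(axis=1)
    n_neg = (arr <= -threshold).sum(axis=1)
    n_ext = n_pos + n_neg

    category = np.where(
        n_ext == 0, "normal",
        np.where((n_pos > 0) & (n_neg > 0), "ambiguous",
                 np.where(n_ext == 1, "single_organ", "multi_organ")),
    )
    direction = np.where(
        n_ext == 0, "none",
        np.where((n_pos > 0) & (n_neg > 0), "mixed",
                 np.where(n_pos > 0, "aged", "youthful")),
    )
    bins = np.array(
        [_multi_bin(k) if c == "multi_organ" else "" for k, c in zip(n_ext, category)],
        dtype=object,
    )
    organs = [
        ";".join(z.columns[np.abs(row) >= threshold]) for row in arr
    ]
    return pd.DataFrame(
        {
            "category": category,
            "direction": direction,
            "organs": organs,
            "n_extreme": n_ext,
            "multi_organ_bin": bins,
        },
        index=z_wide.index,
    )


def bin_gap(z: float, edges: tuple[float, ...] = BIN_EDGES) -> int:
    """Ordinal bin of a z-gap: interior bins are left-closed/right-open
    half-SD intervals; bin 0 is (-inf, -1.5), the top bin is [1.5, inf)."""
    if not np.isfinite(z):
        raise ValueError("z-gap must be finite")
    return int(np.searchsorted(np.asarray(edges), z, side="right"))


def bin_gaps(z: pd.Series, edges: tuple[float, ...] = BIN_EDGES) -> pd.Series:
    arr = np.asarray(z, float)
    if not np.isfinite(arr).all():
        raise ValueError("z-gaps must be finite")
    return pd.Series(np.searchsorted(np.asarray(edges), arr, side="right"),
                     index=z.index, name="gap_bin")


def transition_stats(
    z_visit1: pd.Series,
    z_visit2: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
    direction: str = "aged",
) -> dict:
    """Cross-visit persistence of extreme-ager status for one organ.

    ``repeat_risk_ratio`` = P(extreme at v2 | extreme at v1) /
    P(extreme at v2 | not extreme at v1); ``same_sign_retention`` =
    fraction of v1 extreme agers whose v2 z-gap keeps the same sign.
    ``same_bin_retention`` (identical half-SD bin) is reported as a
    secondary statistic.  Requires paired samples.
    """
    paired = z_visit1.index.intersection(z_visit2.index)
    if len(paired) == 0:
        raise ValueError("no paired samples across visits")
    z1 = z_visit1.loc[paired]
    z2 = z_visit2.loc[paired]
    if direction == "aged":
        ext1, ext2 = z1 >= threshold, z2 >= threshold
    elif direction == "youthful":
        ext1, ext2 = z1 <= -threshold, z2 <= -threshold
    else:
        ext1, ext2 = np.abs(z1) >= threshold, np.abs(z2) >= threshold

    n11 = int((ext1 & ext2).sum())
    n1 = int(ext1.sum())
    n01 = int((~ext1 & ext2).sum())
    n0 = int((~ext1).sum())
    flagged = n1 == 0 or n0 == 0 or n01 == 0
    ratio = (n11 / n1) / (n01 / n0) if not flagged and n1 > 0 else float("nan")

    if n1 > 0:
        same_sign = float((np.sign(z2[ext1]) == np.sign(z1[ext1])).mean())
        same_bin = float((bin_gaps(z2[ext1]).to_numpy()
                          == bin_gaps(z1[ext1]).to_numpy()).mean())
    else:
        same_sign = float("nan")
        same_bin = float("nan")
    return {
        "repeat_risk_ratio": ratio,
        "same_sign_retention": same_sign,
        "same_bin_retention": same_bin,
        "flagged": flagged,
        "counts": {
            "extreme_v1": n1,
            "extreme_both": n11,
            "non_extreme_v1": n0,
            "non_extreme_v1_extreme_v2": n01,
            "n_paired": int(len(paired)),
        },
    }
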