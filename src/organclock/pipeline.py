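"""End-to-end pipeline: simulate (or ingest) -> panels -> preprocess ->
clocks -> age gaps -> ageotypes -> associations -> FIBA.

Each stage persists its artifacts under the output directory and the
run closes with a JSON manifest recording the config hash, derived
seeds, file digests, and every design-decision setting in force, so a
rerun with the same config reproduces deterministic stages
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ageotypes, associations, clocks, panels as panels_mod, preprocessing
from .fiba import fiba_scores
from .simulate import CohortBundle, SimulationConfig, build_atlas, simulate_cohort

log = logging.getLogger("organclock")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


DEFAULTS = {
    "fold": 4.0,
    "missing_threshold": 0.10,
    "perf_fraction": 0.95,
    "extreme_threshold": 1.5,
    "train_center_fraction": 0.5,
    "fiba_clock": "brain",
    "fiba_endpoint": "mortality",
    "fiba_n_perm": 10,
}


def run_pipeline(
    config: SimulationConfig,
    out_dir: str | Path,
    settings: dict | None = None,
) -> dict:
    """Run the whole analysis on a simulated cohort and return a summary
    dict (also written as ``manifest.json`` / ``summary.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    opts = {**DEFAULTS, **(settings or {})}
    config.validate()

    # -- stage: simulate ---------------------------------------------------
    log.info("simulating cohort: n=%d", config.n_subjects)
    bundle = simulate_cohort(config)
    bundle.to_dir(out / "cohort")

    # -- stage: panels -----------------------------------------------------
    atlas = build_atlas(bundle, seed=_stage_seed(config.seed, "atlas"))
    atlas.to_csv(out / "atlas.tsv", sep="\t")
    gene_map = panels_mod.select_organ_enriched_genes(atlas, fold=opts["fold"])
    assay = list(bundle.proteomes[0].columns)
    g2p = pd.DataFrame({"gene": assay, "protein": assay})
    panel_set, warnings_ = panels_mod.build_panels(
        gene_map, assay, g2p, fold=opts["fold"],
        gene_fold=panels_mod.enrichment_ratio(atlas),
    )
    panels_mod.panels_to_json(panel_set, out / "panels.json")
    for w in warnings_:
        log.warning(w)

    # -- stage: preprocess -------------------------------------------------
    centers = sorted(bundle.subjects["center"].unique())
    n_train_centers = max(1, int(round(len(centers) * opts["train_center_fraction"])))
    train_centers = centers[:n_train_centers]
    prep = preprocessing.preprocess(
        bundle.proteomes[0], bundle.subjects, train_centers,
        threshold=opts["missing_threshold"],
    )
    log.info("preprocess: %s", prep.manifest)

    ages = bundle.ages(0)
    train_ages = ages.loc[prep.train.index]
    test_ages = ages.loc[prep.test.index]

    # -- stage: clocks -----------------------------------------------------
    clock_set: dict[str, clocks.OrganAgeClock] = {}
    clock_dir = out / "clocks"
    clock_dir.mkdir(exist_ok=True)
    seed = _stage_seed(config.seed, "clocks")
    for name, panel in panel_set.items():
        usable = [p for p in panel.proteins if p in prep.train.columns]
        if not usable:
            log.warning("panel %s has no usable proteins after filtering", name)
            continue
        clock = clocks.fit_clock(
            prep.train, train_ages, panel=usable,
            perf_fraction=opts["perf_fraction"], name=name, random_state=seed,
        )
        clock.to_json(clock_dir / f"{name}.json")
        if clock.non_predictive_:
            log.warning("clock %s flagged non-predictive", name)
        else:
            clock_set[name] = clock

    full = pd.concat([prep.train, prep.test])
    full_ages = pd.concat([train_ages, test_ages])
    gaps_long = clocks.gap_table(clock_set, full, full_ages)
    gaps_long.to_csv(out / "age_gaps.csv", index=False)
    z_wide = clocks.gap_wide(gaps_long)

    perf = {}
    for name, clock in clock_set.items():
        r_tr = float(np.corrcoef(clock.predict(prep.train), train_ages)[0, 1])
        r_te = float(np.corrcoef(clock.predict(prep.test), test_ages)[0, 1])
        perf[name] = {"r_train": r_tr, "r_test": r_te,
                      "n_proteins": len(clock.nonzero_proteins_)}

    meta = None
    organ_cols = [c for c in clock_set if c not in ("conventional",)]
    if "conventional" in clock_set and len(organ_cols) >= 2:
        pred_ages = pd.DataFrame(
            {c: clock_set[c].predict(full) for c in organ_cols}, index=full.index
        )
        meta = clocks.fit_meta_clock(
            pred_ages, clock_set["conventional"].predict(full),
            random_state=_stage_seed(config.seed, "meta"),
        )

    # -- stage: ageotypes --------------------------------------------------
    eligible = [c for c in z_wide.columns if c != "conventional"]
    labels = ageotypes.classify_cohort(
        z_wide, threshold=opts["extreme_threshold"], eligible_models=eligible
    )
    labels.to_csv(out / "ageotypes.csv")

    # -- stage: associations -----------------------------------------------
    covariates = pd.DataFrame(
        {"age": ages, "sex": bundle.subjects.set_index("subject_id")["sex"]}
    )
    grid = associations.association_grid(z_wide, bundle.events, covariates)
    grid.to_csv(out / "association_grid.csv", index=False)
    gini = associations.gini_per_endpoint(grid)
    gini.to_csv(out / "gini.csv", index=False)

    km = None
    if "mortality" in bundle.events:
        surv = bundle.events["mortality"].set_index("subject_id")[["time", "event"]]
        km = associations.km_curve(surv, labels["category"])
        km.to_csv(out / "km_curves.csv", index=False)

    # -- stage: FIBA -------------------------------------------------------
    fiba_summary = None
    f_clock, f_ep = opts["fiba_clock"], opts["fiba_endpoint"]
    if f_clock in clock_set and f_ep in bundle.events:
        surv = bundle.events[f_ep].set_index("subject_id")[["time", "event"]]
        fr = fiba_scores(
            clock_set[f_clock], full, full_ages, surv, covariates,
            effect="cox", n_perm=opts["fiba_n_perm"],
            seed=_stage_seed(config.seed, "fiba"),
            outcome_name=f_ep,
        )
        fr.scores.to_csv(out / "fiba.csv")
        fiba_summary = {
            "clock": f_clock, "endpoint": f_ep,
            "baseline_log_hr": fr.baseline_effect,
            "top_protein": fr.scores["score"].idxmax(),
        }

    summary = {
        "n_subjects": config.n_subjects,
        "clock_performance": perf,
        "meta_clock": None
        if meta is None
        else {"r2": meta.r2, "relative_weights": meta.relative_weights.to_dict()},
        "ageotype_fractions": labels["category"].value_counts(normalize=True).to_dict(),
        "gini": gini.set_index("endpoint")["gini"].to_dict() if len(gini) else {},
        "fiba": fiba_summary,
        "preprocess": prep.manifest,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=str)

    manifest = {
        "config_hash": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "global_seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s)
                        for s in ("atlas", "clocks", "meta", "fiba")},
        "settings": opts,
        "outputs": {
            str(p.relative_to(out)): _digest(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    summary["manifest"] = manifest
    return summary
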