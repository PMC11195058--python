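"""Organ-enriched gene calls and protein panel construction.

A gene is organ-enriched when its expression in one organ is at least
``fold`` times its expression in every other organ of a bulk-tissue
atlas (GTEx-like, TPM-scale).  Enriched genes are mapped onto the
proteins measured by the plasma assay to form one panel per organ, plus
an "organismal" panel (assay proteins in no organ panel) and a
"conventional" panel (the whole assay).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"


@dataclass
class OrganPanel:
    name: str
    proteins: list[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.proteins)


def load_atlas(path: str | Path) -> pd.DataFrame:
    """Read a TSV atlas: first column gene id, remaining columns organs."""
    atlas = pd.read_csv(path, sep="\t", index_col=0)
    validate_atlas(atlas)
    return atlas


def validate_atlas(atlas: pd.DataFrame) -> None:
    if (atlas.to_numpy() < 0).any():
        raise ValueError("expression atlas contains negative values")
    if atlas.columns.duplicated().any():
        raise ValueError("atlas organ names are not unique")
    if atlas.index.duplicated().any():
        raise ValueError("atlas gene identifiers are not unique")


def select_organ_enriched_genes(atlas: pd.DataFrame, fold: float = 4.0) -> pd.Series:
    """Assign each gene to the organ where it is >= fold x any other organ.

    A gene expressed in exactly one organ and zero elsewhere counts as
    enriched there (infinite ratio); an all-zero gene is unassigned.
    Returns a Series gene -> organ name, with ``"unassigned"`` elsewhere.
    """
    validate_atlas(atlas)
    if atlas.shape[1] < 2:
        raise ValueError("enrichment rule is undefined with fewer than two organs")
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")

    x = atlas.to_numpy(float)
    top_idx = np.argmax(x, axis=1)
    top = x[np.arange(len(x)), top_idx]
    x_masked = x.copy()
    x_masked[np.arange(len(x)), top_idx] = -np.inf
    second = np.max(x_masked, axis=1)

    # top >= fold * second; second == 0 with top > 0 passes (ratio infinite)
    enriched = (top > 0) & (top >= fold * second)
    out = pd.Series(UNASSIGNED, index=atlas.index, name="organ", dtype=object)
    out[enriched] = atlas.columns.to_numpy()[top_idx[enriched]]
    return out


def enrichment_ratio(atlas: pd.DataFrame) -> pd.Series:
    """Per-gene top/second-highest expression ratio (inf when second is 0)."""
    x = atlas.to_numpy(float)
    top_idx = np.argmax(x, axis=1)
    top = x[np.arange(len(x)), top_idx]
    x_masked = x.copy()
    x_masked[np.arange(len(x)), top_idx] = -np.inf
    second = np.max(x_masked, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(second > 0, top / np.maximum(second, 1e-300),
                         np.where(top > 0, np.inf, 0.0))
    return pd.Series(ratio, index=atlas.index, name="fold_ratio")


def build_panels(
    gene_map: pd.Series,
    assay_proteins: list[str],
    gene_to_protein: pd.DataFrame,
    fold: float = 4.0,
    atlas_id: str = "",
    gene_fold: pd.Series | None = None,
) -> tuple[dict[str, OrganPanel], list[str]]:
    """Map enriched genes onto the assay and assemble the panel set.

    ``gene_to_protein`` has columns (gene, protein); many-to-one mappings
    keep the protein if any mapped gene is enriched, taking the organ of
    the highest-fold gene when ``gene_fold`` (see ``enrichment_ratio``) is
    supplied.  Returns panels keyed by name plus a list of warnings for
    organs whose panel came up empty.  Organ panels partition out of the
    conventional panel; leftovers form the organismal panel.
    """
    if not {"gene", "protein"} <= set(gene_to_protein.columns):
        raise ValueError("gene_to_protein mapping needs 'gene' and 'protein' columns")
    assay = list(dict.fromkeys(assay_proteins))
    mapping = gene_to_protein[gene_to_protein["protein"].isin(assay)]

    protein_organ: dict[str, str] = {}
    protein_fold: dict[str, float] = {}
    for _, row in mapping.iterrows():
        organ = gene_map.get(row["gene"], UNASSIGNED)
        if organ == UNASSIGNED:
            continue
        f = float(gene_fold.get(row["gene"], 1.0)) if gene_fold is not None else 1.0
        if row["protein"] not in protein_organ or f > protein_fold[row["protein"]]:
            protein_organ[row["protein"]] = organ
            protein_fold[row["protein"]] = f

    organs = sorted({o for o in gene_map.unique() if o != UNASSIGNED})
    provenance = {"fold": fold, "atlas": atlas_id}
    panels: dict[str, OrganPanel] = {}
    warnings: list[str] = []
    claimed: set[str] = set()
    for organ in organs:
        members = [p for p in assay if protein_organ.get(p) == organ]
        if members:
            panels[organ] = OrganPanel(organ, members, dict(provenance))
            claimed.update(members)
        else:
            warnings.append(f"organ panel '{organ}' is empty after assay mapping")
    organismal = [p for p in assay if p not in claimed]
    panels["organismal"] = OrganPanel("organismal", organismal, dict(provenance))
    panels["conventional"] = OrganPanel("conventional", assay, dict(provenance))
    return panels, warnings


def assign_max_expression_label(expression: pd.DataFrame) -> pd.DataFrame:
    """Label each gene with its arg-max expression group (cell type).

    ``expression`` is genes x groups.  Exact ties and all-zero genes are
    labelled unassigned; ties additionally carry a flag.
    """
    if expression.shape[1] < 2:
        raise ValueError("need at least two groups to assign labels")
    x = expression.to_numpy(float)
    top_idx = np.argmax(x, axis=1)
    top = x[np.arange(len(x)), top_idx]
    n_at_top = (x == top[:, None]).sum(axis=1)
    labels = expression.columns.to_numpy()[top_idx].astype(object)
    tie = n_at_top > 1
    zero = top == 0
    labels[tie | zero] = UNASSIGNED
    return pd.DataFrame(
        {"label": labels, "tie": tie, "all_zero": zero}, index=expression.index
    )


def panels_to_json(panels: dict[str, OrganPanel], path: str | Path) -> None:
    payload = {
        name: {"proteins": p.proteins, "provenance": p.provenance}
        for name, p in panels.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def panels_from_json(path: str | Path) -> dict[str, OrganPanel]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        name: OrganPanel(name, d["proteins"], d.get("provenance", {}))
        for name, d in payload.items()
    }
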