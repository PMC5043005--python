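"""Metagene scores: per-group mean scaled expression of a gene set.

Scaling is per gene, either anchored to the reference group (the
reference score is then exactly 0) or a global z-score over all samples
in the matrix.  Replicates are averaged first, then genes, so the
reported dispersion is a gene-level quantity.
"""

from __future__ import annotations

import logging

import pandas as pd

from .clustering import GeneSetCollection
from .qc import ExpressionMatrix

logger = logging.getLogger(__name__)

_SD_FLOOR = 1e-8


def _scale(x: ExpressionMatrix, scaling: str, reference: str) -> pd.DataFrame:
    vals = x.values
    if scaling == "reference_anchored":
        ref_ids = x.samples_for(reference)
        if not ref_ids:
            raise ValueError(f"no reference samples ({reference!r}) for reference_anchored scaling")
        mu = vals[ref_ids].mean(axis=1)
        sd = vals[ref_ids].std(axis=1, ddof=1).clip(lower=_SD_FLOOR)
    elif scaling == "global_z":
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1).clip(lower=_SD_FLOOR)
    else:
        raise ValueError("scaling must be 'reference_anchored' or 'global_z'")
    return vals.sub(mu, axis=0).div(sd, axis=0)


def metagene_scores(
    x: ExpressionMatrix,
    collection: GeneSetCollection | dict,
    groups: list | None = None,
    scaling: str = "reference_anchored",
    reference: str = "FH",
) -> pd.DataFrame:
    """Per-(set, group) metagene scores.

    ``groups`` is a list of (condition, day) pairs; by default every
    observed combination is scored.  Set members absent from the matrix
    are dropped and counted (``n_missing``); a set with no present member
    is an error.  Returns columns ``set, condition, day, score, n_genes,
    n_missing, dispersion``.
    """
    sets = collection.sets if isinstance(collection, GeneSetCollection) else collection
    if groups is None:
        groups = list(
            x.annotations[["condition", "day"]].drop_duplicates().itertuples(index=False, name=None)
        )
    scaled = _scale(x, scaling, reference)
    rows = []
    for name, members in sets.items():
        present = [g for g in members if g in scaled.index]
        n_missing = len(members) - len(present)
        if not present:
            raise ValueError(f"gene set {name!r} has no members in the matrix")
        if n_missing:
            logger.warning("set %r: %d members absent from matrix", name, n_missing)
        for condition, day in groups:
            ids = x.samples_for(condition, day)
            if not ids:
                raise ValueError(f"no samples in group ({condition!r}, {day!r})")
            per_gene = scaled.loc[present, ids].mean(axis=1)  # replicates first
            rows.append(
                (
                    name,
                    condition,
                    day,
                    float(per_gene.mean()),
                    len(present),
                    n_missing,
                    float(per_gene.std(ddof=1)) if len(present) > 1 else 0.0,
                )
            )
    return pd.DataFrame(
        rows, columns=["set", "condition", "day", "score", "n_genes", "n_missing", "dispersion"]
    )


def top_cluster_metagene(deg: pd.DataFrame, cluster_genes: list, k: int = 10) -> list:
    """The ``k`` cluster genes with largest |log2fc| at the anchor contrast.

    ``deg`` is a single-contrast DEG table (the anchor, e.g. day-1 M_C).
    Ties break by gene ID; fewer than ``k`` qualifying genes returns all
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = deg[deg["gene"].isin(set(cluster_genes))].copy()
    sub["abs_fc"] = sub["log2fc"].abs()
    sub = sub.sort_values(["abs_fc", "gene"], ascending=[False, True])
    if len(sub) < k:
        logger.warning("only %d of requested %d cluster genes available", len(sub), k)
    return list(sub["gene"].head(k))
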