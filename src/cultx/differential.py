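"""Per-contrast differential expression against a fresh-cell reference.

Each contrast compares one (condition, day) sample group with the
reference group using a Welch two-sample t-test on log2 values, adjusts
p-values within the contrast by Benjamini-Hochberg, and gates calls by
adjusted p < alpha AND |log2fc| >= log2(fold-change threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qc import ExpressionMatrix

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8

DEG_COLUMNS = ("gene", "condition", "day", "reference", "log2fc", "p_raw", "p_adj", "call")


@dataclass(frozen=True)
class Contrast:
    """A (condition, day) group vs the reference condition."""

    condition: str
    day: float
    reference: str = "FH"
    species: str | None = None

    def __post_init__(self) -> None:
        if self.condition == self.reference:
            raise ValueError("condition must differ from reference")

    @property
    def label(self) -> str:
        day = int(self.day) if float(self.day).is_integer() else self.day
        return f"{self.condition}_d{day}"


def _welch(group: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t-test per gene (rows); returns (t, p)."""
    n1, n2 = group.shape[1], ref.shape[1]
    m1, m2 = group.mean(axis=1), ref.mean(axis=1)
    v1 = np.maximum(group.var(axis=1, ddof=1), VARIANCE_FLOOR)
    v2 = np.maximum(ref.var(axis=1, ddof=1), VARIANCE_FLOOR)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def compute_deg(
    x: ExpressionMatrix,
    contrast: Contrast,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    strict_fc: bool = False,
) -> pd.DataFrame:
    """DEG table for one contrast.

    Returns a DataFrame with columns ``gene, condition, day, reference,
    log2fc, p_raw, p_adj, call`` where ``call`` is ``up``/``down``/``none``.
    ``strict_fc`` switches the fold-change gate from |log2fc| >= log2(fc)
    to a strict inequality.
    """
    group_ids = x.samples_for(contrast.condition, contrast.day, contrast.species)
    ref_ids = x.samples_for(contrast.reference, species=contrast.species)
    if not group_ids:
        raise ValueError(f"no samples for contrast group {contrast}")
    if not ref_ids:
        raise ValueError(f"no samples for reference {contrast.reference!r}")
    if len(group_ids) < 2 or len(ref_ids) < 2:
        raise ValueError("each group needs >= 2 replicates")

    group = x.values[group_ids].to_numpy(dtype=float)
    ref = x.values[ref_ids].to_numpy(dtype=float)
    if (group.var(axis=1, ddof=1) < VARIANCE_FLOOR).any() or (
        ref.var(axis=1, ddof=1) < VARIANCE_FLOOR
    ).any():
        logger.info("zero within-group variance floored at %g for some genes", VARIANCE_FLOOR)

    log2fc = group.mean(axis=1) - ref.mean(axis=1)
    _, p_raw = _welch(group, ref)
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")

    lfc_gate = np.log2(fc_threshold)
    passes = np.abs(log2fc) > lfc_gate if strict_fc else np.abs(log2fc) >= lfc_gate
    significant = (p_adj < alpha) & passes
    call = np.where(significant & (log2fc > 0), "up", np.where(significant, "down", "none"))

    table = pd.DataFrame(
        {
            "gene": x.gene_ids,
            "condition": contrast.condition,
            "day": contrast.day,
            "reference": contrast.reference,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "call": call,
        }
    )
    table.attrs["contrast"] = contrast
    return table


def count_degs_per_day(deg_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Up/down/total DEG counts per contrast, ordered by (condition, day)."""
    references = {t["reference"].iloc[0] for t in deg_tables if len(t)}
    if len(references) > 1:
        raise ValueError("contrasts must share the reference group")
    rows = []
    for t in deg_tables:
        if not len(t):
            rows.append(("", np.nan, 0, 0, 0))
            continue
        up = int((t["call"] == "up").sum())
        down = int((t["call"] == "down").sum())
        rows.append((t["condition"].iloc[0], t["day"].iloc[0], up, down, up + down))
    out = pd.DataFrame(rows, columns=["condition", "day", "up", "down", "total"])
    return out.sort_values(["condition", "day"]).reset_index(drop=True)


def top_ranked_genes(deg: pd.DataFrame, k: int, direction: str = "up") -> list[str]:
    """Genes called in ``direction``, ranked by |log2fc| descending.

    Ties are broken by gene ID; if fewer than ``k`` genes qualify all of
    them are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    qualifying = deg[deg["call"] == direction].copy()
    qualifying["abs_fc"] = qualifying["log2fc"].abs()
    qualifying = qualifying.sort_values(["abs_fc", "gene"], ascending=[False, True])
    if len(qualifying) < k:
        logger.warning("only %d genes qualify for top-%d %s ranking", len(qualifying), k, direction)
    return list(qualifying["gene"].head(k))


def ranking_overlap(a: list[str], b: list[str], ortholog_map: pd.DataFrame | None = None) -> dict:
    """Intersection / Jaccard of two ranked gene lists.

    When ``ortholog_map`` (columns ``gene_a``, ``gene_b``) is given, list
    ``b`` is translated from species-B IDs to species-A IDs first; genes
    without a mapping are dropped and counted.
    """
    if not a or not b:
        raise ValueError("gene lists must be non-empty")
    n_unmapped = 0
    if ortholog_map is not None:
        translate = dict(zip(ortholog_map["gene_b"], ortholog_map["gene_a"]))
        translated = [translate.get(g) for g in b]
        n_unmapped = sum(1 for g in translated if g is None)
        b = [g for g in translated if g is not None]
    set_a, set_b = set(a), set(b)
    inter = len(set_a & set_b)
    union = len(set_a | set_b)
    return {
        "intersection": inter,
        "jaccard": inter / union if union else 0.0,
        "n_a": len(set_a),
        "n_b": len(set_b),
        "n_unmapped": n_unmapped,
    }
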