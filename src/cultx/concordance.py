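"""Cross-model and cross-species concordance of fold changes.

Covers Spearman correlation between two DEG tables, sign-coincidence
odds ratios (2x2 up/down agreement tables with Fisher exact p), the
time-resolved odds-ratio series, orthologue pairing, fold-change
quadrant assignment and per-quadrant motif overrepresentation and
metagenes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import GeneSetCollection, overrepresentation
from .metagene import metagene_scores
from .qc import ExpressionMatrix

logger = logging.getLogger(__name__)

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class CoincidenceTable:
    """2x2 sign-agreement counts between two comparisons."""

    n_uu: int
    n_ud: int
    n_du: int
    n_dd: int
    odds_ratio: float
    p: float
    universe_policy: str

    @property
    def n(self) -> int:
        return self.n_uu + self.n_ud + self.n_du + self.n_dd

    @property
    def log_odds_ratio(self) -> float:
        return float(np.log(self.odds_ratio))


def _merge_tables(
    deg_a: pd.DataFrame, deg_b: pd.DataFrame, ortholog_map: pd.DataFrame | None = None
) -> pd.DataFrame:
    a = deg_a[["gene", "log2fc", "call"]].rename(
        columns={"log2fc": "log2fc_a", "call": "call_a"}
    )
    b = deg_b[["gene", "log2fc", "call"]].rename(
        columns={"log2fc": "log2fc_b", "call": "call_b"}
    )
    if ortholog_map is not None:
        translate = dict(zip(ortholog_map["gene_b"], ortholog_map["gene_a"]))
        b = b.assign(gene=b["gene"].map(translate)).dropna(subset=["gene"])
    return a.merge(b, on="gene")


def foldchange_correlation(
    deg_a: pd.DataFrame,
    deg_b: pd.DataFrame,
    gene_policy: str = "union_deg",
    ortholog_map: pd.DataFrame | None = None,
) -> tuple[float, float, int]:
    """Spearman correlation of paired log2 fold changes.

    ``gene_policy`` selects the gene universe: ``union_deg`` (called in
    either table), ``intersection_deg`` (called in both) or ``all``.
    Returns (rho, p, n).
    """
    merged = _merge_tables(deg_a, deg_b, ortholog_map)
    if gene_policy == "union_deg":
        merged = merged[(merged["call_a"] != "none") | (merged["call_b"] != "none")]
    elif gene_policy == "intersection_deg":
        merged = merged[(merged["call_a"] != "none") & (merged["call_b"] != "none")]
    elif gene_policy != "all":
        raise ValueError("gene_policy must be union_deg, intersection_deg or all")
    if len(merged) < 3:
        raise ValueError(f"too few paired genes (n={len(merged)}) for correlation")
    rho, p = stats.spearmanr(merged["log2fc_a"], merged["log2fc_b"])
    return float(rho), float(p), len(merged)


def coincidence_odds_ratio(
    deg_a: pd.DataFrame,
    deg_b: pd.DataFrame,
    universe: str = "shared_deg",
    ortholog_map: pd.DataFrame | None = None,
) -> CoincidenceTable:
    """Odds ratio of coincident up/down calls between two DEG tables.

    ``universe="shared_deg"`` (default) restricts to genes called up or
    down in *both* tables and tabulates sign agreement.  The alternative
    ``universe="all"`` tabulates deregulated-vs-not over all shared genes.
    The OR uses a Haldane-Anscombe +0.5 correction when any cell is zero;
    p is two-sided Fisher exact on the uncorrected table.
    """
    merged = _merge_tables(deg_a, deg_b, ortholog_map)
    if universe == "shared_deg":
        merged = merged[(merged["call_a"] != "none") & (merged["call_b"] != "none")]
        if not len(merged):
            raise ValueError("no genes called in both comparisons")
        n_uu = int(((merged["call_a"] == "up") & (merged["call_b"] == "up")).sum())
        n_ud = int(((merged["call_a"] == "up") & (merged["call_b"] == "down")).sum())
        n_du = int(((merged["call_a"] == "down") & (merged["call_b"] == "up")).sum())
        n_dd = int(((merged["call_a"] == "down") & (merged["call_b"] == "down")).sum())
    elif universe == "all":
        if not len(merged):
            raise ValueError("no shared genes")
        a_deg = merged["call_a"] != "none"
        b_deg = merged["call_b"] != "none"
        n_uu = int((a_deg & b_deg).sum())
        n_ud = int((a_deg & ~b_deg).sum())
        n_du = int((~a_deg & b_deg).sum())
        n_dd = int((~a_deg & ~b_deg).sum())
    else:
        raise ValueError("universe must be 'shared_deg' or 'all'")
    table = np.array([[n_uu, n_ud], [n_du, n_dd]], dtype=float)
    if (table == 0).any():
        table = table + 0.5
    odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
    _, p = stats.fisher_exact([[n_uu, n_ud], [n_du, n_dd]], alternative="two-sided")
    return CoincidenceTable(n_uu, n_ud, n_du, n_dd, float(odds), float(p), universe)


def odds_ratio_timecourse(
    degs_by_day: list[pd.DataFrame],
    disease: pd.DataFrame,
    universe: str = "shared_deg",
    ortholog_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Coincidence odds ratio of each culture day against one disease table.

    Per-day failures (e.g. no shared DEGs) become NaN rows with a warning
    rather than aborting the series.
    """
    if len(degs_by_day) < 1:
        raise ValueError("need at least one culture-day DEG table")
    rows = []
    for t in degs_by_day:
        day = t["day"].iloc[0]
        try:
            ct = coincidence_odds_ratio(t, disease, universe=universe, ortholog_map=ortholog_map)
            rows.append((day, ct.n_uu, ct.n_ud, ct.n_du, ct.n_dd, ct.odds_ratio, ct.p))
        except ValueError as err:
            logger.warning("day %s skipped: %s", day, err)
            rows.append((day, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["day", "n_uu", "n_ud", "n_du", "n_dd", "odds_ratio", "p"])
    return out.sort_values("day").reset_index(drop=True)


def map_orthologs(
    deg_a: pd.DataFrame, deg_b: pd.DataFrame, ortholog_map: pd.DataFrame
) -> pd.DataFrame:
    """Join two species' DEG tables through a one-to-one orthologue map.

    Rows of the map with a duplicated gene on either side (many-to-many)
    are dropped and counted; unmatched genes are counted.  Returns a pair
    table with columns ``gene_a, gene_b, log2fc_a, log2fc_b, call_a,
    call_b`` and bookkeeping in ``attrs``.
    """
    omap = ortholog_map[["gene_a", "gene_b"]].copy()
    dup = omap["gene_a"].duplicated(keep=False) | omap["gene_b"].duplicated(keep=False)
    n_dropped = int(dup.sum())
    omap = omap[~dup]
    a = deg_a.set_index("gene")[["log2fc", "call"]]
    b = deg_b.set_index("gene")[["log2fc", "call"]]
    pairs = omap[omap["gene_a"].isin(a.index) & omap["gene_b"].isin(b.index)].copy()
    if not len(pairs):
        raise ValueError("no orthologue pairs resolve against both DEG tables")
    pairs["log2fc_a"] = a.loc[pairs["gene_a"], "log2fc"].to_numpy()
    pairs["call_a"] = a.loc[pairs["gene_a"], "call"].to_numpy()
    pairs["log2fc_b"] = b.loc[pairs["gene_b"], "log2fc"].to_numpy()
    pairs["call_b"] = b.loc[pairs["gene_b"], "call"].to_numpy()
    pairs = pairs.reset_index(drop=True)
    pairs.attrs["n_many_to_many_dropped"] = n_dropped
    pairs.attrs["n_unmatched"] = len(omap) - len(pairs)
    return pairs


def assign_quadrants(pairs: pd.DataFrame, fc_threshold: float = 2.0) -> pd.DataFrame:
    """Label orthologue pairs by joint fold-change quadrant.

    Q1 both up, Q3 both down, Q2 A-down/B-up, Q4 A-up/B-down; any pair
    below |log2fc| >= log2(fc_threshold) in either species is
    ``unassigned``.  Returns a copy of ``pairs`` with a ``quadrant``
    column; the labels partition all pairs.
    """
    thr = np.log2(fc_threshold)
    fa = pairs["log2fc_a"].to_numpy(dtype=float)
    fb = pairs["log2fc_b"].to_numpy(dtype=float)
    quad = np.full(len(pairs), "unassigned", dtype=object)
    quad[(fa >= thr) & (fb >= thr)] = "Q1"
    quad[(fa <= -thr) & (fb >= thr)] = "Q2"
    quad[(fa <= -thr) & (fb <= -thr)] = "Q3"
    quad[(fa >= thr) & (fb <= -thr)] = "Q4"
    out = pairs.copy()
    out["quadrant"] = quad
    return out


def quadrant_enrichment(
    assignment: pd.DataFrame, motif_sets: GeneSetCollection | dict
) -> pd.DataFrame:
    """Overrepresentation of each motif set in each quadrant.

    Motif sets are defined on species-A IDs; the universe is every pair
    (assigned or not).  BH adjustment is applied jointly across
    (quadrant x set).  Empty quadrants are skipped with a note.
    """
    universe = list(assignment["gene_a"])
    sets = motif_sets.sets if isinstance(motif_sets, GeneSetCollection) else motif_sets
    collection = GeneSetCollection.restricted(sets, universe)
    frames = []
    for quadrant in QUADRANTS:
        query = list(assignment.loc[assignment["quadrant"] == quadrant, "gene_a"])
        if not query:
            logger.info("quadrant %s empty; skipped", quadrant)
            continue
        table = overrepresentation(query, collection)
        table.insert(0, "quadrant", quadrant)
        frames.append(table)
    if not frames:
        return pd.DataFrame(
            columns=["quadrant", "set", "overlap", "set_size", "expected", "odds_ratio", "p_raw", "p_adj"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["p_adj"] = multipletests(out["p_raw"], method="fdr_bh")[1]  # joint BH
    return out


def quadrant_metagenes(
    assignment: pd.DataFrame,
    x_a: ExpressionMatrix,
    x_b: ExpressionMatrix,
    k: int = 10,
    groups_a: list | None = None,
    groups_b: list | None = None,
    scaling: str = "reference_anchored",
    reference: str = "FH",
) -> dict:
    """Top-k quadrant metagene scores in both species.

    Within each non-empty quadrant, pairs are ranked by the sum of their
    per-species |log2fc| ranks (rank 1 = largest) and the top ``k`` form
    the metagene set, scored in both species' matrices.  Returns
    ``{quadrant: {"genes_a", "genes_b", "scores_a", "scores_b"}}``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    results = {}
    for quadrant in QUADRANTS:
        sub = assignment[assignment["quadrant"] == quadrant]
        if not len(sub):
            continue
        rank_a = sub["log2fc_a"].abs().rank(ascending=False, method="average")
        rank_b = sub["log2fc_b"].abs().rank(ascending=False, method="average")
        order = (rank_a + rank_b).sort_values(kind="stable")
        top = sub.loc[order.index[: min(k, len(sub))]]
        genes_a, genes_b = list(top["gene_a"]), list(top["gene_b"])
        scores_a = metagene_scores(
            x_a, {quadrant: genes_a}, groups=groups_a, scaling=scaling, reference=reference
        )
        scores_b = metagene_scores(
            x_b, {quadrant: genes_b}, groups=groups_b, scaling=scaling, reference=reference
        )
        results[quadrant] = {
            "genes_a": genes_a,
            "genes_b": genes_b,
            "scores_a": scores_a,
            "scores_b": scores_b,
        }
    return results
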