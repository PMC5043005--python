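"""Fuzzy c-means clustering of time-dependent fold-change profiles,
cluster-count selection, gene-set overrepresentation and motif labelling.

The fuzzy c-means implementation is self-contained (alternating
membership/center updates with Euclidean distance, multiple restarts,
objective traces) so its convergence behaviour can be asserted directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def build_profiles(
    deg_tables: list[pd.DataFrame],
    gene_filter: str = "any-contrast-DEG",
    include_baseline: bool = False,
) -> pd.DataFrame:
    """Per-gene z-scaled log2fc profiles over the (condition, day) grid.

    Rows are genes, columns are contrast labels ``<condition>_d<day>``.
    ``gene_filter="any-contrast-DEG"`` keeps genes called up/down in at
    least one contrast; ``"all"`` keeps every gene.  Rows are scaled to
    mean 0 / SD 1 (ddof=1); zero-variance rows are excluded and counted in
    ``profiles.attrs["n_excluded"]``.

    ``include_baseline`` prepends a ``<condition>_d0`` column of zeros per
    condition (the fold change at the reference timepoint).  This anchors
    each trajectory at the reference state, so after scaling a transiently
    induced gene is distinguishable from a monotonically repressed one.
    """
    if gene_filter not in ("any-contrast-DEG", "all"):
        raise ValueError("gene_filter must be 'any-contrast-DEG' or 'all'")
    if not deg_tables:
        raise ValueError("no DEG tables given")
    days = {(t["condition"].iloc[0], t["day"].iloc[0]) for t in deg_tables}
    if len({d for _, d in days}) < 2:
        raise ValueError("profiles need contrasts covering >= 2 timepoints")

    wide = {}
    called = pd.Series(False, index=deg_tables[0]["gene"])
    for t in deg_tables:
        day = t["day"].iloc[0]
        day = int(day) if float(day).is_integer() else day
        label = f"{t['condition'].iloc[0]}_d{day}"
        wide[label] = t.set_index("gene")["log2fc"]
        called |= (t.set_index("gene")["call"] != "none").reindex(called.index, fill_value=False)
    profiles = pd.DataFrame(wide)
    if include_baseline:
        conditions = {t["condition"].iloc[0] for t in deg_tables}
        for cond in sorted(conditions):
            profiles.insert(0, f"{cond}_d0", 0.0)
    if gene_filter == "any-contrast-DEG":
        profiles = profiles.loc[called[called].index]
    if profiles.empty:
        raise ValueError("no genes left after filtering")

    sd = profiles.std(axis=1, ddof=1)
    keep = sd > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluded %d zero-variance profiles", n_excluded)
    profiles = profiles.loc[keep]
    if profiles.empty:
        raise ValueError("all profiles have zero variance")
    scaled = profiles.sub(profiles.mean(axis=1), axis=0).div(sd[keep], axis=0)
    scaled.attrs["n_excluded"] = n_excluded
    return scaled


# ---------------------------------------------------------------------------
# fuzzy c-means
# ---------------------------------------------------------------------------

@dataclass
class FuzzyClustering:
    """Result of fuzzy c-means: soft memberships plus hard assignments."""

    c: int
    m: float
    centers: np.ndarray  # c x profile-length
    membership: pd.DataFrame  # genes x c
    objective: float
    objective_trace: list = field(default_factory=list)
    converged: bool = True
    membership_min: float = 0.5

    @property
    def hard_label(self) -> pd.Series:
        return self.membership.idxmax(axis=1)

    @property
    def core_flag(self) -> pd.Series:
        return self.membership.max(axis=1) >= self.membership_min

    def core_genes(self, cluster) -> list[str]:
        mask = (self.hard_label == cluster) & self.core_flag
        return list(self.membership.index[mask])


def _fcm_once(x: np.ndarray, c: int, m: float, tol: float, max_iter: int, rng) -> tuple:
    n = x.shape[0]
    u = rng.random((n, c))
    u /= u.sum(axis=1, keepdims=True)
    trace = []
    converged = False
    exponent = 2.0 / (m - 1.0)
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = cdist(x, centers, "sqeuclidean")
        d2 = np.maximum(d2, 1e-12)
        # normalise by the row minimum so small fuzzifiers cannot overflow:
        # u_ij = 1 / sum_k (d_ij / d_ik)^{2/(m-1)}
        ratio = d2 / d2.min(axis=1, keepdims=True)
        inv = ratio ** (-exponent / 2.0)
        u_new = inv / inv.sum(axis=1, keepdims=True)
        trace.append(float(((u_new**m) * d2).sum()))
        shift = np.abs(u_new - u).max()
        u = u_new
        if shift < tol:
            converged = True
            break
    return u, centers, trace, converged


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_restarts: int = 10,
    seed: int = 0,
    membership_min: float = 0.5,
) -> FuzzyClustering:
    """Standard fuzzy c-means on profile rows, best of ``n_restarts``.

    Deterministic for a fixed seed.  Non-convergence within ``max_iter``
    is reported via ``converged=False`` and a warning, not an error.
    """
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if len(profiles) < c:
        raise ValueError("need at least c profiles")
    x = profiles.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        u, centers, trace, conv = _fcm_once(x, c, m, tol, max_iter, rng)
        if best is None or trace[-1] < best[2][-1]:
            best = (u, centers, trace, conv)
    u, centers, trace, conv = best
    if not conv:
        warnings.warn("fuzzy c-means did not converge within max_iter", RuntimeWarning)
    membership = pd.DataFrame(u, index=profiles.index, columns=range(c))
    return FuzzyClustering(
        c=c,
        m=m,
        centers=centers,
        membership=membership,
        objective=trace[-1],
        objective_trace=trace,
        converged=conv,
        membership_min=membership_min,
    )


def select_cluster_count(
    profiles: pd.DataFrame,
    c_range,
    m: float = 2.0,
    seed: int = 0,
    **fcm_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Scan cluster counts; report partition coefficient and Xie-Beni index.

    The chosen ``c`` minimises the Xie-Beni index (compactness over
    separation); the full per-c table is returned for inspection.
    """
    c_range = list(c_range)
    if not c_range:
        raise ValueError("empty c_range")
    rows = []
    x = profiles.to_numpy(dtype=float)
    for c in c_range:
        fit = fuzzy_cmeans(profiles, c=c, m=m, seed=seed, **fcm_kwargs)
        pc = float((fit.membership.to_numpy() ** 2).sum() / len(profiles))
        sep = cdist(fit.centers, fit.centers, "sqeuclidean")
        np.fill_diagonal(sep, np.inf)
        xb = fit.objective / (len(x) * sep.min()) if np.isfinite(sep.min()) else np.inf
        rows.append((c, pc, xb, fit.objective))
    table = pd.DataFrame(rows, columns=["c", "partition_coefficient", "xie_beni", "objective"])
    chosen = int(table.loc[table["xie_beni"].idxmin(), "c"])
    return chosen, table


def split_rescued(
    raw_profiles: pd.DataFrame,
    cluster_genes: list[str],
    rescue_condition: str = "S",
    anchor_condition: str = "M_C",
) -> tuple[list[str], list[str]]:
    """Post-hoc sub-cluster split by condition-specific attenuation.

    A gene counts as "rescued" when its mean |log2fc| across the
    rescue-condition columns is below half its mean |log2fc| across the
    anchor-condition columns.  ``raw_profiles`` must be unscaled log2fc
    with ``<condition>_d<day>`` columns.
    """
    rescue_cols = [c for c in raw_profiles.columns if c.startswith(f"{rescue_condition}_d")]
    anchor_cols = [c for c in raw_profiles.columns if c.startswith(f"{anchor_condition}_d")]
    if not rescue_cols or not anchor_cols:
        raise ValueError("profiles lack rescue or anchor condition columns")
    sub = raw_profiles.loc[[g for g in cluster_genes if g in raw_profiles.index]]
    rescue_mag = sub[rescue_cols].abs().mean(axis=1)
    anchor_mag = sub[anchor_cols].abs().mean(axis=1)
    rescued = rescue_mag < 0.5 * anchor_mag
    return list(sub.index[rescued]), list(sub.index[~rescued])


# ---------------------------------------------------------------------------
# overrepresentation
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are drawn from."""

    sets: dict
    universe: list

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ValueError("duplicate genes in universe")
        for name, members in self.sets.items():
            extra = set(members) - uni
            if extra:
                raise ValueError(f"set {name!r} has members outside the universe: {sorted(extra)[:3]}")

    @classmethod
    def restricted(cls, sets: dict, universe: list) -> "GeneSetCollection":
        """Build a collection, silently dropping members outside the universe."""
        uni = set(universe)
        return cls({n: [g for g in m if g in uni] for n, m in sets.items()}, list(universe))


def overrepresentation(query: list, collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of each set in the query.

    Returns a DataFrame with columns ``set, overlap, set_size, expected,
    odds_ratio, p_raw, p_adj`` (BH across sets).  The odds ratio comes from
    the 2x2 query/set table with a Haldane-Anscombe +0.5 correction when
    any cell is zero.
    """
    if not query:
        raise ValueError("empty query")
    if not collection.universe:
        raise ValueError("empty universe")
    uni = set(collection.universe)
    stray = set(query) - uni
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:3]}")
    qset = set(query)
    n_universe, n_query = len(uni), len(qset)
    rows = []
    for name, members in collection.sets.items():
        mset = set(members)
        k = len(qset & mset)
        big_k = len(mset)
        p = stats.hypergeom.sf(k - 1, n_universe, big_k, n_query)
        a, b = k, n_query - k
        c_, d = big_k - k, n_universe - big_k - (n_query - k)
        if min(a, b, c_, d) == 0:
            a, b, c_, d = a + 0.5, b + 0.5, c_ + 0.5, d + 0.5
        rows.append((name, k, big_k, n_query * big_k / n_universe, (a * d) / (b * c_), p))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "expected", "odds_ratio", "p_raw"])
    if len(table):
        table["p_adj"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    else:
        table["p_adj"] = []
    return table.sort_values("p_raw").reset_index(drop=True)


def assign_motifs(
    clustering: FuzzyClustering,
    enrichments: dict,
    motif_rules: dict,
    alpha: float = 0.05,
) -> dict:
    """Label each cluster with the motif whose rule sets enrich best.

    ``enrichments`` maps cluster -> overrepresentation table; ``motif_rules``
    maps motif name -> list of set names diagnostic for it.  A cluster gets
    the motif with the smallest adjusted p among its rule sets (ties broken
    by larger odds ratio); clusters where no rule passes ``alpha`` stay
    unlabelled (``None``).
    """
    labels = {}
    for cluster in clustering.membership.columns:
        table = enrichments.get(cluster)
        best = None  # (p_adj, -odds_ratio, motif)
        if table is not None and len(table):
            indexed = table.set_index("set")
            for motif, set_names in motif_rules.items():
                hits = indexed.loc[[s for s in set_names if s in indexed.index]]
                if not len(hits):
                    continue
                row = hits.sort_values(["p_adj", "odds_ratio"], ascending=[True, False]).iloc[0]
                if row["p_adj"] >= alpha:
                    continue
                key = (row["p_adj"], -row["odds_ratio"], motif)
                if best is None or key[:2] < best[:2]:
                    best = key
        labels[cluster] = best[2] if best else None
    return labels
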