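"""Expression-matrix container, outlier flagging, variance filtering and PCA.

The :class:`ExpressionMatrix` is the common currency of the pipeline: a
log2-scale genes x samples table plus a per-sample annotation frame with
``condition``, ``day``, ``replicate``, ``species`` and ``model_type``
columns.  All downstream stages (differential calling, clustering,
metagenes, concordance) consume it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SKPCA

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("condition", "day", "replicate", "species", "model_type")


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID, one column per sample ID.
    annotations
        DataFrame indexed by sample ID with columns ``condition`` (label),
        ``day`` (number), ``replicate`` (index), ``species`` (label) and
        ``model_type`` (``culture`` / ``in_vivo`` / ``reference``).
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene IDs")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs")
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.annotations.columns]
        if missing:
            raise ValueError(f"annotation columns missing: {missing}")
        unannotated = self.values.columns.difference(self.annotations.index)
        if len(unannotated):
            raise ValueError(f"samples without annotation: {list(unannotated)[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite expression values")
        # keep annotations aligned to the column order
        self.annotations = self.annotations.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(self.values[sample_ids], self.annotations.loc[sample_ids].copy())

    def filter(self, **criteria) -> "ExpressionMatrix":
        """Subset samples by annotation equality, e.g. ``filter(species="A")``."""
        mask = pd.Series(True, index=self.annotations.index)
        for key, value in criteria.items():
            mask &= self.annotations[key] == value
        return self.subset_samples(self.annotations.index[mask])

    def samples_for(self, condition=None, day=None, species=None) -> list[str]:
        ann = self.annotations
        mask = pd.Series(True, index=ann.index)
        if condition is not None:
            mask &= ann["condition"] == condition
        if day is not None:
            mask &= ann["day"] == day
        if species is not None:
            mask &= ann["species"] == species
        return list(ann.index[mask])


@dataclass
class PCAResult:
    """Sample scores, gene loadings and per-component variance fractions."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # genes x components
    variance_fraction: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if np.any(np.diff(vf) > 1e-9):
            raise ValueError("variance fractions must be non-increasing")
        if vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions sum above 1")


def select_high_variance_genes(x: ExpressionMatrix, k: int) -> list[str]:
    """The ``k`` genes with largest per-gene sample variance.

    Ties are broken by input order (stable sort), so a constant matrix
    returns the first ``k`` genes as listed.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > x.n_genes:
        raise ValueError(f"k={k} exceeds number of genes ({x.n_genes})")
    variances = x.values.var(axis=1, ddof=1).to_numpy()
    order = np.argsort(-variances, kind="stable")
    return list(x.gene_ids[order[:k]])


def pca(x: ExpressionMatrix, genes=None, n_components: int = 2) -> PCAResult:
    """Gene-centered PCA of the (optionally gene-subset) matrix.

    No unit-variance scaling is applied.  Component orientation is fixed by
    making the largest-absolute gene loading positive.
    """
    if x.n_samples < 2:
        raise ValueError("PCA requires at least two samples")
    sub = x.values if genes is None else x.values.loc[list(genes)]
    n_components = int(n_components)
    if n_components > min(sub.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    data = sub.to_numpy(dtype=float).T  # samples x genes
    model = _SKPCA(n_components=n_components, svd_solver="full")
    with np.errstate(invalid="ignore"):
        scores = model.fit_transform(data)
    variance_fraction = np.nan_to_num(model.explained_variance_ratio_, nan=0.0)
    loadings = model.components_.T  # genes x components
    # sign convention: largest-|loading| entry positive per component
    for j in range(n_components):
        anchor = np.argmax(np.abs(loadings[:, j]))
        if loadings[anchor, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=sub.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=sub.index, columns=comp_names),
        variance_fraction=variance_fraction,
    )


def _pairwise_mean_correlation(values: np.ndarray) -> np.ndarray:
    """Per-column mean Pearson correlation to the other columns."""
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values.T)
    corr = np.nan_to_num(corr, nan=0.0)
    n = corr.shape[0]
    np.fill_diagonal(corr, 0.0)
    return corr.sum(axis=1) / (n - 1)


_LOO_SD_FLOOR = 1e-6


def _loo_low_outliers(stat: np.ndarray, z_threshold: float) -> np.ndarray:
    """Indices whose value is z_threshold leave-one-out SDs below the rest.

    Leave-one-out mean/SD avoids the masking effect: with an outlier
    included in the group statistics the largest attainable z-score in a
    group of n is (n-1)/sqrt(n), so small replicate groups could never
    trip a z=2..3 threshold.
    """
    n = len(stat)
    full_sd = stat.std(ddof=1)
    out = []
    for i in range(n):
        rest = np.delete(stat, i)
        # a leave-one-out SD of fewer than 3 values is too unstable; fall
        # back to the (conservative, outlier-inflated) full-group SD there
        sd = rest.std(ddof=1) if len(rest) >= 3 else full_sd
        sd = max(sd, _LOO_SD_FLOOR)
        if stat[i] < rest.mean() - z_threshold * sd:
            out.append(i)
    return np.array(out, dtype=int)


def flag_outlier_samples(x: ExpressionMatrix, z_threshold: float = 3.0) -> list[str]:
    """Flag replicate-group outliers by correlation and PCA distance.

    Within every (species, condition, day) group of at least three samples a
    sample is flagged when its mean Pearson correlation to the other group
    members falls more than ``z_threshold`` SDs (leave-one-out) below the
    rest of the group, or when its distance from the group centroid in the
    top-2 PCA plane exceeds the others' distances by more than
    ``z_threshold`` leave-one-out SDs.  Groups smaller than three are
    skipped with a warning.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    pc = pca(x, n_components=min(2, x.n_samples - 1, x.n_genes))
    flagged: set[str] = set()
    for key, group in x.annotations.groupby(["species", "condition", "day"], sort=False):
        samples = list(group.index)
        if len(samples) < 3:
            logger.warning("outlier check skipped for group %s (n=%d < 3)", key, len(samples))
            continue
        vals = x.values[samples].to_numpy(dtype=float)
        stat = _pairwise_mean_correlation(vals)
        for i in _loo_low_outliers(stat, z_threshold):
            flagged.add(samples[i])
        coords = pc.scores.loc[samples].to_numpy()
        dist = np.linalg.norm(coords - coords.mean(axis=0), axis=1)
        for i in _loo_low_outliers(-dist, z_threshold):
            flagged.add(samples[i])
    return sorted(flagged)
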