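"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from cultx import ExpressionMatrix


def make_deg_table(genes, log2fc, day, condition="M_C", calls=None, reference="FH"):
    """Hand-built single-contrast DEG table."""
    log2fc = np.asarray(log2fc, dtype=float)
    if calls is None:
        calls = np.where(np.abs(log2fc) >= 1, np.where(log2fc > 0, "up", "down"), "none")
    return pd.DataFrame(
        {
            "gene": list(genes),
            "condition": condition,
            "day": day,
            "reference": reference,
            "log2fc": log2fc,
            "p_raw": 0.001,
            "p_adj": 0.01,
            "call": calls,
        }
    )


def make_matrix(values, conditions, days, species=None, replicates=None):
    """ExpressionMatrix from a genes x samples array plus per-sample metadata."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{i:03d}" for i in range(n_samples)]
    species = species or ["A"] * n_samples
    replicates = replicates or list(range(1, n_samples + 1))
    ann = pd.DataFrame(
        {
            "condition": conditions,
            "day": days,
            "replicate": replicates,
            "species": species,
            "model_type": ["reference" if c == "FH" else "culture" for c in conditions],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), ann)


def two_group_matrix(group, ref):
    """Matrix with one condition group (M_C day 1) and an FH reference."""
    group = np.asarray(group, dtype=float)
    ref = np.asarray(ref, dtype=float)
    values = np.concatenate([group, ref], axis=1)
    conditions = ["M_C"] * group.shape[1] + ["FH"] * ref.shape[1]
    days = [1] * group.shape[1] + [0] * ref.shape[1]
    return make_matrix(values, conditions, days)
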