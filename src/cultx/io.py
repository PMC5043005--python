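"""Plain-text readers/writers for the pipeline's file interfaces.

Formats: expression + annotation TSV, DEG tables, GMT gene sets,
two-column orthologue maps, YAML/JSON simulation configs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .clustering import GeneSetCollection
from .qc import ExpressionMatrix
from .simulate import DiseaseSpec, SimulationConfig, SyntheticDataset


def write_expression(x: ExpressionMatrix, expr_path, annot_path) -> None:
    x.values.to_csv(expr_path, sep="\t", index_label="gene")
    x.annotations.to_csv(annot_path, sep="\t", index_label="sample_id")


def read_expression(expr_path, annot_path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    annotations = pd.read_csv(annot_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, annotations)


def write_deg_table(deg: pd.DataFrame, path) -> None:
    deg.to_csv(path, sep="\t", index=False)


def read_deg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(sets: dict, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description or name, *members]) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_gene_set_collection(gmt_path, universe: list) -> GeneSetCollection:
    return GeneSetCollection.restricted(read_gmt(gmt_path), universe)


def write_ortholog_map(omap: pd.DataFrame, path) -> None:
    omap[["gene_a", "gene_b"]].to_csv(path, sep="\t", index=False)


def read_ortholog_map(path) -> pd.DataFrame:
    omap = pd.read_csv(path, sep="\t")
    if not {"gene_a", "gene_b"}.issubset(omap.columns):
        raise ValueError("ortholog map needs 'gene_a' and 'gene_b' columns")
    return omap


def config_to_dict(config: SimulationConfig) -> dict:
    data = {
        "n_genes": config.n_genes,
        "motif_sizes": dict(config.motif_sizes),
        "n_replicates": config.n_replicates,
        "timepoints": list(config.timepoints),
        "conditions": list(config.conditions),
        "disease_conditions": [
            {"name": d.name, "rho_target": d.rho_target, "n_replicates": d.n_replicates}
            for d in config.disease_conditions
        ],
        "noise_sd": config.noise_sd,
        "effect_size_log2": config.effect_size_log2,
        "ortholog_discordant_fraction": config.ortholog_discordant_fraction,
        "species_labels": list(config.species_labels),
        "baseline_mean": config.baseline_mean,
        "baseline_sd": config.baseline_sd,
        "seed": config.seed,
    }
    return data


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    if "disease_conditions" in data:
        data["disease_conditions"] = tuple(
            DiseaseSpec(**d) if isinstance(d, dict) else d for d in data["disease_conditions"]
        )
    for key in ("timepoints", "conditions", "species_labels"):
        if key in data:
            data[key] = tuple(data[key])
    return SimulationConfig(**data)


def read_config(path) -> SimulationConfig:
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return config_from_dict(data)


def write_config(config: SimulationConfig, path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write a synthetic dataset's text artefacts; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_expression(ds.expression, paths["expression"], paths["annotations"])
    ds.truth.rename("motif").to_csv(paths["truth"], sep="\t", index_label="gene")
    if ds.ortholog_map is not None:
        paths["orthologs"] = outdir / "orthologs.tsv"
        write_ortholog_map(ds.ortholog_map, paths["orthologs"])
    if ds.true_disease_fc is not None:
        paths["true_disease_fc"] = outdir / "true_disease_fc.tsv"
        ds.true_disease_fc.to_csv(paths["true_disease_fc"], sep="\t", index_label="gene")
    return paths
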