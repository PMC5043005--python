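"""Synthetic two-species time-course expression data with planted structure.

Generates log2 expression matrices that mimic a cultured-cell experiment:
a fresh-cell reference group at day 0, several culture conditions sampled
over a day grid, optional "disease" conditions whose gene-level fold
changes correlate with the day-1 culture response at a configurable
strength, and a one-to-one orthologue map between two synthetic species
with a configurable fraction of sign-discordant genes.

Gene-level truth (motif labels, true disease fold changes, flipped
orthologues) is carried alongside the expression matrix so downstream
stages can be validated against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .qc import ExpressionMatrix

MOTIFS = (
    "metabolism_down_rescued",
    "metabolism_down_unrescued",
    "inflammation_transient",
    "inflammation_persistent",
    "cellcycle",
    "cholesterol_speciesA_only",
    "background",
)

#: culture condition whose metabolism_down_rescued response is attenuated
RESCUE_CONDITION = "S"
RESCUE_FACTOR = 0.5

REFERENCE_CONDITION = "FH"


@dataclass(frozen=True)
class DiseaseSpec:
    """A disease-like condition with target correlation to day-1 culture."""

    name: str
    rho_target: float
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if abs(self.rho_target) > 1:
            raise ValueError(f"|rho_target| > 1 for {self.name}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 2000
    motif_sizes: dict = field(
        default_factory=lambda: {
            "metabolism_down_rescued": 100,
            "metabolism_down_unrescued": 100,
            "inflammation_transient": 100,
            "inflammation_persistent": 100,
            "cellcycle": 100,
            "cholesterol_speciesA_only": 100,
        }
    )
    n_replicates: int = 3
    timepoints: tuple = (0, 1, 2, 3, 5, 7)
    conditions: tuple = ("M_C", "M_S", "S")
    disease_conditions: tuple = ()  # of DiseaseSpec
    noise_sd: float = 0.3
    effect_size_log2: float | dict = 2.0
    ortholog_discordant_fraction: float = 0.0
    species_labels: tuple = ("A", "B")
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        unknown = set(self.motif_sizes) - set(MOTIFS)
        if unknown:
            raise ValueError(f"unknown motif names: {sorted(unknown)}")
        if any(v <= 0 for v in self.motif_sizes.values()):
            raise ValueError("motif sizes must be positive")
        if sum(self.motif_sizes.values()) > self.n_genes:
            raise ValueError("motif sizes sum exceeds n_genes")
        if not len(self.timepoints):
            raise ValueError("timepoints must be non-empty")
        if 0 not in self.timepoints:
            raise ValueError("timepoint 0 (fresh-cell reference) is required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.ortholog_discordant_fraction <= 1:
            raise ValueError("ortholog_discordant_fraction must be in [0, 1]")
        if len(self.species_labels) != 2:
            raise ValueError("exactly two species labels required")
        if self.disease_conditions and 1 not in self.timepoints:
            raise ValueError("disease conditions anchor on day 1; include it in timepoints")
        for spec in self.disease_conditions:
            if not isinstance(spec, DiseaseSpec):
                raise TypeError("disease_conditions must contain DiseaseSpec entries")

    def effect_for(self, motif: str) -> float:
        if isinstance(self.effect_size_log2, dict):
            return float(self.effect_size_log2.get(motif, 0.0))
        return float(self.effect_size_log2)


@dataclass
class SyntheticDataset:
    """Expression + ground truth produced by the simulator."""

    expression: ExpressionMatrix
    truth: pd.Series  # gene -> motif label
    ortholog_map: pd.DataFrame | None = None  # columns gene_a, gene_b, flipped
    true_disease_fc: pd.DataFrame | None = None  # gene x disease condition
    # pristine generative components; expression = baseline + sign*effect + noise
    _baseline: pd.Series | None = None
    _effect: pd.DataFrame | None = None
    _noise: pd.DataFrame | None = None
    _sign: pd.Series | None = None

    @property
    def flipped_genes(self) -> list[str]:
        if self.ortholog_map is None:
            return []
        return list(self.ortholog_map.loc[self.ortholog_map["flipped"], "gene_b"])

    def species_view(self, species: str) -> ExpressionMatrix:
        """The one-species submatrix: this species' genes x its samples."""
        ann = self.expression.annotations
        samples = list(ann.index[ann["species"] == species])
        genes = [g for g in self.expression.gene_ids if g.startswith(f"{species}_")]
        if not samples or not genes:
            raise ValueError(f"no data for species {species!r}")
        return ExpressionMatrix(
            self.expression.values.loc[genes, samples], ann.loc[samples].copy()
        )


def _trajectory(motif: str, day: float, effect: float, condition: str, is_species_a: bool) -> float:
    """True mean log2 fold change of a motif gene at a given day/condition."""
    t = float(day)
    if t == 0 or motif == "background":
        return 0.0
    if motif in ("metabolism_down_rescued", "metabolism_down_unrescued"):
        value = -effect * (1.0 - np.exp(-t))
        if motif == "metabolism_down_rescued" and condition == RESCUE_CONDITION:
            value *= RESCUE_FACTOR
        return value
    if motif == "inflammation_transient":
        return effect * t * np.exp(1.0 - t)  # peaks at day 1 with value `effect`
    if motif == "inflammation_persistent":
        return effect * (1.0 - np.exp(-2.0 * t))
    if motif == "cellcycle":
        return effect * (t / 2.5) * np.exp(1.0 - t / 2.5)  # peaks at day 2.5
    if motif == "cholesterol_speciesA_only":
        return effect * (1.0 - np.exp(-t)) if is_species_a else 0.0
    raise ValueError(f"unknown motif {motif!r}")


def _gene_table(config: SimulationConfig) -> pd.DataFrame:
    """Gene IDs + motif labels for both species (same layout per species)."""
    labels = []
    for motif, size in config.motif_sizes.items():
        labels.extend([motif] * size)
    labels.extend(["background"] * (config.n_genes - len(labels)))
    rows = []
    for sp in config.species_labels:
        for i, motif in enumerate(labels):
            rows.append((f"{sp}_g{i:05d}", sp, i, motif))
    return pd.DataFrame(rows, columns=["gene", "species", "ortho_index", "motif"]).set_index("gene")


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for sp in config.species_labels:
        for rep in range(1, config.n_replicates + 1):
            rows.append((f"{sp}_{REFERENCE_CONDITION}_d0_r{rep}", REFERENCE_CONDITION, 0, rep, sp, "reference"))
        for cond in config.conditions:
            for day in config.timepoints:
                if day == 0:
                    continue
                for rep in range(1, config.n_replicates + 1):
                    rows.append((f"{sp}_{cond}_d{day}_r{rep}", cond, day, rep, sp, "culture"))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "day", "replicate", "species", "model_type"]
    ).set_index("sample_id")


def _assemble(ds: SyntheticDataset) -> ExpressionMatrix:
    values = ds._effect.mul(ds._sign, axis=0).add(ds._baseline, axis=0) + ds._noise
    return ExpressionMatrix(values, ds.expression.annotations.copy())


def simulate_timecourse(config: SimulationConfig) -> SyntheticDataset:
    """Simulate the reference + culture time-course for both species.

    Per gene, sample values are the true motif trajectory plus i.i.d.
    Gaussian noise on the log2 scale; bit-identical for a fixed seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    genes = _gene_table(config)
    samples = _sample_table(config)

    baseline = pd.Series(
        rng.normal(config.baseline_mean, config.baseline_sd, len(genes)), index=genes.index
    )
    effect = np.zeros((len(genes), len(samples)))
    species_a = config.species_labels[0]
    motif_arr = genes["motif"].to_numpy()
    is_a = (genes["species"] == species_a).to_numpy()
    for j, (sid, ann) in enumerate(samples.iterrows()):
        if ann["day"] == 0:
            continue
        for motif in config.motif_sizes:
            rows = motif_arr == motif
            rows_sp = rows & (genes["species"] == ann["species"]).to_numpy()
            if not rows_sp.any():
                continue
            eff = config.effect_for(motif)
            effect[rows_sp, j] = _trajectory(
                motif, ann["day"], eff, ann["condition"], bool(is_a[rows_sp][0])
            )
    effect = pd.DataFrame(effect, index=genes.index, columns=samples.index)
    noise = pd.DataFrame(
        rng.normal(0.0, config.noise_sd, effect.shape), index=genes.index, columns=samples.index
    )
    sign = pd.Series(1.0, index=genes.index)

    ds = SyntheticDataset(
        expression=ExpressionMatrix(pd.DataFrame(index=genes.index, columns=samples.index, dtype=float).fillna(0.0), samples),
        truth=genes["motif"].copy(),
        _baseline=baseline,
        _effect=effect,
        _noise=noise,
        _sign=sign,
    )
    ds.expression = _assemble(ds)
    return ds


def simulate_disease_conditions(ds: SyntheticDataset, config: SimulationConfig) -> SyntheticDataset:
    """Append disease-like sample groups with controlled concordance.

    For each disease condition and species, per-gene true log2 fold changes
    are a bivariate-normal mixture of the species' day-1 first-condition
    culture effect and independent noise, so that their correlation with
    the culture response equals ``rho_target`` in expectation.
    """
    if ds._effect is None:
        raise ValueError("simulate_timecourse must run first")
    rng = np.random.default_rng([config.seed, 1])
    anchor_cond = config.conditions[0]
    genes = ds._effect.index
    species = ds.expression.annotations["species"]

    new_effect_cols, new_noise_cols, new_rows = {}, {}, []
    fc_records = {}
    for d_idx, spec in enumerate(config.disease_conditions):
        rho = float(spec.rho_target)
        for sp in config.species_labels:
            anchor_sample = f"{sp}_{anchor_cond}_d1_r1"
            if anchor_sample not in ds._effect.columns:
                raise ValueError("day-1 culture samples required for disease simulation")
            c = ds._effect[anchor_sample].loc[[g for g in genes if g.startswith(f"{sp}_")]]
            sigma = float(c.std(ddof=0))
            z = rng.normal(0.0, 1.0, len(c))
            d = rho * c.to_numpy() + np.sqrt(max(0.0, 1.0 - rho**2)) * sigma * z
            d = pd.Series(d, index=c.index)
            fc_records.update({(g, spec.name): v for g, v in d.items()})
            for rep in range(1, spec.n_replicates + 1):
                sid = f"{sp}_{spec.name}_d1_r{rep}"
                col = pd.Series(0.0, index=genes)
                col.loc[d.index] = d
                new_effect_cols[sid] = col
                new_noise_cols[sid] = pd.Series(
                    rng.normal(0.0, config.noise_sd, len(genes)), index=genes
                )
                new_rows.append((sid, spec.name, 1, rep, sp, "in_vivo"))

    if not new_rows:
        return ds
    add_ann = pd.DataFrame(
        new_rows, columns=["sample_id", "condition", "day", "replicate", "species", "model_type"]
    ).set_index("sample_id")
    effect = pd.concat([ds._effect, pd.DataFrame(new_effect_cols)], axis=1)
    noise = pd.concat([ds._noise, pd.DataFrame(new_noise_cols)], axis=1)
    ann = pd.concat([ds.expression.annotations, add_ann])
    true_fc = pd.Series(fc_records).unstack() if fc_records else None

    out = SyntheticDataset(
        expression=ExpressionMatrix(pd.DataFrame(0.0, index=genes, columns=ann.index), ann),
        truth=ds.truth,
        ortholog_map=ds.ortholog_map,
        true_disease_fc=true_fc,
        _baseline=ds._baseline,
        _effect=effect,
        _noise=noise,
        _sign=ds._sign.copy(),
    )
    out.expression = _assemble(out)
    return out


def build_ortholog_map(ds: SyntheticDataset, config: SimulationConfig) -> SyntheticDataset:
    """One-to-one orthologue map between the two species.

    A fraction ``ortholog_discordant_fraction`` of the mapped *effect*
    (non-background) pairs have the species-B motif effect sign flipped;
    flips are recomputed from the pristine effects, so reapplying the map
    is idempotent.
    """
    if ds._effect is None:
        raise ValueError("simulate_timecourse must run first")
    sp_a, sp_b = config.species_labels
    genes_a = [g for g in ds.truth.index if g.startswith(f"{sp_a}_")]
    genes_b = [g for g in ds.truth.index if g.startswith(f"{sp_b}_")]
    pairs = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
    pairs["motif"] = ds.truth.loc[pairs["gene_a"]].to_numpy()

    effect_pairs = pairs.index[pairs["motif"] != "background"].to_numpy()
    n_flip = int(round(config.ortholog_discordant_fraction * len(effect_pairs)))
    rng = np.random.default_rng([config.seed, 2])
    flip_idx = rng.choice(effect_pairs, size=n_flip, replace=False) if n_flip else np.array([], dtype=int)
    pairs["flipped"] = False
    pairs.loc[flip_idx, "flipped"] = True

    sign = pd.Series(1.0, index=ds.truth.index)
    sign.loc[pairs.loc[pairs["flipped"], "gene_b"]] = -1.0

    out = replace(ds)
    out._sign = sign
    out.ortholog_map = pairs[["gene_a", "gene_b", "flipped"]].copy()
    out.expression = _assemble(out)
    return out


def motif_gene_sets(ds: SyntheticDataset, species: str, include_background: bool = False) -> dict:
    """Truth-derived gene sets (motif -> gene list) for one species."""
    prefix = f"{species}_"
    sets: dict[str, list[str]] = {}
    for gene, motif in ds.truth.items():
        if not gene.startswith(prefix):
            continue
        if motif == "background" and not include_background:
            continue
        sets.setdefault(motif, []).append(gene)
    return sets
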