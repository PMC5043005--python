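# cultx

Comparative time-course transcriptomics pipeline: quantify how closely
gene-expression changes in one model system (e.g. cultivated primary
cells) resemble those in another (e.g. diseased tissue), within and
across species.

Stages, each a module with a file-based CLI command:

| Module | What it does |
|---|---|
| `cultx.simulate` | Synthetic two-species log2 expression data with planted motif trajectories (monotone down, transient up, persistent up, delayed peak, species-specific), disease-like conditions with a configurable correlation to the day-1 culture response, and a one-to-one orthologue map with a configurable fraction of sign-discordant genes. Ground truth travels with the data. |
| `cultx.qc` | Expression-matrix container, outlier-sample flagging (replicate correlation + PCA-distance, leave-one-out z-scores), high-variance gene selection, gene-centered PCA. |
| `cultx.differential` | Welch-t differential expression vs a fresh-cell reference per (condition, day), Benjamini-Hochberg adjustment, a `p_adj < alpha AND |log2fc| >= log2(fc)` call gate, DEG counting and top-gene ranking/overlap. |
| `cultx.clustering` | Per-gene z-scaled fold-change profiles, self-contained fuzzy c-means (restarts, objective traces), cluster-count selection (partition coefficient, Xie-Beni), hypergeometric gene-set overrepresentation, motif labelling. |
| `cultx.metagene` | Metagene scores: per-gene scaling (reference-anchored or global z), replicates averaged first, then genes; top-|log2fc| cluster gene selection. |
| `cultx.concordance` | Spearman fold-change correlation, sign-coincidence odds ratios (Haldane-Anscombe corrected, Fisher exact p), time-resolved OR series, orthologue pairing, Q1-Q4 fold-change quadrants with per-quadrant motif enrichment and metagenes. |

## CLI

Everything flows through plain TSV/GMT/YAML files:

```bash
cultx simulate --config config.yaml --outdir sim/ --seed 1
cultx qc       --expr sim/expression.tsv --annot sim/annotations.tsv --z 3
cultx pca      --expr sim/expression.tsv --annot sim/annotations.tsv \
               --top-genes 1000 --components 2 --out-prefix out/pca
cultx deg      --expr sim/expression.tsv --annot sim/annotations.tsv \
               --reference FH --alpha 0.05 --fc 2 --outdir deg/
cultx profiles --deg deg/deg_A_M_C_d1.tsv --deg deg/deg_A_M_C_d2.tsv \
               --include-baseline --out profiles.tsv
cultx cluster  --profiles profiles.tsv --c 5 --m 2 --restarts 10 --seed 11 \
               --out clusters.tsv
cultx enrich   --query query.txt --gmt sets.gmt --universe universe.txt --out enr.tsv
cultx metagene --expr sim/expression.tsv --annot sim/annotations.tsv \
               --gmt sim/motif_sets_A.gmt --species A --out metagenes.tsv
cultx concord  --deg-a deg/deg_A_M_C_d1.tsv --deg-b deg/deg_B_M_C_d1.tsv \
               --orthologs sim/orthologs.tsv --mode quadrants --out quadrants.tsv
```

A minimal simulation config:

```yaml
n_genes: 2000
motif_sizes:
  metabolism_down_rescued: 100
  metabolism_down_unrescued: 100
  inflammation_transient: 100
  inflammation_persistent: 100
  cellcycle: 100
n_replicates: 3
timepoints: [0, 1, 2, 3, 5, 7]
conditions: [M_C, M_S, S]
disease_conditions:
  - {name: acute_damage, rho_target: 0.7}
noise_sd: 0.3
effect_size_log2: 2.0
ortholog_discordant_fraction: 0.1
seed: 1
```

Timepoint 0 is the fresh-cell reference group (condition `FH`); all fold
changes are computed against its per-gene mean.

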