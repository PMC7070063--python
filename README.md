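# magniche

Genome-to-niche analysis for catalogues of metagenome-assembled genomes
(MAGs). The package builds species-level genome clusters from pairwise ANI,
derives gene (orthologous-group) and abundance profiles, constructs a
PCoA-based "virtual niche space" with environmental arrows and a priori
niche gradients, predicts each cluster's niche placement from its gene
content (cross-validated ridge / random-forest / gradient-boosting
regression) and from phylogeny alone (Brownian-motion ancestral-state
estimation), and compares ecology–gene-content vs ecology–phylogeny signal
with Mantel and partial Mantel permutation tests.

A fully parameterized synthetic-data generator with known ground truth
(`magniche.synthetic_data`) makes the entire pipeline testable without any
external data: it simulates a birth–death phylogeny, phylogenetically
correlated gene content (two-state Markov gain/loss with multi-copy genes),
niche traits that are partly gene-determined and partly tree-drifting
(mixing weight `beta`), an environmental sample grid with latent drivers,
Gaussian-response abundances with noise and a detection limit, per-sample
contig count tables, a genome quality table and an ANI matrix.

## Modules

| module | role |
| --- | --- |
| `synthetic_data` | parameterized world generator + on-disk materialization |
| `catalogue` | quality gate (completeness ≥ 75%, contamination ≤ 5%), average-linkage ANI clustering at 96.5%, representative selection, cross-cluster exclusion filter (> 0.95 ANI), rarefaction curves |
| `profiles` | per-MAG `@NOG` gene counting, cluster mean profiles, 10% prevalence filter, (1 − ρ)/2 Spearman dissimilarity |
| `abundance` | contig coverage (count × 200 / length), length-weighted coverage per million read-pairs, representative-based cluster profiles |
| `niche_space` | PCoA with Cailliez correction, variance explained, two-stage Spearman environmental arrows, log-ratio niche gradients with inclusion thresholds |
| `prediction` | 10-fold CV ridge (inner-CV λ), random forest (2000 trees, out-of-bag), gradient boosting (10000 stages, learning rate 0.001, depth 2), Brownian-motion GLS phylogenetic prediction, Spearman evaluation |
| `association` | patristic distances (inter-domain constant 5), one-sided Mantel and partial Mantel permutation tests |

## CLI

```bash
# generate a synthetic world (flat YAML key: value config, all optional)
magniche simulate --config cfg.yaml --outdir world/ --seed 1

# cluster MAGs into species-level clusters and pick representatives
magniche catalogue cluster --ani world/ani.tsv --quality world/quality.tsv --out clusters.tsv
magniche catalogue rarefy --incidence incidence.tsv --nperm 1000 --seed 1 --out rarefy.tsv

# gene profiles (cluster-averaged, prevalence-filtered)
magniche profiles build --annotation world/annotation.tsv --clusters clusters.tsv --out genes.tsv

# niche space and gradients
magniche niche pcoa --dissim diss.tsv --k 10 --outdir pcoa/
magniche niche arrows --abundance abund.tsv --metadata world/metadata.tsv \
    --coords pcoa/coordinates.tsv --out arrows.tsv
magniche niche gradient --abundance abund.tsv --spec salinity.yaml --out gradient.tsv

# cross-validated niche prediction
magniche predict --features genes.tsv --target pc1.tsv --model gbm --folds 10 --seed 1 --out pred.tsv
magniche predict --features genes.tsv --target pc1.tsv --model phylo --tree world/tree.nwk \
    --folds 10 --seed 1 --out pred_phylo.tsv

# distance-matrix association
magniche compare mantel  --x abund_diss.tsv --y gene_diss.tsv --nperm 10000 --seed 1
magniche compare pmantel --x abund_diss.tsv --y gene_diss.tsv --z patristic.tsv --nperm 10000 --seed 1
```

All commands are deterministic given `--seed`: repeated runs produce
byte-identical outputs.

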