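"""Synthetic world generator with known ground truth.

Produces all inputs consumed by the downstream modules — a rooted
ultrametric phylogeny, phylogenetically correlated gene content, niche
traits that are partly gene-determined and partly tree-drifting, an
environmental sample grid with latent drivers, Gaussian-response abundance
profiles with noise and a detection limit, per-sample contig count tables,
a genome quality table and an ANI matrix — so that every analysis stage can
be exercised against a ground truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from dendropy.model import birthdeath

READ_PAIR_LENGTH = 200  # bp per read pair assumed by the coverage formula

OBSERVED_GRADIENTS = ("salinity", "depth", "filter_size")

# spread of each standardized environmental axis; the first (salinity-like)
# axis dominates so PC1 of the abundance ordination aligns with it
_GRADIENT_SCALES = {"observed": (2.5, 1.5, 1.0), "latent": 0.8}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; every randomness source derives from ``seed``."""

    n_taxa: int = 64
    n_genes: int = 400
    n_niche_genes: int = 40
    n_samples: int = 40
    birth_rate: float = 1.0
    death_rate: float = 0.2
    gene_gain_rate: float = 0.4
    gene_loss_rate: float = 0.8
    beta: float = 0.5
    noise_sd: float = 0.3
    detection_limit: float = 1e-3
    contigs_per_genome: tuple[int, int] = (4, 12)
    seed: int = 0
    # secondary knobs (defaults emulate the target data's structure)
    n_latent: int = 2
    multicopy_fraction: float = 0.10
    multicopy_poisson_mean: float = 1.0
    peak_log_abundance: float = 2.0
    niche_width: float = 1.0
    frac_low_quality: float = 0.05
    ani_noise_sd: float = 0.002
    ani_decay: float = 3.0

    def __post_init__(self) -> None:
        for name in ("n_taxa", "n_genes", "n_niche_genes", "n_samples"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.n_niche_genes > self.n_genes:
            raise ValueError("n_niche_genes must not exceed n_genes")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("birth_rate must be > 0 and death_rate >= 0")
        if self.gene_gain_rate <= 0 or self.gene_loss_rate < 0:
            raise ValueError("gene_gain_rate must be > 0, gene_loss_rate >= 0")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        lo, hi = self.contigs_per_genome
        if lo < 1 or hi < lo:
            raise ValueError("contigs_per_genome must be a valid (lo, hi) range")


@dataclass
class SyntheticWorld:
    """A complete synthetic dataset plus its generating ground truth."""

    config: SyntheticConfig
    tree: dendropy.Tree
    gene_matrix: pd.DataFrame  # taxa x genes, integer counts
    niche_traits: pd.DataFrame  # taxa x gradients
    environment: pd.DataFrame  # samples x gradients (standardized axes)
    abundance: pd.DataFrame  # taxa x samples, coverage per million read-pairs
    metadata: pd.DataFrame  # samples x observed variables
    contig_table: pd.DataFrame  # long: taxon, contig_id, length, sample, est_count
    quality_table: pd.DataFrame  # taxon, sample_id, completeness, contamination
    ani_matrix: pd.DataFrame  # taxa x taxa in [0.7, 1]
    brownian_components: pd.DataFrame = field(repr=False, default=None)
    niche_gene_ids: list[str] = field(default_factory=list)

    @property
    def taxa(self) -> list[str]:
        return list(self.gene_matrix.index)


def _taxon_labels(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"T{i:0{width}d}" for i in range(1, n + 1)]


def simulate_tree(cfg: SyntheticConfig, max_retries: int = 100) -> dendropy.Tree:
    """Birth-death tree conditioned on ``cfg.n_taxa`` surviving tips.

    Extinct lineages are pruned, so the returned tree is ultrametric with
    strictly positive branch lengths.  Deterministic given ``cfg.seed``.
    """
    rng = random.Random(cfg.seed)
    last_err: Exception | None = None
    for _ in range(max_retries):
        try:
            tree = birthdeath.birth_death_tree(
                birth_rate=cfg.birth_rate,
                death_rate=cfg.death_rate,
                num_extant_tips=cfg.n_taxa,
                rng=rng,
                repeat_until_success=False,
            )
        except Exception as err:  # extinction before reaching n_taxa
            last_err = err
            continue
        leaves = tree.leaf_nodes()
        if len(leaves) != cfg.n_taxa:
            continue
        # the simulation stops exactly at the final speciation, leaving
        # zero-length leaf edges; extend every leaf edge by one common
        # exponential waiting time (preserves ultrametricity)
        extra = rng.expovariate(cfg.birth_rate * cfg.n_taxa)
        for leaf in leaves:
            leaf.edge.length = (leaf.edge.length or 0.0) + extra
        if any(
            e.length is not None and e.length <= 0
            for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
        ):
            continue
        for label, leaf in zip(_taxon_labels(cfg.n_taxa), leaves):
            leaf.taxon.label = label
        tree.seed_node.edge.length = None
        return tree
    raise RuntimeError(
        f"birth-death simulation failed to yield {cfg.n_taxa} extant tips "
        f"after {max_retries} attempts (last error: {last_err})"
    )


def _transition_probs(t: float, gain: float, loss: float) -> tuple[float, float]:
    """(P(absent->present), P(present->absent)) for a 2-state chain over time t."""
    total = gain + loss
    decay = 1.0 - np.exp(-total * t)
    return gain / total * decay, loss / total * decay


def simulate_gene_content(
    tree: dendropy.Tree, cfg: SyntheticConfig
) -> pd.DataFrame:
    """Gene counts at the tips from a per-gene 2-state Markov chain.

    Presence/absence evolves along branches with the configured gain/loss
    rates starting from a stationary root draw.  A fraction of genes are
    multi-copy: their copy number is drawn once per gain event (1 + Poisson)
    and inherited unchanged until the gene is lost, so zero-length sister
    branches carry identical rows.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n_genes = cfg.n_genes
    gain, loss = cfg.gene_gain_rate, cfg.gene_loss_rate
    p_stationary = gain / (gain + loss)

    multicopy = np.zeros(n_genes, dtype=bool)
    n_multi = int(round(cfg.multicopy_fraction * n_genes))
    if n_multi:
        multicopy[rng.choice(n_genes, size=n_multi, replace=False)] = True

    def draw_copies(present: np.ndarray, prev: np.ndarray) -> np.ndarray:
        """Copy numbers for newly present genes; absent genes get 0."""
        copies = np.where(present, np.maximum(prev, 1), 0)
        fresh = present & (prev == 0) & multicopy
        if fresh.any():
            copies = copies.copy()
            copies[fresh] = 1 + rng.poisson(cfg.multicopy_poisson_mean, fresh.sum())
        return copies

    root = tree.seed_node
    root_present = rng.random(n_genes) < p_stationary
    states: dict[int, np.ndarray] = {
        id(root): draw_copies(root_present, np.zeros(n_genes, dtype=int))
    }

    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_copies = states[id(node.parent_node)]
        parent_present = parent_copies > 0
        t = node.edge.length or 0.0
        p01, p10 = _transition_probs(t, gain, loss)
        u = rng.random(n_genes)
        flip = np.where(parent_present, u < p10, u < p01)
        present = parent_present ^ flip
        states[id(node)] = draw_copies(present, np.where(flip, 0, parent_copies))

    rows = {leaf.taxon.label: states[id(leaf)] for leaf in tree.leaf_node_iter()}
    gene_ids = [f"OG{j:05d}" for j in range(1, n_genes + 1)]
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=gene_ids)
    return matrix.sort_index()


def _brownian_traits(
    tree: dendropy.Tree, n_traits: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Standardized Brownian-motion trait values at the tips."""
    values: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(n_traits)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        step = rng.normal(0.0, np.sqrt(t), size=n_traits)
        values[id(node)] = values[id(node.parent_node)] + step
    rows = {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
    traits = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    return _standardize(traits)


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(axis=0, ddof=0)
    sd = sd.where(sd > 0, 1.0)
    return (df - df.mean(axis=0)) / sd


def simulate_niche_and_abundance(
    tree: dendropy.Tree,
    gene_matrix: pd.DataFrame,
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Niche traits, environment grid and Gaussian-response abundances.

    Each trait is sqrt(beta) * (standardized linear combination of the
    designated niche genes) + sqrt(1-beta) * (standardized Brownian trait).
    Expected log-abundance of a taxon in a sample is the configured peak
    minus the squared standardized distance between trait vector and sample
    environment, plus Normal(0, noise_sd) noise; values below the detection
    limit are recorded as 0.

    Returns (niche_traits, environment, abundance, ground_truth) where
    ground_truth carries the Brownian components and niche gene ids.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n_traits = len(OBSERVED_GRADIENTS) + cfg.n_latent
    gradient_names = list(OBSERVED_GRADIENTS) + [
        f"latent_{i}" for i in range(1, cfg.n_latent + 1)
    ]

    niche_gene_ids = sorted(
        rng.choice(gene_matrix.columns, size=cfg.n_niche_genes, replace=False)
    )
    niche_genes = gene_matrix[niche_gene_ids].to_numpy(dtype=float)
    weights = rng.normal(size=(cfg.n_niche_genes, n_traits))
    gene_component = _standardize(
        pd.DataFrame(niche_genes @ weights, index=gene_matrix.index)
    )
    brownian = _brownian_traits(tree, n_traits, rng)
    brownian = brownian.loc[gene_matrix.index]

    traits = (
        np.sqrt(cfg.beta) * gene_component + np.sqrt(1.0 - cfg.beta) * brownian
    )
    traits.columns = gradient_names
    gene_component.columns = gradient_names
    brownian.columns = gradient_names

    scales = np.array(
        list(_GRADIENT_SCALES["observed"])
        + [_GRADIENT_SCALES["latent"]] * cfg.n_latent
    )
    env = np.empty((cfg.n_samples, n_traits))
    env[:, 0] = np.linspace(-1.0, 1.0, cfg.n_samples) * scales[0]
    for k in range(1, n_traits):
        env[:, k] = rng.uniform(-1.0, 1.0, cfg.n_samples) * scales[k]
    sample_ids = [f"S{i:03d}" for i in range(1, cfg.n_samples + 1)]
    environment = pd.DataFrame(env, index=sample_ids, columns=gradient_names)

    sq_dist = (
        (traits.to_numpy()[:, None, :] - env[None, :, :]) ** 2
    ).sum(axis=2) / (2.0 * cfg.niche_width**2)
    log_abund = cfg.peak_log_abundance - sq_dist
    if cfg.noise_sd > 0:
        log_abund = log_abund + rng.normal(0.0, cfg.noise_sd, size=log_abund.shape)
    abund = np.exp(log_abund)
    abund[abund < cfg.detection_limit] = 0.0
    abundance = pd.DataFrame(abund, index=gene_matrix.index, columns=sample_ids)

    ground_truth = {
        "brownian": brownian,
        "gene_component": gene_component,
        "niche_gene_ids": [str(g) for g in niche_gene_ids],
    }
    return traits, environment, abundance, ground_truth


def _metadata_from_environment(
    environment: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Map standardized axes to physical units and derived covariates."""
    n = len(environment)
    s = environment["salinity"].to_numpy()
    d = environment["depth"].to_numpy()
    f = environment["filter_size"].to_numpy()
    s01 = (s - s.min()) / max(s.max() - s.min(), 1e-12)
    d01 = (d - d.min()) / max(d.max() - d.min(), 1e-12)
    salinity = 2.4 + s01 * (28.0 - 2.4)
    depth = 2.0 + d01 * (78.0)
    filter_size = np.where(f < 0, 0.8, 3.0)
    temperature = 18.0 - 10.0 * d01 + rng.normal(0, 0.5, n)
    oxygen = 10.0 - 6.0 * d01 + rng.normal(0, 0.3, n)
    nitrate = 0.5 + 4.0 * d01 + rng.normal(0, 0.2, n)
    phosphate = 0.1 + 0.8 * d01 + rng.normal(0, 0.05, n)
    silicate = 5.0 + 10.0 * (1 - s01) + rng.normal(0, 0.5, n)
    chlorophyll = 1.0 + 3.0 * (1 - d01) + rng.normal(0, 0.2, n)
    doc = 300.0 + 80.0 * (1 - s01) + rng.normal(0, 5.0, n)
    mapped_pairs = rng.integers(1_000_000, 5_000_000, n)
    meta = pd.DataFrame(
        {
            "salinity": salinity,
            "depth": depth,
            "filter_size": filter_size,
            "temperature": temperature,
            "oxygen": oxygen,
            "nitrate": nitrate,
            "phosphate": phosphate,
            "silicate": silicate,
            "chlorophyll_a": chlorophyll,
            "doc": doc,
            "mapped_read_pairs": mapped_pairs,
            "layer": np.where(depth < 20.0, "surface", "mid"),
            "sample_set": "synthetic",
        },
        index=environment.index,
    )
    meta.index.name = "sample_id"
    return meta


def _contig_table(
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-taxon contigs with per-sample estimated counts.

    Per-contig coverages vary around the taxon's coverage but their
    length-weighted mean reproduces it exactly, so abundance recomputation
    round-trips.
    """
    lo, hi = cfg.contigs_per_genome
    million_pairs = metadata["mapped_read_pairs"].to_numpy() / 1e6
    records = []
    for taxon, row in abundance.iterrows():
        n_contigs = int(rng.integers(lo, hi + 1))
        lengths = rng.integers(20_000, 300_000, n_contigs)
        wobble = rng.uniform(0.5, 1.5, n_contigs)
        # normalize so the length-weighted mean of the factors is exactly 1
        wobble = wobble / (np.dot(wobble, lengths) / lengths.sum())
        # coverage of the taxon in each sample (per-sample, not per-million)
        cov = row.to_numpy() * million_pairs
        counts = cov[None, :] * wobble[:, None] * lengths[:, None] / READ_PAIR_LENGTH
        for c in range(n_contigs):
            rec = {
                "taxon": taxon,
                "contig_id": f"{taxon}_c{c + 1:03d}",
                "length": int(lengths[c]),
            }
            rec.update(dict(zip(abundance.columns, counts[c])))
            records.append(rec)
    return pd.DataFrame.from_records(records)


def _quality_table(
    abundance: pd.DataFrame, cfg: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    taxa = list(abundance.index)
    n = len(taxa)
    completeness = rng.uniform(76.0, 100.0, n)
    contamination = rng.uniform(0.0, 5.0, n)
    n_low = int(round(cfg.frac_low_quality * n))
    if n_low:
        bad = rng.choice(n, size=n_low, replace=False)
        fail_completeness = rng.random(n_low) < 0.5
        completeness[bad[fail_completeness]] = rng.uniform(
            40.0, 74.9, fail_completeness.sum()
        )
        contamination[bad[~fail_completeness]] = rng.uniform(
            5.1, 15.0, (~fail_completeness).sum()
        )
    best_sample = abundance.idxmax(axis=1)
    table = pd.DataFrame(
        {
            "mag_id": taxa,
            "sample_id": best_sample.to_numpy(),
            "completeness": completeness,
            "contamination": contamination,
        }
    )
    return table


def _ani_matrix(
    tree: dendropy.Tree, taxa: list[str], cfg: SyntheticConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Monotone decreasing transform of patristic distance, noise added."""
    pdm = tree.phylogenetic_distance_matrix()
    taxon_map = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pdm.patristic_distance(
                taxon_map[taxa[i]], taxon_map[taxa[j]]
            )
    dmax = dist.max() or 1.0
    ani = 0.7 + 0.3 * np.exp(-cfg.ani_decay * dist / dmax)
    if cfg.ani_noise_sd > 0:
        noise = rng.normal(0.0, cfg.ani_noise_sd, size=(n, n))
        ani = ani + (noise + noise.T) / 2.0
    ani = np.clip(ani, 0.7, 1.0)
    np.fill_diagonal(ani, 1.0)
    return pd.DataFrame(ani, index=taxa, columns=taxa)


def build_world(cfg: SyntheticConfig) -> SyntheticWorld:
    """Run the full generator pipeline; bit-identical given the same config."""
    tree = simulate_tree(cfg)
    gene_matrix = simulate_gene_content(tree, cfg)
    traits, environment, abundance, truth = simulate_niche_and_abundance(
        tree, gene_matrix, cfg
    )
    rng = np.random.default_rng(cfg.seed + 3)
    metadata = _metadata_from_environment(environment, rng)
    contig_table = _contig_table(abundance, metadata, cfg, rng)
    quality_table = _quality_table(abundance, cfg, rng)
    ani_matrix = _ani_matrix(tree, list(gene_matrix.index), cfg, rng)
    return SyntheticWorld(
        config=cfg,
        tree=tree,
        gene_matrix=gene_matrix,
        niche_traits=traits,
        environment=environment,
        abundance=abundance,
        metadata=metadata,
        contig_table=contig_table,
        quality_table=quality_table,
        ani_matrix=ani_matrix,
        brownian_components=truth["brownian"],
        niche_gene_ids=truth["niche_gene_ids"],
    )


def materialize_inputs(world: SyntheticWorld, outdir: str | Path) -> dict[str, str]:
    """Write the on-disk inputs consumed by the downstream modules.

    Layout: per-sample contig count TSVs under ``counts/``, an annotation
    TSV, quality TSV, ANI TSV, metadata TSV, a Newick tree and ground-truth
    tables, plus a ``manifest.yaml`` listing everything.  Floats are written
    at full precision so recomputed abundances round-trip.
    """
    if len(world.taxa) == 0:
        raise ValueError("cannot materialize an empty world")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_dir = outdir / "counts"
    counts_dir.mkdir(exist_ok=True)

    paths: dict[str, str] = {}

    count_files = {}
    for sample in world.abundance.columns:
        sub = world.contig_table[["contig_id", "length", sample]].rename(
            columns={sample: "est_count"}
        )
        path = counts_dir / f"{sample}.tsv"
        sub.to_csv(path, sep="\t", index=False)
        count_files[sample] = str(path.relative_to(outdir))
    paths["counts"] = count_files

    ann_path = outdir / "annotation.tsv"
    with open(ann_path, "w") as fh:
        fh.write("mag_id\tgene_id\tlabels\n")
        for taxon in world.taxa:
            row = world.gene_matrix.loc[taxon]
            gene_no = 0
            for og, count in row.items():
                for _ in range(int(count)):
                    gene_no += 1
                    # each predicted gene carries the NOG label plus a
                    # non-NOG label that downstream counting must ignore
                    fh.write(
                        f"{taxon}\t{taxon}_g{gene_no:05d}\t{og}@NOG,K{gene_no:05d}@ko\n"
                    )
    paths["annotation"] = ann_path.name

    qual_path = outdir / "quality.tsv"
    world.quality_table.to_csv(qual_path, sep="\t", index=False)
    paths["quality"] = qual_path.name

    ani_path = outdir / "ani.tsv"
    world.ani_matrix.to_csv(ani_path, sep="\t", index_label="mag_id")
    paths["ani"] = ani_path.name

    meta_path = outdir / "metadata.tsv"
    world.metadata.to_csv(meta_path, sep="\t")
    paths["metadata"] = meta_path.name

    mapping_path = outdir / "contig_mags.tsv"
    world.contig_table[["contig_id", "taxon"]].rename(
        columns={"taxon": "mag_id"}
    ).to_csv(mapping_path, sep="\t", index=False)
    paths["contig_mags"] = mapping_path.name

    tree_path = outdir / "tree.nwk"
    tree_path.write_text(
        world.tree.as_string(schema="newick", suppress_rooting=True)
    )
    paths["tree"] = tree_path.name

    truth = {}
    for name, frame in (
        ("gene_matrix", world.gene_matrix),
        ("niche_traits", world.niche_traits),
        ("environment", world.environment),
        ("abundance", world.abundance),
    ):
        path = outdir / f"truth_{name}.tsv"
        frame.to_csv(path, sep="\t", index_label="id")
        truth[name] = path.name
    paths["ground_truth"] = truth

    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(paths, fh, sort_keys=True)
    paths["manifest"] = manifest_path.name
    return paths
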