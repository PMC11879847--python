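"""Synthetic cohort generator with known planted structure.

Emulates the data shapes of a functional-metagenomic immunotherapy study:
a two-arm (responder / non-responder) patient cohort pooled across several
study batches, species pangenomes with known lipid A gene complements,
per-sample taxonomic read counts, and per-feature gene counts of the kind a
read-mapping quantifier produces.  Every downstream stage of the pipeline
(rule classification, normalization, ratio statistics, enterotyping,
association tests) can therefore be checked against planted ground truth.

Planted effects follow the directions reported for anti-PD-1 cohorts:
responders carry relatively more hexa-acylated-LPS-encoding taxa (the
hexa:penta ratio roughly doubles), while non-responders carry a higher total
LPS gene load.

Noise model: log-normal base abundances (heavy-tailed, like real gut
communities), log-additive per-(batch, species) study effects,
Dirichlet-multinomial taxon counts and Poisson gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import (
    CORE_GENES,
    GENE_VOCABULARY,
    MODIFICATION_GENES,
    SCHEMA_CHANNELS,
)

#: Planted category -> genes encoded (beyond any modification genes).
CATEGORY_GENE_SETS: dict[str, frozenset[str]] = {
    # non-LPS organisms (e.g. Gram-positives) lack the whole backbone
    "non_lps": frozenset(),
    "tetra": frozenset(CORE_GENES | {"lpxH", "waaA"}),
    "penta": frozenset(CORE_GENES | {"lpxH", "waaA", "lpxL"}),
    "hexa_lpxM": frozenset(CORE_GENES | {"lpxH", "waaA", "lpxL", "lpxM"}),
    "hexa_lpxJ": frozenset(CORE_GENES | {"lpxH", "waaA", "lpxL", "lpxJ"}),
}

HEXA_CATEGORIES = ("hexa_lpxM", "hexa_lpxJ")
LPS_CATEGORIES = ("tetra", "penta", "hexa_lpxM", "hexa_lpxJ")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults describe the emulated study conditions: ~150 species of which
    roughly two thirds encode LPS, 50 patients per response arm pooled from
    3 study batches, a doubled responder hexa:penta contrast and a 1.5-fold
    non-responder total-LPS load, moderate batch effects and overdispersion.
    """

    n_species: int = 150
    n_samples_per_arm: int = 50
    n_batches: int = 3
    category_mix: dict[str, float] = field(
        default_factory=lambda: {
            "non_lps": 0.30,
            "tetra": 0.10,
            "penta": 0.35,
            "hexa_lpxM": 0.15,
            "hexa_lpxJ": 0.10,
        }
    )
    hexa_fold_responder: float = 2.0
    total_lps_fold_nonresponder: float = 1.5
    batch_sd: float = 0.3
    dispersion: float = 0.005
    depth: int = 100_000
    annotation_flip_rate: float = 0.0
    flip_schema_a_lpxM: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.category_mix) != set(CATEGORY_GENE_SETS):
            raise ValueError(
                f"category_mix must cover exactly {sorted(CATEGORY_GENE_SETS)}"
            )
        if any(p < 0 for p in self.category_mix.values()):
            raise ValueError("category_mix proportions must be non-negative")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1 within 1e-9")
        if self.hexa_fold_responder <= 0 or self.total_lps_fold_nonresponder <= 0:
            raise ValueError("fold parameters must be positive")
        if self.batch_sd < 0:
            raise ValueError("batch_sd must be non-negative")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.annotation_flip_rate <= 1.0:
            raise ValueError("annotation_flip_rate must be in [0, 1]")
        if self.n_species < 1 or self.n_samples_per_arm < 1 or self.n_batches < 1:
            raise ValueError("counts must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    species_category: dict[str, str]
    arm: dict[str, str]
    batch: dict[str, str]
    planted_folds: dict[str, float]
    batch_effects: pd.DataFrame  # batches x species, log-multipliers
    base_abundance: pd.Series  # per-species log-normal base abundance


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    """Independent per-stage stream derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def generate_pangenomes(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw species pangenomes consistent with planted LPS categories.

    Each species is assigned a category from ``category_mix``; genes it
    encodes get genome frequencies >= 0.5 (drawn U[0.8, 1]) and genes it
    lacks frequencies < 0.5 (U[0, 0.2]), so thresholding at 0.5 recovers the
    planted category exactly.  Two evidence channels (schema_A, schema_B)
    are emitted per gene; each channel call is independently flipped across
    the 0.5 boundary with probability ``annotation_flip_rate``.  schema_A
    lpxM calls are exempt from flips unless ``flip_schema_a_lpxM`` is set,
    reproducing a curation step in which only one schema is trusted for
    lpxM.

    Returns the two-channel pangenome table (species x (gene, channel)) and
    the truth record (sample maps filled in by
    :func:`generate_taxa_profiles`).
    """
    rng = _rng(config, stage=1)
    cats = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats])
    species = [f"sp{i:04d}" for i in range(config.n_species)]
    assigned = rng.choice(cats, size=config.n_species, p=probs)

    cols = pd.MultiIndex.from_product(
        [GENE_VOCABULARY, SCHEMA_CHANNELS], names=["gene", "schema"]
    )
    table = pd.DataFrame(0.0, index=pd.Index(species, name="species_id"), columns=cols)

    for sp, cat in zip(species, assigned):
        encoded = CATEGORY_GENE_SETS[cat]
        # modification genes are decorative: present at random in LPS species
        mods = {
            g for g in MODIFICATION_GENES
            if cat != "non_lps" and rng.random() < 0.3
        }
        truth_set = encoded | mods
        for gene in GENE_VOCABULARY:
            present = gene in truth_set
            for channel in SCHEMA_CHANNELS:
                flip_allowed = not (
                    gene == "lpxM"
                    and channel == "schema_A"
                    and not config.flip_schema_a_lpxM
                )
                call = present
                if flip_allowed and rng.random() < config.annotation_flip_rate:
                    call = not call
                freq = (
                    rng.uniform(0.8, 1.0) if call else rng.uniform(0.0, 0.2)
                )
                table.loc[sp, (gene, channel)] = freq

    base = pd.Series(
        np.exp(rng.normal(0.0, 1.0, size=config.n_species)),
        index=species, name="base_abundance",
    )
    truth = SyntheticTruth(
        species_category=dict(zip(species, (str(c) for c in assigned))),
        arm={},
        batch={},
        planted_folds={
            "hexa_fold_responder": config.hexa_fold_responder,
            "total_lps_fold_nonresponder": config.total_lps_fold_nonresponder,
        },
        batch_effects=pd.DataFrame(),
        base_abundance=base,
    )
    return table, truth


def generate_taxa_profiles(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample taxon read counts around arm/batch-modified abundances.

    Responders' hexa-encoding taxa are multiplied by ``hexa_fold_responder``;
    non-responders' LPS-encoding taxa by ``total_lps_fold_nonresponder``.
    Batch effects are log-additive per (batch, species), N(0, batch_sd^2).
    Counts are Dirichlet-multinomial with concentration ``1/dispersion``
    (multinomial when dispersion is 0); row sums equal ``depth``.

    Returns (samples x taxa counts, metadata with response and study).
    """
    rng = _rng(config, stage=2)
    species = list(truth.base_abundance.index)
    cats = truth.species_category

    n = config.n_samples_per_arm
    samples = [f"R{i:03d}" for i in range(n)] + [f"NR{i:03d}" for i in range(n)]
    arms = ["R"] * n + ["NR"] * n
    batches = [f"study{(i % config.n_batches) + 1}" for i in range(2 * n)]

    batch_names = [f"study{b + 1}" for b in range(config.n_batches)]
    if config.batch_sd > 0:
        eff = rng.normal(0.0, config.batch_sd, size=(config.n_batches, len(species)))
    else:
        eff = np.zeros((config.n_batches, len(species)))
    batch_effects = pd.DataFrame(eff, index=batch_names, columns=species)

    hexa_mask = np.array([cats[s] in HEXA_CATEGORIES for s in species])
    lps_mask = np.array([cats[s] in LPS_CATEGORIES for s in species])
    base = truth.base_abundance.to_numpy()

    counts = np.zeros((len(samples), len(species)), dtype=np.int64)
    for i, (arm, batch) in enumerate(zip(arms, batches)):
        mean = base.copy()
        if arm == "R":
            mean = np.where(hexa_mask, mean * config.hexa_fold_responder, mean)
        else:
            mean = np.where(lps_mask, mean * config.total_lps_fold_nonresponder, mean)
        mean = mean * np.exp(batch_effects.loc[batch].to_numpy())
        p = mean / mean.sum()
        if config.dispersion > 0:
            conc = 1.0 / config.dispersion
            p = rng.dirichlet(p * conc)
        counts[i] = rng.multinomial(config.depth, p)

    taxa = pd.DataFrame(counts, index=pd.Index(samples, name="sample_id"),
                        columns=species)
    metadata = pd.DataFrame(
        {"response": arms, "study": batches},
        index=pd.Index(samples, name="sample_id"),
    )
    truth.arm = dict(zip(samples, arms))
    truth.batch = dict(zip(samples, batches))
    truth.batch_effects = batch_effects
    return taxa, metadata


def default_gene_lengths(
    config: SimulationConfig, genes: tuple[str, ...] = GENE_VOCABULARY
) -> pd.Series:
    """Per-gene lengths drawn uniformly from 600-3,000 bp (typical bacterial
    ORF range); exercises the length term of GCPM."""
    rng = _rng(config, stage=3)
    return pd.Series(
        rng.integers(600, 3001, size=len(genes)).astype(float),
        index=list(genes), name="length_bp",
    )


def generate_gene_counts(
    taxa: pd.DataFrame,
    pangenome: pd.DataFrame,
    gene_lengths: pd.Series | dict[str, float],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Draw per-feature gene counts from taxon abundances and gene content.

    A feature is one (taxon, gene) ORF.  Its expected count in a sample is
    proportional to taxon read count x gene presence x gene length (longer
    genes soak up more reads, as with a read-mapping quantifier); realized
    counts are Poisson.  Presence is the pangenome frequency thresholded at
    0.5 (two-channel tables are evidence-merged first).

    Returns a frame with index feature_id and columns
    ``ko, taxon, length_bp`` followed by one count column per sample.
    """
    from .annotation import merge_annotation_evidence  # local to avoid cycle

    if isinstance(pangenome.columns, pd.MultiIndex):
        pangenome = merge_annotation_evidence(pangenome)
    lengths = pd.Series(dict(gene_lengths)) if not isinstance(
        gene_lengths, pd.Series
    ) else gene_lengths
    missing = [g for g in pangenome.columns if g not in lengths.index]
    if missing:
        raise ValueError(f"missing gene length for: {missing}")
    if (lengths <= 0).any():
        bad = list(lengths.index[lengths <= 0])
        raise ValueError(f"non-positive gene length for: {bad}")
    shared = [t for t in taxa.columns if t in pangenome.index]
    if not shared:
        raise ValueError("taxa profile and pangenome share no species identifiers")

    rng = _rng(config, stage=4)
    presence = (pangenome.loc[shared] >= 0.5).astype(float)
    genes = list(pangenome.columns)

    features, meta = [], []
    rate_rows = []
    # reads per (taxon copy, kb of gene): fixed so gene depth tracks taxa depth
    per_kb = 0.05
    for taxon in shared:
        for gene in genes:
            if presence.at[taxon, gene] == 0.0:
                continue
            features.append(f"{taxon}|{gene}")
            meta.append((gene, taxon, float(lengths[gene])))
            rate_rows.append(
                taxa[taxon].to_numpy(dtype=float)
                * (lengths[gene] / 1000.0)
                * per_kb
            )
    if features:
        lam = np.vstack(rate_rows)
        counts = rng.poisson(lam)
    else:
        counts = np.zeros((0, taxa.shape[0]), dtype=np.int64)
    out = pd.DataFrame(
        counts, index=pd.Index(features, name="feature_id"), columns=taxa.index
    )
    info = pd.DataFrame(
        meta, index=out.index, columns=["ko", "taxon", "length_bp"]
    )
    return pd.concat([info, out], axis=1)


def generate_cluster_profiles(
    n_clusters: int = 3,
    n_samples: int = 60,
    n_features: int = 40,
    concentration: float = 60.0,
    separation: float = 4.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Relative-abundance profiles with planted community clusters.

    Each cluster has its own Dirichlet centre (a few features boosted by
    ``separation``); samples are Dirichlet draws around their cluster centre
    with the given concentration.  Used to exercise enterotype recovery.

    Returns (samples x features profiles summing to 1, sample -> cluster).
    """
    rng = np.random.default_rng(seed)
    centres = np.full((n_clusters, n_features), 1.0)
    block = max(1, n_features // n_clusters)
    for c in range(n_clusters):
        centres[c, c * block:(c + 1) * block] *= separation
    centres /= centres.sum(axis=1, keepdims=True)
    labels = np.repeat(np.arange(n_clusters), int(np.ceil(n_samples / n_clusters)))
    labels = labels[:n_samples]
    profiles = np.vstack(
        [rng.dirichlet(centres[c] * concentration) for c in labels]
    )
    idx = pd.Index([f"s{i:03d}" for i in range(n_samples)], name="sample_id")
    return (
        pd.DataFrame(profiles, index=idx,
                     columns=[f"KO{j:04d}" for j in range(n_features)]),
        pd.Series(labels, index=idx, name="cluster"),
    )
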