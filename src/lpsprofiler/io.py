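"""File formats, pipeline configuration, run manifest and orchestration.

Interchange is plain text: TSV for matrices (features or species as rows,
first column the identifier), CSV for sample metadata, JSON for
configurations, tallies, reports and the run manifest.  UTF-8, LF endings.

``run_all`` ties the stages together — simulate -> classify -> quantify ->
enterotype -> associate — and records a manifest (config hash, per-file
checksums, before/after counts for every filter) that is byte-identical for
identical config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, association, enterotype, quantify, synthetic

logger = logging.getLogger("lpsprofiler")

_CHANNEL_SEP = "|"

MATRIX_KINDS = ("genes", "taxa", "pangenome", "profiles")


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# readers / writers


def _flatten_columns(df: pd.DataFrame) -> pd.DataFrame:
    if isinstance(df.columns, pd.MultiIndex):
        df = df.copy()
        df.columns = [_CHANNEL_SEP.join(map(str, c)) for c in df.columns]
    return df


def _unflatten_columns(df: pd.DataFrame) -> pd.DataFrame:
    if any(_CHANNEL_SEP in str(c) for c in df.columns):
        df = df.copy()
        df.columns = pd.MultiIndex.from_tuples(
            [tuple(str(c).split(_CHANNEL_SEP, 1)) for c in df.columns],
            names=["gene", "schema"],
        )
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a matrix as TSV (index as first column, LF endings)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _flatten_columns(df).to_csv(path, sep="\t", lineterminator="\n")
    return path


def read_matrix(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a typed TSV matrix.

    ``kind``: ``genes`` (feature table with ko/taxon/length_bp columns then
    counts), ``taxa`` (integer counts), ``pangenome`` (frequencies in [0,1],
    possibly two-channel), ``profiles`` (non-negative abundances).
    Validation failures report the offending row and column.
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}; expected {MATRIX_KINDS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty input file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty input file: {path}") from exc
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = list(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate identifiers in {path}: {dups[:5]}")

    value_cols = [
        c for c in df.columns
        if not (kind == "genes" and c in ("ko", "taxon", "length_bp"))
    ]
    values = df[value_cols].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        r, c = next(
            (r, c) for c in values.columns for r in values.index
            if pd.isna(values.at[r, c])
        )
        raise ValueError(f"non-numeric cell in {path} at row {r!r}, column {c!r}")
    neg = values < 0
    if neg.any().any():
        r, c = next(
            (r, c) for c in values.columns for r in values.index if neg.at[r, c]
        )
        raise ValueError(f"negative value in {path} at row {r!r}, column {c!r}")
    if kind == "pangenome":
        over = values > 1
        if over.any().any():
            r, c = next(
                (r, c) for c in values.columns for r in values.index
                if over.at[r, c]
            )
            raise ValueError(
                f"pangenome frequency > 1 in {path} at row {r!r}, column {c!r}"
            )
        return _unflatten_columns(values)
    if kind == "genes":
        info = df[[c for c in ("ko", "taxon", "length_bp") if c in df.columns]]
        return pd.concat([info, values], axis=1)
    return values


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metadata.to_csv(path, lineterminator="\n")
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, index_col=0)
    if "response" not in df.columns:
        raise ValueError(f"metadata {path} lacks a 'response' column")
    return df


RESPONSE_MAP = {
    "complete response": "R", "partial response": "R", "stable disease": "R",
    "progressive disease": "NR", "CR": "R", "PR": "R", "SD": "R", "PD": "NR",
    "R": "R", "NR": "NR",
}


def map_response_labels(raw: pd.Series) -> pd.Series:
    """Map clinical outcome labels to responder (R) / non-responder (NR).

    Stable disease, partial and complete response count as responders;
    progressive disease as non-responder."""
    unknown = sorted(set(raw.dropna().unique()) - set(RESPONSE_MAP))
    if unknown:
        raise ValueError(f"unmapped response label(s): {unknown}")
    return raw.map(RESPONSE_MAP)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (pd.Series,)):
        return _jsonable(obj.to_dict())
    return obj


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# configuration and manifest


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings (thresholds, ranges, seed)."""

    simulation: synthetic.SimulationConfig = field(
        default_factory=synthetic.SimulationConfig
    )
    presence_threshold: float = 0.5
    rare_min_samples: int = 5
    pseudocount: float = 1e-6
    cpm_mode: str = "pseudolog"
    k_min: int = 2
    k_max: int = 6
    n_restarts: int = 100
    nmds_dims: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.presence_threshold <= 1.0:
            raise ValueError("presence_threshold must be in (0, 1]")
        if self.rare_min_samples < 0:
            raise ValueError("rare_min_samples must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.cpm_mode not in ("pseudolog", "raw"):
            raise ValueError("cpm_mode must be 'pseudolog' or 'raw'")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        sim = synthetic.SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, simulation=self.simulation.with_seed(seed)
        )


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict[str, dict]
    checksums: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
            "checksums": self.checksums,
        }


# ---------------------------------------------------------------------------
# orchestration


def simulate_stage(config: PipelineConfig, outdir: Path) -> dict:
    sim = config.simulation
    pangenome, truth = synthetic.generate_pangenomes(sim)
    taxa, metadata = synthetic.generate_taxa_profiles(sim, truth)
    lengths = synthetic.default_gene_lengths(sim)
    genes = synthetic.generate_gene_counts(taxa, pangenome, lengths, sim)

    write_matrix(pangenome, outdir / "pangenome.tsv")
    write_matrix(taxa.T, outdir / "taxa.tsv")  # rows taxa, columns samples
    write_matrix(genes, outdir / "gene_counts.tsv")
    write_metadata(metadata, outdir / "metadata.csv")
    write_json(
        {
            "species_category": truth.species_category,
            "arm": truth.arm,
            "batch": truth.batch,
            "planted_folds": truth.planted_folds,
            "batch_effects": {
                b: truth.batch_effects.loc[b].to_dict()
                for b in truth.batch_effects.index
            },
        },
        outdir / "truth.json",
    )
    return {
        "n_species": int(pangenome.shape[0]),
        "n_samples": int(taxa.shape[0]),
        "n_gene_features": int(genes.shape[0]),
    }


def classify_stage(config: PipelineConfig, outdir: Path) -> dict:
    pangenome = read_matrix(outdir / "pangenome.tsv", "pangenome")
    merged = annotation.merge_annotation_evidence(pangenome)
    structures = annotation.classify_pangenome(merged, config.presence_threshold)
    annotation.structures_frame(structures).to_csv(
        outdir / "structures.tsv", sep="\t", lineterminator="\n"
    )
    tallies = annotation.tally_lps_categories(structures)
    write_json(tallies, outdir / "tallies.json")
    return {"tallies": tallies}


def quantify_stage(config: PipelineConfig, outdir: Path) -> dict:
    taxa = read_matrix(outdir / "taxa.tsv", "taxa").T  # samples x taxa
    genes = read_matrix(outdir / "gene_counts.tsv", "genes")
    metadata = read_metadata(outdir / "metadata.csv")
    merged = annotation.merge_annotation_evidence(
        read_matrix(outdir / "pangenome.tsv", "pangenome")
    )
    structures = annotation.classify_pangenome(merged, config.presence_threshold)

    abund = annotation.category_abundance(taxa, structures)
    write_matrix(abund, outdir / "category_abundance.tsv")

    info_cols = ["ko", "taxon", "length_bp"]
    counts = genes.drop(columns=info_cols)
    adjusted = quantify.simple_batch_adjust(counts, metadata["study"])
    n_before = counts.shape[0]
    filtered, dropped = quantify.filter_rare_features(
        adjusted, config.rare_min_samples
    )
    cpm = quantify.cpm_pipeline(filtered, config.cpm_mode, config.pseudocount)
    write_matrix(cpm, outdir / "gene_cpm.tsv")

    ko = genes["ko"].reindex(filtered.index)
    ko_cpm = cpm.groupby(ko).sum()
    ratios = {
        "hexa_total_vs_penta": quantify.hexa_penta_ratio(abund, "hexa_total"),
        "hexa_lpxM_vs_penta": quantify.hexa_penta_ratio(abund, "hexa_lpxM"),
    }
    if {"lpxM", "lpxL"} <= set(ko_cpm.index):
        ratios["lpxM_vs_lpxL_genes"] = quantify.gene_ratio(
            ko_cpm.loc["lpxM"], ko_cpm.loc["lpxL"]
        )
    write_matrix(pd.DataFrame(ratios), outdir / "ratios.tsv")
    return {
        "features_before_rare_filter": int(n_before),
        "features_after_rare_filter": int(filtered.shape[0]),
        "features_dropped": len(dropped),
    }


def enterotype_stage(config: PipelineConfig, outdir: Path) -> dict:
    genes = read_matrix(outdir / "gene_counts.tsv", "genes")
    counts = genes.drop(columns=["ko", "taxon", "length_bp"])
    ko_counts = counts.groupby(genes["ko"]).sum()  # KO x samples
    profiles = (ko_counts / ko_counts.sum(axis=0)).T  # samples x KO
    write_matrix(profiles, outdir / "ko_profiles.tsv")

    dist = enterotype.jsd_distance(profiles)
    fit = enterotype.select_k(dist, range(config.k_min, config.k_max + 1))
    fit.assignments.rename("enterotype").to_csv(
        outdir / "enterotypes.csv", lineterminator="\n"
    )
    write_json(fit.ch_scores, outdir / "ch_scores.json")
    ord_pcoa = enterotype.pcoa(dist, n_axes=2)
    write_matrix(ord_pcoa.coordinates, outdir / "pcoa_coordinates.tsv")
    bca = enterotype.between_class_analysis(profiles, fit.assignments)
    write_matrix(bca.coordinates, outdir / "bca_coordinates.tsv")
    return {
        "selected_k": int(fit.k),
        "ch_scores": {str(k): float(v) for k, v in fit.ch_scores.items()},
        "bca_between_total_ratio": float(bca.between_total_ratio),
    }


def associate_stage(config: PipelineConfig, outdir: Path) -> dict:
    genes = read_matrix(outdir / "gene_counts.tsv", "genes")
    # normalized values, not counts (pseudolog CPM may be negative)
    cpm = pd.read_csv(outdir / "gene_cpm.tsv", sep="\t", index_col=0)
    abund = read_matrix(outdir / "category_abundance.tsv", "profiles")
    ratio_table = pd.read_csv(outdir / "ratios.tsv", sep="\t", index_col=0)
    metadata = read_metadata(outdir / "metadata.csv")
    assignments = pd.read_csv(
        outdir / "enterotypes.csv", index_col=0
    )["enterotype"]
    profiles = read_matrix(outdir / "ko_profiles.tsv", "profiles")

    dist = enterotype.jsd_distance(profiles)
    sol = association.nmds(
        dist, dims=config.nmds_dims, n_restarts=config.n_restarts,
        seed=config.seed + 7,
    )
    write_matrix(sol.coordinates, outdir / "nmds_coordinates.tsv")

    reports = association.run_association_suite(
        gene_cpm=cpm,
        gene_ko=genes["ko"].reindex(cpm.index),
        category_abundance=abund,
        ratios={c: ratio_table[c] for c in ratio_table.columns},
        metadata=metadata,
        enterotype_assignments=assignments,
        nmds_solution=sol,
    )
    serial = {
        name: (
            [r.to_dict() for r in rep] if isinstance(rep, list) else rep.to_dict()
        )
        for name, rep in reports.items()
    }
    write_json(serial, outdir / "association_report.json")
    return {
        "n_tests": len(serial),
        "nmds_stress": float(sol.stress),
        "nmds_restarts_used": int(sol.n_restarts_used),
        "nmds_converged": bool(sol.converged),
    }


_STAGES = {
    "simulate": simulate_stage,
    "classify": classify_stage,
    "quantify": quantify_stage,
    "enterotype": enterotype_stage,
    "associate": associate_stage,
}


def run_all(config: PipelineConfig, outdir: str | Path) -> RunManifest:
    """Run the full pipeline on a synthetic cohort and write a manifest.

    Stage failures abort with the stage name; the manifest is written only
    on success and is byte-identical across runs with the same config and
    seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    for name, fn in _STAGES.items():
        logger.info("running stage %s", name)
        try:
            stages[name] = fn(config, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    checksums = {
        p.name: file_checksum(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        stages=stages,
        checksums=checksums,
    )
    write_json(manifest.to_dict(), outdir / "manifest.json")
    return manifest
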