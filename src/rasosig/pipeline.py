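"""File dialects, run configuration and the end-to-end pipeline.

The pipeline composes the analysis stages in order: scaling/log2 and
detection filtering -> confounder removal -> log2-ratio transformation ->
triple-criterion signature selection for the four comparisons ->
permutation-FDR estimation per signature -> full leave-one-out
classification -> optional gene-set enrichment and circuit detection ->
hierarchical clustering. Every intermediate artifact is written to the run
directory together with a machine-readable manifest (package and library
versions, seed, parameter hash, SHA-256 of every output), and a rerun with
the same configuration reproduces every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .classify import loo_classify, score_separation
from .enrich import circuit_detect, circuits_to_json, enrichment_to_frame, \
    hypergeom_enrich, read_gmt
from .explore import cluster_samples, export_heatmap
from .preprocess import ExpressionMatrix, SampleSheet, preprocess
from .signatures import (
    COMPARISONS,
    Thresholds,
    permutation_fdr,
    select_all_signatures,
)

logger = logging.getLogger("rasosig")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path: str | Path, detection_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read the matrix TSV (first column ``probe_id``) and its detection TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
    detection = None
    if detection_path is not None:
        detection = pd.read_csv(detection_path, sep="\t", index_col="probe_id")
        if detection.shape[0] != values.shape[0]:
            raise ValueError(
                f"probe axis mismatch: matrix has {values.shape[0]} rows, "
                f"detection has {detection.shape[0]}"
            )
        if detection.shape[1] != values.shape[1]:
            raise ValueError(
                f"sample axis mismatch: matrix has {values.shape[1]} columns, "
                f"detection has {detection.shape[1]}"
            )
    return ExpressionMatrix(values, detection, log_scale=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", index_col="sample_id"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one pipeline run depends on."""

    matrix: str = "matrix.tsv"
    detection: str = "detection.tsv"
    samples: str = "samples.tsv"
    out_dir: str = "run"
    gmt_files: list[str] = field(default_factory=list)
    # preprocessing
    clip_floor: float = 1.0
    detection_p_threshold: float = 0.01
    detection_min_fraction: float = 0.5
    detection_by_group: bool = True
    confound_alpha: float = 0.01
    # selection thresholds
    min_abs_log2ratio: float = 0.5
    max_t_p: float = 0.01
    min_snr: float = 0.5
    equal_var: bool = False
    # permutation FDR
    n_permutations: int = 2000
    seed: int = 0
    # enrichment / circuits
    enrich_max_p: float = 0.01
    circuit_min_targets: int = 3
    # clustering
    cluster_distance: str = "correlation"
    cluster_linkage: str = "average"
    cluster_k: int = 4
    # heatmap export
    heatmap: bool = True

    def thresholds(self) -> Thresholds:
        return Thresholds(
            self.min_abs_log2ratio, self.max_t_p, self.min_snr, self.equal_var
        )

    def validate(self) -> None:
        for attr in ("matrix", "detection", "samples"):
            p = Path(getattr(self, attr))
            if not p.exists():
                raise FileNotFoundError(f"config.{attr}: no such file: {p}")
        for g in self.gmt_files:
            if not Path(g).exists():
                raise FileNotFoundError(f"GMT file not found: {g}")
        self.thresholds()  # raises on bad values

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def parameter_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sanitize(name: str) -> str:
    return name.replace("/", "_").replace("+", "_")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read inputs"
    try:
        matrix = read_expression(config.matrix, config.detection)
        samples = read_sample_sheet(config.samples)
        missing = set(matrix.sample_ids) - set(samples.sample_ids)
        if missing:
            raise ValueError(f"samples absent from sample sheet: {sorted(missing)}")

        stage = "preprocess"
        ratios, logged, report = preprocess(
            matrix,
            samples,
            clip_floor=config.clip_floor,
            detection_p_threshold=config.detection_p_threshold,
            detection_min_fraction=config.detection_min_fraction,
            detection_by_group=config.detection_by_group,
            confound_alpha=config.confound_alpha,
        )
        with open(out / "filter_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
            fh.write("\n")
        ratios.values.to_csv(
            out / "log2ratio.tsv", sep="\t", index_label="probe_id",
            float_format="%.17g",
        )

        stage = "signature selection"
        thresholds = config.thresholds()
        sigs = select_all_signatures(ratios, samples, thresholds)
        for name, sig in sigs.items():
            sig.to_tsv(out / f"signature_{_sanitize(name)}.tsv")
            logger.info("signature %s: %d probes", name, len(sig))

        stage = "permutation FDR"
        for i, (name, case_groups) in enumerate(COMPARISONS.items()):
            fdr = permutation_fdr(
                ratios,
                samples,
                case_groups,
                thresholds,
                n_permutations=config.n_permutations,
                seed=config.seed + i,
                name=name,
            )
            fdr.to_json(out / f"fdr_{_sanitize(name)}.json")

        stage = "leave-one-out classification"
        scores, _ = loo_classify(ratios, samples, thresholds)
        scores.to_csv(out / "loo_scores.tsv", sep="\t", index=False,
                      float_format="%.17g")
        separations = []
        for name, case_groups in COMPARISONS.items():
            for g in case_groups:
                separations.append(
                    score_separation(scores, name, (g, "control")).to_dict()
                )
        with open(out / "score_separation.json", "w") as fh:
            json.dump(separations, fh, indent=1)
            fh.write("\n")

        stage = "enrichment"
        for gmt in config.gmt_files:
            collection = read_gmt(gmt)
            for name, sig in sigs.items():
                if not len(sig):
                    continue
                try:
                    results = hypergeom_enrich(
                        sig.probe_ids, collection, max_p=config.enrich_max_p
                    )
                except ValueError:
                    logger.info(
                        "signature %s shares no genes with %s; skipped",
                        name, collection.name,
                    )
                    continue
                enrichment_to_frame(results).to_csv(
                    out / f"enrich_{collection.name}_{_sanitize(name)}.tsv",
                    sep="\t", index=False, float_format="%.17g",
                )
                circuits = circuit_detect(
                    sig, collection, min_targets=config.circuit_min_targets
                )
                if circuits:
                    circuits_to_json(
                        circuits,
                        out / f"circuits_{collection.name}_{_sanitize(name)}.json",
                    )

        stage = "clustering"
        clustering = cluster_samples(
            ratios,
            samples,
            distance=config.cluster_distance,
            method=config.cluster_linkage,
            k=config.cluster_k,
        )
        clustering.to_newick(out / "dendrogram.nwk")
        clustering.enrichment.to_csv(
            out / "cluster_enrichment.tsv", sep="\t", float_format="%.17g"
        )

        if config.heatmap:
            stage = "heatmap"
            nonempty = [s for s in sigs.values() if len(s)]
            if nonempty:
                export_heatmap(ratios, nonempty, out / "heatmap.png", samples)

        stage = "manifest"
        _write_manifest(config, out)
    except Exception:
        logger.error("pipeline failed during stage: %s", stage)
        raise
    return out


def _write_manifest(config: PipelineConfig, out: Path) -> None:
    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "rasosig_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "parameter_hash": config.parameter_hash(),
        "config": asdict(config),
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
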