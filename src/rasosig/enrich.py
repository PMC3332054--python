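"""Gene-set over-representation and TF/target circuit detection.

One local statistic replaces the zoo of web-tool lookups a signature is
usually pushed through: upper-tail hypergeometric over-representation of a
signature in user-supplied GMT gene-set collections (kinase substrates,
functional keywords, TF targets, ...). Circuits of transcriptional
regulation are called when a transcription factor is itself in a signature
and the directions of its annotated targets within the same signature are
biased (two-sided exact binomial test against p0 = 0.5).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .signatures import Signature

logger = logging.getLogger("rasosig")


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe.

    Sets are harmonized to the universe on construction (genes outside the
    universe are dropped); sets left empty are discarded with a log note.
    """

    name: str
    sets: dict[str, list[str]]
    universe: list[str] | None = None

    def __post_init__(self) -> None:
        # dedupe, preserving order
        self.sets = {k: list(dict.fromkeys(v)) for k, v in self.sets.items()}
        if self.universe is None:
            seen: dict[str, None] = {}
            for genes in self.sets.values():
                seen.update(dict.fromkeys(genes))
            self.universe = list(seen)
        else:
            self.universe = list(dict.fromkeys(self.universe))
            uni = set(self.universe)
            harmonized = {}
            for k, genes in self.sets.items():
                kept = [g for g in genes if g in uni]
                if kept:
                    harmonized[k] = kept
                else:
                    logger.info(
                        "gene set '%s' empty after universe harmonization; dropped", k
                    )
            self.sets = harmonized

    def restrict_universe(self, universe: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection(self.name, dict(self.sets), list(universe))

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    signature_size: int
    universe_size: int
    p: float
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.overlap > min(self.set_size, self.signature_size):
            raise ValueError("overlap exceeds set or signature size")
        if not 0 < self.p <= 1:
            raise ValueError("p must lie in (0, 1]")


@dataclass
class CircuitResult:
    """A TF present in a signature together with >= min_targets targets."""

    tf: str
    tf_direction: str
    tf_p: float
    n_targets_in_signature: int
    n_targets_up: int
    n_targets_down: int
    direction_bias_p: float
    circuit: bool
    orientation: str  # concordant | discordant | none

    @property
    def n_targets_concordant_with_tf(self) -> int:
        return self.n_targets_up if self.tf_direction == "up" else self.n_targets_down

    def to_dict(self) -> dict:
        return {
            "tf": self.tf,
            "tf_direction": self.tf_direction,
            "tf_p": self.tf_p,
            "n_targets_in_signature": self.n_targets_in_signature,
            "n_targets_up": self.n_targets_up,
            "n_targets_down": self.n_targets_down,
            "n_targets_concordant_with_tf": self.n_targets_concordant_with_tf,
            "direction_bias_p": self.direction_bias_p,
            "circuit": self.circuit,
            "orientation": self.orientation,
        }


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(
    path: str | Path,
    name: str | None = None,
    universe: Sequence[str] | None = None,
) -> GeneSetCollection:
    """Parse a GMT file (set name, description, then tab-separated genes)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            sets[fields[0]] = [g for g in fields[2:] if g]
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(
        name or path.stem, sets, list(universe) if universe is not None else None
    )


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_name, genes in collection.sets.items():
            fh.write("\t".join([set_name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def hypergeom_enrich(
    signature_genes: Sequence[str],
    collection: GeneSetCollection,
    max_p: float = 0.01,
    directions: Mapping[str, str] | None = None,
    direction: str = "both",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation per gene set.

    The signature genes are intersected with the collection's universe
    before testing. ``direction`` = ``up``/``down`` restricts the signature
    to the matching subset (``directions`` maps gene -> direction). Results
    with p < ``max_p``, sorted ascending by p (ties by set name).
    """
    genes = list(dict.fromkeys(signature_genes))
    if direction != "both":
        if directions is None:
            raise ValueError("direction-stratified test needs a directions map")
        genes = [g for g in genes if directions.get(g) == direction]
    uni = set(collection.universe)
    sig = [g for g in genes if g in uni]
    if not sig:
        raise ValueError(
            "no signature genes in the collection universe — harmonize gene "
            "identifiers (the signature and GMT must share a namespace)"
        )
    sig_set = set(sig)
    M, N = len(uni), len(sig_set)
    results = []
    for set_name, members in collection.sets.items():
        K = len(members)
        k = len(sig_set.intersection(members))
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        if p < max_p:
            results.append(
                EnrichmentResult(
                    set_name, k, K, N, M, p, sorted(sig_set.intersection(members))
                )
            )
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "overlap": r.overlap,
                "set_size": r.set_size,
                "signature_size": r.signature_size,
                "universe_size": r.universe_size,
                "p": r.p,
                "genes": ",".join(r.genes),
            }
            for r in results
        ],
        columns=[
            "set_name", "overlap", "set_size", "signature_size",
            "universe_size", "p", "genes",
        ],
    )


# ---------------------------------------------------------------------------
# TF/target circuits
# ---------------------------------------------------------------------------

def circuit_detect(
    signature: Signature,
    tf_targets: GeneSetCollection,
    min_targets: int = 3,
    bias_alpha: float = 0.05,
    probe_to_gene: Mapping[str, str] | None = None,
) -> list[CircuitResult]:
    """Find TFs coregulated with their predicted targets in one signature.

    A TF qualifies when it is itself in the signature and >= ``min_targets``
    of its annotated targets are too; the two-sided exact binomial test
    (p0 = 0.5) asks whether the targets' up/down directions are biased. A
    circuit is flagged when ``direction_bias_p < bias_alpha``; its
    orientation records whether the biased target direction matches the
    TF's own direction.
    """
    mapping = probe_to_gene or {}
    gene_dir: dict[str, str] = {}
    gene_p: dict[str, float] = {}
    for probe, row in signature.entries.iterrows():
        gene = mapping.get(probe, probe)
        if gene not in gene_dir:  # first (strongest-SNR) probe wins
            gene_dir[gene] = row["direction"]
            gene_p[gene] = float(row["t_p"])
    results = []
    for tf, targets in tf_targets.sets.items():
        if tf not in gene_dir:
            continue
        in_sig = [t for t in targets if t in gene_dir and t != tf]
        if len(in_sig) < min_targets:
            logger.info(
                "TF %s: only %d target(s) in signature (< %d); skipped",
                tf, len(in_sig), min_targets,
            )
            continue
        n_up = sum(1 for t in in_sig if gene_dir[t] == "up")
        n = len(in_sig)
        bias_p = float(stats.binomtest(n_up, n, 0.5).pvalue)
        circuit = bias_p < bias_alpha
        if not circuit or n_up == n - n_up:
            orientation = "none"
        else:
            majority = "up" if n_up > n - n_up else "down"
            orientation = (
                "concordant" if majority == gene_dir[tf] else "discordant"
            )
        results.append(
            CircuitResult(
                tf=tf,
                tf_direction=gene_dir[tf],
                tf_p=gene_p[tf],
                n_targets_in_signature=n,
                n_targets_up=n_up,
                n_targets_down=n - n_up,
                direction_bias_p=bias_p,
                circuit=circuit,
                orientation=orientation,
            )
        )
    results.sort(key=lambda r: (r.direction_bias_p, r.tf))
    return results


def circuits_to_json(results: Sequence[CircuitResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=1)
        fh.write("\n")
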