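"""Unsupervised structure checks: sample clustering and heatmap export.

Samples are clustered hierarchically on the filtered log2-ratio matrix
(default: 1 - Pearson correlation distance across probes, average linkage),
the tree is cut into k groups (k = 4 by default, the number of mutation
groups plus controls), and each cluster is tested for enrichment in each
group label with Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skbio import TreeNode

from .preprocess import GROUPS, Log2RatioMatrix, SampleSheet
from .signatures import Signature


@dataclass
class ClusteringResult:
    linkage: np.ndarray  # scipy linkage matrix
    sample_ids: list[str]
    leaf_order: list[str]
    assignments: pd.Series  # sample -> cluster id (1..k)
    enrichment: pd.DataFrame  # cluster x group Fisher exact p
    distance: str
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    def to_newick(self, path: str | Path | None = None) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage, self.sample_ids)
        nwk = str(tree).strip()
        if path is not None:
            Path(path).write_text(nwk + "\n")
        return nwk


def cluster_samples(
    log2ratios: Log2RatioMatrix,
    samples: SampleSheet | None = None,
    distance: str = "correlation",
    method: str = "average",
    k: int = 4,
) -> ClusteringResult:
    """Hierarchical clustering of samples over probes.

    A constant matrix makes the correlation distance undefined; it falls
    back to Euclidean with a warning.
    """
    ids = list(log2ratios.sample_ids)
    if len(ids) < 2:
        raise ValueError("clustering needs >= 2 samples")
    x = log2ratios.values.to_numpy(dtype=float).T  # samples x probes
    if distance == "correlation" and (x.std(axis=1) == 0).any():
        warnings.warn(
            "constant sample profile: correlation distance undefined, "
            "falling back to euclidean",
            stacklevel=2,
        )
        distance = "euclidean"
    d = pdist(x, metric=distance)
    d = np.clip(d, 0.0, None)  # correlation distance can dip below 0 by eps
    z = hierarchy.linkage(d, method=method)
    leaves = hierarchy.leaves_list(z)
    assignments = pd.Series(
        hierarchy.fcluster(z, t=k, criterion="maxclust"), index=ids, name="cluster"
    )
    enrichment = _cluster_group_enrichment(assignments, samples)
    return ClusteringResult(
        z, ids, [ids[i] for i in leaves], assignments, enrichment, distance, method
    )


def _cluster_group_enrichment(
    assignments: pd.Series, samples: SampleSheet | None
) -> pd.DataFrame:
    if samples is None:
        return pd.DataFrame()
    groups = samples.groups().loc[assignments.index]
    rows = {}
    for c in sorted(assignments.unique()):
        in_c = assignments == c
        rows[c] = {}
        for g in GROUPS:
            in_g = groups == g
            if not in_g.any():
                rows[c][g] = np.nan
                continue
            table = [
                [int((in_c & in_g).sum()), int((in_c & ~in_g).sum())],
                [int((~in_c & in_g).sum()), int((~in_c & ~in_g).sum())],
            ]
            rows[c][g] = stats.fisher_exact(table, alternative="greater")[1]
    out = pd.DataFrame(rows).T
    out.index.name = "cluster"
    return out


def export_heatmap(
    log2ratios: Log2RatioMatrix,
    signatures: Sequence[Signature],
    path: str | Path,
    samples: SampleSheet | None = None,
    vlim: float = 2.0,
) -> pd.DataFrame:
    """Signature-block heatmap of log2 ratios, plus the plotted values as TSV.

    Rows are grouped into one block per signature (in the given order);
    columns are ordered control, PTPN11, SOS1, SHOC2 when a sample sheet is
    supplied. Diverging green-black-red scale centred at 0, clipped at
    +/- ``vlim`` log2 units. The TSV of plotted values is written next to
    the image.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    if not signatures:
        raise ValueError("at least one signature is required")
    path = Path(path)
    if samples is not None:
        order = [
            s
            for g in GROUPS
            for s in samples.samples_in([g])
            if s in log2ratios.sample_ids
        ]
    else:
        order = list(log2ratios.sample_ids)
    blocks = []
    row_labels: list[str] = []
    boundaries = []
    for sig in signatures:
        probes = [p for p in sig.probe_ids if p in log2ratios.probe_ids]
        blocks.append(log2ratios.values.loc[probes, order])
        row_labels.extend(probes)
        boundaries.append(len(row_labels))
    data = pd.concat(blocks)
    cmap = LinearSegmentedColormap.from_list("gbr", ["green", "black", "red"])
    height = max(2.0, min(12.0, 0.02 * len(row_labels) + 1.5))
    fig, ax = plt.subplots(figsize=(8, height))
    ax.imshow(
        data.to_numpy(),
        aspect="auto",
        cmap=cmap,
        vmin=-vlim,
        vmax=vlim,
        interpolation="nearest",
    )
    for b in boundaries[:-1]:
        ax.axhline(b - 0.5, color="white", lw=0.8)
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=4)
    ax.set_yticks([])
    ax.set_ylabel(" / ".join(s.name for s in signatures), fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150, metadata={"Software": None})
    plt.close(fig)
    tsv_path = path.with_suffix(".tsv")
    data.to_csv(tsv_path, sep="\t", index_label="probe_id", float_format="%.17g")
    return data
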