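"""Leave-one-out weighted-score classification of samples.

Each sample is held out in turn; all four signatures are re-derived from
scratch on the remaining samples (nothing from the held-out sample enters
any training statistic), and the held-out sample receives one weighted
average score per signature:

    score = sum_g w_g * (x_g - b_g) / sum_g |w_g|

with w_g the probe's training-fold SNR and b_g the midpoint of the two
training group means (Golub-style weighted voting). Positive scores vote
for the case group. Group separation of the resulting scores is assessed
with a two-sided t-test, and an optimal classification threshold is chosen
by maximizing balanced accuracy.

All fold statistics are invariant to any per-probe constant shift of the
expression values, so scoring works identically on log2 or log2-ratio
matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import Log2RatioMatrix, SampleSheet
from .signatures import COMPARISONS, Thresholds, triple_test_mask

SCORE_COLUMNS = ("sample_id", "group", "signature", "score", "fold_signature_size")


@dataclass
class FoldModel:
    """Signatures and voting weights derived with one sample held out.

    ``models`` maps signature name -> DataFrame indexed by probe id with
    columns ``weight`` (training SNR) and ``midpoint`` (mean of the case and
    control training means, on the matrix scale).
    """

    held_out: str
    models: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class ScoreSeparation:
    """Two-group separation of classification scores for one signature."""

    signature: str
    group_pair: tuple[str, str]
    t_p: float
    threshold: float
    balanced_accuracy: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "signature": self.signature,
            "group_pair": list(self.group_pair),
            "t_p": self.t_p,
            "threshold": self.threshold,
            "balanced_accuracy": self.balanced_accuracy,
            "degenerate": self.degenerate,
        }


def weighted_score(
    sample_values: Mapping[str, float] | pd.Series,
    weights: Mapping[str, float] | pd.Series,
    midpoints: Mapping[str, float] | pd.Series,
) -> float:
    """Weighted average vote of a sample against one signature.

    score = sum_g w_g (x_g - b_g) / sum_g |w_g|. Raises when the sample is
    missing any signature probe, naming the offenders.
    """
    weights = pd.Series(weights, dtype=float)
    if weights.empty:
        raise ValueError("weights must be non-empty")
    midpoints = pd.Series(midpoints, dtype=float).reindex(weights.index)
    x = pd.Series(sample_values, dtype=float).reindex(weights.index)
    missing = list(x.index[x.isna()])
    if missing:
        raise ValueError(f"sample lacks values for signature probes: {missing}")
    return float(
        ((x - midpoints) * weights).sum() / np.abs(weights).sum()
    )


def _fold_model(
    values: np.ndarray,
    probe_ids: pd.Index,
    case_cols: np.ndarray,
    ctrl_cols: np.ndarray,
    thresholds: Thresholds,
) -> pd.DataFrame:
    mask, _, _, s = triple_test_mask(values, case_cols, ctrl_cols, thresholds)
    case_mean = values[:, case_cols].mean(axis=1)
    ctrl_mean = values[:, ctrl_cols].mean(axis=1)
    return pd.DataFrame(
        {
            "weight": s[mask],
            "midpoint": 0.5 * (case_mean[mask] + ctrl_mean[mask]),
        },
        index=probe_ids[mask],
    )


def loo_classify(
    log2ratios: Log2RatioMatrix,
    samples: SampleSheet,
    thresholds: Thresholds = Thresholds(),
    control_group: str = "control",
    comparisons: Mapping[str, tuple[str, ...]] | None = None,
) -> tuple[pd.DataFrame, list[FoldModel]]:
    """Full leave-one-out classification over all samples.

    Returns the long-format score table (one row per sample x signature,
    columns of :data:`SCORE_COLUMNS`) and the per-fold models. Folds whose
    re-derived signature is empty score 0 with ``fold_signature_size`` 0.
    """
    if comparisons is None:
        comparisons = COMPARISONS
    counts = samples.groups().value_counts()
    small = counts[counts < 3]
    if not small.empty:
        raise ValueError(
            f"every group needs >= 3 samples for leave-one-out: {dict(small)}"
        )
    order = list(log2ratios.sample_ids)
    group_of = samples.groups().to_dict()
    values = log2ratios.values.to_numpy(dtype=float)
    col_of = {s: i for i, s in enumerate(order)}
    cols_by_group: dict[str, np.ndarray] = {}
    for g in set(group_of.values()):
        cols_by_group[g] = np.array(
            [col_of[s] for s in order if group_of[s] == g], dtype=int
        )

    rows = []
    folds: list[FoldModel] = []
    for held in order:
        h = col_of[held]
        fold = FoldModel(held_out=held)
        for name, case_groups in comparisons.items():
            case_cols = np.concatenate(
                [cols_by_group[g] for g in case_groups if g in cols_by_group]
            )
            ctrl_cols = cols_by_group[control_group]
            case_cols = case_cols[case_cols != h]
            ctrl_cols = ctrl_cols[ctrl_cols != h]
            model = _fold_model(
                values, log2ratios.probe_ids, case_cols, ctrl_cols, thresholds
            )
            fold.models[name] = model
            if model.empty:
                score = 0.0
            else:
                x = pd.Series(values[:, h], index=log2ratios.probe_ids)
                score = weighted_score(x, model["weight"], model["midpoint"])
            rows.append(
                {
                    "sample_id": held,
                    "group": group_of[held],
                    "signature": name,
                    "score": score,
                    "fold_signature_size": len(model),
                }
            )
        folds.append(fold)
    return pd.DataFrame(rows, columns=list(SCORE_COLUMNS)), folds


def _balanced_accuracy(
    case_scores: np.ndarray, other_scores: np.ndarray, threshold: float
) -> float:
    sens = (case_scores > threshold).mean()
    spec = (other_scores <= threshold).mean()
    return 0.5 * (sens + spec)


def score_separation(
    scores: pd.DataFrame,
    signature: str,
    group_pair: tuple[str, str],
) -> ScoreSeparation:
    """t-test separation and optimal threshold for one signature's scores.

    ``group_pair[0]`` is treated as the positive (case) class: samples
    scoring above the threshold are called cases. The threshold maximizes
    balanced accuracy; when a whole interval of thresholds is optimal, its
    midpoint is taken.
    """
    sub = scores[scores["signature"] == signature]
    a = sub.loc[sub["group"] == group_pair[0], "score"].to_numpy(dtype=float)
    b = sub.loc[sub["group"] == group_pair[1], "score"].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 scores")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return ScoreSeparation(signature, group_pair, 1.0, float(pooled[0]),
                               0.5, degenerate=True)
    t_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if np.isnan(t_p):  # both groups constant at different values
        t_p = 1.0 if a[0] == b[0] else 0.0
    u = np.unique(pooled)
    gaps = np.concatenate([[u[0] - 1.0], 0.5 * (u[:-1] + u[1:]), [u[-1] + 1.0]])
    accs = np.array([_balanced_accuracy(a, b, t) for t in gaps])
    best = accs.max()
    best_idx = np.flatnonzero(accs == best)
    # contiguous run of equally good cut intervals -> midpoint of the run
    mid = best_idx[len(best_idx) // 2] if len(best_idx) % 2 else None
    if mid is not None:
        threshold = float(gaps[mid])
    else:
        threshold = float(0.5 * (gaps[best_idx[len(best_idx) // 2 - 1]]
                                 + gaps[best_idx[len(best_idx) // 2]]))
    return ScoreSeparation(signature, group_pair, t_p, threshold, float(best))
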