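"""Differential-expression signature selection and permutation FDR.

A probe enters the signature for a case-vs-control comparison when it passes
all three criteria simultaneously (strict inequalities):

* fold change: |mean case log2-ratio| > ``min_abs_log2ratio`` (default 0.5);
* two-sample t-test: P < ``max_t_p`` (default 0.01; Welch by default);
* signal-to-noise ratio: |SNR| > ``min_snr`` (default 0.5), with the
  Golub-style statistic SNR = (mean_case - mean_control) / (sd_case +
  sd_control), sample standard deviations (ddof = 1).

The false-positive fraction of a signature is estimated by Monte Carlo:
case/control labels are randomly permuted among the samples of the
comparison (group sizes preserved), the full triple test is re-run, and the
mean null hit count is divided by the observed hit count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import GROUPS, Log2RatioMatrix, SampleSheet

#: The four comparisons: signature name -> case groups (control is always the
#: reference arm). The pan-RASopathy signature pools all mutation groups.
COMPARISONS: dict[str, tuple[str, ...]] = {
    "NS+NS/LAH": ("PTPN11", "SOS1", "SHOC2"),
    "PTPN11": ("PTPN11",),
    "SOS1": ("SOS1",),
    "SHOC2": ("SHOC2",),
}


@dataclass(frozen=True)
class Thresholds:
    """The three selection thresholds (all strict)."""

    min_abs_log2ratio: float = 0.5
    max_t_p: float = 0.01
    min_snr: float = 0.5
    equal_var: bool = False  # Student's pooled t instead of Welch

    def __post_init__(self) -> None:
        if min(self.min_abs_log2ratio, self.max_t_p, self.min_snr) <= 0:
            raise ValueError("thresholds must be strictly positive")


@dataclass
class Signature:
    """Probes passing the triple criterion for one comparison.

    ``entries`` columns: ``probe_id`` (index), ``mean_log2ratio``, ``t_p``,
    ``snr``, ``direction`` — sorted by |SNR| descending.
    """

    name: str
    case_groups: tuple[str, ...]
    control_group: str
    entries: pd.DataFrame
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.entries.index)

    def directions(self) -> dict[str, str]:
        return dict(self.entries["direction"])

    def to_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index_label="probe_id",
                            float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "",
                 case_groups: tuple[str, ...] = (),
                 control_group: str = "control") -> "Signature":
        entries = pd.read_csv(path, sep="\t", index_col="probe_id")
        return cls(name, tuple(case_groups), control_group, entries)


@dataclass
class PermutationFDR:
    """Monte Carlo estimate of the false-positive fraction of a signature.

    ``fdr_estimate = mean(null_hit_counts) / max(n_observed_hits, 1)``;
    reported as NaN (not applicable) when nothing was observed.
    """

    name: str
    n_observed_hits: int
    n_permutations: int
    null_hit_counts: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.null_hit_counts = np.asarray(self.null_hit_counts, dtype=int)
        if len(self.null_hit_counts) != self.n_permutations:
            raise ValueError("one null count per permutation required")

    @property
    def mean_null_hits(self) -> float:
        return float(self.null_hit_counts.mean()) if self.n_permutations else 0.0

    @property
    def fdr_estimate(self) -> float:
        if self.n_observed_hits == 0:
            return float("nan")
        return self.mean_null_hits / self.n_observed_hits

    def to_json(self, path: str | Path) -> None:
        est = self.fdr_estimate
        payload = {
            "signature": self.name,
            "n_observed_hits": self.n_observed_hits,
            "n_permutations": self.n_permutations,
            "mean_null_hits": self.mean_null_hits,
            "fdr_estimate": None if np.isnan(est) else est,
            "seed": self.seed,
            "null_hit_counts": self.null_hit_counts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def snr(case_values: Sequence[float], control_values: Sequence[float]) -> float:
    """Golub signal-to-noise ratio of two sample groups.

    (mean_case - mean_control) / (sd_case + sd_control) with ddof=1 standard
    deviations. When both groups are constant: 0 for equal means, signed
    infinity otherwise (so the magnitude threshold always passes).
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if len(case) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 values")
    num = case.mean() - control.mean()
    den = case.std(ddof=1) + control.std(ddof=1)
    if den == 0:
        return 0.0 if num == 0 else float(np.copysign(np.inf, num))
    return float(num / den)


def _group_stats(
    values: np.ndarray,
    case_cols: np.ndarray,
    control_cols: np.ndarray,
    equal_var: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-probe (mean diff, t p-value, SNR) for two column sets."""
    case = values[:, case_cols]
    ctrl = values[:, control_cols]
    diff = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_p = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var).pvalue
    t_p = np.nan_to_num(t_p, nan=1.0)  # zero-variance probes: no evidence
    den = case.std(axis=1, ddof=1) + ctrl.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = diff / den
    s[(den == 0) & (diff == 0)] = 0.0
    s[(den == 0) & (diff != 0)] = np.copysign(np.inf, diff[(den == 0) & (diff != 0)])
    return diff, t_p, s


def triple_test_mask(
    values: np.ndarray,
    case_cols: np.ndarray,
    control_cols: np.ndarray,
    thresholds: Thresholds,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Boolean pass mask plus the three per-probe statistics."""
    diff, t_p, s = _group_stats(values, case_cols, control_cols, thresholds.equal_var)
    mask = (
        (np.abs(diff) > thresholds.min_abs_log2ratio)
        & (t_p < thresholds.max_t_p)
        & (np.abs(s) > thresholds.min_snr)
    )
    return mask, diff, t_p, s


def _comparison_columns(
    log2ratios: Log2RatioMatrix,
    samples: SampleSheet,
    case_groups: Iterable[str],
    control_group: str,
) -> tuple[np.ndarray, np.ndarray]:
    case_groups = tuple(case_groups)
    unknown = set(case_groups) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown case groups: {sorted(unknown)}")
    col_of = {s: i for i, s in enumerate(log2ratios.sample_ids)}
    case = np.array(
        [col_of[s] for s in samples.samples_in(case_groups) if s in col_of], dtype=int
    )
    ctrl = np.array(
        [col_of[s] for s in samples.samples_in([control_group]) if s in col_of],
        dtype=int,
    )
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError(
            f"comparison {case_groups} vs {control_group} needs >= 2 samples "
            f"per arm (got {len(case)} and {len(ctrl)})"
        )
    return case, ctrl


def select_signature(
    log2ratios: Log2RatioMatrix,
    samples: SampleSheet,
    case_groups: Iterable[str],
    thresholds: Thresholds = Thresholds(),
    control_group: str = "control",
    name: str | None = None,
) -> Signature:
    """Apply the triple criterion to one case-vs-control comparison."""
    case_groups = tuple(case_groups)
    case_cols, ctrl_cols = _comparison_columns(
        log2ratios, samples, case_groups, control_group
    )
    values = log2ratios.values.to_numpy(dtype=float)
    mask, diff, t_p, s = triple_test_mask(values, case_cols, ctrl_cols, thresholds)
    entries = pd.DataFrame(
        {
            "mean_log2ratio": diff[mask],
            "t_p": t_p[mask],
            "snr": s[mask],
            "direction": np.where(diff[mask] > 0, "up", "down"),
        },
        index=log2ratios.probe_ids[mask],
    )
    entries = entries.iloc[np.argsort(-np.abs(entries["snr"].to_numpy()), kind="stable")]
    if name is None:
        name = "+".join(case_groups)
    return Signature(name, case_groups, control_group, entries, thresholds)


def permutation_fdr(
    log2ratios: Log2RatioMatrix,
    samples: SampleSheet,
    case_groups: Iterable[str],
    thresholds: Thresholds = Thresholds(),
    n_permutations: int = 2000,
    seed: int = 0,
    control_group: str = "control",
    name: str | None = None,
) -> PermutationFDR:
    """Estimate the false-positive fraction by label permutation.

    Labels are shuffled only among the samples participating in the
    comparison, preserving the case/control group sizes; the full triple
    test is re-run per permutation.
    """
    case_groups = tuple(case_groups)
    case_cols, ctrl_cols = _comparison_columns(
        log2ratios, samples, case_groups, control_group
    )
    values = log2ratios.values.to_numpy(dtype=float)
    observed = int(
        triple_test_mask(values, case_cols, ctrl_cols, thresholds)[0].sum()
    )
    # canonical pool order (sorted sample ids) so the estimate is invariant
    # to the column order of the matrix and the row order of the sheet
    ids = log2ratios.sample_ids
    pool = np.concatenate([case_cols, ctrl_cols])
    pool = pool[np.argsort(ids[pool])]
    n_case = len(case_cols)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_permutations, dtype=int)
    for i in range(n_permutations):
        perm = rng.permutation(pool)
        mask = triple_test_mask(values, perm[:n_case], perm[n_case:], thresholds)[0]
        null_counts[i] = int(mask.sum())
    if name is None:
        name = "+".join(case_groups)
    return PermutationFDR(name, observed, n_permutations, null_counts, seed)


def signature_overlap(a: Signature, b: Signature) -> tuple[set[str], int, int]:
    """Shared probes between two signatures, split by direction agreement.

    Returns ``(shared probe ids, n concordant, n discordant)``.
    """
    da, db = a.directions(), b.directions()
    shared = set(da) & set(db)
    concordant = sum(1 for p in shared if da[p] == db[p])
    return shared, concordant, len(shared) - concordant


def select_all_signatures(
    log2ratios: Log2RatioMatrix,
    samples: SampleSheet,
    thresholds: Thresholds = Thresholds(),
    control_group: str = "control",
) -> dict[str, Signature]:
    """Run all four standard comparisons."""
    return {
        nm: select_signature(
            log2ratios, samples, case, thresholds, control_group, name=nm
        )
        for nm, case in COMPARISONS.items()
    }
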