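"""Expression-matrix containers and preprocessing.

The preprocessing chain mirrors the standard workflow for bead-array PBMC
profiling after instrument-side normalization:

1. per-sample intensity scaling to a common mean and log2 transformation;
2. detection filtering on the per-probe/per-sample detection p-values;
3. removal of probes correlated with known confounders of bulk PBMC
   expression (age, sex, differential leukocyte count);
4. log2-ratio transformation against the control-group mean.

All operations are pure: they return new containers and a
:class:`FilterReport` describing what was removed and why.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("rasosig")

#: Closed vocabulary of sample groups. ``control`` is always the reference.
GROUPS: tuple[str, ...] = ("control", "PTPN11", "SOS1", "SHOC2")

#: Differential leukocyte count columns of the sample sheet (fractions of a
#: five-part differential; they sum to ~1 per sample).
LEUKOCYTE_COLS: tuple[str, ...] = (
    "neut_frac",
    "lymph_frac",
    "mono_frac",
    "eos_frac",
    "baso_frac",
)

#: Confounders tested by :func:`confound_filter`: age (Pearson), sex
#: (point-biserial, i.e. Pearson against the 0/1 code) and the five leukocyte
#: fractions (Pearson each) — seven per-probe tests in total.
CONFOUNDERS: tuple[str, ...] = ("age", "sex") + LEUKOCYTE_COLS


@dataclass
class ExpressionMatrix:
    """Probes x samples intensity matrix with detection p-values.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample. Linear
        intensities unless ``log_scale`` is set.
    detection_p
        DataFrame of detection p-values with identical shape/labels, or
        ``None`` when detection information is unavailable.
    log_scale
        Whether ``values`` is on the log2 scale.
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("probe ids must be unique")
        if self.values.columns.has_duplicates:
            raise ValueError("sample ids must be unique")
        if self.detection_p is not None:
            if self.detection_p.shape != self.values.shape:
                raise ValueError(
                    "values and detection_p dimensions differ: "
                    f"{self.values.shape} vs {self.detection_p.shape}"
                )
            if not self.detection_p.index.equals(self.values.index):
                raise ValueError("detection_p probe ids differ from values")
            if not self.detection_p.columns.equals(self.values.columns):
                raise ValueError("detection_p sample ids differ from values")
            dp = self.detection_p.to_numpy()
            if np.nanmin(dp) < 0 or np.nanmax(dp) > 1:
                raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        det = None if self.detection_p is None else self.detection_p.loc[probes]
        return ExpressionMatrix(self.values.loc[probes], det, self.log_scale)


@dataclass
class SampleSheet:
    """Per-sample group label and confounders.

    ``table`` is indexed by sample id and carries ``group`` (one of
    :data:`GROUPS`), ``age`` in years, ``sex`` coded 0/1, and the five
    leukocyte fractions of :data:`LEUKOCYTE_COLS`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "age", "sex", *LEUKOCYTE_COLS}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if (self.table["age"] < 0).any():
            raise ValueError("ages must be non-negative")
        fr = self.table[list(LEUKOCYTE_COLS)].sum(axis=1)
        if not np.allclose(fr, 1.0, atol=0.05):
            raise ValueError("leukocyte fractions must sum to ~1 per sample")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def groups(self) -> pd.Series:
        return self.table["group"]

    def samples_in(self, groups: Iterable[str]) -> list[str]:
        groups = set(groups)
        return [s for s, g in self.table["group"].items() if g in groups]

    def subset(self, sample_ids: Sequence[str]) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)])


@dataclass
class FilterReport:
    """Bookkeeping for the detection and confounder filters."""

    n_input_probes: int
    n_detected: int
    n_after_confound_removal: int
    removed_by_confounder: dict[str, list[str]] = field(default_factory=dict)
    thresholds: dict[str, float | str | bool] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (
            self.n_after_confound_removal <= self.n_detected <= self.n_input_probes
        ):
            raise ValueError("filter counts must be non-increasing")

    def to_dict(self) -> dict:
        return {
            "n_input_probes": self.n_input_probes,
            "n_detected": self.n_detected,
            "n_after_confound_removal": self.n_after_confound_removal,
            "removed_by_confounder": self.removed_by_confounder,
            "thresholds": self.thresholds,
            "notes": self.notes,
        }


@dataclass
class Log2RatioMatrix:
    """Probes x samples log2 expression relative to the reference-group mean.

    When the reference is the control-group mean, control rows are zero-mean
    by construction.
    """

    values: pd.DataFrame
    reference: str = "control"

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# step 1: scaling + log2
# ---------------------------------------------------------------------------

def scale_and_log(
    matrix: ExpressionMatrix,
    target_mean: float | None = None,
    clip_floor: float = 1.0,
) -> ExpressionMatrix:
    """Rescale each sample column to a common mean intensity, then log2.

    Parameters
    ----------
    matrix
        Linear-scale intensities (instrument-normalized).
    target_mean
        Common per-column mean after scaling; defaults to the grand mean of
        the per-column means, so the overall intensity scale is preserved.
    clip_floor
        Intensities are clipped from below at this value before the log;
        must leave every value strictly positive.
    """
    if matrix.log_scale:
        raise ValueError("matrix is already log2-scaled")
    vals = matrix.values.to_numpy(dtype=float)
    if clip_floor > 0:
        vals = np.maximum(vals, clip_floor)
    if (vals <= 0).any():
        raise ValueError("non-positive intensities remain after floor clipping")
    col_means = vals.mean(axis=0)
    if target_mean is None:
        target_mean = float(col_means.mean())
    scaled = vals * (target_mean / col_means)
    out = pd.DataFrame(
        np.log2(scaled), index=matrix.probe_ids, columns=matrix.sample_ids
    )
    return ExpressionMatrix(out, matrix.detection_p, log_scale=True)


# ---------------------------------------------------------------------------
# step 2a: detection filter
# ---------------------------------------------------------------------------

def detection_filter(
    matrix: ExpressionMatrix,
    p_threshold: float = 0.01,
    min_fraction: float = 0.5,
    samples: SampleSheet | None = None,
    by_group: bool = True,
) -> tuple[list[str], FilterReport]:
    """Keep probes reliably detected across samples.

    A probe is kept when its detection p-value is below ``p_threshold`` in at
    least ``min_fraction`` of samples — within at least one group when
    ``by_group`` is set and a sample sheet is supplied, else across all
    samples.
    """
    if matrix.detection_p is None:
        raise ValueError("matrix has no detection p-values")
    det = matrix.detection_p.to_numpy() < p_threshold
    if by_group and samples is not None:
        keep = np.zeros(det.shape[0], dtype=bool)
        groups = samples.groups()
        for g in GROUPS:
            cols = [matrix.sample_ids.get_loc(s) for s in samples.samples_in([g])]
            if not cols:
                continue
            frac = det[:, cols].mean(axis=1)
            keep |= frac >= min_fraction
    else:
        keep = det.mean(axis=1) >= min_fraction
    kept = list(matrix.probe_ids[keep])
    if not kept:
        warnings.warn("detection filter removed every probe", stacklevel=2)
    report = FilterReport(
        n_input_probes=matrix.values.shape[0],
        n_detected=len(kept),
        n_after_confound_removal=len(kept),
        thresholds={
            "detection_p_threshold": p_threshold,
            "detection_min_fraction": min_fraction,
            "detection_by_group": bool(by_group and samples is not None),
        },
    )
    logger.info(
        "detection filter: %d of %d probes kept", len(kept), matrix.values.shape[0]
    )
    return kept, report


# ---------------------------------------------------------------------------
# step 2b: confounder filter
# ---------------------------------------------------------------------------

def _pearson_p(values: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Two-sided Pearson correlation p-value of each row against a covariate.

    Rows with zero variance get p = NaN (association undefined).
    """
    n = values.shape[1]
    x = covariate - covariate.mean()
    sx = x.std(ddof=0)
    xc = values - values.mean(axis=1, keepdims=True)
    sr = xc.std(axis=1, ddof=0)
    # zero variance up to rounding noise counts as constant
    degenerate = sr <= 1e-12 * (np.abs(values).max(axis=1) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ x) / (n * sr * sx)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    # |r| == 1 exactly: t is inf, sf gives 0 — fine; r undefined: NaN carries.
    p[np.isnan(r) | degenerate] = np.nan
    return p


def confound_filter(
    matrix: ExpressionMatrix,
    samples: SampleSheet,
    alpha: float = 0.01,
    report: FilterReport | None = None,
) -> tuple[list[str], FilterReport]:
    """Remove probes associated with age, sex or leukocyte composition.

    Each probe is tested against the seven confounders of
    :data:`CONFOUNDERS`; it is removed if any association p-value falls below
    ``alpha`` (any-hit rule). Constant probes, whose association is
    undefined, are retained with a logged note; constant confounders are
    skipped likewise.
    """
    if not matrix.log_scale:
        raise ValueError("confound filter expects a log2-scale matrix")
    order = list(matrix.sample_ids)
    tab = samples.table.loc[order]
    vals = matrix.values.to_numpy(dtype=float)
    removed_by: dict[str, list[str]] = {}
    notes: list[str] = []
    remove = np.zeros(vals.shape[0], dtype=bool)
    const_rows = vals.std(axis=1) <= 1e-12 * (np.abs(vals).max(axis=1) + 1.0)
    if const_rows.any():
        notes.append(
            f"{int(const_rows.sum())} constant probe(s) retained: "
            "confounder association undefined"
        )
        logger.info(notes[-1])
    for conf in CONFOUNDERS:
        cov = tab[conf].to_numpy(dtype=float)
        if cov.std() <= 1e-12 * (np.abs(cov).max() + 1.0):
            notes.append(f"confounder '{conf}' is constant; test skipped")
            logger.info(notes[-1])
            continue
        p = _pearson_p(vals, cov)
        hit = (p < alpha) & ~np.isnan(p)
        removed_by[conf] = list(matrix.probe_ids[hit])
        remove |= hit
    kept = list(matrix.probe_ids[~remove])
    n_input = report.n_input_probes if report is not None else vals.shape[0]
    n_detected = report.n_detected if report is not None else vals.shape[0]
    thresholds = dict(report.thresholds) if report is not None else {}
    thresholds.update({"confound_alpha": alpha, "confound_method": "pearson"})
    out = FilterReport(
        n_input_probes=n_input,
        n_detected=n_detected,
        n_after_confound_removal=len(kept),
        removed_by_confounder=removed_by,
        thresholds=thresholds,
        notes=(list(report.notes) if report is not None else []) + notes,
    )
    logger.info(
        "confound filter: %d of %d probes kept (alpha=%g)",
        len(kept),
        vals.shape[0],
        alpha,
    )
    return kept, out


# ---------------------------------------------------------------------------
# step 3: log2-ratio transformation
# ---------------------------------------------------------------------------

def to_log2ratio(
    matrix: ExpressionMatrix,
    samples: SampleSheet,
    reference: str = "control",
) -> Log2RatioMatrix:
    """Subtract, per probe, the mean over reference-group samples."""
    if not matrix.log_scale:
        raise ValueError("log2-ratio transformation expects a log2-scale matrix")
    ref_samples = samples.samples_in([reference])
    ref_samples = [s for s in ref_samples if s in matrix.sample_ids]
    if not ref_samples:
        raise ValueError(f"reference group '{reference}' has no samples in matrix")
    ref_mean = matrix.values[ref_samples].mean(axis=1)
    return Log2RatioMatrix(matrix.values.sub(ref_mean, axis=0), reference=reference)


def preprocess(
    matrix: ExpressionMatrix,
    samples: SampleSheet,
    target_mean: float | None = None,
    clip_floor: float = 1.0,
    detection_p_threshold: float = 0.01,
    detection_min_fraction: float = 0.5,
    detection_by_group: bool = True,
    confound_alpha: float = 0.01,
    reference: str = "control",
) -> tuple[Log2RatioMatrix, ExpressionMatrix, FilterReport]:
    """Run the full preprocessing chain.

    Returns the log2-ratio matrix on the surviving probes, the filtered
    log2-scale expression matrix, and the combined filter report.
    """
    logged = scale_and_log(matrix, target_mean=target_mean, clip_floor=clip_floor)
    detected, det_report = detection_filter(
        logged,
        p_threshold=detection_p_threshold,
        min_fraction=detection_min_fraction,
        samples=samples,
        by_group=detection_by_group,
    )
    logged = logged.subset_probes(detected)
    kept, report = confound_filter(
        logged, samples, alpha=confound_alpha, report=det_report
    )
    logged = logged.subset_probes(kept)
    ratios = to_log2ratio(logged, samples, reference=reference)
    return ratios, logged, report
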