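"""Synthetic bead-array-style PBMC expression datasets.

The generator emulates the statistical structure the downstream analysis
assumes: a probes x samples intensity matrix on an Illumina BeadChip scale
with per-probe/per-sample detection p-values, group-specific planted
signatures on the log2 scale, probes correlated with the confounders of bulk
PBMC expression (age, sex, differential leukocyte count), and a sample sheet
for four groups (controls and PTPN11 / SOS1 / SHOC2 mutation carriers).

Model, per probe g and sample s, on the log2 scale::

    x_gs = mu_g + delta_g * sign_g * 1[s in group(g)]
               + beta * c_s * 1[g confound probe] + eps_gs

with ``mu_g ~ Normal(baseline_mean, baseline_sd)``, ``eps_gs ~ Normal(0,
residual_sd)`` and ``c_s`` the probe's standardized confounder. The emitted
matrix is the linear intensity ``2**x`` times a per-sample scale factor, so
the scaling/log step of the preprocessing chain has real work to do.

Planted signature probes and confounder probes are drawn disjointly from the
probes *above* the low-expression quantile, so detection filtering does not
silently delete the planted truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import (
    GROUPS,
    LEUKOCYTE_COLS,
    ExpressionMatrix,
    SampleSheet,
)

#: Group sizes of the emulated study design: 21 controls, 17 PTPN11, 6 SOS1,
#: 5 SHOC2 mutation carriers.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "control": 21,
    "PTPN11": 17,
    "SOS1": 6,
    "SHOC2": 5,
}

#: Dirichlet concentration for the five-part differential leukocyte count,
#: centred on typical pediatric whole-blood proportions
#: (neutrophils/lymphocytes/monocytes/eosinophils/basophils ~ 50/38/8/3/1 %).
LEUKOCYTE_ALPHA: tuple[float, ...] = (25.0, 19.0, 4.0, 1.5, 0.5)


@dataclass
class SignatureSpec:
    """Planted differential expression for one mutation group."""

    n_probes: int
    effect_size: float  # log2 units
    fraction_up: float = 0.5

    def __post_init__(self) -> None:
        if self.n_probes < 0:
            raise ValueError("n_probes must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.fraction_up <= 1:
            raise ValueError("fraction_up must lie in [0, 1]")


@dataclass
class ConfoundSpec:
    """Planted confounder-correlated probes.

    ``confound_beta`` is the slope in log2 units per standard deviation of
    the confounder; leukocyte probes are assigned round-robin to the five
    fractions.
    """

    n_age_probes: int = 150
    n_sex_probes: int = 150
    n_leukocyte_probes: int = 150
    confound_beta: float = 0.5

    def __post_init__(self) -> None:
        if min(self.n_age_probes, self.n_sex_probes, self.n_leukocyte_probes) < 0:
            raise ValueError("confound probe counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_age_probes + self.n_sex_probes + self.n_leukocyte_probes


@dataclass
class DetectionModel:
    """Detection p-value generator.

    Probes whose baseline mean lies in the lowest ``low_expression_quantile``
    are dropout-prone: each of their sample measurements independently fails
    detection with probability ``dropout_p``. Detected probe/sample pairs get
    p ~ Uniform(0, 0.01); dropouts get p ~ Uniform(0.05, 1).
    """

    low_expression_quantile: float = 0.70
    dropout_p: float = 0.85

    def __post_init__(self) -> None:
        if not 0 <= self.low_expression_quantile <= 1:
            raise ValueError("low_expression_quantile must lie in [0, 1]")
        if not 0 <= self.dropout_p <= 1:
            raise ValueError("dropout_p must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Full description of a simulated dataset.

    Defaults reproduce the emulated study design: 20,589 probes on the
    array, 49 samples (21/17/6/5), planted group signatures at one log2
    unit, and confounder-correlated probes strong enough for the confound
    filter to find.
    """

    n_probes: int = 20589
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    signature_spec: dict[str, SignatureSpec] = field(
        default_factory=lambda: {
            "PTPN11": SignatureSpec(200, 1.0),
            "SOS1": SignatureSpec(60, 1.0),
            "SHOC2": SignatureSpec(400, 1.0),
        }
    )
    confound_spec: ConfoundSpec = field(default_factory=ConfoundSpec)
    baseline_mean: float = 8.0  # log2 units
    baseline_sd: float = 2.0
    residual_sd: float = 0.5
    #: shape of an inverse-gamma per-probe variance (mean held at
    #: residual_sd**2); None keeps a single homoscedastic residual_sd.
    #: Real array data are heteroscedastic; shape ~3-5 is realistic.
    variance_shape: float | None = None
    sample_scale_sd: float = 0.1  # log2 units of array-to-array scale wobble
    age_range: tuple[float, float] = (2.0, 18.0)
    detection_model: DetectionModel = field(default_factory=DetectionModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 0:
            raise ValueError("n_probes must be >= 0")
        bad = set(self.group_sizes) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown groups in group_sizes: {sorted(bad)}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        bad = set(self.signature_spec) - (set(GROUPS) - {"control"})
        if bad:
            raise ValueError(f"signatures may only be planted in case groups: {sorted(bad)}")
        n_planted = sum(s.n_probes for s in self.signature_spec.values())
        n_high = self.n_probes - int(
            round(self.detection_model.low_expression_quantile * self.n_probes)
        )
        if n_planted + self.confound_spec.total > n_high:
            raise ValueError(
                "planted signature and confound probes "
                f"({n_planted + self.confound_spec.total}) exceed the "
                f"{n_high} probes above the low-expression quantile"
            )


@dataclass
class SimulatedDataset:
    """A simulated matrix, its sample sheet, and the planted truth.

    ``truth`` maps probe id -> ``{"label": <group or confounder>,
    "direction": "up"|"down"}``. Confounder probes carry the direction of
    their slope.
    """

    matrix: ExpressionMatrix
    samples: SampleSheet
    truth: dict[str, dict[str, str]]
    config: SimulationConfig

    def __post_init__(self) -> None:
        probe_set = set(self.matrix.probe_ids)
        if not set(self.truth) <= probe_set:
            raise ValueError("truth keys must be a subset of matrix probe ids")
        if list(self.matrix.sample_ids) != list(self.samples.sample_ids):
            raise ValueError("matrix samples and sample sheet disagree")

    def planted_probes(self, group: str) -> list[str]:
        return [p for p, t in self.truth.items() if t["label"] == group]


_SAMPLE_PREFIX = {"control": "C", "PTPN11": "PT", "SOS1": "SO", "SHOC2": "SH"}


def _sample_sheet(config: SimulationConfig, rng: np.random.Generator) -> SampleSheet:
    rows = []
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        lo, hi = config.age_range
        for i in range(n):
            fracs = rng.dirichlet(LEUKOCYTE_ALPHA)
            rows.append(
                {
                    "sample_id": f"{_SAMPLE_PREFIX[group]}-{i + 1:03d}",
                    "group": group,
                    "age": float(np.round(rng.uniform(lo, hi), 1)),
                    "sex": int(rng.integers(0, 2)),
                    **dict(zip(LEUKOCYTE_COLS, np.round(fracs, 6))),
                }
            )
    table = pd.DataFrame(rows).set_index("sample_id")
    # rounding the fractions can leave the sum a hair off 1; renormalize
    fr = table[list(LEUKOCYTE_COLS)]
    table[list(LEUKOCYTE_COLS)] = fr.div(fr.sum(axis=1), axis=0)
    return SampleSheet(table)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset from the generative model (reproducible per seed)."""
    rng = np.random.default_rng(config.seed)
    samples = _sample_sheet(config, rng)
    n_samples = len(samples.sample_ids)
    n_probes = config.n_probes

    probe_ids = np.array([f"ILMN_{i + 1:06d}" for i in range(n_probes)])
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=n_probes)
    if config.variance_shape is not None:
        a = config.variance_shape
        if a <= 1:
            raise ValueError("variance_shape must exceed 1 (finite mean variance)")
        # inverse-gamma per-probe variance with mean residual_sd**2
        scale = config.residual_sd**2 * (a - 1)
        probe_sd = np.sqrt(scale / rng.gamma(a, 1.0, size=n_probes))
    else:
        probe_sd = np.full(n_probes, config.residual_sd)
    x = mu[:, None] + probe_sd[:, None] * rng.normal(
        0.0, 1.0, size=(n_probes, n_samples)
    )

    # eligible probes for planting: above the low-expression quantile
    q = config.detection_model.low_expression_quantile
    cut = np.quantile(mu, q) if n_probes else np.inf
    eligible = np.flatnonzero(mu >= cut)
    eligible = rng.permutation(eligible)

    truth: dict[str, dict[str, str]] = {}
    pos = 0
    group_cols = {
        g: np.array(
            [samples.sample_ids.get_loc(s) for s in samples.samples_in([g])],
            dtype=int,
        )
        for g in GROUPS
    }

    for group in sorted(config.signature_spec):
        spec = config.signature_spec[group]
        idx = eligible[pos : pos + spec.n_probes]
        pos += spec.n_probes
        if spec.n_probes == 0 or spec.effect_size == 0:
            # a zero effect plants nothing: the global null stays a null
            continue
        n_up = int(round(spec.fraction_up * len(idx)))
        signs = np.array([1.0] * n_up + [-1.0] * (len(idx) - n_up))
        cols = group_cols[group]
        x[np.ix_(idx, cols)] += spec.effect_size * signs[:, None]
        for p, s in zip(probe_ids[idx], signs):
            truth[p] = {"label": group, "direction": "up" if s > 0 else "down"}

    conf = config.confound_spec
    tab = samples.table
    covariates: list[tuple[str, np.ndarray, int]] = [
        ("age", tab["age"].to_numpy(float), conf.n_age_probes),
        ("sex", tab["sex"].to_numpy(float), conf.n_sex_probes),
    ]
    per_frac = np.full(len(LEUKOCYTE_COLS), conf.n_leukocyte_probes // len(LEUKOCYTE_COLS))
    per_frac[: conf.n_leukocyte_probes % len(LEUKOCYTE_COLS)] += 1
    for col, k in zip(LEUKOCYTE_COLS, per_frac):
        covariates.append((col, tab[col].to_numpy(float), int(k)))

    for label, cov, k in covariates:
        idx = eligible[pos : pos + k]
        pos += k
        if k == 0:
            continue
        z = _standardize(cov)
        signs = np.where(rng.random(len(idx)) < 0.5, 1.0, -1.0)
        x[idx, :] += conf.confound_beta * signs[:, None] * z[None, :]
        for p, s in zip(probe_ids[idx], signs):
            truth[p] = {"label": label, "direction": "up" if s > 0 else "down"}

    # detection p-values: dropout-prone probes are those below the quantile
    detect_p = rng.uniform(0.0, 0.01, size=(n_probes, n_samples))
    low = mu < cut
    dropout = low[:, None] & (
        rng.random((n_probes, n_samples)) < config.detection_model.dropout_p
    )
    detect_p[dropout] = rng.uniform(0.05, 1.0, size=int(dropout.sum()))

    # linear-scale intensities with per-array scale wobble
    scale = 2.0 ** rng.normal(0.0, config.sample_scale_sd, size=n_samples)
    linear = (2.0**x) * scale[None, :]

    index = pd.Index(probe_ids, name="probe_id")
    cols = samples.sample_ids.rename(None)
    values = pd.DataFrame(linear, index=index, columns=cols)
    detection = pd.DataFrame(detect_p, index=index, columns=cols)
    matrix = ExpressionMatrix(values, detection, log_scale=False)
    return SimulatedDataset(matrix, samples, truth, config)


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

MATRIX_FILE = "matrix.tsv"
DETECTION_FILE = "detection.tsv"
SAMPLES_FILE = "samples.tsv"
TRUTH_FILE = "truth.json"

_FLOAT_FMT = "%.17g"  # lossless decimal representation of float64


def write_fixture(dataset: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write matrix/detection/sample-sheet TSVs and the truth JSON.

    The TSV dialect round-trips bit-identically through
    :func:`rasosig.pipeline.read_expression` /
    :func:`rasosig.pipeline.read_sample_sheet`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / MATRIX_FILE,
        "detection": directory / DETECTION_FILE,
        "samples": directory / SAMPLES_FILE,
        "truth": directory / TRUTH_FILE,
    }
    dataset.matrix.values.to_csv(
        paths["matrix"], sep="\t", index_label="probe_id", float_format=_FLOAT_FMT
    )
    dataset.matrix.detection_p.to_csv(
        paths["detection"], sep="\t", index_label="probe_id", float_format=_FLOAT_FMT
    )
    dataset.samples.table.to_csv(
        paths["samples"], sep="\t", index_label="sample_id", float_format=_FLOAT_FMT
    )
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
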