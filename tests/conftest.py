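import numpy as np
import pandas as pd
import pytest

import rasosig as rs


def small_config(seed: int = 7, **kwargs) -> rs.SimulationConfig:
    """A fast dataset of the full study design: 600 probes, 49 samples."""
    defaults = dict(
        n_probes=600,
        signature_spec={
            "PTPN11": rs.SignatureSpec(40, 1.0),
            "SOS1": rs.SignatureSpec(10, 1.0),
            "SHOC2": rs.SignatureSpec(20, 1.0),
        },
        confound_spec=rs.ConfoundSpec(15, 15, 15, 0.6),
        seed=seed,
    )
    defaults.update(kwargs)
    return rs.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset() -> rs.SimulatedDataset:
    return rs.simulate(small_config())


@pytest.fixture(scope="session")
def small_ratios(small_dataset):
    """Log2-ratio matrix of the small dataset with all probes retained."""
    logged = rs.scale_and_log(small_dataset.matrix)
    return rs.to_log2ratio(logged, small_dataset.samples)


@pytest.fixture(scope="session")
def small_signatures(small_ratios, small_dataset):
    return rs.select_all_signatures(small_ratios, small_dataset.samples)


def toy_sample_sheet(groups: dict[str, int]) -> rs.SampleSheet:
    """Minimal valid sample sheet with deterministic confounders."""
    rows = []
    i = 0
    for g, n in groups.items():
        for _ in range(n):
            i += 1
            rows.append(
                {
                    "sample_id": f"S{i:02d}",
                    "group": g,
                    "age": 5.0 + i,
                    "sex": i % 2,
                    "neut_frac": 0.5,
                    "lymph_frac": 0.35,
                    "mono_frac": 0.1,
                    "eos_frac": 0.04,
                    "baso_frac": 0.01,
                }
            )
    return rs.SampleSheet(pd.DataFrame(rows).set_index("sample_id"))


def ratios_from_array(
    values: np.ndarray, samples: rs.SampleSheet
) -> rs.Log2RatioMatrix:
    probe_ids = [f"P{j}" for j in range(values.shape[0])]
    return rs.Log2RatioMatrix(
        pd.DataFrame(values, index=probe_ids, columns=samples.sample_ids)
    )
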