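from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from methylnorm.datatypes import IntensityDataset
from methylnorm.simulate import SimulationConfig, simulate_dataset


def make_dataset(
    meth,
    unmeth,
    assay_types,
    chromosomes=None,
    is_snp=None,
    is_idmr=None,
    sexes=None,
    with_positions=True,
) -> IntensityDataset:
    """Assemble a small IntensityDataset from plain arrays."""
    meth = np.atleast_2d(np.asarray(meth, dtype=float))
    unmeth = np.atleast_2d(np.asarray(unmeth, dtype=float))
    n_probes, n_samples = meth.shape
    probe_ids = [f"cg{i:05d}" for i in range(n_probes)]
    sample_ids = [f"S{j}" for j in range(n_samples)]
    assay_types = list(assay_types)
    probes = pd.DataFrame(
        {
            "AssayType": assay_types,
            "Chromosome": chromosomes if chromosomes is not None else ["1"] * n_probes,
            "Channel": ["Both" if t == "II" else "Red" for t in assay_types],
            "IsSNP": is_snp if is_snp is not None else [False] * n_probes,
            "IsIDMR": is_idmr if is_idmr is not None else [False] * n_probes,
        },
        index=pd.Index(probe_ids, name="ProbeID"),
    )
    samples = pd.DataFrame(
        {
            "Sex": sexes if sexes is not None else ["unknown"] * n_samples,
            "ChipID": ["chip00"] * n_samples,
            "ChipRow": (np.arange(n_samples) % 6 + 1) if with_positions else [np.nan] * n_samples,
            "ChipCol": ([1] * n_samples) if with_positions else [np.nan] * n_samples,
        },
        index=pd.Index(sample_ids, name="SampleID"),
    )
    return IntensityDataset(
        methylated=pd.DataFrame(meth, index=probes.index, columns=samples.index),
        unmethylated=pd.DataFrame(unmeth, index=probes.index, columns=samples.index),
        probes=probes,
        samples=samples,
    )


SMALL_SIM = SimulationConfig(
    n_samples=12,
    n_autosomal=3000,
    n_idmr=60,
    n_snp=20,
    n_x=120,
    seed=7,
)


@pytest.fixture(scope="session")
def small_sim():
    """A reduced-scale simulated dataset shared across tests (read-only)."""
    dataset, truth = simulate_dataset(SMALL_SIM)
    return dataset, truth


@pytest.fixture(scope="session")
def default_sim():
    """One full-scale simulated dataset (default study conditions)."""
    dataset, truth = simulate_dataset(SimulationConfig(seed=101))
    return dataset, truth
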