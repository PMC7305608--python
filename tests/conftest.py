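import numpy as np
import pandas as pd
import pytest

from pelletome import (
    CountMatrix,
    SampleManifest,
    SampleRecord,
    SimulationConfig,
    simulate_pelletome,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_manifest(groups=("control", "AD"), n_subjects=2):
    """Complete paired design: every subject has soluble + pellet samples."""
    prefixes = {"control": "C", "AD": "AD", "MCI": "M"}
    records = []
    for group in groups:
        for j in range(1, n_subjects + 1):
            subject = f"{prefixes[group]}{j}"
            for fraction in ("soluble", "pellet"):
                records.append(
                    SampleRecord(
                        sample_id=f"{subject}_{fraction[:3]}",
                        subject_id=subject,
                        group=group,
                        fraction=fraction,
                    )
                )
    return SampleManifest(tuple(records))


@pytest.fixture
def paired_manifest():
    return make_manifest()


@pytest.fixture
def paired_counts(paired_manifest, rng):
    data = rng.integers(0, 50, size=(5, len(paired_manifest.sample_ids)))
    return CountMatrix(
        pd.DataFrame(
            data,
            index=[f"P{i}" for i in range(5)],
            columns=paired_manifest.sample_ids,
        ).astype(np.int64)
    )


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulated dataset shared across read-only tests."""
    return simulate_pelletome(SimulationConfig(n_per_group=4, n_proteins=300, seed=7))
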