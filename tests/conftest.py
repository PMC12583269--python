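import numpy as np
import pytest

from immunorank.normalize import RawPanelCounts, ReferenceModel, build_reference_model
from immunorank.simulate import SimulationConfig, generate_reference, generate_study_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Down-scaled study for fast unit tests (same structure as defaults)."""
    return SimulationConfig(seed=11, n_reference=150, n_study=160)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_study_cohort(small_config)


@pytest.fixture(scope="session")
def tiny_panel():
    """Hand-sized panel: 3 assay genes + 10 housekeeping genes, one batch."""
    genes = ["GENE_A", "GENE_B", "GENE_C"] + [f"HK{i}" for i in range(10)]
    rng = np.random.default_rng(5)
    counts = rng.integers(50, 2000, size=(6, len(genes)))
    sample_ids = [f"S{i}" for i in range(6)]
    raw = RawPanelCounts(
        sample_ids=sample_ids,
        gene_ids=genes,
        counts=counts,
        batch_of={s: "b1" for s in sample_ids},
        ntc_of={"b1": rng.integers(0, 10, size=len(genes))},
    )
    model = build_reference_model(raw, [f"HK{i}" for i in range(10)])
    return raw, model
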