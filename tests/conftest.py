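import numpy as np
import pytest

import tetragp as tg


@pytest.fixture(scope="session")
def small_map() -> tg.MarkerMap:
    """4 chromosomes x 30 markers, 6 markers per probe."""
    return tg.simulate_marker_map(
        n_chrom=4, markers_per_chrom=30, markers_per_probe=6, seed=42
    )


@pytest.fixture(scope="session")
def one_chrom_map() -> tg.MarkerMap:
    return tg.simulate_marker_map(
        n_chrom=1, markers_per_chrom=20, markers_per_probe=5, seed=7
    )


@pytest.fixture(scope="session")
def small_study() -> tg.StudyData:
    """Small synthetic study reused across pipeline-level tests."""
    return tg.simulate_study(
        n_founders=16,
        n_families=12,
        family_size=10,
        n_chrom=4,
        markers_per_chrom=40,
        seed=99,
    )


def make_parent(dosage: int, n_markers: int) -> np.ndarray:
    """Tetraploid parent with the given alternative-allele dosage at every
    marker (alleles packed into the first `dosage` homologs)."""
    haps = np.zeros((4, n_markers), dtype=np.uint8)
    haps[:dosage, :] = 1
    return haps
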