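import numpy as np
import pandas as pd
import pytest

from methtrend.manifest_io import CpGSite, Manifest
from methtrend.synthetic_data import CohortSpec, generate_beta, generate_cohort, generate_manifest


@pytest.fixture(scope="session")
def small_manifest() -> Manifest:
    """Three annotated sites on two chromosomes."""
    return Manifest(
        [
            CpGSite("cg000001", "1", 100, "Island", "TSS200", "GENEA"),
            CpGSite("cg000002", "1", 250, "Shore", "Body", "GENEA"),
            CpGSite("cg000003", "2", 500, "OpenSea", "IGR", None),
        ]
    )


def dense_manifest(n: int, gap: int = 100, chrom: str = "1") -> Manifest:
    """Evenly spaced sites on one chromosome (for scanner scenarios)."""
    return Manifest(
        [
            CpGSite(f"cg{i:06d}", chrom, 1000 + i * gap, "Island", "TSS200", "GENEX")
            for i in range(n)
        ]
    )


def gapped_manifest(gaps) -> Manifest:
    """Sites on one chromosome with the given adjacent gaps."""
    pos = np.concatenate([[1000], 1000 + np.cumsum(gaps)])
    return Manifest(
        [
            CpGSite(f"cg{i:06d}", "1", int(p), "Island", "TSS200", None)
            for i, p in enumerate(pos)
        ]
    )


@pytest.fixture(scope="session")
def cohort280() -> pd.DataFrame:
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def null_dataset(cohort280):
    """10k-site null β matrix (no spiked effects) with its manifest."""
    manifest = generate_manifest(10_000, seed=21)
    beta = generate_beta(manifest, cohort280, seed=22)
    return manifest, beta
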