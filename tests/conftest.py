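import numpy as np
import pandas as pd
import pytest

from admixmort.genotypes import GenotypeMatrix


def make_matrix(dosage, chrom=None, samples=None):
    """Small GenotypeMatrix from a dense array (NaN = missing)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    variants = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "id": [f"v{j}" for j in range(m)],
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return GenotypeMatrix(
        samples=samples or [f"s{i}" for i in range(n)],
        variants=variants,
        dosage=dosage,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_panel():
    """K=3 reference panel with well-separated frequencies."""
    from admixmort.ancestry import ReferencePanel

    rng = np.random.default_rng(11)
    freqs = np.clip(rng.uniform(0.05, 0.95, (3, 200)), 1e-6, 1 - 1e-6)
    return ReferencePanel(
        populations=["P1", "P2", "P3"],
        freqs=freqs,
        n_samples={"P1": 20, "P2": 20, "P3": 20},
    )
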