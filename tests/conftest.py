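import numpy as np
import pytest

from sorlscan.types import GenotypeMatrix, SampleRecord


def make_samples(n_cases, n_controls, ancestry="EUR", phenotype="AD", seed=0):
    """Deterministic sample records with complete covariates."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_cases + n_controls):
        is_case = i < n_cases
        out.append(
            SampleRecord(
                sample_id=f"S{i}",
                ancestry=ancestry,
                phenotype=phenotype if is_case else "control",
                sex=int(rng.integers(1, 3)),
                age_years=float(rng.normal(65, 10)),
                aao_years=float(rng.normal(60, 10)) if is_case else None,
                family_history=["yes", "no", "unknown"][i % 3],
                pcs=tuple(rng.normal(size=10)),
            )
        )
    return out


def make_matrix(dosages, seed=0, chrom="11", start=121_500_000):
    """GenotypeMatrix with generated sample ids and variant keys."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    keys = [f"{chrom}:{start + 10 * j}:A:G" for j in range(m)]
    return GenotypeMatrix([f"S{i}" for i in range(n)], keys, dosages)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
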