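import numpy as np
import pytest

from ribodelta.datatypes import CountTable, GeneAnnotation, SampleMeta, TruthRecord


@pytest.fixture
def design_samples():
    """Standard 2x2 duplicate design: mRNA/RPF x t0/t30 x 2 reps."""
    return [
        SampleMeta(f"{assay}_{cond}_r{rep}", assay, cond, rep)
        for assay in ("mRNA", "RPF")
        for cond in ("t0", "t30")
        for rep in (1, 2)
    ]


@pytest.fixture
def design_matrix():
    a = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
    c = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=float)
    return np.column_stack([np.ones(8), a, c, a * c])


@pytest.fixture
def small_table(design_samples):
    rng = np.random.default_rng(123)
    counts = rng.poisson(200.0, size=(5, 8))
    return CountTable([f"g{i}" for i in range(5)], design_samples, counts)


def make_null_truths(n, base_mean=200.0, dispersion=0.1):
    return [
        TruthRecord(f"g{i:05d}", "not_regulated", 0.0, 0.0, base_mean, dispersion)
        for i in range(1, n + 1)
    ]


def make_annotations(n, utr5=50, cds=300, utr3=50):
    return [GeneAnnotation(f"g{i:05d}", utr5, cds, utr3) for i in range(1, n + 1)]
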