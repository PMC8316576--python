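import numpy as np
import pandas as pd
import pytest

from dmrkit.core import MethylationMatrix


def build_matrix(positions, ratios, coverage=None, chrom="chr1", samples=None):
    """Assemble a MethylationMatrix from a position list and a
    (n_sites, n_samples) ratio array; coverage defaults to 10 where the
    ratio is present and 0 where it is NaN."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.ndim == 1:
        ratios = ratios.reshape(-1, 1)
    n_sites, n_samples = ratios.shape
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    if coverage is None:
        coverage = np.where(np.isnan(ratios), 0, 10)
    return MethylationMatrix(
        chroms=np.full(n_sites, chrom, dtype=object),
        starts=np.asarray(positions, dtype=np.int64),
        samples=list(samples),
        ratio=ratios,
        coverage=np.asarray(coverage, dtype=np.int64),
    )


def build_metadata(samples, groups, ages=None, sexes=None):
    n = len(samples)
    ages = ages if ages is not None else [10.0] * n
    sexes = sexes if sexes is not None else ["M", "F"] * (n // 2 + 1)
    return pd.DataFrame(
        {"sample": samples, "group": groups, "age": ages, "sex": sexes[:n]}
    )


@pytest.fixture
def two_group_cohort():
    """12 CpGs spaced 50 bp, 3 test samples around 0.3 vs 3 reference
    samples around 0.8 (clear hypomethylation in the test group)."""
    rng = np.random.default_rng(0)
    positions = 1000 + 50 * np.arange(12)
    test = np.clip(rng.normal(0.30, 0.02, (12, 3)), 0, 1)
    ref = np.clip(rng.normal(0.80, 0.02, (12, 3)), 0, 1)
    matrix = build_matrix(positions, np.hstack([test, ref]),
                          samples=["t1", "t2", "t3", "r1", "r2", "r3"])
    meta = build_metadata(
        ["t1", "t2", "t3", "r1", "r2", "r3"],
        ["case", "case", "case", "control", "control", "control"],
        ages=[5.0, 9.0, 14.0, 6.0, 11.0, 20.0],
    )
    return matrix, meta
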