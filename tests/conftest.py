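import numpy as np
import pandas as pd
import pytest

from seroprog import CohortConfig, NPXMatrix, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """150-sample cohort with two strong planted markers (one harmful, one
    protective), used across selection and inference tests."""
    config = CohortConfig(
        n_samples=150,
        planted_effects={
            "P001": (np.log(2.0), np.log(2.0)),
            "P020": (np.log(0.5), np.log(0.5)),
        },
        censoring_rate=0.3,
        seed=11,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects and independent proteins."""
    config = CohortConfig(n_samples=150, n_proteins=30, correlation_blocks=(),
                          planted_effects={}, censoring_rate=0.3, seed=5)
    return generate_cohort(config)


@pytest.fixture
def toy_npx():
    """4 samples x 3 proteins with one NA and known LODs."""
    values = np.array([
        [3.0, 5.0, 2.0],
        [1.8, 4.0, np.nan],
        [0.5, 6.0, 2.5],
        [2.5, 5.5, 3.0],
    ])
    return NPXMatrix(
        sample_ids=["s1", "s2", "s3", "s4"],
        protein_ids=["A", "B", "C"],
        values=values,
        lod=np.array([2.0, 1.0, 1.0]),
        lod_sd=np.array([0.5, 0.0, 0.0]),
    )


def brute_force_harrell(time, event, risk):
    """O(n^2) pair enumeration oracle for Harrell's C."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


def brute_force_fisher_p(table):
    """Two-sided Fisher p by hypergeometric enumeration over all tables with
    the observed margins."""
    from scipy.stats import hypergeom

    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, col1, row1)
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    p_obs = rv.pmf(a)
    return float(sum(rv.pmf(x) for x in support if rv.pmf(x) <= p_obs * (1 + 1e-9)))


def brute_force_bh(pvals, m):
    """Step-up enumeration oracle for Benjamini-Hochberg q-values."""
    idx = sorted(range(len(pvals)), key=lambda i: pvals[i])
    q = [0.0] * len(pvals)
    prev = 1.0
    for rank_pos in range(len(pvals) - 1, -1, -1):
        i = idx[rank_pos]
        val = min(prev, pvals[i] * m / (rank_pos + 1), 1.0)
        q[i] = val
        prev = val
    return q
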