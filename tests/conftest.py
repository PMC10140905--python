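"""Shared fixtures and independent oracles."""

import math
from itertools import combinations

import numpy as np
import pytest

import renalmtr as rm


def exact_ranksum_p(a, b) -> float:
    """Brute-force two-sided rank-sum p by complete enumeration.

    Enumerates every assignment of ranks to the first arm under the null
    and counts assignments whose rank sum is at least as far from its null
    expectation as the observed one. Valid for tie-free inputs only.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    assert np.unique(pooled).size == pooled.size, "oracle requires tie-free data"
    ranks = pooled.argsort().argsort() + 1
    obs = ranks[: a.size].sum()
    n = pooled.size
    mu = a.size * (n + 1) / 2.0
    count = 0
    total = 0
    for combo in combinations(range(1, n + 1), a.size):
        total += 1
        if abs(sum(combo) - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


@pytest.fixture(scope="session")
def meta128():
    return rm.AcquisitionMeta(field_strength=3.0, offset_frequency=600, matrix_size=128)


@pytest.fixture(scope="session")
def geometry128(meta128):
    return rm.build_geometry(meta128, seed=1)


@pytest.fixture(scope="session")
def truth_3t600():
    """Tissue truths matching the 3T/600Hz group means (muscle MTR 0.40)."""
    return rm.TissueTruth(
        kidney_mtr={
            "left": {"cortex": 0.75 * 0.40, "medulla": 0.74 * 0.40},
            "right": {"cortex": 0.64 * 0.40, "medulla": 0.53 * 0.40},
        }
    )


@pytest.fixture(scope="session")
def noiseless_sim(geometry128, truth_3t600, meta128):
    """Noiseless, uniform-B1 acquisition of the fixture geometry."""
    return rm.simulate_acquisition(
        geometry128,
        truth_3t600,
        meta128,
        b1=rm.B1FieldSpec(amplitude=0.0),
        noise=rm.NoiseSpec(snr=math.inf),
        seed=0,
    )


@pytest.fixture()
def tiny_spec():
    """Small single-stratum cohort for fast structural tests."""
    return rm.CohortSpec(
        n_ras=2,
        n_sham=1,
        matrix_size=64,
        n_slices=2,
        field_strengths=(3.0,),
        offset_frequencies=(600,),
        timepoints=(1,),
    )
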