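import numpy as np
import pytest

from iegnet import (CohortSpec, RegionTable, ThresholdSpec, make_ground_truth,
                    simulate_cohort)


@pytest.fixture
def small_table() -> RegionTable:
    """5 regions × 4 animals, hand-written non-negative densities."""
    rng = np.random.default_rng(42)
    values = rng.uniform(0.5, 3.0, size=(5, 4))
    return RegionTable([f"REG{i}" for i in range(5)], [f"M{j}" for j in range(4)], values)


@pytest.fixture
def toy_corr():
    """Fixed 4-region correlation fixture with one significant negative pair.

    p-values hand-assigned so that exactly (A,B) [r>0] and (C,D) [r<0] pass
    alpha=0.05 uncorrected.
    """
    from iegnet import CorrelationResult

    regions = ["A", "B", "C", "D"]
    r = np.eye(4)
    pairs = {(0, 1): (0.92, 0.001), (0, 2): (0.30, 0.40), (0, 3): (0.10, 0.80),
             (1, 2): (0.25, 0.50), (1, 3): (-0.20, 0.60), (2, 3): (-0.90, 0.002)}
    p = np.full((4, 4), np.nan)
    for (i, j), (rij, pij) in pairs.items():
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij
    return CorrelationResult(regions=regions, r=r, p=p, n=12)


@pytest.fixture(scope="session")
def paper_scale_cohort() -> RegionTable:
    """60 regions × 12 animals with intermediate effect size — the shape of
    the motivating study (fixed seeds)."""
    truth = make_ground_truth(60, 0.1, seed=0, effect_r=0.5)
    return simulate_cohort(truth, CohortSpec(n_animals=12), seed=1)


@pytest.fixture
def alpha_only_spec() -> ThresholdSpec:
    """Uncorrected significance at alpha = 0.05, anticorrelations excluded."""
    return ThresholdSpec(alpha=0.05, fdr_q=None)
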