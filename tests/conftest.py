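import numpy as np
import pytest

from optimcv import (
    CaseControlDataset,
    calibrate_scale_constant,
    cesarean_like_spec,
    down_like_spec,
    draw_case_control,
)


def brute_force_concordance(scores, outcome):
    """Independent all-pairs C: explicit enumeration of case-control pairs."""
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome)
    cases = scores[outcome == 1]
    controls = scores[outcome == 0]
    conc = tied = 0
    for a in cases:
        for b in controls:
            if a > b:
                conc += 1
            elif a == b:
                tied += 1
    return (conc + 0.5 * tied) / (len(cases) * len(controls)), conc, tied


@pytest.fixture(scope="session")
def down_spec_small_mc():
    """Down-like spec calibrated to C=0.90 at reduced Monte-Carlo size (for unit tests)."""
    return calibrate_scale_constant(down_like_spec(), 0.90, tol=0.004,
                                    rng=np.random.default_rng(1234), n_mc=120_000)


@pytest.fixture(scope="session")
def cesarean_spec_small_mc():
    return calibrate_scale_constant(cesarean_like_spec(), 0.71, tol=0.004,
                                    rng=np.random.default_rng(1234), n_mc=120_000)


@pytest.fixture(scope="session")
def epv5_dataset(down_spec_small_mc):
    """One simulated down-like small dataset: 15 cases, 60 controls (EPV 5)."""
    return draw_case_control(down_spec_small_mc, 15, 60, np.random.default_rng(77))


@pytest.fixture
def tiny_overlap_dataset():
    """12 rows, one covariate, informative but not separable (nor in resamples)."""
    rng = np.random.default_rng(42)
    y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
    x = np.where(y == 1, 1.0, 0.0) + rng.normal(0, 1.0, 12)
    return CaseControlDataset(y, x)


@pytest.fixture
def perfect_dataset():
    """A single perfectly predictive covariate (but overlapping enough to fit)."""
    y = np.array([1] * 5 + [0] * 20)
    x = np.concatenate([np.linspace(2.0, 3.0, 5), np.linspace(-1.0, 1.5, 20)])
    return CaseControlDataset(y, x)
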