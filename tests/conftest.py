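import numpy as np
import pytest
from hypothesis import settings

from coldstun_mpi import (
    BloodPanel,
    ScoredCohort,
    default_band_tables,
    load_coefficients,
)

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tables():
    return default_band_tables()


@pytest.fixture(scope="session")
def coeffs():
    return load_coefficients("human-default")


@pytest.fixture
def worked_panel():
    """The documented worked example: pH 7.35, pCO2 48, Na 180, K 6.6."""
    return BloodPanel(animal_id="worked", pH=7.35, pCO2=48.0, sodium=180.0, potassium=6.6)


@pytest.fixture
def all_normal_panel():
    """A panel falling in every analyte's normal gap: scores 0 on all indices."""
    return BloodPanel(
        animal_id="normal",
        pH=7.55,
        pCO2=30.0,
        pO2=80.0,
        sodium=150.0,
        potassium=3.5,
        glucose=5.0,
        ionized_calcium=0.9,
        chloride=115.0,
        anion_gap=20.0,
        osmolality=330.0,
        bicarbonate=25.0,
    )


@pytest.fixture
def four_animal_cohort():
    """Two died (scores 10, 4), two survived (scores 2, 12)."""
    return ScoredCohort.from_pairs([(10, 1), (4, 1), (2, 0), (12, 0)])


def random_cohort(rng: np.random.Generator, max_n: int = 200) -> ScoredCohort:
    """A random valid cohort with at least one member per class."""
    m = int(rng.integers(1, max_n // 2))
    n = int(rng.integers(1, max_n // 2))
    # integer-ish scores so ties actually occur
    pos = rng.integers(0, 15, size=m) + rng.choice([0.0, 0.5], size=m)
    neg = rng.integers(0, 12, size=n) + rng.choice([0.0, 0.5], size=n)
    return ScoredCohort(
        np.concatenate([pos, neg]),
        np.concatenate([np.ones(m, dtype=int), np.zeros(n, dtype=int)]),
    )


def mann_whitney_auc(cohort: ScoredCohort) -> float:
    """Independent brute-force pair-counting oracle (ties counted 1/2)."""
    pos = cohort.pos_scores
    neg = cohort.neg_scores
    wins = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(pos) * len(neg))
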