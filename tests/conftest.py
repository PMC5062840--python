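"""Shared fixtures.

The expensive fixture is the default synthetic cohort (100 samples per
reliability group) with its extracted features; it is computed once per
session and shared between the feature-contrast, classifier and
simulation-recovery tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from cnqc.cbs import CBSConfig
from cnqc.classifier import TrainingSet, train_model
from cnqc.features import extract_features
from cnqc.simulate import SimProfileSpec, simulate_cohort
from cnqc.stepfit import StepFitConfig

COHORT_SEED = 0
N_PER_GROUP = 100
CBS_PERMUTATIONS = 500


@pytest.fixture(scope="session")
def default_cohort():
    """100 samples per group at the default simulation conditions."""
    return simulate_cohort(N_PER_GROUP, spec=SimProfileSpec(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    """(sample, FeatureVector) pairs for the default cohort; CBS at 500
    permutations to keep the run inside a desk-scale budget."""
    out = []
    for s in default_cohort:
        fv = extract_features(
            s.profile,
            StepFitConfig(K=120),
            CBSConfig(alpha=0.01, n_permutations=CBS_PERMUTATIONS, rng_seed=s.seed),
            with_medasp=True,
        )
        out.append((s, fv))
    return out


@pytest.fixture(scope="session")
def cohort_training_set(cohort_features):
    return TrainingSet(
        features=[fv for _, fv in cohort_features],
        labels=[s.label for s, _ in cohort_features],
    )


@pytest.fixture(scope="session")
def trained_model(cohort_training_set):
    return train_model(cohort_training_set)


def group_features(cohort_features, group):
    return [(s, fv) for s, fv in cohort_features if s.group == group]


def median_feature(cohort_features, group, attr):
    return float(np.median([getattr(fv, attr) for _, fv in group_features(cohort_features, group)]))
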