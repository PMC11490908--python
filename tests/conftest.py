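import numpy as np
import pytest

from distressfuse.synthetic import CohortSpec, SignalModel, iter_cohort
from distressfuse.preprocess import align_cohort


def small_cohort_spec(n=8, frac=0.5, seed=7, dur=(30.0, 60.0), rate=12.0):
    return CohortSpec(n_sessions=n, depressed_fraction=frac,
                      duration_range=dur, utterance_rate=rate, seed=seed)


@pytest.fixture(scope="session")
def tiny_bundles():
    """8 short sessions (30-60 s) with a strong audio signal."""
    spec = small_cohort_spec()
    signal = SignalModel.single_modality("audio", 1.5)
    return list(iter_cohort(spec, signal))


@pytest.fixture(scope="session")
def tiny_aligned(tiny_bundles):
    ds, featurizer = align_cohort(tiny_bundles, L=12)
    return ds, featurizer


def make_aligned_cohort(n_sessions, signal, L=12, seed=0, frac=0.5,
                        dur=(30.0, 60.0), rate=12.0):
    """Generate + align a small cohort in one call (used by model tests)."""
    spec = small_cohort_spec(n=n_sessions, frac=frac, seed=seed, dur=dur,
                             rate=rate)
    bundles = list(iter_cohort(spec, signal))
    ds, featurizer = align_cohort(bundles, L=L)
    return bundles, ds, featurizer
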