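"""Shared fixtures: synthetic sessions at the study's scale (2000 voxels).

Heavy objects (cross-validation reports, the recovery cohort) are session
scoped so unit tests and the acceptance suite share one computation.
"""
import numpy as np
import pytest

import attnstates as a
from attnstates.core import CONDITIONS, LabeledSamples
from attnstates.pipeline import PipelineConfig, _subject_seeds, run_subject

N_VOXELS = 2000


@pytest.fixture(scope="session")
def default_design():
    return a.build_ia_design(seed=11)


@pytest.fixture(scope="session")
def signal_patterns():
    return a.make_state_patterns(N_VOXELS, overlap=0.0, amplitude=1.0, sparsity=0.1, seed=5)


@pytest.fixture(scope="session")
def noiseless_samples(signal_patterns, default_design):
    ts, design = a.simulate_ia_session(
        signal_patterns, default_design, noise_sd=0.0, seed=21
    )
    return a.extract_labeled_samples(ts, design)


@pytest.fixture(scope="session")
def noiseless_report(noiseless_samples):
    return a.crossvalidate_by_block(noiseless_samples)


@pytest.fixture(scope="session")
def noisy_samples(signal_patterns, default_design):
    ts, design = a.simulate_ia_session(
        signal_patterns, default_design, noise_sd=1.0, seed=22
    )
    return a.extract_labeled_samples(ts, design)


@pytest.fixture(scope="session")
def shuffled_report(noisy_samples):
    """Labels randomly permuted: the classifier should fall to chance."""
    rng = np.random.default_rng(99)
    perm = rng.permutation(noisy_samples.n_samples)
    shuffled = LabeledSamples(
        features=noisy_samples.features,
        labels=noisy_samples.labels[perm],
        blocks=noisy_samples.blocks,
        trial_ids=noisy_samples.trial_ids,
    )
    return a.crossvalidate_by_block(shuffled)


@pytest.fixture(scope="session")
def null_report(default_design):
    """All-zero state patterns: pure noise, accuracy should sit at chance."""
    patterns = a.StatePatterns(
        patterns=np.zeros((5, N_VOXELS)), state_order=CONDITIONS, overlap=0.0, seed=0
    )
    ts, design = a.simulate_ia_session(patterns, default_design, noise_sd=1.0, seed=23)
    samples = a.extract_labeled_samples(ts, design)
    return a.crossvalidate_by_block(samples)


@pytest.fixture(scope="session")
def recovery_cohort():
    """20 simulated subjects with planted stationary law (50/30/20)%."""
    config = PipelineConfig(n_subjects=20, n_voxels=N_VOXELS, seed=17)
    seeds = _subject_seeds(config.seed, config.n_subjects)
    return config, [
        run_subject(config, s, f"sub-{i + 1:02d}") for i, s in enumerate(seeds)
    ]


@pytest.fixture
def tiny_config():
    """A minutes-scale pipeline configuration for end-to-end tests."""
    return PipelineConfig(
        n_subjects=2,
        n_voxels=150,
        n_blocks=2,
        per_condition_block_seconds=32.0,
        meditation_duration_trs=80,
        seed=3,
    )
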