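import numpy as np
import pytest

from critsort.synth import GeneratorConfig, SubjectDataset, generate_cohort


@pytest.fixture(scope="session")
def strong_cohort():
    """Small high-SNR cohort with late-component latent coupling."""
    cfg = GeneratorConfig(
        n_subjects=5,
        n_trials=150,
        noise_sd=0.6,
        trial_seed=3,
        spatial_pattern_seed=3,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with zero sensitivity and zero coupling: no class signal."""
    cfg = GeneratorConfig(
        n_subjects=4,
        n_trials=120,
        d_prime=0.0,
        coupling=(0.0, 0.0, 0.0),
        liberal_criteria=(-0.6,),
        conservative_criteria=(0.6,),
        trial_seed=5,
        spatial_pattern_seed=5,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def pas_cohort():
    cfg = GeneratorConfig(
        n_subjects=3,
        n_trials=120,
        mode="pas",
        liberal_criteria=(0.0, 0.8, 1.6),
        conservative_criteria=(1.0, 1.8, 2.6),
        condition_scheme="sessionwise",
        trial_seed=7,
        spatial_pattern_seed=7,
    )
    return cfg, generate_cohort(cfg)


def make_toy_dataset(
    epochs,
    is_target,
    condition=None,
    response=None,
    subject_id=0,
    mode="yes_no",
    times=None,
):
    """Wrap raw arrays into a SubjectDataset for unit tests."""
    epochs = np.asarray(epochs, dtype=float)
    n, c, t = epochs.shape
    is_target = np.asarray(is_target, dtype=bool)
    if times is None:
        times = np.arange(t, dtype=float)  # includes 0 at the first sample
    if condition is None:
        condition = np.where(np.arange(n) % 2 == 0, "liberal", "conservative")
    if response is None:
        response = is_target.astype(int)
    return SubjectDataset(
        subject_id=subject_id,
        epochs=epochs,
        times=np.asarray(times, dtype=float),
        channel_names=tuple(f"ch{i:02d}" for i in range(c)),
        stimulus=np.where(is_target, "target", "no_target"),
        condition=np.asarray(condition),
        response=np.asarray(response, dtype=int),
        latent_strength=np.zeros(n),
        session=np.ones(n, dtype=int),
        block=np.ones(n, dtype=int),
        mode=mode,
    )
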