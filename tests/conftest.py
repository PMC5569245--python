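import warnings

import pytest
from hypothesis import HealthCheck, settings

import actvalid as av

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Kendall tau on degenerate (all-equal) differences is undefined by design
warnings.filterwarnings("ignore", message="Kendall tau undefined")


@pytest.fixture(scope="session")
def classifier() -> av.ClassifierConfig:
    return av.ClassifierConfig()


def noise_free_config(**overrides) -> av.SimulationConfig:
    """A cohort whose two methods agree exactly: between-participant spread
    only, identity misclassification, full annotation, no nonwear."""
    base = dict(
        n_participants=8, n_days=4, periods=("week3",), seed=42,
        sigma_participant=60.0, sigma_method=0.0, sigma_residual=0.0,
        sigma_true_day=0.0, annotation_completeness=1.0, nonwear_prob=0.0,
    )
    base.update(overrides)
    return av.SimulationConfig(**base)


@pytest.fixture(scope="session")
def noise_free_cohort(classifier):
    cfg = noise_free_config()
    sim = av.simulate_paired_cohort(cfg)
    paired = av.flag_valid_days(
        av.build_paired_day_table(sim.epoch_log, sim.device_events, classifier,
                                  cfg.study_start),
        classifier,
    )
    return cfg, sim, paired


@pytest.fixture(scope="session")
def noisy_cohort(classifier):
    """Moderately noisy cohort spanning baseline and intervention periods."""
    cfg = av.SimulationConfig(
        n_participants=12, n_days=5, periods=("week2", "week3", "week7"),
        seed=7, sigma_participant=90.0, sigma_method=40.0, sigma_residual=50.0,
        annotation_completeness=0.95, nonwear_prob=0.05,
    )
    sim = av.simulate_paired_cohort(cfg)
    paired = av.flag_valid_days(
        av.build_paired_day_table(sim.epoch_log, sim.device_events, classifier,
                                  cfg.study_start),
        classifier,
    )
    return cfg, sim, paired
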