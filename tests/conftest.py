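import numpy as np
import pytest

from nof1series import GenParams, TrialSchedule, generate_participant


@pytest.fixture
def schedule():
    return TrialSchedule("ABAB")


@pytest.fixture
def noise_free_series(schedule):
    """Deterministic series: A-days exactly 4, B-days exactly 5."""
    params = GenParams(
        baseline_mean=5.0,
        baseline_sd_between=0.0,
        mean_effect=-1.0,
        effect_sd_between=0.0,
        innovation_sd=0.0,
        weekend_offset=0.0,
        missing_prob=0.0,
        adherence_prob=1.0,
        integer_rounding=False,
    )
    return generate_participant(params, schedule, participant_seed=1)


def recovery_params(**overrides) -> GenParams:
    """Continuous-mode generator settings for parameter-recovery checks."""
    base = dict(
        baseline_mean=5.0,
        baseline_sd_between=0.0,
        mean_effect=-1.0,
        effect_sd_between=0.0,
        ar_coefficient=0.5,
        innovation_sd=2.41,
        weekend_offset=0.0,
        missing_prob=0.0,
        adherence_prob=1.0,
        integer_rounding=False,
        clip_to_scale=False,
    )
    base.update(overrides)
    return GenParams(**base)
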