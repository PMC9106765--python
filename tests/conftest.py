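import pytest

import spartapace as sp


@pytest.fixture(scope="session")
def spartathlon():
    return sp.spartathlon_course()


@pytest.fixture(scope="session")
def flat_course():
    """Equal-segment, no-time-limit course: every checkpoint is exchangeable,
    so zero-effect simulations are true nulls for the whole battery."""
    return sp.course_from_segments("flat10", [24.68] * 10)


@pytest.fixture(scope="session")
def toy_course():
    return sp.course_from_segments("toy", [19.5, 22.7], time_limit_hours=36.0)


@pytest.fixture(scope="session")
def small_cohort(spartathlon):
    cfg = sp.default_config(spartathlon, n_runners=300, seed=7)
    return sp.generate(cfg, spartathlon)
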