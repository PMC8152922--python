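import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tojcortex as tc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ground_truth_subject() -> tc.GroundTruthSubject:
    """A mid-range participant: good uncrossed performance, partial reversal."""
    return tc.GroundTruthSubject(
        id="sub-001",
        sex="F",
        sigmoid=tc.SigmoidParams(p_max=0.98, p_min=0.02, sigma_u=50.0, d_u=5.0),
        flip=tc.FlipParams(a_l=0.5, a_r=0.4, sigma_f=200.0, d=0.0, c=0.2),
        seed=3,
    )


@pytest.fixture(scope="session")
def session_pair(ground_truth_subject):
    """One simulated uncrossed + crossed session under the study design."""
    uncrossed = tc.simulate_toj_session(
        ground_truth_subject, tc.make_soa_schedule("uncrossed", 8, 16, seed=1), seed=11
    )
    crossed = tc.simulate_toj_session(
        ground_truth_subject, tc.make_soa_schedule("crossed", 8, 16, seed=2), seed=12
    )
    return uncrossed, crossed


@pytest.fixture(scope="session")
def fitted_pair(session_pair):
    uncrossed, crossed = session_pair
    u_fit = tc.fit_uncrossed(tc.tabulate_judgments(uncrossed), seed=1)
    c_fit = tc.fit_crossed(tc.tabulate_judgments(crossed), u_fit, seed=2)
    return u_fit, c_fit


@pytest.fixture(scope="session")
def coupled_cohort():
    """42-subject cortical cohort with a two-feature probit coupling."""
    spec = tc.CortexSpec(
        coupling=tc.ProbitCoupling(
            feature_ids=(("rh_parsorbitalis", "mct"), ("rh_postcentral", "ratio")),
            coefficients=(0.9, -0.7),
        ),
        obs_noise_sd=0.05,
    )
    subjects, vertex_tables = tc.simulate_cohort(spec, 42, seed=5)
    return spec, subjects, vertex_tables


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
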