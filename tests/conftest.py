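import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from astamix import datasets

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# Printed validation table for the three-source reference model:
# (actual per source, observed mean channel areas, calculated per source,
# recovery of the first source in percent).
PRINTED_VERIFICATION = [
    ((25, 5, 5), (215.80, 272.68, 861.04), (24.15, 5.23, 4.96), 96.6),
    ((25, 25, 25), (1084.81, 1189.62, 1211.06), (23.56, 24.92, 26.35), 94.2),
    ((25, 75, 100), (3706.90, 4376.76, 2641.15), (25.53, 75.03, 105.52), 102.1),
    ((10, 25, 10), (804.46, 601.49, 472.68), (9.41, 24.41, 10.25), 94.1),
    ((30, 25, 15), (879.53, 818.29, 1174.93), (28.24, 23.99, 15.44), 94.1),
    ((50, 75, 25), (2429.42, 1825.07, 2179.89), (51.78, 74.55, 29.27), 103.6),
    ((100, 50, 25), (1846.67, 1787.07, 3829.39), (101.36, 50.91, 31.36), 101.4),
]


@pytest.fixture(scope="session")
def ref_model():
    return datasets.reference_model()


@pytest.fixture(scope="session")
def ref_mixtures():
    return datasets.reference_verification_mixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def random_full_rank_model(rng, n=3, min_cond_gap=1e-3):
    """A random well-conditioned mixture model for property tests."""
    from astamix.calibration import CalibrationCurve, SourceProfile
    from astamix.channels import CHANNELS
    from astamix.unmix import assemble_model

    while True:
        A = rng.uniform(0.5, 40.0, size=(3, n))
        sv = np.linalg.svd(A, compute_uv=False)
        if sv[-1] > min_cond_gap * sv[0]:
            break
    b = rng.uniform(-10.0, 10.0, size=(3, n))
    profiles = []
    for j in range(n):
        curves = tuple(
            CalibrationCurve(
                source_id=f"src{j}",
                channel_id=CHANNELS[m],
                slope_a=float(A[m, j]),
                intercept_b=float(b[m, j]),
                r_squared=1.0,
                valid_range=(0.0, 200.0),
            )
            for m in range(3)
        )
        profiles.append(SourceProfile(f"src{j}", curves))
    return assemble_model(profiles)
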