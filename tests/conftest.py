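import logging

import pytest

from hcpmeta import GeneratorConfig, generate_database


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # effect/summary stages log audit warnings by design; keep test output sane
    logging.getLogger("hcpmeta").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def small_noisy_db():
    """A 40-study default-conditions database, shared across read-only tests."""
    cfg = GeneratorConfig(n_studies=40, seed=11)
    return generate_database(cfg)


@pytest.fixture(scope="session")
def noiseless_db():
    """Degenerate no-noise, no-modifier conditions: every effect is 7.3."""
    cfg = GeneratorConfig(
        n_studies=25, seed=5,
        within_study_sd=0.0, between_study_sd=0.0, measurement_noise_sd=0.0,
        attribute_effects={}, waning_slope=0.0, baseline_gradient=0.0,
    )
    return generate_database(cfg)
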