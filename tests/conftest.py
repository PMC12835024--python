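import pytest

from kips.synthetic import (
    CLEAN,
    CohortConfig,
    Messiness,
    build_subject,
    generate_immunization,
    generate_medication_dispense,
    generate_snuh_bundle,
    worked_example_procedure,
)


@pytest.fixture
def worked_example():
    return worked_example_procedure()


@pytest.fixture
def messy_config():
    return CohortConfig(seed=7)


@pytest.fixture
def clean_config():
    return CohortConfig(seed=7, messiness=CLEAN)


def cohort_resources(config):
    """In-memory cohort: the six app exports plus one hospital bundle."""
    resources = []
    for i in range(config.n_subjects):
        subject = build_subject(config, i)
        import random

        rng = random.Random(f"{config.seed}:subject:{i}:medication")
        resources.append(generate_medication_dispense(subject, rng, config.messiness))
        rng = random.Random(f"{config.seed}:subject:{i}:immunization")
        resources.append(generate_immunization(subject, rng, config.messiness))
        if config.snuh_subject_index == i:
            rng = random.Random(f"{config.seed}:subject:{i}:snuh")
            resources.append(generate_snuh_bundle(subject, rng, config.messiness))
    return resources


@pytest.fixture
def messy_cohort(messy_config):
    return cohort_resources(messy_config)


@pytest.fixture
def clean_cohort(clean_config):
    return cohort_resources(clean_config)


@pytest.fixture
def single_knob():
    """Factory: a cohort with exactly one messiness knob enabled."""

    def make(knob: str):
        m = Messiness(0.0, 0.0, 0.0, 0.0)
        setattr(m, knob, 1.0)
        return cohort_resources(CohortConfig(seed=7, messiness=m))

    return make
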