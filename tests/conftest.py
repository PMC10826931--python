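import numpy as np
import pytest

from emsflags.flags import default_term_sets
from emsflags.records import Cohort, EncounterRecord
from emsflags.synth import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def term_sets():
    return default_term_sets()


@pytest.fixture(scope="session")
def small_cohort():
    """A tiny hand-written cohort with known keyword content."""
    return Cohort(
        [
            EncounterRecord(
                record_id="A1",
                county="Travis",
                chief_narrative="Pt given NARCAN for suspected heroin OD.",
                primary_impression="overdose",
                label=1,
                ethnicity="White",
                gender="male",
                age=34,
            ),
            EncounterRecord(
                record_id="A2",
                county="Travis",
                chief_narrative="patient found seated, vitals stable",
                chief_complaint="chest pain",
                label=0,
                ethnicity="unknown",
                gender="female",
                age=58,
            ),
            EncounterRecord(
                record_id="A3",
                county="El Paso",
                chief_narrative="body found responsive, denies intox history",
                label=0,
                gender="male",
            ),
        ],
        provenance="hand-written fixture",
    )


@pytest.fixture(scope="session")
def default_benchmark_cohort():
    """The default synthetic benchmark cohort (n=3000, prevalence 0.15)."""
    config = GeneratorConfig(seed=20240130)
    return generate_cohort(config)


def make_separable_cohort(n=400, seed=7):
    """Signal probability 1 everywhere, confounders off: flags separate
    the classes perfectly by construction."""
    config = GeneratorConfig(
        n=n,
        prevalence=0.3,
        field_signal={f: 1.0 for f in GeneratorConfig().field_signal},
        confounder_rates={k: 0.0 for k in GeneratorConfig().confounder_rates},
        seed=seed,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def separable_cohort():
    return make_separable_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
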