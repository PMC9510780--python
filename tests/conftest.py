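import dataclasses

import numpy as np
import pytest

from doa_ecog import (
    GeneratorConfig,
    STEPPED_PROTOCOL_PERCENT,
    make_protocol,
    simulate_cohort,
    simulate_recording,
)
from doa_ecog.estimator import EstimatorConfig, build_feature_table, run_doa_experiment

# Desk-scale study conditions: the 7-segment stepped protocol with segments
# shortened to 3 min (1 min transient discarded), 5 animals, fixed cohort seed.
COHORT_SEED = 11
SEGMENT_MINUTES = 3.0
DISCARD_MINUTES = 1.0
N_ANIMALS = 5


@pytest.fixture(scope="session")
def stepped_protocol_short():
    return make_protocol(list(STEPPED_PROTOCOL_PERCENT), SEGMENT_MINUTES)


@pytest.fixture(scope="session")
def generator_config():
    # shorter depth transient to suit the shortened segments
    return GeneratorConfig(seed=COHORT_SEED, depth_tau_s=20.0)


@pytest.fixture(scope="session")
def cohort(generator_config, stepped_protocol_short):
    return simulate_cohort(
        N_ANIMALS, generator_config, stepped_protocol_short, seed=COHORT_SEED
    )


@pytest.fixture(scope="session")
def cohort_table(cohort):
    return build_feature_table(cohort, discard_minutes=DISCARD_MINUTES, with_era=True)


@pytest.fixture(scope="session")
def cohort_experiment(cohort, cohort_table):
    return run_doa_experiment(
        cohort,
        target="isoflurane",
        est_cfg=EstimatorConfig(seed=COHORT_SEED),
        discard_minutes=DISCARD_MINUTES,
        feature_table=cohort_table,
    )


@pytest.fixture(scope="session")
def coherence_only_experiment(generator_config, stepped_protocol_short):
    cfg = dataclasses.replace(
        generator_config,
        modulate_bursts=False,
        modulate_slow=False,
        modulate_evoked=False,
    )
    recs = simulate_cohort(N_ANIMALS, cfg, stepped_protocol_short, seed=COHORT_SEED)
    return run_doa_experiment(
        recs,
        target="isoflurane",
        est_cfg=EstimatorConfig(seed=COHORT_SEED),
        discard_minutes=DISCARD_MINUTES,
        with_time_control=False,
    )


@pytest.fixture(scope="session")
def single_recording(generator_config):
    """One short two-concentration recording for preprocessing/feature tests."""
    proto = make_protocol([1.0, 2.3], 1.5)
    return simulate_recording(generator_config, proto, animal_id="m00", seed=3)
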