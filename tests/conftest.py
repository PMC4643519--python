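"""Shared fixtures: synthetic cohorts at two scales plus derived pipeline stages."""

from __future__ import annotations

import io

import pytest
from hypothesis import HealthCheck, settings

import cohortflow as cf
from cohortflow.synth import SynthConfig, generate, synth_factor_map

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

SEED = 314159


@pytest.fixture(scope="session")
def ckd_map():
    return cf.default_ckd_map()


@pytest.fixture(scope="session")
def synth_map():
    return synth_factor_map()


@pytest.fixture(scope="session")
def cohort1000():
    """1,000-patient synthetic cohort with deterministic and mixed transitions."""
    cfg = SynthConfig(n_patients=1000, seed=SEED, deterministic_fraction=0.3)
    events, truth = generate(cfg)
    return cfg, events, truth


@pytest.fixture(scope="session")
def pop1000(cohort1000, synth_map):
    cfg, events, _ = cohort1000
    records = cf.read_events(io.StringIO(events.to_csv(index=False)))
    return cf.build_trajectories(records, synth_map)


@pytest.fixture(scope="session")
def spec3(cohort1000):
    """Three-stage design: pre-index (all factors), first year (HD only), post."""
    cfg, _, _ = cohort1000
    return cf.WindowSpec(
        cfg.windows,
        watch=[None, {"HD"}, {"Death", "PD", "RTPL"}],
        labels=["pre", "year1", "post"],
    )


@pytest.fixture(scope="session")
def wtrajs1000(pop1000, spec3, synth_map):
    return cf.partition(pop1000, spec3, vocabulary=synth_map)


@pytest.fixture(scope="session")
def net1000(wtrajs1000, spec3):
    """Exact-combination cohorts per window, connected across windows."""
    sets = [
        cf.frequency_cluster(cf.group_by_comorbidity(wtrajs1000, l), 0, window=l)
        for l in range(spec3.n_windows)
    ]
    return cf.build_network(sets)


def make_cohort(window: int, members, common=(), partial=False, contains_index=False):
    """Hand-built cohort for toy network tests."""
    return cf.Cohort(window, tuple(sorted(members)), frozenset(common), partial, contains_index)


@pytest.fixture()
def toy_net():
    """A={1,2,3} splitting into B'={1,2} and C'={3}; D={9} flowing whole to E'={9}."""
    w0 = cf.CohortSet(0, [make_cohort(0, ["1", "2", "3"], {"HTN"}), make_cohort(0, ["9"], {"DM"})])
    w1 = cf.CohortSet(
        1,
        [
            make_cohort(1, ["1", "2"], {"HTN"}),
            make_cohort(1, ["3"], {"HTN", "HD"}),
            make_cohort(1, ["9"], {"DM"}),
        ],
    )
    return cf.build_network([w0, w1])
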