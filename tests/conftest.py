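import numpy as np
import pytest

from hicsig import synthetic


@pytest.fixture(scope="session")
def default_scenario():
    return synthetic.SimulationScenario(seed=11)


@pytest.fixture(scope="session")
def scenario_world(default_scenario):
    """Toy genome + enumerated zero-count records with covariates + truth
    spline spec for the default ~50k-record scenario (built once)."""
    genome = synthetic.make_toy_genome(default_scenario)
    records, features, spec = synthetic.build_scenario_records(
        default_scenario, genome)
    return {"genome": genome, "records": records, "features": features,
            "spec": spec, "scenario": default_scenario}


@pytest.fixture(scope="session")
def null_records(scenario_world):
    """One seeded null count draw over the default world."""
    return synthetic.simulate_null_counts(
        scenario_world["records"], scenario_world["scenario"],
        scenario_world["spec"])


@pytest.fixture(scope="session")
def small_scenario():
    """A fast ~2k-record world for pipeline/CLI tests."""
    return synthetic.SimulationScenario(
        seed=7, chrom_sizes={"chrT": 150_000}, max_distance=120_000.0,
        spike_dmin=20_000.0, spike_dmax=120_000.0, spike_frac=0.02)


@pytest.fixture(scope="session")
def small_world(small_scenario):
    return synthetic.simulate_scenario(small_scenario, spikes=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
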