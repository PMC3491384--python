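import numpy as np
import pytest

from nanosmallrna.pipeline import RunConfig, run_all
from nanosmallrna.synthetic import Scenario, generate_genome, simulate_reads


@pytest.fixture(scope="session")
def flagship():
    """The default synthetic scenario (seed 42) run end to end once."""
    scenario = Scenario(seed=42)
    genome, features, truth = generate_genome(scenario)
    reads = simulate_reads(genome, truth, scenario)
    summary = run_all(
        RunConfig(seed=42),
        genome=genome,
        features=features,
        reads=reads,
        write=False,
    )
    return {
        "scenario": scenario,
        "genome": genome,
        "features": features,
        "truth": truth,
        "reads": reads,
        "summary": summary,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
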