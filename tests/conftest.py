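import pytest

from famevol.simulate import (
    PopSpec,
    SimulationConfig,
    default_pair_spec,
    default_pop_spec,
    generate_all,
)


def small_config(seed: int = 11) -> SimulationConfig:
    """A reduced study: 80 family genes, 3 planted clusters, 20 pairs,
    200 loci — every planted structure present at test-friendly size."""
    return SimulationConfig(
        seed=seed,
        n_family=80,
        n_decoy=24,
        tandem_cluster_spec=[
            ("Chr01", 3, 150_000),
            ("Chr02", 4, 80_000),
            ("Chr03", 2, 120_000),
        ],
        duplicate_pair_spec=default_pair_spec(20, 120),
        pop_spec=default_pop_spec(200),
        n_unplaced=2,
    )


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return small_config()


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, sim_config):
    """Generated input files plus in-memory truth for the small study."""
    outdir = tmp_path_factory.mktemp("bundle")
    truth = generate_all(sim_config, outdir)
    return {"dir": outdir, "truth": truth, "config": sim_config}
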