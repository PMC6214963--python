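import numpy as np
import pytest

from srnamir.simulate import SimulationConfig, simulate_libraries, write_bundle


def small_config(seed: int = 11) -> SimulationConfig:
    """A scaled-down study for smoke/contract tests (seconds, not minutes)."""
    return SimulationConfig(
        rng_seed=seed,
        n_background_refs=8,
        ref_length=1200,
        n_known_families=8,
        members_per_family=2,
        n_conserved_families=6,
        n_novel_hairpins=4,
        n_star_detectable=2,
        library_depth=20_000,
        n_background_tags=150,
    )


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_libraries(small_config())


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(small_bundle, outdir)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
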