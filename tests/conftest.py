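import numpy as np
import pytest

from pannovel.synth import SyntheticConfig, generate_strain_panel


@pytest.fixture(scope="session")
def default_panel():
    """One shared desk-scale panel (6 strains, 3 chromosomes) with truth."""
    cfg = SyntheticConfig(seed=11)
    assemblies, truth = generate_strain_panel(cfg)
    return cfg, assemblies, truth


@pytest.fixture(scope="session")
def focal_assembly(default_panel):
    cfg, assemblies, _ = default_panel
    return next(a for a in assemblies if a.genome_id == cfg.focal_id)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
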