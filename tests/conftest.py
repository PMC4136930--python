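import numpy as np
import pytest

from ampliscreen.pipeline import ScreenConfig, run_screen
from ampliscreen.simulate import (
    SimConfig,
    default_design,
    make_reference_panel,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_panel():
    """Reference panel at V4 length: 6 family species, 2 outgroup diatoms,
    2 far outgroups."""
    cfg = SimConfig(seed=7, region_length=390)
    panel, master = make_reference_panel(cfg)
    return cfg, panel, master


@pytest.fixture(scope="session")
def small_study(small_panel):
    """Quick 6-site study (150 reads/sample) for unit-level checks."""
    cfg, panel, master = small_panel
    cfg = SimConfig(seed=7, region_length=390, reads_per_sample=150)
    reads, meta, truth = simulate_study(cfg, default_design(), panel)
    return cfg, panel, master, reads, meta, truth


@pytest.fixture(scope="session")
def small_screen(small_study):
    cfg, panel, master, reads, meta, truth = small_study
    result = run_screen(reads, panel, master, meta, ScreenConfig(), dataset="small")
    return result, meta, truth


@pytest.fixture(scope="session")
def full_study():
    """The full-scale recovery study: 6 sites x 1000 reads, 1% error,
    planted novel clade at one site."""
    cfg = SimConfig(seed=11, region_length=390, reads_per_sample=1000)
    panel, master = make_reference_panel(cfg)
    reads, meta, truth = simulate_study(cfg, default_design(), panel)
    return cfg, panel, master, reads, meta, truth


@pytest.fixture(scope="session")
def full_screen(full_study):
    cfg, panel, master, reads, meta, truth = full_study
    result = run_screen(reads, panel, master, meta, ScreenConfig(), dataset="full")
    return result, meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
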