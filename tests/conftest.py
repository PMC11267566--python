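import numpy as np
import pytest

from cleavescan.ffenergy import default_forcefield
from cleavescan.fixtures import FixtureSpec, make_peptide, make_poi, make_receptor
from cleavescan.lesampler import (
    LEConfig,
    SamplerConfig,
    random_frame_selection,
    sample_conformers,
)
from cleavescan.stitcher import stitch_ensemble

# study-scale fixture conditions shared across the suite
FIXTURE_LE = dict(grid_min=0.3, grid_max=2.6, n_grid=40, cles=0.5)


@pytest.fixture(scope="session")
def params():
    return default_forcefield()


@pytest.fixture(scope="session")
def peptide():
    """Five flexible residues plus the overlap residue, capped."""
    return make_peptide("AVSTLS", "extended", capped=True)


@pytest.fixture(scope="session")
def poi():
    """(body, peptide, plan) for the default fixture system."""
    return make_poi(FixtureSpec())


@pytest.fixture(scope="session")
def open_template():
    return make_receptor(FixtureSpec(groove="open"))


@pytest.fixture(scope="session")
def blocked_template():
    return make_receptor(FixtureSpec(groove="blocked"))


@pytest.fixture(scope="session")
def small_ensemble(poi, params):
    """A short sampling run over the fixture peptide (12 frames)."""
    _, pep, _ = poi
    cfg = SamplerConfig(n_steps=300, n_replicates=2, seed=100, save_interval=25)
    ens = sample_conformers(pep, cfg, LEConfig(**FIXTURE_LE), params)
    return random_frame_selection(ens, n=12, seed=101)


@pytest.fixture(scope="session")
def stitched_small(small_ensemble, poi, params):
    """Stitched + filtered version of ``small_ensemble``."""
    body, _, plan = poi
    stitched, table, retained = stitch_ensemble(
        small_ensemble, body, plan, params
    )
    return stitched, table, retained
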