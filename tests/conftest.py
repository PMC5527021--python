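import numpy as np
import pytest

from mimevolve import synthetic
from mimevolve.pedigree import Individual, Pedigree


@pytest.fixture(scope="session")
def rendered_wing():
    """A standard unrotated render with distinct spots, shared across tests."""
    spec = synthetic.WingRenderSpec(target_white_fraction=0.08, rotation_deg=0.0, seed=3)
    return synthetic.render_wing(spec)


@pytest.fixture(scope="session")
def rendered_wing_rotated():
    spec = synthetic.WingRenderSpec(target_white_fraction=0.08, rotation_deg=30.0, seed=3)
    return synthetic.render_wing(spec)


@pytest.fixture()
def toy_pedigree():
    """Founder grandmother GM, her daughter M, unrelated sire P with known
    mother PGM; granddaughter D carries both lineages."""
    ped = Pedigree()
    ped.add(Individual("GM", "F", generation=0, white_rel=0.10, red_rel=0.05))
    ped.add(Individual("PGM", "F", generation=0, white_rel=0.12, red_rel=0.06))
    ped.add(Individual("GF", "M", generation=0))
    ped.add(Individual("PGF", "M", generation=0))
    ped.add(Individual("M", "F", "GM", "GF", generation=1, white_rel=0.09, red_rel=0.04))
    ped.add(Individual("P", "M", "PGM", "PGF", generation=1))
    ped.add(Individual("D", "F", "M", "P", generation=2, white_rel=0.11, red_rel=0.055))
    ped.validate()
    return ped
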