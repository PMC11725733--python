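import numpy as np
import pytest

import porkfresh as pf
from porkfresh import cascade as C


@pytest.fixture(scope="session")
def design():
    return pf.StudyDesign()


@pytest.fixture(scope="session")
def gencfg():
    return pf.GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def chem_tables(design, gencfg):
    met = pf.gen_metabolite_profiles(design, gencfg)
    qual = pf.gen_quality(met, gencfg)
    return met, qual


@pytest.fixture(scope="session")
def spectra_and_scans(design, gencfg, chem_tables):
    met, qual = chem_tables
    return pf.gen_spectra(met, qual, design, gencfg)


@pytest.fixture(scope="session")
def small_state(design):
    """A reduced cascade state shared by the slower integration tests."""
    cfg = pf.CascadeConfig(
        n_augment=600,
        max_lv_spectra=6,
        max_lv_metabolites=6,
        preprocessing_grid=("raw", "snv"),
    )
    return C.build_state(design, pf.GeneratorConfig(seed=11), cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
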