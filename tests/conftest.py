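"""Shared fixtures.

The default synthetic study and its derived artifacts are expensive enough
(a few seconds) to build once per session and share read-only.
"""

import numpy as np
import pytest

from hypoxmet.quantify import quantify_study
from hypoxmet.spectra_prep import bin_matrix
from hypoxmet.synthdata import make_study


@pytest.fixture(scope="session")
def study():
    """(spectra, ground-truth table) for the default study, seed 1."""
    return make_study(seed=1)


@pytest.fixture(scope="session")
def spectra(study):
    return study[0]


@pytest.fixture(scope="session")
def truth(study):
    return study[1]


@pytest.fixture(scope="session")
def binned48(spectra):
    """Binned matrix of the 18 preprocessed 48 h spectra."""
    return bin_matrix([s for s in spectra if s.time_point == 48])


@pytest.fixture(scope="session")
def conc_table(spectra):
    """Quantified concentration table for all 54 spectra."""
    return quantify_study(spectra)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
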