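import hypothesis

from ampselect import melittin_cell, melittin_membrane
from ampselect.presets import MELITTIN_PEPTIDE

import pytest

hypothesis.settings.register_profile(
    "deterministic", derandomize=True, database=None, deadline=None
)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture
def peptide():
    """Melittin-like peptide geometry: v_p = 33^3 A^3, A_p = 400 A^2."""
    return MELITTIN_PEPTIDE


@pytest.fixture
def cell_preset():
    """Intercept-anchored cell scenario, N_p = 5e7 for both classes."""
    return melittin_cell(n_trapped=5e7)


@pytest.fixture
def cell_preset_np1e7():
    return melittin_cell(n_trapped=1e7)


@pytest.fixture
def membrane_preset():
    """Energy-anchored model-bilayer scenario, N_p = 0, A_H = 200 um^2."""
    return melittin_membrane()
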