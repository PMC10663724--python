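"""Unit conventions, physical constants, and count/molar conversions.

Internal unit system (fixed conventions, used by every other module):

* concentration — mol per liter (user-facing I/O is in μM);
* length — Å (cell areas are accepted in μm² and converted: 1 μm² = 10⁸ Å²);
* cell density — accepted as cells per mL, converted to cells per liter
  (× 10³) wherever it multiplies a per-cell peptide count;
* energy — dimensionless, in units of k_BT.  The model never needs an
  absolute temperature except in the Debye-length helper.
"""

from __future__ import annotations

import math

from scipy import constants

#: Avogadro constant, per mol.
N_AVOGADRO: float = constants.N_A

#: Conversion: 1 μm² in Å².
UM2_TO_A2: float = 1e8

#: Conversion: 1 Å³ in liters.
A3_TO_LITER: float = 1e-27

#: Conversion: cells per mL to cells per liter.
PER_ML_TO_PER_L: float = 1e3

#: Conversion: mol/L to μM and back.
MOLAR_TO_UM: float = 1e6
UM_TO_MOLAR: float = 1e-6

#: Default temperature (K); only the Debye helper uses it.
DEFAULT_TEMPERATURE_K: float = 298.15


def counts_per_cell_to_molar(count: float, density_per_ml: float) -> float:
    """Convert a per-cell peptide count at a given cell density to mol/L.

    Parameters
    ----------
    count : float
        Peptides consumed per cell (dimensionless count, ≥ 0).
    density_per_ml : float
        Cell density in cells per mL (≥ 0).

    Returns
    -------
    float
        The equivalent bulk concentration, ``count × density × 10³ / N_A``
        in mol/L.
    """
    if count < 0:
        raise ValueError(f"count must be >= 0, got {count}")
    if density_per_ml < 0:
        raise ValueError(f"density must be >= 0, got {density_per_ml}")
    return count * density_per_ml * PER_ML_TO_PER_L / N_AVOGADRO


def molar_to_counts_per_cell(concentration: float, density_per_ml: float) -> float:
    """Inverse of :func:`counts_per_cell_to_molar` at fixed density (> 0)."""
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    if density_per_ml <= 0:
        raise ValueError(f"density must be > 0, got {density_per_ml}")
    return concentration * N_AVOGADRO / (density_per_ml * PER_ML_TO_PER_L)


def number_density_per_A3(concentration: float) -> float:
    """Molar concentration to a number density in Å⁻³ (ρ = c·N_A·10⁻²⁷)."""
    return concentration * N_AVOGADRO * A3_TO_LITER


def debye_length(
    ionic_strength: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
    relative_permittivity: float = 78.5,
) -> float:
    """Debye screening length of a 1:1 electrolyte, in Å.

    r_D = sqrt(ε₀ ε_r k_B T / (2 N_A e² I)), with the ionic strength I in
    mol/L.  At physiological salt (0.1 M, 298 K, water) this is ≈ 10 Å — the
    scale beyond which peptide–peptide electrostatic repulsion on the
    membrane is screened, which is why the binding energy w can be treated
    as coverage-independent.
    """
    if ionic_strength <= 0:
        raise ValueError(f"ionic strength must be > 0, got {ionic_strength}")
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    ionic_strength_si = ionic_strength * 1e3  # mol/L -> mol/m^3
    meters = math.sqrt(
        constants.epsilon_0
        * relative_permittivity
        * constants.k
        * temperature
        / (2.0 * constants.N_A * constants.e**2 * ionic_strength_si)
    )
    return meters * 1e10
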