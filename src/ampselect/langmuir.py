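"""Langmuir equilibrium binding of peptides to membranes.

A bound peptide occupies an exclusion area A_p on the membrane, so the
occupied area fraction x = σ_p·A_p (σ_p the planar density of adsorbed
peptides) saturates at 1.  Equating the chemical potential of bound
peptides, μ_bound = w + ln[x/(1−x)] (k_BT units), with that of free
peptides, μ_free = ln(v_p ρ_free), gives the isotherm

    x/(1−x) = v_p ρ_free exp(−w),

with ρ_free the free-peptide number density and w the effective adsorption
free energy per peptide (negative for binding; electrostatics, lipid
demixing and pore effects are subsumed into w, which is treated as
coverage-independent).  Coverage is reported as the peptide-to-lipid molar
ratio P/L = x·a_l/A_p, with a_l the lipid headgroup area.

The free concentration at which P/L reaches the rupture threshold P/L* is
the zero-cell-density intercept of the MIC/MHC-vs-density line (MIC₀ or
MHC₀); it is exponentially sensitive to w, and the w ↔ intercept mapping is
invertible in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .quantities import number_density_per_A3, N_AVOGADRO, A3_TO_LITER, UM2_TO_A2

#: Relative tolerance beyond which a doubly-anchored membrane (both w and
#: c0 given) is rejected as inconsistent.
ANCHOR_CONSISTENCY_RTOL = 1e-9


class AnchorError(ValueError):
    """Membrane binding anchor (w or c0) missing, duplicated or inconsistent."""


@dataclass(frozen=True)
class PeptideParams:
    """Bulk and surface footprint of one peptide.

    Attributes
    ----------
    v_p : float
        Volume per peptide in the bulk (Å³).
    A_p : float
        Cross-sectional (exclusion) area of a membrane-bound peptide (Å²).
    """

    v_p: float
    A_p: float

    def __post_init__(self) -> None:
        if self.v_p <= 0:
            raise ValueError(f"v_p must be > 0, got {self.v_p}")
        if self.A_p <= 0:
            raise ValueError(f"A_p must be > 0, got {self.A_p}")


@dataclass(frozen=True)
class MembraneClass:
    """One membrane/cell type (bacterial or host).

    Attributes
    ----------
    label : str
        ``"bacterial"`` or ``"host"``.
    area_um2 : float
        Membrane area per cell, μm².  Counts BOTH leaflets (peptides
        distribute symmetrically between the layers), e.g. 12 μm² for
        E. coli = 2 × 6 μm².
    lipid_area_A2 : float
        Lipid headgroup area a_l (Å²).
    pl_star : float
        Threshold coverage P/L* at which the membrane ruptures.
    w : float or None
        Effective binding energy in k_BT (typically negative).  Anchor
        mode "energy".
    c0 : float or None
        Imposed low-density threshold concentration MIC₀/MHC₀ (mol/L).
        Anchor mode "intercept".
    n_trapped : float
        N_p*: peptides trapped per cell, engaged at and above this class's
        threshold (half the trapped count of a dead cell).
    coverage_w : float or None
        Optional "raw-energy" override: when set, sub/above-threshold
        coverage is evaluated with this energy instead of the effective
        anchor energy, while MIC₀/MHC₀ keep their imposed values.
    """

    label: str
    area_um2: float
    lipid_area_A2: float
    pl_star: float
    w: float | None = None
    c0: float | None = None
    n_trapped: float = 0.0
    coverage_w: float | None = None

    def __post_init__(self) -> None:
        if self.label not in ("bacterial", "host"):
            raise ValueError(f"label must be 'bacterial' or 'host', got {self.label!r}")
        if self.area_um2 <= 0 or self.lipid_area_A2 <= 0:
            raise ValueError("area_um2 and lipid_area_A2 must be > 0")
        if self.pl_star < 0:
            raise ValueError(f"pl_star must be >= 0, got {self.pl_star}")
        if self.n_trapped < 0:
            raise ValueError(f"n_trapped must be >= 0, got {self.n_trapped}")
        if self.c0 is not None and self.c0 <= 0:
            raise ValueError(f"c0 must be > 0, got {self.c0}")

    @property
    def area_A2(self) -> float:
        """Membrane area per cell in Å²."""
        return self.area_um2 * UM2_TO_A2

    @property
    def lipids_per_cell(self) -> float:
        """A_cell/a_l: number of lipid sites per cell."""
        return self.area_A2 / self.lipid_area_A2

    def saturation_fraction(self, peptide: PeptideParams) -> float:
        """x* = P/L*·A_p/a_l, the occupied area fraction at threshold."""
        return self.pl_star * peptide.A_p / self.lipid_area_A2

    def check_saturation(self, peptide: PeptideParams) -> None:
        x_star = self.saturation_fraction(peptide)
        if x_star >= 1.0:
            raise ValueError(
                f"threshold coverage saturates the monolayer: "
                f"P/L*·A_p/a_l = {x_star:.3g} >= 1"
            )

    def effective_w(self, peptide: PeptideParams) -> float:
        """Energy used for coverage: the raw override if set, else the anchor."""
        if self.coverage_w is not None:
            return self.coverage_w
        resolved = resolve_anchor(self, peptide)
        assert resolved.w is not None
        return resolved.w


@dataclass(frozen=True)
class Population:
    """A membrane class at a number density (cells per mL)."""

    membrane: MembraneClass
    density_per_ml: float

    def __post_init__(self) -> None:
        if self.density_per_ml < 0:
            raise ValueError(f"density must be >= 0, got {self.density_per_ml}")


def _vp_rho(c_free: float, peptide: PeptideParams) -> float:
    """Dimensionless v_p·ρ_free for a molar free concentration."""
    return peptide.v_p * number_density_per_A3(c_free)


def coverage_from_free(
    c_free: float, membrane: MembraneClass, peptide: PeptideParams
) -> float:
    """Equilibrium coverage P/L at a given free peptide concentration.

    Solves the saturating isotherm x/(1−x) = v_p ρ exp(−w) and returns
    P/L = x·a_l/A_p.  Strictly increasing in ``c_free`` and bounded above
    by the monolayer limit a_l/A_p.
    """
    if c_free < 0:
        raise ValueError(f"c_free must be >= 0, got {c_free}")
    w = membrane.effective_w(peptide)
    y = _vp_rho(c_free, peptide) * math.exp(-w)
    x = y / (1.0 + y)
    return x * membrane.lipid_area_A2 / peptide.A_p


def binding_equilibrium_residual(
    c_free: float, pl: float, membrane: MembraneClass, peptide: PeptideParams
) -> float:
    """μ_bound − μ_free in k_BT at a trial coverage.

    Zero exactly when ``pl`` equals :func:`coverage_from_free`; positive if
    the membrane is over-covered relative to equilibrium, negative if
    under-covered.
    """
    if c_free <= 0:
        raise ValueError("residual requires c_free > 0")
    x = pl * peptide.A_p / membrane.lipid_area_A2
    if not 0.0 < x < 1.0:
        raise ValueError(
            f"coverage out of range: occupied fraction {x:.3g} not in (0, 1)"
        )
    w = membrane.effective_w(peptide)
    mu_bound = w + math.log(x / (1.0 - x))
    mu_free = math.log(_vp_rho(c_free, peptide))
    return mu_bound - mu_free


def intercept_from_energy(membrane: MembraneClass, peptide: PeptideParams) -> float:
    """Zero-density threshold concentration (MIC₀/MHC₀) from a binding energy.

    c0 = [x*/(1−x*)]·exp(w) / (v_p N_A per liter), with x* = P/L*·A_p/a_l —
    the free concentration at which coverage reaches P/L*.  Exponentially
    sensitive to w.
    """
    if membrane.w is None:
        raise AnchorError("membrane has no binding energy anchor (w is None)")
    membrane.check_saturation(peptide)
    x_star = membrane.saturation_fraction(peptide)
    per_molar = peptide.v_p * N_AVOGADRO * A3_TO_LITER  # v_p * rho per mol/L
    return (x_star / (1.0 - x_star)) * math.exp(membrane.w) / per_molar


def energy_from_intercept(membrane: MembraneClass, peptide: PeptideParams) -> float:
    """Binding energy w (k_BT) from an imposed MIC₀/MHC₀; exact inverse of
    :func:`intercept_from_energy`."""
    if membrane.c0 is None:
        raise AnchorError("membrane has no intercept anchor (c0 is None)")
    membrane.check_saturation(peptide)
    x_star = membrane.saturation_fraction(peptide)
    per_molar = peptide.v_p * N_AVOGADRO * A3_TO_LITER
    return math.log(membrane.c0 * per_molar * (1.0 - x_star) / x_star)


def resolve_anchor(membrane: MembraneClass, peptide: PeptideParams) -> MembraneClass:
    """Return a copy with both ``w`` and ``c0`` populated.

    Exactly one of the two must be set on input (if both are set they must
    already agree to 1e-9 relative, in which case this is the identity).
    Idempotent.
    """
    membrane.check_saturation(peptide)
    if membrane.w is None and membrane.c0 is None:
        raise AnchorError(
            f"membrane {membrane.label!r} has neither an energy (w) nor an "
            "intercept (c0) anchor"
        )
    if membrane.w is not None and membrane.c0 is not None:
        implied = intercept_from_energy(membrane, peptide)
        if abs(implied - membrane.c0) > ANCHOR_CONSISTENCY_RTOL * membrane.c0:
            raise AnchorError(
                f"inconsistent anchors on {membrane.label!r}: w={membrane.w} "
                f"implies c0={implied:.6e} mol/L but c0={membrane.c0:.6e}"
            )
        return membrane
    if membrane.w is not None:
        return replace(membrane, c0=intercept_from_energy(membrane, peptide))
    return replace(membrane, w=energy_from_intercept(membrane, peptide))
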