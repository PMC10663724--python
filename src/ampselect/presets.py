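"""Parameter presets for melittin-like peptides, plus YAML (de)serialization.

Two scenario families are shipped:

``melittin_membrane``
    Model lipid bilayers mimicking bacterial and host-cell membranes.
    Energy-anchored (w_B = −16.6 k_BT, w_H = −6.72 k_BT, mapped for
    melittin on charged vs neutral bilayers); no trapping (N_p = 0: model
    membranes have no cytoplasm to trap peptides in).

``melittin_cell``
    Real cells (E. coli vs human red blood cells).  Intercept-anchored at
    biophysically-typical MIC₀ = 1 μM and MHC₀ = 5 μM — for cells the
    effective binding energy is confounded by the outer membrane and is
    better imposed through the measured intercepts — with trapping
    N_p ∈ {0, 10⁷, 5×10⁷} per cell (equal for both classes).

Shared geometry: A_B = 12 μm² (both leaflets of the E. coli cytoplasmic
membrane), A_H = 200 μm² ≈ 17·A_B (human red blood cell), a_B = 71 Å²,
a_H = 74 Å², v_p = 33³ Å³, A_p = 400 Å².

The melittin rupture thresholds P/L* are known only to be of order 0.01,
somewhat larger for PE-containing bacterial membranes.  Defaults here:
pl_star = 0.01 for both classes in the cell preset (the thresholds enter
the cell preset only through the slope term, which trapping dominates
anyway), and pl_star_B = 0.02 / pl_star_H = 0.01 for the membrane preset.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Any

import yaml

from .langmuir import MembraneClass, PeptideParams

MELITTIN_PEPTIDE = PeptideParams(v_p=33.0**3, A_p=400.0)

#: Membrane binding energies (k_BT) mapped for melittin on model bilayers.
W_B_MELITTIN = -16.6
W_H_MELITTIN = -6.72

A_B_UM2 = 12.0
A_H_UM2 = 200.0  # ~17 x A_B, human red blood cell
A_B_LIPID_A2 = 71.0
A_H_LIPID_A2 = 74.0

MIC0_CELL_M = 1e-6
MHC0_CELL_M = 5e-6


@dataclass(frozen=True)
class ScenarioPreset:
    """A named peptide + bacterial-membrane + host-membrane parameter set."""

    name: str
    peptide: PeptideParams
    bacterial: MembraneClass
    host: MembraneClass
    notes: str = ""

    def to_dict(self) -> dict[str, Any]:
        d = {
            "name": self.name,
            "notes": self.notes,
            "peptide": asdict(self.peptide),
            "bacterial": asdict(self.bacterial),
            "host": asdict(self.host),
        }
        # report anchors in uM for readability
        for key in ("bacterial", "host"):
            c0 = d[key].pop("c0")
            d[key]["c0_uM"] = None if c0 is None else c0 * 1e6
        return d


def melittin_membrane(
    host_area_um2: float = A_H_UM2,
    pl_star_bacterial: float = 0.02,
    pl_star_host: float = 0.01,
) -> ScenarioPreset:
    """Model-membrane scenario: energy-anchored, no trapping.

    ``host_area_um2`` may be set to ``A_B_UM2`` (12) for the equal-area
    bilayer variant.
    """
    bacterial = MembraneClass(
        label="bacterial",
        area_um2=A_B_UM2,
        lipid_area_A2=A_B_LIPID_A2,
        pl_star=pl_star_bacterial,
        w=W_B_MELITTIN,
        n_trapped=0.0,
    )
    host = MembraneClass(
        label="host",
        area_um2=host_area_um2,
        lipid_area_A2=A_H_LIPID_A2,
        pl_star=pl_star_host,
        w=W_H_MELITTIN,
        n_trapped=0.0,
    )
    return ScenarioPreset(
        name="melittin_membrane",
        peptide=MELITTIN_PEPTIDE,
        bacterial=bacterial,
        host=host,
        notes="model bilayers; binding-energy anchored; N_p = 0",
    )


def melittin_cell(
    n_trapped: float = 5e7,
    raw_energy_coverage: bool = False,
    pl_star: float = 0.01,
) -> ScenarioPreset:
    """Cell scenario: intercept-anchored (MIC₀ = 1 μM, MHC₀ = 5 μM),
    trapped count ``n_trapped`` per cell for both classes.

    With ``raw_energy_coverage=True`` the membrane-mapped energies
    (w_B = −16.6, w_H = −6.72 k_BT) are used for coverage while the imposed
    intercepts still define the thresholds; by default coverage uses the
    effective energies implied by the intercepts, so the isotherm passes
    through (c0, P/L*).
    """
    bacterial = MembraneClass(
        label="bacterial",
        area_um2=A_B_UM2,
        lipid_area_A2=A_B_LIPID_A2,
        pl_star=pl_star,
        c0=MIC0_CELL_M,
        n_trapped=n_trapped,
        coverage_w=W_B_MELITTIN if raw_energy_coverage else None,
    )
    host = MembraneClass(
        label="host",
        area_um2=A_H_UM2,
        lipid_area_A2=A_H_LIPID_A2,
        pl_star=pl_star,
        c0=MHC0_CELL_M,
        n_trapped=n_trapped,
        coverage_w=W_H_MELITTIN if raw_energy_coverage else None,
    )
    return ScenarioPreset(
        name="melittin_cell",
        peptide=MELITTIN_PEPTIDE,
        bacterial=bacterial,
        host=host,
        notes=f"E. coli vs red blood cell; intercept anchored; N_p = {n_trapped:g}",
    )


PRESET_FACTORIES = {
    "melittin_membrane": melittin_membrane,
    "melittin_cell": melittin_cell,
}


def get_preset(name: str, **kwargs: Any) -> ScenarioPreset:
    """Look up a preset by name; keyword arguments forward to its factory."""
    try:
        factory = PRESET_FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESET_FACTORIES)}"
        ) from None
    return factory(**kwargs)


def preset_with_trapping(preset: ScenarioPreset, n_trapped: float) -> ScenarioPreset:
    """Copy of a preset with N_p set (same value for both classes)."""
    return replace(
        preset,
        bacterial=replace(preset.bacterial, n_trapped=n_trapped),
        host=replace(preset.host, n_trapped=n_trapped),
    )


# ---------------------------------------------------------------------------
# YAML config round trip.  Units in files: concentrations in uM, areas in
# um^2 (cells) / A^2 (lipids, peptide cross-section), volumes in A^3,
# energies in kBT, counts dimensionless.
# ---------------------------------------------------------------------------

def _membrane_from_dict(d: dict[str, Any]) -> MembraneClass:
    c0_uM = d.get("c0_uM")
    return MembraneClass(
        label=d["label"],
        area_um2=float(d["area_um2"]),
        lipid_area_A2=float(d["lipid_area_A2"]),
        pl_star=float(d["pl_star"]),
        w=None if d.get("w") is None else float(d["w"]),
        c0=None if c0_uM is None else float(c0_uM) * 1e-6,
        n_trapped=float(d.get("n_trapped", 0.0)),
        coverage_w=None if d.get("coverage_w") is None else float(d["coverage_w"]),
    )


def scenario_from_dict(d: dict[str, Any]) -> ScenarioPreset:
    pep = d.get("peptide", {})
    return ScenarioPreset(
        name=d.get("name", "custom"),
        peptide=PeptideParams(v_p=float(pep["v_p"]), A_p=float(pep["A_p"])),
        bacterial=_membrane_from_dict(d["bacterial"]),
        host=_membrane_from_dict(d["host"]),
        notes=d.get("notes", ""),
    )


def load_scenario_yaml(path: str) -> ScenarioPreset:
    """Read a ScenarioPreset from a YAML file (see module docstring units)."""
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def dump_scenario_yaml(preset: ScenarioPreset) -> str:
    """Serialize a preset to YAML (inverse of :func:`load_scenario_yaml`)."""
    return yaml.safe_dump(preset.to_dict(), sort_keys=False)
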