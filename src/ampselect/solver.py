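"""MIC/MHC solver: mass balance over free, membrane-bound and trapped pools.

The total peptide concentration splits as

    C_p = c_free + Σ_i (P/L)_i(c_free)·(A_i/a_i + N_p,i·[trapped_i]) · C_i

summed over cell populations i (densities converted from cells/mL to a
molar consumption).  Because every term is closed-form and strictly
increasing in the free concentration, thresholds are found by continuation
in c_free rather than by stepping C_p: the MIC is the total concentration
evaluated at the bacterial threshold free concentration (= MIC₀), with
bacterial trapping engaged and host trapping absent (the host is still
below its own threshold there); the MHC is the total at the host threshold
free concentration with both trapping pools engaged and the bacterial
coverage evaluated above its threshold.

Trapping is a step function: N_p* peptides per cell engage exactly at and
above a class's threshold and stay constant beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .langmuir import (
    MembraneClass,
    PeptideParams,
    Population,
    coverage_from_free,
    resolve_anchor,
)
from .quantities import counts_per_cell_to_molar


class NoSelectiveWindowError(ValueError):
    """The host membrane would rupture at or before the bacterial one.

    The competitive construction presumes the MIC is reached first as C_p
    increases; if the host threshold free concentration falls below the
    bacterial one there is no concentration window that kills bacteria
    while sparing host cells.
    """

    def __init__(self, c0_bacterial: float, c0_host: float):
        self.c0_bacterial = c0_bacterial
        self.c0_host = c0_host
        super().__init__(
            "no selective window: host threshold free concentration "
            f"({c0_host:.4e} mol/L) <= bacterial threshold ({c0_bacterial:.4e} mol/L)"
        )


@dataclass(frozen=True)
class SystemState:
    """Mass-balance snapshot at one free concentration.

    ``c_total = c_free + sum(bound_molar) + sum(trapped_molar)`` holds by
    construction; coverages are per population, in P/L units.
    """

    c_total: float
    c_free: float
    coverage: tuple[float, ...]
    bound_molar: tuple[float, ...]
    trapped_molar: tuple[float, ...]
    trapped_engaged: tuple[bool, ...]

    def mass_balance_residual(self) -> float:
        return self.c_total - self.c_free - sum(self.bound_molar) - sum(
            self.trapped_molar
        )


@dataclass(frozen=True)
class ActivityResult:
    """MIC, MHC and selectivity for one scenario.

    Concentrations in mol/L; ``selectivity = mhc/mic``; ``protocol`` is
    "competitive" (mixture) or "noncompetitive" (separate single-population
    measurements combined); ``ordering_ok`` records that the bacterial
    threshold is reached first.
    """

    mic: float
    mhc: float
    c_free_at_mic: float
    c_free_at_mhc: float
    protocol: str
    ordering_ok: bool = True
    anchors: dict = field(default_factory=dict)

    @property
    def selectivity(self) -> float:
        return self.mhc / self.mic

    def to_dict(self) -> dict:
        """JSON-friendly summary; concentrations reported in μM."""
        return {
            "protocol": self.protocol,
            "MIC_uM": self.mic * 1e6,
            "MHC_uM": self.mhc * 1e6,
            "selectivity": self.selectivity,
            "c_free_at_MIC_uM": self.c_free_at_mic * 1e6,
            "c_free_at_MHC_uM": self.c_free_at_mhc * 1e6,
            "ordering_ok": self.ordering_ok,
            "anchors": self.anchors,
        }


def consumption_per_cell(
    population: Population,
    c_free: float,
    trapped: bool,
    peptide: PeptideParams,
) -> float:
    """Peptides consumed per cell: membrane-bound + (if engaged) trapped.

    coverage(c_free)·A_cell/a_l + N_p*·[trapped].
    """
    m = population.membrane
    bound = coverage_from_free(c_free, m, peptide) * m.lipids_per_cell
    return bound + (m.n_trapped if trapped else 0.0)


def total_from_free(
    c_free: float,
    populations: Sequence[Population],
    trapped_rule: Sequence[bool],
    peptide: PeptideParams,
) -> float:
    """Total concentration C_p implied by a free concentration (mol/L).

    Strictly increasing in ``c_free`` for fixed trapping flags.
    """
    return system_state(c_free, populations, trapped_rule, peptide).c_total


def system_state(
    c_free: float,
    populations: Sequence[Population],
    trapped_rule: Sequence[bool],
    peptide: PeptideParams,
) -> SystemState:
    """Full mass-balance state at ``c_free`` (see :class:`SystemState`)."""
    if len(populations) != len(trapped_rule):
        raise ValueError("one trapping flag per population required")
    coverage, bound, trapped = [], [], []
    for pop, engaged in zip(populations, trapped_rule):
        m = pop.membrane
        pl = coverage_from_free(c_free, m, peptide)
        coverage.append(pl)
        bound.append(
            counts_per_cell_to_molar(pl * m.lipids_per_cell, pop.density_per_ml)
        )
        trapped.append(
            counts_per_cell_to_molar(m.n_trapped, pop.density_per_ml)
            if engaged
            else 0.0
        )
    c_total = c_free + sum(bound) + sum(trapped)
    return SystemState(
        c_total=c_total,
        c_free=c_free,
        coverage=tuple(coverage),
        bound_molar=tuple(bound),
        trapped_molar=tuple(trapped),
        trapped_engaged=tuple(bool(t) for t in trapped_rule),
    )


def _threshold_homogeneous(population: Population, peptide: PeptideParams) -> float:
    """Linear inoculum relation for a single-class solution (mol/L).

    c* = c0 + (P/L*·A_cell/a_l + N_p*)·C_cell, densities in molar terms.
    """
    m = resolve_anchor(population.membrane, peptide)
    per_cell = m.pl_star * m.lipids_per_cell + m.n_trapped
    assert m.c0 is not None
    return m.c0 + counts_per_cell_to_molar(per_cell, population.density_per_ml)


def mic_homogeneous(bacterial: Population, peptide: PeptideParams) -> float:
    """MIC of a bacteria-only solution: MIC₀ + per-cell consumption × C_B."""
    return _threshold_homogeneous(bacterial, peptide)


def mhc_homogeneous(host: Population, peptide: PeptideParams) -> float:
    """MHC of a host-cell-only solution: MHC₀ + per-cell consumption × C_H."""
    return _threshold_homogeneous(host, peptide)


def _resolved_pair(
    bacterial: Population, host: Population, peptide: PeptideParams
) -> tuple[Population, Population]:
    b = Population(resolve_anchor(bacterial.membrane, peptide), bacterial.density_per_ml)
    h = Population(resolve_anchor(host.membrane, peptide), host.density_per_ml)
    assert b.membrane.c0 is not None and h.membrane.c0 is not None
    if b.membrane.c0 > h.membrane.c0:
        raise NoSelectiveWindowError(b.membrane.c0, h.membrane.c0)
    return b, h


def find_mic_competitive(
    bacterial: Population, host: Population, peptide: PeptideParams
) -> ActivityResult:
    """Competitive MIC of a bacteria + host-cell mixture.

    The free concentration at the MIC equals the bacterial threshold MIC₀;
    bacterial trapping is engaged (the cells die) while host trapping is
    not (host cells are still intact below their own threshold), but
    sub-threshold host membrane binding does consume peptide and inflates
    the MIC.
    """
    b, h = _resolved_pair(bacterial, host, peptide)
    c_free = b.membrane.c0
    state = system_state(c_free, [b, h], [True, False], peptide)
    return ActivityResult(
        mic=state.c_total,
        mhc=float("nan"),
        c_free_at_mic=c_free,
        c_free_at_mhc=float("nan"),
        protocol="competitive",
        ordering_ok=True,
        anchors=_anchor_audit(b, h),
    )


def find_mhc_competitive(
    bacterial: Population, host: Population, peptide: PeptideParams
) -> ActivityResult:
    """Competitive MHC of the mixture: free concentration = MHC₀, both
    trapping pools engaged, bacterial coverage evaluated above its
    threshold."""
    b, h = _resolved_pair(bacterial, host, peptide)
    c_free = h.membrane.c0
    state = system_state(c_free, [b, h], [True, True], peptide)
    return ActivityResult(
        mic=float("nan"),
        mhc=state.c_total,
        c_free_at_mic=float("nan"),
        c_free_at_mhc=c_free,
        protocol="competitive",
        ordering_ok=True,
        anchors=_anchor_audit(b, h),
    )


def solve_competitive(
    bacterial: Population, host: Population, peptide: PeptideParams
) -> ActivityResult:
    """Competitive MIC and MHC combined into one result."""
    mic_part = find_mic_competitive(bacterial, host, peptide)
    mhc_part = find_mhc_competitive(bacterial, host, peptide)
    return ActivityResult(
        mic=mic_part.mic,
        mhc=mhc_part.mhc,
        c_free_at_mic=mic_part.c_free_at_mic,
        c_free_at_mhc=mhc_part.c_free_at_mhc,
        protocol="competitive",
        ordering_ok=True,
        anchors=mic_part.anchors,
    )


def solve_noncompetitive(
    bacterial: Population, host: Population, peptide: PeptideParams
) -> ActivityResult:
    """Noncompetitive result: MIC from a bacteria-only solution at C_B and
    MHC from a host-only solution at C_H, combined.

    The two measurements are independent, so an inverted threshold ordering
    is reported via ``ordering_ok`` rather than raised.
    """
    b = Population(resolve_anchor(bacterial.membrane, peptide), bacterial.density_per_ml)
    h = Population(resolve_anchor(host.membrane, peptide), host.density_per_ml)
    assert b.membrane.c0 is not None and h.membrane.c0 is not None
    return ActivityResult(
        mic=mic_homogeneous(b, peptide),
        mhc=mhc_homogeneous(h, peptide),
        c_free_at_mic=b.membrane.c0,
        c_free_at_mhc=h.membrane.c0,
        protocol="noncompetitive",
        ordering_ok=b.membrane.c0 <= h.membrane.c0,
        anchors=_anchor_audit(b, h),
    )


def mic_mhc_high_host_approx(
    bacterial: Population, host: Population, peptide: PeptideParams
) -> tuple[float, float]:
    """Host-dominated (C_H ≫ C_B, as in whole blood) approximations.

    MIC ≈ MIC₀ + (A_H/a_H)·(P/L)_H(at the MIC)·C_H and MHC ≈ the host-only
    linear relation; bacterial consumption terms are dropped entirely.
    Accuracy is reported by comparison with the full solver, not enforced.
    """
    b, h = _resolved_pair(bacterial, host, peptide)
    hm = h.membrane
    assert b.membrane.c0 is not None
    pl_h_at_mic = coverage_from_free(b.membrane.c0, hm, peptide)
    mic = b.membrane.c0 + counts_per_cell_to_molar(
        pl_h_at_mic * hm.lipids_per_cell, h.density_per_ml
    )
    mhc = mhc_homogeneous(h, peptide)
    return mic, mhc


def selectivity_ratio_high_host(
    bacterial: Population, host: Population, peptide: PeptideParams
) -> float:
    """Approximate MHC/MIC in the host-dominated limit.

    Monotonically increasing in the host trapped count N_pH: trapping in
    host cells raises the MHC but not the MIC, so it widens the selective
    window.
    """
    mic, mhc = mic_mhc_high_host_approx(bacterial, host, peptide)
    return mhc / mic


def _anchor_audit(b: Population, h: Population, ) -> dict:
    """Resolved anchors (w_eff in k_BT, c0 in μM) for result serialization."""
    out = {}
    for pop in (b, h):
        m = pop.membrane
        out[m.label] = {
            "w_eff_kBT": m.w,
            "c0_uM": None if m.c0 is None else m.c0 * 1e6,
            "coverage_w_kBT": m.coverage_w,
            "N_p": m.n_trapped,
        }
    return out
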