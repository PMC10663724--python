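"""Protocol-level API: scenarios, density sweeps, fitting and synthesis.

This module glues the solver to user-facing workflows: one-shot scenario
evaluation under a competitive or noncompetitive protocol, log-spaced
density sweeps producing tidy tables of MIC/MHC/selectivity curves, the
inverse mode (ordinary least squares on measured threshold-vs-density data
to recover intercept, slope, binding energy and trapped count), and a
reproducible generator of noisy synthetic inoculum-effect measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .langmuir import MembraneClass, PeptideParams, Population, resolve_anchor
from .presets import ScenarioPreset
from .quantities import N_AVOGADRO, PER_ML_TO_PER_L
from .solver import (
    ActivityResult,
    NoSelectiveWindowError,
    mhc_homogeneous,
    mic_homogeneous,
    solve_competitive,
    solve_noncompetitive,
)

SWEEP_COLUMNS = [
    "density",
    "C_B",
    "C_H",
    "MIC_uM",
    "MHC_uM",
    "selectivity",
    "protocol",
    "preset",
]


def run_protocol(
    preset: ScenarioPreset,
    c_b: float,
    c_h: float,
    protocol: str = "competitive",
) -> ActivityResult:
    """Evaluate one scenario.

    ``competitive``: MIC and MHC of the actual mixture at (C_B, C_H).
    ``noncompetitive``: MIC from a bacteria-only solution at C_B combined
    with MHC from a host-only solution at C_H.  Densities in cells/mL.
    """
    bacterial = Population(preset.bacterial, c_b)
    host = Population(preset.host, c_h)
    if protocol == "competitive":
        return solve_competitive(bacterial, host, preset.peptide)
    if protocol == "noncompetitive":
        return solve_noncompetitive(bacterial, host, preset.peptide)
    raise ValueError(f"protocol must be 'competitive' or 'noncompetitive', got {protocol!r}")


@dataclass(frozen=True)
class SweepSpec:
    """One density-sweep request.

    ``vary`` selects the x axis: "C_B" (C_H fixed), "C_H" (C_B fixed), or
    "both" (C_B = C_H locked together).  ``grid`` is the density grid in
    cells/mL (default log-spaced 10³–10¹⁰, 60 points); fixed densities
    default to 0.
    """

    preset: ScenarioPreset
    vary: str = "both"
    fixed_c_b: float = 0.0
    fixed_c_h: float = 0.0
    protocols: tuple[str, ...] = ("competitive", "noncompetitive")
    grid: Sequence[float] = field(
        default_factory=lambda: np.logspace(3, 10, 60).tolist()
    )

    def densities(self, x: float) -> tuple[float, float]:
        if self.vary == "both":
            return x, x
        if self.vary == "C_B":
            return x, self.fixed_c_h
        if self.vary == "C_H":
            return self.fixed_c_b, x
        raise ValueError(f"vary must be 'C_B', 'C_H' or 'both', got {self.vary!r}")


def sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate :func:`run_protocol` over the grid into a long-format table.

    Columns: density, C_B, C_H, MIC_uM, MHC_uM, selectivity, protocol,
    preset — one row per (grid point × protocol).  Grid points where the
    competitive construction has no selective window are kept as rows with
    NaN thresholds and protocol suffixed ``!no_selective_window`` rather
    than dropped silently.
    """
    rows = []
    for x in spec.grid:
        c_b, c_h = spec.densities(float(x))
        for protocol in spec.protocols:
            try:
                res = run_protocol(spec.preset, c_b, c_h, protocol)
                rows.append(
                    {
                        "density": float(x),
                        "C_B": c_b,
                        "C_H": c_h,
                        "MIC_uM": res.mic * 1e6,
                        "MHC_uM": res.mhc * 1e6,
                        "selectivity": res.selectivity,
                        "protocol": protocol,
                        "preset": spec.preset.name,
                    }
                )
            except NoSelectiveWindowError:
                rows.append(
                    {
                        "density": float(x),
                        "C_B": c_b,
                        "C_H": c_h,
                        "MIC_uM": np.nan,
                        "MHC_uM": np.nan,
                        "selectivity": np.nan,
                        "protocol": f"{protocol}!no_selective_window",
                        "preset": spec.preset.name,
                    }
                )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


# ---------------------------------------------------------------------------
# Inverse mode: fit measured threshold-vs-density data and extract N_p, w
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InoculumDataset:
    """(density, threshold concentration) measurements for one cell class.

    ``data`` has columns ``density_cells_per_mL`` and ``c_star_uM`` (and
    optionally ``sd_uM``, ``truncated``); ``noise_sd_uM``/``seed``/
    ``true_params`` record synthesis provenance when applicable.
    """

    data: pd.DataFrame
    noise_sd_uM: float | None = None
    seed: int | None = None
    true_params: dict | None = None


@dataclass(frozen=True)
class LinearFitResult:
    """OLS/WLS fit of the linear inoculum relation c* = c0 + slope·C_cell.

    Intercept in μM, slope in μM per (cells/mL), with standard errors;
    ``n_p_hat``/``w_hat`` are filled by :func:`extract_Np` /
    :func:`extract_energy` when geometry is supplied.
    """

    intercept_uM: float
    intercept_se_uM: float
    slope_uM_per_cell_per_mL: float
    slope_se_uM_per_cell_per_mL: float
    n_obs: int
    residual_sd_uM: float
    r_squared: float
    weighted: bool = False

    def confidence_intervals(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        """(1−alpha) t-based confidence intervals for intercept and slope."""
        from scipy import stats

        z = stats.t.ppf(1 - alpha / 2, df=max(self.n_obs - 2, 1))
        return {
            "intercept_uM": (
                self.intercept_uM - z * self.intercept_se_uM,
                self.intercept_uM + z * self.intercept_se_uM,
            ),
            "slope_uM_per_cell_per_mL": (
                self.slope_uM_per_cell_per_mL - z * self.slope_se_uM_per_cell_per_mL,
                self.slope_uM_per_cell_per_mL + z * self.slope_se_uM_per_cell_per_mL,
            ),
        }

    def to_dict(self) -> dict:
        return {
            "intercept_uM": self.intercept_uM,
            "intercept_se_uM": self.intercept_se_uM,
            "slope_uM_per_cell_per_mL": self.slope_uM_per_cell_per_mL,
            "slope_se_uM_per_cell_per_mL": self.slope_se_uM_per_cell_per_mL,
            "n_obs": self.n_obs,
            "residual_sd_uM": self.residual_sd_uM,
            "r_squared": self.r_squared,
            "weighted": self.weighted,
        }


def fit_linear(dataset: InoculumDataset, weighted: bool = False) -> LinearFitResult:
    """Least-squares fit of threshold concentration on cell density.

    Unweighted OLS by default; with ``weighted=True`` and a per-point
    ``sd_uM`` column, WLS with weights 1/sd².  Requires at least two
    distinct densities.  A negative fitted intercept is physically
    suspect (thresholds are positive at zero density) and is flagged with
    a warning, not an error.
    """
    df = dataset.data
    density = np.asarray(df["density_cells_per_mL"], dtype=float)
    c_star = np.asarray(df["c_star_uM"], dtype=float)
    if np.unique(density).size < 2:
        raise ValueError("need measurements at >= 2 distinct densities")
    design = sm.add_constant(density)
    if weighted:
        if "sd_uM" not in df.columns:
            raise ValueError("weighted fit requires an 'sd_uM' column")
        sd = np.asarray(df["sd_uM"], dtype=float)
        model = sm.WLS(c_star, design, weights=1.0 / sd**2)
    else:
        model = sm.OLS(c_star, design)
    fit = model.fit()
    intercept, slope = fit.params
    if intercept < 0:
        import warnings

        warnings.warn(
            f"fitted intercept is negative ({intercept:.3g} uM); the linear "
            "inoculum model expects a positive zero-density threshold",
            stacklevel=2,
        )
    return LinearFitResult(
        intercept_uM=float(intercept),
        intercept_se_uM=float(fit.bse[0]),
        slope_uM_per_cell_per_mL=float(slope),
        slope_se_uM_per_cell_per_mL=float(fit.bse[1]),
        n_obs=int(fit.nobs),
        residual_sd_uM=float(np.sqrt(fit.scale)),
        r_squared=float(fit.rsquared),
        weighted=weighted,
    )


def slope_to_counts_per_cell(slope_uM_per_cell_per_mL: float) -> float:
    """Convert an inoculum slope (μM per cells/mL) to peptides per cell."""
    return slope_uM_per_cell_per_mL * 1e-6 * N_AVOGADRO / PER_ML_TO_PER_L


def extract_Np(
    fit: LinearFitResult, membrane: MembraneClass, peptide: PeptideParams
) -> float:
    """Trapped count from a fitted slope.

    The slope counts all peptides consumed per cell; subtracting the
    membrane-bound share P/L*·A_cell/a_l leaves the trapped pool:
    N_p_hat = slope·N_A/10³ − P/L*·A_cell/a_l.  A negative estimate
    (membrane-binding-only regime) is returned as-is with a warning.
    """
    consumed = slope_to_counts_per_cell(fit.slope_uM_per_cell_per_mL)
    n_p_hat = consumed - membrane.pl_star * membrane.lipids_per_cell
    if n_p_hat < 0:
        import warnings

        warnings.warn(
            f"extracted N_p is negative ({n_p_hat:.3g}): the fitted slope is "
            "below the membrane-binding share; trapping is not resolvable",
            stacklevel=2,
        )
    return n_p_hat


def extract_energy(
    fit: LinearFitResult, membrane: MembraneClass, peptide: PeptideParams
) -> float:
    """Binding energy w (k_BT) from a fitted intercept, via the Langmuir
    intercept inversion with the membrane's geometry and P/L*."""
    from .langmuir import energy_from_intercept
    from dataclasses import replace

    anchored = replace(membrane, w=None, c0=fit.intercept_uM * 1e-6)
    return energy_from_intercept(anchored, peptide)


def generate_synthetic_inoculum_data(
    membrane: MembraneClass,
    peptide: PeptideParams,
    densities: Sequence[float],
    noise_sd_uM: float = 0.5,
    seed: int = 0,
) -> InoculumDataset:
    """Simulate noisy noncompetitive threshold measurements.

    For each density the exact linear relation c* = c0 + (P/L*·A_cell/a_l
    + N_p)·C_cell is evaluated and an independent Gaussian deviate of
    standard deviation ``noise_sd_uM`` is added, emulating plate-assay
    scatter.  Negative draws are truncated at 0 and flagged in a
    ``truncated`` column.  Fully reproducible from ``seed``.
    """
    if noise_sd_uM < 0:
        raise ValueError(f"noise_sd_uM must be >= 0, got {noise_sd_uM}")
    m = resolve_anchor(membrane, peptide)
    rng = np.random.default_rng(seed)
    density = np.asarray(densities, dtype=float)
    exact_uM = np.array(
        [
            mic_homogeneous(Population(m, d), peptide) * 1e6
            if m.label == "bacterial"
            else mhc_homogeneous(Population(m, d), peptide) * 1e6
            for d in density
        ]
    )
    noisy = exact_uM + rng.normal(0.0, noise_sd_uM, size=density.size)
    truncated = noisy < 0
    noisy = np.where(truncated, 0.0, noisy)
    assert m.c0 is not None
    data = pd.DataFrame(
        {
            "density_cells_per_mL": density,
            "c_star_uM": noisy,
            "truncated": truncated,
        }
    )
    per_cell = m.pl_star * m.lipids_per_cell + m.n_trapped
    return InoculumDataset(
        data=data,
        noise_sd_uM=noise_sd_uM,
        seed=seed,
        true_params={
            "intercept_uM": m.c0 * 1e6,
            "slope_uM_per_cell_per_mL": per_cell * PER_ML_TO_PER_L / N_AVOGADRO * 1e6,
            "N_p": m.n_trapped,
            "w_kBT": m.w,
        },
    )
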