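# Methods

## Model

`ampselect` implements an equilibrium partitioning model for antimicrobial
peptides (AMPs) in suspensions of cells or model membranes. Peptides are
free, membrane-bound, or trapped inside dead cells. The three pools obey a
mass balance at fixed total peptide concentration; membranes rupture in an
all-or-none fashion when the bound-peptide-to-lipid ratio P/L reaches a
class-specific threshold P/L*.

**Binding.** Bound and free chemical potentials (k_BT units) are

    μ_bound = w + ln[x/(1−x)],      μ_free = ln(v_p ρ_free),

with x = σ_p·A_p the occupied area fraction (A_p the exclusion area per
bound peptide, σ_p the planar density of bound peptides, P/L = x·a_l/A_p).
Equating them gives the saturating isotherm x/(1−x) = v_p ρ_free e^(−w).
The logarithmic term counts arrangements of bound peptides on the surface;
the saturating form matters because threshold occupancies for the default
parameters are x* ≈ 0.05–0.11, not dilute. The effective energy w subsumes
electrostatics, lipid demixing and pore formation; it is treated as
coverage-independent because at P/L ≲ 0.01 the peptide–peptide spacing
(~85 Å) well exceeds the Debye length at physiological salt (~10 Å — the
`debye_length` helper computes this).

**Anchoring.** The free concentration at which coverage reaches P/L* is
the zero-density threshold intercept,

    c0 = (1/(v_p N_A per L)) · [x*/(1−x*)] · e^w,   x* = P/L*·A_p/a_l,

exponentially sensitive to w and invertible in closed form
(`intercept_from_energy` / `energy_from_intercept`). A membrane class may
be anchored either by w (model membranes, where w has been mapped) or by
an imposed intercept MIC₀/MHC₀ (cells, where the measurable thresholds are
better known than the microscopic energy); `resolve_anchor` fills in the
other member. For intercept-anchored cells, sub- and above-threshold
coverage is computed from the *effective* energy implied by the intercept
(w_eff,B ≈ −7.92, w_eff,H ≈ −6.27 k_BT for the defaults), so the isotherm
passes through (c0, P/L*) and the competitive solver degenerates exactly
to the homogeneous line when the other class's density is zero. A
`raw_energy_coverage` switch instead uses the membrane-mapped energies
(−16.6/−6.72 k_BT) for coverage while keeping the imposed intercepts; the
two readings differ modestly (the competitive whole-blood MIC moves from
6.5 to 9.2 μM in the headline scenario) and the anchored mode is the
default because it is internally consistent.

**Trapping.** Each dead cell sequesters N_p peptides — defined as half the
trapped count of a fully dead cell, since at threshold half the population
is ruptured. Trapping is a step function: zero below a class's threshold,
N_p at and above it, with no further C_p dependence. The trapped pool is
an input parameter, not derived from a trapping energy: the energetics of
intracellular binding and crowding are not modeled here.

**Thresholds.** The MIC of a mixture is the total concentration when the
bacterial coverage reaches its threshold: free pool at c0_B, bacterial
membrane + trapped consumption, plus *sub-threshold* host membrane binding
(host cells are intact at the MIC, so no host trapping). The MHC is the
total at c0_H with both trapped pools engaged and bacterial coverage
evaluated above threshold. Every pool is closed-form and strictly
increasing in the free concentration, so the solver parameterizes states
by c_free (continuation) instead of stepping the total concentration;
equivalence with a brute-force bisection in c_total (bracket [0, 2c0],
grown geometrically; relative tolerance 1e-10) is asserted in the test
suite over randomized parameter draws. If the host threshold falls below
the bacterial one the construction's asymmetry breaks down, and the solver
raises `NoSelectiveWindowError` (reporting both thresholds) rather than
returning a silent selectivity < 1; density-sweep tables keep such grid
points as flagged NaN rows.

**Host-dominated limit.** For C_H ≫ C_B (whole blood: ~5×10⁹ host
cells/mL against ≤10⁵ bacteria/mL) the bacterial consumption terms are
negligible: MIC ≈ MIC₀ + (A_H/a_H)·(P/L)_H(at the MIC)·C_H and MHC ≈ the
host-only linear relation. `mic_mhc_high_host_approx` implements these
truncations; their accuracy (≈5% on the MIC, ≈1% on the MHC in the
regimes above) is measured against the full solver in tests, not assumed.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| v_p | peptide volume | 33³ Å³ | melittin-like peptide |
| A_p | bound-peptide exclusion area | 400 Å² | melittin on bilayers |
| A_B | bacterial membrane area (both leaflets) | 12 μm² | 2 × 6 μm², E. coli cytoplasmic membrane; peptides distribute symmetrically across leaflets |
| A_H | host membrane area | 200 μm² (≈17·A_B) | human red blood cell |
| a_B, a_H | lipid headgroup areas | 71, 74 Å² | PE-rich vs PC-rich bilayers |
| w_B, w_H | binding energies | −16.6, −6.72 k_BT | melittin on charged vs neutral model bilayers |
| MIC₀, MHC₀ | cell-preset intercepts | 1, 5 μM | typical measured dilute-limit thresholds |
| P/L* | rupture threshold | 0.01 (cells, both classes); 0.02/0.01 (membrane preset B/H) | thresholds are of order 0.01; the bacterial value is somewhat larger on PE-containing membranes but known only to order of magnitude — an assumption, configurable |
| N_p | trapped peptides per cell | 5×10⁷ (cell preset default; 0 and 10⁷ common alternatives) | measured trapped counts in dead bacteria span 10⁷–10⁸; model membranes use 0 |

Units: concentrations mol/L internally, μM at every user-facing surface;
densities cells/mL; areas μm² (cells) and Å² (lipids/peptide); energies
k_BT. Temperature enters only via k_BT scaling and the Debye helper
(default 298.15 K).

## Synthetic data and the inverse mode

`generate_synthetic_inoculum_data` emulates noncompetitive plate-assay
measurements: the exact linear inoculum relation evaluated on a density
grid plus i.i.d. Gaussian noise (default SD 0.5 μM, a typical serial-
dilution resolution scale at low-μM thresholds), truncated at zero with a
per-row flag, fully reproducible from one integer seed. It does *not*
emulate two-fold dilution discretization, density-dependent error, plate
edge effects, or the stochastic survival of subpopulations near the MIC —
so passing recovery tests show the estimator is correct under the model's
own error assumptions, not that real assays are this well behaved.

`fit_linear` is unweighted OLS of threshold concentration on density
(statsmodels; WLS by reported per-point SD is available — no error model
is imposed beyond what the data provide). The intercept inverts to the
effective binding energy; the slope, converted to peptides per cell,
minus the membrane share P/L*·A_cell/a_l, gives the trapped count
(`extract_Np`). A negative extracted N_p (slope below the membrane share)
is flagged, not raised: it is the membrane-binding-only regime.

Simulation sizes in tests: confidence-interval coverage uses 500 seeds of
20-point datasets; recovery round trips use 12–20 points; the bisection
oracle uses 100 random parameter draws. These sizes give stable results
in seconds.

## Numerical choices

- Continuation in c_free avoids all root finding in the solver path;
  brentq is used only in test oracles (xtol effectively 0, rtol 1e-14/1e-12).
- Anchor consistency: if both w and c0 are supplied they must agree to
  1e-9 relative; `resolve_anchor` is idempotent.
- Degenerate inputs: zero density contributes nothing (the dilute limit is
  exact, not a special case); zero free concentration gives zero coverage;
  coverage at or above monolayer saturation a_l/A_p is rejected where it
  would be an input (the isotherm itself never produces it).
- Confidence intervals are t-based with n−2 degrees of freedom.

## Limitations

- Equilibrium only: no killing kinetics, no peptide expression or
  protease degradation, no stochastic population dynamics.
- N_p is an input; the trapping energetics (and hence its dependence on
  peptide or cell type) is outside the model.
- w is constant in coverage; strong electrostatic crowding at low salt
  would violate this.
- The outer membrane of Gram-negative bacteria is not modeled
  structurally; its effect is subsumed into MIC₀ (or w_B).
- The linear inoculum relation assumes thresholds well above zero
  density; fitted intercepts near zero are flagged as suspect.
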