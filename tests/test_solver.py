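"""MIC/MHC mass-balance solver: homogeneous lines, competitive mixtures,
host-dominated approximations, and the total-concentration bisection oracle."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from ampselect.langmuir import (
    MembraneClass,
    Population,
    coverage_from_free,
    resolve_anchor,
)
from ampselect.presets import melittin_cell
from ampselect.quantities import counts_per_cell_to_molar
from ampselect.solver import (
    NoSelectiveWindowError,
    consumption_per_cell,
    find_mhc_competitive,
    find_mic_competitive,
    mhc_homogeneous,
    mic_homogeneous,
    mic_mhc_high_host_approx,
    selectivity_ratio_high_host,
    solve_competitive,
    solve_noncompetitive,
    system_state,
    total_from_free,
)

UM = 1e-6


class TestConsumptionPerCell:
    def test_bacterial_cell_at_threshold_with_trapping(self, cell_preset):
        # membrane share 0.01 * (1.2e9/71) ~ 1.7e5; trapping dominates
        m = resolve_anchor(cell_preset.bacterial, cell_preset.peptide)
        pop = Population(m, 1e8)
        n = consumption_per_cell(pop, m.c0, True, cell_preset.peptide)
        expected = 0.01 * 1.2e9 / 71.0 + 5e7
        assert n == pytest.approx(expected, rel=1e-9)
        assert n == pytest.approx(5.02e7, rel=1e-3)

    def test_no_peptide_no_consumption(self, cell_preset):
        pop = Population(cell_preset.bacterial, 1e8)
        assert consumption_per_cell(pop, 0.0, False, cell_preset.peptide) == 0.0

    def test_host_membrane_share_at_threshold(self, cell_preset):
        # P/L* x A_H/a_H with A_H = 200 um^2, a_H = 74 A^2: ~2.7e6 per cell
        m = resolve_anchor(cell_preset.host, cell_preset.peptide)
        n = consumption_per_cell(Population(m, 5e9), m.c0, False, cell_preset.peptide)
        assert n == pytest.approx(0.01 * 2.0e10 / 74.0, rel=1e-9)


class TestTotalFromFree:
    def test_identity_with_no_cells(self, peptide):
        assert total_from_free(3e-6, [], [], peptide) == 3e-6

    def test_strict_monotonicity_on_grid(self, cell_preset):
        b = Population(cell_preset.bacterial, 1e8)
        h = Population(cell_preset.host, 5e9)
        grid = np.linspace(0.0, 1e-3, 1000)
        totals = [
            total_from_free(c, [b, h], [True, True], cell_preset.peptide)
            for c in grid
        ]
        assert np.all(np.diff(totals) > 0)

    def test_bacteria_only_threshold_total(self, cell_preset):
        m = resolve_anchor(cell_preset.bacterial, cell_preset.peptide)
        pop = Population(m, 1e8)
        total = total_from_free(m.c0, [pop], [True], cell_preset.peptide)
        drain = counts_per_cell_to_molar(0.01 * 1.2e9 / 71.0 + 5e7, 1e8)
        assert total == pytest.approx(m.c0 + drain, rel=1e-12)
        assert drain == pytest.approx(8.33e-6, rel=2e-3)

    def test_mass_balance_closure(self, cell_preset):
        rng = np.random.default_rng(11)
        for _ in range(50):
            b = Population(cell_preset.bacterial, float(10 ** rng.uniform(3, 9)))
            h = Population(cell_preset.host, float(10 ** rng.uniform(3, 10)))
            c_free = float(10 ** rng.uniform(-8, -4))
            state = system_state(
                c_free, [b, h], [True, rng.random() < 0.5], cell_preset.peptide
            )
            assert abs(state.mass_balance_residual()) <= 1e-12 * state.c_total


class TestHomogeneous:
    def test_cell_preset_mic_tenfold_at_1e8(self, cell_preset):
        mic = mic_homogeneous(Population(cell_preset.bacterial, 1e8), cell_preset.peptide)
        assert mic == pytest.approx(9.33 * UM, rel=1e-3)

    def test_zero_density_returns_intercept(self, cell_preset):
        mic = mic_homogeneous(Population(cell_preset.bacterial, 0.0), cell_preset.peptide)
        assert mic == pytest.approx(1.0 * UM, rel=1e-12)
        mhc = mhc_homogeneous(Population(cell_preset.host, 0.0), cell_preset.peptide)
        assert mhc == pytest.approx(5.0 * UM, rel=1e-12)

    def test_zero_consumption_gives_flat_line(self, peptide):
        m = MembraneClass(
            label="bacterial",
            area_um2=12.0,
            lipid_area_A2=71.0,
            pl_star=1e-12,  # negligible membrane share, no trapping
            c0=1e-6,
            n_trapped=0.0,
        )
        for density in (0.0, 1e6, 1e10):
            assert mic_homogeneous(Population(m, density), peptide) == pytest.approx(
                1e-6, rel=1e-4
            )

    def test_cell_preset_mhc_at_whole_blood_density(self, cell_preset):
        mhc = mhc_homogeneous(Population(cell_preset.host, 5e9), cell_preset.peptide)
        assert mhc == pytest.approx(4.4e2 * UM, rel=0.02)

    def test_slope_proportional_to_area_without_trapping(self, peptide):
        def slope(area):
            m = MembraneClass(
                label="host", area_um2=area, lipid_area_A2=74.0, pl_star=0.01, c0=5e-6
            )
            lo = mhc_homogeneous(Population(m, 1e8), peptide)
            return mhc_homogeneous(Population(m, 2e8), peptide) - lo

        assert slope(400.0) == pytest.approx(2 * slope(200.0), rel=1e-9)


class TestCompetitive:
    def test_mic_low_host_density_matches_homogeneous(self, cell_preset):
        b = Population(cell_preset.bacterial, 1e8)
        h = Population(cell_preset.host, 1e3)
        res = find_mic_competitive(b, h, cell_preset.peptide)
        assert res.mic == pytest.approx(9.33 * UM, rel=1e-3)
        homog = mic_homogeneous(b, cell_preset.peptide)
        assert abs(res.mic - homog) < 1e-5 * homog

    def test_mic_host_binding_inflation(self, cell_preset_np1e7):
        p = cell_preset_np1e7
        res = find_mic_competitive(
            Population(p.bacterial, 1e4), Population(p.host, 5e9), p.peptide
        )
        # sub-threshold host coverage consumes ~4.7 uM on top of MIC0
        assert 5.0 * UM < res.mic < 10.0 * UM
        assert res.c_free_at_mic == pytest.approx(1e-6, rel=1e-12)

    def test_mhc_bacterial_trapping_inflation(self, cell_preset):
        res = find_mhc_competitive(
            Population(cell_preset.bacterial, 1e8),
            Population(cell_preset.host, 1e3),
            cell_preset.peptide,
        )
        assert res.mhc == pytest.approx(13.4 * UM, rel=3e-3)
        assert res.mhc / (5 * UM) == pytest.approx(2.7, rel=0.02)

    def test_mhc_dominated_by_host_when_bacteria_scarce(self, cell_preset):
        res = find_mhc_competitive(
            Population(cell_preset.bacterial, 5e4),
            Population(cell_preset.host, 5e9),
            cell_preset.peptide,
        )
        homog = mhc_homogeneous(Population(cell_preset.host, 5e9), cell_preset.peptide)
        assert abs(res.mhc - homog) / homog < 1e-3

    def test_zero_densities_reduce_to_intercepts(self, cell_preset):
        b = Population(cell_preset.bacterial, 0.0)
        h = Population(cell_preset.host, 0.0)
        comp = solve_competitive(b, h, cell_preset.peptide)
        noncomp = solve_noncompetitive(b, h, cell_preset.peptide)
        for res in (comp, noncomp):
            assert res.mic == pytest.approx(1.0 * UM, rel=1e-12)
            assert res.mhc == pytest.approx(5.0 * UM, rel=1e-12)
        assert comp.selectivity == pytest.approx(noncomp.selectivity, rel=1e-12)

    def test_consistency_with_homogeneous_at_zero_other_density(self, cell_preset):
        pep = cell_preset.peptide
        b = Population(cell_preset.bacterial, 1e8)
        h0 = Population(cell_preset.host, 0.0)
        assert find_mic_competitive(b, h0, pep).mic == pytest.approx(
            mic_homogeneous(b, pep), rel=1e-12
        )
        b0 = Population(cell_preset.bacterial, 0.0)
        h = Population(cell_preset.host, 5e9)
        assert find_mhc_competitive(b0, h, pep).mhc == pytest.approx(
            mhc_homogeneous(h, pep), rel=1e-12
        )

    def test_inverted_thresholds_raise(self, peptide):
        # host ruptures below the bacterial threshold: no selective window
        bacterial = MembraneClass(
            label="bacterial", area_um2=12.0, lipid_area_A2=71.0, pl_star=0.01, c0=5e-6
        )
        host = MembraneClass(
            label="host", area_um2=200.0, lipid_area_A2=74.0, pl_star=0.01, c0=1e-6
        )
        with pytest.raises(NoSelectiveWindowError) as err:
            find_mic_competitive(
                Population(bacterial, 1e6), Population(host, 1e6), peptide
            )
        assert err.value.c0_host == pytest.approx(1e-6)
        assert err.value.c0_bacterial == pytest.approx(5e-6)

    def test_monotone_in_densities_and_trapping(self):
        rng = np.random.default_rng(3)
        base = dict(c_b=1e6, c_h=1e8, n_trapped=1e7)
        for _ in range(20):
            scale = float(10 ** rng.uniform(0.1, 2))
            for knob in ("c_b", "c_h", "n_trapped"):
                lo_kw = dict(base)
                hi_kw = dict(base)
                hi_kw[knob] = base[knob] * scale
                results = []
                for kw in (lo_kw, hi_kw):
                    preset = melittin_cell(n_trapped=kw["n_trapped"])
                    b = Population(preset.bacterial, kw["c_b"])
                    h = Population(preset.host, kw["c_h"])
                    comp = solve_competitive(b, h, preset.peptide)
                    noncomp = solve_noncompetitive(b, h, preset.peptide)
                    results.append((comp, noncomp))
                (comp_lo, nc_lo), (comp_hi, nc_hi) = results
                assert comp_hi.mic >= comp_lo.mic
                assert comp_hi.mhc >= comp_lo.mhc
                assert nc_hi.mic >= nc_lo.mic
                assert nc_hi.mhc >= nc_lo.mhc

    @pytest.mark.parametrize("n_p, bound_frac", [(1e7, 0.1), (5e7, 0.05)])
    def test_bound_term_negligible_against_trapping_at_mhc(self, n_p, bound_frac):
        # above the MIC, membrane-bound peptides on bacteria are a small
        # correction to the trapped pool (the trapping-dominated regime):
        # at threshold coverage the membrane share is ~2% of N_p, and the
        # above-threshold coverage at the MHC stays a minor correction
        preset = melittin_cell(n_trapped=n_p)
        pep = preset.peptide
        b = resolve_anchor(preset.bacterial, pep)
        h = resolve_anchor(preset.host, pep)
        assert b.pl_star * b.lipids_per_cell / n_p < 0.02
        pl_b_at_mhc = coverage_from_free(h.c0, b, pep)
        assert pl_b_at_mhc * b.lipids_per_cell / n_p < bound_frac


def _threshold_by_total_bisection(populations, trapped_rule, target_index, peptide):
    """Independent oracle: bisection in total concentration.

    For each candidate C_p, invert the (strictly increasing) mass balance
    for the free concentration, then check whether the target population's
    coverage has reached its threshold; bracketed from [0, 2 c0] and grown
    geometrically.
    """

    target = populations[target_index].membrane

    drain_at_zero_free = total_from_free(0.0, populations, trapped_rule, peptide)

    def coverage_gap(c_total):
        # below the fixed trapped drain there is no free peptide at all
        if c_total <= drain_at_zero_free:
            return -target.pl_star
        c_free = brentq(
            lambda cf: total_from_free(cf, populations, trapped_rule, peptide)
            - c_total,
            0.0,
            c_total,
            xtol=1e-300,
            rtol=1e-14,
        )
        return coverage_from_free(c_free, target, peptide) - target.pl_star

    hi = 2.0 * target.c0
    while coverage_gap(hi) < 0:
        hi *= 2.0
    return brentq(coverage_gap, 0.0, hi, xtol=1e-300, rtol=1e-12)


class TestTotalBisectionOracle:
    def test_oracle_matches_continuation_solver(self, peptide):
        rng = np.random.default_rng(19)
        for _ in range(100):
            c0_b = float(10 ** rng.uniform(-7.0, -6.0))
            c0_h = c0_b * float(10 ** rng.uniform(0.2, 1.2))
            n_p = float(10 ** rng.uniform(5, 8))
            bact = resolve_anchor(
                MembraneClass(
                    label="bacterial",
                    area_um2=12.0,
                    lipid_area_A2=71.0,
                    pl_star=float(rng.uniform(0.005, 0.02)),
                    c0=c0_b,
                    n_trapped=n_p,
                ),
                peptide,
            )
            host = resolve_anchor(
                MembraneClass(
                    label="host",
                    area_um2=200.0,
                    lipid_area_A2=74.0,
                    pl_star=float(rng.uniform(0.005, 0.02)),
                    c0=c0_h,
                    n_trapped=n_p,
                ),
                peptide,
            )
            b = Population(bact, float(10 ** rng.uniform(4, 9)))
            h = Population(host, float(10 ** rng.uniform(4, 10)))
            mic = find_mic_competitive(b, h, peptide).mic
            mic_oracle = _threshold_by_total_bisection([b, h], [True, False], 0, peptide)
            assert mic_oracle == pytest.approx(mic, rel=1e-10)
            mhc = find_mhc_competitive(b, h, peptide).mhc
            mhc_oracle = _threshold_by_total_bisection([b, h], [True, True], 1, peptide)
            assert mhc_oracle == pytest.approx(mhc, rel=1e-10)


class TestHighHostApproximation:
    def test_mic_within_5pct_of_full_solver(self, cell_preset):
        b = Population(cell_preset.bacterial, 5e4)
        h = Population(cell_preset.host, 5e9)
        mic_approx, _ = mic_mhc_high_host_approx(b, h, cell_preset.peptide)
        full = find_mic_competitive(b, h, cell_preset.peptide).mic
        assert mic_approx == pytest.approx(full, rel=0.05)

    def test_mhc_within_1pct_of_host_only(self, cell_preset):
        h = Population(cell_preset.host, 5e9)
        for c_b in (1e3, 1e5):
            b = Population(cell_preset.bacterial, c_b)
            _, mhc_approx = mic_mhc_high_host_approx(b, h, cell_preset.peptide)
            assert mhc_approx == pytest.approx(
                mhc_homogeneous(h, cell_preset.peptide), rel=0.01
            )

    def test_zero_density_limits(self, cell_preset):
        b = Population(cell_preset.bacterial, 0.0)
        h = Population(cell_preset.host, 0.0)
        mic_approx, mhc_approx = mic_mhc_high_host_approx(b, h, cell_preset.peptide)
        assert mic_approx == pytest.approx(1e-6, rel=1e-12)
        assert mhc_approx == pytest.approx(5e-6, rel=1e-12)

    def test_ratio_agrees_with_full_solver(self, cell_preset):
        b = Population(cell_preset.bacterial, 5e4)
        h = Population(cell_preset.host, 5e9)
        ratio = selectivity_ratio_high_host(b, h, cell_preset.peptide)
        full = solve_competitive(b, h, cell_preset.peptide).selectivity
        assert ratio == pytest.approx(full, rel=0.10)

    def test_host_trapping_enhances_selectivity(self):
        # trapping in host cells raises the MHC but not the MIC
        ratios = []
        for n_p in (0.0, 5e7):
            preset = melittin_cell(n_trapped=n_p)
            b = Population(preset.bacterial, 5e4)
            h = Population(preset.host, 5e9)
            ratios.append(selectivity_ratio_high_host(b, h, preset.peptide))
        assert ratios[1] > ratios[0]

    def test_zero_host_density_ratio_is_intercept_ratio(self, cell_preset):
        b = Population(cell_preset.bacterial, 0.0)
        h = Population(cell_preset.host, 0.0)
        assert selectivity_ratio_high_host(b, h, cell_preset.peptide) == pytest.approx(
            5.0, rel=1e-12
        )
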