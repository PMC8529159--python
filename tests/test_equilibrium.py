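"""Equilibrium ternary-complex model: closed form vs brute-force oracle,
dose-response shape, Keff, the Michaelis-Menten approximation and the pSTAT
layer."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from ifnsig import defaults, equilibrium as eq
from ifnsig.params import (AffinitySet, PStatParams, ReceptorSurface,
                           affinities_from_solution)
from conftest import random_affinity, random_surface


class TestTernaryComplexes:
    def test_no_ligand_no_complex(self, ligands, surf2000):
        for aff in ligands:
            assert eq.ternary_complexes(aff, surf2000, 0.0) == 0.0

    def test_infinitely_strong_recruitment_pairs_all_subunits(self):
        """Balanced subunits + K4 -> 0 at the optimal dose: T -> RT/2."""
        surf = ReceptorSurface(1.0, 1.0)
        k4 = 1e-13 * surf.RT  # deviation from RT/2 scales like sqrt(K4/RT)
        aff = AffinitySet(K1=1e-6, K2=1e-8, K3=k4 * 1e-2, K4=k4)
        T = eq.ternary_complexes(aff, surf, math.sqrt(aff.K1 * aff.K2))
        assert T == pytest.approx(surf.RT / 2, rel=1e-6)

    def test_prozone_suppression_at_huge_dose(self, ligands, surf2000):
        for aff in ligands:
            T = eq.ternary_complexes(aff, surf2000, 1e6 * aff.K1)
            assert T < 1e-3 * surf2000.RT

    def test_matches_brute_force_oracle(self, rng):
        """Closed form vs independent two-conservation root-finder, 200 sets."""
        for _ in range(200):
            aff = random_affinity(rng)
            surf = random_surface(rng)
            I = 10 ** rng.uniform(-13, -6)
            closed = eq.ternary_complexes(aff, surf, I)
            brute = eq.ternary_complexes_numeric(aff, surf, I)
            assert closed == pytest.approx(brute, rel=1e-8, abs=1e-300)

    def test_bounded_by_limiting_subunit(self, rng):
        for _ in range(50):
            aff = random_affinity(rng)
            surf = random_surface(rng)
            I = 10 ** rng.uniform(-13, -5)
            T = eq.ternary_complexes(aff, surf, I)
            assert 0.0 <= T <= min(surf.R1, surf.R2) * (1 + 1e-12)

    def test_negative_dose_rejected(self, ligands, surf2000):
        with pytest.raises(ValueError):
            eq.ternary_complexes(ligands[0], surf2000, -1e-12)

    def test_one_subunit_absent_gives_zero(self, ligands):
        surf = ReceptorSurface(2.0, 0.0)
        assert eq.ternary_complexes(ligands[0], surf, 1e-9) == pytest.approx(0.0, abs=1e-12)

    def test_subunit_label_exchange_symmetry(self, rng):
        """T is invariant under swapping (K1,K4)<->(K2,K3) with delta -> -delta."""
        for _ in range(20):
            aff = random_affinity(rng)
            surf = random_surface(rng)
            swapped = AffinitySet(K1=aff.K2, K2=aff.K1, K3=aff.K4, K4=aff.K3)
            mirrored = ReceptorSurface(surf.R2, surf.R1)
            I = 10 ** rng.uniform(-12, -6)
            assert eq.ternary_complexes(aff, surf, I) == pytest.approx(
                eq.ternary_complexes(swapped, mirrored, I), rel=1e-12)


class TestPeak:
    def test_argmax_on_log_grid_is_geometric_mean_affinity(self, rng):
        for _ in range(10):
            aff = random_affinity(rng)
            surf = random_surface(rng)
            grid = np.geomspace(aff.K2 / 100, 100 * aff.K1, 400)
            T = eq.ternary_complexes(aff, surf, grid)
            im_expected = math.sqrt(aff.K1 * aff.K2)
            i = int(np.argmax(T))
            # within one grid step of sqrt(K1*K2)
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, grid.size - 1)]
            assert lo <= im_expected <= hi

    def test_strong_recruitment_limit_is_limiting_subunit(self):
        surf = ReceptorSurface(0.8, 2.0)
        k4 = 1e-9
        aff = AffinitySet(K1=1e-6, K2=1e-8, K3=k4 * 1e-2, K4=k4)
        tmax, _ = eq.tmax_imax(aff, surf)
        assert tmax == pytest.approx(min(surf.R1, surf.R2), rel=1e-6)

    def test_scale_invariance_in_rt_delta_k4(self, ligands):
        """Doubling R1, R2 and K4 (with K3, preserving balance) doubles Tmax."""
        aff = ligands[0]
        surf = ReceptorSurface(1.0, 2.5)
        tmax1, _ = eq.tmax_imax(aff, surf)
        aff2 = dataclasses.replace(aff, K3=2 * aff.K3, K4=2 * aff.K4)
        surf2 = ReceptorSurface(2.0, 5.0)
        tmax2, _ = eq.tmax_imax(aff2, surf2)
        assert tmax2 == pytest.approx(2 * tmax1, rel=1e-9)


class TestKeff:
    def test_definition_half_max_on_rising_branch(self, ligands, surf2000):
        for aff in ligands:
            tmax, im = eq.tmax_imax(aff, surf2000)
            ke = eq.keff(aff, surf2000, method="numeric")
            assert ke < im
            assert eq.ternary_complexes(aff, surf2000, ke) == pytest.approx(
                tmax / 2, rel=1e-6)

    def test_closed_form_matches_numeric(self, rng):
        for _ in range(50):
            aff = random_affinity(rng)
            surf = random_surface(rng)
            assert eq.keff(aff, surf, "closed_form") == pytest.approx(
                eq.keff(aff, surf, "numeric"), rel=1e-9)

    def test_monotone_nondecreasing_in_k2(self, surf2000):
        K1 = 1e-6
        vals = []
        for K2 in np.geomspace(1e-10, 1e-6, 10):
            vals.append(eq.keff(affinities_from_solution(K1, K2), surf2000))
        assert all(b >= a * (1 - 1e-12) for a, b in zip(vals, vals[1:]))

    def test_correlates_with_k1k2_product(self):
        """Over a 5x5 affinity grid, log Keff tracks log(K1*K2) (r > 0.9)."""
        surf = ReceptorSurface(1.0, 1.0)
        xs, ys = [], []
        for K1 in np.geomspace(1e-7, 1e-5, 5):
            for K2 in np.geomspace(1e-10, 1e-8, 5):
                aff = affinities_from_solution(K1, K2)
                xs.append(np.log10(K1 * K2))
                ys.append(np.log10(eq.keff(aff, surf)))
        assert np.corrcoef(xs, ys)[0, 1] > 0.9


class TestMMApproximation:
    def test_half_max_by_construction(self, ligands, surf2000):
        aff = ligands[0]
        tmax, _ = eq.tmax_imax(aff, surf2000)
        ke = eq.keff(aff, surf2000)
        assert eq.mm_approximation(aff, surf2000, ke).value == pytest.approx(
            tmax / 2, rel=1e-12)

    def test_zero_dose(self, ligands, surf2000):
        assert eq.mm_approximation(ligands[0], surf2000, 0.0).value == 0.0

    def test_low_dose_accuracy_over_regime_grid(self):
        """Below Im/10 the MM form tracks the exact curve to ~30% everywhere
        on the affinity grid and to ~13% for the default ligands (the MM form
        matches exactly at Keff and at saturation; its low-dose slope carries
        an intrinsic finite bias)."""
        worst = 0.0
        for K1 in np.geomspace(1e-7, 1e-5, 4):
            for X in np.geomspace(1e-4, 1e-1, 4):
                aff = affinities_from_solution(K1, K1 * X)
                surf = ReceptorSurface(1.0, 1.0)
                _, im = eq.tmax_imax(aff, surf)
                for f in (1e-3, 1e-2, 1e-1):
                    worst = max(worst,
                                eq.mm_approximation(aff, surf, f * im).rel_deviation)
        assert worst < 0.30

    def test_beyond_peak_is_flagged(self, ligands, surf2000):
        _, im = eq.tmax_imax(ligands[0], surf2000)
        assert eq.mm_approximation(ligands[0], surf2000, 2 * im).outside_validity


class TestPStatLayer:
    def test_saturation_and_zero(self, ligands, surf2000, geom450, pstat_params):
        aff = ligands[1]
        assert eq.pstat_equilibrium(aff, surf2000, geom450, pstat_params, 0.0) == 0.0
        # drive T*A to >= 100 Kp via a huge STAT reservoir check instead:
        tmax, im = eq.tmax_imax(aff, surf2000)
        pp = PStatParams(1000.0, tmax * geom450.area / 100.0)
        p = eq.pstat_equilibrium(aff, surf2000, geom450, pp, im)
        assert p >= 0.99 * pp.ST * (1 - 1e-12)

    def test_bounded_by_total_stat(self, rng, geom450, pstat_params):
        for _ in range(30):
            aff = random_affinity(rng)
            surf = random_surface(rng)
            I = 10 ** rng.uniform(-13, -5)
            p = eq.pstat_equilibrium(aff, surf, geom450, pstat_params, I)
            assert 0.0 <= p <= pstat_params.ST

    def test_ec50_formula_vs_numeric_in_mm_regime(self, geom450):
        """Weak recruitment + strong affinity asymmetry + large Kp: the
        closed-form EC50 matches the numeric half-max to 0.1%."""
        surf = ReceptorSurface.from_copies(1000, 1000, geom450.area)
        aff = affinities_from_solution(1e-6, 1e-10)
        aff = dataclasses.replace(aff, K4=3.0 * surf.RT, K3=3.0 * surf.RT * aff.X)
        pp = PStatParams(485.0, 5000.0)
        _, im = eq.tmax_imax(aff, surf)
        formula = eq.pstat_ec50(aff, surf, geom450, pp)
        pmax = eq.pstat_max(aff, surf, geom450, pp)
        numeric = brentq(
            lambda I: eq.pstat_equilibrium(aff, surf, geom450, pp, I) - pmax / 2,
            im * 1e-14, im, rtol=1e-13, xtol=im * 1e-20)
        assert formula == pytest.approx(numeric, rel=1e-3)

    def test_weaker_ifnar1_binder_has_lower_saturating_pstat(
            self, ligands, surf2000, geom450, pstat_params):
        """~15% lower pSTATmax for IFN-alpha2 than IFN-beta at RT = 2000
        copies on 450 um^2 with Kp = 900."""
        alpha, beta = ligands
        fc = eq.pstat_max_fold_change(alpha, beta, surf2000, geom450,
                                      pstat_params)
        assert 1 - fc == pytest.approx(0.15, abs=0.05)

    def test_fold_change_consistency_and_limits(self, ligands, surf2000, geom450):
        alpha, beta = ligands
        ta, _ = eq.tmax_imax(alpha, surf2000)
        tb, _ = eq.tmax_imax(beta, surf2000)
        pp = PStatParams(485.0, 900.0)
        fc = eq.pstat_max_fold_change(alpha, beta, surf2000, geom450, pp)
        direct = (eq.pstat_max(alpha, surf2000, geom450, pp)
                  / eq.pstat_max(beta, surf2000, geom450, pp))
        assert fc == pytest.approx(direct, rel=1e-12)
        # identical ligands -> ratio exactly 1
        assert eq.pstat_max_fold_change(alpha, alpha, surf2000, geom450,
                                        pp) == pytest.approx(1.0, rel=1e-12)
        # large Kp/A: ratio -> Tmax ratio; small Kp/A: ratio -> 1
        big = PStatParams(485.0, 1e6 * max(ta, tb) * geom450.area)
        small = PStatParams(485.0, 1e-6 * min(ta, tb) * geom450.area)
        assert eq.pstat_max_fold_change(alpha, beta, surf2000, geom450,
                                        big) == pytest.approx(ta / tb, rel=1e-4)
        assert eq.pstat_max_fold_change(alpha, beta, surf2000, geom450,
                                        small) == pytest.approx(1.0, rel=1e-4)


class TestPerturbations:
    def test_ifnar2_fold_moves_keff_not_tmax(self, surf2000):
        """In the K2 << K1 regime, a 50-fold IFNAR2 change shifts Keff > 2x
        while Tmax moves < 15% (M148A-style behaviour)."""
        aff = defaults.IFN_ALPHA2
        mut = aff.perturb(ifnar2_affinity_fold=50.0)
        tmax_wt, _ = eq.tmax_imax(aff, surf2000)
        tmax_mut, _ = eq.tmax_imax(mut, surf2000)
        assert abs(tmax_mut - tmax_wt) / tmax_wt < 0.15
        assert eq.keff(mut, surf2000) / eq.keff(aff, surf2000) > 2.0

    def test_usp18_priming_lowers_tmax_raises_keff(self, ligands, surf2000):
        for aff in ligands:
            primed = aff.perturb(usp18_fold=15.0)
            assert eq.tmax_imax(primed, surf2000)[0] < eq.tmax_imax(aff, surf2000)[0]
            assert eq.keff(primed, surf2000) > eq.keff(aff, surf2000)

    def test_tmax_less_sensitive_than_keff_to_k2(self, surf2000):
        """|d ln Tmax / d ln K2| < |d ln Keff / d ln K2| for K2/K1 <= 0.01."""
        K1 = 3e-6
        for K2 in np.geomspace(1e-10, K1 * 0.01, 5):
            lo = affinities_from_solution(K1, K2)
            hi = affinities_from_solution(K1, K2 * 1.1)
            dlnk2 = math.log(1.1)
            s_tmax = abs(math.log(eq.tmax_imax(hi, surf2000)[0]
                                  / eq.tmax_imax(lo, surf2000)[0])) / dlnk2
            s_keff = abs(math.log(eq.keff(hi, surf2000)
                                  / eq.keff(lo, surf2000))) / dlnk2
            assert s_tmax < s_keff
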