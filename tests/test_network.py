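"""Kinetic network: topology, conservation, and consistency with the
equilibrium model when feedbacks are off."""

import numpy as np
import pytest

from ifnsig import defaults, equilibrium as eq, network
from ifnsig.params import ReceptorSurface
from conftest import random_affinity


def feedback_free_kinetics(aff, **kw):
    zeros = dict(k_int_induced=0.0, k_socs=0.0, k_socs_on=0.0,
                 k_socs_off=0.0, k_socs_decay=0.0, k_int_basal=0.0,
                 k_rec1=0.0, k_rec2=0.0)
    zeros.update(kw)
    return network.KineticParameters.from_affinities(aff, **zeros)


@pytest.fixture(scope="module")
def base_system(geom450, surf2000, pstat_params):
    kin = network.KineticParameters.from_affinities(defaults.IFN_ALPHA2,
                                                    "IFNa2")
    return network.build_model(kin, surf2000, geom450, pstat_params)


class TestTopology:
    def test_feedback_free_system_reduces_to_core_reactions(
            self, geom450, surf2000, pstat_params):
        kin = feedback_free_kinetics(defaults.IFN_ALPHA2)
        system = network.build_model(kin, surf2000, geom450, pstat_params,
                                     ligand_conc=1e-9)
        names = {r.name for r in system.active_reactions()}
        assert names == {"bind_R1", "unbind_B1", "bind_R2", "unbind_B2",
                         "recruit_R2", "release_R2", "recruit_R1",
                         "release_R1", "phosphorylate", "dephosphorylate"}

    def test_conservation_vectors_span_left_null_space(self, base_system):
        laws = base_system.conservation_laws()
        assert laws.shape[0] == 3
        n = base_system.stoichiometry_matrix()
        expected = np.zeros((3, len(network.SPECIES)))
        groups = [["R1", "B1", "T", "R1s", "B1s", "Ts", "R1i"],
                  ["R2", "B2", "T", "Ts", "R2i"],
                  ["STAT", "PSTAT"]]
        for row, members in zip(expected, groups):
            for m in members:
                row[network.SPECIES.index(m)] = 1.0
        assert np.allclose(expected @ n, 0.0, atol=1e-12)

    def test_usp18_priming_changes_only_one_rate(self, base_system):
        primed = network.set_feedbacks(base_system, usp18_fold=15.0)
        diffs = [(a.name, a.rate_constant, b.rate_constant)
                 for a, b in zip(base_system.reactions, primed.reactions)
                 if a.rate_constant != b.rate_constant]
        assert len(diffs) == 1
        name, k_un, k_pr = diffs[0]
        assert name == "release_R1" and k_pr == pytest.approx(15.0 * k_un)

    def test_detailed_balance_violation_rejected(self):
        with pytest.raises(ValueError, match="detailed balance"):
            network.KineticParameters(
                ka1=1.0, kd1=1.0, ka2=1.0, kd2=1.0, ka3=1.0, kd3=1.0,
                ka4=1.0, kd4=2.0, kp_plus=1.0, kp_minus=1.0)

    def test_reaction_list_is_human_readable(self, base_system):
        text = base_system.describe()
        assert "phosphorylate: STAT -> PSTAT" in text


class TestSimulate:
    def test_no_ligand_no_response(self, base_system):
        traj = network.simulate(base_system, 0.0, np.array([5.0, 30.0, 60.0]))
        assert np.all(traj.pstat == 0.0)

    def test_stat_conservation_along_trajectory(self, base_system,
                                                pstat_params):
        traj = network.simulate(base_system, 1e-9, np.array(defaults.TIMES_MIN))
        total = traj.species("STAT") + traj.species("PSTAT")
        assert np.allclose(total, pstat_params.ST, rtol=1e-6)

    def test_receptor_conservation_along_trajectory(self, base_system):
        traj = network.simulate(base_system, 1e-9, np.array(defaults.TIMES_MIN))
        r1 = sum(traj.species(s) for s in
                 ["R1", "B1", "T", "R1s", "B1s", "Ts", "R1i"])
        r2 = sum(traj.species(s) for s in ["R2", "B2", "T", "Ts", "R2i"])
        assert np.allclose(r1, r1[0], rtol=1e-6)
        assert np.allclose(r2, r2[0], rtol=1e-6)

    def test_all_species_nonnegative(self, base_system):
        traj = network.simulate(base_system, 1e-8, np.array(defaults.TIMES_MIN))
        assert np.all(traj.y >= 0.0)

    def test_bad_time_grid_rejected(self, base_system):
        with pytest.raises(ValueError):
            network.simulate(base_system, 1e-9, np.array([10.0, 5.0]))

    def test_feedback_free_steady_state_matches_equilibrium(
            self, rng, geom450, pstat_params):
        """Cross-module oracle: ODE steady state vs the closed-form
        equilibrium, 12 random parameter sets, 0.5%."""
        for _ in range(12):
            aff = random_affinity(rng)
            n1, n2 = 10 ** rng.uniform(2.2, 3.3), 10 ** rng.uniform(2.2, 3.3)
            surf = ReceptorSurface.from_copies(n1, n2, geom450.area)
            kin = feedback_free_kinetics(aff)
            system = network.build_model(kin, surf, geom450, pstat_params)
            I = 10 ** rng.uniform(-11, -8)
            ss = network.steady_state(system, I)
            p_ode = ss[network.SPECIES.index("PSTAT")]
            t_ode = ss[network.SPECIES.index("T")] / geom450.area
            p_eq = eq.pstat_equilibrium(aff, surf, geom450, pstat_params, I)
            t_eq = eq.ternary_complexes(aff, surf, I)
            assert p_ode == pytest.approx(p_eq, rel=5e-3)
            assert t_ode == pytest.approx(t_eq, rel=5e-3)


class TestDoseResponse:
    def test_empty_dose_list(self, base_system):
        resp, summary = network.dose_response(base_system, [], 60.0)
        assert resp.size == 0 and summary is None

    def test_unsorted_doses_rejected(self, base_system):
        with pytest.raises(ValueError):
            network.dose_response(base_system, [1e-9, 1e-10], 60.0)

    def test_monotone_below_prozone(self, geom450, surf2000, pstat_params):
        kin = feedback_free_kinetics(defaults.IFN_BETA)
        system = network.build_model(kin, surf2000, geom450, pstat_params)
        _, im = eq.tmax_imax(defaults.IFN_BETA, surf2000)
        doses = np.geomspace(im / 1e4, im / 10, 5)
        resp, _ = network.dose_response(system, doses, 60.0,
                                        hill_summary=False)
        assert np.all(np.diff(resp) >= -1e-9)

    def test_high_affinity_ligand_wins_without_feedback(
            self, geom450, surf2000, pstat_params):
        """Saturating-dose pSTAT at 60 min, no feedback: IFN-beta (stronger
        IFNAR1 binder) above IFN-alpha2."""
        vals = {}
        for name, aff in defaults.DEFAULT_LIGANDS.items():
            kin = feedback_free_kinetics(aff)
            system = network.build_model(kin, surf2000, geom450, pstat_params)
            resp, _ = network.dose_response(system, [1e-8], 60.0,
                                            hill_summary=False)
            vals[name] = resp[0]
        assert vals["IFNb"] > vals["IFNa2"]

    def test_hill_summary_recovers_ec50_scale(self, geom450, surf2000,
                                              pstat_params):
        kin = feedback_free_kinetics(defaults.IFN_ALPHA2)
        system = network.build_model(kin, surf2000, geom450, pstat_params)
        ec50_eq = eq.pstat_ec50(defaults.IFN_ALPHA2, surf2000, geom450,
                                pstat_params)
        doses = np.geomspace(ec50_eq / 30, ec50_eq * 30, 7)
        _, summary = network.dose_response(system, doses, 600.0,
                                           t_grid=np.array([300.0, 600.0]))
        assert summary["ec50"] == pytest.approx(ec50_eq, rel=0.3)


class TestSetFeedbacks:
    def test_original_untouched(self, base_system):
        k_before = base_system.kin.k_socs
        network.set_feedbacks(base_system, socs=False, internalization=False)
        assert base_system.kin.k_socs == k_before

    def test_both_off_matches_no_feedback_equilibrium(
            self, geom450, surf2000, pstat_params):
        kin = network.KineticParameters.from_affinities(defaults.IFN_ALPHA2,
                                                        "IFNa2")
        system = network.build_model(kin, surf2000, geom450, pstat_params)
        bare = network.set_feedbacks(system, socs=False, internalization=False)
        # basal internalization is part of the internalization group
        assert bare.kin.k_int_basal == 0.0
        ss = network.steady_state(bare, 1e-9)
        p_eq = eq.pstat_equilibrium(defaults.IFN_ALPHA2, surf2000, geom450,
                                    pstat_params, 1e-9)
        assert ss[network.SPECIES.index("PSTAT")] == pytest.approx(p_eq,
                                                                  rel=5e-3)
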