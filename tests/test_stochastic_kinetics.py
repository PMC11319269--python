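"""Exact SSA / tau-leap engine: propensities, conservation, ODE limits."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from signalfate.errors import ExtinctSystemError, InvalidGeometryError
from signalfate.fate_switch import SwitchParams
from signalfate.signal_fields import RDParams, integrate_rd, SignalField
from signalfate.stochastic_kinetics import (
    LatticeState,
    Reaction,
    build_reaction_table,
    gillespie_step,
    reaction_kinds,
    simulate,
)

# a tamed channel for stochastic tests: same kinetics shape, gentler rates
SLOW = RDParams(gamma=50.0, Du=0.0, Dv=0.0, su_max=50.0)


def one_site_state(omega=100.0, su=1.0, sv=1.0):
    return LatticeState(
        {"su1": np.array([[round(su * omega)]]),
         "sv1": np.array([[round(sv * omega)]]),
         "su2": np.array([[0]]), "sv2": np.array([[0]])},
        omega=omega)


class TestReactionTable:
    def test_twenty_reaction_kinds(self, sw_default):
        rxs = build_reaction_table((RDParams(), RDParams()), sw_default, 3,
                                   lineages=np.array([[1, 1, 2]] * 3))
        kinds = reaction_kinds(rxs)
        assert len(kinds) == 20
        assert {row for row, _ in kinds} == set(range(1, 11))

    def test_row1_propensity(self):
        # gamma (A su + C) at su = 4, Omega = 1
        st = LatticeState({"su1": np.array([[4]]), "sv1": np.array([[0]])},
                          omega=1.0)
        rx = Reaction(1, 1, "production", "su1", (0, 0), rd=RDParams())
        assert rx.propensity(st) == pytest.approx(38_000.0)

    def test_su_diffusion_hop_rate(self):
        # Du/h^2 = 1e4 per molecule per neighbor direction at Du=1, h=0.01
        st = LatticeState({"su1": np.array([[3, 0]]), "sv1": np.zeros((1, 2))},
                          omega=1.0)
        rx = Reaction(3, 1, "diffusion", "su1", (0, 0), neighbor=(0, 1),
                      rd=RDParams())
        assert rx.propensity(st) == pytest.approx(3 * 1e4)

    def test_bad_geometry(self, sw_default):
        with pytest.raises(InvalidGeometryError):
            build_reaction_table(None, sw_default, (3, 2, 1))


class TestGillespieStep:
    def test_waiting_time_and_symmetric_selection(self, rng):
        # two symmetric degradation channels with equal propensity
        taus, picks = [], []
        for _ in range(4000):
            st = LatticeState({"su1": np.array([[50]]),
                               "su2": np.array([[50]])}, omega=1.0)
            rxs = [Reaction(2, 1, "degradation", "su1", (0, 0),
                            rd=RDParams(gamma=1.0)),
                   Reaction(2, 2, "degradation", "su2", (0, 0),
                            rd=RDParams(gamma=1.0))]
            st.counts["sv1"] = np.array([[50]])
            st.counts["sv2"] = np.array([[50]])
            ev = gillespie_step(st, rxs, rng)
            taus.append(ev.waiting_time)
            picks.append(ev.reaction.species)
        a_tot = 2 * 1.0 * 50.0  # two channels, gamma*sv*omega = 50 each
        assert np.mean(taus) == pytest.approx(1 / a_tot, rel=0.05)
        frac = picks.count("su1") / len(picks)
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_extinct_system(self, rng):
        st = LatticeState({"su1": np.array([[0]]), "sv1": np.array([[0]])},
                          omega=1.0)
        rxs = [Reaction(2, 1, "degradation", "su1", (0, 0), rd=RDParams())]
        with pytest.raises(ExtinctSystemError):
            gillespie_step(st, rxs, rng)


class TestSimulate:
    def test_diffusion_only_conserves_totals(self):
        p = RDParams(gamma=0.0, Du=1.0, Dv=20.0, su_max=1000.0)
        rng = np.random.default_rng(3)
        st = LatticeState(
            {"su1": rng.integers(0, 20, (3, 3)),
             "sv1": rng.integers(0, 20, (3, 3)),
             "su2": np.zeros((3, 3), dtype=int),
             "sv2": np.zeros((3, 3), dtype=int)},
            omega=1.0)
        tot_u, tot_v = st.counts["su1"].sum(), st.counts["sv1"].sum()
        rxs = build_reaction_table((p, p), None, 3)
        snaps = simulate(st, rxs, horizon=1e-5, method="ssa", seed=9,
                         max_events=3000)
        assert snaps[-1].counts["su1"].sum() == tot_u
        assert snaps[-1].counts["sv1"].sum() == tot_v

    def test_same_seed_identical_trajectories(self):
        def run():
            st = one_site_state(omega=50.0)
            rxs = build_reaction_table((SLOW, SLOW), None, 1)
            return simulate(st, rxs, horizon=0.05, method="ssa", seed=42)

        a, b = run(), run()
        assert a[-1].t == b[-1].t
        for k in a[-1].counts:
            assert np.array_equal(a[-1].counts[k], b[-1].counts[k])

    def test_ssa_ensemble_tracks_ode_root(self):
        """Single-site kinetics: the SSA ensemble mean follows the ODE."""
        horizon = 0.25

        def ode(_, z):
            su, sv = np.maximum(z, 0.0)
            return [SLOW.gamma * (SLOW.A * su - sv + SLOW.C),
                    SLOW.gamma * (SLOW.B * su - sv - 1.0)]

        ref = solve_ivp(ode, (0, horizon), [1.0, 1.0], rtol=1e-9).y[:, -1]
        finals = []
        for seed in range(30):
            st = one_site_state(omega=50.0)
            rxs = build_reaction_table((SLOW, SLOW), None, 1)
            rxs = [r for r in rxs if r.channel == 1]
            out = simulate(st, rxs, horizon=horizon, method="ssa", seed=seed)
            finals.append([out[-1].counts["su1"][0, 0] / 50.0,
                           out[-1].counts["sv1"][0, 0] / 50.0])
        finals = np.array(finals)
        mean = finals.mean(axis=0)
        sem = finals.std(axis=0, ddof=1) / np.sqrt(len(finals))
        assert abs(mean[0] - ref[0]) < 3 * sem[0] + 0.05
        assert abs(mean[1] - ref[1]) < 3 * sem[1] + 0.05

    def test_tau_leap_matches_ssa_mean(self):
        def mean_final(method, seeds):
            vals = []
            for seed in seeds:
                st = one_site_state(omega=60.0)
                rxs = [r for r in build_reaction_table((SLOW, SLOW), None, 1)
                       if r.channel == 1]
                out = simulate(st, rxs, horizon=0.25, method=method, seed=seed)
                vals.append(out[-1].counts["su1"][0, 0] / 60.0)
            return np.mean(vals), np.std(vals, ddof=1) / np.sqrt(len(vals))

        m_ssa, e_ssa = mean_final("ssa", range(25))
        m_tau, e_tau = mean_final("tau_leap", range(25, 50))
        assert abs(m_ssa - m_tau) < 3 * np.hypot(e_ssa, e_tau) + 0.1

    def test_confinement_cap_is_respected(self):
        p = RDParams(gamma=50.0, Du=0.0, Dv=0.0, su_max=2.0)
        cap = round(p.su_max * 40.0)
        st = LatticeState({"su1": np.array([[cap]]), "sv1": np.array([[10]])},
                          omega=40.0)
        rxs = [r for r in build_reaction_table((p, p), None, 1)
               if r.species in ("su1", "sv1")]
        snaps = simulate(st, rxs, horizon=0.3, method="ssa", seed=5,
                         snapshot_every=0.02)
        for s in snaps:
            assert s.counts["su1"][0, 0] <= cap

    def test_lattice_means_approach_pde_with_omega(self):
        """Mean absolute deviation from the deterministic field shrinks as
        the copy-number resolution Omega grows."""
        # diffusively stable channel (d = 1): realizations fluctuate about
        # the deterministic relaxation instead of amplifying Turing modes
        p = RDParams(gamma=20.0, Du=1.0, Dv=1.0, su_max=50.0, h=1.0)
        sz, horizon = 3, 0.3
        init_su = np.array([[1.0, 2.0, 1.0]] * 3)
        init_sv = np.ones((3, 3))
        det_su, _ = integrate_rd(
            p, init=(SignalField(init_su), SignalField(init_sv)),
            t_end=horizon)

        def mad(omega, seeds):
            devs = []
            for seed in seeds:
                st = LatticeState(
                    {"su1": np.round(init_su * omega).astype(int),
                     "sv1": np.round(init_sv * omega).astype(int),
                     "su2": np.zeros((sz, sz), dtype=int),
                     "sv2": np.zeros((sz, sz), dtype=int)},
                    omega=omega)
                rxs = [r for r in build_reaction_table((p, p), None, sz)
                       if r.channel == 1]
                out = simulate(st, rxs, horizon=horizon, method="tau_leap",
                               seed=seed)
                devs.append(np.abs(out[-1].counts["su1"] / omega
                                   - det_su.values).mean())
            return np.mean(devs)

        m10, m100 = mad(10.0, range(3)), mad(100.0, range(3, 6))
        assert m100 < m10

    def test_production_changes_totals_by_one(self, rng):
        st = one_site_state(omega=1.0, su=5, sv=5)
        rx = Reaction(1, 1, "production", "su1", (0, 0), rd=SLOW)
        before = st.counts["su1"].sum()
        rx.apply(st)
        assert st.counts["su1"].sum() == before + 1
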