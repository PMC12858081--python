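"""Hybrid cellular-automaton rules and the coupled simulation loop."""

import numpy as np
import pytest

from gliotan import CAConfig, CARules, CAState, DomainGrid, ModelParameters, ca_simulate
from gliotan.ca import (N1_TAN, N2_TAN, TROJAN, TUMOR_CORE, TUMOR_INV,
                        attempt_division, build_ca_state, choose_move,
                        contact_kill, ca_surgery, go_or_grow, phenotype_update)
from gliotan.geometry import build_tissue_map
from gliotan.scenarios import ResectionRegion


def make_state(nx=21, **rule_kw):
    grid = DomainGrid(nx, nx)
    tissue = build_tissue_map("uniform_white", grid)
    rng = np.random.default_rng(0)
    return CAState(tissue, ModelParameters(), CARules(**rule_kw), rng), rng


class TestGoOrGrow:
    def test_degenerate_probabilities(self):
        state, rng = make_state()
        idx = state.spawn(TUMOR_CORE, 10, 10)
        assert go_or_grow(state, idx, CARules(q=0.0), rng) == "grow"
        assert go_or_grow(state, idx, CARules(q=1.0), rng) == "migrate"

    def test_binomial_fraction(self):
        state, rng = make_state()
        idx = state.spawn(TUMOR_CORE, 10, 10)
        rules = CARules(q=0.5)
        n = 10_000
        mig = sum(go_or_grow(state, idx, rules, rng) == "migrate" for _ in range(n))
        assert abs(mig / n - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_rejects_non_tumor(self):
        state, rng = make_state()
        idx = state.spawn(N1_TAN, 5, 5)
        with pytest.raises(ValueError):
            go_or_grow(state, idx, CARules(), rng)


class TestChooseMove:
    def test_blocked_cell_stays(self):
        state, rng = make_state()
        idx = state.spawn(TUMOR_INV, 10, 10)
        for dj, di in ((a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)):
            state.spawn(TUMOR_CORE, 10 + dj, 10 + di)
        assert choose_move(state, idx, CARules(), rng) is None

    def test_tan_climbs_tgf_gradient(self):
        state, rng = make_state()
        X, _ = state.grid.meshgrid()
        state.G[:] = X  # increases strictly to the east
        idx = state.spawn(N1_TAN, 10, 10)
        tgt = choose_move(state, idx, CARules(), rng)
        assert tgt == (10, 11)

    def test_uniform_over_free_neighbors_without_gradient(self):
        """Zero gradient and p=1: the empirical move distribution is uniform
        over the free Moore neighbors (chi-square at 1e4 trials)."""
        state, rng = make_state()
        idx = state.spawn(N1_TAN, 10, 10)
        rules = CARules(p_move=1.0)
        counts = {}
        n = 10_000
        for _ in range(n):
            tgt = choose_move(state, idx, rules, rng)
            counts[tgt] = counts.get(tgt, 0) + 1
        assert len(counts) == 8
        exp = n / 8
        chi2 = sum((c - exp) ** 2 / exp for c in counts.values())
        assert chi2 < 24.3  # chi2_{0.999, df=7}

    def test_invasive_moves_radially_outward(self):
        state, rng = make_state()
        idx = state.spawn(TUMOR_INV, 10, 14)  # east of center
        state.R_c, state.R_I = 0.1, 0.3
        tgt = choose_move(state, idx, CARules(), rng)
        assert tgt == (10, 15)


class TestAttemptDivision:
    def test_cycle_gate(self):
        state, rng = make_state()
        idx = state.spawn(TUMOR_CORE, 10, 10, clock=3.0)
        assert attempt_division(state, idx, CARules(), rng) is None

    def test_enclosed_no_daughter(self):
        state, rng = make_state()
        idx = state.spawn(TUMOR_CORE, 10, 10, clock=8.0)
        for dj, di in ((a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)):
            state.spawn(TUMOR_CORE, 10 + dj, 10 + di)
        assert attempt_division(state, idx, CARules(), rng) is None
        assert state.clock[idx] == 8.0  # held, retried next step

    def test_forced_placement_resets_clocks(self):
        state, rng = make_state()
        idx = state.spawn(TUMOR_CORE, 0, 0, clock=8.0)
        state.spawn(TUMOR_CORE, 0, 1)
        state.spawn(TUMOR_CORE, 1, 0)
        daughter = attempt_division(state, idx, CARules(r_div=1.0), rng)
        assert daughter is not None
        assert (state.cj[daughter], state.ci[daughter]) == (1, 1)
        assert state.clock[idx] == 0.0 and state.clock[daughter] == 0.0


class TestPhenotypeUpdate:
    def test_neutral_environment_no_switch(self):
        state, _ = make_state()
        idx = state.spawn(N1_TAN, 5, 5)
        phenotype_update(state, idx, CARules())
        assert state.ctype[idx] == N1_TAN

    def test_tgf_drives_n1_to_n2(self):
        state, _ = make_state()
        idx = state.spawn(N1_TAN, 5, 5)
        state.G[5, 5] = 1e-8
        phenotype_update(state, idx, CARules())
        assert state.ctype[idx] == N2_TAN

    def test_ifn_drives_n2_to_n1(self):
        state, _ = make_state()
        idx = state.spawn(N2_TAN, 5, 5)
        state.S[5, 5] = 1e-7
        phenotype_update(state, idx, CARules())
        assert state.ctype[idx] == N1_TAN

    def test_trojan_rejected(self):
        state, _ = make_state()
        idx = state.spawn(TROJAN, 5, 5)
        with pytest.raises(ValueError):
            phenotype_update(state, idx, CARules())


class TestContactKill:
    def test_no_killers_noop(self):
        state, _ = make_state()
        state.spawn(TUMOR_CORE, 10, 10)
        state.spawn(N2_TAN, 10, 11)
        assert contact_kill(state) == 0
        assert state.counts()["tumor_core"] == 1

    def test_trojan_contact_kills(self):
        state, _ = make_state()
        t = state.spawn(TUMOR_CORE, 10, 10)
        state.spawn(TROJAN, 11, 11)
        assert contact_kill(state) == 1
        assert not state.alive[t]

    def test_n1_contact_kills_n2_does_not(self):
        state, _ = make_state()
        state.spawn(TUMOR_CORE, 3, 3)
        state.spawn(N1_TAN, 3, 4)
        state.spawn(TUMOR_CORE, 15, 15)
        state.spawn(N2_TAN, 15, 16)
        contact_kill(state)
        assert state.counts()["tumor_core"] == 1  # only the N2-flanked survives


class TestCASurgery:
    def test_whole_domain(self):
        state, _ = make_state()
        for i in range(5):
            state.spawn(TUMOR_CORE, 10, 3 + i)
        state.spawn(N1_TAN, 2, 2)
        ca_surgery(state, ResectionRegion(radius=2.0))
        assert state.counts()["tumor_total"] == 0
        assert state.counts()["n1_tan"] == 1  # TANs retained

    def test_core_disc_spares_outside_invasive(self):
        state, _ = make_state()
        inside = state.spawn(TUMOR_CORE, 10, 10)
        outside = state.spawn(TUMOR_INV, 2, 2)
        ca_surgery(state, ResectionRegion(center=(0.5, 0.5), radius=0.1))
        assert not state.alive[inside]
        assert state.alive[outside]


class TestCASimulate:
    def _config(self, **kw):
        base = dict(grid=DomainGrid(35, 35), tumor_radius=0.12, initial_n1=4,
                    n1_influx_per_h=0.5, t_end=24.0, seed=5)
        base.update(kw)
        return CAConfig(**base)

    def test_determinism(self):
        a = ca_simulate(self._config())
        b = ca_simulate(self._config())
        assert a.counts.equals(b.counts)

    def test_occupancy_and_bookkeeping(self):
        traj = ca_simulate(self._config())
        st = traj.state
        st.assert_occupancy()
        initial = traj.counts.iloc[0]["tumor_total"]
        final = traj.counts.iloc[-1]["tumor_total"]
        assert final == initial + st.births - st.contact_kills - st.resected

    def test_monotone_growth_without_predators(self):
        """q=0, no TANs, no surgery: the colony only grows (Eden-like)."""
        cfg = self._config(rules=CARules(q=0.0), initial_n1=0, n1_influx_per_h=0.0,
                           t_end=40.0)
        traj = ca_simulate(cfg)
        tumor = traj.counts["tumor_total"].to_numpy()
        assert np.all(np.diff(tumor) >= 0)
        assert tumor[-1] > tumor[0]

    def test_empty_tumor_limit(self):
        """No tumor cells: no TGF-beta is produced and TANs survive as
        wanderers."""
        cfg = self._config(tumor_radius=0.0, initial_n1=6, t_end=10.0,
                           rules=CARules(tan_death=False))
        traj = ca_simulate(cfg)
        assert traj.state.G.max() == 0.0
        assert traj.counts.iloc[-1]["tumor_total"] == 0
        assert traj.counts.iloc[-1]["n1_tan"] >= 6

    def test_trojan_influx_and_killing(self):
        cfg = self._config(trojan_influx_per_h=4.0, t_end=40.0)
        traj = ca_simulate(cfg)
        control = ca_simulate(self._config(t_end=40.0))
        assert traj.counts.iloc[-1]["trojan_n1"] > 0
        assert (traj.counts.iloc[-1]["tumor_total"]
                < control.counts.iloc[-1]["tumor_total"])

    def test_ca_surgery_event_removes_tumor(self):
        from gliotan.ca import CAEvent

        def cut(state):
            ca_surgery(state, ResectionRegion(radius=1.0))

        cfg = self._config(t_end=20.0, events=[CAEvent(10.0, cut, label="surgery")])
        traj = ca_simulate(cfg)
        i = int(np.argmin(np.abs(traj.times - 10.0)))
        assert traj.counts.iloc[i]["tumor_total"] == 0
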