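"""Initial layouts, surgical resection and the scenario registry."""

import numpy as np
import pytest

from gliotan import (DomainGrid, InitialLayoutSpec, ModelParameters,
                     ResectionRegion, SolverControls, apply_resection,
                     build_tissue_map, list_scenarios, run_scenario,
                     seed_initial_state, total_population)
from gliotan.pde import FIELD_NAMES

FAST = SolverControls(dt=0.2, keep_states=False)


class TestSeedInitialState:
    def test_empty_layout_is_zero(self, small_grid):
        spec = InitialLayoutSpec(n_aggregates=0, tumor_discs=())
        state, _ = seed_initial_state(spec, small_grid)
        for f in FIELD_NAMES:
            assert np.all(getattr(state, f) == 0.0)

    def test_deterministic_for_seed(self, small_grid):
        a, la = seed_initial_state(InitialLayoutSpec(seed=7), small_grid)
        b, lb = seed_initial_state(InitialLayoutSpec(seed=7), small_grid)
        assert la["aggregates"] == lb["aggregates"]
        for f in FIELD_NAMES:
            assert np.array_equal(getattr(a, f), getattr(b, f))

    def test_different_seeds_differ(self, small_grid):
        a, _ = seed_initial_state(InitialLayoutSpec(seed=1), small_grid)
        b, _ = seed_initial_state(InitialLayoutSpec(seed=2), small_grid)
        assert not np.array_equal(a.N1, b.N1)

    def test_coexistence_is_balanced(self, params):
        """Equal N1/N2 aggregate counts with equal peaks give matching
        initial integrals (within 1%; placement asymmetry only)."""
        g = DomainGrid(81, 81)
        state, layout = seed_initial_state(InitialLayoutSpec(seed=3), g, params)
        types = [t for t, _, _ in layout["aggregates"]]
        assert types.count("N1") == types.count("N2") == 4
        n1 = total_population(state.N1, g)
        n2 = total_population(state.N2, g)
        assert abs(n1 - n2) / n2 < 0.01

    def test_dominance_presets(self, small_grid):
        for preset, t_exp in (("n1_dominant", "N1"), ("n2_dominant", "N2")):
            _, layout = seed_initial_state(
                InitialLayoutSpec(preset=preset, seed=1), small_grid)
            assert all(t == t_exp for t, _, _ in layout["aggregates"])

    def test_cytokines_start_at_zero(self, small_grid):
        state, _ = seed_initial_state(InitialLayoutSpec(seed=0), small_grid)
        assert state.A.max() == state.S.max() == state.G.max() == 0.0

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            InitialLayoutSpec(tumor_discs=((1.5, 0.5, 0.05),))
        with pytest.raises(ValueError):
            InitialLayoutSpec(explicit_aggregates=(("N1", -0.1, 0.5),))

    def test_placement_respects_allowed_mask(self, params):
        g = DomainGrid(51, 51)
        tissue = build_tissue_map("wrinkle", g)
        spec = InitialLayoutSpec(seed=5, annulus=(0.08, 0.25))
        _, layout = seed_initial_state(spec, g, params,
                                       allowed=tissue.white | tissue.vessel)
        for _, cx, cy in layout["aggregates"]:
            j, i = round(cy * (g.ny - 1)), round(cx * (g.nx - 1))
            assert not tissue.gray[j, i]


class TestApplyResection:
    def _state(self, grid):
        state, _ = seed_initial_state(InitialLayoutSpec(seed=0), grid)
        return state

    def test_full_domain_resection(self, small_grid):
        state = self._state(small_grid)
        out = apply_resection(state, ResectionRegion(radius=2.0), small_grid)
        assert total_population(out.n, small_grid) == 0.0

    def test_disjoint_region_noop(self, small_grid):
        state = self._state(small_grid)
        out = apply_resection(state, ResectionRegion(center=(0.05, 0.05), radius=0.02),
                              small_grid)
        assert np.array_equal(out.n, state.n)

    def test_other_fields_untouched(self, small_grid):
        state = self._state(small_grid)
        out = apply_resection(state, ResectionRegion(radius=0.2), small_grid)
        assert np.array_equal(out.N1, state.N1)
        assert np.array_equal(out.N2, state.N2)

    def test_residual_mass_outside_disc(self, small_grid):
        state = self._state(small_grid)
        region = ResectionRegion(radius=0.15)
        mask = region.node_mask(small_grid)
        expected = total_population(np.where(mask, 0.0, state.n), small_grid)
        out = apply_resection(state, region, small_grid)
        assert total_population(out.n, small_grid) == pytest.approx(expected)


class TestScenarioRegistry:
    def test_unknown_scenario(self):
        with pytest.raises(KeyError, match="unknown scenario"):
            run_scenario("figure_everything")

    def test_registry_contents(self):
        names = list_scenarios()
        for expected in ("baseline", "dominance", "cytokine_shift",
                         "antibody_injection", "antibody_dose", "injection_site",
                         "wrinkle", "star", "vessel_horizontal_constant",
                         "vessel_vertical_periodic", "cc_surgery",
                         "trojan_therapy", "extended_surgery",
                         "butterfly_combination"):
            assert expected in names

    def test_zero_dose_equals_control(self):
        """A zero injection rate reproduces the no-antibody control exactly."""
        g = DomainGrid(26, 26)
        res = run_scenario("antibody_injection", seed=2, grid=g, controls=FAST,
                          t_end=20.0, rate=0.0)
        ft = res.summary["final_tumor"]
        assert ft["constant"] == pytest.approx(ft["control"], rel=1e-12)

    def test_equal_total_dose_by_construction(self):
        g = DomainGrid(41, 41)
        res = run_scenario("injection_site", seed=1, grid=g, controls=FAST, t_end=10.0)
        doses = list(res.summary["total_dose"].values())
        assert max(doses) == pytest.approx(min(doses), rel=1e-9)

    def test_manifest_reproducibility(self):
        g = DomainGrid(26, 26)
        a = run_scenario("baseline", seed=9, grid=g, controls=FAST, t_end=12.0)
        b = run_scenario("baseline", seed=9, grid=g, controls=FAST, t_end=12.0)
        assert a.summary == b.summary

    def test_surgery_removes_visible_core(self):
        g = DomainGrid(41, 41)
        res = run_scenario("cc_surgery", seed=3, grid=g,
                           controls=SolverControls(dt=0.2, keep_states=False,
                                                   sample_times=(0.0, 84.0, 90.0)),
                           t_end=90.0, arm="surgery")
        pops = {k: v.populations["n"] for k, v in res.arms.items()}
        t = res.arms["surgery"].times
        i84 = int(np.argmin(np.abs(t - 84.0)))
        # resection at 84 h removes most of the tumor relative to control
        assert pops["surgery"][i84] < 0.5 * pops["control"][i84]
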