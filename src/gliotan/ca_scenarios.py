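"""Hybrid-model experiments: Trojan-neutrophil therapy, surgical resection
variants in the two-hemisphere domain, and butterfly-glioma prevention."""

from __future__ import annotations

import numpy as np

from .ca import (CAConfig, CAEvent, CARules, TUMOR_CORE, TUMOR_TYPES,
                 ca_simulate, ca_surgery, _vessel_strip)
from .geometry import DomainGrid, build_tissue_map
from .metrics import relative_change
from .scenarios import ResectionRegion, ScenarioResult, register

TROJAN_INFLUX = 5.0    # Trojan N1 cells per hour from the vessel
N1_INFLUX = 1.0        # endogenous N1 TANs per hour from the vessel


def _ca_grid(grid):
    return grid if grid is not None else DomainGrid(101, 101)


@register("trojan_therapy")
def _scn_trojan(seed, grid, controls, params, t_end=180.0, rules=None,
                arms=("control", "trojan", "antibody", "combined")):
    """Central tumor with a left blood vessel sourcing TANs; treatment arms
    add Trojan N1 influx, vessel-borne antibody, or both (synergy test)."""
    del controls
    grid = _ca_grid(grid)
    rules = rules or CARules()
    results, traj_arms = {}, {}
    for arm in arms:
        cfg = CAConfig(
            grid=grid, rules=rules, params=params, seed=seed,
            tumor_center=(0.5, 0.5), tumor_radius=0.08,
            initial_n1=10, n1_influx_per_h=N1_INFLUX,
            trojan_influx_per_h=TROJAN_INFLUX if arm in ("trojan", "combined") else 0.0,
            antibody_rate=params.lambda_A if arm in ("antibody", "combined") else 0.0,
            t_end=t_end,
        )
        traj = ca_simulate(cfg)
        traj_arms[arm] = traj
        last = traj.counts.iloc[-1]
        results[arm] = {"invasive": int(last["tumor_invasive"]),
                        "total": int(last["tumor_total"])}
    summary = {"final": results}
    if "control" in results:
        inv0 = max(1, results["control"]["invasive"])
        tot0 = max(1, results["control"]["total"])
        for arm in arms:
            if arm == "control":
                continue
            summary[f"invasive_reduction_{arm}"] = relative_change(
                results[arm]["invasive"], inv0)
            summary[f"total_reduction_{arm}"] = relative_change(
                results[arm]["total"], tot0)
    return ScenarioResult("trojan_therapy", seed, traj_arms, summary)


# --- two-hemisphere surgery experiments ------------------------------------

TUMOR_CENTER_CC = (0.36, 0.5)


def _cc_setup(grid):
    tissue = build_tissue_map("cc_two_hemisphere", grid)
    vessel = _vessel_strip(grid, (0.06, 0.09)) & tissue.omega_minus
    return tissue, vessel


def _surgery_action(center, extra_masks=()):
    def action(state):
        region = ResectionRegion(center=center,
                                 radius=state.R_c + 2 * state.grid.hx)
        mask = region.node_mask(state.grid)
        for m in extra_masks:
            mask = mask | m
        ca_surgery(state, ResectionRegion(mask=mask))
    return action


def _extension_masks(grid, which):
    """Extended-surgery regions: tissue near the CC entrance and/or near the
    vessel."""
    X, Y = grid.meshgrid()
    masks = []
    if which in ("cc", "both"):
        masks.append((X >= 0.38) & (X <= 0.56) & (np.abs(Y - 0.5) <= 0.10))
    if which in ("bv", "both"):
        masks.append((X >= 0.05) & (X <= 0.20) & (np.abs(Y - 0.5) <= 0.18))
    return masks


@register("extended_surgery")
def _scn_extended_surgery(seed, grid, controls, params, t_end=360.0,
                          t_surgery=120.0, rules=None,
                          arms=("core", "es_cc", "es_bv", "es_both")):
    """Resection variants in the two-hemisphere domain: core-only surgery
    versus extended resections near the CC entrance, near the vessel, or
    both; tracks escape into the contralateral hemisphere."""
    del controls
    grid = _ca_grid(grid)
    rules = rules or CARules()
    tissue, vessel = _cc_setup(grid)
    ext = {"core": (), "es_cc": _extension_masks(grid, "cc"),
           "es_bv": _extension_masks(grid, "bv"),
           "es_both": _extension_masks(grid, "both")}
    traj_arms, summary_arms = {}, {}
    for arm in arms:
        cfg = CAConfig(
            grid=grid, tissue=tissue, vessel=vessel, rules=rules, params=params,
            seed=seed, tumor_center=TUMOR_CENTER_CC, tumor_radius=0.07,
            initial_n1=10, n1_influx_per_h=N1_INFLUX, t_end=t_end,
            events=[CAEvent(t_surgery,
                            _surgery_action(TUMOR_CENTER_CC, ext[arm]),
                            label=arm)],
        )
        traj = ca_simulate(cfg)
        traj_arms[arm] = traj
        last = traj.counts.iloc[-1]
        st = traj.state
        idxs = st.live_indices(*TUMOR_TYPES)
        contra = st.tissue.omega_plus[st.cj[idxs], st.ci[idxs]]
        recurrent = int(np.count_nonzero(
            contra & (st.ctype[idxs] == TUMOR_CORE)))
        summary_arms[arm] = {
            "total": int(last["tumor_total"]),
            "contralateral": int(last["tumor_in_contralateral"]),
            "along_bv": int(last["tumor_along_bv"]),
            "recurrent_contralateral": recurrent,
            "resected": st.resected,
        }
    return ScenarioResult("extended_surgery", seed, traj_arms, {"arms": summary_arms})


@register("butterfly_combination")
def _scn_butterfly(seed, grid, controls, params, t_end=360.0, t_surgery=120.0,
                   rules=None, arms=("no_surgery", "surgery", "surgery_trojan")):
    """Butterfly-glioma formation across the CC and its prevention by
    surgery plus Trojan-neutrophil injection from the vessel."""
    del controls
    grid = _ca_grid(grid)
    rules = rules or CARules()
    tissue, vessel = _cc_setup(grid)
    traj_arms, summary_arms = {}, {}
    for arm in arms:
        events = []
        if arm != "no_surgery":
            events.append(CAEvent(t_surgery,
                                  _surgery_action(TUMOR_CENTER_CC,
                                                  _extension_masks(grid, "both")),
                                  label="surgery"))
        cfg = CAConfig(
            grid=grid, tissue=tissue, vessel=vessel, rules=rules, params=params,
            seed=seed, tumor_center=TUMOR_CENTER_CC, tumor_radius=0.07,
            initial_n1=10, n1_influx_per_h=N1_INFLUX,
            trojan_influx_per_h=TROJAN_INFLUX if arm == "surgery_trojan" else 0.0,
            trojan_start=t_surgery if arm == "surgery_trojan" else 0.0,
            t_end=t_end, events=events,
        )
        traj = ca_simulate(cfg)
        traj_arms[arm] = traj
        last = traj.counts.iloc[-1]
        summary_arms[arm] = {
            "total": int(last["tumor_total"]),
            "contralateral": int(last["tumor_in_contralateral"]),
            "along_bv": int(last["tumor_along_bv"]),
        }
    return ScenarioResult("butterfly_combination", seed, traj_arms,
                          {"arms": summary_arms})
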