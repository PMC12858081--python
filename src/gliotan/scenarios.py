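"""Reproducible builders for the in-silico experiments.

Each registered scenario assembles a geometry, a seeded initial layout
(central tumor disc surrounded by random N1/N2 TAN aggregates), a therapy
schedule and any timed interventions (surgical resection, post-surgery
cytokine or antibody dosing), runs the continuum model and reports the
summary metrics used throughout the study: final populations, treatment
reductions, TAN compositions, and region-resolved tumor burdens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import metrics
from .geometry import DomainGrid, build_tissue_map
from .params import ModelParameters
from .pde import (Event, InjectionSchedule, SolverControls, StateFields,
                  Trajectory, simulate, total_injected_dose)

PRESETS = ("n2_dominant", "n1_dominant", "coexistence")

#: default peak density of a TAN aggregate (cells/cm^3); equal for both
#: phenotypes so that dominance arms start from the same total TAN mass
AGGREGATE_PEAK = 2.0e6
TUMOR_FRACTION = 0.1      # initial tumor disc amplitude as fraction of n0


@dataclass
class InitialLayoutSpec:
    """Seeded initial layout: tumor disc(s) plus TAN aggregates.

    Aggregates are isotropic Gaussian bumps (peak ``aggregate_peak``,
    std ``aggregate_radius``) at random centers in an annulus around the
    tumor; ``preset`` fixes the phenotype assignment.  ``explicit_aggregates``
    overrides random placement with (type, cx, cy) triples.
    """

    preset: str = "coexistence"
    n_aggregates: int = 8
    aggregate_radius: float = 0.03
    aggregate_peak: float = AGGREGATE_PEAK
    tumor_discs: tuple = ((0.5, 0.5, 0.05),)
    tumor_amplitude: float | None = None   # None -> TUMOR_FRACTION * n0
    annulus: tuple[float, float] = (0.12, 0.30)
    center: tuple[float, float] = (0.5, 0.5)
    explicit_aggregates: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        for cx, cy, rad in self.tumor_discs:
            if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0) or rad < 0:
                raise ValueError("tumor disc outside the unit square")
        for _, cx, cy in self.explicit_aggregates:
            if not (0.0 <= cx <= 1.0 and 0.0 <= cy <= 1.0):
                raise ValueError("aggregate center outside the unit square")


def _assign_types(preset: str, count: int) -> list[str]:
    if preset == "n1_dominant":
        return ["N1"] * count
    if preset == "n2_dominant":
        return ["N2"] * count
    return ["N1" if i % 2 == 0 else "N2" for i in range(count)]


def draw_aggregate_centers(spec: InitialLayoutSpec, rng: np.random.Generator,
                           allowed: np.ndarray | None = None,
                           grid: DomainGrid | None = None) -> list[tuple[float, float]]:
    """Sample aggregate centers in the annulus (rejection against a node mask)."""
    lo, hi = spec.annulus
    cx0, cy0 = spec.center
    centers = []
    for _ in range(spec.n_aggregates):
        for _try in range(500):
            rad = rng.uniform(lo, hi)
            th = rng.uniform(0.0, 2.0 * math.pi)
            cx, cy = cx0 + rad * math.cos(th), cy0 + rad * math.sin(th)
            if not (0.02 <= cx <= 0.98 and 0.02 <= cy <= 0.98):
                continue
            if allowed is not None:
                j = int(round(cy * (grid.ny - 1)))
                i = int(round(cx * (grid.nx - 1)))
                if not allowed[j, i]:
                    continue
            centers.append((cx, cy))
            break
        else:
            raise RuntimeError("could not place aggregate inside the allowed region")
    return centers


def seed_initial_state(spec: InitialLayoutSpec, grid: DomainGrid,
                       params: ModelParameters | None = None,
                       allowed: np.ndarray | None = None):
    """Build the initial continuum state from a layout spec.

    Returns ``(state, layout)`` where ``layout`` records the realized
    aggregate centers/types (for support masks and manifests).  A, S and G
    start at zero.  Deterministic for a fixed seed.
    """
    params = params or ModelParameters()
    rng = np.random.default_rng(spec.seed)
    state = StateFields.zeros(grid)
    X, Y = grid.meshgrid()

    amp_n = spec.tumor_amplitude if spec.tumor_amplitude is not None else TUMOR_FRACTION * params.n0
    for cx, cy, rad in spec.tumor_discs:
        state.n += np.where(np.hypot(X - cx, Y - cy) <= rad, amp_n, 0.0)

    if spec.explicit_aggregates:
        placed = [(t, cx, cy) for t, cx, cy in spec.explicit_aggregates]
    else:
        centers = draw_aggregate_centers(spec, rng, allowed=allowed, grid=grid)
        types = _assign_types(spec.preset, len(centers))
        placed = [(t, cx, cy) for t, (cx, cy) in zip(types, centers)]

    sig2 = 2.0 * spec.aggregate_radius ** 2
    for typ, cx, cy in placed:
        bump = spec.aggregate_peak * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / sig2)
        if typ == "N1":
            state.N1 += bump
        else:
            state.N2 += bump

    layout = {"aggregates": placed, "seed": spec.seed, "preset": spec.preset,
              "tumor_discs": spec.tumor_discs}
    return state, layout


# ---------------------------------------------------------------------------
# surgery

@dataclass
class ResectionRegion:
    """Disc (or explicit mask) removed by surgery; extension flags mark the
    extended-surgery variants that also clear tissue near the CC or vessel."""

    center: tuple[float, float] = (0.5, 0.5)
    radius: float = 0.1
    mask: np.ndarray | None = None
    near_cc: bool = False
    near_bv: bool = False

    def node_mask(self, grid: DomainGrid) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != grid.shape:
                raise ValueError("resection mask shape does not match grid")
            return self.mask
        X, Y = grid.meshgrid()
        return np.hypot(X - self.center[0], Y - self.center[1]) <= self.radius


def apply_resection(state: StateFields, region: ResectionRegion,
                    grid: DomainGrid) -> StateFields:
    """Surgical removal of tumor only: n is zeroed on the region, all other
    fields untouched."""
    out = state.copy()
    out.n[region.node_mask(grid)] = 0.0
    return out


def visible_core_region(state: StateFields, grid: DomainGrid,
                        center: tuple[float, float], params: ModelParameters,
                        fraction: float = 0.05) -> ResectionRegion:
    """Disc covering the 'visible' tumor core: smallest disc centered at the
    primary site containing every node with n > fraction * n0."""
    above = state.n > fraction * params.n0
    if not np.any(above):
        return ResectionRegion(center=center, radius=0.0)
    X, Y = grid.meshgrid()
    rad = float(np.hypot(X[above] - center[0], Y[above] - center[1]).max())
    return ResectionRegion(center=center, radius=rad + max(grid.hx, grid.hy))


def _disc_mask(grid: DomainGrid, center, radius) -> np.ndarray:
    X, Y = grid.meshgrid()
    return np.hypot(X - center[0], Y - center[1]) <= radius


def _annulus_mask(grid: DomainGrid, center, r_in, r_out) -> np.ndarray:
    X, Y = grid.meshgrid()
    R = np.hypot(X - center[0], Y - center[1])
    return (R > r_in) & (R <= r_out)


# ---------------------------------------------------------------------------
# scenario registry

@dataclass
class ScenarioResult:
    name: str
    seed: int
    arms: dict
    summary: dict
    manifest: dict = dc_field(default_factory=dict)


SCENARIOS: dict[str, object] = {}


def register(name):
    def deco(fn):
        SCENARIOS[name] = fn
        return fn
    return deco


def list_scenarios() -> list[str]:
    return sorted(SCENARIOS)


def run_scenario(name: str, seed: int = 0, grid: DomainGrid | None = None,
                 controls: SolverControls | None = None,
                 params: ModelParameters | None = None,
                 **options) -> ScenarioResult:
    """Run a registered scenario and return trajectories plus summary metrics."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {list_scenarios()}")
    grid = grid or DomainGrid()
    controls = controls or SolverControls()
    params = params or ModelParameters()
    result = SCENARIOS[name](seed=seed, grid=grid, controls=controls,
                             params=params, **options)
    result.manifest.setdefault("scenario", name)
    result.manifest.setdefault("seed", seed)
    result.manifest.setdefault("grid", (grid.nx, grid.ny))
    result.manifest.setdefault("dt", controls.dt)
    return result


def _final_pops(traj: Trajectory) -> dict[str, float]:
    return {f: float(traj.populations[f][-1]) for f in traj.populations}


def _run(initial, tissue, params, schedule, t_end, controls, events=None):
    return simulate(initial, tissue, params, schedule, t_end,
                    controls=controls, events=events)


@register("baseline")
def _scn_baseline(seed, grid, controls, params, t_end=240.0, preset="coexistence"):
    """Central tumor interacting with randomly placed N1/N2 TAN aggregates."""
    tissue = build_tissue_map("uniform_white", grid)
    state, layout = seed_initial_state(
        InitialLayoutSpec(preset=preset, seed=seed), grid, params)
    traj = _run(state, tissue, params, InjectionSchedule(), t_end, controls)
    return ScenarioResult("baseline", seed, {"control": traj},
                          {"final": _final_pops(traj)}, {"layout": layout})


@register("dominance")
def _scn_dominance(seed, grid, controls, params, t_end=240.0):
    """Three arms sharing aggregate positions: all-N1, all-N2, and mixed
    phenotype assignment.  Summarizes final tumor burden relative to the
    coexistence arm."""
    tissue = build_tissue_map("uniform_white", grid)
    arms, layouts = {}, {}
    for preset in ("n1_dominant", "coexistence", "n2_dominant"):
        state, layout = seed_initial_state(
            InitialLayoutSpec(preset=preset, seed=seed), grid, params)
        arms[preset] = _run(state, tissue, params, InjectionSchedule(), t_end, controls)
        layouts[preset] = layout
    final = {k: _final_pops(v)["n"] for k, v in arms.items()}
    coex = final["coexistence"]
    summary = {
        "final_tumor": final,
        "n1_dominant_pct_of_coexistence": 100.0 * final["n1_dominant"] / coex,
        "n2_dominant_pct_increase": 100.0 * (final["n2_dominant"] - coex) / coex,
    }
    return ScenarioResult("dominance", seed, arms, summary, {"layouts": layouts})


@register("cytokine_shift")
def _scn_cytokine(seed, grid, controls, params, t_end=240.0, factor=100.0,
                  arms_selected=("control", "ifn_rich", "tgf_rich")):
    """Cytokine-rich environments: IFN-beta-rich (lambda_S x factor) and
    TGF-beta-prevalent (lambda_G x factor) versus the control rates."""
    tissue = build_tissue_map("uniform_white", grid)
    spec = InitialLayoutSpec(preset="coexistence", seed=seed)
    arms = {}
    for arm, p, sched in (
        ("control", params, InjectionSchedule()),
        # IFN-beta-rich: whole-domain source switched on at factor x base rate
        ("ifn_rich", params,
         InjectionSchedule(ifnb_active=True, ifnb_rate=factor * params.lambda_S)),
        ("tgf_rich", params.with_overrides(lambda_G=factor * params.lambda_G),
         InjectionSchedule()),
    ):
        if arm not in arms_selected:
            continue
        state, layout = seed_initial_state(spec, grid, p)
        arms[arm] = _run(state, tissue, p, sched, t_end, controls)
    comp = {}
    for arm, traj in arms.items():
        pops = _final_pops(traj)
        n1c, n2c = metrics.composition(pops["N1"], pops["N2"])
        comp[arm] = {"pct_N1": n1c, "pct_N2": n2c, "final_tumor": pops["n"]}
    summary = {
        "composition": comp,
        "final_tumor": {k: comp[k]["final_tumor"] for k in comp},
    }
    if "tgf_rich" in comp:
        summary["n2_share_tgf_rich"] = comp["tgf_rich"]["pct_N2"]
    return ScenarioResult("cytokine_shift", seed, arms, summary, {"layout": layout})


@register("sensitivity_baseline")
def _scn_sensitivity_baseline(seed, grid, controls, params, t_end=100.0):
    """Scenario used for the global sensitivity analysis: the mixed-layout
    tumor/TAN system with every source pathway active (constant antibody at
    the N2 sites and a whole-domain IFN-beta source), so that all sampled
    parameters influence the outputs."""
    tissue = build_tissue_map("uniform_white", grid)
    state, layout = seed_initial_state(
        InitialLayoutSpec(preset="coexistence", seed=seed), grid, params)
    sched = InjectionSchedule(mode="constant", rate=params.lambda_A,
                              omega_A=_n2_site_mask(grid, layout),
                              ifnb_active=True, ifnb_rate=params.lambda_S)
    traj = _run(state, tissue, params, sched, t_end, controls)
    return ScenarioResult("sensitivity_baseline", seed, {"run": traj},
                          {"final": _final_pops(traj)}, {"layout": layout})


def _n2_site_mask(grid, layout, radius=0.03):
    mask = np.zeros(grid.shape, dtype=bool)
    for typ, cx, cy in layout["aggregates"]:
        if typ == "N2":
            mask |= _disc_mask(grid, (cx, cy), radius)
    if not mask.any():   # no N2 aggregates: fall back to tumor neighborhood
        mask = _disc_mask(grid, (0.5, 0.5), radius)
    return mask


DEFAULT_PULSES = (30.0, 90.0, 150.0, 210.0)


@register("antibody_injection")
def _scn_antibody(seed, grid, controls, params, t_end=240.0, rate=None,
                  pulses=DEFAULT_PULSES, tau=1.0,
                  arms_selected=("control", "constant", "periodic")):
    """Anti-N2 antibody dosed on discs at the N2 aggregate sites: control,
    constant and periodic (pulsed, 100x amplified) schedules."""
    tissue = build_tissue_map("uniform_white", grid)
    spec = InitialLayoutSpec(preset="coexistence", seed=seed)
    state, layout = seed_initial_state(spec, grid, params)
    omega_A = _n2_site_mask(grid, layout)
    rate = params.lambda_A if rate is None else rate
    scheds = {
        "control": InjectionSchedule(),
        "constant": InjectionSchedule(mode="constant", rate=rate, omega_A=omega_A)
        if rate > 0 else InjectionSchedule(),
        "periodic": InjectionSchedule(mode="periodic", rate=rate, omega_A=omega_A,
                                      pulse_starts=pulses, tau=tau)
        if rate > 0 else InjectionSchedule(),
    }
    arms = {a: _run(state.copy(), tissue, params, scheds[a], t_end, controls)
            for a in arms_selected}
    summary = {"final_tumor": {k: _final_pops(v)["n"] for k, v in arms.items()}}
    if "control" in arms:
        ctrl = summary["final_tumor"]["control"]
        for a in arms:
            if a != "control":
                summary[f"reduction_{a}"] = metrics.relative_change(
                    summary["final_tumor"][a], ctrl)
    return ScenarioResult("antibody_injection", seed, arms, summary, {"layout": layout})


@register("antibody_dose")
def _scn_antibody_dose(seed, grid, controls, params, t_end=240.0,
                       doses=(0.0, 0.0289, 2.89, 289.0), mode="constant",
                       pulses=DEFAULT_PULSES, tau=1.0):
    """Dose-response sweep of the antibody injection rate lambda_A*."""
    tissue = build_tissue_map("uniform_white", grid)
    spec = InitialLayoutSpec(preset="coexistence", seed=seed)
    state, layout = seed_initial_state(spec, grid, params)
    omega_A = _n2_site_mask(grid, layout)
    arms = {}
    for dose in doses:
        if dose == 0.0:
            sched = InjectionSchedule()
        elif mode == "constant":
            sched = InjectionSchedule(mode="constant", rate=dose, omega_A=omega_A)
        else:
            sched = InjectionSchedule(mode="periodic", rate=dose, omega_A=omega_A,
                                      pulse_starts=pulses, tau=tau)
        arms[f"dose_{dose:g}"] = _run(state.copy(), tissue, params, sched, t_end, controls)
    finals = {k: _final_pops(v)["n"] for k, v in arms.items()}
    summary = {"final_tumor": finals, "doses": list(doses), "mode": mode,
               "final_tumor_by_dose": [finals[f"dose_{d:g}"] for d in doses]}
    return ScenarioResult("antibody_dose", seed, arms, summary, {"layout": layout})


@register("injection_site")
def _scn_injection_site(seed, grid, controls, params, t_end=240.0,
                        site_radius=0.03, da_factor=0.01):
    """Effect of the injection site with slowed antibody diffusion
    (DA scaled by ``da_factor``): targeted N2-site discs, a single central
    disc, and four far-corner discs, all with the same total dose
    (equal support area x rate x duration by construction)."""
    p = params.with_overrides(DA=params.DA * da_factor)
    tissue = build_tissue_map("uniform_white", grid)
    spec = InitialLayoutSpec(preset="coexistence", seed=seed)
    state, layout = seed_initial_state(spec, grid, p)
    n2_sites = [(cx, cy) for t, cx, cy in layout["aggregates"] if t == "N2"]
    m = max(1, len(n2_sites))
    masks = {
        "targeted": _n2_site_mask(grid, layout, site_radius),
        # one central disc with the same total area as m site discs
        "central": _disc_mask(grid, (0.5, 0.5), site_radius * math.sqrt(m)),
        "corner": np.zeros(grid.shape, dtype=bool),
    }
    corner_r = site_radius * math.sqrt(m) / 2.0
    for cx, cy in ((0.08, 0.08), (0.92, 0.08), (0.08, 0.92), (0.92, 0.92)):
        masks["corner"] |= _disc_mask(grid, (cx, cy), corner_r)
    arms, doses = {}, {}
    vol = grid.node_volumes()
    for arm, mask in masks.items():
        # rate scaled so the total injected mass matches the targeted arm
        area = float(vol[mask].sum())
        base_area = float(vol[masks["targeted"]].sum())
        sched = InjectionSchedule(mode="constant", rate=p.lambda_A * base_area / area,
                                 omega_A=mask)
        arms[arm] = _run(state.copy(), tissue, p, sched, t_end, controls)
        doses[arm] = total_injected_dose(sched, t_end, grid)
    summary = {"final_tumor": {k: _final_pops(v)["n"] for k, v in arms.items()},
               "total_dose": doses}
    return ScenarioResult("injection_site", seed, arms, summary, {"layout": layout})


def _white_layout(grid, tissue, seed, params, center=(0.5, 0.5), annulus=(0.10, 0.25)):
    spec = InitialLayoutSpec(preset="coexistence", seed=seed, center=center,
                             annulus=annulus, tumor_discs=((center[0], center[1], 0.05),))
    allowed = tissue.white | tissue.omega_cc | tissue.vessel
    return seed_initial_state(spec, grid, params, allowed=allowed), spec


@register("wrinkle")
def _scn_wrinkle(seed, grid, controls, params, t_end=240.0):
    """Growth inside a single white-matter fold surrounded by gray matter."""
    tissue = build_tissue_map("wrinkle", grid)
    (state, layout), _ = _white_layout(grid, tissue, seed, params)
    traj = _run(state, tissue, params, InjectionSchedule(), t_end, controls)
    final = traj.final()
    summary = {"final": _final_pops(traj),
               "sn21r_max": float(metrics.sn21r(final.N1, final.N2).max())}
    return ScenarioResult("wrinkle", seed, {"control": traj}, summary, {"layout": layout})


@register("star")
def _scn_star(seed, grid, controls, params, t_end=240.0, valleys=3):
    """Growth of tumor foci seeded in the valleys of a star-shaped
    white-matter region."""
    tissue = build_tissue_map("star", grid, valleys=valleys)
    r_mid = 0.25
    discs = tuple(
        (0.5 + r_mid * math.cos(2 * math.pi * j / valleys),
         0.5 + r_mid * math.sin(2 * math.pi * j / valleys), 0.04)
        for j in range(valleys)
    )
    spec = InitialLayoutSpec(preset="coexistence", seed=seed, tumor_discs=discs,
                             annulus=(0.05, 0.20))
    allowed = tissue.white
    state, layout = seed_initial_state(spec, grid, params, allowed=allowed)
    traj = _run(state, tissue, params, InjectionSchedule(), t_end, controls)
    return ScenarioResult("star", seed, {"control": traj},
                          {"final": _final_pops(traj)}, {"layout": layout})


def _vessel_scenario(orientation, mode, seed, grid, controls, params, t_end,
                     pulses=DEFAULT_PULSES, tau=1.0):
    tissue = build_tissue_map(f"vessel_{orientation}", grid)
    (state, layout), _ = _white_layout(grid, tissue, seed, params)
    omega_A = tissue.vessel
    if mode == "constant":
        sched = InjectionSchedule(mode="constant", rate=params.lambda_A, omega_A=omega_A)
    else:
        sched = InjectionSchedule(mode="periodic", rate=params.lambda_A, omega_A=omega_A,
                                  pulse_starts=pulses, tau=tau)
    arms = {
        "control": _run(state.copy(), tissue, params, InjectionSchedule(), t_end, controls),
        "treated": _run(state.copy(), tissue, params, sched, t_end, controls),
    }
    ctrl = _final_pops(arms["control"])["n"]
    summary = {
        "final_tumor": {k: _final_pops(v)["n"] for k, v in arms.items()},
        "reduction": metrics.relative_change(_final_pops(arms["treated"])["n"], ctrl),
    }
    return ScenarioResult(f"vessel_{orientation}_{mode}", seed, arms, summary,
                          {"layout": layout})


@register("vessel_horizontal_constant")
def _scn_vh_const(seed, grid, controls, params, t_end=240.0):
    """Antibody entering from a horizontal vessel strip (constant schedule)."""
    return _vessel_scenario("horizontal", "constant", seed, grid, controls, params, t_end)


@register("vessel_horizontal_periodic")
def _scn_vh_per(seed, grid, controls, params, t_end=240.0):
    return _vessel_scenario("horizontal", "periodic", seed, grid, controls, params, t_end)


@register("vessel_vertical_constant")
def _scn_vv_const(seed, grid, controls, params, t_end=240.0):
    """Antibody entering from a vertical vessel strip (constant schedule)."""
    return _vessel_scenario("vertical", "constant", seed, grid, controls, params, t_end)


@register("vessel_vertical_periodic")
def _scn_vv_per(seed, grid, controls, params, t_end=240.0):
    return _vessel_scenario("vertical", "periodic", seed, grid, controls, params, t_end)


# --- corpus-callosum surgery family ---------------------------------------

CC_TUMOR_CENTER = (0.36, 0.5)


def _make_surgery_event(t_surgery, center, params, fraction, rim_width,
                        ifnb=False, antibody=False, ifnb_factor=100.0):
    def action(state, ctx):
        grid = ctx["stepper"].grid
        region = visible_core_region(state, grid, center, params, fraction)
        new = apply_resection(state, region, grid)
        sched = ctx["schedule"]
        rim = _annulus_mask(grid, center, region.radius, region.radius + rim_width)
        if ifnb:
            sched.ifnb_active = True
            sched.ifnb_mask = rim
            sched.ifnb_rate = ifnb_factor * params.lambda_S
        if antibody:
            sched.omega_A = rim
        return new
    return action


@register("cc_surgery")
def _scn_cc_surgery(seed, grid, controls, params, t_end=240.0, t_surgery=84.0,
                    arm="surgery", fraction=0.05, rim_width=0.05,
                    include_control=True):
    """Tumor near the corpus-callosum entrance in a two-hemisphere domain;
    arms: control (no surgery), surgery, surgery+IFN-beta on the resection
    rim, surgery+antibody on the rim."""
    tissue = build_tissue_map("cc_two_hemisphere", grid)
    spec = InitialLayoutSpec(preset="coexistence", seed=seed, center=CC_TUMOR_CENTER,
                             annulus=(0.10, 0.22),
                             tumor_discs=(CC_TUMOR_CENTER + (0.05,),))
    allowed = tissue.white | tissue.omega_cc
    arms_def = {
        "control": (False, False, False),
        "surgery": (True, False, False),
        "surgery_ifnb": (True, True, False),
        "surgery_antibody": (True, False, True),
    }
    if arm == "all":
        selected = list(arms_def)
    else:
        if arm not in arms_def:
            raise ValueError(f"unknown arm {arm!r}")
        selected = [arm] if (arm == "control" or not include_control) else ["control", arm]
    arms = {}
    for name in selected:
        do_surgery, ifnb, antibody = arms_def[name]
        state, layout = seed_initial_state(spec, grid, params, allowed=allowed)
        # antibody arms start undosed; the surgery event points the support at
        # the resection rim and a companion event switches dosing on
        sched = InjectionSchedule(mode="none")
        events = []
        if do_surgery:
            events.append(Event(t_surgery,
                                _make_surgery_event(t_surgery, CC_TUMOR_CENTER, params,
                                                    fraction, rim_width,
                                                    ifnb=ifnb, antibody=antibody),
                                label=name))
            if antibody:
                events.append(Event(t_surgery, _start_antibody(params), label="antibody_on"))
        arms[name] = _run(state, tissue, params, sched, t_end, controls, events=events)
    summary = {"arms": {}}
    for name, traj in arms.items():
        pops = _final_pops(traj)
        n1c, n2c = metrics.composition(pops["N1"], pops["N2"])
        cc_burden = metrics.total_population(traj.final().n, grid, tissue.omega_cc)
        plus_burden = metrics.total_population(traj.final().n, grid, tissue.omega_plus)
        summary["arms"][name] = {
            "pct_N1": n1c, "pct_N2": n2c, "final_tumor": pops["n"],
            "tumor_in_cc": cc_burden, "tumor_in_contralateral": plus_burden,
        }
    return ScenarioResult("cc_surgery", seed, arms, summary, {"layout": layout})


def _start_antibody(params):
    def action(state, ctx):
        sched = ctx["schedule"]
        sched.mode = "constant"
        sched.rate = params.lambda_A
        return None
    return action
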