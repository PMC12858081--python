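"""Hybrid cellular-automaton model: discrete cells coupled to continuum
cytokine/antibody fields.

Five cell types live on the lattice — non-invasive (core) glioma cells,
invasive glioma cells, N1 TANs, N2 TANs and exogenous Trojan N1 TANs
(nanoparticle carriers).  Core cells on the tumor surface either turn
invasive (go) or proliferate (grow); invasive cells in the rim migrate
radially outward, elsewhere they random-walk; TANs chemotax up the TGF-beta
gradient toward the tumor.  N1/N2 phenotype switches follow the local
IFN-beta/TGF-beta balance; N1 and Trojan cells kill tumor cells on Moore
contact; the antibody removes N2 TANs.  TGF-beta is sourced at tumor-cell
sites, and IFN-beta/TGF-beta/antibody diffuse and decay on the same grid
(backward-Euler diffusion, exact exponential decay).

One seeded generator drives every random draw; cells are processed in
randomized order within each stage to avoid lattice sweep bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, correlate, distance_transform_edt

from .geometry import DomainGrid, TissueMap, build_tissue_map, diffusion_field
from .params import ModelParameters
from .pde import diffusion_matrix
from scipy.sparse import identity as sp_identity
from scipy.sparse.linalg import splu

TUMOR_CORE, TUMOR_INV, N1_TAN, N2_TAN, TROJAN = 1, 2, 3, 4, 5
TYPE_NAMES = {TUMOR_CORE: "tumor_core", TUMOR_INV: "tumor_invasive",
              N1_TAN: "n1_tan", N2_TAN: "n2_tan", TROJAN: "trojan_n1"}
TUMOR_TYPES = (TUMOR_CORE, TUMOR_INV)
TAN_TYPES = (N1_TAN, N2_TAN, TROJAN)

MOORE = tuple((dj, di) for dj in (-1, 0, 1) for di in (-1, 0, 1) if (dj, di) != (0, 0))


@dataclass
class CARules:
    """Stochastic rule parameters of the cell layer.

    ``q``: per-step probability that a surface core cell turns invasive;
    ``p_move``: random-walk move probability when there is no gradient cue;
    ``r_div``: division probability once the 8-h cycle completes and space
    exists; ``rim_width``: width of the invasive rim (domain units) beyond
    the core radius; ``theta``: hysteresis margin of the phenotype switch
    (compared on the w2*G vs w1*S scale, cells/cm^3); ``cc_extra_moves``:
    extra move attempts per step inside the corpus callosum (fast track);
    ``density_equiv``: tissue density equivalent of one occupied site used
    for the per-cell TGF-beta source (defaults to the tumor carrying
    capacity n0).
    """

    q: float = 0.3
    p_move: float = 0.8
    r_div: float = 1.0
    cycle_h: float = 8.0
    dt: float = 1.0
    rim_width: float = 0.05
    periph_width: float | None = None   # None -> 2 lattice spacings
    theta: float = 0.0
    cc_extra_moves: int = 1
    trojan_one_shot: bool = False
    tan_death: bool = True
    density_equiv: float | None = None
    field_substeps: int = 2

    def __post_init__(self) -> None:
        for nm in ("q", "p_move", "r_div"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{nm} must be a probability, got {v}")
        if self.cycle_h <= 0 or self.dt <= 0:
            raise ValueError("cycle_h and dt must be positive")


class CAState:
    """Cell roster + occupancy lattice + coupled continuum fields."""

    def __init__(self, tissue: TissueMap, params: ModelParameters,
                 rules: CARules, rng: np.random.Generator,
                 tumor_center=(0.5, 0.5)):
        self.tissue = tissue
        self.grid = tissue.grid
        self.params = params
        self.rules = rules
        self.rng = rng
        self.tumor_center = tumor_center
        ny, nx = self.grid.shape
        self.occ = np.full((ny, nx), -1, dtype=np.int32)
        self.ctype = np.zeros(0, dtype=np.int8)
        self.ci = np.zeros(0, dtype=np.int32)   # x index
        self.cj = np.zeros(0, dtype=np.int32)   # y index
        self.clock = np.zeros(0, dtype=float)
        self.alive = np.zeros(0, dtype=bool)
        self.allowed = ~tissue.gray             # cells cannot enter gray matter
        # continuum fields
        self.S = np.zeros((ny, nx))
        self.G = np.zeros((ny, nx))
        self.A = np.zeros((ny, nx))
        self._setup_field_solvers()
        self.R_c = 0.0
        self.R_I = rules.rim_width
        # bookkeeping of tumor-count changes
        self.births = self.contact_kills = self.resected = 0

    # -- infrastructure ----------------------------------------------------
    def _setup_field_solvers(self):
        g, p = self.grid, self.params
        dt = self.rules.dt / self.rules.field_substeps
        ident = sp_identity(g.nx * g.ny, format="csr")
        self._lu = {}
        for nm, D in (("S", p.DS), ("G", p.DG), ("A", p.DA)):
            Df = diffusion_field(D, self.tissue)
            self._lu[nm] = splu((ident - dt * diffusion_matrix(Df, g)).tocsc())

    def _grow_arrays(self, extra):
        n = len(self.ctype)
        for nm, dtype in (("ctype", np.int8), ("ci", np.int32), ("cj", np.int32),
                          ("clock", float), ("alive", bool)):
            arr = getattr(self, nm)
            new = np.zeros(n + extra, dtype=dtype)
            new[:n] = arr
            setattr(self, nm, new)
        self._cap = n + extra

    def spawn(self, ctype: int, j: int, i: int, clock: float = 0.0) -> int:
        """Add a cell at (row j, col i); the site must be free and allowed."""
        if self.occ[j, i] != -1:
            raise ValueError(f"site ({j},{i}) already occupied")
        idx = len(self.ctype)
        self._grow_arrays(1)
        self.ctype[idx] = ctype
        self.cj[idx], self.ci[idx] = j, i
        self.clock[idx] = clock
        self.alive[idx] = True
        self.occ[j, i] = idx
        return idx

    def remove(self, idx: int) -> None:
        if not self.alive[idx]:
            return
        self.alive[idx] = False
        self.occ[self.cj[idx], self.ci[idx]] = -1

    def move_cell(self, idx: int, j: int, i: int) -> None:
        if self.occ[j, i] != -1:
            raise ValueError("target site occupied")
        self.occ[self.cj[idx], self.ci[idx]] = -1
        self.cj[idx], self.ci[idx] = j, i
        self.occ[j, i] = idx

    def live_indices(self, *types) -> np.ndarray:
        mask = self.alive.copy()
        if types:
            mask &= np.isin(self.ctype, types)
        return np.flatnonzero(mask)

    def counts(self) -> dict[str, int]:
        out = {}
        for code, nm in TYPE_NAMES.items():
            out[nm] = int(np.count_nonzero(self.alive & (self.ctype == code)))
        out["tumor_total"] = out["tumor_core"] + out["tumor_invasive"]
        return out

    def free_moore(self, j: int, i: int) -> list[tuple[int, int]]:
        ny, nx = self.grid.shape
        out = []
        for dj, di in MOORE:
            jj, ii = j + dj, i + di
            if 0 <= jj < ny and 0 <= ii < nx and self.occ[jj, ii] == -1 \
                    and self.allowed[jj, ii]:
                out.append((jj, ii))
        return out

    def has_neighbor_of(self, j: int, i: int, types) -> bool:
        ny, nx = self.grid.shape
        for dj, di in MOORE:
            jj, ii = j + dj, i + di
            if 0 <= jj < ny and 0 <= ii < nx:
                k = self.occ[jj, ii]
                if k != -1 and self.ctype[k] in types:
                    return True
        return False

    def cell_radius(self, idx: int) -> float:
        cx, cy = self.tumor_center
        return float(np.hypot(self.ci[idx] * self.grid.hx - cx,
                              self.cj[idx] * self.grid.hy - cy))

    def update_radii(self) -> None:
        core = self.live_indices(TUMOR_CORE)
        if len(core) == 0:
            self.R_c = 0.0
        else:
            cx, cy = self.tumor_center
            d = np.hypot(self.ci[core] * self.grid.hx - cx,
                         self.cj[core] * self.grid.hy - cy)
            self.R_c = float(np.percentile(d, 95.0))
        self.R_I = self.R_c + self.rules.rim_width

    def enclosed_lattice(self) -> np.ndarray:
        """Boolean lattice: True where all 8 Moore neighbors are blocked
        (occupied, gray matter, or outside the domain)."""
        blocked = (self.occ >= 0) | ~self.allowed
        kernel = np.ones((3, 3), dtype=int)
        kernel[1, 1] = 0
        # out-of-domain neighbors count as blocked
        cnt = correlate(blocked.astype(np.int8), kernel, mode="constant", cval=1)
        return cnt >= 8

    def assert_occupancy(self) -> None:
        live = self.live_indices()
        assert len(live) == np.count_nonzero(self.occ >= 0), "occupancy corruption"
        for idx in live:
            assert self.occ[self.cj[idx], self.ci[idx]] == idx, "occupancy corruption"


# ---------------------------------------------------------------------------
# individual rules (exposed for testing)

def go_or_grow(state: CAState, idx: int, rules: CARules, rng) -> str:
    """Surface core cell turns invasive with probability q, else grows."""
    if state.ctype[idx] not in TUMOR_TYPES:
        raise ValueError("go-or-grow applies to tumor cells only")
    return "migrate" if rng.random() < rules.q else "grow"


def choose_move(state: CAState, idx: int, rules: CARules, rng):
    """Target site for a mobile cell, or None to stay.

    Invasive cells inside the rim step to the free neighbor most aligned
    with the outward radial direction; outside the rim they random-walk
    with probability ``p_move``.  TANs step to the free neighbor with the
    highest TGF-beta (chemotaxis); with no uphill option they random-walk
    with probability ``p_move``.
    """
    ctype = state.ctype[idx]
    j, i = int(state.cj[idx]), int(state.ci[idx])
    free = state.free_moore(j, i)
    if not free:
        return None
    if ctype == TUMOR_INV:
        rad = state.cell_radius(idx)
        if rad <= state.R_I:
            cx, cy = state.tumor_center
            vx = i * state.grid.hx - cx
            vy = j * state.grid.hy - cy
            norm = np.hypot(vx, vy)
            if norm == 0:
                return free[rng.integers(len(free))]
            scores = [(vx * (ii - i) + vy * (jj - j)) / np.hypot(ii - i, jj - j)
                      for jj, ii in free]
            best = max(scores)
            cand = [s for s, sc in zip(free, scores) if sc >= best - 1e-12]
            return cand[rng.integers(len(cand))]
        if rng.random() < rules.p_move:
            return free[rng.integers(len(free))]
        return None
    if ctype in TAN_TYPES:
        G = state.G
        ny, nx = state.grid.shape
        gx = (G[j, min(i + 1, nx - 1)] - G[j, max(i - 1, 0)]) / state.grid.hx
        gy = (G[min(j + 1, ny - 1), i] - G[max(j - 1, 0), i]) / state.grid.hy
        if gx != 0.0 or gy != 0.0:
            scores = [(gx * (ii - i) + gy * (jj - j)) / np.hypot(ii - i, jj - j)
                      for jj, ii in free]
            best = max(scores)
            if best > 0.0:
                cand = [s for s, sc in zip(free, scores) if sc >= best - 1e-12 * abs(best)]
                return cand[rng.integers(len(cand))]
        if rng.random() < rules.p_move:
            return free[rng.integers(len(free))]
        return None
    return None


def attempt_division(state: CAState, idx: int, rules: CARules, rng):
    """Division of a tumor cell whose cycle is complete; enclosed cells hold
    their clock and retry.  An invasive mother settles: both mother and
    daughter are non-invasive afterwards."""
    if state.ctype[idx] not in TUMOR_TYPES:
        return None
    if state.clock[idx] < rules.cycle_h:
        return None
    free = state.free_moore(int(state.cj[idx]), int(state.ci[idx]))
    if not free:
        state.clock[idx] = rules.cycle_h   # enclosed: hold and retry next step
        return None
    if rng.random() >= rules.r_div:
        state.clock[idx] = rules.cycle_h
        return None
    jj, ii = free[rng.integers(len(free))]
    state.ctype[idx] = TUMOR_CORE
    state.clock[idx] = 0.0
    daughter = state.spawn(TUMOR_CORE, jj, ii, clock=0.0)
    state.births += 1
    return daughter


def phenotype_update(state: CAState, idx: int, rules: CARules) -> None:
    """N1 <-> N2 switch from the local w2*G vs w1*S balance (margin theta);
    Trojan N1 cells are switch-immune."""
    ctype = state.ctype[idx]
    if ctype not in (N1_TAN, N2_TAN):
        raise ValueError("phenotype update applies to endogenous TANs only")
    j, i = state.cj[idx], state.ci[idx]
    p = state.params
    drive_n2 = p.w2 * state.G[j, i]
    drive_n1 = p.w1 * state.S[j, i]
    if ctype == N1_TAN and drive_n2 > drive_n1 + rules.theta:
        state.ctype[idx] = N2_TAN
    elif ctype == N2_TAN and drive_n1 > drive_n2 + rules.theta:
        state.ctype[idx] = N1_TAN


def contact_kill(state: CAState) -> int:
    """Remove every tumor cell with an N1 or Trojan neighbor; returns kills."""
    killers = (N1_TAN, TROJAN)
    kills = 0
    used_trojans = set()
    killer_idx = state.live_indices(*killers)
    if len(killer_idx) == 0:
        return 0
    killer_mask = np.zeros(state.grid.shape, dtype=bool)
    killer_mask[state.cj[killer_idx], state.ci[killer_idx]] = True
    reach = binary_dilation(killer_mask, structure=np.ones((3, 3), dtype=bool))
    for idx in state.live_indices(*TUMOR_TYPES):
        j, i = int(state.cj[idx]), int(state.ci[idx])
        if reach[j, i] and state.has_neighbor_of(j, i, killers):
            state.remove(idx)
            kills += 1
            if state.rules.trojan_one_shot:
                for dj, di in MOORE:
                    jj, ii = j + dj, i + di
                    if 0 <= jj < state.grid.shape[0] and 0 <= ii < state.grid.shape[1]:
                        k = state.occ[jj, ii]
                        if k != -1 and state.ctype[k] == TROJAN and k not in used_trojans:
                            used_trojans.add(k)
                            state.remove(k)
                            break
    state.contact_kills += kills
    state.update_radii()
    return kills


def ca_surgery(state: CAState, region) -> int:
    """Remove all tumor cells (both types) inside the region; TANs retained."""
    mask = region.node_mask(state.grid)
    removed = 0
    for idx in state.live_indices(*TUMOR_TYPES):
        if mask[state.cj[idx], state.ci[idx]]:
            state.remove(idx)
            removed += 1
    state.resected += removed
    state.update_radii()
    return removed


# ---------------------------------------------------------------------------
# configuration & simulation loop

@dataclass
class CAEvent:
    time: float
    action: object     # action(state) -> None
    label: str = ""


@dataclass
class CAConfig:
    """Scenario configuration for the hybrid model."""

    grid: DomainGrid = dc_field(default_factory=lambda: DomainGrid(101, 101))
    tissue: TissueMap | None = None          # None -> uniform white
    rules: CARules = dc_field(default_factory=CARules)
    params: ModelParameters = dc_field(default_factory=ModelParameters)
    tumor_center: tuple[float, float] = (0.5, 0.5)
    tumor_radius: float = 0.08
    vessel: np.ndarray | None = None         # None -> tissue vessel labels
    initial_n1: int = 10
    initial_n2: int = 0
    n1_influx_per_h: float = 1.0
    trojan_influx_per_h: float = 0.0
    trojan_start: float = 0.0
    antibody_rate: float = 0.0               # g/(cm^3 h) on the vessel mask
    antibody_start: float = 0.0
    ifnb_rate: float = 0.0
    ifnb_mask: np.ndarray | None = None
    t_end: float = 180.0
    record_every: float = 10.0
    events: list = dc_field(default_factory=list)
    seed: int = 0


@dataclass
class CATrajectory:
    times: np.ndarray
    counts: pd.DataFrame           # per-type and region-resolved counts
    state: CAState                 # final state
    event_log: list


def _vessel_strip(grid: DomainGrid, x_range=(0.02, 0.05)) -> np.ndarray:
    X, _ = grid.meshgrid()
    return (X >= x_range[0]) & (X <= x_range[1])


def build_ca_state(config: CAConfig) -> tuple[CAState, np.ndarray, np.random.Generator]:
    """Initialize roster (tumor disc of non-invasive cells, TANs in the
    vessel) and return (state, vessel_mask, rng)."""
    rng = np.random.default_rng(config.seed)
    tissue = config.tissue or build_tissue_map("uniform_white", config.grid)
    state = CAState(tissue, config.params, config.rules, rng,
                    tumor_center=config.tumor_center)
    vessel = config.vessel
    if vessel is None:
        vessel = tissue.vessel
        if not vessel.any():
            vessel = _vessel_strip(config.grid)
    X, Y = config.grid.meshgrid()
    cx, cy = config.tumor_center
    if config.tumor_radius > 0:
        disc = (np.hypot(X - cx, Y - cy) <= config.tumor_radius) & state.allowed
        for j, i in zip(*np.nonzero(disc)):
            state.spawn(TUMOR_CORE, int(j), int(i),
                        clock=float(rng.uniform(0.0, config.rules.cycle_h)))
    free_vessel = [(int(j), int(i)) for j, i in zip(*np.nonzero(vessel))]
    rng.shuffle(free_vessel)
    placed = 0
    for ctype, count in ((N1_TAN, config.initial_n1), (N2_TAN, config.initial_n2)):
        for _ in range(count):
            while placed < len(free_vessel):
                j, i = free_vessel[placed]
                placed += 1
                if state.occ[j, i] == -1:
                    state.spawn(ctype, j, i)
                    break
    state.update_radii()
    return state, vessel, rng


def _influx(state, vessel_sites, rng, ctype, count):
    added = 0
    order = rng.permutation(len(vessel_sites))
    for k in order:
        if added >= count:
            break
        j, i = vessel_sites[k]
        if state.occ[j, i] == -1:
            state.spawn(ctype, j, i)
            added += 1
    return added


def _update_fields(state: CAState, config: CAConfig, vessel: np.ndarray, t: float):
    """Advance S, G, A by one CA step: exact exponential decay with constant
    source, then backward-Euler diffusion (substepped)."""
    p = state.params
    rules = state.rules
    dt = rules.dt / rules.field_substeps
    rho = rules.density_equiv if rules.density_equiv is not None else p.n0
    src_G = np.zeros(state.grid.shape)
    tumor = state.live_indices(*TUMOR_TYPES)
    np.add.at(src_G, (state.cj[tumor], state.ci[tumor]), p.lambda_G * rho)
    src_A = np.where(vessel, config.antibody_rate, 0.0) \
        if (config.antibody_rate > 0 and t >= config.antibody_start) else 0.0
    if config.ifnb_rate > 0:
        mask = config.ifnb_mask if config.ifnb_mask is not None else np.ones(state.grid.shape, bool)
        src_S = np.where(mask, config.ifnb_rate, 0.0)
    else:
        src_S = 0.0
    for nm, mu, src in (("G", p.mu_G, src_G), ("S", p.mu_S, src_S), ("A", p.mu_A, src_A)):
        u = getattr(state, nm)
        for _ in range(rules.field_substeps):
            decay = np.exp(-mu * dt)
            u = u * decay + np.asarray(src) * (1.0 - decay) / mu
            u = state._lu[nm].solve(u.ravel()).reshape(state.grid.shape)
        setattr(state, nm, np.clip(u, 0.0, None))


def ca_simulate(config: CAConfig) -> CATrajectory:
    """Run the hybrid model to ``t_end`` (CA step = rules.dt hours)."""
    state, vessel, rng = build_ca_state(config)
    vessel_sites = [(int(j), int(i)) for j, i in zip(*np.nonzero(vessel))]
    rules = config.rules
    events = sorted(config.events, key=lambda e: e.time)
    ev_i = 0
    event_log = []
    periph = rules.periph_width if rules.periph_width is not None \
        else 2.0 * max(config.grid.hx, config.grid.hy)

    along_bv = distance_transform_edt(~vessel) * config.grid.hx <= 0.06
    regions = {
        "in_cc": state.tissue.omega_cc,
        "in_contralateral": state.tissue.omega_plus,
        "along_bv": along_bv,
    }
    acc_n1 = acc_trojan = 0.0
    times, rows = [], []

    def record(t):
        row = state.counts()
        for nm, mask in regions.items():
            idxs = state.live_indices(*TUMOR_TYPES)
            if mask is None or not mask.any():
                row[f"tumor_{nm}"] = 0
            else:
                row[f"tumor_{nm}"] = int(np.count_nonzero(mask[state.cj[idxs], state.ci[idxs]]))
        times.append(t)
        rows.append(row)

    record(0.0)
    n_steps = int(round(config.t_end / rules.dt))
    rec_stride = max(1, int(round(config.record_every / rules.dt)))
    for step in range(1, n_steps + 1):
        t = step * rules.dt
        state.update_radii()

        # Go or grow on the core surface (enclosed interior cells skipped)
        enclosed = state.enclosed_lattice()
        core = state.live_indices(TUMOR_CORE)
        cx0, cy0 = state.tumor_center
        dist = np.hypot(state.ci[core] * state.grid.hx - cx0,
                        state.cj[core] * state.grid.hy - cy0)
        surface = core[(dist >= state.R_c - periph)
                       & ~enclosed[state.cj[core], state.ci[core]]]
        for idx in rng.permutation(surface):
            if not state.free_moore(int(state.cj[idx]), int(state.ci[idx])):
                continue
            if go_or_grow(state, idx, rules, rng) == "migrate":
                state.ctype[idx] = TUMOR_INV

        # migration
        movers = state.live_indices(TUMOR_INV, *TAN_TYPES)
        for idx in rng.permutation(movers):
            if not state.alive[idx]:
                continue
            attempts = 1
            if state.tissue.omega_cc[state.cj[idx], state.ci[idx]]:
                attempts += rules.cc_extra_moves
            for _ in range(attempts):
                tgt = choose_move(state, idx, rules, rng)
                if tgt is not None:
                    state.move_cell(idx, *tgt)

        # division (tumor cells age by one step; enclosed cells hold their
        # clock at the cycle length and retry once space opens)
        tumor = state.live_indices(*TUMOR_TYPES)
        state.clock[tumor] = np.minimum(state.clock[tumor] + rules.dt, rules.cycle_h)
        enclosed = state.enclosed_lattice()
        ready = tumor[(state.clock[tumor] >= rules.cycle_h)
                      & ~enclosed[state.cj[tumor], state.ci[tumor]]]
        for idx in rng.permutation(ready):
            if state.alive[idx]:
                attempt_division(state, idx, rules, rng)

        # phenotype switching + antibody/natural death of TANs
        p = state.params
        for idx in rng.permutation(state.live_indices(N1_TAN, N2_TAN)):
            phenotype_update(state, idx, rules)
            if state.ctype[idx] == N2_TAN:
                a_loc = state.A[state.cj[idx], state.ci[idx]]
                if a_loc > 0 and rng.random() < -np.expm1(-p.beta * a_loc * rules.dt):
                    state.remove(idx)
                    continue
            if rules.tan_death and rng.random() < -np.expm1(-p.mu1 * rules.dt):
                state.remove(idx)
        if rules.tan_death:
            for idx in state.live_indices(TROJAN):
                if rng.random() < -np.expm1(-p.mu1 * rules.dt):
                    state.remove(idx)

        # contact killing by N1 / Trojan
        contact_kill(state)

        # timed interventions (surgery etc.)
        while ev_i < len(events) and events[ev_i].time <= t + 1e-9:
            events[ev_i].action(state)
            event_log.append((t, events[ev_i].label or "event"))
            ev_i += 1

        # influx from the vessel
        acc_n1 += config.n1_influx_per_h * rules.dt
        if acc_n1 >= 1.0:
            k = int(acc_n1)
            acc_n1 -= k
            _influx(state, vessel_sites, rng, N1_TAN, k)
        if t >= config.trojan_start and config.trojan_influx_per_h > 0:
            acc_trojan += config.trojan_influx_per_h * rules.dt
            if acc_trojan >= 1.0:
                k = int(acc_trojan)
                acc_trojan -= k
                _influx(state, vessel_sites, rng, TROJAN, k)

        # continuum fields
        _update_fields(state, config, vessel, t)

        if step % rec_stride == 0 or step == n_steps:
            record(t)

    counts = pd.DataFrame(rows, index=pd.Index(times, name="t"))
    return CATrajectory(times=np.asarray(times), counts=counts, state=state,
                        event_log=event_log)
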