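"""Six-field glioma/TAN reaction-diffusion system: reactions, heterogeneous
diffusion, injection schedules and time integration.

The continuum state couples the densities of anti-tumorigenic N1 TANs,
pro-tumorigenic N2 TANs and glioma cells with the concentrations of the
anti-N2 antibody, IFN-beta and TGF-beta.  N1/N2 compete Lotka-Volterra
style, the cytokines tilt the respective carrying capacities, N2 boosts
tumor growth through a Hill switch, N1 kills tumor cells, and the antibody
removes N2.  All species diffuse with space-dependent coefficients induced
by the tissue map, under zero-flux (Neumann) boundaries.

Time stepping is a splitting scheme: reactions are advanced with a
positivity-preserving two-stage exponential integrator on a
production/loss decomposition (exact for linear source-decay balances,
second-order otherwise), slow cell fields diffuse explicitly, and the fast
cytokine/antibody diffusers use backward-Euler solves with prefactorized
sparse operators.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import DomainGrid, TissueMap, diffusion_field, face_coefficient
from .params import ModelParameters

FIELD_NAMES = ("N1", "N2", "A", "n", "S", "G")
#: white-matter diffusion parameter backing each field
FIELD_DIFFUSION = {"N1": "D1", "N2": "D2", "A": "DA", "n": "Dn", "S": "DS", "G": "DG"}
#: fields stiff enough (fast diffusers) to require implicit treatment
IMPLICIT_FIELDS = ("A", "S", "G")


@dataclass
class StateFields:
    """The six continuum fields on one grid at one time.

    Densities (N1, N2, n) in cells/cm^3; concentrations (A, S, G) in g/cm^3.
    """

    N1: np.ndarray
    N2: np.ndarray
    A: np.ndarray
    n: np.ndarray
    S: np.ndarray
    G: np.ndarray

    @classmethod
    def zeros(cls, grid: DomainGrid) -> "StateFields":
        return cls(*(np.zeros(grid.shape) for _ in FIELD_NAMES))

    def copy(self) -> "StateFields":
        return StateFields(*(getattr(self, f).copy() for f in FIELD_NAMES))

    def as_dict(self) -> dict[str, np.ndarray]:
        return {f: getattr(self, f) for f in FIELD_NAMES}

    def validate(self) -> None:
        for f in FIELD_NAMES:
            v = getattr(self, f)
            if not np.all(np.isfinite(v)):
                raise FloatingPointError(f"non-finite values in field {f}")
            if np.any(v < 0):
                raise ValueError(f"negative values in field {f}")


@dataclass
class InjectionSchedule:
    """Antibody dosing and IFN-beta sourcing.

    Antibody (Eq. for A): ``mode='constant'`` applies ``rate`` at all times;
    ``mode='periodic'`` applies ``multiplier * rate`` during each pulse
    window ``[t_j, t_j + tau]``; ``mode='none'`` disables dosing.  The dose
    is deposited on the support mask ``omega_A`` (``None`` = whole domain).

    IFN-beta: the source indicator is an *injection* switch — off in
    untreated scenarios (S stays 0 without therapy).  While ``ifnb_active``,
    a source of strength ``ifnb_rate`` (defaults to the model's secretion
    rate) acts on ``ifnb_mask`` (``None`` = whole domain); therapy events may
    re-point the mask and raise the rate.
    """

    mode: str = "none"
    rate: float = 2.89e1          # lambda_A*, g/(cm^3 h)
    multiplier: float = 100.0     # pulse amplification of the periodic mode
    pulse_starts: tuple[float, ...] = ()
    tau: float = 1.0              # pulse width, h
    omega_A: np.ndarray | None = None
    ifnb_active: bool = False
    ifnb_rate: float | None = None  # g/(cm^3 h); None -> params.lambda_S
    ifnb_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "constant", "periodic"):
            raise ValueError(f"unknown injection mode {self.mode!r}")
        if self.mode == "periodic":
            ts = tuple(self.pulse_starts)
            if len(ts) == 0:
                raise ValueError("periodic mode needs at least one pulse start")
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError("pulse starts must be strictly increasing")
            if self.tau <= 0:
                raise ValueError("pulse width tau must be positive")
        if self.omega_A is not None and self.mode != "none" and not np.any(self.omega_A):
            raise ValueError("antibody support mask is empty while dosing is active")


def injection_rate(t: float, schedule: InjectionSchedule) -> float:
    """Antibody injection rate (g cm^-3 h^-1) on the support at time ``t``."""
    if schedule.mode == "none":
        return 0.0
    if schedule.mode == "constant":
        return schedule.rate
    for tj in schedule.pulse_starts:
        if tj <= t <= tj + schedule.tau:
            return schedule.multiplier * schedule.rate
    return 0.0


def mean_injection_rate(t0: float, t1: float, schedule: InjectionSchedule) -> float:
    """Time-average of the injection rate over [t0, t1].

    Used by the stepper so that the deposited dose is exact regardless of
    how the step boundaries fall relative to the pulse windows.
    """
    if t1 <= t0 or schedule.mode == "none":
        return 0.0
    if schedule.mode == "constant":
        return schedule.rate
    overlap = 0.0
    for tj in schedule.pulse_starts:
        overlap += max(0.0, min(t1, tj + schedule.tau) - max(t0, tj))
    return schedule.multiplier * schedule.rate * overlap / (t1 - t0)


def total_injected_dose(schedule: InjectionSchedule, t_end: float, grid: DomainGrid) -> float:
    """Grid-integrated antibody mass injected over [0, t_end] (g per unit depth)."""
    if schedule.omega_A is None:
        area = 1.0
    else:
        area = float(grid.node_volumes()[schedule.omega_A].sum())
    return mean_injection_rate(0.0, t_end, schedule) * t_end * area


# ---------------------------------------------------------------------------
# reactions

def reaction_rates(state, params: ModelParameters, a_rate=0.0, s_rate=0.0) -> dict:
    """Pointwise reaction contributions du/dt (diffusion excluded).

    ``state`` may be a :class:`StateFields` or a mapping of the six field
    names to scalars/arrays.  ``a_rate`` / ``s_rate`` are the local antibody
    injection and IFN-beta source strengths.
    """
    get = state.as_dict() if isinstance(state, StateFields) else dict(state)
    N1, N2, A, n, S, G = (np.asarray(get[f], dtype=float) for f in FIELD_NAMES)
    for name, v in zip(FIELD_NAMES, (N1, N2, A, n, S, G)):
        if np.any(v < 0):
            raise ValueError(f"negative {name} passed to reaction_rates")
    p = params
    dN1 = p.r1 * N1 * (1.0 - N1 / (p.w1 * S + p.K1)) - p.alpha1 * N1 * N2 - p.mu1 * N1
    dN2 = (p.r2 * N2 * (1.0 - N2 / (p.w2 * G + p.K2)) - p.alpha2 * N1 * N2
           - p.mu2 * N2 - p.beta * N2 * A)
    dA = np.asarray(a_rate, dtype=float) - p.mu_A * A
    growth = p.r * (1.0 + p.rN * N2 ** 2 / (p.k ** 2 + N2 ** 2))
    dn = growth * n * (1.0 - n / p.n0) - p.mu_n * N1 * n
    dS = np.asarray(s_rate, dtype=float) - p.mu_S * S
    dG = p.lambda_G * n - p.mu_G * G
    return {"N1": dN1, "N2": dN2, "A": dA, "n": dn, "S": dS, "G": dG}


def _production_loss(fields: dict, params: ModelParameters, a_rate, s_rate):
    """Split each reaction into nonnegative production P and loss-rate L
    (du/dt = P - L*u) for the positivity-preserving exponential step."""
    N1, N2, A, n, S, G = (fields[f] for f in FIELD_NAMES)
    p = params
    P = {}
    L = {}
    P["N1"] = p.r1 * N1
    L["N1"] = p.r1 * N1 / (p.w1 * S + p.K1) + p.alpha1 * N2 + p.mu1
    P["N2"] = p.r2 * N2
    L["N2"] = p.r2 * N2 / (p.w2 * G + p.K2) + p.alpha2 * N1 + p.mu2 + p.beta * A
    P["A"] = a_rate
    L["A"] = p.mu_A
    growth = p.r * (1.0 + p.rN * N2 ** 2 / (p.k ** 2 + N2 ** 2))
    P["n"] = growth * n
    L["n"] = growth * n / p.n0 + p.mu_n * N1
    P["S"] = s_rate
    L["S"] = p.mu_S
    P["G"] = p.lambda_G * n
    L["G"] = p.mu_G
    return P, L


def _etd_update(u, P, L, dt):
    """u <- u e^{-L dt} + P (1 - e^{-L dt})/L, with the L->0 limit."""
    x = L * dt
    decay = np.exp(-x)
    # phi(x) = (1 - e^-x)/x, series for small x
    phi = np.where(x > 1e-8, -np.expm1(-x) / np.where(x == 0.0, 1.0, x), 1.0 - 0.5 * x)
    return u * decay + dt * P * phi


def _reaction_step(fields: dict, params, a_rate, s_rate, dt) -> dict:
    """Two-stage exponential (Heun-type) reaction update; positive by construction."""
    P0, L0 = _production_loss(fields, params, a_rate, s_rate)
    stage = {f: _etd_update(fields[f], P0[f], L0[f], dt) for f in FIELD_NAMES}
    P1, L1 = _production_loss(stage, params, a_rate, s_rate)
    return {
        f: _etd_update(fields[f], 0.5 * (P0[f] + P1[f]), 0.5 * (L0[f] + L1[f]), dt)
        for f in FIELD_NAMES
    }


# ---------------------------------------------------------------------------
# diffusion

def _face_coeffs(Dfield: np.ndarray, grid: DomainGrid, mode: str = "harmonic"):
    cx = face_coefficient(Dfield[:, :-1], Dfield[:, 1:], mode=mode) / grid.hx ** 2
    cy = face_coefficient(Dfield[:-1, :], Dfield[1:, :], mode=mode) / grid.hy ** 2
    return cx, cy


def apply_diffusion(field: np.ndarray, Dfield: np.ndarray, grid: DomainGrid,
                    mode: str = "harmonic") -> np.ndarray:
    """Conservative finite-volume discretization of div(D grad u), zero-flux.

    Returns the rate array (units of ``field`` per hour).  Boundary nodes own
    half control volumes (mirror-ghost Neumann closure), which keeps the
    stencil second-order up to the boundary; the volume-weighted grid
    integral of the output vanishes to rounding — no mass crosses the
    boundary.
    """
    if field.shape != grid.shape or Dfield.shape != grid.shape:
        raise ValueError("field/Dfield shape does not match grid")
    cx, cy = _face_coeffs(Dfield, grid, mode)
    fx = cx * (field[:, 1:] - field[:, :-1])   # flux/h^2 across vertical faces
    fy = cy * (field[1:, :] - field[:-1, :])
    outx = np.zeros_like(field)
    outx[:, :-1] += fx
    outx[:, 1:] -= fx
    # boundary nodes own half cells in the direction of the flux difference
    outx[:, 0] *= 2.0
    outx[:, -1] *= 2.0
    outy = np.zeros_like(field)
    outy[:-1, :] += fy
    outy[1:, :] -= fy
    outy[0, :] *= 2.0
    outy[-1, :] *= 2.0
    return outx + outy


def diffusion_matrix(Dfield: np.ndarray, grid: DomainGrid, mode: str = "harmonic") -> sp.csr_matrix:
    """Sparse matrix of the same conservative Neumann operator."""
    ny, nx = grid.shape
    cx, cy = _face_coeffs(Dfield, grid, mode)
    idx = np.arange(ny * nx).reshape(ny, nx)
    # directional half-cell weights at the respective boundaries
    wx = np.ones((ny, nx))
    wx[:, 0] = wx[:, -1] = 2.0
    wy = np.ones((ny, nx))
    wy[0, :] = wy[-1, :] = 2.0
    rows, cols, vals = [], [], []
    for a, b, c, wa, wb in (
        (idx[:, :-1].ravel(), idx[:, 1:].ravel(), cx.ravel(),
         wx[:, :-1].ravel(), wx[:, 1:].ravel()),
        (idx[:-1, :].ravel(), idx[1:, :].ravel(), cy.ravel(),
         wy[:-1, :].ravel(), wy[1:, :].ravel()),
    ):
        rows.extend((a, b, a, b))
        cols.extend((b, a, a, b))
        vals.extend((c * wa, c * wb, -c * wa, -c * wb))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.coo_matrix((vals, (rows, cols)), shape=(ny * nx, ny * nx)).tocsr()


class Stepper:
    """Carries the prefactorized implicit solvers and advances the state."""

    def __init__(self, tissue: TissueMap, params: ModelParameters,
                 schedule: InjectionSchedule, gray_factor: float = 1e-6,
                 face_mode: str = "harmonic"):
        self.tissue = tissue
        self.grid = tissue.grid
        self.params = params
        self.schedule = schedule
        self.face_mode = face_mode
        self.D = {
            f: diffusion_field(getattr(params, FIELD_DIFFUSION[f]), tissue, gray_factor)
            for f in FIELD_NAMES
        }
        self._mat = {f: diffusion_matrix(self.D[f], self.grid, face_mode)
                     for f in IMPLICIT_FIELDS}
        self._lu: dict[tuple[str, float], object] = {}
        self._ident = sp.identity(self.grid.nx * self.grid.ny, format="csr")
        # explicit stability bound for the slow cell fields
        h2 = min(self.grid.hx, self.grid.hy) ** 2
        Dmax = max(self.D[f].max() for f in FIELD_NAMES if f not in IMPLICIT_FIELDS)
        self.dt_explicit = 0.9 * h2 / (4.0 * Dmax)

    def _solver(self, fname: str, dt: float):
        key = (fname, round(dt, 12))
        if key not in self._lu:
            self._lu[key] = splu((self._ident - dt * self._mat[fname]).tocsc())
        return self._lu[key]

    def _source_fields(self, t0: float, t1: float):
        shape = self.grid.shape
        rate = mean_injection_rate(t0, t1, self.schedule)
        if rate == 0.0:
            a_rate = 0.0
        elif self.schedule.omega_A is None:
            a_rate = rate
        else:
            a_rate = np.where(self.schedule.omega_A, rate, 0.0)
        if not self.schedule.ifnb_active:
            s_rate = 0.0
        else:
            sr = self.schedule.ifnb_rate
            if sr is None:
                sr = self.params.lambda_S
            if self.schedule.ifnb_mask is None:
                s_rate = sr
            else:
                s_rate = np.where(self.schedule.ifnb_mask, sr, 0.0)
        # broadcast scalars lazily; reaction code handles both
        del shape
        return a_rate, s_rate

    def step(self, state: StateFields, t: float, dt: float) -> StateFields:
        if dt <= 0:
            raise ValueError("dt must be positive")
        a_rate, s_rate = self._source_fields(t, t + dt)
        fields = state.as_dict()
        fields = _reaction_step(fields, self.params, a_rate, s_rate, dt)
        # diffusion: explicit sub-cycled for slow fields, backward Euler for fast
        for f in FIELD_NAMES:
            if f in IMPLICIT_FIELDS:
                lu = self._solver(f, dt)
                fields[f] = lu.solve(fields[f].ravel()).reshape(self.grid.shape)
            else:
                nsub = max(1, int(np.ceil(dt / self.dt_explicit)))
                sub = dt / nsub
                u = fields[f]
                for _ in range(nsub):
                    u = u + sub * apply_diffusion(u, self.D[f], self.grid, self.face_mode)
                fields[f] = u
        for f in FIELD_NAMES:
            u = fields[f]
            # flush vanishing tails to zero: physically negligible and keeps
            # the arithmetic out of subnormal range
            u[u < 1e-30] = 0.0
        out = StateFields(**{f: fields[f] for f in FIELD_NAMES})
        for f in FIELD_NAMES:
            arr = getattr(out, f)
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(
                    f"non-finite values in {f} at t={t + dt:.3f} h — unstable step?")
        return out


def advance(state: StateFields, tissue: TissueMap, params: ModelParameters,
            schedule: InjectionSchedule, t: float, dt: float, **kwargs) -> StateFields:
    """Advance the coupled system by one step of size ``dt`` hours.

    Convenience wrapper that builds a fresh :class:`Stepper`; long runs
    should go through :func:`simulate`, which reuses the factorized solvers.
    """
    return Stepper(tissue, params, schedule, **kwargs).step(state, t, dt)


# ---------------------------------------------------------------------------
# trajectories and events

@dataclass
class Event:
    """A timed intervention applied to the state during a simulation.

    ``action(state, context) -> StateFields | None`` — may return a new state
    or mutate in place; ``context`` carries the stepper and schedule so an
    event can also re-point source masks (e.g. post-surgery cytokine dosing).
    """

    time: float
    action: object
    label: str = ""


@dataclass
class Trajectory:
    """Sampled times, state snapshots and per-time population integrals."""

    times: np.ndarray
    states: list
    populations: dict[str, np.ndarray]
    grid: DomainGrid
    event_log: list = dc_field(default_factory=list)

    def state_at(self, t: float) -> StateFields:
        if len(self.states) != len(self.times):
            raise ValueError("snapshots were not kept; only final() is available")
        i = int(np.argmin(np.abs(self.times - t)))
        return self.states[i]

    def final(self) -> StateFields:
        return self.states[-1]


@dataclass
class SolverControls:
    dt: float = 0.01             # h
    sample_times: tuple[float, ...] | None = None
    gray_factor: float = 1e-6
    face_mode: str = "harmonic"
    keep_states: bool = True


def simulate(initial: StateFields, tissue: TissueMap, params: ModelParameters,
             schedule: InjectionSchedule, t_end: float,
             controls: SolverControls | None = None,
             events: list[Event] | None = None) -> Trajectory:
    """Integrate the six-field system from 0 to ``t_end`` hours.

    Events are applied exactly at their nominal times (step boundaries are
    inserted as needed) and their times are also snapshot times.
    """
    controls = controls or SolverControls()
    events = sorted(events or [], key=lambda e: e.time)
    for ev in events:
        if not (0.0 <= ev.time <= t_end):
            raise ValueError(f"event time {ev.time} outside [0, {t_end}]")
    grid = tissue.grid

    sample = set(controls.sample_times or (0.0, t_end))
    sample.update((0.0, t_end))
    sample.update(ev.time for ev in events)
    sample = sorted(tm for tm in sample if 0.0 <= tm <= t_end)

    # step boundaries: uniform dt grid plus all sample/event times
    n_steps = max(1, int(round(t_end / controls.dt))) if t_end > 0 else 0
    bounds = np.unique(np.concatenate([
        np.linspace(0.0, t_end, n_steps + 1) if t_end > 0 else [0.0],
        np.asarray(sample, dtype=float),
    ]))

    stepper = Stepper(tissue, params, schedule,
                      gray_factor=controls.gray_factor, face_mode=controls.face_mode)
    state = StateFields(**{f: np.asarray(getattr(initial, f), dtype=float).copy()
                           for f in FIELD_NAMES})
    state.validate()

    times_out, states_out = [], []
    pops: dict[str, list] = {f: [] for f in FIELD_NAMES}
    event_log = []
    vol = grid.node_volumes()
    ev_iter = iter(events)
    next_ev = next(ev_iter, None)
    sample_set = set(np.round(sample, 9))

    def record(t, st):
        times_out.append(t)
        if controls.keep_states:
            states_out.append(st.copy())
        else:
            # keep only the most recent snapshot so final() stays available
            states_out[:] = [st.copy()]
        for f in FIELD_NAMES:
            pops[f].append(float((getattr(st, f) * vol).sum()))

    def fire_events(t, st):
        nonlocal next_ev
        while next_ev is not None and next_ev.time <= t + 1e-9:
            res = next_ev.action(st, {"stepper": stepper, "schedule": schedule, "t": t})
            if res is not None:
                st = res
            event_log.append((t, next_ev.label or getattr(next_ev.action, "__name__", "event")))
            next_ev = next(ev_iter, None)
        return st

    state = fire_events(0.0, state)
    record(0.0, state)
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        dt = t1 - t0
        if dt <= 1e-12:
            continue
        state = stepper.step(state, t0, dt)
        state = fire_events(t1, state)
        if round(float(t1), 9) in sample_set:
            record(float(t1), state)

    return Trajectory(
        times=np.asarray(times_out),
        states=states_out,
        populations={f: np.asarray(v) for f, v in pops.items()},
        grid=grid,
        event_log=event_log,
    )
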