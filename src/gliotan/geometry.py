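"""Computational domain, brain-tissue labelings and heterogeneous diffusion fields.

The model lives on the unit square (interpreted as 1 cm x 1 cm of brain
tissue) discretized with a node-centered uniform grid.  Tissue heterogeneity
enters only through space-dependent diffusion coefficients: gray matter
damps motility/diffusion of every species by a large factor relative to
white matter, the corpus callosum (CC) is a white-matter corridor joining
two hemispheres, and blood vessels are node masks that act purely as source
supports (drug / neutrophil entry sites), not as flow models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# tissue labels
WHITE = 0
GRAY = 1
CC = 2
VESSEL = 3

_LABELS = {"white": WHITE, "gray": GRAY, "cc": CC, "vessel_lumen": VESSEL}

GEOMETRY_KINDS = (
    "uniform_white",
    "wrinkle",
    "star",
    "vessel_horizontal",
    "vessel_vertical",
    "cc_two_hemisphere",
)


@dataclass(frozen=True)
class DomainGrid:
    """Node-centered uniform grid on [0,1]^2.

    ``nx, ny`` are node counts along x and y; spacings ``hx = 1/(nx-1)``.
    The default 101x101 grid gives hx = hy = 0.01.
    """

    nx: int = 101
    ny: int = 101

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid needs at least 3 nodes per axis")

    @property
    def hx(self) -> float:
        return 1.0 / (self.nx - 1)

    @property
    def hy(self) -> float:
        return 1.0 / (self.ny - 1)

    @property
    def shape(self) -> tuple[int, int]:
        # array convention: index [j, i] = (row=y, col=x)
        return (self.ny, self.nx)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.nx)

    @property
    def y(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.ny)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of shape (ny, nx)."""
        return np.meshgrid(self.x, self.y)

    @property
    def cell_area(self) -> float:
        return self.hx * self.hy

    def node_volumes(self) -> np.ndarray:
        """Control-volume area per node: boundary nodes own half cells, so
        the volumes tile [0,1]^2 exactly (trapezoidal quadrature weights)."""
        wx = np.full(self.nx, self.hx)
        wx[0] = wx[-1] = self.hx / 2.0
        wy = np.full(self.ny, self.hy)
        wy[0] = wy[-1] = self.hy / 2.0
        return np.outer(wy, wx)


@dataclass
class TissueMap:
    """Per-node tissue labels plus the derived region masks.

    ``labels`` holds one of WHITE/GRAY/CC/VESSEL per node.  ``omega_minus`` /
    ``omega_plus`` are the left/right hemispheres when the two-hemisphere
    geometry is active (empty masks otherwise), ``omega_cc`` the corridor,
    ``vessel`` the vessel lumen nodes.
    """

    grid: DomainGrid
    labels: np.ndarray
    kind: str = "uniform_white"
    omega_minus: np.ndarray = field(default=None)  # type: ignore[assignment]
    omega_plus: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.labels.shape != self.grid.shape:
            raise ValueError("label array does not match grid shape")
        zeros = np.zeros(self.grid.shape, dtype=bool)
        if self.omega_minus is None:
            self.omega_minus = zeros.copy()
        if self.omega_plus is None:
            self.omega_plus = zeros.copy()

    @property
    def white(self) -> np.ndarray:
        return self.labels == WHITE

    @property
    def gray(self) -> np.ndarray:
        return self.labels == GRAY

    @property
    def omega_cc(self) -> np.ndarray:
        return self.labels == CC

    @property
    def vessel(self) -> np.ndarray:
        return self.labels == VESSEL

    def interface_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """The interface Gamma: faces whose two adjacent nodes differ in label.

        Returns boolean arrays for vertical faces (between x-neighbors,
        shape (ny, nx-1)) and horizontal faces (between y-neighbors,
        shape (ny-1, nx)).
        """
        lab = self.labels
        return lab[:, 1:] != lab[:, :-1], lab[1:, :] != lab[:-1, :]


def _check_inset(center: tuple[float, float], extent: float) -> None:
    cx, cy = center
    if not (0.0 <= cx - extent and cx + extent <= 1.0 and 0.0 <= cy - extent and cy + extent <= 1.0):
        raise ValueError(f"inset (center={center}, extent={extent}) exceeds the unit square")


def build_tissue_map(kind: str, grid: DomainGrid | None = None, **geom_params) -> TissueMap:
    """Construct one of the archetypal tissue geometries.

    Parameters
    ----------
    kind
        One of ``uniform_white`` (all white matter), ``wrinkle`` (a sinuous
        white-matter fold surrounded by gray matter), ``star`` (a star-shaped
        white-matter region with ``valleys`` lobes inside gray matter),
        ``vessel_horizontal`` / ``vessel_vertical`` (the wrinkle geometry with
        a straight blood-vessel strip through the domain center), and
        ``cc_two_hemisphere`` (two white-matter hemispheres separated by a
        gray septum, joined by a corpus-callosum corridor).
    geom_params
        Shape parameters; all have defaults.  ``corridor_half_width`` (cc),
        ``septum_half_width`` (cc), ``band_center``, ``band_amplitude``,
        ``band_half_width`` (wrinkle), ``valleys``, ``r0``, ``r1`` (star),
        ``vessel_half_width`` (vessels).

    The wrinkle/star shapes are parameterized stand-ins for cortical folds:
    the archetypes are illustrative, so their dimensions are tunable rather
    than fixed.
    """
    if grid is None:
        grid = DomainGrid()
    if kind not in GEOMETRY_KINDS:
        raise ValueError(f"unknown geometry kind {kind!r}; choose from {GEOMETRY_KINDS}")
    X, Y = grid.meshgrid()
    labels = np.full(grid.shape, WHITE, dtype=np.int8)
    omega_minus = omega_plus = None

    if kind == "uniform_white":
        pass

    elif kind in ("wrinkle", "vessel_horizontal", "vessel_vertical"):
        # single cortical fold: white band of half-width wb around a sinuous
        # center line, gray matter elsewhere
        y0 = geom_params.get("band_center", 0.5)
        amp = geom_params.get("band_amplitude", 0.12)
        wb = geom_params.get("band_half_width", 0.16)
        _check_inset((0.5, y0), amp + wb)
        yc = y0 - amp * np.sin(np.pi * X)
        labels[:] = GRAY
        labels[np.abs(Y - yc) <= wb] = WHITE
        if kind == "vessel_horizontal":
            vw = geom_params.get("vessel_half_width", 0.01)
            labels[np.abs(Y - 0.5) <= vw] = VESSEL
        elif kind == "vessel_vertical":
            vw = geom_params.get("vessel_half_width", 0.01)
            labels[np.abs(X - 0.5) <= vw] = VESSEL

    elif kind == "star":
        k = int(geom_params.get("valleys", 3))
        if k < 2:
            raise ValueError("star needs at least 2 valleys")
        r0 = geom_params.get("r0", 0.25)
        r1 = geom_params.get("r1", 0.15)
        if r1 >= r0:
            raise ValueError("star requires r1 < r0")
        _check_inset((0.5, 0.5), r0 + r1)
        R = np.hypot(X - 0.5, Y - 0.5)
        TH = np.arctan2(Y - 0.5, X - 0.5)
        labels[:] = GRAY
        labels[R <= r0 + r1 * np.cos(k * TH)] = WHITE

    elif kind == "cc_two_hemisphere":
        w = geom_params.get("corridor_half_width", 0.05)
        sw = geom_params.get("septum_half_width", 0.05)
        margin = geom_params.get("hemisphere_margin", 0.02)
        labels[:] = GRAY
        left = (X < 0.5 - sw) & (X > margin) & (Y > margin) & (Y < 1 - margin)
        right = (X > 0.5 + sw) & (X < 1 - margin) & (Y > margin) & (Y < 1 - margin)
        labels[left | right] = WHITE
        corridor = (np.abs(Y - 0.5) <= w) & (np.abs(X - 0.5) <= sw)
        labels[corridor] = CC
        omega_minus = left
        omega_plus = right

    return TissueMap(grid=grid, labels=labels, kind=kind,
                     omega_minus=omega_minus, omega_plus=omega_plus)


def diffusion_field(D_white: float, tissue: TissueMap, gray_factor: float = 1e-6) -> np.ndarray:
    """Space-dependent diffusion coefficient induced by the tissue labeling.

    White matter, CC and vessel nodes take the white-matter coefficient
    ``D_white``; gray matter nodes take ``gray_factor * D_white`` (the
    default contrast is a factor 1e-6, i.e. gray matter is effectively
    impermeable on the simulated time scales).
    """
    if D_white <= 0:
        raise ValueError("D_white must be strictly positive")
    D = np.full(tissue.grid.shape, D_white, dtype=float)
    D[tissue.gray] = gray_factor * D_white
    return D


def face_coefficient(D_a, D_b, mode: str = "harmonic"):
    """Symmetric face-averaged coefficient for the conservative flux stencil.

    The harmonic mean 2ab/(a+b) (default) is dominated by the smaller side,
    which prevents spurious flux leaking across the white/gray interface at
    the 1e6-fold contrast; ``mode='arithmetic'`` is offered for comparison.
    Accepts scalars or arrays.
    """
    D_a = np.asarray(D_a, dtype=float)
    D_b = np.asarray(D_b, dtype=float)
    if np.any(D_a <= 0) or np.any(D_b <= 0):
        raise ValueError("face coefficients require strictly positive inputs")
    if mode == "harmonic":
        out = 2.0 * D_a * D_b / (D_a + D_b)
    elif mode == "arithmetic":
        out = 0.5 * (D_a + D_b)
    else:
        raise ValueError(f"unknown averaging mode {mode!r}")
    return float(out) if out.ndim == 0 else out
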