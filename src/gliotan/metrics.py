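"""Scalar and field summaries: population integrals, N2-to-N1 ratio maps,
treatment reductions and TAN compositions."""

from __future__ import annotations

import numpy as np

from .geometry import DomainGrid


def total_population(field: np.ndarray, grid: DomainGrid,
                     region: np.ndarray | None = None) -> float:
    """Grid integral of a density field (cells or g per unit depth).

    Node-centered quadrature with trapezoidal control volumes (boundary
    nodes own half cells), so a constant field c on the unit square
    integrates to exactly c.  ``region`` restricts the integral to a
    boolean node mask; the integral is additive over disjoint regions.
    """
    if field.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    vol = grid.node_volumes()
    if region is None:
        s = (field * vol).sum()
    else:
        if region.shape != grid.shape:
            raise ValueError("region mask shape does not match grid")
        s = (field[region] * vol[region]).sum()
    return float(s)


def sn21r(N1: np.ndarray, N2: np.ndarray, eps: float = 0.01) -> np.ndarray:
    """Pointwise N2-to-N1 balance map N2/(eps + N1).

    A spatial index of pro-tumor immune imbalance; ``eps`` regularizes the
    ratio where N1 vanishes (default 0.01, same density units as N1).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    return np.asarray(N2, dtype=float) / (eps + np.asarray(N1, dtype=float))


def relative_change(treated: float, control: float) -> float:
    """Percent reduction of ``treated`` relative to ``control`` (positive = smaller)."""
    if control <= 0:
        raise ValueError("control must be positive")
    return 100.0 * (control - treated) / control


def composition(N1_hat: float, N2_hat: float) -> tuple[float, float]:
    """(percent N1, percent N2) of the total TAN population."""
    total = N1_hat + N2_hat
    if total <= 0:
        raise ValueError("total TAN population must be positive")
    return 100.0 * N1_hat / total, 100.0 * N2_hat / total


def area_above_threshold(field: np.ndarray, grid: DomainGrid, threshold: float) -> float:
    """Alternative 'tumor size': area (cm^2) where the field exceeds a threshold."""
    if field.shape != grid.shape:
        raise ValueError("field shape does not match grid")
    return float(np.count_nonzero(field > threshold) * grid.cell_area)
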