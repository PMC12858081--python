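"""Model parameters of the glioma/TAN continuum system.

Defaults are the calibrated reference set of the model.  Units follow the
field conventions: densities in cells/cm^3, concentrations in g/cm^3, time
in hours, diffusion in cm^2/h (white-matter values; gray matter is derived
via :func:`gliotan.geometry.diffusion_field`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class ModelParameters:
    # growth & carrying capacities
    r1: float = 8.0e-2      # N1 TAN growth rate, 1/h
    r2: float = 8.0e-2      # N2 TAN growth rate, 1/h
    K1: float = 5.0e6       # N1 carrying capacity, cells/cm^3
    K2: float = 4.0e6       # N2 carrying capacity, cells/cm^3
    w1: float = 1.0e14      # IFN-beta promotion of N1 capacity, cells/g
    w2: float = 1.0e15      # TGF-beta promotion of N2 capacity, cells/g
    # competition / decay / killing
    alpha1: float = 1.5e-8  # killing of N1 by competition with N2, cm^3/(cells h)
    alpha2: float = 0.5e-8  # killing of N2 by competition with N1, cm^3/(cells h)
    mu1: float = 4.01e-2    # N1 decay, 1/h
    mu2: float = 4.01e-2    # N2 decay, 1/h
    beta: float = 1.5e-1    # N2 kill rate by antibody, cm^3/(g h)
    # antibody / cytokines
    lambda_A: float = 2.89e1      # antibody injection rate, g/(cm^3 h)
    mu_A: float = 2.89e-2         # antibody decay, 1/h
    lambda_S: float = 1.386e-8    # IFN-beta secretion rate, g/(cm^3 h)
    mu_S: float = 1.386e-1        # IFN-beta decay, 1/h
    lambda_G: float = 2.8881e-19  # TGF-beta secretion per tumor cell, g/(cells h)
    mu_G: float = 2.8881e-2       # TGF-beta decay, 1/h
    # tumor cells
    r: float = 8.40e-2      # tumor growth rate, 1/h
    rN: float = 1.0         # N2-mediated growth enhancement (dimensionless)
    k: float = 1.0e6        # Hill coefficient of the N2 enhancement, cells/cm^3
    n0: float = 1.0e9       # tumor carrying capacity, cells/cm^3
    mu_n: float = 5.0e-8    # tumor kill rate by N1, cm^3/(cells h)
    # white-matter diffusion coefficients, cm^2/h
    D1: float = 3.96e-6
    D2: float = 3.96e-6
    DA: float = 1.044e-3
    DS: float = 7.668e-2
    DG: float = 7.668e-2
    Dn: float = 3.6e-6

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "rN":
                if v < 0:
                    raise ValueError("rN must be >= 0")
            elif v <= 0:
                raise ValueError(f"parameter {f.name} must be strictly positive")

    def with_overrides(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given parameters replaced."""
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: The 26 parameters swept in the global sensitivity analysis.
SENSITIVITY_PARAMETERS: tuple[str, ...] = (
    "D1", "D2", "DA", "DS", "DG", "Dn",
    "r1", "r2", "K1", "K2", "alpha1", "alpha2", "mu1", "mu2",
    "lambda_A", "mu_A", "lambda_S", "mu_S", "lambda_G", "mu_G",
    "r", "rN", "k", "n0", "mu_n", "beta",
)
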