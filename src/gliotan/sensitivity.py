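"""Global sensitivity analysis: Latin hypercube sampling over the model
parameters and partial rank correlation coefficients (PRCC) of the
population integrals at selected times.

PRCC is the rank-based analogue of partial correlation: inputs and output
are rank-transformed, every other parameter is regressed out of both the
parameter of interest and the output, and the residuals are correlated.
It is invariant under strictly monotone transforms of either side, which
makes it the standard global measure for monotone but nonlinear dynamic
models.  Significance uses the t-statistic with n - 2 - #controlled
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .geometry import DomainGrid
from .params import ModelParameters, SENSITIVITY_PARAMETERS
from .pde import FIELD_NAMES, SolverControls


@dataclass
class ParameterRanges:
    """Per-parameter sampling intervals.

    Defaults span [0.1x, 10x] of each reference value, sampled log-uniformly
    — wide enough to cover the 100-fold perturbation experiments while
    staying in plausible regimes.  ``n_strata`` is the number of
    equal-probability subintervals of the Latin hypercube.
    """

    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    log_scale: bool = True
    n_strata: int = 1000

    @classmethod
    def default(cls, params: ModelParameters | None = None,
                names: tuple[str, ...] = SENSITIVITY_PARAMETERS,
                span: float = 10.0, **kwargs) -> "ParameterRanges":
        params = params or ModelParameters()
        rng = {nm: (getattr(params, nm) / span, getattr(params, nm) * span)
               for nm in names}
        return cls(ranges=rng, **kwargs)

    def __post_init__(self) -> None:
        for nm, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"invalid range for {nm}: [{lo}, {hi}]")
            if self.log_scale and lo <= 0:
                raise ValueError(f"log-scale range for {nm} requires lo > 0")

    @property
    def names(self) -> list[str]:
        return list(self.ranges)


def lhs_sample(ranges: ParameterRanges, n_samples: int, seed: int = 0) -> pd.DataFrame:
    """Latin hypercube sample: each column holds exactly one draw per
    equal-probability stratum, in randomly permuted order."""
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    names = ranges.names
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    U = sampler.random(n=n_samples)  # stratified uniforms in [0,1)
    cols = {}
    for j, nm in enumerate(names):
        lo, hi = ranges.ranges[nm]
        if ranges.log_scale:
            cols[nm] = np.exp(np.log(lo) + U[:, j] * (np.log(hi) - np.log(lo)))
        else:
            cols[nm] = lo + U[:, j] * (hi - lo)
    return pd.DataFrame(cols)


@dataclass
class PRCCResult:
    """PRCC coefficients, p-values and significance stars, indexed by
    (parameter, output, time)."""

    coefficients: pd.DataFrame  # rows = parameters, columns = (output, time)
    p_values: pd.DataFrame
    n_samples: int
    warnings: list[str] = field(default_factory=list)

    def stars(self) -> pd.DataFrame:
        def mark(p):
            return "**" if p < 0.01 else ("*" if p < 0.05 else "")
        return self.p_values.map(mark)

    def table(self) -> str:
        """Rendered significance table: coefficient with star marks."""
        coef = self.coefficients
        stars = self.stars()
        out = coef.round(3).astype(str) + stars
        return out.to_string()


def _rank(a: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, a)


def prcc_single(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PRCC of each column of X with y, controlling for all other columns.

    Returns (coefficients, p_values).  Constant columns (undefined ranks)
    yield coefficient 0 with p-value 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y must have aligned rows")
    if n <= p + 2:
        raise ValueError(f"need more than p+2={p + 2} samples for p-values, got {n}")
    Xr = _rank(X)
    yr = stats.rankdata(y)
    coefs = np.zeros(p)
    pvals = np.ones(p)
    dof = n - 2 - (p - 1)
    for j in range(p):
        xj = Xr[:, j]
        if np.ptp(xj) == 0 or np.ptp(yr) == 0:
            continue
        Z = np.column_stack([np.ones(n), np.delete(Xr, j, axis=1)])
        rx = xj - Z @ np.linalg.lstsq(Z, xj, rcond=None)[0]
        ry = yr - Z @ np.linalg.lstsq(Z, yr, rcond=None)[0]
        denom = np.sqrt((rx @ rx) * (ry @ ry))
        if denom == 0:
            continue
        rho = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
        coefs[j] = rho
        if abs(rho) < 1.0:
            t = rho * np.sqrt(dof / (1.0 - rho ** 2))
            pvals[j] = 2.0 * stats.t.sf(abs(t), dof)
        else:
            pvals[j] = 0.0
    return coefs, pvals


def prcc(X: pd.DataFrame | np.ndarray, Y: pd.DataFrame | np.ndarray) -> PRCCResult:
    """PRCC of every parameter column of X against every output column of Y."""
    if isinstance(X, pd.DataFrame):
        pnames = list(X.columns)
        Xa = X.to_numpy()
    else:
        Xa = np.asarray(X, dtype=float)
        pnames = [f"x{j}" for j in range(Xa.shape[1])]
    if isinstance(Y, pd.DataFrame):
        onames = list(Y.columns)
        Ya = Y.to_numpy()
    else:
        Ya = np.asarray(Y, dtype=float)
        if Ya.ndim == 1:
            Ya = Ya[:, None]
        onames = [f"y{j}" for j in range(Ya.shape[1])]
    warnings = []
    coefs = np.zeros((Xa.shape[1], Ya.shape[1]))
    pvals = np.ones_like(coefs)
    for c in range(Ya.shape[1]):
        coefs[:, c], pvals[:, c] = prcc_single(Xa, Ya[:, c])
    for j, nm in enumerate(pnames):
        if np.ptp(Xa[:, j]) == 0:
            warnings.append(f"constant parameter column {nm}: PRCC reported as 0")
    return PRCCResult(
        coefficients=pd.DataFrame(coefs, index=pnames, columns=onames),
        p_values=pd.DataFrame(pvals, index=pnames, columns=onames),
        n_samples=Xa.shape[0],
        warnings=warnings,
    )


def run_sensitivity(ranges: ParameterRanges | None = None,
                    times: tuple[float, ...] = (1.0, 50.0, 100.0),
                    n_samples: int = 50, seed: int = 0,
                    grid: DomainGrid | None = None,
                    controls: SolverControls | None = None,
                    scenario: str = "sensitivity_baseline",
                    layout_seed: int = 0) -> PRCCResult:
    """One model run per LHS sample; PRCC of the six population integrals
    at each requested time against every sampled parameter.

    The default scenario keeps every source pathway active (antibody and
    IFN-beta dosing) so that all 26 parameters can express an effect.  The
    output columns are named ``{field}@{time}``.  Failed runs are excluded
    and reported in ``PRCCResult.warnings``.
    """
    from .scenarios import run_scenario  # deferred: avoid circular import

    ranges = ranges or ParameterRanges.default()
    grid = grid or DomainGrid(51, 51)
    controls = controls or SolverControls(dt=0.1, keep_states=False)
    sample = lhs_sample(ranges, n_samples, seed=seed)
    t_end = max(times)
    controls.sample_times = tuple(sorted(set(times) | {0.0, t_end}))

    rows, ok_idx, failures = [], [], []
    base = ModelParameters()
    for i in range(len(sample)):
        p = base.with_overrides(**{nm: float(sample.iloc[i][nm]) for nm in ranges.names})
        try:
            res = run_scenario(scenario, seed=layout_seed, grid=grid,
                               controls=controls, params=p, t_end=t_end)
            traj = next(iter(res.arms.values()))
            row = {}
            for tm in times:
                k = int(np.argmin(np.abs(traj.times - tm)))
                for f in FIELD_NAMES:
                    row[f"{f}@{tm:g}"] = traj.populations[f][k]
            rows.append(row)
            ok_idx.append(i)
        except (FloatingPointError, RuntimeError, ValueError) as exc:  # pragma: no cover
            failures.append(f"sample {i}: {exc}")
    Y = pd.DataFrame(rows)
    result = prcc(sample.iloc[ok_idx], Y)
    result.warnings.extend(failures)
    if failures:
        result.warnings.append(f"{len(failures)} failed runs excluded")
    return result
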