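"""Parameter estimation: SSQ objective, exponent bounds, Saltelli-sampled
multistart, bounded trust-region least-squares refinement.

The calibration strategy is sample-then-refine: unknown rate constants can
span orders of magnitude, so bounds are given as base-10 exponents and the
space is swept uniformly in log10 with a Saltelli design of N×(2D+2)
quasi-random points built on the Sobol sequence.  Every sample is scored
by the sum of squared differences between model prediction and data; the
best-ranked starts are refined with bounded trust-region least squares
(the Levenberg–Marquardt family; termination tolerances ftol = xtol = 1e-8
by default), which steps inside the box by shaping the trust region by the
distance to the bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .core import CompositeModel, ModelError, SimulationSpec, SubModel, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "FitSpec",
    "FitResult",
    "objective_ssq",
    "exponent_bounds_to_linear",
    "saltelli_design",
    "multistart_fit",
]


@dataclass
class Dataset:
    """An observed or synthetic time course for one observable.

    ``observable`` is the (namespaced) species the rows refer to.  ``sigma``
    is an optional per-point standard deviation (µM) used as weights.
    """

    observable: str
    times: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    provenance: str = "user"  # "fixture" | "synthetic" | "user"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ModelError("Dataset times/values length mismatch")
        if not np.all(np.diff(self.times) > 0):
            raise ModelError("Dataset times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ModelError("Dataset values must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.times.shape:
                raise ModelError("Dataset sigma length mismatch")

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = {"time_s": self.times, "value_uM": self.values}
        if self.sigma is not None:
            cols["sigma_uM"] = self.sigma
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path, observable: str, provenance: str = "user") -> "Dataset":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            observable=observable,
            times=df["time_s"].to_numpy(),
            values=df["value_uM"].to_numpy(),
            sigma=df["sigma_uM"].to_numpy() if "sigma_uM" in df else None,
            provenance=provenance,
        )


@dataclass
class FitSpec:
    """What to fit: free parameters with exponent bounds, datasets, sampler
    scale and refinement tolerances."""

    free: dict[str, tuple[float, float]]  # param -> (lo_exp, hi_exp)
    datasets: list[Dataset]
    fixed: dict[str, float] = field(default_factory=dict)
    n_scale: int = 8          # Saltelli scaling factor N
    top_k: int = 5            # starts refined after ranking
    ftol: float = 1e-8
    xtol: float = 1e-8
    gtol: float = 1e-8
    diff_step: float = 1e-5   # finite-difference step in log10 space
    max_nfev: int = 3000
    sim: SimulationSpec | None = None
    weights: dict[int, float] | None = None  # optional per-dataset weights

    def __post_init__(self) -> None:
        if not self.free:
            raise ModelError("FitSpec needs at least one free parameter")
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ModelError(f"parameters both free and fixed: {sorted(overlap)}")
        if self.n_scale < 1:
            raise ModelError("sampler scaling factor N must be >= 1")
        for name, (lo, hi) in self.free.items():
            if not lo < hi:
                raise ModelError(f"{name}: lower exponent must be < upper")
        if not self.datasets:
            raise ModelError("FitSpec needs at least one dataset")


@dataclass
class FitResult:
    """One refined calibration outcome."""

    estimates: dict[str, float]
    ssq: float
    start_rank: int
    converged: bool
    n_iterations: int

    def __post_init__(self) -> None:
        if self.ssq < 0:
            raise ModelError("ssq must be >= 0")


def objective_ssq(predicted: Sequence[float], observed: Sequence[float],
                  sigma: Sequence[float] | None = None) -> float:
    """Sum of squared differences S = Σᵢ (xᵢ − x̄ᵢ)² (µM²).

    With ``sigma`` given, each difference is divided by its standard
    deviation first (weighted SSQ).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ModelError("objective_ssq: length mismatch")
    if predicted.size < 1:
        raise ModelError("objective_ssq: need at least one point")
    diff = predicted - observed
    if sigma is not None:
        diff = diff / np.asarray(sigma, dtype=float)
    return float(np.sum(diff * diff))


def exponent_bounds_to_linear(lower_exp: float, upper_exp: float
                              ) -> tuple[float, float]:
    """Map base-10 exponent bounds to linear units: (−3, 2) → (1e−3, 1e2)."""
    if not lower_exp < upper_exp:
        raise ModelError(
            f"reversed exponent bounds ({lower_exp}, {upper_exp})"
        )
    return 10.0 ** lower_exp, 10.0 ** upper_exp


def saltelli_design(n_scale: int, dims: int,
                    bounds: Sequence[tuple[float, float]],
                    seed: int = 0) -> np.ndarray:
    """Saltelli cross-sampling design: exactly N×(2D+2) rows, D columns.

    Built from a scrambled Sobol base sequence in 2D dimensions split into
    matrices A and B, plus the D column-swapped matrices ABᵢ (A with column
    i from B) and BAᵢ.  Values are uniform in exponent (log10) space within
    ``bounds``; the returned table holds exponents.  Deterministic for a
    given seed.
    """
    if n_scale < 1 or dims < 1:
        raise ModelError("saltelli_design requires N >= 1 and D >= 1")
    bounds = list(bounds)
    if len(bounds) != dims:
        raise ModelError("saltelli_design: one (lo, hi) exponent pair per dimension")
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if not np.all(lo < hi):
        raise ModelError("saltelli_design: invalid bounds (lower >= upper)")

    import warnings

    with warnings.catch_warnings():
        # Sobol balance warning for non-power-of-two N is expected here
        warnings.simplefilter("ignore", UserWarning)
        base = qmc.Sobol(2 * dims, scramble=True, seed=seed).random(n_scale)
    A, B = base[:, :dims], base[:, dims:]
    blocks = [A, B]
    for i in range(dims):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
    for i in range(dims):
        BA = B.copy()
        BA[:, i] = A[:, i]
        blocks.append(BA)
    unit = np.vstack(blocks)
    assert unit.shape == (n_scale * (2 * dims + 2), dims)
    return lo + unit * (hi - lo)


def _predict(model, overrides: Mapping[str, float], datasets: list[Dataset],
             sim: SimulationSpec) -> list[np.ndarray]:
    """Simulate once on the union of dataset time grids and extract each
    observable at its own times."""
    all_times = np.unique(np.concatenate([d.times for d in datasets]))
    if all_times[0] > sim.t_start:
        grid = np.concatenate([[sim.t_start], all_times])
    else:
        grid = all_times
    spec = SimulationSpec(t_start=sim.t_start, t_end=max(sim.t_end, grid[-1]),
                          output_times=grid, rel_tol=sim.rel_tol,
                          abs_tol=sim.abs_tol, method=sim.method)
    ts = simulate(model, spec, overrides)
    out = []
    for d in datasets:
        col = ts[_canonical(model, d.observable)]
        idx = np.searchsorted(grid, d.times)
        out.append(col[idx])
    return out


def _canonical(model, name: str) -> str:
    if isinstance(model, SubModel):
        return name
    return model.canonical(name) if name in model.alias else name


def multistart_fit(model: CompositeModel | SubModel, spec: FitSpec,
                   seed: int = 0) -> list[FitResult]:
    """Rank a Saltelli sweep by SSQ, refine the best starts, sort by final
    SSQ.

    Simulation failures score +∞ and are logged; the run continues.  If
    every sample fails the result list is empty (with a logged diagnostic).
    Refinement operates in log10-parameter space within the exponent
    bounds and never returns a worse SSQ than its start point.
    """
    if isinstance(model, SubModel):
        from .core import compose

        model = compose([model], name=model.name)
    sim = spec.sim or SimulationSpec(rel_tol=1e-7, abs_tol=1e-10)
    names = list(spec.free)
    bounds = [spec.free[n] for n in names]
    weights = spec.weights or {}

    def score(exps: np.ndarray) -> float:
        overrides = dict(spec.fixed)
        overrides.update({n: 10.0 ** e for n, e in zip(names, exps)})
        try:
            preds = _predict(model, overrides, spec.datasets, sim)
        except Exception as err:  # simulation failure at this sample
            logger.warning("sample %s failed: %s", dict(zip(names, exps)), err)
            return np.inf
        return sum(weights.get(i, 1.0) * objective_ssq(p, d.values, d.sigma)
                   for i, (p, d) in enumerate(zip(preds, spec.datasets)))

    samples = saltelli_design(spec.n_scale, len(names), bounds, seed=seed)
    ssqs = np.array([score(s) for s in samples])
    order = np.argsort(ssqs)
    if not np.isfinite(ssqs[order[0]]):
        logger.warning("all %d samples failed to simulate", len(samples))
        return []

    def residuals(exps: np.ndarray) -> np.ndarray:
        overrides = dict(spec.fixed)
        overrides.update({n: 10.0 ** e for n, e in zip(names, exps)})
        preds = _predict(model, overrides, spec.datasets, sim)
        out = []
        for i, (p, d) in enumerate(zip(preds, spec.datasets)):
            r = p - d.values
            if d.sigma is not None:
                r = r / d.sigma
            out.append(np.sqrt(weights.get(i, 1.0)) * r)
        return np.concatenate(out)

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    results = []
    for rank in range(min(spec.top_k, int(np.isfinite(ssqs).sum()))):
        x0 = samples[order[rank]]
        start_ssq = ssqs[order[rank]]
        try:
            # diff_step well above the integrator's relative error (else the
            # finite-difference Jacobian is solver noise); 3-point stencil and
            # Jacobian scaling keep progress along near-degenerate ridges
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                ftol=spec.ftol, xtol=spec.xtol, gtol=spec.gtol,
                                diff_step=spec.diff_step, x_scale="jac",
                                jac="3-point", max_nfev=spec.max_nfev)
            final_ssq = float(np.sum(sol.fun ** 2))
            if final_ssq <= start_ssq:
                est_exp, converged, nit = sol.x, bool(sol.success), sol.nfev
            else:  # refinement may not worsen the start point
                est_exp, converged, nit = x0, False, sol.nfev
                final_ssq = start_ssq
        except Exception as err:
            logger.warning("refinement from rank %d failed: %s", rank, err)
            est_exp, converged, nit, final_ssq = x0, False, 0, start_ssq
        results.append(FitResult(
            estimates={n: 10.0 ** e for n, e in zip(names, est_exp)},
            ssq=final_ssq,
            start_rank=rank,
            converged=converged,
            n_iterations=int(nit),
        ))
    results.sort(key=lambda r: r.ssq)
    return results
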