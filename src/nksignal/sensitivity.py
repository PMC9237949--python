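"""One-at-a-time sensitivity sweeps, error-landscape classification, and
the feasible-parameter census.

OAT sweeps vary one parameter over its (log10) range with all others held
at a reference (best-fit) point and record the SSQ error against data at
each grid point.  The resulting error curve is classified:

* ``sensitive`` — interior minimum: the data pin the parameter down;
* ``edge_minimum`` — the minimum sits at (or within ``edge_margin`` grid
  steps of) a bound: the model changes on one side of the minimum only,
  so the parameter may be varied within the flat region in later fits;
* ``flat`` — the error barely moves: the model is insensitive and the
  parameter is free in subsequent calibrations.

The census asks a different question: over the full joint parameter space
(Saltelli-sampled), which parameter combinations predict cytokine
concentrations that stay physiologically plausible — within a multiplier
(default 2) of the experimental mean at every checked time?  Such accepted
sets are alternative parameterisations consistent with cell function, a
direct probe of non-uniqueness of the best fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .calibration import Dataset, objective_ssq, saltelli_design, _predict
from .core import CompositeModel, ModelError, SimulationSpec, SubModel, compose, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "OATProfile",
    "Classification",
    "AcceptanceBand",
    "CensusResult",
    "oat_sweep",
    "classify",
    "find_alternate_solutions",
]


@dataclass
class OATProfile:
    """Error landscape of one parameter: SSQ over a log-spaced grid."""

    parameter: str
    exponents: np.ndarray
    errors: np.ndarray
    reference_value: float

    def __post_init__(self) -> None:
        self.exponents = np.asarray(self.exponents, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if self.exponents.shape != self.errors.shape:
            raise ModelError("OATProfile grid/error length mismatch")
        if np.any(self.errors[np.isfinite(self.errors)] < 0):
            raise ModelError("OATProfile errors must be >= 0")


@dataclass
class Classification:
    """Three-way sensitivity label with its supporting statistics."""

    label: str  # "sensitive" | "edge_minimum" | "flat"
    argmin_exponent: float
    relative_range: float


@dataclass
class AcceptanceBand:
    """Per-cytokine experimental mean ± sd (µM) and acceptance multiplier.

    A parameter set is physiologically feasible when each observable stays
    within [0, multiplier × mean] at every checked time (inclusive)."""

    means: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)
    multiplier: float = 2.0

    def __post_init__(self) -> None:
        for name, m in self.means.items():
            if m <= 0:
                raise ModelError(f"acceptance band mean for {name!r} must be > 0")

    def upper(self, observable: str) -> float:
        return self.multiplier * self.means[observable]


@dataclass
class CensusResult:
    """Outcome of a feasible-parameter census."""

    accepted: list[dict[str, float]]
    ssqs: list[float]
    n_sampled: int
    n_failed: int
    seed: int


def oat_sweep(model: CompositeModel | SubModel,
              datasets: Sequence[Dataset],
              parameter: str,
              bounds: tuple[float, float],
              reference: Mapping[str, float] | None = None,
              grid_size: int = 25,
              sim: SimulationSpec | None = None) -> OATProfile:
    """Sweep one parameter over a log-spaced grid, others held at the
    reference point; grid points whose simulation fails score +∞."""
    if isinstance(model, SubModel):
        model = compose([model], name=model.name)
    lo, hi = bounds
    if not lo < hi:
        raise ModelError(f"oat_sweep: invalid exponent bounds ({lo}, {hi})")
    sim = sim or SimulationSpec(rel_tol=1e-7, abs_tol=1e-10)
    reference = dict(reference or {})
    ref_value = reference.get(parameter, model.value_of(parameter))
    grid = np.linspace(lo, hi, grid_size)
    errors = np.empty(grid_size)
    datasets = list(datasets)
    for i, e in enumerate(grid):
        overrides = dict(reference)
        overrides[parameter] = 10.0 ** e
        try:
            preds = _predict(model, overrides, datasets, sim)
            errors[i] = sum(objective_ssq(p, d.values, d.sigma)
                            for p, d in zip(preds, datasets))
        except Exception as err:
            logger.warning("oat %s = 1e%g failed: %s", parameter, e, err)
            errors[i] = np.inf
    return OATProfile(parameter, grid, errors, ref_value)


def classify(profile: OATProfile, flat_tol: float = 0.01,
             edge_margin: int = 1) -> Classification:
    """Label an error landscape flat / edge_minimum / sensitive.

    flat when (max − min)/max(min, ε) < ``flat_tol``; edge_minimum when the
    argmin lies within ``edge_margin`` grid steps of a boundary; otherwise
    sensitive (interior minimum).  Invariant under uniform rescaling of
    the error curve.
    """
    finite = np.isfinite(profile.errors)
    if not finite.any():
        raise ModelError(
            f"profile for {profile.parameter!r}: no finite error values"
        )
    errs = np.where(finite, profile.errors, np.inf)
    emin = float(errs.min())
    emax = float(profile.errors[finite].max())
    eps = 1e-300
    rel_range = (emax - emin) / max(emin, eps) if emax > emin else 0.0
    i_min = int(np.argmin(errs))
    argmin_exp = float(profile.exponents[i_min])
    n = len(errs)
    if rel_range < flat_tol:
        label = "flat"
    elif i_min <= edge_margin or i_min >= n - 1 - edge_margin:
        label = "edge_minimum"
    else:
        label = "sensitive"
    return Classification(label, argmin_exp, rel_range)


def find_alternate_solutions(model: CompositeModel | SubModel,
                             bounds: Mapping[str, tuple[float, float]],
                             band: AcceptanceBand,
                             check_times: Sequence[float],
                             observables: Mapping[str, str],
                             n_scale: int = 8,
                             seed: int = 0,
                             datasets: Sequence[Dataset] = (),
                             sim: SimulationSpec | None = None,
                             fixed: Mapping[str, float] | None = None
                             ) -> CensusResult:
    """Census of physiologically feasible parameter combinations.

    Saltelli-samples the joint exponent space in ``bounds``; each sampled
    set is simulated and accepted when every observable named in
    ``observables`` (cytokine name → species) stays within
    [0, multiplier×mean] at every ``check_times`` point, bounds inclusive.
    Accepted sets are returned with their SSQ against ``datasets`` (NaN
    when no data given), sorted by SSQ.  Simulation failures are logged
    and rejected; the census is reproducible for a fixed seed.
    """
    if isinstance(model, SubModel):
        model = compose([model], name=model.name)
    names = list(bounds)
    sim = sim or SimulationSpec(rel_tol=1e-7, abs_tol=1e-10)
    check_times = np.asarray(sorted(check_times), dtype=float)
    samples = saltelli_design(n_scale, len(names),
                              [bounds[n] for n in names], seed=seed)
    grid = check_times if check_times[0] == sim.t_start else np.concatenate(
        [[sim.t_start], check_times])
    spec = SimulationSpec(t_start=sim.t_start,
                          t_end=max(sim.t_end, check_times[-1]),
                          output_times=grid, rel_tol=sim.rel_tol,
                          abs_tol=sim.abs_tol, method=sim.method)
    idx = np.searchsorted(grid, check_times)
    accepted, ssqs, n_failed = [], [], 0
    datasets = list(datasets)
    for row in samples:
        overrides = dict(fixed or {})
        overrides.update({n: 10.0 ** e for n, e in zip(names, row)})
        try:
            ts = simulate(model, spec, overrides)
        except Exception as err:
            logger.warning("census sample failed: %s", err)
            n_failed += 1
            continue
        ok = True
        for cname, species in observables.items():
            pred = ts[model.canonical(species)][idx]
            if np.any(pred < 0) or np.any(pred > band.upper(cname)):
                ok = False
                break
        if not ok:
            continue
        if datasets:
            ssq = 0.0
            for d in datasets:
                col = ts[model.canonical(d.observable)]
                ssq += objective_ssq(np.interp(d.times, ts.times, col),
                                     d.values, d.sigma)
        else:
            ssq = float("nan")
        accepted.append({n: 10.0 ** e for n, e in zip(names, row)})
        ssqs.append(ssq)
    if datasets:
        order = np.argsort(ssqs)
        accepted = [accepted[i] for i in order]
        ssqs = [ssqs[i] for i in order]
    return CensusResult(accepted, ssqs, len(samples), n_failed, seed)
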