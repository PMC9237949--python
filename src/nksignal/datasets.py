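"""Packaged fixtures, unit conversion and synthetic time-course generation.

The experimental time courses the pathway was originally fitted to were
digitized from figures in the primary literature and are not printed
anywhere in the pathway description, so they cannot be redistributed.
What *is* printed — every parameter table, initial-condition table,
exponent-bound table and the cytokine mean/sd table — ships here as a
structured text fixture (``data/tables.yaml``), including flagged
conflicting duplicate values, which are stored verbatim on both readings
rather than resolved.

For calibration and sensitivity work the synthetic generator stands in
for the digitized data: it simulates a model at known parameters, adds
seeded Gaussian noise, and embeds the generating-parameter hash so tests
can verify provenance exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .calibration import Dataset
from .core import CompositeModel, ModelError, SimulationSpec, SubModel, simulate

__all__ = [
    "Fixture",
    "NoiseModel",
    "load_fixture",
    "list_fixtures",
    "pg_per_ml_to_micromolar",
    "generate_synthetic_timecourse",
]

#: column names in the printed tables use "NFAT Cycling equation(s)/…"; the
#: package uses the submodel name NFAT_cycling throughout.


@dataclass
class Fixture:
    """One published table: values plus units, provenance notes and any
    flagged discrepancies with other tables."""

    table_id: str
    title: str
    units: str
    values: dict
    provenance: dict = field(default_factory=dict)
    notes: str = ""
    conflicts: dict = field(default_factory=dict)


def _load_tables() -> dict:
    with resources.files("nksignal.data").joinpath("tables.yaml").open() as fh:
        return yaml.safe_load(fh)


_TABLES = None


def _tables() -> dict:
    global _TABLES
    if _TABLES is None:
        _TABLES = _load_tables()
    return _TABLES


def list_fixtures() -> list[str]:
    return sorted(k for k in _tables() if k != "conflicts")


def load_fixture(table_id: str) -> Fixture:
    """Load a published table by id (T1, T2, T3, ..., T11).

    Values known to conflict between tables (k_f2, k_f4, k_r4) carry both
    readings in ``Fixture.conflicts``.
    """
    tables = _tables()
    if table_id not in tables or table_id == "conflicts":
        raise KeyError(f"unknown fixture table {table_id!r}; "
                       f"available: {list_fixtures()}")
    entry = tables[table_id]
    conflicts = {k: v for k, v in tables.get("conflicts", {}).items()
                 if table_id in v.get("readings", {})}
    return Fixture(
        table_id=table_id,
        title=entry.get("title", ""),
        units=entry.get("units", ""),
        values=entry["values"],
        provenance=entry.get("provenance", {}),
        notes=entry.get("notes", ""),
        conflicts=conflicts,
    )


def pg_per_ml_to_micromolar(density_pg_per_ml: float,
                            molar_mass_g_per_mol: float) -> float:
    """Convert a mass density to molarity: cᵢ = ρᵢ / Mᵢ.

    pg/ml → g/L (×1e-9), divided by g/mol gives mol/L, ×1e6 gives µM;
    net factor 1e-3/M.
    """
    if molar_mass_g_per_mol <= 0:
        raise ModelError(
            f"molar mass must be > 0 g/mol, got {molar_mass_g_per_mol}"
        )
    if density_pg_per_ml < 0:
        raise ModelError("density must be >= 0")
    grams_per_litre = density_pg_per_ml * 1e-9
    mol_per_litre = grams_per_litre / molar_mass_g_per_mol
    return mol_per_litre * 1e6


@dataclass
class NoiseModel:
    """Additive Gaussian measurement noise.

    ``sigma`` is in µM, or a fraction of the signal when
    ``relative=True`` (heteroscedastic option).  The true digitization
    error structure of the original data is unknown; additive Gaussian is
    the neutral default.
    """

    sigma: float = 0.0
    relative: bool = False
    seed: int = 0
    kind: str = "gaussian-additive"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ModelError("noise sigma must be >= 0")
        if self.kind != "gaussian-additive":
            raise ModelError(f"unknown noise kind {self.kind!r}")


def generate_synthetic_timecourse(model: CompositeModel | SubModel,
                                  observables: Sequence[str],
                                  times: Sequence[float],
                                  noise: NoiseModel | None = None,
                                  overrides: Mapping[str, float] | None = None,
                                  sim: SimulationSpec | None = None
                                  ) -> list[Dataset]:
    """Simulate and sample observables at given times with seeded noise.

    Returns one synthetic :class:`Dataset` per observable, provenance
    ``"synthetic"``, with the generating-parameter hash in the metadata
    so downstream code can verify exactly which parameters produced it.
    """
    from .core import compose

    if isinstance(model, SubModel):
        model = compose([model], name=model.name)
    noise = noise or NoiseModel()
    times = np.asarray(sorted(times), dtype=float)
    sim = sim or SimulationSpec(rel_tol=1e-9, abs_tol=1e-12)
    grid = times if times[0] == sim.t_start else np.concatenate(
        [[sim.t_start], times])
    spec = SimulationSpec(t_start=sim.t_start, t_end=max(sim.t_end, times[-1]),
                          output_times=grid, rel_tol=sim.rel_tol,
                          abs_tol=sim.abs_tol, method=sim.method)
    ts = simulate(model, spec, overrides)
    idx = np.searchsorted(grid, times)
    rng = np.random.default_rng(noise.seed)
    phash = hashlib.sha256(
        (ts.metadata["parameters_hash"] + repr(sorted((overrides or {}).items()))
         ).encode()).hexdigest()[:16]
    out = []
    for obs in observables:
        clean = ts[model.canonical(obs)][idx]
        if noise.sigma > 0:
            scale = noise.sigma * (np.abs(clean) if noise.relative else 1.0)
            values = clean + rng.normal(0.0, 1.0, clean.shape) * scale
            sigma = np.broadcast_to(np.maximum(scale, 1e-300), clean.shape).copy()
        else:
            values, sigma = clean, None
        out.append(Dataset(
            observable=obs,
            times=times,
            values=values,
            sigma=sigma,
            provenance="synthetic",
            metadata={"generator_hash": phash, "noise_sigma": noise.sigma,
                      "noise_relative": noise.relative, "seed": noise.seed},
        ))
    return out
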