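"""Modular mass-action modelling core.

Sub-models are self-contained bundles of species, parameters and reactions
with named *ports*.  Ports are wired together by :class:`PortMapping` objects
and :func:`compose` flattens a set of sub-models into a single
:class:`CompositeModel` whose ODE system is assembled by stoichiometry ×
flux and integrated with a stiff-capable solver.

Conventions (package-wide): concentrations in µM, time in s, first-order
rate constants in s⁻¹, bimolecular constants in µM⁻¹·s⁻¹.  Parameters are
namespaced ``submodel/symbol`` after composition because symbol names are
re-used across sub-models.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "Parameter",
    "RateLaw",
    "Reaction",
    "SubModel",
    "PortMapping",
    "CompositeModel",
    "SimulationSpec",
    "TimeSeries",
    "ModelError",
    "CompositionError",
    "SimulationError",
    "ConfigError",
    "register_rate",
    "mass_action_flux",
    "hill_flux",
    "compose",
    "assemble_odes",
    "simulate",
    "conserved_totals",
    "submodel_to_dict",
    "submodel_from_dict",
    "save_submodel_yaml",
    "load_submodel_yaml",
]


class ModelError(ValueError):
    """Invalid model structure or state."""


class CompositionError(ModelError):
    """Port wiring failed (dangling port, unit mismatch, double mapping)."""


class SimulationError(RuntimeError):
    """Integrator failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class ConfigError(ValueError):
    """Malformed structured-text model configuration."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Species:
    """A chemical state variable.

    ``clamped`` species are held constant during integration (used for the
    phosphate pool Pi, which the pathway treats as a fixed-concentration
    parameter, and for externally imposed drives).
    """

    name: str
    compartment: str = "cell"
    initial_concentration: float = 0.0
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ModelError(
                f"species {self.name!r}: initial concentration must be >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass
class Parameter:
    """A rate constant or scalar model input.

    ``bound_exponents`` are base-10 exponents (lo, hi): a parameter with
    bounds (-3, 2) is searched between 1e-3 and 1e2 during calibration.
    """

    name: str
    value: float
    status: str = "fixed"  # "fixed" | "fit"
    bound_exponents: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.status not in ("fixed", "fit"):
            raise ModelError(f"parameter {self.name!r}: bad status {self.status!r}")
        if self.bound_exponents is not None:
            lo, hi = self.bound_exponents
            if not lo < hi:
                raise ModelError(
                    f"parameter {self.name!r}: lower exponent must be < upper, "
                    f"got ({lo}, {hi})"
                )
            if self.status == "fit" and not (10.0 ** lo <= self.value <= 10.0 ** hi):
                raise ModelError(
                    f"parameter {self.name!r}: value {self.value} outside "
                    f"[1e{lo}, 1e{hi}]"
                )


class RateLaw(str, Enum):
    MASS_ACTION_IRREVERSIBLE = "mass_action_irreversible"
    MASS_ACTION_REVERSIBLE = "mass_action_reversible"
    HILL = "hill"
    CUSTOM = "custom"


#: registry of named custom rate laws: name -> (fn, species names, param names)
_RATE_REGISTRY: dict[str, tuple[Callable[..., float], tuple[str, ...], tuple[str, ...]]] = {}


def register_rate(name: str, species: Sequence[str], params: Sequence[str]):
    """Register a named custom rate law.

    The decorated function receives the listed species concentrations then
    the listed parameter values, positionally, and returns a (possibly
    signed) net flux in µM·s⁻¹.  Registration by name keeps custom laws
    round-trippable through the text configuration format.
    """

    def deco(fn: Callable[..., float]):
        _RATE_REGISTRY[name] = (fn, tuple(species), tuple(params))
        return fn

    return deco


def get_rate_law(name: str):
    try:
        return _RATE_REGISTRY[name]
    except KeyError:
        raise ConfigError(f"unknown custom rate law {name!r}") from None


@dataclass
class Reaction:
    """A reaction with stoichiometry and a rate law.

    ``constants`` maps rate-law roles to parameter names local to the
    sub-model: ``{"k": ...}`` (irreversible), ``{"kf": ..., "kr": ...}``
    (reversible), ``{"vmax": ..., "k": ..., "n": ...}`` (Hill, substrate =
    sole reactant).  ``modifiers`` enter mass-action rate laws as catalysts
    (multiply the rate) without being consumed.  ``law=CUSTOM`` instead
    names a registered rate function via ``rate_fn``.
    """

    id: str
    reactants: dict[str, float] = field(default_factory=dict)
    products: dict[str, float] = field(default_factory=dict)
    modifiers: tuple[str, ...] = ()
    law: RateLaw = RateLaw.MASS_ACTION_IRREVERSIBLE
    constants: dict[str, str] = field(default_factory=dict)
    rate_fn: str | None = None

    def __post_init__(self) -> None:
        self.law = RateLaw(self.law)
        need = {
            RateLaw.MASS_ACTION_IRREVERSIBLE: {"k"},
            RateLaw.MASS_ACTION_REVERSIBLE: {"kf", "kr"},
            RateLaw.HILL: {"vmax", "k", "n"},
            RateLaw.CUSTOM: set(),
        }[self.law]
        if self.law is RateLaw.CUSTOM:
            if not self.rate_fn:
                raise ModelError(f"reaction {self.id!r}: custom law needs rate_fn")
        elif set(self.constants) != need:
            raise ModelError(
                f"reaction {self.id!r}: law {self.law.value} requires constants "
                f"{sorted(need)}, got {sorted(self.constants)}"
            )
        if self.law is RateLaw.HILL and len(self.reactants) != 1:
            raise ModelError(f"reaction {self.id!r}: Hill law needs one substrate")

    def species_referenced(self) -> set[str]:
        refs = set(self.reactants) | set(self.products) | set(self.modifiers)
        if self.law is RateLaw.CUSTOM:
            _, sp, _ = get_rate_law(self.rate_fn)
            refs |= set(sp)
        return refs

    def params_referenced(self) -> set[str]:
        if self.law is RateLaw.CUSTOM:
            _, _, pp = get_rate_law(self.rate_fn)
            return set(pp)
        return set(self.constants.values())


@dataclass
class SubModel:
    """A self-contained model component exposing named ports.

    Ports name species or parameters that may be wired to other sub-models
    when composing; everything else is private to the component.
    """

    name: str
    species: list[Species]
    parameters: list[Parameter]
    reactions: list[Reaction]
    ports: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            raise ModelError(f"submodel {self.name!r}: duplicate species names")
        pnames = [p.name for p in self.parameters]
        if len(pnames) != len(set(pnames)):
            raise ModelError(f"submodel {self.name!r}: duplicate parameter names")
        sset, pset = set(names), set(pnames)
        for r in self.reactions:
            missing = r.species_referenced() - sset
            if missing:
                raise ModelError(
                    f"submodel {self.name!r}, reaction {r.id!r}: unknown species "
                    f"{sorted(missing)}"
                )
            missing_p = r.params_referenced() - pset
            if missing_p:
                raise ModelError(
                    f"submodel {self.name!r}, reaction {r.id!r}: unresolved "
                    f"constants {sorted(missing_p)}"
                )
        for port in self.ports:
            if port not in sset and port not in pset:
                raise ModelError(f"submodel {self.name!r}: port {port!r} references nothing")

    # convenience lookups -------------------------------------------------
    def species_map(self) -> dict[str, Species]:
        return {s.name: s for s in self.species}

    def parameter_map(self) -> dict[str, Parameter]:
        return {p.name: p for p in self.parameters}

    def port_kind(self, port: str) -> str:
        if port not in self.ports:
            raise CompositionError(f"submodel {self.name!r} has no port {port!r}")
        return "species" if port in self.species_map() else "parameter"


@dataclass
class PortMapping:
    """Wire two ports together.

    ``identity`` merges the two variables into one shared state (species) or
    one shared value (parameters).  ``flux_coupling`` makes the *target
    parameter* track ``gain × [source species]`` at every instant — used
    where one component's output rescales another's rate (e.g. active PLC
    scaling IP3 synthesis).
    """

    source: tuple[str, str]
    target: tuple[str, str]
    mode: str = "identity"  # "identity" | "flux_coupling"
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("identity", "flux_coupling"):
            raise CompositionError(f"unknown mapping mode {self.mode!r}")


@dataclass
class SimulationSpec:
    """Integration settings: span, output grid, tolerances, method."""

    t_start: float = 0.0
    t_end: float = 3600.0
    output_times: np.ndarray | None = None
    rel_tol: float = 1e-9
    abs_tol: float = 1e-9
    method: str = "LSODA"
    n_points: int = 201  # used when output_times is None

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ModelError("t_end must be > t_start")
        if self.output_times is not None:
            t = np.asarray(self.output_times, dtype=float)
            if t.min() < self.t_start or t.max() > self.t_end:
                raise ModelError("output_times must lie within [t_start, t_end]")
            self.output_times = t

    def grid(self) -> np.ndarray:
        if self.output_times is not None:
            return self.output_times
        return np.linspace(self.t_start, self.t_end, self.n_points)


@dataclass
class TimeSeries:
    """A trajectory: one row per output time, one column per species (µM)."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, n_species)
    species: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.times.size, len(self.species)):
            raise ModelError("TimeSeries shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ModelError("TimeSeries contains non-finite values")

    def __getitem__(self, species: str) -> np.ndarray:
        try:
            return self.values[:, self.species.index(species)]
        except ValueError:
            raise KeyError(species) from None

    def total(self, group: Sequence[str]) -> np.ndarray:
        """Summed concentration of a species group at each output time."""
        if not group:
            raise ModelError("empty species group")
        return sum(self[s] for s in group)

    def to_csv(self, path_or_buf) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.species)
        df.insert(0, "time_s", self.times)
        df.to_csv(path_or_buf, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path_or_buf) -> "TimeSeries":
        import pandas as pd

        df = pd.read_csv(path_or_buf)
        if df.columns[0] != "time_s":
            raise ConfigError("trajectory CSV must start with a 'time_s' column")
        return cls(
            times=df["time_s"].to_numpy(),
            values=df.iloc[:, 1:].to_numpy(),
            species=list(df.columns[1:]),
        )


# --------------------------------------------------------------------------
# flux primitives
# --------------------------------------------------------------------------

def mass_action_flux(reaction: Reaction, state: Mapping[str, float],
                     constants: Mapping[str, float]) -> float:
    """Net mass-action flux of one reaction at a state (µM·s⁻¹).

    Irreversible: k·Π[reactants]; reversible: kf·Π[reactants] − kr·Π[products].
    Modifiers multiply the forward rate.  Stoichiometric coefficients enter
    as powers.
    """
    for name in reaction.species_referenced():
        if name not in state:
            raise ModelError(f"reaction {reaction.id!r}: missing species {name!r}")
        if state[name] < 0:
            raise ModelError(
                f"reaction {reaction.id!r}: negative concentration for {name!r}"
            )

    def prod(side: dict[str, float]) -> float:
        out = 1.0
        for name, stoich in side.items():
            out *= state[name] ** stoich
        for name in reaction.modifiers:
            out *= state[name]
        return out

    if reaction.law is RateLaw.MASS_ACTION_IRREVERSIBLE:
        return constants["k"] * prod(reaction.reactants)
    if reaction.law is RateLaw.MASS_ACTION_REVERSIBLE:
        fwd = constants["kf"] * prod(reaction.reactants)
        rev = constants["kr"] * 1.0
        for name, stoich in reaction.products.items():
            rev *= state[name] ** stoich
        return fwd - rev
    raise ModelError(f"mass_action_flux: reaction {reaction.id!r} is not mass-action")


def hill_flux(C: float, VMP: float, Kp: float, np_: float) -> float:
    """Hill-saturating flux VMP·Cⁿ/(Kpⁿ + Cⁿ), e.g. the SERCA-type Ca²⁺ pump."""
    if Kp <= 0:
        raise ModelError(f"Hill law: Kp must be > 0, got {Kp}")
    if np_ <= 0:
        raise ModelError(f"Hill law: np must be > 0, got {np_}")
    if C < 0:
        raise ModelError(f"Hill law: negative substrate concentration {C}")
    if C == 0.0:
        return 0.0
    cn = C ** np_
    return VMP * cn / (Kp ** np_ + cn)


# --------------------------------------------------------------------------
# composition
# --------------------------------------------------------------------------

def _qual(sm: str, name: str) -> str:
    return f"{sm}/{name}"


@dataclass
class CompositeModel:
    """A flattened model produced by :func:`compose`.

    Species and parameters carry namespaced names ``submodel/symbol``.
    ``alias`` maps every namespaced variable name (including merged ones) to
    its canonical state name; ``couplings`` holds flux-coupling links
    (target parameter → (canonical source species, gain)).
    """

    name: str
    submodels: list[SubModel]
    mappings: list[PortMapping]
    species: list[Species]            # canonical, namespaced
    parameters: dict[str, Parameter]  # namespaced name -> Parameter
    reactions: list[tuple[str, Reaction]]  # (submodel name, reaction)
    alias: dict[str, str]
    param_alias: dict[str, str]
    couplings: dict[str, tuple[str, float]]

    def canonical(self, name: str) -> str:
        """Resolve a (possibly merged) namespaced species name."""
        try:
            return self.alias[name]
        except KeyError:
            raise ModelError(f"unknown species {name!r}") from None

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def parameter_value(self, name: str) -> float:
        return self.parameters[self.param_alias.get(name, name)].value

    def value_of(self, name: str) -> float:
        """Value of a parameter, or the initial concentration of a species
        (clamped species double as constant-valued inputs, e.g. Pi)."""
        key = self.param_alias.get(name, name)
        if key in self.parameters:
            return self.parameters[key].value
        canon = self.alias.get(name)
        for sp in self.species:
            if sp.name == canon:
                return sp.initial_concentration
        raise ModelError(f"unknown parameter or species {name!r}")


def compose(submodels: Sequence[SubModel],
            mappings: Sequence[PortMapping] = (),
            name: str = "composite") -> CompositeModel:
    """Flatten sub-models wired through port mappings into one model.

    Identity-mapped species collapse to a single state (the source's name is
    canonical); identity-mapped parameters share the source's value.
    Flattening preserves the total reaction count.
    """
    by_name = {sm.name: sm for sm in submodels}
    if len(by_name) != len(submodels):
        raise CompositionError("duplicate submodel names")

    # validate mappings and collect merges
    parent: dict[str, str] = {}  # union-find over namespaced species names

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    param_alias: dict[str, str] = {}
    couplings: dict[str, tuple[str, float]] = {}
    identity_targets: set[str] = set()

    for m in mappings:
        for end, (sm_name, port) in (("source", m.source), ("target", m.target)):
            if sm_name not in by_name:
                raise CompositionError(f"mapping {end} references unknown submodel {sm_name!r}")
            by_name[sm_name].port_kind(port)  # raises on dangling port
        skind = by_name[m.source[0]].port_kind(m.source[1])
        tkind = by_name[m.target[0]].port_kind(m.target[1])
        if m.mode == "identity":
            if skind != tkind:
                raise CompositionError(
                    f"identity mapping units disagree: {m.source} is a {skind}, "
                    f"{m.target} is a {tkind}"
                )
            tq = _qual(*m.target)
            if tq in identity_targets:
                raise CompositionError(f"port {tq!r} is the target of two identity mappings")
            identity_targets.add(tq)
            if skind == "species":
                sq = _qual(*m.source)
                parent[find(tq)] = find(sq)
            else:
                param_alias[_qual(*m.target)] = _qual(*m.source)
        else:  # flux_coupling
            if skind != "species" or tkind != "parameter":
                raise CompositionError(
                    "flux_coupling requires a species source and a parameter target"
                )
            couplings[_qual(*m.target)] = (_qual(*m.source), m.gain)

    # canonicalise species
    alias: dict[str, str] = {}
    merged: dict[str, Species] = {}
    for sm in submodels:
        for sp in sm.species:
            q = _qual(sm.name, sp.name)
            root = find(q)
            alias[q] = root
            if root not in merged:
                merged[root] = Species(root, sp.compartment,
                                       sp.initial_concentration, sp.clamped)
    # second pass: merge ICs/clamps of non-canonical members
    for sm in submodels:
        for sp in sm.species:
            q = _qual(sm.name, sp.name)
            root = alias[q]
            if root == q:
                continue
            tgt = merged[root]
            if sp.clamped:
                tgt.clamped = True
            if sp.initial_concentration != 0.0:
                if tgt.initial_concentration not in (0.0, sp.initial_concentration):
                    raise CompositionError(
                        f"merged species {root!r}: conflicting initial conditions "
                        f"({tgt.initial_concentration} vs {sp.initial_concentration})"
                    )
                tgt.initial_concentration = sp.initial_concentration

    # resolve parameter aliases transitively
    def resolve_param(q: str) -> str:
        seen = set()
        while q in param_alias:
            if q in seen:
                raise CompositionError(f"cyclic parameter mapping at {q!r}")
            seen.add(q)
            q = param_alias[q]
        return q

    parameters: dict[str, Parameter] = {}
    for sm in submodels:
        for p in sm.parameters:
            q = _qual(sm.name, p.name)
            if resolve_param(q) == q:
                parameters[q] = Parameter(q, p.value, p.status, p.bound_exponents)
    param_alias = {k: resolve_param(k) for k in param_alias}

    for tgt in couplings:
        if resolve_param(tgt) != tgt or tgt not in parameters:
            raise CompositionError(f"flux_coupling target {tgt!r} is not a free parameter")

    reactions = [(sm.name, r) for sm in submodels for r in sm.reactions]
    assert len(reactions) == sum(len(sm.reactions) for sm in submodels)

    # canonical couplings sources
    couplings = {t: (alias[s], g) for t, (s, g) in couplings.items()}

    ordered = [merged[alias[_qual(sm.name, sp.name)]]
               for sm in submodels for sp in sm.species
               if alias[_qual(sm.name, sp.name)] == _qual(sm.name, sp.name)]
    return CompositeModel(
        name=name,
        submodels=list(submodels),
        mappings=list(mappings),
        species=ordered,
        parameters=parameters,
        reactions=reactions,
        alias=alias,
        param_alias=param_alias,
        couplings=couplings,
    )


# --------------------------------------------------------------------------
# ODE assembly
# --------------------------------------------------------------------------

class ODESystem:
    """Compiled derivative contract: ``rhs(t, y) -> dy/dt``.

    d[s]/dt = Σ_r stoich(s, r)·J_r; clamped species have zero derivative.
    Concentrations are clipped at zero inside rate evaluation only (the
    guard is reported via ``clip_triggered``, never silently applied to
    output).
    """

    def __init__(self, model: CompositeModel,
                 overrides: Mapping[str, float] | None = None):
        self.model = model
        self.species_names = model.species_names()
        self.index = {n: i for i, n in enumerate(self.species_names)}
        n_s = len(self.species_names)
        n_r = len(model.reactions)

        overrides = dict(overrides or {})
        # split overrides into parameter overrides and IC overrides
        pvals: dict[str, float] = {q: p.value for q, p in model.parameters.items()}
        y0 = np.array([sp.initial_concentration for sp in model.species])
        self.clamped = np.array([sp.clamped for sp in model.species])
        for key, val in overrides.items():
            if key in model.parameters or key in model.param_alias:
                pvals[model.param_alias.get(key, key)] = float(val)
            elif key in model.alias:
                y0[self.index[model.alias[key]]] = float(val)
            else:
                raise ModelError(f"override target {key!r} is neither parameter nor species")
        if (y0 < 0).any():
            raise ModelError("initial conditions must be >= 0")
        self.y0 = y0
        self.param_values = pvals

        # stoichiometry matrix
        S = np.zeros((n_s, n_r))
        compiled = []
        for j, (sm_name, r) in enumerate(model.reactions):
            def gidx(local: str) -> int:
                return self.index[model.alias[_qual(sm_name, local)]]

            def gpar(local: str) -> str:
                q = _qual(sm_name, local)
                return model.param_alias.get(q, q)

            for sp, st in r.reactants.items():
                S[gidx(sp), j] -= st
            for sp, st in r.products.items():
                S[gidx(sp), j] += st

            if r.law is RateLaw.CUSTOM:
                fn, sp_names, p_names = get_rate_law(r.rate_fn)
                sidx = np.array([gidx(s) for s in sp_names], dtype=int)
                pkeys = [gpar(p) for p in p_names]
                compiled.append(("custom", fn, sidx, pkeys))
            elif r.law is RateLaw.HILL:
                (sub, _), = r.reactants.items()
                compiled.append(("hill", gidx(sub),
                                 [gpar(r.constants["vmax"]),
                                  gpar(r.constants["k"]),
                                  gpar(r.constants["n"])]))
            else:
                ridx = np.array([gidx(s) for s in r.reactants], dtype=int)
                rpow = np.array([r.reactants[s] for s in r.reactants])
                midx = np.array([gidx(s) for s in r.modifiers], dtype=int)
                if r.law is RateLaw.MASS_ACTION_IRREVERSIBLE:
                    compiled.append(("ma_irr", ridx, rpow, midx, gpar(r.constants["k"])))
                else:
                    pidx = np.array([gidx(s) for s in r.products], dtype=int)
                    ppow = np.array([r.products[s] for s in r.products])
                    compiled.append(("ma_rev", ridx, rpow, midx, pidx, ppow,
                                     gpar(r.constants["kf"]), gpar(r.constants["kr"])))
        self.S = S
        self._compiled = compiled
        self._couplings = [(model.param_alias.get(t, t), self.index[src], gain)
                           for t, (src, gain) in model.couplings.items()]
        self.clip_triggered = False
        self._abs_tol = 1e-9
        self._ntol = [-1e-9]  # mutable: shared with the generated closure
        self._fast_rhs = None

    # -- code-generated fast path ----------------------------------------
    def _codegen_rhs(self):
        """Compile the derivative into a single scalar-arithmetic function.

        Generic interpreted evaluation (see :meth:`fluxes`) costs hundreds
        of µs per call on numpy overhead alone, which dominates long stiff
        integrations of the oscillating composite; the generated closure
        evaluates the same fluxes in a few µs.  Parameter values are baked
        in as literals, so the function is regenerated per ODESystem.
        """
        model = self.model
        n_s = len(self.species_names)
        p = self.param_values
        # coupling-overridden parameters become locals computed from state
        coupled = {key: f"pc{i}" for i, (key, _, _) in enumerate(self._couplings)}

        def pexpr(key: str) -> str:
            return coupled.get(key, repr(float(p[key])))

        env: dict = {"np": np}
        lines = ["def _rhs(t, y):"]
        for i in range(n_s):
            lines.append(f"    y{i} = y[{i}]")
            lines.append(f"    if y{i} < 0.0:")
            lines.append(f"        if y{i} < _ntol[0]: _clip()")
            lines.append(f"        y{i} = 0.0")
        for i, (key, sidx, gain) in enumerate(self._couplings):
            lines.append(f"    pc{i} = {gain!r} * y{sidx}")

        def monomial(k_expr: str, idx, pow_) -> str:
            terms = [k_expr]
            for ii, pw in zip(idx, pow_):
                terms.append(f"y{ii}" if pw == 1 else f"y{ii}**{pw!r}")
            return "*".join(terms)

        for j, c in enumerate(self._compiled):
            kind = c[0]
            if kind == "ma_irr":
                _, ridx, rpow, midx, k = c
                expr = monomial(pexpr(k), ridx, rpow)
                for ii in midx:
                    expr += f"*y{ii}"
                lines.append(f"    J{j} = {expr}")
            elif kind == "ma_rev":
                _, ridx, rpow, midx, pidx, ppow, kf, kr = c
                fwd = monomial(pexpr(kf), ridx, rpow)
                for ii in midx:
                    fwd += f"*y{ii}"
                rev = monomial(pexpr(kr), pidx, ppow)
                lines.append(f"    J{j} = {fwd} - {rev}")
            elif kind == "hill":
                _, sidx, (vk, kk, nk) = c
                if float(p[kk]) <= 0 or float(p[nk]) <= 0:
                    raise ModelError("Hill law requires Kp > 0 and np > 0")
                lines.append(
                    f"    J{j} = {pexpr(vk)}*y{sidx}**{pexpr(nk)}"
                    f"/({pexpr(kk)}**{pexpr(nk)} + y{sidx}**{pexpr(nk)})"
                    f" if y{sidx} > 0.0 else 0.0"
                )
            else:  # custom
                _, fn, sidx, pkeys = c
                env[f"fn{j}"] = fn
                args = [f"y{ii}" for ii in sidx] + [pexpr(k) for k in pkeys]
                lines.append(f"    J{j} = fn{j}({', '.join(args)})")

        derivs = []
        for i in range(n_s):
            if self.clamped[i]:
                derivs.append("0.0")
                continue
            terms = []
            for j in range(len(self._compiled)):
                coef = self.S[i, j]
                if coef == 1:
                    terms.append(f"+J{j}")
                elif coef == -1:
                    terms.append(f"-J{j}")
                elif coef != 0:
                    terms.append(f"+{coef!r}*J{j}")
            derivs.append("".join(terms) if terms else "0.0")
        lines.append("    return np.array((%s))" % ", ".join(derivs))

        def _clip():
            self.clip_triggered = True

        env["_clip"] = _clip
        env["_ntol"] = self._ntol
        exec("\n".join(lines), env)
        return env["_rhs"]

    # -- evaluation -------------------------------------------------------
    def fluxes(self, y: np.ndarray) -> np.ndarray:
        """Per-reaction net fluxes at state y (µM·s⁻¹)."""
        if (y < -self._abs_tol).any():
            self.clip_triggered = True
        yc = np.maximum(y, 0.0)
        p = self.param_values
        if self._couplings:
            p = dict(p)
            for tgt, sidx, gain in self._couplings:
                p[tgt] = gain * yc[sidx]
        J = np.empty(len(self._compiled))
        for j, c in enumerate(self._compiled):
            kind = c[0]
            if kind == "ma_irr":
                _, ridx, rpow, midx, k = c
                J[j] = p[k] * np.prod(yc[ridx] ** rpow) * np.prod(yc[midx])
            elif kind == "ma_rev":
                _, ridx, rpow, midx, pidx, ppow, kf, kr = c
                J[j] = (p[kf] * np.prod(yc[ridx] ** rpow) * np.prod(yc[midx])
                        - p[kr] * np.prod(yc[pidx] ** ppow))
            elif kind == "hill":
                _, sidx, (vk, kk, nk) = c
                J[j] = hill_flux(yc[sidx], p[vk], p[kk], p[nk])
            else:  # custom
                _, fn, sidx, pkeys = c
                J[j] = fn(*yc[sidx], *(p[k] for k in pkeys))
        return J

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        if self._fast_rhs is None:
            self._fast_rhs = self._codegen_rhs()
        return self._fast_rhs(t, y)

    def rhs_reference(self, t: float, y: np.ndarray) -> np.ndarray:
        """Interpreted derivative (slow path); used to cross-check the
        generated fast path."""
        dydt = self.S @ self.fluxes(y)
        dydt[self.clamped] = 0.0
        return dydt


def assemble_odes(model: CompositeModel,
                  overrides: Mapping[str, float] | None = None) -> ODESystem:
    """Compile a composite model into an :class:`ODESystem`."""
    return ODESystem(model, overrides)


def simulate(model: CompositeModel | SubModel,
             spec: SimulationSpec,
             overrides: Mapping[str, float] | None = None) -> TimeSeries:
    """Integrate a model on the spec's output grid.

    A bare :class:`SubModel` is wrapped in a trivial composite, so species
    columns are always namespaced ``submodel/species``.
    """
    if isinstance(model, SubModel):
        model = compose([model], name=model.name)
    system = assemble_odes(model, overrides)
    system._abs_tol = spec.abs_tol
    system._ntol[0] = -spec.abs_tol
    grid = spec.grid()
    sol = solve_ivp(
        system.rhs,
        (spec.t_start, spec.t_end),
        system.y0,
        method=spec.method,
        t_eval=grid,
        rtol=spec.rel_tol,
        atol=spec.abs_tol,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else None
        raise SimulationError(
            f"integrator failed for model {model.name!r}: {sol.message}", last_time=last
        )
    phash = hashlib.sha256(
        repr(sorted(system.param_values.items())).encode()
    ).hexdigest()[:16]
    return TimeSeries(
        times=sol.t,
        values=sol.y.T,
        species=model.species_names(),
        metadata={
            "model": model.name,
            "parameters_hash": phash,
            "clip_triggered": system.clip_triggered,
            "rel_tol": spec.rel_tol,
            "abs_tol": spec.abs_tol,
            "method": spec.method,
        },
    )


def conserved_totals(ts: TimeSeries,
                     moieties: Mapping[str, Sequence[str]]) -> dict[str, float]:
    """Max relative drift |total(t) − total(0)| / total(0) per moiety group."""
    out = {}
    for name, group in moieties.items():
        if not group:
            raise ModelError(f"moiety {name!r}: empty species group")
        tot = ts.total(group)
        ref = tot[0]
        if ref == 0.0:
            out[name] = float(np.max(np.abs(tot)))
        else:
            out[name] = float(np.max(np.abs(tot - ref)) / abs(ref))
    return out


# --------------------------------------------------------------------------
# structured-text configuration round-trip
# --------------------------------------------------------------------------

def submodel_to_dict(sm: SubModel) -> dict:
    return {
        "name": sm.name,
        "species": [
            {"name": s.name, "compartment": s.compartment,
             "initial_concentration": s.initial_concentration, "clamped": s.clamped}
            for s in sm.species
        ],
        "parameters": [
            {"name": p.name, "value": p.value, "status": p.status,
             **({"bound_exponents": list(p.bound_exponents)}
                if p.bound_exponents else {})}
            for p in sm.parameters
        ],
        "reactions": [
            {"id": r.id, "reactants": dict(r.reactants), "products": dict(r.products),
             "modifiers": list(r.modifiers), "law": r.law.value,
             "constants": dict(r.constants),
             **({"rate_fn": r.rate_fn} if r.rate_fn else {})}
            for r in sm.reactions
        ],
        "ports": list(sm.ports),
    }


def submodel_from_dict(d: dict) -> SubModel:
    try:
        return SubModel(
            name=d["name"],
            species=[Species(s["name"], s.get("compartment", "cell"),
                             s.get("initial_concentration", 0.0),
                             s.get("clamped", False)) for s in d["species"]],
            parameters=[Parameter(p["name"], p["value"], p.get("status", "fixed"),
                                  tuple(p["bound_exponents"])
                                  if p.get("bound_exponents") else None)
                        for p in d["parameters"]],
            reactions=[Reaction(r["id"], dict(r.get("reactants", {})),
                                dict(r.get("products", {})),
                                tuple(r.get("modifiers", ())),
                                RateLaw(r.get("law", "mass_action_irreversible")),
                                dict(r.get("constants", {})),
                                r.get("rate_fn")) for r in d["reactions"]],
            ports=list(d.get("ports", [])),
        )
    except KeyError as e:
        raise ConfigError(f"submodel config missing key {e}") from None


def save_submodel_yaml(sm: SubModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(submodel_to_dict(sm), fh, sort_keys=False)


def load_submodel_yaml(path) -> SubModel:
    if isinstance(path, io.IOBase):
        return submodel_from_dict(yaml.safe_load(path))
    with open(path) as fh:
        return submodel_from_dict(yaml.safe_load(fh))
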