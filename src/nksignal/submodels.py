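"""Re-used level-1 sub-models: the IP3/Ca²⁺ oscillator and the NFAT
futile cycle.

Ca²⁺ oscillator
---------------
Cytosolic calcium follows

    d[Ccyto]/dt = k_1·(b + Ira)·(Catot − Ccyto·(α+1)) − VMP·Ccyto^np/(Kp^np + Ccyto^np)

where Ira is the fraction of active IP3-receptor channels, α the
store/cytosol volume ratio, b a basal leak fraction, and the second term a
Hill-type SERCA pump.  The channel dynamics use the standard two-gate
reduction of the IP3 receptor: Ira relaxes quickly toward m∞³·h³ (m∞ the
instantaneous IP3/Ca activation) while h carries slow Ca²⁺-dependent
inactivation — fast positive and slow negative feedback, which is what
produces the oscillation.  IP3 metabolism comprises PLC-driven synthesis
(scalable by an upstream ``stimulus`` port), a Ca²⁺-activated 3-kinase
converting IP3 to IP4 (maximal velocity ``V3k``), and a first-order
5-phosphatase.  Zeroing V3k removes the IP4 branch entirely: Ca²⁺
oscillations persist but IP3 settles to the flat balance of synthesis and
5-phosphatase, and IP4 stays at zero.

The numerical constants for the receptor gates and IP3 turnover are
package defaults tuned once to the physiological oscillatory regime
(sub-µM calcium, ~0.4 µM IP3, period of tens of seconds); they are shipped
in ``data/ca_oscillator.yaml`` and every value is overridable.

NFAT futile cycle
-----------------
Four pools — phosphorylated/dephosphorylated × cytosolic/nuclear — cycle
through dephosphorylation by active calcineurin (CaN), nuclear import,
nuclear rephosphorylation and export:

    J1 = kf_21·NFATp_c·N_tot·act_N − kr_21·NFATN_c·(1 − act_N)
    J2 = kf_22·NFATN_c
    J3 = kf_23·NFATN_n − kr_23·NFATp_n·N_tot·act_N
    J4 = kf_24·NFATp_n

Translocations (J2, J4) have no back reactions, so total NFAT is exactly
conserved.  act_N (fraction of activated CaN, 0–1) is an input port: left
undriven it is clamped at its initial value; the composite pathway drives
it from cytosolic Ca²⁺.  The reverse term of J3 is taken as bimolecular
with active CaN, which is the reading consistent with kr_23 carrying
µM⁻¹·s⁻¹ units.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .core import (
    ModelError,
    Parameter,
    RateLaw,
    Reaction,
    Species,
    SubModel,
    register_rate,
)

CA_NAME = "dupont_Ca"
NFAT_NAME = "NFAT_cycling"


def _load_defaults(fname: str) -> dict:
    with resources.files("nksignal.data").joinpath(fname).open() as fh:
        return yaml.safe_load(fh)


_CA = _load_defaults("ca_oscillator.yaml")
_NFAT = _load_defaults("nfat_defaults.yaml")


# --------------------------------------------------------------------------
# Ca2+ oscillator
# --------------------------------------------------------------------------

@dataclass
class CaParams:
    """Ca²⁺ sub-model constants (concentrations µM, times s).

    The printed-equation constants are k_1, b, alpha, VMP, Kp, np; the
    receptor-gate constants (d1, d2, d3, d5, a2, tau_a) and IP3-turnover
    constants (Vplc, V3k, K3k, Km3, r5p, r4p) complete the oscillator.
    """

    k_1: float = _CA["values"]["k_1"]          # s⁻¹, release scale
    b: float = _CA["values"]["b"]              # basal leak fraction
    alpha: float = _CA["values"]["alpha"]      # store/cytosol volume ratio
    VMP: float = _CA["values"]["VMP"]          # µM·s⁻¹, max pump velocity
    Kp: float = _CA["values"]["Kp"]            # µM, pump half-activation
    np: float = _CA["values"]["np"]            # pump Hill coefficient
    Catot: float = _CA["values"]["Catot"]      # µM, total Ca²⁺ (closed cell)
    d1: float = _CA["values"]["d1"]            # µM, receptor IP3 binding
    d2: float = _CA["values"]["d2"]            # µM, Ca²⁺ inactivation
    d3: float = _CA["values"]["d3"]            # µM, IP3 dep. of inactivation
    d5: float = _CA["values"]["d5"]            # µM, Ca²⁺ activation
    a2: float = _CA["values"]["a2"]            # µM⁻¹·s⁻¹, gate rate
    tau_a: float = _CA["values"]["tau_a"]      # s, active-fraction relaxation
    Vplc: float = _CA["values"]["Vplc"]        # µM·s⁻¹, max IP3 synthesis
    stimulus: float = _CA["values"]["stimulus"]  # PLC activity scaling (port)
    V3k: float = _CA["values"]["V3k"]          # µM·s⁻¹, max 3-kinase velocity
    K3k: float = _CA["values"]["K3k"]          # µM, Ca²⁺ half-act. of 3-kinase
    Km3: float = _CA["values"]["Km3"]          # µM, IP3 Km of the 3-kinase
    r5p: float = _CA["values"]["r5p"]          # s⁻¹, 5-phosphatase rate
    r4p: float = _CA["values"]["r4p"]          # s⁻¹, IP4 degradation rate

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ModelError(f"Ca parameter {name} must be >= 0, got {value}")
        if self.np < 1:
            raise ModelError("pump Hill coefficient np must be >= 1")


@register_rate("ca_release", species=["Ccyto", "Ira", "Catot"],
               params=["k_1", "b", "alpha"])
def _ca_release(Ccyto, Ira, Catot, k_1, b, alpha):
    return k_1 * (b + Ira) * (Catot - Ccyto * (alpha + 1.0))


@register_rate("ca_ira_relax", species=["Ccyto", "IP3", "h_gate", "Ira"],
               params=["d1", "d5", "tau_a"])
def _ca_ira_relax(Ccyto, IP3, h_gate, Ira, d1, d5, tau_a):
    m_inf = (IP3 / (IP3 + d1)) * (Ccyto / (Ccyto + d5))
    return ((m_inf ** 3) * (h_gate ** 3) - Ira) / tau_a


@register_rate("ca_h_gate", species=["Ccyto", "IP3", "h_gate"],
               params=["a2", "d1", "d2", "d3"])
def _ca_h_gate(Ccyto, IP3, h_gate, a2, d1, d2, d3):
    Q2 = d2 * (IP3 + d1) / (IP3 + d3)
    return a2 * (Q2 - (Q2 + Ccyto) * h_gate)


@register_rate("ip3_synthesis", species=[], params=["Vplc", "stimulus"])
def _ip3_synthesis(Vplc, stimulus):
    return Vplc * stimulus


@register_rate("ip3_3kinase", species=["Ccyto", "IP3"],
               params=["V3k", "K3k", "Km3"])
def _ip3_3kinase(Ccyto, IP3, V3k, K3k, Km3):
    act = Ccyto * Ccyto / (K3k * K3k + Ccyto * Ccyto)
    return V3k * act * IP3 / (Km3 + IP3)


def build_dupont_ca(params: CaParams | None = None,
                    zero_v3k: bool = False,
                    ip3_initial: float | None = None) -> SubModel:
    """Build the Ca²⁺ oscillator sub-model.

    ``zero_v3k=True`` zeroes the IP3 3-kinase (V3k = 0): the IP3→IP4 branch
    vanishes, IP3 stops oscillating while Ca²⁺ oscillations persist.
    ``ip3_initial`` defaults to the synthesis/5-phosphatase balance at the
    resting stimulus (the composite passes 0: no IP3 before receptor
    engagement).  Ports: Ccyto and IP3 (species), stimulus (parameter, for
    upstream PLC coupling).
    """
    params = params or CaParams()
    pdict = dict(params.__dict__)
    if zero_v3k:
        pdict["V3k"] = 0.0
    if ip3_initial is None:
        ip3_initial = (pdict["Vplc"] * pdict["stimulus"] / pdict["r5p"]
                       if pdict["r5p"] > 0 else 0.4)
    ic = _CA["initial_conditions"]
    species = [
        Species("Ccyto", initial_concentration=ic["Ccyto"]),
        Species("Catot", initial_concentration=pdict.pop("Catot"), clamped=True),
        Species("Ira", initial_concentration=ic["Ira"]),
        Species("h_gate", initial_concentration=ic["h_gate"]),
        Species("IP3", initial_concentration=ip3_initial),
        Species("IP4", initial_concentration=0.0),
    ]
    parameters = [Parameter(k, v) for k, v in pdict.items()]
    irr = RateLaw.MASS_ACTION_IRREVERSIBLE
    reactions = [
        Reaction("release", {}, {"Ccyto": 1}, law=RateLaw.CUSTOM, rate_fn="ca_release"),
        Reaction("pump", {"Ccyto": 1}, {}, law=RateLaw.HILL,
                 constants={"vmax": "VMP", "k": "Kp", "n": "np"}),
        Reaction("ira_relax", {}, {"Ira": 1}, law=RateLaw.CUSTOM,
                 rate_fn="ca_ira_relax"),
        Reaction("h_gate_dyn", {}, {"h_gate": 1}, law=RateLaw.CUSTOM,
                 rate_fn="ca_h_gate"),
        Reaction("ip3_syn", {}, {"IP3": 1}, law=RateLaw.CUSTOM,
                 rate_fn="ip3_synthesis"),
        Reaction("ip3_to_ip4", {"IP3": 1}, {"IP4": 1}, law=RateLaw.CUSTOM,
                 rate_fn="ip3_3kinase"),
        Reaction("ip3_5phosphatase", {"IP3": 1}, {}, law=irr, constants={"k": "r5p"}),
        Reaction("ip4_degradation", {"IP4": 1}, {}, law=irr, constants={"k": "r4p"}),
    ]
    return SubModel(
        name=CA_NAME,
        species=species,
        parameters=parameters,
        reactions=reactions,
        ports=["Ccyto", "IP3", "stimulus"],
    )


# --------------------------------------------------------------------------
# NFAT futile cycle
# --------------------------------------------------------------------------

@dataclass
class NFATParams:
    """NFAT cycle constants.  Defaults are the composite-pathway fitted
    values; N_tot and the initial NFAT pool are package defaults (the
    source model's pools are not printed in the pathway description)."""

    kf_21: float = _NFAT["values"]["kf_21"]  # µM⁻¹·s⁻¹, dephosphorylation
    kr_21: float = _NFAT["values"]["kr_21"]  # s⁻¹, reverse (inactive CaN)
    kf_22: float = _NFAT["values"]["kf_22"]  # s⁻¹, nuclear import
    kf_23: float = _NFAT["values"]["kf_23"]  # s⁻¹, nuclear rephosphorylation
    kr_23: float = _NFAT["values"]["kr_23"]  # µM⁻¹·s⁻¹, reverse (active CaN)
    kf_24: float = _NFAT["values"]["kf_24"]  # s⁻¹, nuclear export
    N_tot: float = _NFAT["values"]["N_tot"]  # µM, total calcineurin
    act_N: float = _NFAT["values"]["act_N"]  # initial/clamped active fraction

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ModelError(f"NFAT parameter {name} must be >= 0, got {value}")
        if not 0.0 <= self.act_N <= 1.0:
            raise ModelError("act_N must lie in [0, 1]")


#: default initial NFAT pool (µM): all NFAT starts phosphorylated-cytosolic
NFAT_POOL_UM = float(_NFAT["pool_uM"])


@register_rate("nfat_j1", species=["NFATp_c", "NFATN_c", "act_N"],
               params=["kf_21", "kr_21", "N_tot"])
def _nfat_j1(NFATp_c, NFATN_c, act_N, kf_21, kr_21, N_tot):
    return kf_21 * NFATp_c * N_tot * act_N - kr_21 * NFATN_c * (1.0 - act_N)


@register_rate("nfat_j3", species=["NFATN_n", "NFATp_n", "act_N"],
               params=["kf_23", "kr_23", "N_tot"])
def _nfat_j3(NFATN_n, NFATp_n, act_N, kf_23, kr_23, N_tot):
    return kf_23 * NFATN_n - kr_23 * NFATp_n * N_tot * act_N


def build_nfat_cooling(params: NFATParams | None = None,
                       pool: float = NFAT_POOL_UM,
                       drive_act_n: bool = False) -> SubModel:
    """Build the NFAT futile-cycle sub-model.

    ``pool`` is the total NFAT (µM), all initially phosphorylated-cytosolic.
    With ``drive_act_n=False`` the CaN activation fraction act_N is clamped
    at ``params.act_N``; with ``drive_act_n=True`` it is an unclamped state
    for an upstream connector to drive.  Ports: act_N, NFATN_n and the full
    cycle states.
    """
    params = params or NFATParams()
    species = [
        Species("NFATp_c", initial_concentration=pool),
        Species("NFATN_c"),
        Species("NFATN_n"),
        Species("NFATp_n"),
        Species("act_N", initial_concentration=params.act_N,
                clamped=not drive_act_n),
    ]
    parameters = [Parameter(k, v) for k, v in params.__dict__.items()
                  if k != "act_N"]
    irr = RateLaw.MASS_ACTION_IRREVERSIBLE
    reactions = [
        Reaction("J1", {"NFATp_c": 1}, {"NFATN_c": 1}, law=RateLaw.CUSTOM,
                 rate_fn="nfat_j1"),
        Reaction("J2", {"NFATN_c": 1}, {"NFATN_n": 1}, law=irr,
                 constants={"k": "kf_22"}),
        Reaction("J3", {"NFATN_n": 1}, {"NFATp_n": 1}, law=RateLaw.CUSTOM,
                 rate_fn="nfat_j3"),
        Reaction("J4", {"NFATp_n": 1}, {"NFATp_c": 1}, law=irr,
                 constants={"k": "kf_24"}),
    ]
    return SubModel(
        name=NFAT_NAME,
        species=species,
        parameters=parameters,
        reactions=reactions,
        ports=["act_N", "NFATp_c", "NFATN_c", "NFATN_n", "NFATp_n"],
    )


NFAT_MOIETY = [f"{NFAT_NAME}/{s}"
               for s in ("NFATp_c", "NFATN_c", "NFATN_n", "NFATp_n")]
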