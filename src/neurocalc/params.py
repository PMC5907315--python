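"""Model configuration: parameters, initial conditions, derived constants,
nucleotide pools and scenario presets.

The parameter set is the single source of truth for every rate constant in
the composite model.  Units follow the source tables literally: maximal
transport rates in nmol/(mg·min), concentrations in the compartment's
working unit (cytosolic/mitochondrial/ER Ca2+ in uM, adenine nucleotides and
NADH in mM, amyloid in nM), membrane potential in mV.  The integration
variable ``t`` is the model's displayed time unit; the literal conversion
constants ``uMmM`` and ``tau_min`` appear in the rate expressions exactly as
the model defines them and no further dimensional reconciliation is applied.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field, replace
from typing import Any

from .errors import ConfigurationError, StateDomainError

__all__ = [
    "ModelParameters",
    "InitialState",
    "CompartmentConstants",
    "NucleotidePools",
    "SolverOptions",
    "Scenario",
    "STATE_VARS",
    "derive_compartments",
    "nucleotide_pools",
    "make_scenario",
    "read_config",
    "write_config",
    "PARAM_ALIASES",
    "SCENARIO_NAMES",
]

#: Canonical ordering of the 13 dynamic variables (CSV column order).
STATE_VARS = (
    "CAC", "CAM", "CAER", "a", "PTPh", "PTPl", "y",
    "H_M", "PSI", "NADH_m", "ADP_m", "ADP_i", "h",
)


@dataclass(frozen=True)
class ModelParameters:
    """Every constant of the composite model, with table defaults.

    Attributes
    ----------
    V : float
        Total cell volume (ml).
    uMmM : float
        Literal conversion constant between uM and mM scales (1000).
    tau_min : float
        Literal minutes-to-seconds conversion (60); also used wherever the
        rate tables write ``minute``.
    p_cytosol, p_mito, p_er : float
        Volume fractions of cytosol, mitochondria and ER.
    d_cytosol, d_mito, d_er : float
        Protein densities (mg/ml) of the three compartments.
    c_mito : float
        Mitochondrial membrane capacitance-like constant, nmol/(mV·mg).
    rho_uni, rho_nc : float
        Maximal uniporter and Na+/Ca2+ exchanger rates, nmol/(mg·min).
        ``rho_nc`` is also accepted under the alias ``rho_Na_Ca``.
    rho_res, rho_F1 : float
        Respiration coefficient and F0/F1-ATPase density factor.
    pim : float
        Free matrix phosphate concentration [P_i]_m (mM).
    rho_leak : float
        Proton-leak conductance factor, nmol/(mg·min·mV).
    J_red_basal : float
        Basal NADH reduction rate, nmol/(mg·min).
    J_max_ANT : float
        Maximal adenine-nucleotide-translocator flux, nmol/(mg·min).
    glc : float
        Cytosolic glucose (mM).
    J_hyd_max : float
        Maximal glucose-dependent ATP hydrolysis term (mM scale factor).
    V_IP3 : float
        IP3-receptor maximal release rate (uM scale).
    v_leak : float
        ER leak rate; the source lists this constant twice (as an IP3R leak
        proportion and as an ER leak), both 0.1 — one field backs both
        names (aliases ``V_leak`` and ``J_leak``).
    d_IP3, d_ACT, d_INH : float
        IP3-receptor IP3 sensitivity, Ca2+ activation and Ca2+ inhibition
        constants (uM).
    tau : float
        IP3-receptor inhibition gate time constant.
    V_serca, k_serca : float
        SERCA maximal rate (nmol/(mg·min)) and Ca2+ half-saturation (uM).
    V1, V_alpha, K_alpha, k_beta, K1 : float
        Amyloid kinetics: constant synthesis rate (nM/s), maximal
        Ca2+-stimulated synthesis rate (nM/s), half-saturation (nM), the
        amyloid->Ca2+ entry rate constant, and first-order elimination
        (1/s).
    n, m : int
        Hill coefficient of Ca2+-stimulated amyloid synthesis and the
        cooperativity of the amyloid->Ca2+ entry term.
    f_m, f_i : float
        Mitochondrial and cytosolic fast Ca2+ buffering fractions.
    A_tot_cyt : float
        Total cytosolic adenine nucleotide pool (mM); the closure
        ATP_i = A_tot_cyt - ADP_i mirrors the mitochondrial conservation
        relation.
    s_a : float
        Unit-coupling scale on the amyloid Ca2+-entry term (default 1,
        i.e. the term is applied exactly as printed).
    K_nc : float
        Na+/Ca2+ exchanger Ca2+ half-saturation (uM).  The source writes
        it as 0.003*d_mito, i.e. 3 uM at the default density; it is kept
        as an explicit constant.
    CAM_star : float
        Mitochondrial Ca2+ threshold (uM) of the slow trigger process.
    y_star : float
        Slow-process threshold for high-conductance PTP opening.
    f_HM : float
        Fast proton-buffering constant of the matrix.
    p1, p2, p3, p4, amp_tau, p6 : float
        Shape constants of the low-conductance gate (tanh midpoint/width
        and its time-constant profile).
    perm_H, perm_Ca : float
        PTP permeabilities to protons and Ca2+.
    postptp : float
        Indicator constant switching the PTP Ca2+ flux sign convention
        once the high-conductance state engages.
    """

    # -- global geometry / conversions (Table of general constants)
    V: float = 1.0
    uMmM: float = 1000.0
    tau_min: float = 60.0
    p_cytosol: float = 0.5
    d_cytosol: float = 75.0
    p_mito: float = 0.05
    d_mito: float = 1000.0
    p_er: float = 0.1
    d_er: float = 1000.0
    c_mito: float = 0.0725
    # -- mitochondrial transport and bioenergetics
    rho_uni: float = 300.0
    rho_nc: float = 3.0
    rho_res: float = 0.4
    rho_F1: float = 0.7
    pim: float = 20.0
    rho_leak: float = 0.2
    J_red_basal: float = 20.0
    J_max_ANT: float = 900.0
    glc: float = 1.0
    J_hyd_max: float = 30.1
    # -- ER / IP3 receptor
    V_IP3: float = 3000.0
    v_leak: float = 0.1
    d_IP3: float = 0.25
    d_ACT: float = 1.0
    d_INH: float = 1.4
    tau: float = 4.0
    V_serca: float = 110.0
    k_serca: float = 0.4
    # -- amyloid subsystem
    V1: float = 0.0065
    V_alpha: float = 0.05
    K_alpha: float = 120.0
    k_beta: float = 0.2
    K1: float = 0.01
    n: int = 2
    m: int = 4
    # -- buffering
    f_m: float = 0.0003
    f_i: float = 0.01
    # -- closures chosen where the source is silent (see docs/methods.md)
    A_tot_cyt: float = 2.0
    s_a: float = 1.0
    K_nc: float = 3.0
    # -- PTP gating constants
    CAM_star: float = 4.0
    y_star: float = 0.8
    f_HM: float = 1.28e-6
    p1: float = 0.022
    p2: float = 0.0001
    p3: float = 0.0231
    p4: float = 0.0001
    amp_tau: float = 26000.0
    p6: float = 0.001
    perm_H: float = 3.0
    perm_Ca: float = 0.4
    postptp: float = 2.0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` on out-of-domain parameters."""
        positive = (
            "V", "uMmM", "tau_min", "d_cytosol", "d_mito", "d_er",
            "c_mito", "tau",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"parameter {name} must be > 0")
        nonneg = (
            "rho_uni", "rho_nc", "rho_res", "rho_F1", "pim", "rho_leak",
            "J_red_basal", "J_max_ANT", "glc", "J_hyd_max", "V_IP3",
            "v_leak", "d_IP3", "d_ACT", "d_INH", "V_serca", "k_serca",
            "V1", "V_alpha", "K_alpha", "k_beta", "K1", "f_m", "f_i",
            "A_tot_cyt", "s_a", "K_nc", "CAM_star", "y_star", "f_HM",
            "amp_tau", "p6", "perm_H", "perm_Ca", "postptp",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"parameter {name} must be >= 0")
        for name in ("p_cytosol", "p_mito", "p_er"):
            if not 0 < getattr(self, name) <= 1:
                raise ConfigurationError(f"parameter {name} must be in (0, 1]")
        if self.p_cytosol + self.p_mito + self.p_er > 1 + 1e-12:
            raise ConfigurationError(
                "volume proportions p_cytosol + p_mito + p_er must not exceed 1")
        for name in ("n", "m"):
            value = getattr(self, name)
            if not (isinstance(value, int) and value > 0):
                raise ConfigurationError(
                    f"Hill coefficient {name} must be a positive integer")

    # Accepted alternative spellings (the tables use several).
    @property
    def rho_Na_Ca(self) -> float:
        return self.rho_nc

    @property
    def V_leak(self) -> float:
        return self.v_leak

    @property
    def J_leak(self) -> float:
        return self.v_leak

    @property
    def minute(self) -> float:
        return self.tau_min

    def with_overrides(self, **overrides: Any) -> "ModelParameters":
        """Return a copy with ``overrides`` applied (aliases accepted)."""
        resolved = {}
        for key, value in overrides.items():
            canonical = PARAM_ALIASES.get(key, key)
            if canonical not in _PARAM_FIELDS:
                raise ConfigurationError(
                    f"unknown parameter {key!r}; valid keys: "
                    + ", ".join(sorted(_PARAM_FIELDS)))
            resolved[canonical] = _coerce(canonical, value)
        return replace(self, **resolved)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}

#: Alternative spellings appearing in the source tables, all accepted in
#: config files and CLI overrides.
PARAM_ALIASES = {
    "rho_Na_Ca": "rho_nc",
    "V_leak": "v_leak",
    "J_leak": "v_leak",
    "minute": "tau_min",
    "Valpha": "V_alpha",
    "Kalpha": "K_alpha",
    "P_i_m": "pim",
    "f_H_M": "f_HM",
    "perm_l_H": "perm_H",
}


def _coerce(field_name: str, value: Any):
    if field_name in ("n", "m"):
        iv = int(value)
        if iv != float(value):
            raise ConfigurationError(f"{field_name} must be an integer")
        return iv
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(
            f"cannot interpret {value!r} as a number for {field_name}") from exc


@dataclass(frozen=True)
class InitialState:
    """Initial values of the 13 dynamic variables.

    The closed-channel fraction ``h`` is stored as a fraction (0.95, printed
    as 95%).  ``H_M`` has no tabulated initial value; the default equals
    ``p3`` = 0.0231, which puts the low-conductance gate target
    ``PTPl_inf = 0.5*(1 + tanh((p1 - H_M)/p2))`` at ~0, consistent with
    PTPl(0) = 0.
    """

    CAC: float = 0.05     # uM
    CAM: float = 0.05     # uM
    CAER: float = 11.0    # uM
    a: float = 0.0        # nM
    PTPh: float = 0.0
    PTPl: float = 0.0
    y: float = 0.0
    H_M: float = 0.0231
    PSI: float = 164.0    # mV
    NADH_m: float = 0.16  # mM
    ADP_m: float = 4.46   # mM
    ADP_i: float = 0.028  # mM
    h: float = 0.95

    def __post_init__(self):
        for name in ("CAC", "CAM", "CAER", "a", "NADH_m", "ADP_m", "ADP_i",
                     "H_M"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"initial {name} must be >= 0")
        for name in ("h", "y", "PTPh", "PTPl"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"initial {name} must be in [0, 1]")

    def to_array(self):
        import numpy as np
        return np.array([getattr(self, k) for k in STATE_VARS], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def with_overrides(self, **overrides: Any) -> "InitialState":
        fields = {f.name for f in dataclasses.fields(InitialState)}
        for key in overrides:
            if key not in fields:
                raise ConfigurationError(
                    f"unknown initial-state key {key!r}; valid keys: "
                    + ", ".join(sorted(fields)))
        return replace(self, **{k: float(v) for k, v in overrides.items()})


@dataclass(frozen=True)
class CompartmentConstants:
    """Protein amounts (mg) and volumes (ml) of the three compartments."""

    M: float
    C: float
    E: float
    V_m: float
    V_c: float
    V_e: float


def derive_compartments(params: ModelParameters) -> CompartmentConstants:
    """Protein amounts and compartment volumes from the cell geometry.

    M = V*p_mito*d_mito, C = V*p_cytosol*d_cytosol, E = V*p_er*d_er;
    V_x = V*p_x.  Homogeneous of degree 1 in the total volume V.
    """
    p = params
    if p.V <= 0:
        raise ConfigurationError("total volume V must be > 0")
    return CompartmentConstants(
        M=p.V * p.p_mito * p.d_mito,
        C=p.V * p.p_cytosol * p.d_cytosol,
        E=p.V * p.p_er * p.d_er,
        V_m=p.V * p.p_mito,
        V_c=p.V * p.p_cytosol,
        V_e=p.V * p.p_er,
    )


@dataclass(frozen=True)
class NucleotidePools:
    """Algebraic nucleotide pools at one state (all mM).

    ATP_m and NAD close the mitochondrial conservation relations
    (total adenine 12*d_mito/uMmM, total pyridine 8*d_mito/uMmM); the
    free and charged fractions are fixed proportions.
    """

    ATP_m: float
    NAD: float
    ADP_mf: float
    ADP_if: float
    ADP3_m: float
    ADP3_i: float
    MgADP_i: float
    ATP4_i: float
    ATP4_m: float
    ATP_i: float


def nucleotide_pools(ADP_m: float, ADP_i: float, NADH_m: float,
                     params: ModelParameters) -> NucleotidePools:
    """Evaluate conservation closures and free/charged fractions.

    Raises
    ------
    StateDomainError
        If ADP_m exceeds the total adenine pool or NADH_m the total
        pyridine pool (either would make a conserved partner negative).
    """
    p = params
    atp_m = 12.0 * p.d_mito / p.uMmM - ADP_m
    if atp_m < 0:
        raise StateDomainError(
            f"ADP_m={ADP_m} exceeds the total adenine pool "
            f"{12.0 * p.d_mito / p.uMmM} mM")
    nad = 8.0 * p.d_mito / p.uMmM - NADH_m
    if nad < 0:
        raise StateDomainError(
            f"NADH_m={NADH_m} exceeds the total pyridine pool "
            f"{8.0 * p.d_mito / p.uMmM} mM")
    adp_mf = 0.8 * ADP_m
    adp_if = 0.3 * ADP_i
    atp_i = p.A_tot_cyt - ADP_i
    return NucleotidePools(
        ATP_m=atp_m,
        NAD=nad,
        ADP_mf=adp_mf,
        ADP_if=adp_if,
        ADP3_m=0.45 * adp_mf,
        ADP3_i=0.45 * adp_if,
        MgADP_i=0.55 * adp_if,
        ATP4_i=0.05 * atp_i,
        ATP4_m=0.05 * atp_m,
        ATP_i=atp_i,
    )


@dataclass(frozen=True)
class SolverOptions:
    """Stiff-integration settings.

    ``max_step`` bounds the step so threshold crossings of the Heaviside
    gate targets are never stepped over undetected.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "BDF"
    max_step: float = 0.5
    dt_out: float = 0.05
    t_end: float = 1000.0

    def __post_init__(self):
        if self.rtol <= 0 or self.atol <= 0:
            raise ConfigurationError("solver tolerances must be > 0")
        if self.max_step <= 0 or self.dt_out <= 0:
            raise ConfigurationError("max_step and dt_out must be > 0")


SCENARIO_NAMES = ("no_pathology", "pathology")


@dataclass(frozen=True)
class Scenario:
    """A fully resolved preset: parameters, initial state, stimulus, solver."""

    name: str
    params: ModelParameters
    init: InitialState
    stim: "StimulusSpec"
    solver: SolverOptions


def make_scenario(name: str, **overrides: Any) -> Scenario:
    """Resolve a named preset.

    ``pathology`` is the full default parameter set integrated to t=1000.
    ``no_pathology`` disables the amyloid pathway (V1 = V_alpha = K1 = 0,
    a(0) = 0) and integrates to t=500.
    """
    from .er import StimulusSpec  # local import avoids a cycle

    if name == "pathology":
        params = ModelParameters()
        init = InitialState()
        solver = SolverOptions(t_end=1000.0)
    elif name == "no_pathology":
        params = ModelParameters().with_overrides(V1=0.0, V_alpha=0.0, K1=0.0)
        init = InitialState(a=0.0)
        solver = SolverOptions(t_end=500.0)
    else:
        raise ConfigurationError(
            f"unknown scenario {name!r}; available presets: "
            + ", ".join(SCENARIO_NAMES))
    stim = StimulusSpec()
    if overrides:
        params = params.with_overrides(**overrides)
    return Scenario(name=name, params=params, init=init, stim=stim,
                    solver=solver)


# ---------------------------------------------------------------------------
# Config file IO (TOML sections [parameters] [initial_state] [stimulus]
# [solver] [scenario]); unknown keys are rejected by name.

_CONFIG_SECTIONS = ("parameters", "initial_state", "stimulus", "solver",
                    "scenario")


def read_config(path) -> Scenario:
    """Load a TOML config and return the fully resolved scenario.

    Every section and key is optional; omitted values fall back to the
    scenario preset named in ``[scenario] name`` (default ``pathology``).
    """
    from .er import StimulusSpec

    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigurationError(f"malformed config file {path}: {exc}")
    for section in raw:
        if section not in _CONFIG_SECTIONS:
            raise ConfigurationError(
                f"unknown config section [{section}]; valid sections: "
                + ", ".join(_CONFIG_SECTIONS))

    scen_block = dict(raw.get("scenario", {}))
    name = scen_block.pop("name", "pathology")
    for key in scen_block:
        if key != "t_end":
            raise ConfigurationError(
                f"unknown key {key!r} in [scenario]; valid keys: name, t_end")
    base = make_scenario(name)

    params = base.params.with_overrides(**raw.get("parameters", {}))
    init = base.init.with_overrides(**raw.get("initial_state", {}))

    stim_fields = {f.name for f in dataclasses.fields(StimulusSpec)}
    stim_over = raw.get("stimulus", {})
    for key in stim_over:
        if key not in stim_fields:
            raise ConfigurationError(
                f"unknown key {key!r} in [stimulus]; valid keys: "
                + ", ".join(sorted(stim_fields)))
    stim = replace(base.stim, **{k: float(v) for k, v in stim_over.items()})

    solver_fields = {f.name for f in dataclasses.fields(SolverOptions)}
    solver_over = dict(raw.get("solver", {}))
    for key in solver_over:
        if key not in solver_fields:
            raise ConfigurationError(
                f"unknown key {key!r} in [solver]; valid keys: "
                + ", ".join(sorted(solver_fields)))
    if "t_end" in scen_block:
        solver_over.setdefault("t_end", float(scen_block["t_end"]))
    solver = replace(base.solver, **{
        k: (v if k == "method" else float(v)) for k, v in solver_over.items()})

    return Scenario(name=name, params=params, init=init, stim=stim,
                    solver=solver)


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        # repr round-trips every finite double exactly
        text = repr(value)
        return text if ("." in text or "e" in text or "E" in text
                        or "inf" in text or "nan" in text) else text + ".0"
    return '"' + str(value).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_config(path, scenario: Scenario) -> None:
    """Serialize a resolved scenario to TOML (round-trips bit-exactly)."""
    blocks = {
        "scenario": {"name": scenario.name},
        "parameters": scenario.params.to_dict(),
        "initial_state": scenario.init.to_dict(),
        "stimulus": dataclasses.asdict(scenario.stim),
        "solver": dataclasses.asdict(scenario.solver),
    }
    lines = []
    for section in _CONFIG_SECTIONS:
        block = blocks[section]
        lines.append(f"[{section}]")
        for key, value in block.items():
            lines.append(f"{key} = {_toml_value(value)}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
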