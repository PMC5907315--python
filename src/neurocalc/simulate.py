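"""Assembly and stiff integration of the 13-variable composite model.

State ordering (= CSV column order):
``CAC, CAM, CAER, a, PTPh, PTPl, y, H_M, PSI, NADH_m, ADP_m, ADP_i, h``.

The right-hand side combines the cytosolic/mitochondrial/ER Ca2+ balances,
the amyloid feedback, the PTP gating subsystem and the bioenergetic ODEs
(NADH_m, ADP_m, ADP_i, PSI) plus the IP3R inhibition gate ``h``.  The two
conserved pools (total adenine, total pyridine) are algebraic closures, so
ATP_m + ADP_m and NADH_m + NAD are constant by construction.

Integration is event-aware: the IP3 step edges partition the time axis,
and crossings of the two Heaviside thresholds (CAM = CAM*, y = y*) are
located by root-finding on dense output, logged, and used as restart
points so the discontinuous derivative never sits inside a solver step.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import amyloid as amy
from . import er, fluxes, ptp
from .errors import SolverError
from .params import (STATE_VARS, CompartmentConstants, InitialState,
                     ModelParameters, SolverOptions, derive_compartments,
                     nucleotide_pools)

__all__ = ["ModelState", "Trajectory", "evaluate_fluxes", "rhs", "simulate"]

logger = logging.getLogger(__name__)

_IDX = {name: i for i, name in enumerate(STATE_VARS)}

FLUX_COLUMNS = (
    "J_uni", "J_nc", "J_res_H", "J_o", "J_p_F1", "J_H_F1", "J_H_leak",
    "J_ANT", "J_p_TCA", "J_red", "J_gly_total", "J_p_gly", "J_hyd",
    "J_serca", "J_er_out", "J_PTP_H", "J_PTP_Ca", "f_PDH", "MWC", "IP3",
)


@dataclass(frozen=True)
class ModelState:
    """One point of the 13-dimensional state, by name."""

    CAC: float
    CAM: float
    CAER: float
    a: float
    PTPh: float
    PTPl: float
    y: float
    H_M: float
    PSI: float
    NADH_m: float
    ADP_m: float
    ADP_i: float
    h: float

    @classmethod
    def from_array(cls, vec) -> "ModelState":
        return cls(**{name: float(vec[i]) for name, i in _IDX.items()})

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STATE_VARS], dtype=float)


def _clip0(x: float) -> float:
    """Concentrations are clipped at 0 inside flux evaluation only; the
    integrated state itself is never modified.  NaN propagates (so a
    corrupt state is reported, not silently zeroed)."""
    return 0.0 if x <= 0.0 else x


def evaluate_fluxes(t: float, state, params: ModelParameters,
                    stim: er.StimulusSpec) -> fluxes.FluxSet:
    """Evaluate the full flux set at one (t, state) point."""
    s = state
    cac = _clip0(s[_IDX["CAC"]])
    cam = _clip0(s[_IDX["CAM"]])
    caer = s[_IDX["CAER"]]
    ptp_h = s[_IDX["PTPh"]]
    ptp_l = s[_IDX["PTPl"]]
    h_m = s[_IDX["H_M"]]
    psi = s[_IDX["PSI"]]
    nadh = _clip0(s[_IDX["NADH_m"]])
    adp_m = _clip0(s[_IDX["ADP_m"]])
    adp_i = _clip0(s[_IDX["ADP_i"]])
    h = s[_IDX["h"]]

    pools = nucleotide_pools(adp_m, adp_i, nadh, params)
    ip3 = er.ip3_stimulus(t, stim)

    j_uni = fluxes.uniporter_flux(cac, cam, psi, ptp_h, params)
    j_nc = fluxes.naca_flux(cam, psi, ptp_h, params)
    j_res_h, j_o = fluxes.respiration_fluxes(nadh, pools.NAD, psi, params)
    j_p_f1, j_h_f1 = fluxes.atpase_fluxes(pools, psi, params)
    j_leak = fluxes.proton_leak(psi, params)
    j_ant = fluxes.ant_flux(pools, psi, params)
    j_gly, j_p_gly, j_hyd = fluxes.glycolysis_fluxes(params.glc, pools.ATP_i,
                                                     params)
    f_pdh, j_red, j_p_tca = fluxes.pyruvate_reduction(cam, j_gly, params)
    j_serca = er.serca_flux(cac, params)
    j_er_out = er.ip3r_leak_flux(cac, caer, ip3, h, params)
    j_ptp_h_flux, j_ptp_ca = ptp.ptp_fluxes(ptp_l, ptp_h, psi, h_m, j_uni,
                                            params)
    return fluxes.FluxSet(
        J_uni=j_uni, J_nc=j_nc, J_res_H=j_res_h, J_o=j_o, J_p_F1=j_p_f1,
        J_H_F1=j_h_f1, J_H_leak=j_leak, J_ANT=j_ant, J_p_TCA=j_p_tca,
        J_red=j_red, J_gly_total=j_gly, J_p_gly=j_p_gly, J_hyd=j_hyd,
        J_serca=j_serca, J_er_out=j_er_out, J_PTP_H=j_ptp_h_flux,
        J_PTP_Ca=j_ptp_ca, f_PDH=f_pdh, MWC=fluxes.uniporter_mwc(cac, params),
        IP3=ip3)


def rhs(t: float, state, params: ModelParameters, stim: er.StimulusSpec,
        comps: Optional[CompartmentConstants] = None) -> np.ndarray:
    """Time derivative of the 13-variable state.

    Raises
    ------
    SolverError
        If any derivative evaluates non-finite (names the offender).
    """
    p = params
    if comps is None:
        comps = derive_compartments(p)
    fx = evaluate_fluxes(t, state, p, stim)

    cac = state[_IDX["CAC"]]
    cam = state[_IDX["CAM"]]
    a = state[_IDX["a"]]
    ptp_h = state[_IDX["PTPh"]]
    ptp_l = state[_IDX["PTPl"]]
    y = state[_IDX["y"]]
    h_m = state[_IDX["H_M"]]
    h = state[_IDX["h"]]

    d = np.empty(len(STATE_VARS))
    ca_mito = fx.J_nc - fx.J_uni - fx.J_PTP_Ca          # net mito -> cytosol
    ca_er = fx.J_serca - fx.J_er_out                    # net cytosol -> ER
    d[_IDX["CAC"]] = (p.f_i / (comps.V_c * p.tau_min)
                      * (comps.M * ca_mito - comps.E * ca_er)
                      + amy.amyloid_ca_entry(_clip0(a), p))
    d[_IDX["CAM"]] = (p.f_m * comps.M / (comps.V_m * p.tau_min) * (-ca_mito))
    d[_IDX["CAER"]] = p.f_i * comps.E / (comps.V_e * p.tau_min) * ca_er
    d[_IDX["a"]] = amy.amyloid_rate(_clip0(cac), a, p)

    dy, tau_y = ptp.slow_process_rate(_clip0(cam), y, p)
    tau_h = tau_y / 8.0
    d[_IDX["y"]] = dy
    d[_IDX["PTPh"]] = ptp.ptp_high_rate(y, ptp_h, _clip0(cam), p)
    dptpl, _ = ptp.ptp_low_rate(h_m, ptp_l, p)
    d[_IDX["PTPl"]] = dptpl
    d[_IDX["H_M"]] = ptp.matrix_proton_rate(fx.J_H_leak, fx.J_H_F1,
                                            fx.J_res_H, fx.J_PTP_H, tau_h, p)

    mv = p.uMmM * comps.V_m * p.tau_min
    d[_IDX["NADH_m"]] = (fx.J_red - fx.J_o) * comps.M / mv
    d[_IDX["ADP_m"]] = (fx.J_ANT - fx.J_p_TCA - fx.J_p_F1) * comps.M / mv
    d[_IDX["ADP_i"]] = ((-fx.J_ANT * comps.M + (fx.J_hyd - fx.J_p_gly) * comps.C)
                        / (p.uMmM * comps.V_c * p.tau_min))
    d[_IDX["PSI"]] = (-(-fx.J_res_H + fx.J_H_F1 + fx.J_ANT + fx.J_PTP_H
                        + fx.J_H_leak + 2.0 * fx.J_uni + 2.0 * fx.J_PTP_Ca)
                      * comps.M / (p.c_mito * p.tau_min))
    d[_IDX["h"]] = er.h_gate_rate(_clip0(cac), h, p)

    if not np.all(np.isfinite(d)):
        bad = [STATE_VARS[i] for i in np.where(~np.isfinite(d))[0]]
        raise SolverError(
            f"non-finite derivative for {', '.join(bad)} at t={t}; "
            f"fluxes: {fx}", t_last=t, state_last=np.asarray(state).copy())
    return d


@dataclass
class Trajectory:
    """Integrated time course on the output grid, plus the event log."""

    t: np.ndarray
    states: np.ndarray          # shape (len(t), 13), columns = STATE_VARS
    events: list = field(default_factory=list)
    fluxes: Optional[np.ndarray] = None   # shape (len(t), len(FLUX_COLUMNS))
    scenario: str = "custom"
    params: Optional[ModelParameters] = None
    stim: Optional[er.StimulusSpec] = None
    solver: Optional[SolverOptions] = None

    def __getitem__(self, variable: str) -> np.ndarray:
        if variable == "t":
            return self.t
        if variable in _IDX:
            return self.states[:, _IDX[variable]]
        if self.fluxes is not None and variable in FLUX_COLUMNS:
            return self.fluxes[:, FLUX_COLUMNS.index(variable)]
        raise KeyError(variable)

    @property
    def variables(self) -> tuple:
        cols = STATE_VARS
        if self.fluxes is not None:
            cols = cols + FLUX_COLUMNS
        return cols

    def final_state(self) -> ModelState:
        return ModelState.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t}
        for i, name in enumerate(STATE_VARS):
            data[name] = self.states[:, i]
        if self.fluxes is not None:
            for j, name in enumerate(FLUX_COLUMNS):
                data[name] = self.fluxes[:, j]
        return pd.DataFrame(data)

    def write_csv(self, path) -> None:
        """Full-precision RFC-4180 CSV with header ``t,CAC,...``."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g",
                               lineterminator="\n")

    @classmethod
    def read_csv(cls, path) -> "Trajectory":
        frame = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in ("t",) + STATE_VARS if c not in frame.columns]
        if missing:
            raise ValueError("missing required columns: " + ", ".join(missing))
        flux_cols = [c for c in FLUX_COLUMNS if c in frame.columns]
        flux = frame[flux_cols].to_numpy() if len(flux_cols) == len(
            FLUX_COLUMNS) else None
        return cls(t=frame["t"].to_numpy(),
                   states=frame[list(STATE_VARS)].to_numpy(),
                   fluxes=flux)


def _threshold_events(params: ModelParameters):
    def cam_crossing(t, s, *args):
        return s[_IDX["CAM"]] - params.CAM_star

    def y_crossing(t, s, *args):
        return s[_IDX["y"]] - params.y_star

    cam_crossing.terminal = True
    y_crossing.terminal = True
    return [cam_crossing, y_crossing]


_EVENT_NAMES = ("CAM_threshold", "y_threshold")
#: Dead time after a located crossing during which the same event is
#: masked, so the restart at the root does not re-trigger it.
_EVENT_DEADTIME = 1e-6


def simulate(params: ModelParameters, init: InitialState,
             stim: er.StimulusSpec, opts: SolverOptions | None = None,
             record_fluxes: bool = False,
             scenario_name: str = "custom") -> Trajectory:
    """Integrate the composite model with discontinuity-aware restarts.

    The run is split at the stimulus edges; within each span, crossings of
    CAM = CAM* and y = y* terminate the solver, are appended to the event
    log, and integration restarts from the crossing point.  Dense output
    is sampled on the uniform grid ``opts.dt_out``.  Identical inputs give
    bit-identical trajectories.

    Raises
    ------
    SolverError
        On integrator failure, carrying the last good time and state.
    """
    if opts is None:
        opts = SolverOptions()
    if opts.t_end <= 0:
        raise SolverError("t_end must be > 0")
    comps = derive_compartments(params)
    events = _threshold_events(params)

    grid = np.arange(0.0, opts.t_end + 0.5 * opts.dt_out, opts.dt_out)
    grid[-1] = min(grid[-1], opts.t_end)

    breakpoints = sorted({opts.t_end}
                         | {e for e in stim.edges if 0.0 < e < opts.t_end})
    event_log: list[dict] = []
    for edge, name in zip(stim.edges, ("stimulus_on", "stimulus_off")):
        if 0.0 <= edge <= opts.t_end:
            event_log.append({"event": name, "time": float(edge)})

    t_out = [np.array([0.0])]
    y_out = [init.to_array()[None, :]]
    t0 = 0.0
    y0 = init.to_array()
    masked: dict[int, float] = {}   # event index -> mask expiry time

    def fun(t, s):
        return rhs(t, s, params, stim, comps)

    n_restarts = 0
    for t_stop in breakpoints:
        while t0 < t_stop - 1e-12:
            n_restarts += 1
            if n_restarts > 100000:
                raise SolverError("too many event restarts (chattering "
                                  "threshold crossing?)", t_last=t0,
                                  state_last=y0)
            active = []
            index_map = []
            seg_end = t_stop
            for k, ev in enumerate(events):
                expiry = masked.get(k, -math.inf)
                if expiry <= t0:
                    active.append(ev)
                    index_map.append(k)
                else:
                    # masked event: stop the sub-segment at its expiry so
                    # the mask lasts only for the dead time
                    seg_end = min(seg_end, expiry)
            seg_grid = grid[(grid > t0) & (grid <= seg_end)]
            sol = solve_ivp(fun, (t0, seg_end), y0, method=opts.method,
                            rtol=opts.rtol, atol=opts.atol,
                            max_step=opts.max_step, t_eval=seg_grid,
                            events=active, dense_output=False)
            sol_t = np.asarray(sol.t, dtype=float)
            sol_y = (np.asarray(sol.y, dtype=float) if sol_t.size
                     else np.empty((len(STATE_VARS), 0)))
            if sol.status == -1:
                t_last = sol_t[-1] if sol_t.size else t0
                raise SolverError(
                    f"integration failed at t={t_last}: {sol.message}",
                    t_last=t_last,
                    state_last=sol_y[:, -1] if sol_t.size else y0)
            if sol_t.size:
                t_out.append(sol_t)
                y_out.append(sol_y.T)
            if sol.status == 1:      # a threshold crossing terminated the span
                hit = [k for k, te in enumerate(sol.t_events) if te.size]
                k_local = hit[0]
                k_global = index_map[k_local]
                t_ev = float(sol.t_events[k_local][0])
                y_ev = sol.y_events[k_local][0]
                event_log.append({"event": _EVENT_NAMES[k_global],
                                  "time": t_ev})
                logger.info("restart at %s crossing, t=%.6f",
                            _EVENT_NAMES[k_global], t_ev)
                masked[k_global] = t_ev + _EVENT_DEADTIME
                t0, y0 = t_ev, np.asarray(y_ev, dtype=float)
            else:
                if sol_t.size and abs(sol_t[-1] - seg_end) < 1e-9:
                    y0 = sol_y[:, -1]
                else:
                    # seg_end not on the output grid (mask expiry): re-run
                    # the tail stretch exactly
                    tail = solve_ivp(fun, (sol_t[-1] if sol_t.size else t0,
                                           seg_end),
                                     sol_y[:, -1] if sol_t.size else y0,
                                     method=opts.method, rtol=opts.rtol,
                                     atol=opts.atol, max_step=opts.max_step)
                    y0 = tail.y[:, -1]
                t0 = seg_end
        # clear masks at stimulus edges; restart there regardless
        logger.debug("restart at span boundary t=%.6f", t_stop)

    t_arr = np.concatenate(t_out)
    y_arr = np.vstack(y_out)
    keep = np.ones(t_arr.size, dtype=bool)
    keep[1:] = np.diff(t_arr) > 0
    t_arr, y_arr = t_arr[keep], y_arr[keep]

    traj = Trajectory(t=t_arr, states=y_arr,
                      events=sorted(event_log, key=lambda e: e["time"]),
                      scenario=scenario_name, params=params, stim=stim,
                      solver=opts)
    if record_fluxes:
        flux_rows = np.empty((t_arr.size, len(FLUX_COLUMNS)))
        for i, (ti, si) in enumerate(zip(t_arr, y_arr)):
            fx = evaluate_fluxes(ti, si, params, stim)
            flux_rows[i] = [getattr(fx, name) for name in FLUX_COLUMNS]
        traj.fluxes = flux_rows
    return traj
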