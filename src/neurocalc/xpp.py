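"""Export the resolved model as an XPP/XPPAUT ``.ode`` file.

Exporter only (no parser): emits ``par`` lines for every constant,
``init`` lines for the 13 state variables, the algebraic flux definitions
and the 13 ``d<var>/dt`` equations, using XPP's built-in ``heav()``.  The
file encodes exactly the model the simulator integrates, for
cross-validation in XPPAUT.
"""

from __future__ import annotations

from .params import InitialState, ModelParameters
from .er import StimulusSpec

__all__ = ["export_xpp_ode"]


def _fmt(x) -> str:
    if isinstance(x, int):
        return str(x)
    return repr(float(x))


def export_xpp_ode(params: ModelParameters, init: InitialState,
                   stim: StimulusSpec, path) -> None:
    """Write the ``.ode`` file to ``path``."""
    p = params
    par_items = [
        ("V", p.V), ("uMmM", p.uMmM), ("taumin", p.tau_min),
        ("pcyt", p.p_cytosol), ("dcyt", p.d_cytosol),
        ("pmito", p.p_mito), ("dmito", p.d_mito),
        ("per", p.p_er), ("der", p.d_er), ("cmito", p.c_mito),
        ("rhouni", p.rho_uni), ("rhonc", p.rho_nc), ("rhores", p.rho_res),
        ("rhof1", p.rho_F1), ("pim", p.pim), ("rholeak", p.rho_leak),
        ("jredbasal", p.J_red_basal), ("jmaxant", p.J_max_ANT),
        ("glc", p.glc), ("jhydmax", p.J_hyd_max),
        ("vip3", p.V_IP3), ("vleak", p.v_leak), ("dip3", p.d_IP3),
        ("dact", p.d_ACT), ("dinh", p.d_INH), ("tauh_ip3", p.tau),
        ("vserca", p.V_serca), ("kserca", p.k_serca),
        ("V1", p.V1), ("Valpha", p.V_alpha), ("Kalpha", p.K_alpha),
        ("kbeta", p.k_beta), ("K1", p.K1), ("nhill", p.n), ("mcoop", p.m),
        ("fm", p.f_m), ("fi", p.f_i),
        ("atotcyt", p.A_tot_cyt), ("sa", p.s_a), ("knc", p.K_nc),
        ("camstar", p.CAM_star), ("ystar", p.y_star), ("fhm", p.f_HM),
        ("p1", p.p1), ("p2", p.p2), ("p3", p.p3), ("p4", p.p4),
        ("amptau", p.amp_tau), ("p6", p.p6),
        ("permh", p.perm_H), ("permca", p.perm_Ca), ("postptp", p.postptp),
        ("baseline", stim.baseline), ("amplitude", stim.amplitude),
        ("tinit", stim.init), ("dur", stim.duration),
    ]
    lines = ["# composite neuronal calcium / PTP model", "#"]
    for name, value in par_items:
        lines.append(f"par {name}={_fmt(value)}")
    lines.append("")
    for name, value in (
            ("CAC", init.CAC), ("CAM", init.CAM), ("CAER", init.CAER),
            ("a", init.a), ("PTPh", init.PTPh), ("PTPl", init.PTPl),
            ("y", init.y), ("HM", init.H_M), ("PSI", init.PSI),
            ("NADHm", init.NADH_m), ("ADPm", init.ADP_m),
            ("ADPi", init.ADP_i), ("h", init.h)):
        lines.append(f"init {name}={_fmt(value)}")
    lines += [
        "",
        "# compartments and pools",
        "!M=V*pmito*dmito",
        "!C=V*pcyt*dcyt",
        "!E=V*per*der",
        "!Vm=V*pmito",
        "!Vc=V*pcyt",
        "!Ve=V*per",
        "ATPm=12*dmito/uMmM-ADPm",
        "NAD=8*dmito/uMmM-NADHm",
        "ADPmf=0.8*ADPm",
        "ADPif=0.3*ADPi",
        "ADP3m=0.45*ADPmf",
        "ADP3i=0.45*ADPif",
        "ATPi=atotcyt-ADPi",
        "ATP4i=0.05*ATPi",
        "ATP4m=0.05*ATPm",
        "",
        "# stimulus",
        "IP3=baseline+amplitude*(heav(t-tinit)-heav(t-(tinit+dur)))",
        "",
        "# uniporter and exchanger",
        "mwcnum=(CAC/6)*(1+CAC/6)^3",
        "mwcden=(1+CAC/6)^4+50/(1+CAC/0.38)^2.8",
        "mwc=mwcnum/mwcden",
        "vduni=(PSI-91)/13.35",
        "juni=(rhouni*vduni*(mwc-CAM*exp(-vduni))/(1-exp(-vduni)))*(1-PTPh)",
        "jnc=(rhonc*exp((PSI-91)/53.4)*(1/(1+(9.4/30)^2))*(1/(1+knc/CAM)))*(1-PTPh)",
        "",
        "# respiration",
        "ares=1.35e18*sqrt(NADHm/NAD)",
        "vdres=exp(0.191*PSI)",
        "jresh=360*rhores*(7e-7+2.54e-3*ares-0.639*vdres)/(7.58e13+1.57e-4*ares+(1.73+1.06e-17*ares)*vdres)",
        "jo=30*rhores*(2.55e-3*ares+2e-5*ares-0.639*vdres+vdres*ares*8.63e-18)/((1+2.08e-18*ares)*7.54e13+(1.73+1.06e-17*ares)*vdres)",
        "",
        "# F0/F1 ATPase",
        "af1=1.71e9*ATPm/(ADPmf*pim)",
        "vdf1=exp(0.112*PSI)",
        "jpf1=-60*rhof1*((10.5*af1-166*vdf1+4.85e-12*af1*vdf1)/((1e7+0.135*af1)*275+(7.74+6.65e-8*af1)*vdf1))",
        "jhf1=-180*rhof1*(0.213+10.5*af1-169*vdf1)/((1e7+0.135*af1)*275+(7.74+6.65e-8*af1)*vdf1)",
        "",
        "# leak, ANT, glycolysis, PDH coupling",
        "jhleak=rholeak*(PSI+24.6)",
        "ant1=(ATP4i/ADP3i)*(ADP3m/ATP4m)*exp(-PSI/26.7)",
        "ant2=1+(ATP4i/ADP3i)*exp(-PSI/53.4)",
        "ant3=1+(ADP3m/ATP4m)",
        "jant=jmaxant*((1-ant1)/(ant2*ant3))",
        "jgly=(123.3*(1+1.66*glc)*(glc*ATPi))*0.0249/(1+4*ATPi+(1+2.83*ATPi)*1.3*glc+(1+2.66*ATPi)*0.16*glc^2)",
        "jpgly=2*jgly",
        "jhyd=41*ATPi+jhydmax/(1+(8.7/glc)^2.7)",
        "fpdh=1/(1+1.1*(1+15/(1+CAM/0.05)^2))",
        "jred=jredbasal+6.3944*fpdh*jgly",
        "jptca=jredbasal/3+0.84*fpdh*jgly",
        "",
        "# ER handling",
        "jerout=(vip3*((IP3/(IP3+dip3))^3)*((CAC/(CAC+dact))^3)*h^3+vleak)*(CAER-CAC)",
        "jserca=vserca*CAC^2/(kserca^2+CAC^2)",
        "",
        "# PTP gating",
        "tauy=1000*((1000/cosh(CAM/0.1))+0.1)",
        "tauhc=tauy/8",
        "taul=p6+amptau/cosh((HM-p3)/p4)",
        "ptplinf=0.5*(1+tanh((p1-HM)/p2))",
        "jptph=permh*PTPl*PSI*(HM-0.0000000398*exp(-37.434*PSI)/(1-exp(-37.434*PSI)))",
        "jptpca=permca*PTPl*juni*(1-postptp*PTPh)",
        "",
        "# ODEs",
        "dCAC/dt=(fi/(Vc*taumin))*(M*(jnc-juni-jptpca)-E*(jserca-jerout))+sa*kbeta*a^mcoop",
        "dCAM/dt=(fm*M/(Vm*taumin))*(juni-jnc+jptpca)",
        "dCAER/dt=(fi*E/(Ve*taumin))*(jserca-jerout)",
        "da/dt=V1+Valpha*(1/(1+(Kalpha/CAC)^nhill))-K1*a",
        "dPTPh/dt=(heav(y-ystar)-PTPh)/tauhc",
        "dPTPl/dt=(ptplinf-PTPl)/taul",
        "dy/dt=(heav(CAM-camstar)-y)/tauy",
        "dHM/dt=(fhm/tauhc)*(jhleak+jhf1-jresh+jptph)",
        "dPSI/dt=-(-jresh+jhf1+jant+jptph+jhleak+2*juni+2*jptpca)*M/(cmito*taumin)",
        "dNADHm/dt=(jred-jo)*M/(uMmM*Vm*taumin)",
        "dADPm/dt=(jant-jptca-jpf1)*M/(uMmM*Vm*taumin)",
        "dADPi/dt=(-jant*M+(jhyd-jpgly)*C)/(uMmM*Vc*taumin)",
        "dh/dt=(dinh-(CAC+dinh)*h)/tauh_ip3",
        "",
        "@ method=stiff, total=1000, dt=0.05",
        "done",
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
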