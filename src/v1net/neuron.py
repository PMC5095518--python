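"""Adaptive-exponential integrate-and-fire membrane dynamics.

Each cell follows the AdEx model with three slow variables:

    C du/dt = g_l (E_l - u) + g_l Delta_T exp((u - V_T)/Delta_T)
              - w_ad + z + I_FF + I_Lat + I_inh + I_noise
    tau_VT  dV_T/dt  = V_Trest - V_T
    tau_wad dw_ad/dt = -w_ad
    tau_z   dz/dt    = -z

Units: mV, ms, pA, pF, nS (so pF * mV / ms = pA and nS * mV = pA).

A spike is registered when u reaches V_PEAK; the voltage is then clipped to
V_PEAK for one further 1-ms step and reset to E_l, producing a stereotyped
spike crest (this matters for the voltage-dependent plasticity rule, which
only reads the crest of each spike).  On each spike V_T jumps to V_TMAX and
then relaxes back to V_Trest, w_ad is incremented by b_wad, and z is set to
I_sp.  There is no subthreshold adaptation coupling: w_ad decays purely
exponentially between spikes.

Integration is forward Euler at a fixed dt = 1 ms; the exponential term's
argument is capped so a large Euler overshoot saturates instead of
overflowing (the overshoot value is irrelevant because the voltage is
clipped to V_PEAK anyway).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

DT_MS = 1.0
_EXP_ARG_CAP = 20.0


@dataclass(frozen=True)
class NeuronParams:
    """AdEx parameters (defaults follow the standard published values)."""

    C: float = 281.0          # membrane capacitance, pF
    g_l: float = 30.0         # leak conductance, nS
    E_l: float = -70.6        # resting potential, mV
    Delta_T: float = 2.0      # slope factor, mV
    V_Trest: float = -50.4    # resting threshold, mV
    V_TMAX: float = -30.4     # post-spike threshold, mV
    tau_VT: float = 50.0      # threshold decay, ms
    b_wad: float = 80.5       # adaptation increment per spike, pA
    tau_wad: float = 144.0    # adaptation decay, ms
    I_sp: float = 400.0       # spike afterpotential amplitude, pA
    tau_z: float = 40.0       # afterpotential decay, ms
    V_PEAK: float = 20.0      # spike detection / clipping voltage, mV
    exponential_enabled: bool = True

    def __post_init__(self):
        if min(self.C, self.g_l, self.Delta_T, self.tau_VT, self.tau_wad,
               self.tau_z) <= 0:
            raise ValueError("C, g_l, Delta_T and all time constants must be > 0")
        if not (self.V_Trest < self.V_TMAX < self.V_PEAK):
            raise ValueError("require V_Trest < V_TMAX < V_PEAK")


@dataclass
class NeuronState:
    """Dynamical variables of one cell.

    ``clip_countdown`` is 1 while the voltage is about to be held at V_PEAK
    for the post-spike clipped millisecond; ``pending_reset`` (internal)
    marks that the next step starts from the reset value E_l.
    """

    u: float                  # membrane potential, mV
    V_T: float                # adaptive threshold, mV
    w_ad: float = 0.0         # adaptation current, pA
    z: float = 0.0            # spike afterpotential, pA
    clip_countdown: int = 0   # 1 while the voltage is held at V_PEAK
    pending_reset: bool = False

    @classmethod
    def resting(cls, params: NeuronParams) -> "NeuronState":
        return cls(u=params.E_l, V_T=params.V_Trest)


@njit(cache=True, inline="always")
def _adex_update(u, v_t, w_ad, z, i_total, C, g_l, E_l, Delta_T, V_Trest,
                 tau_VT, tau_wad, tau_z, exp_enabled):
    """One Euler step of the subthreshold dynamics; returns new (u,V_T,w_ad,z)."""
    du = g_l * (E_l - u) - w_ad + z + i_total
    if exp_enabled:
        arg = (u - v_t) / Delta_T
        if arg > _EXP_ARG_CAP:
            arg = _EXP_ARG_CAP
        du += g_l * Delta_T * np.exp(arg)
    u_new = u + DT_MS * du / C
    v_t_new = v_t + DT_MS * (V_Trest - v_t) / tau_VT
    w_ad_new = w_ad - DT_MS * w_ad / tau_wad
    z_new = z - DT_MS * z / tau_z
    return u_new, v_t_new, w_ad_new, z_new


def adex_step(state: NeuronState, I_FF: float = 0.0, I_Lat: float = 0.0,
              I_inh: float = 0.0, I_noise: float = 0.0,
              params: NeuronParams = NeuronParams(),
              dt: float = DT_MS) -> tuple[NeuronState, bool]:
    """Advance one cell by a single 1-ms Euler step.

    Returns the new state and whether a spike was registered on this step.
    During the clipped post-spike step the voltage is held at V_PEAK, no new
    spike is registered, and the membrane is reset to E_l for the next step;
    the slow variables keep decaying throughout.
    """
    if dt != DT_MS:
        raise ValueError("fixed-step contract: dt must be 1 ms")
    vals = (state.u, state.V_T, state.w_ad, state.z, I_FF, I_Lat, I_inh,
            I_noise)
    if not all(np.isfinite(v) for v in vals):
        raise FloatingPointError("non-finite neuron state or input")

    i_total = I_FF + I_Lat + I_inh + I_noise
    if state.clip_countdown > 0:
        # clipped crest step: voltage held at V_PEAK, slow variables decay,
        # no new spike; the following step starts from the reset value E_l
        _, v_t, w_ad, z = _adex_update(
            params.E_l, state.V_T, state.w_ad, state.z, 0.0, params.C,
            params.g_l, params.E_l, params.Delta_T, params.V_Trest,
            params.tau_VT, params.tau_wad, params.tau_z, False)
        return NeuronState(u=params.V_PEAK, V_T=v_t, w_ad=w_ad, z=z,
                           clip_countdown=0, pending_reset=True), False

    u_start = params.E_l if state.pending_reset else state.u
    u, v_t, w_ad, z = _adex_update(
        u_start, state.V_T, state.w_ad, state.z, i_total, params.C,
        params.g_l, params.E_l, params.Delta_T, params.V_Trest, params.tau_VT,
        params.tau_wad, params.tau_z, params.exponential_enabled)
    spiked = bool(u >= params.V_PEAK)
    new = NeuronState(u=u, V_T=v_t, w_ad=w_ad, z=z, clip_countdown=0)
    if spiked:
        new = apply_spike(new, params)
    return new, spiked


def apply_spike(state: NeuronState, params: NeuronParams) -> NeuronState:
    """Apply the stereotyped per-spike adjustments.

    u is clipped to V_PEAK (held there for one further step before the reset
    to E_l), V_T jumps to V_TMAX, w_ad is incremented by b_wad, and z is set
    to I_sp.
    """
    return NeuronState(u=params.V_PEAK, V_T=params.V_TMAX,
                       w_ad=state.w_ad + params.b_wad, z=params.I_sp,
                       clip_countdown=1)


def block_spiking(params: NeuronParams) -> NeuronParams:
    """Disable the exponential spike-initiation term.

    Without the exponential runaway no bounded input below V_PEAK can produce
    a spike, while subthreshold dynamics are otherwise unchanged; used for
    the spike-blocking prediction experiment.
    """
    return replace(params, exponential_enabled=False)


def unblock_spiking(params: NeuronParams) -> NeuronParams:
    """Inverse of :func:`block_spiking`."""
    return replace(params, exponential_enabled=True)
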