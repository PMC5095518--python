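"""Voltage-dependent STDP with weight-dependent LTP and homeostatic LTD.

Feedforward and lateral E-E synapses share a single rule of the
Clopath-Gerstner family, with two modifications:

* **Weight-dependent LTP.**  The LTP magnitude carries a factor
  ``1 / (gamma * (w + w_eps))``, so larger weights are harder to increase.
  This replaces a hard upper weight clip and yields graded, smoothly
  decaying weight distributions.  ``w_eps`` keeps the factor finite at
  w = 0 (lateral weights start at exactly zero and must be able to grow).
* **Long homeostatic trace.**  The slow trace ``u_long`` is an exponential
  trace (time constant ~20 s) of how far the *spike crest* of the voltage
  lies above the plasticity threshold theta_plus, rather than an average of
  raw depolarization.  LTD scales with ``(u_long / u_ref)**2``, making
  depression a superlinear function of long-term firing and stabilizing
  overall activity.

Per 1-ms step, for a synapse with presynaptic arrival indicator X(t):

    LTD:  dw = -A_LTD * (u_long/u_ref)^2 * max(u_minus - theta_minus, 0) * X(t)
    LTP:  dw = +A_LTP / (gamma * (w + w_eps))
               * x_bar * max(u_crest - theta_plus, 0)
               * max(u_plus - theta_minus, 0)

where ``u_plus`` and ``u_minus`` are short exponential traces of the
(post-clipping) membrane voltage, ``x_bar`` is an exponential trace of
presynaptic arrivals (jumping by 1 per arrival), and ``u_crest`` equals the
membrane voltage during the stereotyped spike crest (u >= V_TMAX) and is
treated as subthreshold (zero LTP drive) otherwise — only the crest of each
spike counts toward potentiation and the homeostatic trace.  theta_minus is
the resting potential; theta_plus = (V_TMAX + V_Trest)/2.  Weights are
hard-clipped from below at zero and have no upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DT_MS = 1.0


@dataclass(frozen=True)
class PlasticityParams:
    """Parameters of the plasticity rule.

    ``A_LTD``/``A_LTP`` are in weight units (pA) per mV (per mV^2 for LTP)
    per event; the voltage thresholds are in mV.  ``u_ref`` (mV) sets the
    homeostatic set point: the long trace of crest activity at which LTD
    runs at its nominal rate.  ``gamma`` (1/pA) and ``w_eps`` (pA) shape the
    weight dependence of LTP.
    """

    A_LTD: float = 2e-3
    A_LTP: float = 0.65e-5
    tau_uplus: float = 7.0       # ms, LTP voltage trace (short)
    tau_uminus: float = 10.0     # ms, LTD voltage trace (slightly longer)
    tau_long: float = 20000.0    # ms, homeostatic trace (much longer)
    tau_x: float = 15.0          # ms, presynaptic arrival trace
    theta_minus: float = -70.6   # mV, = resting potential E_l
    theta_plus: float = -40.4    # mV, = (V_TMAX + V_Trest)/2
    crest_gate: float = -30.4    # mV, = V_TMAX; only the spike crest
    #                              (u >= crest_gate) drives LTP and u_long
    u_ref: float = 2.5           # mV, homeostatic reference
    gamma: float = 0.012         # 1/pA, weight-dependence scale of LTP
    w_eps: float = 30.0          # pA, regularizer so LTP is finite at w = 0

    def __post_init__(self):
        if min(self.tau_uplus, self.tau_uminus, self.tau_long,
               self.tau_x) <= 0:
            raise ValueError("all time constants must be > 0")
        if not (self.tau_uplus < self.tau_uminus < self.tau_long):
            raise ValueError(
                "require tau_uplus < tau_uminus < tau_long "
                "(short, slightly longer, much longer)")
        if self.u_ref <= 0 or self.gamma <= 0 or self.w_eps <= 0:
            raise ValueError("u_ref, gamma and w_eps must be > 0")


@dataclass
class PlasticityTraces:
    """Per-neuron voltage traces and per-synapse presynaptic traces.

    ``u_plus``/``u_minus``/``u_long`` have one entry per postsynaptic cell;
    ``x_bar`` has one entry per synapse (keyed by *arrival*, i.e. after the
    conduction delay).
    """

    u_plus: np.ndarray
    u_minus: np.ndarray
    u_long: np.ndarray
    x_bar: np.ndarray

    @classmethod
    def zeros(cls, n_post: int, n_syn_shape) -> "PlasticityTraces":
        return cls(u_plus=np.zeros(n_post), u_minus=np.zeros(n_post),
                   u_long=np.zeros(n_post), x_bar=np.zeros(n_syn_shape))


def crest_drive(u, params: PlasticityParams):
    """Suprathreshold drive of the homeostatic trace.

    Equals max(u - theta_plus, 0) during the stereotyped spike crest
    (u >= V_TMAX) and zero otherwise.
    """
    u = np.asarray(u, dtype=float)
    out = np.where(u >= params.crest_gate,
                   np.maximum(u - params.theta_plus, 0.0), 0.0)
    return out if out.ndim else float(out)


def update_traces(traces: PlasticityTraces, u, presyn_arrivals,
                  params: PlasticityParams,
                  dt: float = DT_MS) -> PlasticityTraces:
    """Advance all traces one Euler step.

    ``u`` is the post-clipping membrane voltage of the current step (so the
    crest of each spike is the constant V_PEAK).  ``presyn_arrivals`` is the
    binary arrival indicator, one entry per synapse; arrivals make ``x_bar``
    jump by 1.
    """
    u = np.asarray(u, dtype=float)
    x = np.asarray(presyn_arrivals, dtype=float)
    return PlasticityTraces(
        u_plus=traces.u_plus + dt * (u - traces.u_plus) / params.tau_uplus,
        u_minus=traces.u_minus + dt * (u - traces.u_minus) / params.tau_uminus,
        u_long=traces.u_long
        + dt * (crest_drive(u, params) - traces.u_long) / params.tau_long,
        x_bar=traces.x_bar * (1.0 - dt / params.tau_x) + x,
    )


def ltd_delta(w, traces: PlasticityTraces, X, params: PlasticityParams):
    """Depression on presynaptic arrival (non-positive).

    Proportional to recent depolarization (the u_minus trace above resting
    potential) and to the square of the long-term crest-activity trace.
    ``w`` is accepted for interface symmetry; LTD is weight-independent.
    """
    X = np.asarray(X, dtype=float)
    rect = np.maximum(traces.u_minus - params.theta_minus, 0.0)
    homeo = (traces.u_long / params.u_ref) ** 2
    return -params.A_LTD * homeo * rect * X


def ltp_delta(w, traces: PlasticityTraces, u, params: PlasticityParams):
    """Potentiation gated by the spike crest (non-negative).

    Requires the (crest-gated) voltage above theta_plus, recent
    depolarization (u_plus above resting potential) and a recent presynaptic
    arrival (x_bar > 0); attenuated by 1/(gamma * (w + w_eps)) so larger
    weights are harder to increase.
    """
    w = np.asarray(w, dtype=float)
    gate = crest_drive(u, params)
    depol = np.maximum(traces.u_plus - params.theta_minus, 0.0)
    return (params.A_LTP * gate * depol * traces.x_bar
            / (params.gamma * (w + params.w_eps)))


def apply_update(w, delta):
    """Apply a weight change with the hard floor at zero (no ceiling)."""
    return np.maximum(np.asarray(w, dtype=float) + delta, 0.0)
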