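# Model and methods

## Overview

`v1net` simulates a small patch of developing primary visual cortex: 100
excitatory (E) and 20 inhibitory (I) adaptive-exponential integrate-and-fire
neurons, fully connected, driven by ON/OFF retina-like input from 17x17
image patches. Feedforward and lateral E-E synapses follow a
voltage-dependent STDP rule with weight-dependent potentiation and a slow
homeostatic depression term; all synapses to and from I cells are fixed.
Under exposure to naturalistic stimuli the network develops
orientation-selective receptive fields and groups of reciprocally connected,
similarly tuned cells whose joint activity exhibits fast, non-persistent
attractor dynamics.

## Stimulus pipeline

Patches of 17x17 pixels are cut at uniformly random positions and random
rotations (bilinear interpolation) from difference-of-Gaussians-filtered
grayscale images (centre/surround s.d. 1 and 2 pixels; both Gaussians unit
sum, so a uniform field maps to zero). Each patch is mean-subtracted and
scaled to peak amplitude 1; a constant (degenerate) patch maps to all zeros
— null input. The signed patch is split into half-rectified ON and OFF
channel vectors, concatenated ON-first into a 578-vector whose entries set
the rates of independent Poisson trains via the intensity-to-rate factor
`rate_scale` (Hz per unit intensity). ON minus OFF reconstructs the patch
exactly; this identity is also how receptive fields are reconstructed from
feedforward weights.

Because the original image corpus is not available, the package generates
synthetic naturalistic images: Gaussian white noise shaped in the Fourier
domain to a 1/f amplitude spectrum (the hallmark second-order statistic of
natural scenes), zero mean, unit variance, default 128x128 with 50 patches
drawn per image. These images reproduce the spatial-correlation structure
that drives the development of oriented receptive fields; they do **not**
contain the higher-order structure of real scenes (edges, occlusions,
textures), so receptive fields learned here are quantitatively milder than
those from real photographs. The pixel-shuffle control permutes each
patch's 289 pixels uniformly at random after normalization, preserving the
intensity distribution exactly while destroying all spatial correlation.

## Neuron model

AdEx dynamics at a fixed 1-ms forward-Euler step (units mV, ms, pA, pF,
nS):

    C du/dt   = g_l (E_l - u) + g_l Delta_T exp((u - V_T)/Delta_T)
                - w_ad + z + I_FF + I_lat + I_noise
    tau_VT  dV_T/dt  = V_Trest - V_T
    tau_wad dw_ad/dt = -w_ad
    tau_z   dz/dt    = -z

A spike is registered when u reaches V_PEAK = 20 mV. The voltage is held at
V_PEAK for the detection step plus one clipped step and then reset to E_l,
giving every spike an identical two-sample crest; the plasticity rule reads
only this stereotyped crest, which removes the sensitivity of
voltage-dependent plasticity to the (timestep-dependent) shape of the
exponential runaway. On each spike V_T jumps to V_TMAX and decays back to
V_Trest, the adaptation current w_ad increments by b_wad, and the spike
afterpotential z is set to I_sp. w_ad has no subthreshold coupling: it
decays purely exponentially between spikes. The exponential term's argument
is capped at +20 so an Euler overshoot saturates instead of overflowing
(the clip to V_PEAK makes the exact overshoot value irrelevant).

Membrane parameters are the standard published AdEx set: C = 281 pF,
g_l = 30 nS, E_l = -70.6 mV, Delta_T = 2 mV, V_Trest = -50.4 mV,
V_TMAX = -30.4 mV, tau_VT = 50 ms, b_wad = 80.5 pA, tau_wad = 144 ms,
I_sp = 400 pA, tau_z = 40 ms. E and I cells use the same parameters.

## Plasticity rule

Feedforward and lateral E-E weights share one rule and one parameter set;
weights are clipped below at zero and have no upper bound. Per 1-ms step,
for a synapse with presynaptic-arrival indicator X(t) (arrival = spike time
plus conduction delay):

    LTD: dw = -A_LTD (u_long/u_ref)^2 max(u_minus - theta_minus, 0) X(t)
    LTP: dw = +A_LTP/(gamma (w + w_eps))
              x_bar max(u_crest - theta_plus, 0) max(u_plus - theta_minus, 0)

`u_plus` (tau 7 ms) and `u_minus` (tau 10 ms) are exponential traces of the
post-clipping membrane voltage; `x_bar` (tau 15 ms) is a per-synapse trace
of arrivals (+1 per arrival); `u_long` (tau 20 s) is the homeostatic trace,
driven by the suprathreshold excess max(u - theta_plus, 0) counted **only
during the spike crest** (u >= V_TMAX) — it is effectively a slow record of
firing, and its square makes depression a superlinear function of long-term
activity. `u_crest` in the LTP gate is likewise crest-gated, so
potentiation occurs only at (stereotyped) spikes. theta_minus = E_l;
theta_plus = (V_TMAX + V_Trest)/2 = -40.4 mV.

The 1/(gamma (w + w_eps)) factor makes large weights harder to increase,
replacing a hard weight ceiling and yielding a graded weight distribution
with a single smoothly decaying non-zero mode. `w_eps` keeps the factor
finite at w = 0 (lateral weights start at exactly zero and must be able to
grow); it acts as the soft scale below which potentiation stops
accelerating.

Updates are applied every step (event terms gated by spike/arrival
indicators), not batched. Within a step: currents are assembled from the
arrival queues, membranes integrate and spikes are detected, traces advance
using the post-clipping voltage, LTD is applied for this step's arrivals
and LTP for cells at their crest, and new spikes are queued.

## Network construction

Feedforward weights initialize uniformly on [0, w_ff_init_max]; lateral E-E
weights start at exactly zero; E-I, I-E and I-I weights are drawn uniformly
on [0, Wmax] (negated for I sources) and stay fixed. No autapses. Every
recurrent input is multiplied by A_lat = 5.0. Integer conduction delays per
directed connection are exponential with median 4 ms (scale = 4/ln 2),
rounded up to the 1-ms grid with a hard 1-ms minimum; feedforward Poisson
input arrives with zero delay (stimulus trains are generated, not
conducted). Every cell, E and I, receives an independent 1800-Hz Poisson
excitatory noise train of weight w_noise, which sustains sparse spontaneous
activity and bootstraps plasticity.

For the quadrupled network (400 E / 80 I) A_lat is divided by 4, keeping
the overall recurrent input per cell in the same regime; the +/-20%
robustness sweep multiplies A_lat, the three inhibitory maxima, gamma,
A_LTP and A_LTD by 1.2 or 0.8.

## Calibration of unprinted parameters

The intensity-to-rate factor, noise weight, inhibitory-path maxima,
feedforward initialization scale, and the plasticity magnitudes (A_LTP,
A_LTD, gamma, w_eps, u_ref) are not published; they were calibrated once,
as part of the model's construction, against the reported operating regime:
sparse spontaneous activity (most 50-ms bins empty), evoked firing with a
low median and a long high tail, inhibition strong enough that silencing it
produces runaway firing, and stable (non-oscillating) weight development at
the desk-scale training horizon. The governing constraints found during
calibration:

* the per-presentation gross weight change must stay small relative to the
  weight scale, or the 20-s homeostatic lag turns development into a global
  boom-bust relaxation oscillation;
* inhibitory cells must track the excitatory population with high gain
  (strong E->I), or transient population booms synchronize the cells'
  homeostatic cycles;
* the noise floor cannot be reduced much below its default: depression is
  gated by depolarization above rest and arrives with every presynaptic
  spike, so a cell that stops firing loses its remaining weights — noise-
  driven spikes keep the potentiation side of the balance alive.

* the stimulus-driven current must dominate the noise drive, or spikes are
  noise-timed and carry no learning signal (feedforward weights then relax
  to a flat, untuned profile);
* lateral weights reach a plasticity equilibrium whose value is nearly
  independent of the firing rate (potentiation and depression both scale
  with the pre/post rate product), so the lateral skeleton forms on the
  same schedule as — not after — feedforward tuning.  At the compressed
  horizon this ordering problem leaves a narrow corridor between a sparse,
  perpetually reorganizing regime and a lateral-amplified regime with
  elevated baseline rates; the defaults sit at the stable edge of that
  corridor.

Defaults: rate_scale = 800 Hz/unit, w_noise = 230 pA, Wmax_EI = 200,
Wmax_IE = 600, Wmax_II = 5 pA, w_ff_init_max = 40 pA, A_LTP = 0.65e-5,
A_LTD = 2e-3, gamma = 0.012/pA, w_eps = 30 pA, u_ref = 2.5 mV.

## Protocols and analyses

Training presents each patch for 300 ms followed by 50 ms of null input;
testing freezes all weights and counts spikes over the stimulus window.
Spontaneous activity is recorded with no stimulus (noise drive only),
default 100 s, binned at 50 ms; the 30% most active bins (ties to earlier
bins) form the spontaneous pattern set. Response clustering uses
correlation distance (1 - Pearson) with average linkage; the presentation
order is the dendrogram leaf order; zero-variance response columns get
correlation 0 by convention and sort last. The cluster count is the
silhouette-optimal partition (k = 2..8), reported as 1 when no partition
reaches silhouette 0.25.

The stimulus-mixture experiment blends two source patches at the
normalized-patch stage (so the endpoints are exactly the pure stimuli),
splits each blend into ON/OFF channels, records frozen-network responses,
normalizes all response vectors to unit norm and regresses each mixture
response on the two pure responses without intercept. Transition sharpness
is the largest single-step coefficient change along the 30-step series.
Subthreshold variants use the mean membrane potential per presentation with
crest samples excluded, baseline-corrected by the potential under null
input. Spike blocking removes the exponential AdEx term in every cell;
inhibition silencing pins I cells at rest; lateral ablation removes
recurrent inputs (all, or E-E only). The manipulation comparison (intact /
inhibition silenced / silenced plus lateral ablation) measures E-cell rates
under ongoing naturalistic stimulation: runaway excitation is a property of
the recurrently amplified active state, and the sparse noise-driven resting
state cannot ignite it.

## Problem sizes

Presets and the acceptance pipeline train on 50,000 presentations of
synthetic 1/f stimuli (the published experiment used 10^6 presentations of
natural-image patches; the desk-scale statistics are correspondingly
noisier, and the stabilization checkpoint correlation quantifies how far
development has converged at this horizon). Frozen-network statistics use
1,000 test presentations; the shuffled-pixel control uses a shorter
(12,000-presentation) run, which is ample for its qualitative endpoint —
feedforward-weight collapse and a single response group.

## Numerical choices and degenerate inputs

Fixed dt = 1 ms everywhere (test oracles use finer steps where stated);
spike detection at u >= V_PEAK; event queues sized so each directed pair
can hold one in-flight spike per delay cycle, which is sufficient because
the crest/reset sequence enforces a 2-ms minimum inter-spike interval.
Degenerate constant patches normalize to null input; zero-variance response
vectors are excluded from clustering and assigned correlation 0; an
all-equal lateral matrix has undefined transpose correlation and is
reported as NaN. The lateral presynaptic traces are stored lazily
(value + last-arrival time, exponentiation by table lookup), which is exact
to double precision for gaps up to 512 ms and truncates to zero beyond —
where the trace is below 1e-15 anyway.

## Known limitations

* Synthetic 1/f images lack the higher-order structure of natural scenes;
  receptive fields and cluster statistics are weaker than with a real
  corpus, and the quantitative connectivity statistics at the desk-scale
  horizon carry substantial run-to-run variance.
* The 20-s homeostatic trace is long relative to a compressed training
  horizon; at 20x compression the separation of timescales that the
  original 10^6-presentation schedule enjoys is only partially preserved.
* Because lateral and feedforward plasticity share one parameter set and
  lateral equilibrium is rate-independent, the lateral skeleton at this
  horizon is not yet aligned with stimulus tuning: reciprocity (transpose
  correlation), receptive-field similarity of strongly connected pairs and
  the weight share of response-correlated pairs all fall well short of
  their long-horizon values, and the baseline firing rate sits above the
  reported median.  Two-cell experiments show reciprocal weights require
  sustained episodic co-bursts, which only tuned cells with consolidated
  receptive fields deliver — a slow, late stage of development.
* Single interneuron class, no conductance synapses, no short-term
  plasticity, no distance structure — by design of the underlying model.
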