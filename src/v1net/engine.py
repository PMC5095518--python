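"""Forward-Euler simulation loop (1-ms timestep).

The engine advances every cell by one AdEx step per millisecond, assembling
for each cell its feedforward Poisson input, its delayed recurrent input
(scaled by the common factor A_lat), and its excitatory noise input.  Spikes
are queued into per-delay event buffers and delivered after their integer
conduction delay.  When plasticity is enabled, feedforward and lateral E-E
weights are updated every step by the voltage-dependent STDP rule, with LTD
gated by presynaptic arrivals at the synapse and LTP gated by the
postsynaptic spike crest.

Within each step the order of operations is: (1) deliver queued arrivals and
assemble input currents, (2) integrate all membranes and detect spikes,
(3) advance all plasticity traces using the post-clipping voltage,
(4) apply LTD for this step's arrivals and LTP for cells at their spike
crest, (5) queue newly emitted spikes.  A run is fully determined by (seed,
config, stimulus stream).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from numba import njit

from .network import Network
from .stimuli import N_CHANNELS

DT_MS = 1.0

#: phase codes for the stereotyped spike shape
_PH_NORMAL, _PH_CREST_HOLD, _PH_RESET = 0, 1, 2


@dataclass
class Protocol:
    """Timing of a stimulus-presentation protocol."""

    stim_duration: int = 300      # ms of stimulus per presentation
    blank_duration: int = 50      # ms of null input between presentations
    n_presentations: int = 1
    plastic: bool = False
    record_potentials: bool = False

    def __post_init__(self):
        if self.stim_duration < 0 or self.blank_duration < 0:
            raise ValueError("durations must be non-negative")
        if self.n_presentations < 1:
            raise ValueError("n_presentations must be >= 1")


@dataclass
class SpikeRaster:
    """Spike events of one run: (time_ms, neuron_id), sorted by time."""

    times: np.ndarray             # int64 ms
    neurons: np.ndarray           # int32 ids (E cells first, then I)
    duration: int                 # ms
    n_E: int
    n_I: int

    def counts(self) -> np.ndarray:
        """Total spikes per cell over the whole raster."""
        out = np.zeros(self.n_E + self.n_I, dtype=np.int64)
        np.add.at(out, self.neurons, 1)
        return out

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.neurons]),
                   fmt="%d", header="time_ms neuron_id")


class SimulationError(RuntimeError):
    pass


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _poisson_knuth(L):
    """Poisson sample given L = exp(-lambda)."""
    k = 0
    p = np.random.random()
    while p >= L:
        p *= np.random.random()
        k += 1
    return k


@njit(cache=True)
def _run_steps(
        # dynamic state (in place)
        u, vt, wad, z, phase,
        uplus, uminus, ulong, xbar_ff, xbar_lat, xbar_lat_t, decay_pow,
        # weights and structure (feedforward stored channel-major)
        W_ffT, W_rec, delays,
        # event ring buffer
        ev_count, ev_pre, ev_post,
        # time
        t_start, n_steps,
        # feedforward input: exp(-rate*dt) per channel, and whether any
        lam_L_ff, ff_active,
        # noise
        noise_L, w_noise,
        # neuron parameters
        C, g_l, E_l, Delta_T, V_Trest, V_TMAX, tau_VT, b_wad, tau_wad,
        I_sp, tau_z, V_PEAK, exp_enabled,
        # plasticity parameters
        plastic, A_LTD, A_LTP, tau_up, tau_um, tau_long, tau_x,
        th_minus, th_plus, crest_gate, u_ref, gamma, w_eps,
        # network-level parameters and manipulation flags
        nE, A_lat, lat_mode, inh_silenced,
        # outputs
        spike_counts, rast_t, rast_id, rast_n, record_raster,
        pot_sum, pot_cnt, record_pot,
        err):
    n = u.shape[0]
    D = ev_pre.shape[0]
    nC = xbar_ff.shape[0]
    n_pow = decay_pow.shape[0]
    I_rec = np.zeros(n)
    I_ff = np.zeros(nE)
    ff_ch = np.empty(nC, dtype=np.int32)
    ff_cnt = np.empty(nC, dtype=np.int64)
    ltd_post = np.empty(nE)
    decay_x = 1.0 - DT_MS / tau_x
    exp_cap = 20.0

    for istep in range(n_steps):
        t = t_start + istep
        slot = t % D
        m = ev_count[slot]

        # --- (1) deliver queued arrivals and draw feedforward/noise input
        for i in range(n):
            I_rec[i] = 0.0
        for k in range(m):
            pre = ev_pre[slot, k]
            post = ev_post[slot, k]
            if lat_mode == 2:
                continue
            if lat_mode == 1 and pre < nE and post < nE:
                continue
            I_rec[post] += A_lat * W_rec[post, pre]

        nff = 0
        for j in range(nE):
            I_ff[j] = 0.0
        if ff_active:
            for c in range(nC):
                L = lam_L_ff[c]
                if L >= 1.0:
                    continue
                cnt = _poisson_knuth(L)
                if cnt > 0:
                    ff_ch[nff] = c
                    ff_cnt[nff] = cnt
                    nff += 1
                    row = W_ffT[c]
                    for j in range(nE):
                        I_ff[j] += row[j] * cnt

        # --- (2) integrate membranes, detect spikes
        for i in range(n):
            if inh_silenced and i >= nE:
                u[i] = E_l
                continue
            ph = phase[i]
            # slow variables decay in every phase
            vt[i] += DT_MS * (V_Trest - vt[i]) / tau_VT
            wad[i] -= DT_MS * wad[i] / tau_wad
            z[i] -= DT_MS * z[i] / tau_z
            if ph == _PH_CREST_HOLD:
                u[i] = V_PEAK
                phase[i] = _PH_RESET
                continue
            u0 = E_l if ph == _PH_RESET else u[i]
            phase[i] = _PH_NORMAL
            i_noise = 0.0
            if noise_L < 1.0:
                i_noise = w_noise * _poisson_knuth(noise_L)
            i_total = I_rec[i] + i_noise
            if i < nE:
                i_total += I_ff[i]
            du = g_l * (E_l - u0) - wad[i] + z[i] + i_total
            if exp_enabled:
                arg = (u0 - vt[i]) / Delta_T
                if arg > exp_cap:
                    arg = exp_cap
                du += g_l * Delta_T * np.exp(arg)
            un = u0 + DT_MS * du / C
            if not np.isfinite(un):
                err[0] = t
                err[1] = i
                return
            if un >= V_PEAK:
                # spike: clip, stereotyped adjustments, queue arrivals
                u[i] = V_PEAK
                vt[i] = V_TMAX
                wad[i] += b_wad
                z[i] = I_sp
                phase[i] = _PH_CREST_HOLD
                spike_counts[i] += 1
                if record_raster and rast_n[0] < rast_t.shape[0]:
                    rast_t[rast_n[0]] = t
                    rast_id[rast_n[0]] = i
                    rast_n[0] += 1
                for j in range(n):
                    if j == i:
                        continue
                    s2 = (t + delays[j, i]) % D
                    k2 = ev_count[s2]
                    ev_pre[s2, k2] = i
                    ev_post[s2, k2] = j
                    ev_count[s2] = k2 + 1
            else:
                u[i] = un

        # --- (3) advance plasticity traces (E cells only)
        if plastic:
            for j in range(nE):
                uj = u[j]
                uplus[j] += DT_MS * (uj - uplus[j]) / tau_up
                uminus[j] += DT_MS * (uj - uminus[j]) / tau_um
                drive = 0.0
                if uj >= crest_gate and uj > th_plus:
                    drive = uj - th_plus
                ulong[j] += DT_MS * (drive - ulong[j]) / tau_long
            for c in range(nC):
                xbar_ff[c] *= decay_x
            for idx in range(nff):
                xbar_ff[ff_ch[idx]] += 1.0
            # lateral presynaptic traces are lazy: decayed on access
            for k in range(m):
                pre = ev_pre[slot, k]
                post = ev_post[slot, k]
                if pre < nE and post < nE:
                    gap = t - xbar_lat_t[post, pre]
                    old = xbar_lat[post, pre] * decay_pow[gap] \
                        if gap < n_pow else 0.0
                    xbar_lat[post, pre] = old + 1.0
                    xbar_lat_t[post, pre] = t

            # --- (4) LTD on arrivals, LTP at spike crests
            for j in range(nE):
                r = uminus[j] - th_minus
                if r < 0.0:
                    r = 0.0
                h = ulong[j] / u_ref
                ltd_post[j] = A_LTD * h * h * r
            for idx in range(nff):
                row = W_ffT[ff_ch[idx]]
                for j in range(nE):
                    dj = ltd_post[j]
                    if dj > 0.0:
                        w = row[j] - dj
                        row[j] = w if w > 0.0 else 0.0
            for k in range(m):
                pre = ev_pre[slot, k]
                post = ev_post[slot, k]
                if pre < nE and post < nE:
                    w = W_rec[post, pre] - ltd_post[post]
                    W_rec[post, pre] = w if w > 0.0 else 0.0
            for j in range(nE):
                if u[j] >= crest_gate:
                    depol = uplus[j] - th_minus
                    gate = u[j] - th_plus
                    if depol > 0.0 and gate > 0.0:
                        f = A_LTP * gate * depol
                        for c in range(nC):
                            xb = xbar_ff[c]
                            if xb > 1e-12:
                                w = W_ffT[c, j]
                                W_ffT[c, j] = w + f * xb / (gamma * (w + w_eps))
                        for i2 in range(nE):
                            if i2 != j:
                                gap = t - xbar_lat_t[j, i2]
                                if gap < n_pow:
                                    xb = xbar_lat[j, i2] * decay_pow[gap]
                                    if xb > 1e-12:
                                        w = W_rec[j, i2]
                                        W_rec[j, i2] = (
                                            w + f * xb
                                            / (gamma * (w + w_eps)))

        # --- (5) subthreshold-potential recording (crest samples excluded)
        if record_pot:
            for j in range(nE):
                if u[j] < crest_gate:
                    pot_sum[j] += u[j]
                    pot_cnt[j] += 1

        ev_count[slot] = 0


class Simulation:
    """A live simulation session bound to one network.

    Owns all dynamic state (membranes, traces, event queues).  Weights are
    edited in place on the bound :class:`~v1net.network.Network` when
    plasticity is on; call sites that need the original intact should pass a
    ``network.copy()``.
    """

    _ZERO_L = None  # cached all-ones exp(-0) vector

    def __init__(self, network: Network, seed: int, plastic: bool = False):
        network.validate()
        self.network = network
        self.plastic = plastic and not network.spikes_blocked
        n, nE = network.n_total, network.n_E
        p = network.neuron_params
        self.u = np.full(n, p.E_l)
        self.vt = np.full(n, p.V_Trest)
        self.wad = np.zeros(n)
        self.z = np.zeros(n)
        self.phase = np.zeros(n, dtype=np.int8)
        self.uplus = np.full(nE, p.E_l)
        self.uminus = np.full(nE, p.E_l)
        self.ulong = np.zeros(nE)
        self.xbar_ff = np.zeros(N_CHANNELS)
        self.xbar_lat = np.zeros((nE, nE))
        self.xbar_lat_t = np.zeros((nE, nE), dtype=np.int64)
        # lazy-trace decay lookup: (1 - dt/tau_x)^k, truncated to zero
        pl = network.plasticity_params
        self.decay_pow = (1.0 - 1.0 / pl.tau_x) ** np.arange(512)
        self.W_ffT = np.ascontiguousarray(network.W_ff.T)  # channel-major
        self.W_rec = network.recurrent_matrix()
        D = int(network.delays.max()) + 1
        self.ev_count = np.zeros(D, dtype=np.int64)
        self.ev_pre = np.zeros((D, n * n), dtype=np.int32)
        self.ev_post = np.zeros((D, n * n), dtype=np.int32)
        self.t = 0
        self.spike_counts = np.zeros(n, dtype=np.int64)
        self.pot_sum = np.zeros(nE)
        self.pot_cnt = np.zeros(nE, dtype=np.int64)
        self._rast_t = np.zeros(0, dtype=np.int64)
        self._rast_id = np.zeros(0, dtype=np.int32)
        self._rast_n = np.zeros(1, dtype=np.int64)
        self._err = np.full(2, -1, dtype=np.int64)
        _seed(int(seed) & 0x7FFFFFFF)

    def run(self, duration: int, ff_rates: np.ndarray | None = None,
            record_raster: bool = False, raster_capacity: int = 0) -> None:
        """Advance ``duration`` ms with constant feedforward rates (Hz)."""
        net = self.network
        cfg = net.config
        p = net.neuron_params
        pl = net.plasticity_params
        if ff_rates is None or not np.any(ff_rates):
            lam_L = np.ones(N_CHANNELS)
            ff_active = False
        else:
            rates = np.asarray(ff_rates, dtype=float)
            if rates.shape != (N_CHANNELS,):
                raise ValueError(f"ff_rates must have length {N_CHANNELS}")
            if np.any(rates < 0):
                raise ValueError("rates must be non-negative")
            lam_L = np.exp(-rates * DT_MS * 1e-3)
            ff_active = True
        noise_lam = cfg.noise_rate * DT_MS * 1e-3
        noise_L = float(np.exp(-noise_lam)) if noise_lam > 0 else 1.0
        if record_raster and self._rast_t.shape[0] < raster_capacity:
            self._rast_t = np.zeros(raster_capacity, dtype=np.int64)
            self._rast_id = np.zeros(raster_capacity, dtype=np.int32)
        lat_mode = {"none": 0, "ee_only": 1, "all": 2}[net.lateral_disabled]
        exp_enabled = p.exponential_enabled and not net.spikes_blocked

        _run_steps(
            self.u, self.vt, self.wad, self.z, self.phase,
            self.uplus, self.uminus, self.ulong, self.xbar_ff, self.xbar_lat,
            self.xbar_lat_t, self.decay_pow,
            self.W_ffT, self.W_rec, net.delays,
            self.ev_count, self.ev_pre, self.ev_post,
            self.t, int(duration),
            lam_L, ff_active,
            noise_L, cfg.w_noise,
            p.C, p.g_l, p.E_l, p.Delta_T, p.V_Trest, p.V_TMAX, p.tau_VT,
            p.b_wad, p.tau_wad, p.I_sp, p.tau_z, p.V_PEAK, exp_enabled,
            self.plastic, pl.A_LTD, pl.A_LTP, pl.tau_uplus, pl.tau_uminus,
            pl.tau_long, pl.tau_x, pl.theta_minus, pl.theta_plus,
            pl.crest_gate, pl.u_ref, pl.gamma, pl.w_eps,
            net.n_E, cfg.A_lat, lat_mode, net.inhibition_silenced,
            self.spike_counts, self._rast_t, self._rast_id, self._rast_n,
            record_raster, self.pot_sum, self.pot_cnt,
            True,
            self._err)
        if self._err[0] >= 0:
            raise SimulationError(
                f"numerical blow-up at t={self._err[0]} ms "
                f"in neuron {self._err[1]}")
        self.t += int(duration)
        if self.plastic:
            self.network.set_lateral_from_combined(self.W_rec)
            self.network.W_ff[:] = self.W_ffT.T

    def raster(self) -> SpikeRaster:
        n = int(self._rast_n[0])
        return SpikeRaster(times=self._rast_t[:n].copy(),
                           neurons=self._rast_id[:n].copy(),
                           duration=self.t, n_E=self.network.n_E,
                           n_I=self.network.n_I)


def step(network: Network, ff_rates: np.ndarray | None = None,
         seed: int = 0, sim: Simulation | None = None,
         plastic: bool = False) -> tuple[Simulation, np.ndarray]:
    """Advance an existing (or fresh) session by a single 1-ms step.

    Returns the session and the ids of cells that spiked on this step.
    """
    if sim is None:
        sim = Simulation(network, seed=seed, plastic=plastic)
    before = sim.spike_counts.copy()
    sim.run(1, ff_rates)
    spiked = np.flatnonzero(sim.spike_counts - before)
    return sim, spiked


def train(network: Network, patch_stream, n_presentations: int,
          seed: int = 0, protocol: Protocol | None = None,
          checkpoint_fracs: tuple = (0.5, 1.0),
          log_every: int = 0) -> dict:
    """Expose the network to a stream of patches with plasticity enabled.

    ``patch_stream`` must provide ``next_on_off()``.  Returns a dict mapping
    each checkpoint fraction to a flattened copy of the lateral E-E weight
    vector at that point (used for the stabilization statistic).  The
    network's weights are updated in place.
    """
    proto = protocol or Protocol(plastic=True)
    if not (protocol is None or protocol.plastic):
        raise ValueError("training requires a plastic protocol")
    if n_presentations == 0:
        return {1.0: network.W_lat_EE.flatten().copy()}
    sim = Simulation(network, seed=seed, plastic=True)
    rate_scale = network.config.rate_scale
    marks = {max(1, int(round(f * n_presentations))): f
             for f in checkpoint_fracs}
    checkpoints = {}
    for k in range(1, n_presentations + 1):
        rates = rate_scale * patch_stream.next_on_off()
        sim.run(proto.stim_duration, rates)
        sim.run(proto.blank_duration, None)
        if k in marks:
            checkpoints[marks[k]] = network.W_lat_EE.flatten().copy()
        if log_every and k % log_every == 0:
            nE = network.n_E
            rate = sim.spike_counts[:nE].sum() / nE / (
                k * (proto.stim_duration + proto.blank_duration) * 1e-3)
            print(f"presentation {k}/{n_presentations} "
                  f"mean_E_rate_Hz {rate:.2f} "
                  f"ff_norm {np.linalg.norm(network.W_ff):.1f} "
                  f"lat_norm {np.linalg.norm(network.W_lat_EE):.1f}")
    network.validate()
    return checkpoints


def test_responses(network: Network, stimuli, seed: int = 0,
                   protocol: Protocol | None = None):
    """Frozen-weight responses to a list of ON/OFF stimulus vectors.

    Returns a :class:`~v1net.analysis.ResponseMatrix` of total spike counts
    per E cell per presentation, counted over the stimulus window; when the
    protocol requests it, mean subthreshold potentials (crest samples
    excluded) are recorded as well.
    """
    from .analysis import ResponseMatrix

    proto = protocol or Protocol()
    if proto.plastic:
        raise ValueError("test_responses requires frozen weights "
                         "(protocol.plastic must be False)")
    net = network
    nE = net.n_E
    sim = Simulation(net, seed=seed, plastic=False)
    P = len(stimuli)
    counts = np.zeros((nE, P))
    potentials = np.zeros((nE, P)) if proto.record_potentials else None
    rate_scale = net.config.rate_scale
    for k, on_off in enumerate(stimuli):
        rates = rate_scale * np.asarray(on_off, dtype=float)
        c0 = sim.spike_counts[:nE].copy()
        sim.pot_sum[:] = 0.0
        sim.pot_cnt[:] = 0
        sim.run(proto.stim_duration, rates)
        counts[:, k] = sim.spike_counts[:nE] - c0
        if potentials is not None:
            with np.errstate(invalid="ignore"):
                potentials[:, k] = np.where(
                    sim.pot_cnt > 0, sim.pot_sum / np.maximum(sim.pot_cnt, 1),
                    net.neuron_params.E_l)
        sim.run(proto.blank_duration, None)
    return ResponseMatrix(counts=counts,
                          stimulus_ids=np.arange(P),
                          stim_duration=proto.stim_duration,
                          potentials=potentials)


def record_spontaneous(network: Network, duration: int = 100_000,
                       seed: int = 0) -> SpikeRaster:
    """Record activity with no stimulus (noise drive only), frozen weights."""
    sim = Simulation(network, seed=seed, plastic=False)
    # the 2-sample crest enforces a 2-ms minimum ISI, so this bound is exact
    cap = max(int((duration // 2 + 1) * network.n_total), 10_000)
    sim.run(int(duration), None, record_raster=True, raster_capacity=cap)
    return sim.raster()


MANIPULATIONS = ("silence_inhibition", "disable_lateral", "block_spikes")


def apply_manipulation(network: Network, kind: str,
                       lateral_scope: str = "all") -> Network:
    """Return a copy of the network with one manipulation applied.

    ``silence_inhibition`` prevents all I cells from spiking;
    ``disable_lateral`` removes recurrent inputs (``lateral_scope`` selects
    ``"ee_only"`` or ``"all"``, the latter covering both excitatory and
    inhibitory lateral connections); ``block_spikes`` removes the exponential
    spike-initiation term from every cell so no cell can spike while
    subthreshold dynamics are preserved.
    """
    net = network.copy()
    if kind == "silence_inhibition":
        net.inhibition_silenced = True
    elif kind == "disable_lateral":
        if lateral_scope not in ("ee_only", "all"):
            raise ValueError("lateral_scope must be 'ee_only' or 'all'")
        net.lateral_disabled = lateral_scope
    elif kind == "block_spikes":
        net.spikes_blocked = True
        net.neuron_params = _dc_replace(net.neuron_params,
                                        exponential_enabled=False)
    else:
        raise ValueError(f"unknown manipulation {kind!r}; "
                         f"expected one of {MANIPULATIONS}")
    return net
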