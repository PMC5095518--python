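"""Construction of the 100 E + 20 I fully connected cortical patch.

Connectivity conventions (all weight matrices are [postsynaptic, presynaptic]):

* ``W_ff``      (n_E x 578, >= 0)  plastic feedforward weights from the ON/OFF
                channels; initialized uniformly at random.
* ``W_lat_EE``  (n_E x n_E, >= 0)  plastic lateral weights between principal
                cells; initialized to exactly zero; zero diagonal (no autapses).
* ``W_EI``      (n_I x n_E, >= 0)  fixed E->I weights, uniform on [0, Wmax_EI].
* ``W_IE``      (n_E x n_I, <= 0)  fixed I->E weights, uniform then negated.
* ``W_II``      (n_I x n_I, <= 0)  fixed I->I weights, uniform then negated,
                zero diagonal.

Every recurrent input is multiplied by the common factor ``A_lat``.  Each
directed inter-neuron connection carries a fixed integer conduction delay
drawn from an exponential distribution with median 4 ms (hard minimum 1 ms);
feedforward Poisson input arrives with zero delay.  Every cell additionally
receives an excitatory Poisson noise train (1800 Hz) of fixed weight
``w_noise``, which sustains sparse spontaneous activity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np

from .neuron import NeuronParams
from .plasticity import PlasticityParams
from .stimuli import N_CHANNELS


@dataclass(frozen=True)
class NetworkConfig:
    """Structural and input parameters of the network."""

    n_E: int = 100
    n_I: int = 20
    A_lat: float = 5.0          # common multiplier of all recurrent inputs
    Wmax_EI: float = 200.0      # pA, E->I uniform maximum
    Wmax_IE: float = 600.0      # pA, I->E uniform maximum (stored negative)
    Wmax_II: float = 5.0        # pA, I->I uniform maximum (stored negative)
    w_ff_init_max: float = 40.0  # pA, feedforward initialization maximum
    delay_median: float = 4.0   # ms
    delay_min: int = 1          # ms
    noise_rate: float = 1800.0  # Hz, per-cell excitatory noise
    w_noise: float = 230.0      # pA, weight of each noise spike
    rate_scale: float = 800.0   # Hz per unit ON/OFF intensity
    seed: int = 0

    def __post_init__(self):
        if self.n_E <= 0 or self.n_I <= 0:
            raise ValueError("n_E and n_I must be positive")
        if min(self.Wmax_EI, self.Wmax_IE, self.Wmax_II) <= 0:
            raise ValueError("inhibitory-path weight maxima must be > 0")
        if self.delay_min < 1:
            raise ValueError("delay_min must be at least 1 ms")
        if self.noise_rate < 0 or self.rate_scale < 0 or self.w_noise < 0:
            raise ValueError("rates and noise weight must be non-negative")


@dataclass
class Network:
    """Weight matrices, delays, parameters and manipulation flags."""

    config: NetworkConfig
    W_ff: np.ndarray
    W_lat_EE: np.ndarray
    W_EI: np.ndarray
    W_IE: np.ndarray
    W_II: np.ndarray
    delays: np.ndarray          # (n_total, n_total) int32 ms, [post, pre]
    neuron_params: NeuronParams = field(default_factory=NeuronParams)
    plasticity_params: PlasticityParams = field(default_factory=PlasticityParams)
    # manipulation flags
    inhibition_silenced: bool = False
    lateral_disabled: str = "none"    # none | ee_only | all
    spikes_blocked: bool = False

    @property
    def n_E(self) -> int:
        return self.config.n_E

    @property
    def n_I(self) -> int:
        return self.config.n_I

    @property
    def n_total(self) -> int:
        return self.config.n_E + self.config.n_I

    def validate(self) -> None:
        """Assert the structural invariants (signs, zero diagonals, shapes)."""
        nE, nI = self.n_E, self.n_I
        assert self.W_ff.shape == (nE, N_CHANNELS)
        assert self.W_lat_EE.shape == (nE, nE)
        assert self.W_EI.shape == (nI, nE)
        assert self.W_IE.shape == (nE, nI)
        assert self.W_II.shape == (nI, nI)
        if np.any(self.W_ff < 0) or np.any(self.W_lat_EE < 0) \
                or np.any(self.W_EI < 0):
            raise AssertionError("excitatory weights must be non-negative")
        if np.any(self.W_IE > 0) or np.any(self.W_II > 0):
            raise AssertionError("inhibitory weights must be non-positive")
        if np.any(np.diag(self.W_lat_EE) != 0) or np.any(np.diag(self.W_II) != 0):
            raise AssertionError("autapses are disallowed")
        if np.any(self.delays < self.config.delay_min):
            raise AssertionError("delays below the hard minimum")

    def copy(self) -> "Network":
        return Network(
            config=self.config, W_ff=self.W_ff.copy(),
            W_lat_EE=self.W_lat_EE.copy(), W_EI=self.W_EI.copy(),
            W_IE=self.W_IE.copy(), W_II=self.W_II.copy(),
            delays=self.delays.copy(), neuron_params=self.neuron_params,
            plasticity_params=self.plasticity_params,
            inhibition_silenced=self.inhibition_silenced,
            lateral_disabled=self.lateral_disabled,
            spikes_blocked=self.spikes_blocked)

    def recurrent_matrix(self) -> np.ndarray:
        """Combined (n_total x n_total) recurrent matrix, [post, pre].

        E cells first (indices 0..n_E-1), then I cells.  Inhibitory entries
        are negative; the A_lat multiplier is *not* folded in.
        """
        nE, nI = self.n_E, self.n_I
        W = np.zeros((nE + nI, nE + nI))
        W[:nE, :nE] = self.W_lat_EE
        W[nE:, :nE] = self.W_EI
        W[:nE, nE:] = self.W_IE
        W[nE:, nE:] = self.W_II
        return W

    def set_lateral_from_combined(self, W: np.ndarray) -> None:
        """Write the plastic E-E block back from a combined matrix."""
        nE = self.n_E
        self.W_lat_EE = W[:nE, :nE].copy()
        np.fill_diagonal(self.W_lat_EE, 0.0)


def sample_delays(n: int, config: NetworkConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` integer conduction delays (ms).

    Exponential with median ``delay_median`` (scale = median / ln 2), rounded
    up to the 1-ms integration grid, with the hard minimum ``delay_min``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    scale = config.delay_median / np.log(2.0)
    raw = rng.exponential(scale, size=n)
    return np.maximum(np.ceil(raw), config.delay_min).astype(np.int32)


def build_network(config: NetworkConfig,
                  neuron_params: NeuronParams | None = None,
                  plasticity_params: PlasticityParams | None = None,
                  rng: np.random.Generator | None = None) -> Network:
    """Construct a network with the stated initialization conventions.

    Feedforward weights start uniform on [0, w_ff_init_max]; lateral E-E
    weights start at exactly zero; inhibitory-path weights are uniform on
    [0, Wmax] and (for I sources) switched to negative sign, then fixed
    forever.  Same seed, same network, bit for bit.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nE, nI = config.n_E, config.n_I
    n = nE + nI
    W_ff = rng.uniform(0.0, config.w_ff_init_max, size=(nE, N_CHANNELS))
    W_lat_EE = np.zeros((nE, nE))
    W_EI = rng.uniform(0.0, config.Wmax_EI, size=(nI, nE))
    W_IE = -rng.uniform(0.0, config.Wmax_IE, size=(nE, nI))
    W_II = -rng.uniform(0.0, config.Wmax_II, size=(nI, nI))
    np.fill_diagonal(W_II, 0.0)
    delays = sample_delays(n * n, config, rng).reshape(n, n)
    np.fill_diagonal(delays, config.delay_min)  # diagonal is never used
    net = Network(config=config, W_ff=W_ff, W_lat_EE=W_lat_EE, W_EI=W_EI,
                  W_IE=W_IE, W_II=W_II, delays=delays,
                  neuron_params=neuron_params or NeuronParams(),
                  plasticity_params=plasticity_params or PlasticityParams())
    net.validate()
    return net


def scale_for_size(config: NetworkConfig, factor: int) -> NetworkConfig:
    """Scale the population by ``factor``, dividing A_lat accordingly.

    Multiplying both populations by ``factor`` while dividing the common
    lateral multiplier keeps the overall recurrent input per cell in the
    same regime relative to the (unchanged) feedforward input.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    return dataclasses.replace(config, n_E=config.n_E * factor,
                               n_I=config.n_I * factor,
                               A_lat=config.A_lat / factor)


def perturb_config(config: NetworkConfig, plasticity: PlasticityParams,
                   factor: float) -> tuple[NetworkConfig, PlasticityParams]:
    """Multiply the seven free parameters by ``factor`` (robustness sweep).

    The swept parameters are A_lat, Wmax_II, Wmax_IE, Wmax_EI, gamma, A_LTP
    and A_LTD; factors 1.2 and 0.8 give the +/-20% conditions.
    """
    cfg = dataclasses.replace(config, A_lat=config.A_lat * factor,
                              Wmax_II=config.Wmax_II * factor,
                              Wmax_IE=config.Wmax_IE * factor,
                              Wmax_EI=config.Wmax_EI * factor)
    pl = dataclasses.replace(plasticity, gamma=plasticity.gamma * factor,
                             A_LTP=plasticity.A_LTP * factor,
                             A_LTD=plasticity.A_LTD * factor)
    return cfg, pl


def save_network(net: Network, path) -> None:
    """Serialize a network to HDF5 (weights, delays, all parameters)."""
    with h5py.File(path, "w") as f:
        for name in ("W_ff", "W_lat_EE", "W_EI", "W_IE", "W_II", "delays"):
            f.create_dataset(name, data=getattr(net, name))
        g = f.create_group("config")
        for k, v in dataclasses.asdict(net.config).items():
            g.attrs[k] = v
        g = f.create_group("neuron_params")
        for k, v in dataclasses.asdict(net.neuron_params).items():
            g.attrs[k] = v
        g = f.create_group("plasticity_params")
        for k, v in dataclasses.asdict(net.plasticity_params).items():
            g.attrs[k] = v
        g = f.create_group("flags")
        g.attrs["inhibition_silenced"] = net.inhibition_silenced
        g.attrs["lateral_disabled"] = net.lateral_disabled
        g.attrs["spikes_blocked"] = net.spikes_blocked


def load_network(path) -> Network:
    """Inverse of :func:`save_network`."""
    with h5py.File(path, "r") as f:
        def attrs(group, cls):
            kw = {k: v for k, v in f[group].attrs.items()}
            for k in list(kw):
                if isinstance(kw[k], np.generic):
                    kw[k] = kw[k].item()
            return cls(**kw)
        net = Network(
            config=attrs("config", NetworkConfig),
            W_ff=f["W_ff"][...], W_lat_EE=f["W_lat_EE"][...],
            W_EI=f["W_EI"][...], W_IE=f["W_IE"][...], W_II=f["W_II"][...],
            delays=f["delays"][...].astype(np.int32),
            neuron_params=attrs("neuron_params", NeuronParams),
            plasticity_params=attrs("plasticity_params", PlasticityParams),
            inhibition_silenced=bool(f["flags"].attrs["inhibition_silenced"]),
            lateral_disabled=str(f["flags"].attrs["lateral_disabled"]),
            spikes_blocked=bool(f["flags"].attrs["spikes_blocked"]))
    net.validate()
    return net
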