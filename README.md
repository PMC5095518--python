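# v1net

A spiking-network model of developing primary visual cortex in which fast,
non-persistent attractor dynamics emerge spontaneously from a single
voltage-dependent plasticity rule.

## The science

The model is a fully connected network of 100 excitatory and 20 inhibitory
adaptive-exponential (AdEx) integrate-and-fire neurons. Each excitatory cell
receives feedforward Poisson input from 578 ON/OFF retinal channels encoding
a 17x17 patch of a difference-of-Gaussians-filtered naturalistic image.
Feedforward and lateral excitatory synapses are plastic under a
voltage-dependent STDP rule with two structural ingredients:

* **weight-dependent potentiation** — LTP is scaled by
  `1/(gamma (w + w_eps))`, so strong synapses saturate softly instead of
  hitting a hard ceiling, and
* **slow homeostatic depression** — LTD is scaled by the square of a 20-second
  trace of suprathreshold activity, so persistently active cells depress
  their inputs until firing returns to a sparse operating point.

Under continued exposure to naturalistic patches (300 ms per patch, 50 ms
blank) the excitatory cells develop localized receptive fields, and the
initially empty lateral connectivity organizes into a sparse skeleton in
which a small fraction of connections carries almost all of the weight.
Cells bound by strong lateral weights respond to similar stimuli; their
joint activation is stimulus-locked and collapses within tens of
milliseconds of stimulus offset — attractor-like selection without
persistent activity. Silencing inhibition produces runaway firing that is
rescued by ablating the learned lateral connections, and shuffling the
stimulus pixels (which preserves the intensity distribution but destroys
spatial correlations) prevents any of this structure from forming.

See `docs/methods.md` for the full model description, parameter table,
calibration rationale and known limitations.

## Worked example

Train a network on 2,000 synthetic naturalistic patches (a few minutes;
the full default schedule is 50,000), then probe it:

```
v1net train --seed 1 --n-presentations 2000 --out-dir run1
v1net test  --seed 2 --network run1/trained_network.h5 --out-dir run1
v1net spontaneous --seed 3 --network run1/trained_network.h5 --out-dir run1
v1net mixture --seed 4 --network run1/trained_network.h5 --condition full
```

The same pipeline from Python:

```python
from v1net import analysis
from v1net.config import load_config
from v1net.experiments import develop, evoked_test, response_stats

cfg = load_config()                       # calibrated defaults
net, ckpt = develop(cfg, seed=1, n_presentations=2000)
rm, patches = evoked_test(cfg, net, seed=2, n_test=200)
print(response_stats(net, rm))
print("clusters:", analysis.count_response_clusters(rm))
```

which prints (2,000 presentations is early development — rates are still
settling toward their 50,000-presentation values):

```
{'median_rate_hz': 26.666..., 'max_rate_hz': 30.0,
 'median_max_rate_hz': 26.666..., 'correlated_pair_weight_share': 0.0446...}
clusters: 2
```

Figure-style presets (`fig2` … `fig8`, `robustness_sweep`, `size_x4`) run
complete experiments end to end:

```
v1net preset --name fig5 --seed 1 --out-dir preset_out
```

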