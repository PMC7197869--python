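# msninfer

Simulation and simulation-based inference for striatal medium-spiny-neuron
(MSN) networks.  MSNs — over 90% of striatal cells — inhibit each other
through sparse collaterals, and in vivo they fire in slow coherent bursts
whose loss is a hallmark of striatal pathology such as Huntington's
disease.  `msninfer` is for researchers who want to ask, quantitatively:
*given only single-unit spike trains, what levels of feedforward
excitation and recurrent inhibition best explain them?*

The package implements the full loop:

* **`msninfer.network` / `msninfer.cell`** — a deterministic network of N
  conductance-based MSN cells (default N = 2500) wired randomly with
  probability p = 0.2.  Two dimensionless parameters define a simulation:
  excitation g_E (per-cell constant conductance
  G_ex ~ U[0.04381, 0.04381 + 0.002 g_E]) and inhibition g_I (per-synapse
  G_syn ~ U[0.001 g_I, 0.001 g_I + 0.001], first-order gating
  ds/dt = 2 H(V_pre)(1 − s) − B s, chloride reversal −80 mV).  As g_I
  grows the network crosses from a frozen winner-take-all state to an
  active regime of chaotic, bursty firing; near the transition the
  activity is slow, coherent and low-dimensional.
* **`msninfer.features` / `msninfer.spectra`** — fifteen ISI statistics
  per 200-s spike-train segment (serial correlations ρ(1), ρ(2); μ, CV,
  rescaled skew, rate; local-CV quintiles; ML lognormal, gamma and
  inverse-Gaussian parameters), plus censorship-corrected cumulative ISI
  distributions, Kolmogorov-Smirnov distances to the fitted families and
  Morlet-wavelet power spectra.
* **`msninfer.klfit`** — the inference engine: observed and simulated
  feature sets are reduced to joint above/below-median distributions over
  random 7-feature subsets, compared by Kullback-Leibler distance
  K = Σ P_D ln(P_D/(P_M + ε)) across a (g_E, g_I) simulation library, and
  turned into weighted estimates gE*, gI* by a K^(−3) soft minimum with
  inverse-spread aggregation over 30 subsets.  Includes half-split
  recovery validation and errors-in-both-coordinates trend regression.
  `KLParameterEstimator` follows the scikit-learn estimator protocol.
* **`msninfer.population`** — multi-unit diagnostics: explained-variance
  entropy of binned-rate correlations (dimensionality), K-means raster
  ordering, active-cell accounting and the mean-field rescaling r·g_I/g_E.
* **`msninfer.synthetic` / `msninfer.segments`** — surrogate
  "experimental" sessions (two-state Markov-modulated Poisson cells with
  bursty and near-Poisson presets), 200-s segmentation conventions,
  analysis filters and age-interval dataset construction, so the whole
  pipeline runs without any external data.

## Worked example

```python
from msninfer import NetworkConfig, simulate, ipsp_probe
from msninfer.network import scaled_screen_realization
from msninfer.pipeline import result_features

amp, half_decay, area = ipsp_probe(33.0)
print(f"IPSP at g_I=33: {amp:.2f} mV peak, {half_decay:.1f} ms half-decay, "
      f"{area:.0f} uV*s area")

cfg = NetworkConfig(n_cells=300, p_connect=100/299, g_e=50.0, g_i=15.0,
                    duration=60.0, dt=0.1, seed=8000)
res = simulate(scaled_screen_realization(cfg), cfg)
feats = result_features(res)
print(f"{len(feats)} active cells; "
      f"mean rate {feats.rate.mean():.1f} Hz, mean ISI CV {feats.cv.mean():.2f}, "
      f"mean sigma_LN {feats.sigma_ln.mean():.2f}")
```

prints

```
IPSP at g_I=33: 1.80 mV peak, 19.9 ms half-decay, 53 uV*s area
86 active cells; mean rate 35.8 Hz, mean ISI CV 0.97, mean sigma_LN 0.86
```

The first line is the two-cell synapse probe: at the inhibition level that
best fits healthy (wild-type-like) data, a single presynaptic spike
hyperpolarizes a just-subthreshold postsynaptic cell by ~1.8 mV with a
~20 ms half-decay — squarely in the physiological IPSP range, which is
what makes the fitted parameter region credible.  The second line runs a
small screening-scale network near the frozen-to-active transition and
extracts the per-cell feature table used for fitting: roughly a quarter
of the cells are active, their ISI irregularity (CV ≈ 1) and lognormal
shape below 1 marking the edge of the transition.

A command-line interface mirrors the library
(`msninfer simulate|synth|features|fit|sweep|recover|popdyn|trend`); spike
trains travel as `cell_id<TAB>time_s` TSV with JSON provenance sidecars,
features and KL grids as CSV.

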