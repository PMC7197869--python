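# Methods

`msninfer` implements a complete loop for studying how striatal activity
statistics constrain network parameters: a recurrent inhibitory network of
medium spiny neurons (MSNs) parameterized by feedforward excitation `g_E`
and recurrent inhibition `g_I`; a battery of fifteen inter-spike-interval
(ISI) statistics ("features"); and a simulation-based inference engine that
estimates `(g_E, g_I)` for any single-unit spike-train dataset by
Kullback-Leibler (KL) matching of feature distributions against a library
of simulations.

## Network model

The network has `N` identical single-compartment MSN cells wired by
directed inhibitory collaterals; each ordered pair is connected
independently with probability `p` (defaults `N = 2500`, `p = 0.2`, giving
a binomial in-degree, mean ~500, SD ~20).  Two dimensionless levels define
a simulation:

* excitation `g_E`: each cell receives a constant excitatory conductance
  `G_ex ~ U[0.04381, 0.04381 + 0.002 g_E]` (cation reversal 0 mV), fixed
  for the whole run.  The draw floor sits just above the single-cell
  firing threshold (rheobase conductance 0.0437 by bisection), so every
  cell is driven suprathreshold in isolation;
* inhibition `g_I`: each collateral synapse has maximal conductance
  `G_syn ~ U[0.001 g_I, 0.001 g_I + 0.001]` (chloride reversal −80 mV),
  gated by `ds/dt = a H(V_pre)(1 − s) − B s` with `a = 2` and per-cell
  `B ~ U[0.08, 0.09]` (so one presynaptic spike opens the synapse for
  roughly an IPSP timescale of ~12 ms).  `H` is 1 while the presynaptic
  membrane overshoots 0 mV.

Simulations are fully deterministic given the realization: there is no
external noise; all firing irregularity is generated by the recurrent
inhibitory dynamics.  Simulations at one `g_I` level share one master seed
across all `g_E`, so they differ only in the excitation scaling.

### Cell model

The analysis only requires an excitable cell with the MSN signature
properties: rest near the −90 mV leak reversal, quiescence below a
threshold excitatory conductance and tonic firing above it, spikes that
overshoot 0 mV, a long delay to sustained firing near threshold, and
IPSPs of physiological size and timescale near threshold.  The package
ships its own reference model (`msninfer.cell`): Wang-Buzsáki Na+/K+
spike currents, an inward-rectifier K+ current stabilizing the
hyperpolarized down-state, and a slowly inactivating A-type K+ current
with slow activation (τ_a = 180 ms) and slow inactivation (τ_b = 1 s).
The A-current's activation curve is steep and saturates just above
threshold: it balances the DC threshold (setting rheobase) without
tracking fast synaptic transients (setting the slow IPSP recovery) and
without throttling bursts (its driving gate is already saturated during
sustained depolarization).  The conductance values were calibrated once
against three anchors and then frozen:

* rheobase conductance 0.0437, just below the `G_ex` draw floor;
* single-IPSP probe at `g_I = 33`: peak 1.80 mV, half-decay 19.9 ms,
  area ≈ 53 µV·s, in a postsynaptic cell held just below threshold;
* IPSP amplitude strictly increasing with `g_I` and zero without a
  synapse.

Known deviations of the reference cell, relevant when interpreting
results: (i) a cell stepped from rest fires a single onset spike ~20 ms
after the step, because the slow activation gate starts closed at −90 mV;
the long latency property appears as a ~2.7 s delay to *sustained* firing
near rheobase.  Network runs discard a 2 s settling transient that
absorbs the synchronized onset volley.  (ii) Its minimum sustained firing
rate near threshold is ~13 Hz and its maximal rates under strong drive
(~140 Hz) exceed the ~80 Hz of real MSNs; consequences are noted under
Limitations.

### Integration

Fixed-step scheme, default dt = 0.05 ms (tests and screens use 0.1 ms):
channel gates relax by exponential Euler against steady states tabulated
on a 0.05 mV voltage grid; the membrane potential advances by RK4 within
the step with gates frozen; the synaptic gating variable follows its
exact exponential solution.  The summed inhibitory conductance onto each
cell is refreshed by a sparse gather every 0.5 ms (the gating variable
varies on the ~12 ms IPSP timescale).  Spikes are upward 0 mV crossings
with a 2 ms lockout.  Divergence (|V| > 200 mV) aborts with a step
report.  Halving dt changes population rate and CV by well under the
sampling variability at the default settings.

## Dynamical regimes

As `g_I` grows at fixed `g_E` the network crosses from a *frozen* regime
(winner-take-all: strongly excited cells fire regularly, the rest are
suppressed; ISI CV ≈ 0) to an *active* regime (chaotically wandering
input currents; bursty, irregular firing).  Near the transition the
fluctuations are slow and coherent: the ISI CV peaks, the number of
active cells passes through a minimum, the maximum-likelihood lognormal
shape σ_LN crosses unity, and the explained-variance entropy of the
binned-rate correlation matrix dips (low-dimensional coherent rate
fluctuations — visible as cell-assembly stripes in K-means-ordered
rasters).  Deeper in the active regime firing approaches Poisson.  The
rescaled rate `r·g_I/g_E` is approximately constant across the active
regime, the mean-field balance signature.

## ISI features

From each 200 s spike-train segment with at least 11 spikes we compute:
the first two serial ISI autocorrelations ρ(1), ρ(2) with
`ρ(n) = (⟨I_{i+n}I_i⟩ − μ²)/σ²`; the mean ISI μ, the CV σ/μ, the rescaled
skew S/CV and the firing rate; four quintile masses of the local-CV
distribution `X_i = |I_{i+1} − I_i|/(I_{i+1} + I_i)` (the middle quintile
is excluded from the feature set by convention; bins are half-open so the
quintiles partition and sum to one); and maximum-likelihood parameters of
three ISI families — lognormal (μ_LN = ⟨ln I⟩, σ_LN), gamma (closed-form
shape approximation `σ_γ = (3 − z + sqrt((3 − z)² + 24 z))/(12 z)` with
`z = ln μ − μ_LN`, scale stored as ln μ_γ) and inverse-Gaussian
(`σ_IG = (⟨I⁻¹⟩ − μ⁻¹)⁻¹`).  Degenerate (near-periodic) trains are
rejected with a logged reason.

Goodness-of-fit diagnostics (not used for fitting): the
censorship-corrected cumulative ISI distribution, where each interval is
weighted by `T/(T − I)` to compensate the finite window's bias against
long intervals, and Kolmogorov-Smirnov distances
`max_n |1 − D(n) − Q(n)|` to the four fitted families on a 0.1 ms
lattice up to the last bin with Q > 1e-8 (Q is piecewise constant between
occupied bins, so only run endpoints are evaluated — identical to the
full scan); and a Morlet-wavelet power spectrum of 4 ms spike counts on a
geometric frequency ladder (1/64 Hz × 2^{k/8} up to the 125 Hz Nyquist,
σ_t = 6/(2πf), width 3σ_t, edges within 3σ_t of the window discarded,
capped so at least half the window survives), normalized by the mean rate
so Poisson trains give S ≈ 1.

## KL inference

To fit a dataset D (one feature row per segment; at least 10 segments,
or 100 when segments are drawn by overlapping sampling), each model
simulation M on the `(g_E, g_I)` grid is reduced, for a random subset R
of 7 of the 15 features, to a probability vector over the 2⁷ binary
"above/below the experimental median" bins (medians always come from D;
ties count as below).  The mismatch is
`K = Σ P_D ln(P_D/(P_M + ε))`, ε = 1e-7.  A soft minimum over the grid,
`α_m ∝ K_m^{-β}` with β = 3 (K floored at 1e-6), gives a weighted point
estimate and weighted spread per subset; 30 independent subsets are
aggregated with weights `φ_R ∝ σ(x_R)^{-1}` (computed per estimated
parameter; the α weights are shared between g_E and g_I) into the final
estimate and its weighted standard error.  Estimates always lie inside
the grid hull, which biases recovery downward at the top of the grid and
upward at the bottom — visible in the validation below.

Validation follows the half-split design: each grid simulation is cut
into two non-overlapping halves, the first treated as data and the
second as the model library; interior grid points are recovered within
one grid step, edge biases have the signs implied by the hull constraint,
and regressions of estimated g_E on estimated g_I per g_E level (straight
lines with errors in both coordinates, effective-variance iteration,
slope SE from the χ² curvature, two-tailed t test) give slopes
indistinguishable from zero (tested at the Bonferroni-corrected level
0.05/3 across the three g_E rows).

## Scaled screening protocol

Reference-scale simulations (2500 cells, 200 s) take hours of CPU; the
test suite instead uses a screening protocol: 300 cells with the
in-degree held at ~100 by raising `p`, 60–80 s runs at dt = 0.1 ms, and
every synaptic conductance multiplied by `sqrt(500/100)`
(`scaled_screen_realization`).  The square-root compensation preserves
the variance of the summed recurrent input (∝ K·G²), which controls the
location of the frozen-to-active transition; the mean input (∝ K·G) is
then ~2.2× the reference, so screen firing rates at matched `(g_E, g_I)`
are comparable to, though not identical with, full-scale rates.  All
regime-structure and recovery checks above were verified under this
protocol with fixed seeds.

## Synthetic experimental data

Real recordings behind this kind of analysis are archival 20–30 min
single-unit sessions and are not bundled.  Two surrogate routes stand in:

* model-simulation surrogates (network runs fed back through the same
  feature pipeline) — faithful to the inference assumptions, used for the
  recovery validation;
* two-state Markov-modulated Poisson process (MMPP) sessions — each cell
  alternates between a burst state and a quiescent state with exponential
  dwell times.  The `wt` preset (8 Hz bursts of ~2 s against a 0.1 Hz
  background with ~20 s gaps) produces population CV > 1.3 with positive
  serial ISI correlations; the `hd` preset (3 Hz bursts, 1 Hz background,
  ~5 s gaps) produces weakly modulated trains with CV ≈ 1.0–1.3.  These
  presets emulate the bursty/non-bursty phenotypes for exercising the
  feature and fitting stack; they contain no network coupling, no
  refractoriness and no rate heterogeneity, so passing tests on MMPP data
  validates the *pipeline*, never the network model.

Sessions default to the cohort durations 1200/1800/3600 s.  Analysis
segments are 200 s windows: non-overlapping tiling for descriptive
statistics, or exactly `10·T/200` uniformly-placed overlapping windows
to enlarge fitting datasets.  Age-interval datasets group segments into
`[αi, α(i+1))` week bins (α ∈ {23, 10, 3}); groups with fewer than 10
non-overlapping (100 overlapping) segments are flagged unusable.

## Numerical choices and edge cases

* Channel tables: linear interpolation on a 0.05 mV grid, clamped at the
  ends; rheobase bisection brackets adaptively and converges to 1e-5.
* The IPSP probe uses the nominal synaptic conductance `0.001·g_I` and
  the central gating decay B = 0.085, making targets deterministic; the
  postsynaptic hold is 0.75× rheobase and the presynaptic drive 1.005×
  rheobase (slow tonic firing, so successive IPSPs are separable).
* Feature degeneracies: σ = 0, z ≤ 0 or ⟨1/I⟩ ≤ 1/μ raise a degenerate
  train error and the segment is dropped with a reason.
* K-means raster ordering uses k-means++ with a fixed seed; cells are
  ordered by cluster and, within a cluster, by correlation with the
  cluster mean.
* All randomness flows through explicit integer seeds (wiring/conductance
  draws, subset draws, segment sampling, K-means, surrogates).

## Limitations

* The reference cell model is the package's own; the cell originally
  used for this class of striatal models is specified in the literature
  we could not transcribe directly.  It meets the rheobase, IPSP and
  regime-structure anchors, but its near-threshold rate floor (~13 Hz)
  and fast intraburst spiking reshape the short-ISI region of the ISI
  distribution.  One documented consequence: at the wild-type best-fit
  point the gamma family edges out the lognormal as the best-fitting ISI
  distribution (KS_γ < KS_LN), where the reference phenomenology expects
  lognormal-best; the burstiness and rate orderings between the WT and
  HD best-fit points are unaffected.  The corresponding acceptance check
  asserts the lognormal-best property and fails honestly.
* Peak ISI CV at the transition reaches ~1.2–2.4 depending on scale and
  seed, below the ~1.7 reference value at the WT point itself.
* The screening protocol trades mean-input fidelity for
  fluctuation-variance fidelity; absolute rates at matched parameters
  differ from full scale by a factor of order unity.
* D1/D2 cell types, spatial structure, gap junctions, synaptic
  plasticity and time-varying cortical drive are out of scope by design.
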