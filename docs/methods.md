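# Methods

This note records the models, estimators and design choices behind
`entropix`, in enough detail to reproduce or challenge any number the
package emits.

## The direct (quadratic-extrapolations) entropy-rate estimator

The plug-in Shannon entropy of a finite recording depends on three
arbitrary choices: the fraction of the recording used (*Size*), the number
of equal-width amplitude classes (*v*), and the word length in samples
(*T*). The estimator computes the plug-in entropy H over a full grid of
probability spaces — by default Size ∈ {1, 0.9, 0.8, 0.7, 0.6, 0.5},
v ∈ {2, 4, …, 256}, T ∈ {1, …, 8}, i.e. 384 values — and extrapolates
three times to remove each choice:

1. for every (v, T), an ordinary-least-squares quadratic in 1/Size,
   evaluated at 1/Size = 0 (infinite recording);
2. for every T, a quadratic in 1/v at 1/v = 0 (infinite quantization);
3. the stage-2 intercepts are divided by T and fitted by a quadratic in
   1/T; the intercept at 1/T = 0 is the entropy rate R_S in bits/sample.

Words are non-overlapping blocks of T consecutive symbols (trailing
remainder discarded); the Size fraction takes the leading prefix of the
signal; quantization bins span the observed [min, max] with the last bin
right-closed. Grid cells with fewer than two words are flagged unreliable
and excluded from the stage-1 fits rather than silently dropped.

**Final-stage fallback.** The stage-3 curve H_T/T versus 1/T is strongly
concave whenever the word alphabet v^T outruns the data, and the quadratic
intercept then lands below zero or above log2(v_max). The estimator
accepts the quadratic intercept only when its R² ≥ 0.9 and the intercept
lies inside [0, log2(v_max)]; otherwise it extrapolates the line through
the two *shortest-word* points (T = 1, 2 — the best-sampled entries; for
the equally spaced default grid this equals 2·y(T=2) − y(T=1)). The
`method_tag` of every estimate records which path fired. With this rule
the estimator reproduces the textbook behaviours: ~0.99 bits/point for
500-point binary noise, ~1.96 for 1,000-point 4-level noise, and a
severe *underestimate* (~6.1 bits/point instead of 8) for 10,000-point
256-level noise — the sampling disaster the grid cannot overcome.

**Known bias.** The stage-2 quadratic in 1/v is fitted to a curve that is
logarithmic in v for genuinely high-entropy sources; when the measured
entropies mix unsaturated and saturated v points (e.g. an 8-level source
probed with v ≥ 8) the intercept overshoots by up to ~3% regardless of
data volume. This is a property of the extrapolation procedure itself,
not of the implementation; the long-signal recovery tests budget for it.

**Trial matrices.** The signal entropy rate R_S of repeated trials is the
arithmetic mean of per-trial estimates. The noise entropy rate R_N applies
the identical machinery to the transposed matrix — each time point's
across-trial vector is one "signal" — and averages over time points; a
`column_stride` option evaluates a regular subgrid of time points, which
is unbiased for the mean and proportionally faster. For matrix estimates
the quantization bins are shared across the whole matrix (one amplitude
scale for all trials and times); per-row bins would rescale sub-millivolt
across-trial jitter to full range and make R_N meaningless. Per-row rates
are floored at zero before averaging, since an entropy rate is
non-negative and the extrapolation can undershoot on near-constant rows.
The information transfer rate is R = R_S − R_N.

## The PNG-Rate proxy

A minimal grayscale PNG writer (signature, IHDR, a single IDAT, IEND; no
ancillary chunks; scanline filter fixed to None; zlib level 6 by default,
exposed 0–9) makes the file size a pure function of pixel content plus a
small deterministic overhead — 90 bytes for a 100×100 all-zero 8-bit
image. The PNG Rate is total file bytes divided by pixel count; multiplied
by the sampling rate it becomes bytes/s. Against uniform-noise ladders
with 2–256 gray levels at 10,000 pixels, the PNG Rate is linear in the
true entropy rate with R² ≈ 0.99 (slope ≈ 0.116 B/pixel per bit, intercept
≈ 0.09), and square versus single-row layouts differ by ~1%.

The filter-None choice keeps rates interpretable as compressibility of
the raw pixel stream; adaptive filters would make sizes depend on encoder
heuristics. The reader verifies chunk CRCs, supports scanline filters 0–4,
grayscale only, bit depths 1 and 8, and rejects everything else loudly.

**Mutual information by rotate-and-recompress.** A trials × time matrix is
written once (compression runs along time → signal proxy) and once after a
90° rotation (compression runs across trials → noise proxy); the
difference of the two rates tracks R. Two mechanical facts matter when
interpreting it:

* DEFLATE's back-reference window is 32 KiB. When rows are longer than
  that (5 s at 10 kHz = 50,000 samples), the signal image pays every
  trial's content separately while the rotated image pays it once, which
  is exactly why reproducible trials yield a large positive difference.
  With rows much shorter than the window the asymmetry disappears and the
  sign can invert; protocols therefore keep the 5-s trial length.
* The rotated (tall) image spends one filter byte and ~1–2 compressed
  bytes per scanline; with few trials this per-row floor can exceed the
  content signal. The efficacy protocol's 1-bit rasters resolve their
  curve only from roughly 50–100 trials for this reason.

## Synthetic signal families

`uniform_noise` draws i.i.d. symbols over v ∈ {2, 4, …, 256} evenly
spaced gray values on [0, 255] (round(k·255/(v−1))), so one array serves
both estimators without re-normalization; `bernoulli_signal` draws 0/1
trains. True entropies are log2(v) and the binary entropy function. All
generators are pure functions of a `NoiseSpec` using numpy's PCG64
(`default_rng`); identical specs give identical arrays on any platform.

## The spiking-neuron benchmark

A single-compartment conductance-based cell: transient Na⁺ (0.04 S/cm²,
E = +60 mV), delayed-rectifier K⁺ (0.01 S/cm², −90 mV) and leak
(3.33×10⁻⁵ S/cm², −77 mV), C = 1 µF/cm², dt = 100 µs, 37 °C. The
voltage-gated kinetics are Traub–Miles-type rate functions (threshold
near −50 mV) with an optional Q10 factor; they are a documented stand-in,
so every model-level result in the tests is a trend or property, never a
trace-exact value.

*Integration.* Gating variables use exponential Euler. The voltage uses
exponential Euler on the conductance form of the membrane equation
(V relaxes toward the instantaneous equilibrium potential with rate
g_tot/C): during the Na⁺ upstroke the membrane time constant drops to
~25 µs, less than the step, and explicit forward Euler diverges. A
classical RK4 path exists for cross-checks and matches the default
integrator to <0.1 mV off-spike.

*Membrane size.* Area 50,000 µm² (input resistance ≈ 60 MΩ, membrane
time constant 30 ms), in the range of thick-tufted L5 pyramidal neurons —
the cell class whose synaptic amplitude statistics the model borrows. At
much smaller areas the stated 0.0005 nA noise current dominates the
voltage budget and frozen-input trials decorrelate completely.

*Synapses.* Alpha-conductance synapses (τ = 0.5 ms, reversal 0 mV), each
firing once at a uniform random onset. Strengths are specified as target
somatic EPSP peaks in mV and converted to peak conductances through a
calibration table built by fixed-point iteration at anchor amplitudes
(log-log interpolated in between; accurate to ≪1%). A second calibration
loop (bracket + bisection) maps a requested firing rate to a background
synapse count, so protocols are stated in Hz and mV.

*Background populations.* Two lognormal EPSP-amplitude populations are
used, each chosen to put the model in the operating regime its protocol
describes:

* **Frozen-input protocols** (entropy ladder, information vs rate):
  ln-mean −1.5, ln-SD 2.0 — a heavy tail in which low-rate spiking is
  triggered by single large EPSPs (~100 synapses/s per Hz at 1 Hz — the
  economical synapse budget characteristic of tail-driven firing). Spike times then lock to the input pattern across repeated
  trials, with the small Gaussian noise current (SD 0.0005 nA)
  contributing sub-millisecond jitter — the regime in which mutual
  information grows with firing rate.
* **Synaptic-efficacy protocol**: ln-mean −1.0, ln-SD 0.3 — dense weak
  bombardment (~0.37 mV quanta at ~1,000 synapses/s) that parks the
  operating point ~11 mV below threshold, so the supplementary synapse's
  0.5–8 mV range spans sub- to supra-threshold efficacy and its strength
  ladder traces a rising curve. No single population does both jobs in
  this kinetics stand-in: the heavy tail leaves an 8 mV synapse far from
  threshold, while the dense population makes high-rate frozen trials
  chaotic.

*Protocol hygiene.* Every protocol simulates a 1-s settle period before
the analysis window and discards it: trials otherwise all start at rest
and the onset transient, not steady-state noise, dominates across-trial
variability. The efficacy protocol reuses the same background patterns at
every supplementary-synapse strength (patterns keyed by seed and trial
index only), a matched-pairs design whose per-seed curve differences
isolate the supplementary synapse; backgrounds remain re-randomized
across trials, as the protocol requires.

*Rasters.* Spikes are upward 0 mV crossings with a 2-ms refractory rule;
rastergrams mark a 1 in each 1/3-ms bin (3 kHz) containing at least one
spike onset; the efficacy analysis runs the direct method on the binary
alphabet with word lengths {1, 2, 5, 10, 20, 30, 40} and the PNG proxy on
1-bit images.

## Place fields

A mock animal walks a 20 × 20 arena (1 s per step), choosing uniformly
among the feasible subset of the 8 neighbours plus staying put (moves off
the arena are excluded and the choice renormalized). A place cell at the
centre fires at F_max/(1 + e^((x−x0)·Slope)) with x0 = 7, Slope = 2,
F_max = 10 (x = Euclidean distance from the arena centre in bins); with
probability `strength` the field emits Poisson(rate) spikes in a step,
and independent background noise adds one spike with probability 0.1.
Spatial information is the Skaggs rate I_sec = Σ pᵢ λᵢ log2(λᵢ/λ) in
bits/s over visited bins (zero-rate bins contribute zero). The pairing
image maps each step to (column = row-major flattened bin index,
row = visit ordinal for that bin), holes zero-filled and counts scaled to
8-bit gray; its PNG-Rate difference under rotation tracks I_sec across
the strength ladder (rank agreement ρ ≈ 1 at 10,000 steps).

## 2-D complexity

Images are thresholded (default: intensities < 10 → 0) after conversion
to 8-bit gray (channel 2 selected for multi-channel stains by default).
The cylindrical anamorphosis samples 360 angles × integer radii by
nearest neighbour out to the farthest corner; each radius column is
encoded as its own PNG, so size-versus-radius reads as radial complexity
and peaks where a Sholl intersection count peaks (verified on seeded
synthetic branching trees, which stand in for real micrographs
throughout the tests). Tile profiles split the image into an n × n grid
(remainders folded into the last tile). Soma counts for the per-cell
normalization are user input; no detection is attempted.

## Problem sizes and determinism

Everything is seeded and every stochastic path takes an explicit seed; no
wall-clock seeding anywhere. Default test/benchmark sizes were chosen so
a full run stays in the minutes range on one core: noise benchmarks use
500–20,000 samples (spanning both estimators' convergence points), the
neuron information ladder runs 3 seeds × 4 rates × 20 trials of 5 s, the
efficacy ladder 5 seeds × 5 strengths × 20 trials of 5 s, and place-field
suites 10 seeds × 10,000 steps. The `experiments` module exposes a
`scale` knob; at scale = 1 the efficacy experiment runs the full
100-trial design, which is also where the PNG readout of the efficacy
curve becomes resolvable (see the window/floor notes above).

## Limitations

* The PNG Rate is a relative proxy: compare conditions at matched image
  geometry, bit depth and encoder settings, never read it as bits.
* The direct estimator inherits the sampling disaster: with 10,000
  samples it cannot see past ~6 bits/sample no matter the extrapolation,
  and the 1/v stage carries a small intrinsic bias for mid-sized
  alphabets.
* The neuron is a stand-in: its kinetics, EPSP populations and membrane
  size are calibrated to reproduce described operating regimes, not to
  match any particular recorded voltage trace or regression coefficient.
* White-noise generators cover i.i.d. sources only; no colored-noise
  families are provided.
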