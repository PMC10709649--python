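# Methods

`neuroei` studies how two summary statistics of cortical field potentials —
normalized Lempel–Ziv complexity (LZc) and the aperiodic 1/f exponent of
the power spectrum — move together across brain states, and how both track
the balance between synaptic excitation and inhibition (E/I). Everything
below is computed on data the package generates itself; an optional
empirical mode reads user-supplied multichannel recordings.

## Surrogate signals from the frequency domain

Signals are constructed by prescribing one-sided spectral power
`P(f) = O · f^−s` between a knee `f0` and a cutoff `ff`, converting to
amplitudes `A(f) = √P(f)`, drawing one random phase per positive-frequency
bin, and applying an inverse real FFT. Below `f0` amplitudes are held at
`A(f0)` (this keeps the variance finite and the signal stationary); above
`ff` they are zero. Defaults are 5 s at 1 kHz, `f0 = 1` Hz, `ff` at the
Nyquist frequency.

Numerical conventions, chosen here and fixed:

- The DC bin is zero, so signals are exactly zero-mean.
- The Nyquist bin is zeroed: it has no phase freedom for a real signal,
  and excluding it makes the discrete Parseval identity
  `var(x) = Σ_f A(f)²/2` hold to machine precision (a property test).
- The inverse transform is scaled so a lone bin of amplitude `A` and phase
  `θ` produces `A·cos(2πft + θ)` exactly.
- Phases are uniform on (−π, π] by default; a von Mises option (mean `mu`,
  concentration `kappa`) exists for phase-concentration experiments, and
  `uniform` is implemented as von Mises with `kappa = 0` so both kinds
  consume the random stream identically. Phases are the only randomness.

## Lempel–Ziv complexity

A signal is binarized at the median of the whole analysis window (strictly
greater → 1, ties → 0), which makes LZc invariant under any strictly
increasing transform of the samples. The binary sequence is parsed with
the exhaustive-history production rule: the current word grows while it can
be copied from an earlier starting position (overlap allowed) and each
failure to copy ends a production; the final word is counted either way.
The normalization is `LZc = c · log2(n) / n`, which approaches 1 for long
random sequences. Finite random sequences can slightly exceed 1; values
are reported unclipped. The parser runs the substring search at C speed;
the test suite checks it against an independent index-scanning parser on
every binary string up to length 14 and on random strings.

## Spectral estimation and the aperiodic fit

PSDs come from Welch's method (Hann taper, 50% overlap; 1 s segments by
default, 0.5 s in the network sweep where more segment averaging matters
more than frequency resolution). The aperiodic component is a straight
line in log10-power versus log10-frequency over a fixed band, 30–80 Hz by
default — the band in which inhibitory tone most directly shapes the decay
of cortical spectra. Oscillatory peaks are removed iteratively: fit,
mask points whose positive residual exceeds 2 SD of the residuals (peaks
only add power), refit, up to 5 passes or until stable. The slope is
reported as positive steepness `s` (`P ∝ f^−s`) together with the log10
offset at 1 Hz, the mask counts and the in-band R². There is no knee
parameter: the band is treated as a single power-law regime.

## The LZc(s) law

Across surrogate grids the complexity–slope curve follows an x-inverted
asymmetric sigmoid,

    LZc(s) = a1 · exp(−b · ln²(s^c + 1))            (scaled form)
    LZc(s) = a2 + (1 − a2) · exp(−b · ln²(s^c + 1)) (floored form)

with natural logarithms; `b, c > 0` shape the curve, `a1` compresses the
range from above (appropriate for a low-pass cutoff `ff`), `a2` lifts the
floor (appropriate for a knee `f0 > 1` Hz, which prevents complexity from
reaching zero). With `a2 = 0` the floored form reduces to the scaled form
with `a1 = 1`. Fitting is bounded nonlinear least squares (`a ∈ (0,1]`,
`b, c > 0`) from the start (1 or 0, 1, 2) plus three jittered restarts in
`(b, c)` to avoid boundary-local minima; R² is `1 − SS_res/SS_tot` on the
fitted points. The default variant is the floored form whenever the
generating `f0 > 1` Hz, the scaled form otherwise.

## Intrinsic timescale (tau)

The ACF is computed by FFT on the mean-subtracted signal with the biased
(1/n) normalization and `ACF[0] = 1`. The estimator takes the segment from
lag 0 to the first lag below 0.8, fits a quadratic to it, and solves
`quadratic = 0.5` for the smallest positive real root; estimates from a
generator are averaged over 20 independent realizations by default.

Degenerate cases are handled explicitly. A convex quadratic whose minimum
grazes 0.5 has numerically complex roots; the vertex is then taken when its
value lies within 0.05 of 0.5. When the quadratic never reaches 0.5 at all
— typical for shallow-slope signals whose ACF collapses within one or two
lags, where a three-point quadratic is ill-posed — the estimator falls back
to the raw ACF's first linearly interpolated 0.5 crossing. For an
exponential ACF (`exp(−lag/τ0)`), the quadratic extrapolation has a closed
form that lands near `τ0·ln 2` (38.0 ms for τ0 = 50 ms); the tests pin the
estimator to that value.

## The recurrent E/I network

Conductance-based leaky integrate-and-fire neurons, 80% excitatory
(AMPA-like) and 20% inhibitory (GABA-like), randomly connected with
probability 0.2 and no autapses. Membrane dynamics
`Cm dv/dt = gL(EL − v) + gE(EE − v) + gI(EI − v) + ξ`; threshold crossing
resets to the resting potential for a refractory period. Synaptic
conductances follow peak-normalized difference-of-exponentials kernels
(AMPA rise/decay 0.1/2 ms, reversal 0 mV; GABA 0.5/10 ms, −80 mV), driven
by presynaptic spikes. E/I balance is manipulated by a dimensionless
factor `g_scale` multiplying every inhibitory unitary conductance (I→E and
I→I), swept over 21 log-spaced values on [1/4, 4].

Parameters the synaptic constants do not fix are engineering defaults from
the standard cortical LIF family, calibrated once so the network sits in an
asynchronous irregular, fluctuation-driven regime across the whole sweep
(single-cell CV near 1, population Fano factor near 1, no prominent fast
network oscillation): resting/reset −65 mV, threshold −50 mV, membrane τ
20 ms (E, Cm 500 pF) and 10 ms (I, Cm 200 pF), refractory 2 ms (E) / 1 ms
(I). External drive per neuron combines an independent Ornstein–Uhlenbeck
current (mean 0, SD 400 pA, τ 5 ms — the thalamic stream) and an excitatory
Poisson conductance bombardment (3000 s⁻¹ onto E, 2500 s⁻¹ onto I, 0.4 nS
peak — the cortico-cortical stream). Interneuron firing is anchored by this
feed-forward drive: projections onto I cells are relatively weak (E→I 0.5,
I→I 0.15 of their E-cell counterparts). That choice matters: when interneuron
rates are instead set by strong recurrent loops, the loop gain rises with
`g_scale` and actively whitens the population spike trains in-band, masking
the synaptic-filter effect the sweep is designed to expose. Reference
unitary conductances (0.05 nS at the 5000-neuron reference size) are scaled
by `reference_n / n_total` so reduced networks preserve the summed synaptic
drive per neuron.

Integration is forward Euler at dt = 0.1 ms for the voltage; synaptic and
OU states advance with exact exponential decay factors, so dt equal to the
fastest synaptic rise time (0.1 ms) loses nothing in the conductance path.
Per-neuron OU states advance on a 1 ms stride (exact discretization on that
grid); external Poisson events are drawn per population per step and
assigned uniformly to neurons, which is distributionally identical to
independent per-neuron processes. A convergence test checks that halving
dt moves population rates by less than 5%.

## Kernel LFP and the scaling sweep

The LFP proxy convolves each population's spike train with a unitary
bi-exponential kernel shaped by its synaptic time constants — excitatory:
amplitude −1, rise/decay 0.1/2 ms, 1.5 ms latency; inhibitory: amplitude
+0.7, 0.5/10 ms, 0.5 ms latency — on the simulation grid, then
polyphase-resamples to 1 kHz. The amplitude ratio places the crossover
between AMPA- and GABA-dominated spectra near the middle of the scaling
range, so the 30–80 Hz slope keeps moving across the whole sweep. Because `g_scale` multiplies the inhibitory unitary conductance,
and a unitary field contribution is proportional to unitary synaptic
strength, the inhibitory kernel amplitude carries the same factor in the
sweep (this can be disabled). An alternative proxy, the summed magnitudes
of the mean synaptic drives on the excitatory population, is available as a
sensitivity check.

The sweep mechanism is then transparent: the LFP spectrum is a mixture of
the two kernel filters weighted by (amplitude² × population spike rate).
As `g_scale` grows, the inhibitory weight rises roughly as `g_scale²` while
the excitatory rate falls, so the 30–80 Hz slope moves from the shallow
AMPA-filter regime toward the steep GABA-filter regime and LZc falls
accordingly; at the extremes of the factor range the mixture saturates and
both curves flatten. The first 0.5 s of every run is discarded as warmup.

## The two-state fixture

The awake/anesthesia stand-in draws per-channel spectral exponents from
truncated normal distributions (awake mean 1.0, anesthesia mean 2.0, SD
0.3), synthesizes each channel as a power-law surrogate, normalizes to unit
variance and adds a 10 Hz alpha sinusoid (amplitude 0.5) with random phase.
Ground-truth slopes travel with the recordings. What it emulates: the
between-state shift of the aperiodic exponent and its channel-to-channel
variability. What it does not: oscillatory state changes beyond the fixed
alpha, spatial correlation between channels, nonstationarity within a
recording, or artifacts — so passing fixture tests demonstrates the
pipeline's statistics under the stated spectral model, not robustness to
real-data pathologies.

The analysis pipeline cuts recordings into non-overlapping 5 s epochs
(matching the LZc window), computes LZc and the 30–80 Hz fit per channel ×
epoch, averages across epochs, differences the two states per channel, and
relates the two deltas by OLS (optionally with per-subject indicator terms)
and by Spearman correlation; for n ≤ 8 the Spearman p value is the exact
permutation tail probability.

## Problem sizes and determinism

Acceptance-level computations use: the 256-signal default grid; 64-slope ×
5-seed grids for the knee/cutoff conditions; a 1250-neuron network (fifth
of the reference population, with conductance rescaling), 21 factors ×
3 seeds × 10 s LFP; and 100 seeded fixture runs of 16 channels. In the
sweep, one network and drive realization per seed is shared across all
scaling factors (common random numbers), so factor-to-factor contrasts are
paired and realization noise cancels from the trend. All randomness flows
through named integer seeds; a run with a fixed configuration and seed is
bit-for-bit reproducible.

## Known limitations

- The LZc(s) law is empirical; no analytic derivation is attempted.
- The aperiodic fit assumes a single power-law regime in-band; spectra with
  a knee inside 30–80 Hz will be summarized by an intermediate slope.
- Tau for shallow-slope signals rests on the raw-ACF fallback and is only
  as fine as the sampling interval.
- The reduced network reproduces the direction and strength of the
  slope/LZc relation, not the absolute spectra of any particular cortical
  recording; kernel amplitudes are in arbitrary units.
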