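# Methods

## Overview

`usvdend` simulates how a single central auditory neuron combines pairs of
ultrasonic-vocalization-like (USV) stimuli, and quantifies the resulting
feature-recombination function with the summation index (SmI). The
pipeline has four stages:

1. **Stimulus synthesis** — USV-like syllables (~100 ms FM tones confined
   to 30–120 kHz) that can be superimposed at controlled lags,
   pitch-shifted, and concatenated into adaptation trains.
2. **Peripheral encoding** — a bank of 4th-order gammatone filters
   (ERB-rate spaced, 30–120 kHz; 3000 channels at full scale) followed by
   half-wave rectification, cube-root compression, and one noisy leaky
   integrate-and-fire (LIF) neuron per channel.
3. **Compartmental neuron** — a soma electrically coupled to 10 passive
   dendritic subunits carrying AMPA (and optionally NMDA) synapses from
   the encoder channels, with spike-triggered adaptation and coloured
   noise at the soma.
4. **Analysis** — trial-wise firing rates, SmI with inclusion criteria and
   MAX-like / sublinear / AND-like classes, pitch selectivity, input
   overlap metrics, and survey drivers for the model manipulations.

## Stimulus model

Syllables are single-component FM tones: mouse USVs are near-pure
whistles, so a tone with a constant, linear, or half-cosine frequency
contour between two endpoints in [30, 120] kHz is an adequate stand-in.
Each syllable gets 5-ms raised-cosine onset/offset ramps and is calibrated
so its peak pressure corresponds to a target level in dB SPL re 20 µPa
(default 85 dB SPL, the presentation ceiling). The sampling rate is
250 kHz, Nyquist-safe for 120 kHz content.

Pitch shifting preserves duration: the waveform is time-stretched with a
phase vocoder by the frequency ratio `2^(semitones/12)` and resampled back
to its original length, scaling every spectral component by that ratio.

Superposition sums two calibrated waveforms sample-wise with the second
clip's onset delayed by the requested lag; negative lags advance it and
shift the common time origin so no samples are discarded. Summed clips are
not renormalized; the 85 dB SPL cap applies to each component.

**Pair sets for surveys.** `generate_pair_set` draws reproducible syllable
pairs with controlled spectral separation: *high*-separation pairs come
from disjoint low/high halves of the band, *low*-separation pairs from one
shared 20-kHz region, and *mixed* alternates. Temporal structure covaries
the way it does between co-occurring natural syllables: same-band pairs
receive independent, deeply modulated envelopes (1–2 narrow energy humps),
while disjoint-band pairs keep flat envelopes. On a tonotopically wired
dendritic tree this yields both clustered-and-uncorrelated and
dispersed-and-correlated synaptic input patterns, the two categories the
overlap analysis contrasts. Deep modulation is needed because the
encoder's cube-root compression flattens shallow amplitude modulation.

## Peripheral encoder

Channel center frequencies are equally spaced on the Glasberg–Moore
ERB-rate scale, `E(f) = 21.4 log10(4.37 f/1000 + 1)`, extrapolated to the
ultrasonic range; bandwidths follow `ERB(f) = 24.7 (4.37 f/1000 + 1)`.
Filters are truncated 4th-order gammatone impulse responses
(`t^3 e^{-2π·1.019·ERB·t} cos(2πf t)`), each normalized to unit magnitude
response at its own CF, applied by FFT convolution.

The filtered pressure `x` is transduced to a current
`I_stim = 3·max(g·x, 0)^{1/3}` at the audio rate (rectifying after any
down-sampling would cancel the carrier) and then bin-averaged onto the
0.025-ms integration grid. The gain `g` (`pressure_scale`, default 10^4)
sets the encoder's operating point: with the LIF parameters below, an
85 dB SPL tone at CF holds the membrane's steady-state voltage a fraction
of a noise standard deviation below threshold, so firing is graded,
stimulus-locked and noise-assisted, and off-CF channels fall off with the
filter attenuation. The value was chosen by closed-form analysis of the
steady state (`V_ss = E_L + I_eff/g_L` against `V_th − E_L = 20 mV` with a
cycle-average factor of ≈0.41 for the rectified compressed carrier).

Each channel is a LIF neuron, `C dV/dt = −g_L(V−E_L) + I_stim + I_noise`,
with C = 1 mF, g_L = 1 S (τ_m = 1 ms), E_L = −60 mV, threshold −40 mV,
reset −20 mV, 5-ms refractory hold and white-noise current of s.d. 3 mA
(per-step discretization `σ√(2τ_m/dt)·N(0,1)`). Units are kept in the
(mF, S, mV, ms, mA) system, in which these constants are mutually
consistent. Because the reset sits *above* threshold, a naive
"spike whenever V > V_th" rule would latch; spikes therefore require an
upward crossing — after the refractory hold the neuron is eligible again
only once V has fallen back below threshold. With a reset below threshold
this is the standard LIF rule, and the analytic constant-drive period
`t_ref + τ_m ln[(I/g_L−(V_r−E_L))/(I/g_L−(V_th−E_L))]` applies (verified
to 1%). The above-threshold reset makes encoder responses onset-emphasized
for strong drive, a phasic characteristic of auditory nerve responses.

Integration is forward Euler at dt = 0.025 ms (≪ τ_m). Noise is drawn
per channel from seeds derived with `SeedSequence`, so rasters are
bit-reproducible given the stimulus and seed.

## Compartmental neuron

Eleven compartments: one soma (25 × 25 µm cylinder) and ten dendrites
(100 × 1 µm cylinders). Membrane area is the cylinder's lateral area; for
dendrites it is additionally multiplied by the spine area factor (1.5) and
the area scale factor (3), representing spines and unmodelled membrane.
(The assignment of these two factors to compartments is a modelling
choice; both are config-exposed.) With specific capacitance 0.5 µF/cm²
and resistivity 20 kΩ·cm² every compartment has τ_m = 10 ms. The printed
resistivity unit is read as Ω·cm² (a per-area resistance; the reciprocal
unit would give unphysical time constants).

Axial currents are ohmic with coupling conductance g_c = 0.8 nS taken
directly from the parameter table (the axial resistivity r_a = 150 Ω·cm
is retained in config for documentation only). Dendrites are passive —
no threshold or reset — and receive the synaptic current

    I_syn = g_syn · s_syn · (E_syn − V_d) · σ(V_d),

written in the depolarizing convention (E_syn = 0 mV pulls the dendrite
up). The magnesium-block factor
`σ(V) = 1/(1 + ([Mg]/β)·e^{−α(V−γ)})` ([Mg] = 1 mM, β = 3.57 mM,
α = 0.062 mV⁻¹, γ = 0 mV) applies to NMDA only; AMPA is unblocked.
Conductance gating follows the two-state rise/decay kinetics
`ds/dt = −s/τ_decay + x`, `dx/dt = −x/τ_rise`, with x incremented by the
synaptic weight on each presynaptic spike (AMPA: 0.2/3 ms, w = 0.5;
NMDA: 2/60 ms, w = 0.05; g = 0.8 nS each).

The soma is an adaptive integrate-and-fire unit: crossing −50 mV steps V
to 0 mV (the spike), increments the adaptation current w by b = 200 pA,
and after a 0.2-ms hold (2 steps at dt = 0.1 ms; w keeps integrating, V
clamped at the spike value) resets V to −58 mV. Adaptation follows
`τ_w dw/dt = a(V−E_L) − w` with a = 0.8 nS, τ_w = 100 ms. Somatic noise is
Ornstein–Uhlenbeck with τ = 20 ms and stationary s.d. 35 pA, giving
trial-to-trial variability of a few mV.

**Connectivity.** Structured maps assign contiguous CF blocks of equal
size to each dendrite (300 afferents per dendrite at full scale), making
branches frequency-tuned. `randomized_connectivity(f)` selects a fraction
f of each dendrite's afferents and permutes their dendrite labels among
the selected set, preserving every fan-in exactly; f = 1 is a full
shuffle.

**Reduced scale.** Surveys and tests run with 300 encoder channels (30
per dendrite). Synaptic weights are scaled by `300 / fan_in` so the total
synaptic drive per dendrite matches the full-scale model; without this the
scaled-down population could not depolarize the tree. All structural
counts scale proportionally.

## Response analysis

Firing rates count somatic spikes from stimulus onset to offset plus a
50-ms latency allowance, with one common window for the two individual
syllables and every superposition (the window covers the longest
stimulus). Spontaneous rates come from the pre-stimulus window; surveys
simulate 200 ms of pre-stimulus silence (the analysis default window is
500 ms when that much is available).

A pair enters the SmI analysis if (i) each individual response exceeds
the spontaneous rate by a one-sided Wilcoxon signed-rank test at α = 0.05
across trials, or (ii) the combined response is at least 25% above the
dominant individual response. SmI = (R_ab − max(R_a,R_b)) / min(R_a,R_b);
SmI ≤ 0 is MAX-like, 0 < SmI < 1 sublinear, SmI ≥ 1 AND-like (the
AND boundary is config-exposed). Subthreshold pairs admitted through path
(ii) with min(R_a,R_b) = 0 get an SmI of +∞ and class AND-like — they are
the limit case of conjunction-only responses — and are counted separately
in summaries. The PSTH bin defaults to 10 ms.

Pitch selectivity uses the sparseness form
`S = [1 − (Σr/n)²/(Σr²/n)] / (1 − 1/n)` ∈ [0, 1]. Cross-adaptation
categorizes input independence by the after/before response ratio with
the 0.6 criterion in each presentation order. Leave-one-trial-out SmI
variability pairs trials by index; with unequal counts it runs over the
smallest (logged).

**Optimal lag.** Per pair, the lag whose superposition evoked the highest
combined response; ties break toward the smaller absolute lag, then the
negative one.

## Overlap metrics

For each syllable, the per-dendrite time integral of the summed AMPA
gating variable gives a spatial profile, and the per-step sum across
dendrites a temporal profile. Pearson correlations of the two profiles
between the syllables of a pair classify the input pattern
(dispersed-and-correlated: temporal r above threshold, spatial r below;
clustered-and-uncorrelated: the reverse). Default thresholds are 0.3
(temporal) and 0.1 (spatial); because those values were originally dataset
medians, `compare_overlap_groups` recomputes median thresholds from the
surveyed pairs by default (`threshold_mode="median"`). Group differences
use a Kruskal–Wallis rank test implemented in-package (tie-corrected) and
cross-checked against an independent reference implementation in the
tests.

Stimulus dissimilarity uses magnitude spectrograms (Hann window,
nfft = 1024, 75% overlap; onset-aligned, the shorter clip zero-padded) for
the flattened-spectrogram Euclidean distance, and a 5-vector of spectral
mean, quartiles and s.d. (from a single periodogram of a 55-ms window
centered on the firing response, quartiles by cumulative-power
interpolation) for the feature distance. A dB-scaled spectrogram distance
is available by flag.

## Surveys and problem sizes

`run_smi_survey` presents each pair's two syllables and their
superpositions at lags 0–20 ms in 5-ms steps (146 pairs × 5 lags = 730
records at full scale), computes trial-averaged rates, SmI, class, and the
per-pair optimal-lag record, and summarizes medians/IQRs over included
records. Seeds are derived from the master seed per
(pair, stimulus, trial) with `SeedSequence` spawn keys, so adding pairs
never perturbs earlier ones, and matched surveys (connectivity sweep, NMDA
comparison) see identical stimuli and encoder/somatic noise.

The packaged reduced scale — 300 channels, 20 pairs, 5 trials, 200 ms
pre-silence — keeps a full survey around 1–2 minutes on one CPU while
preserving every direction of effect: optimal-lag selection shifts the SmI
distribution upward; full connectivity randomization lowers the median
SmI; adding NMDA boosts individual-syllable responses and lowers the
median SmI; dispersed-and-correlated pairs integrate more AND-like than
clustered-and-uncorrelated ones. Five trials is the minimum at which the
Wilcoxon inclusion path can fire (all-positive differences give
p ≈ 0.031).

## What the synthetic data does and does not show

The generator reproduces the band limits, durations, ramps, levels and
the spectral/temporal contrast structure of USV syllable pairs, but not
the acoustic statistics of recorded vocalizations (harmonics, jitter,
syllable-duration distributions, natural AM shapes). Consequently the
pipeline's SmI *distributions* are not comparable number-for-number with
values measured on recorded syllables — the tests and the acceptance
script assert counts, closed-form identities, integration properties and
directions of effect, not distribution medians of the original
experiments.

## Numerical choices and degenerate inputs

- Forward Euler throughout; encoder dt 0.025 ms, neuron dt 0.1 ms (both
  configurable; the LIF period test checks the discretization error ≤1%).
- Float32 is used for the filtered pressure and transduction current
  (values O(10), noise s.d. 3 mA — representation error is negligible);
  all state variables integrate in float64.
- All-zero clips cannot be level-calibrated (error); silent analysis
  windows and zero-variance profiles raise instead of returning NaN.
- SmI with min(R_a,R_b) = 0 raises in `summation_index`; only the survey
  path assigns the +∞ sentinel, and only via inclusion path (ii).
- Non-finite membrane potentials abort a simulation with the offending
  compartment and time; the survey logs and skips such pairs.

## Known limitations

- No cochlear adaptation, efferents or middle-ear filtering; encoder
  channels are independent.
- Dendrites are passive cables with point synapses; no voltage-gated
  Na/Ca channels, no plasticity, no morphological detail.
- The Wilcoxon inclusion test is underpowered below ~6 trials, so weakly
  responding pairs are conservatively excluded at reduced scale.
- Phase-vocoder pitch shifting assumes quasi-stationary spectra over the
  4-ms analysis window; extremely fast FM sweeps would smear.
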