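# Model and methods

`mecgamma` simulates a medial-entorhinal-cortex (mEC) microcircuit of 100
fast-spiking PV+ interneurons (I) and 400 stellate cells (E) under a
simulated 8 Hz optogenetic conductance drive, and analyzes the resulting
theta-nested gamma oscillations with the same wavelet pipeline used for
intracellular recordings. This note documents the model equations, the
calibrated defaults, the numerical choices, and the limits of what the
synthetic tests demonstrate.

## Single-cell models

Both cell types are single-compartment conductance-based neurons in fixed
units (mV, ms, nS, pF, pA; 1 nS x 1 mV = 1 pA):

C dV/dt = g_Na m^3 h (E_Na - V) + g_Kv3 n^4 (E_K - V) + g_Kv1 a^4 (E_K - V)
        + g_L (E_L - V) + g_drive(t) (0 - V) + I_syn + I_gap

for the interneuron (E_Na = 50, E_K = -90, E_L = -65 mV), and a classic
Hodgkin–Huxley Na/K/leak set for the stellate cell (E_K = -77 mV), which
additionally receives two Ornstein–Uhlenbeck conductances (excitatory,
reversal 0 mV, tau = 10.49 ms; inhibitory, reversal -75 mV, tau =
2.728 ms; stationary mean 0.9 nS each).

Interneuron gating variables relax as dx/dt = open(V)(1-x) - close(V)x
with two rate shapes: a "linoid" alpha(V) = k1 |sigma1| u/(e^u - 1),
u = (theta - V)/sigma1, and an exponential beta(V) = k2 exp(V/sigma2).
The activation gates are (theta, sigma1, sigma2, k1, k2):

| gate | theta  | sigma1 | sigma2 | k1    | k2    | role |
|------|--------|--------|--------|-------|-------|------|
| m    | -53.0  | 4      | -13    | 0.25  | 0.1   | Na activation (fast) |
| n    | 5.9    | 12     | -8.5   | 1     | 0.001 | Kv3 activation |
| a    | 51.36  | 12     | -80    | 1     | 0.02  | Kv1 activation (slow, adapting) |
| h    | -55.71 | 3.5    | -20    | 0.2   | 0.012 | Na inactivation |

For h the roles are swapped (dh/dt = beta(1-h) - alpha h): the
exponential rate (k2 = 0.012, slope -20 mV) opens the gate and falls with
depolarization, while the linoid (half-point -55.71 mV, slope 3.5 mV)
closes it. This yields half-inactivation near -60 mV, ~2 ms recovery at
hyperpolarized potentials and sub-millisecond inactivation at spike
peaks — the canonical fast-spiking Na phenotype. Other assignments of
the four h-row constants to the two rate formulas were examined and all
produce dynamically inconsistent gates (negative rates, fixed points
outside [0, 1], or a persistent-sodium plateau that abolishes repetitive
firing); the swap adopted here is the unique reading that produces a
working fast-spiking cell from these constants.

### Calibrated maximal conductances

The maximal conductances and capacitances are not constrained by printed
values; they were calibrated once so that (i) a constant 4 nS drive
conductance elicits tonic firing near 150 Hz with sub-millisecond spikes
and no firing at zero drive, (ii) the pure-ING network peak lands in the
fast-gamma band, and (iii) stellate cells are silent at the drive trough
and fire sparsely near the crest:

* PV+ interneuron: C = 50 pF, g_Na = 14000 nS, g_Kv3 = 250 nS,
  g_Kv1 = 30 nS, g_L = 6 nS. With these kinetics Kv3 activates steeply
  around -52 mV, so it acts both as the spike repolarizer and as a
  subthreshold brake; the Na/Kv3 ratio must be large for spike initiation
  to win, which is why g_Na is high and g_Kv3 comparatively small.
* Stellate cell: C = 60 pF, g_Na = 7000 nS, g_K = 1000 nS, g_L = 12 nS.

Population heterogeneity: per-cell Gaussian jitter of the maximal
conductances, truncated at zero — CV 0.2 for interneurons (the
interneuron population is deliberately broad) and 0.03 for stellate
cells; interneurons additionally receive per-cell drive peaks drawn
Normal(4, 0.4) nS. Stellate-cell irregularity comes mainly from the OU
noise: the package's simulation default raises the OU noise SD to 0.1 nS
(constant `DEFAULT_E_NOISE`), strong enough that the common theta drive
alone does not synchronize the E population — which is the stated role
of this noise — while `E_NOISE`/`I_NOISE` keep the published 0.02 nS SD
for reference. With 0.02 nS the E population is effectively
deterministic and phase-locks to its own onset every cycle, which
produces spurious E coherence.

## Connectivity

Ordered cell pairs connect independently: I->I with probability 0.30
(fixed weight, default 0.3 nS), I->E with 0.40 (log-normal weights, CV 1,
arithmetic mean `ie_base_mean x 2.5`, default base 0.08 nS), E->I with
0.30. E cells are mutually unconnected. Unordered interneuron pairs form
gap junctions with probability 0.18 (default 0.6 nS). Synaptic delays
are uniform on 0.6–1.0 ms per edge. One integer seed reproduces the
whole graph; heterogeneity (jitter, drive peaks) follows the same seed,
while initial conditions and the OU path follow the runtime seed.

Five readout cells per population are voltage-clamped at 0 mV and record
synaptic current only. Their sampled outgoing chemical edges are retained
in the graph (keeping edge counts exactly binomial) but are inert because
a clamped cell never spikes; they are excluded from gap junctions, which
would physically leak current into the clamp.

### The E->I conductance axis

The swept excitation parameter `ei_gmax` (0–60 nS) is interpreted by
default as the peak AMPA conductance an interneuron feels during one
coherent E-population gamma volley; the per-connection weight is
`ei_gmax / ei_coincident` with `ei_coincident = 18`, the expected number
of E->I afferents coactive within the 1 ms AMPA decay when a volley
spans a few milliseconds (120 expected afferents x volley participation
x 1 ms / volley width). Two alternative interpretations are available in
config: `"total"` (divide by the expected in-degree 120, i.e. the axis
is the summed synaptic weight per interneuron) and `"per_connection"`.
The coincident interpretation is the one for which the model reproduces
the full ING-to-PING transition across 0–60 nS: under the summed-weight
interpretation per-connection kicks of at most 0.5 nS never allow the E
population to pace the interneurons, and under the raw per-connection
interpretation already 6 nS slaves the network completely. It also puts
the physiological per-cell gamma-conductance range measured in slices
(5–10 nS) at the low, ING-preserving end of the axis, where it belongs.

## Synapses and integration

GABA_A synapses are difference-of-two-exponentials conductances
normalized so one spike of weight w peaks at exactly w: I->I rise 0.3 ms
/ decay 4 ms (reversal -75 mV, or -55 mV in the shunting variant), I->E
rise 0.4 ms / decay 6 ms (reversal -65 mV). AMPA E->I synapses are
single-exponential, decay 1 ms, reversal 0 mV. Delays are rounded to the
integration grid and enqueued so that no postsynaptic change precedes
spike + sampled delay.

Integration is a fixed-step staggered exponential-Euler scheme
(dt = 0.025 ms): gates advance by exact exponential relaxation at the
frozen voltage, then the voltage advances by exponential Euler (the
membrane equation is linear in V once conductances and gap-junction peer
voltages are frozen). Spikes are upward 0 mV crossings with a 1 ms
detection refractory; spike times are linearly interpolated within the
step. The scheme is unconditionally stable for the stiff gate rates; its
spike-time accuracy is first-order, so individual spike times converge
to ~0.01 ms per interspike interval as dt is halved, and phase drift
accumulates to a few tenths of a millisecond over 500 ms of tonic firing
at ~170 Hz. The dt-convergence test therefore checks the first ~10 spike
times (drift < 0.1 ms); long-horizon spike phases should not be treated
as dt-exact. The OU processes use the exact discretization, so their
stationary statistics are dt-independent.

The inner loop is a numba-compiled kernel; a pure-Python single-cell
integrator built from the public rate functions serves as an independent
reference and the two are cross-checked in the tests.

## Analysis pipeline

Clamp traces (sampled at 0.1 ms) are optionally band-passed 50–200 Hz
with a zero-phase 4th-order Butterworth, then transformed with an
analytic Morlet wavelet (omega0 = 6 rad/s, 32 scales per octave,
frequencies 30–250 Hz, scale-to-frequency f = omega0/(2 pi s)). The
transform is L1-normalized (a sinusoid of amplitude A gives |W| ~ A), is
computed on the continuous trace and segmented into theta cycles
afterwards, so interior cycle boundaries carry no edge artifacts; the
cone of influence (e-folding time sqrt(2) s of the wavelet envelope)
applies at the recording edges. The first theta cycle and any cycle
containing |current| > 3,000 pA are excluded; remaining per-cycle power
surfaces are averaged.

The gamma peak is the global maximum of the averaged surface; SNR is
peak power over the mean of the whole surface (the "average" in the SNR
criterion is read as the whole-scalogram mean); bandwidth is the FWHM
along frequency at the peak phase. Quality control removes peaks with
power < 20 pA^2 (Thy1 mode; 10 in PV mode), bandwidth > 100 Hz (110 in
PV mode), or SNR < 5; thresholds are inclusive for passing. Total gamma
power sums the 60–140 Hz band inside the cone of influence.

Spike statistics: 30-bin theta-phase histograms and 10 Hz-bin
instantaneous-frequency (1000/ISI) histograms, both normalized by the
number of cycles; population spike-time histograms at 1 ms; and an
autocorrelogram frequency defined as the reciprocal of the first
non-zero-lag autocorrelation peak, computed after subtracting a 7 ms
moving average from the histogram (this removes the theta-envelope
component, which otherwise swamps the gamma comb when E cells fire
sparsely) with parabolic sub-bin interpolation of the peak lag.

Welch PSDs use 40 segments at 50% overlap (segment length floor(N/20.5)).

## Campaigns and regime classification

`sweep_ei` / `heatmap_ei_ie` / `shunting_control` rebuild the network per
(condition, seed), simulate 41 theta cycles (the CI profile uses 11:
1 discarded + 10 analyzed), analyze all five E readouts, and tabulate one
row per readout. The aggregation statistic is the median across readouts
and seeds with interquartile whiskers.

`classify_regime` groups each interneuron's spikes into bursts with a
gap of half the network gamma period and labels a run PING-dominated
when active cells average > 1.5 spikes per burst and the median
intraburst interval is below half the period — i.e. the rhythm is set by
the interburst rather than the interspike interval. These thresholds are
an operationalization of the qualitative burst-grouping description and
are exposed in the function signature.

## What the defaults reproduce, and known divergences

At the calibrated defaults with 40 analyzed cycles and seeds {1, 2, 3}:

* pure ING (E->I = 0, hyperpolarizing I->I): IPSC scalogram peak
  ~145 Hz, E-population autocorrelogram ~143–157 Hz (median within 3% of
  the wavelet peak), interneurons firing single spikes per gamma cycle;
* strong excitation (E->I = 60 nS): PING-dominated regime at ~62 Hz with
  burst-grouped interneuron firing (~3.5 spikes/burst) and peak power at
  or above the ING level;
* along the axis {0, 6, 12, 24, 60} nS the per-seed Spearman correlation
  of frequency with conductance is negative for every seed.

Two reported behaviors are *not* reproduced by this implementation and
are deliberately left as failing checks rather than papered over:

1. **Weak-excitation slowing.** Raising E->I from 0 to 6 nS shifts the
   peak *up* by ~10 Hz here (coherent E volleys phase-advance the
   interneurons) instead of down by ~10 Hz. Many mechanisms were
   explored — stronger I->I recruitment, spike-triggered Kv1 adaptation,
   interneuron heterogeneity, asynchronous noise-driven E firing,
   log-normal E->I weights — and the sign of the weak-coupling effect
   consistently follows the phase-advance of excitation arriving late in
   the interneuron's gamma cycle, a property of this cell's phase
   response. The non-monotone hump at low conductance precedes a sharp
   transition to the slow PING regime between 12 and 24 nS.
2. **Shunting control.** With I->I reversal at -55 mV and no E->I
   coupling, the interneuron network here still synchronizes (SNR >> 5):
   the deep Kv3-mediated AHP (~-66 mV) makes -55 mV inhibition act as a
   strong depolarizing reset that is, if anything, a better synchronizer
   than hyperpolarizing inhibition. Abolishing ING under shunting
   appears to require an interspike voltage trajectory hovering at or
   above -55 mV, i.e. a shallower AHP than this fast-spiking phenotype
   produces without losing repetitive firing.

## What the synthetic data do and do not show

The surrogate generator produces exactly the structure the analysis
expects (raised-cosine theta envelope, single gamma carrier, white
noise, isolated +/-5,000 pA artifacts, crest-locked spikes with
geometric cycle skipping). Passing recovery tests on surrogates
demonstrates that the pipeline is unbiased and correctly excludes
contaminated cycles under those assumptions; it does not demonstrate
robustness to colored noise, drifting theta frequency, multi-component
gamma, or slow artifacts below the 3,000 pA criterion, none of which the
generator emulates.

## Problem sizes

Full runs are 500 cells x 41 theta cycles (5.125 s) at dt = 0.025 ms
(~30 s wall-clock each). The test suite uses 11-cycle runs for the sweep
campaigns plus full 41-cycle runs for the pure-ING condition; the
acceptance script runs six full-size simulations.
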