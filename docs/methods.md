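# Methods

## Model

Neurons are isopotential spheres; there are no dendritic or axonal
compartments and no synapses between interneurons. All quantities are kept
in a consistent small-signal unit system (mV, ms, pA, nS, pF; 1 pA into 1 pF
= 1 mV/ms), and the per-area parameters are converted once at construction
through the sphere surface *A* = π d² (d in cm).

Passive membrane (defaults): c_m = 1 µF/cm², g_leak = 0.3 mS/cm²,
E_leak = V_rest = −60 mV. Hence C = c_m A, G = g_leak A, Rin = 1/G and
τ = c_m/g_leak = 3.333 ms for every isolated soma regardless of size — the
size-independence of τ is a structural feature of the parameter set, and it
matters below.

Spiking (integrate-and-fire): threshold −40 mV, spike peak +10 mV,
relative accommodation 0.3 with τ = 10 ms, AHP conductance 0.4 mS/cm² with
τ = 3 ms and reversal −70 mV, absolute refractory period 2 ms. There is no
hard voltage reset: repolarisation is driven by the AHP conductance. The
spike itself is a stylised forced waveform — a linear rise from the voltage
at threshold crossing to +10 mV and a linear return, 1 ms total — during
which the forced voltage drives gap-junction currents. This is what
produces electrical PSPs ("spikelets") in coupled neurons; only the peak
voltage is constrained by the parameter set, so the 1 ms symmetric shape is
a package choice. Chemical release is triggered at the threshold crossing.

Accommodation raises the threshold toward θ₀ + 0.3·max(V − V_rest, 0) with
a 10 ms time constant. The one-sided form is deliberate: accommodation is a
response to sustained depolarisation, and letting the threshold track
hyperpolarisation downward would fire a spurious "rebound spike" at the end
of every large hyperpolarising step (a −5 pA step deflects the 1 µm neuron
by −530 mV in this fully linear subthreshold regime).

Synapses. Chemical: conductance increments by g_norm·A_post
(g_norm = 0.25 mS/cm²) per presynaptic spike, decays mono-exponentially
with τ = 1 ms, reversal 0 mV; the area scaling makes the uncoupled cEPSP
waveform exactly size-invariant (conductance and capacitance both scale
with d²). Electrical: non-rectifying ohmic conductances in absolute nS;
onto a motor neuron of diameter x each junction carries 0.01·x³ nS, read as
the per-synapse weight (the alternative — a summed coupling budget per
neuron — would make input resistance independent of convergence, which
defeats the construction).

Convergence network. One block = 10 electrical interneurons (7 µm), where
interneuron k contacts motor neurons of diameter ≥ k µm; the block is
duplicated n = 0..10 times, so motor neuron x receives n·x synapses
(10·x % of the pool at any n ≥ 1) and the pool totals 10·n. Chemical drive:
one shared 5 µm interneuron contacting all ten motor neurons, or one
dedicated interneuron per motor neuron.

## Integration

Subthreshold dynamics are linear, so whenever no spike waveform is in
progress and no AHP/chemical conductance is active (> 1e-12 nS) the
simulator advances with the exact propagator of the passive system:
V(t+dt) = V_ss + P (V(t) − V_ss), with P = C^(−1/2) U e^(−Λ dt) U′ C^(1/2)
from the symmetric eigendecomposition of the whitened conductance matrix
(computed once per run) and V_ss the conductance-matrix solve for the
current injection. Steady states and relaxation eigenvalues are therefore
step-size independent — important because the strongest coupled cells have
local time constants of microseconds (3.14 pF against 1000 nS), and an
explicit treatment of the coupling biases the slow relaxation mode by
~15% at dt = 0.01 ms. During spike/AHP/synaptic transients the integrator
falls back to exponential Euler per neuron (conductances frozen over one
step), dt = 0.01 ms by default; halving the step changes no reported
steady-state voltage by more than 0.1%.

## Measurement procedures

All measurements are applied identically to simulated traces and synthetic
recordings.

- **Input resistance**: mean of ≥ 3 hyperpolarising steps (−5 pA, 50 ms in
  the simulated protocol); per sweep ΔV_ss/I with ΔV_ss read as the mean of
  the last 5 ms of the pulse (≥ 14 isolated time constants) minus the
  pre-pulse baseline.
- **Membrane time constant**: double-exponential least-squares fit
  a·e^(−t/τ₁) + b·e^(−t/τ₂) of the relaxation after the step, reported as
  the amplitude-weighted τ = a/(a+b)·τ₁ + b/(a+b)·τ₂. The fit is
  multi-started from τ pairs spanning 0.5–50 ms, amplitudes constrained to
  the sign of the initial deflection, components ordered fast-first;
  near-single-exponential data returns one negligible component.
- **PSP amplitude**: peak depolarisation within 20 ms of the presynaptic
  spike minus the mean of the 2 ms pre-spike baseline. On noisy sweeps the
  amplitude is taken on the averaged trace: the maximum of many noisy
  samples is biased upward.
- **Failures**: a sweep is a chemical failure when its baseline-subtracted
  deflection inside the chemical window (1.5–8 ms after the spike; the
  electrical component occupies the first ~1.5 ms) stays below 3× the
  sweep-set baseline noise SD. Sweeps are smoothed with a 0.3 ms boxcar
  before peak picking, and the classification is refined iteratively: the
  mean of currently-flagged failures estimates the electrical template,
  deflections are re-measured after subtracting it, repeat to a fixed
  point. The 3×SD criterion and the refinement are package choices (the
  original procedure was visual); both are tunable.
- **Chemical-component isolation**: the failure-average template is
  subtracted from every sweep; undefined when no failures exist. Re-adding
  the stored template reconstructs the originals exactly.
- **PSP decay**: double-exponential fit restricted to [peak, first crossing
  of 20% of peak]; the reported constant is the fastest component carrying
  ≥ 5% of the fitted amplitude (slow electrical tails otherwise confound
  the chemical decay; the amplitude filter keeps a pure single exponential
  from returning a spurious fast junk component).
- **Ohmic current**: I = V/R (mV/MΩ → nA, ×1000 → pA). **Percent of
  control**: 100 × post/pre. **Swim peaks**: per-bout maximum inward
  deflection from the pre-bout baseline; the per-bout vector and its mean
  are both reported (mean is the default summary; the max across bouts is
  available from the vector).

## Statistics

Spearman rank correlation on midranks, two-sided, reported with df = n − 2;
exact permutation p for n ≤ 8 (all n! orderings), t-approximation
otherwise. Mann-Whitney U as min(U_a, U_b) with midrank ties, exact
enumeration of all C(n₁+n₂, n₁) assignments for n₁+n₂ ≤ 12, otherwise the
normal approximation with tie and continuity corrections. Significance
convention p < 0.05. Semi-log trends are OLS of y on log₁₀ x.

## Synthetic recordings

The generator emulates three regimes of whole-cell data with stored ground
truth; the single stored seed drives every stochastic draw, so regeneration
is bit-identical. Defaults are chosen to sit in the biologically observed
ranges: Rin 500 MΩ; relaxation 0.75/0.25 split between 2 and 10 ms;
electrical PSP 1.5 mV with fast kinetics (0.15/0.5 ms rise/decay, 0.2 ms
latency), chemical PSP 2.0 mV (0.5/3 ms, 2.5 ms latency) failing with
p = 0.25; swim bouts with peaks 100–140 pA and a within-bout cycle
frequency chirping linearly 75 → 20 Hz (oscillatory drive is faster early
in an episode; the linear law is a stand-in). Noise is additive i.i.d.
Gaussian (0.1 mV on PSP sweeps, 0.2 mV on steps, 2 pA on current traces).

What the generator does *not* emulate — electrode artifacts, series
resistance, correlated (1/f) noise, spike-shape realism, amplitude
jitter of successes — bounds what recovery tests show: they validate the
analysis algebra and its detection thresholds against known truth, not
robustness to every pathology of real recordings.

## Design notes on the virtual experiments

- The Rin/τ protocol rejects any run in which a spike occurs (it never
  should, under hyperpolarisation).
- The PSP protocol enforces exactly one presynaptic spike per run; the
  standard drives are 5 ms pulses of 10 pA (5 µm chemical interneurons) and
  30 pA (7 µm electrical interneurons).
- The eEPSP-vs-size series is measured on bare interneuron/motor-neuron
  pairs with a brief strong drive (300 pA, 0.5 ms) and postsynaptic spiking
  disabled: without the full network's shunt the spikelet exceeds
  threshold, a slow approach to threshold pre-depolarises the target
  through the junction, and drive current outlasting the spike waveform
  inflates the amplitude. The brief-pulse pair isolates the passive
  spikelet, which grows monotonically with target size (0.01x³ coupling vs
  x² membrane conductance).
- The coupling map (dedicated chemical wiring, full convergence) spikes
  each motor neuron's own chemical interneuron and records all ten motor
  neurons; shared-afferent counts accompany the amplitude and time-to-peak
  matrices. "Low-pass filtered" amplitudes are raw peaks — the network
  itself is the filter.

## Known limitations

Two intuitive properties of the published construction fail under the
exact dynamics, and the package reports them as measured:

1. **Weighted τ is not monotone in convergence for large motor neurons.**
   Because every cell shares c_m/g_leak, the slowest network mode is pinned
   just below 3.333 ms at any coupling strength (the infinitely-coupled
   pool is a single RC with the same ratio). At high convergence a large
   motor neuron charges together with the pool, so its relaxation is
   dominated by that slow global mode: measured τ for the 10 µm neuron goes
   3.333 → 3.114 → 3.174 → 3.181 ms across 0×/10×/50×/100×. τ always drops
   below the isolated value, and for small motor neurons (whose 0.01x³
   coupling dwarfs their x² leak) it collapses monotonically, but strict
   monotonicity across all levels holds only for d ≤ 3 µm. For the same
   reason τ-vs-Rin is not monotone across the whole sweep: small neurons
   keep the highest Rin yet show the shortest τ.
2. **Coupling potentials are not always ≪ the direct cEPSP.** The synaptic
   charge through a 10 µm motor neuron's chemical synapse (~47 fC)
   redistributes across the entire pool (~174 pF) within microseconds at
   full convergence, so every neuron rides the same ~0.15 mV envelope and
   the direct cEPSP exceeds the coupling potentials by only ~7%. For small
   and mid-sized input neurons the separation is 1–3 orders of magnitude —
   the regime the published example traces illustrate. Coupling potentials
   are always slower to peak, and their amplitude in a fixed recorded
   neuron grows with the shared-afferent count of the input neuron.

Other limitations: no dendritic filtering (somatic coupling only), no
rectifying junctions, no interneuron-interneuron synapses, and protocol
durations (50 ms steps, ~65 ms PSP runs) chosen as the shortest windows
that leave all measured quantities step- and duration-independent at the
reported precision.
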