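"""Seeded generators of experiment-like sweeps with known ground truth.

Three kinds of synthetic whole-cell data are produced, emulating the regimes
of larval-zebrafish spinal recordings so that every analysis operation can be
exercised against a stored truth without external data:

* hyperpolarizing current-step sweeps with bi-exponential onset/offset,
* spike-triggered mixed-PSP sweeps (fast, reliable electrical component plus
  a later chemical component with Bernoulli failures),
* fictive-swim current traces: a stimulus artifact followed by bouts of
  oscillatory inward current whose cycle frequency chirps from high to low
  within each bout.

Noise is additive i.i.d. Gaussian and is the only stochastic element besides
the chemical failures; all draws flow from the single seed stored in the
ground truth, so regeneration is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .sweeps import SweepSet

__all__ = ["GroundTruth", "generate_step_response_sweeps",
           "generate_mixed_psp_sweeps", "generate_fictive_swim_trace"]


@dataclass
class GroundTruth:
    """True parameters behind a synthetic sweep set.

    Membrane: rin_mohm with a bi-exponential relaxation split into fractional
    amplitudes a (fast, tau1) and b (slow, tau2); a + b should be 1. PSPs:
    electrical_mv and chemical_mv component amplitudes and the chemical
    failure probability. Swim: per-bout peak inward currents (pA) and the
    within-bout cycle-frequency chirp (Hz, high to low). noise_sd is in the
    units of the generated trace (mV or pA).
    """

    seed: int = 0
    rin_mohm: float = 500.0
    a: float = 1.0
    tau1_ms: float = 3.333
    b: float = 0.0
    tau2_ms: float = 10.0
    v_rest_mv: float = -60.0
    electrical_mv: float = 1.5
    chemical_mv: float = 2.0
    failure_prob: float = 0.25
    chem_latency_ms: float = 2.5
    chem_rise_ms: float = 0.5
    chem_decay_ms: float = 3.0
    elec_latency_ms: float = 0.2
    elec_rise_ms: float = 0.15
    elec_decay_ms: float = 0.5
    swim_peaks_pa: tuple = (100.0, 110.0, 120.0, 130.0, 140.0)
    swim_freq_hz: tuple = (75.0, 20.0)
    noise_sd: float = 0.1

    @property
    def weighted_tau_ms(self) -> float:
        return (self.a * self.tau1_ms + self.b * self.tau2_ms) / (self.a + self.b)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["swim_peaks_pa"] = tuple(d["swim_peaks_pa"])
        d["swim_freq_hz"] = tuple(d["swim_freq_hz"])
        return cls(**d)


def _alpha_kernel(t, latency, rise, decay):
    """Difference-of-exponentials PSP shape, peak-normalised to 1."""
    s = np.clip(t - latency, 0.0, None)
    raw = np.exp(-s / decay) - np.exp(-s / rise)
    raw[t < latency] = 0.0
    # analytic peak of the difference of exponentials
    tp = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-tp / decay) - np.exp(-tp / rise)
    return raw / peak


def generate_step_response_sweeps(
    truth: GroundTruth,
    n_sweeps: int = 5,
    current_pa: float = -5.0,
    dt: float = 0.05,
    baseline_ms: float = 20.0,
    step_ms: float = 50.0,
    tail_ms: float = 40.0,
) -> SweepSet:
    """Hyperpolarizing step responses with bi-exponential onset and offset.

    The deflection amplitude is current * rin; the charging and relaxation
    both follow the ground-truth double exponential (fractions a, b at tau1,
    tau2). Gaussian noise of noise_sd mV is added per sample.
    """
    if n_sweeps < 3:
        raise ValueError("generate at least three sweeps for Rin analysis")
    rng = np.random.default_rng(truth.seed)
    t = np.arange(0.0, baseline_ms + step_ms + tail_ms, dt)
    dv = current_pa * truth.rin_mohm * 1e-3  # pA * MOhm = uV*1e3 -> mV
    w = truth.a + truth.b
    fa, fb = truth.a / w, truth.b / w

    def relax(s):  # fraction of deflection remaining after s ms
        return fa * np.exp(-s / truth.tau1_ms) + fb * np.exp(-s / truth.tau2_ms)

    v = np.full_like(t, truth.v_rest_mv)
    on = t >= baseline_ms
    v[on] += dv * (1.0 - relax(t[on] - baseline_ms))
    off = t >= baseline_ms + step_ms
    v[off] = truth.v_rest_mv + dv * relax(t[off] - baseline_ms - step_ms)

    data = v[None, :] + rng.normal(0.0, truth.noise_sd, size=(n_sweeps, t.size))
    return SweepSet(
        time=t,
        data=data,
        units="mV",
        stim_onset=baseline_ms,
        stim_duration=step_ms,
        stim_amplitude=current_pa,
        ground_truth=truth,
        meta={"kind": "step"},
    )


def generate_mixed_psp_sweeps(
    truth: GroundTruth,
    n_sweeps: int = 80,
    dt: float = 0.05,
    spike_time: float = 10.0,
    sweep_ms: float = 40.0,
) -> SweepSet:
    """Spike-triggered mixed-PSP sweeps with stochastic chemical failures.

    Every sweep carries the deterministic electrical template (fast
    kinetics, always present); the chemical component (slower kinetics,
    ``chemical_mv``) is added with probability 1 - failure_prob. Which
    sweeps failed is stored in ``meta['true_failures']``.
    """
    if not 0.0 <= truth.failure_prob <= 1.0:
        raise ValueError("failure probability must lie in [0, 1]")
    rng = np.random.default_rng(truth.seed)
    t = np.arange(0.0, sweep_ms, dt)
    rel = t - spike_time
    elec = truth.electrical_mv * _alpha_kernel(
        rel, truth.elec_latency_ms, truth.elec_rise_ms, truth.elec_decay_ms
    )
    chem = truth.chemical_mv * _alpha_kernel(
        rel, truth.chem_latency_ms, truth.chem_rise_ms, truth.chem_decay_ms
    )
    failures = rng.random(n_sweeps) < truth.failure_prob
    data = np.empty((n_sweeps, t.size))
    for i in range(n_sweeps):
        data[i] = truth.v_rest_mv + elec + (0.0 if failures[i] else 1.0) * chem
    data += rng.normal(0.0, truth.noise_sd, size=data.shape)
    return SweepSet(
        time=t,
        data=data,
        units="mV",
        spike_time=spike_time,
        ground_truth=truth,
        meta={"kind": "psp", "true_failures": failures},
    )


def generate_fictive_swim_trace(
    truth: GroundTruth,
    dt: float = 0.1,
    bout_ms: float = 400.0,
    gap_ms: float = 300.0,
    baseline_ms: float = 200.0,
):
    """Fictive-swim current trace: stimulus artifact then oscillatory bouts.

    Each programmed bout is an inward (negative) oscillation at a cycle
    frequency chirping linearly from swim_freq_hz[0] down to swim_freq_hz[1],
    under a raised-sine envelope whose deepest excursion equals the
    programmed per-bout peak. Returns (time, current, bout_windows) with
    bout_windows a list of (start, end) ms for peak_swim_current.
    """
    hi, lo = truth.swim_freq_hz
    if hi <= 0 or lo <= 0 or lo > hi:
        raise ValueError("swim frequency range must satisfy 0 < low <= high")
    rng = np.random.default_rng(truth.seed)
    n_bouts = len(truth.swim_peaks_pa)
    total = baseline_ms + n_bouts * (bout_ms + gap_ms)
    t = np.arange(0.0, total, dt)
    i_pa = np.zeros_like(t)

    # brief stimulus artifact at the end of the baseline period
    art = (t >= baseline_ms - 2.0) & (t < baseline_ms)
    i_pa[art] += 200.0 * np.sin(np.pi * (t[art] - (baseline_ms - 2.0)) / 2.0)

    bouts = []
    for k, peak in enumerate(truth.swim_peaks_pa):
        start = baseline_ms + 5.0 + k * (bout_ms + gap_ms)
        end = start + bout_ms
        m = (t >= start) & (t < end)
        s = (t[m] - start) / bout_ms  # 0..1 within the bout
        freq = hi + (lo - hi) * s     # linear chirp, Hz
        phase = 2.0 * np.pi * np.cumsum(freq) * dt / 1e3
        envelope = np.sin(np.pi * s)
        osc = envelope * 0.5 * (1.0 - np.cos(phase))  # in [0, envelope]
        i_pa[m] -= peak * osc / max(osc.max(), 1e-12)
        bouts.append((start, end))

    i_pa += rng.normal(0.0, truth.noise_sd, size=t.size)
    return t, i_pa, bouts
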