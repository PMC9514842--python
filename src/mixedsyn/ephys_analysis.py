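"""Whole-cell sweep analysis: Rin, time constants, PSP amplitudes, failures.

These are the measurement procedures applied identically to simulated traces
and to synthetic (or imported) recordings: input resistance from averaged
hyperpolarizing steps, the membrane time constant from a double-exponential
fit of the relaxation with an amplitude-weighted mean tau, EPSP amplitudes
against a 2 ms pre-spike baseline, chemical failure-rate counting,
electrical-template subtraction to isolate the chemical component of mixed
PSPs, decay time constants fit between the peak and 20% of peak, Ohm's-law
current estimates, and peak inward current per fictive-swim bout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    CannotIsolateError,
    FitFailureError,
    InsufficientDataError,
    WindowTruncationError,
)
from .sweeps import SweepSet

__all__ = [
    "FitResult",
    "PSPMeasurement",
    "SwimPeaks",
    "input_resistance",
    "fit_double_exponential",
    "psp_amplitude",
    "classify_failures",
    "isolate_chemical_component",
    "psp_decay_tau",
    "ohmic_current",
    "percent_control",
    "peak_swim_current",
]

#: window after the presynaptic spike in which the chemical component of a
#: mixed PSP is expected (ms); the electrical component occupies the first
#: ~1.5 ms
DEFAULT_CHEM_WINDOW = (1.5, 8.0)

#: failure criterion: deflection must exceed this multiple of the sweep-set
#: baseline noise SD to count as a chemical success
DEFAULT_FAILURE_CRITERION_SD = 3.0

#: boxcar width (ms) used to smooth sweeps before peak picking in failure
#: classification, so single-sample noise excursions do not defeat the
#: criterion
_CLASSIFY_SMOOTH_MS = 0.3

_BASELINE_MS = 2.0  # pre-spike baseline window, ms


@dataclass(frozen=True)
class FitResult:
    """Double-exponential fit a*exp(-t/tau1) + b*exp(-t/tau2).

    Components are ordered fast-first (tau1 <= tau2). weighted_tau is the
    amplitude-weighted mean a/(a+b)*tau1 + b/(a+b)*tau2 (weights on
    magnitudes), always inside [tau1, tau2].
    """

    a: float
    tau1: float
    b: float
    tau2: float
    weighted_tau: float
    rmse: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.a * np.exp(-t / self.tau1) + self.b * np.exp(-t / self.tau2)


@dataclass(frozen=True)
class PSPMeasurement:
    """Per-sweep PSP quantification."""

    amplitude: float          # mV, from the 2 ms pre-spike baseline
    is_failure: bool
    decay_tau: float | None   # ms, fast constant; None when not measurable
    time_to_peak: float       # ms after the presynaptic spike


@dataclass(frozen=True)
class SwimPeaks:
    """Per-bout peak inward currents (pA, magnitudes) and their mean."""

    peaks: np.ndarray
    mean: float


def input_resistance(sweeps: SweepSet, injected_current: float | None = None) -> float:
    """Input resistance (MOhm) from >=3 hyperpolarizing step sweeps.

    Each sweep contributes delta-V_ss / I where delta-V_ss is the mean over
    the last 5 ms of the pulse minus the pre-pulse baseline mean; the
    per-sweep resistances are averaged.
    """
    if sweeps.n_sweeps < 3:
        raise InsufficientDataError(
            f"input resistance requires at least three pulses, got {sweeps.n_sweeps}"
        )
    current = sweeps.stim_amplitude if injected_current is None else injected_current
    if current is None or current == 0:
        raise ValueError("injected current must be nonzero (pA)")
    if sweeps.stim_onset is None or sweeps.stim_duration is None:
        raise ValueError("sweep set lacks step onset/duration metadata")
    t = sweeps.time
    on, dur = sweeps.stim_onset, sweeps.stim_duration
    base = t < on
    steady = (t >= on + dur - 5.0) & (t < on + dur)
    if not base.any() or not steady.any():
        raise ValueError("step window leaves no baseline or steady-state samples")
    dv = sweeps.data[:, steady].mean(axis=1) - sweeps.data[:, base].mean(axis=1)
    r_gohm = dv / current  # mV / pA = GOhm
    return float(np.mean(r_gohm) * 1e3)


def _fit_once(t, y, tau1_0, tau2_0):
    y0 = abs(y[0]) + abs(y).max()

    def resid(p):
        a, lt1, b, lt2 = p
        return a * np.exp(-t * np.exp(-lt1)) + b * np.exp(-t * np.exp(-lt2)) - y

    res = least_squares(
        resid,
        x0=[0.7 * y[0], np.log(tau1_0), 0.3 * y[0], np.log(tau2_0)],
        bounds=([0, np.log(1e-3), 0, np.log(1e-3)], [2 * y0, np.log(1e5), 2 * y0, np.log(1e5)]),
        method="trf",
        max_nfev=2000,
    )
    a, lt1, b, lt2 = res.x
    return a, np.exp(lt1), b, np.exp(lt2), float(np.sqrt(np.mean(res.fun**2))), res.success


_TAU_STARTS = (0.5, 2.0, 10.0, 50.0)


def fit_double_exponential(time: np.ndarray, values: np.ndarray, baseline: float = 0.0) -> FitResult:
    """Least-squares double-exponential fit of a relaxation toward baseline.

    ``values`` is the decaying segment; ``baseline`` is subtracted before
    fitting so the model decays to zero. Nonlinear least squares is started
    from a grid of (tau1, tau2) pairs spanning 0.5-50 ms and the lowest
    residual wins; amplitudes are constrained to share the sign of the
    initial deflection, and near-single-exponential data comes back with one
    negligible component.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(values, dtype=float) - baseline
    if t.size != y.size:
        raise ValueError("time and values must have equal length")
    if t.size < 20:
        raise InsufficientDataError(
            f"double-exponential fit requires >=20 samples, got {t.size}"
        )
    t = t - t[0]
    sign = 1.0 if y[: max(3, t.size // 50)].mean() >= 0 else -1.0
    ys = sign * y
    scale = np.abs(ys).max()
    if scale == 0:
        raise FitFailureError("segment is identically zero; nothing to fit")

    best = None
    for i, t1 in enumerate(_TAU_STARTS):
        for t2 in _TAU_STARTS[i:]:
            a, tau1, b, tau2, rmse, ok = _fit_once(t, ys / scale, t1, t2)
            if ok and (best is None or rmse < best[4]):
                best = (a, tau1, b, tau2, rmse)
    if best is None:
        raise FitFailureError(
            "double-exponential fit failed to converge from every starting "
            f"tau pair in {_TAU_STARTS}"
        )
    a, tau1, b, tau2, rmse = best
    a, b = a * scale * sign, b * scale * sign
    if tau1 > tau2:
        a, tau1, b, tau2 = b, tau2, a, tau1
    wa, wb = abs(a), abs(b)
    if wa + wb == 0:
        raise FitFailureError("fit collapsed to zero amplitude")
    weighted = (wa * tau1 + wb * tau2) / (wa + wb)
    return FitResult(a=a, tau1=tau1, b=b, tau2=tau2, weighted_tau=weighted, rmse=rmse * scale)


def psp_amplitude(
    time: np.ndarray,
    values: np.ndarray,
    spike_time: float,
    search_window: float = 20.0,
) -> float:
    """PSP amplitude (mV): peak depolarization minus the 2 ms pre-spike baseline.

    The peak is the maximum within ``search_window`` ms after the presynaptic
    spike. Invariant to any constant offset added to the sweep.
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(values, dtype=float)
    base = (t >= spike_time - _BASELINE_MS) & (t < spike_time)
    if not base.any() or t[0] > spike_time - _BASELINE_MS + t[1] - t[0]:
        raise InsufficientDataError(
            "need >=2 ms of pre-spike baseline to measure a PSP amplitude"
        )
    win = (t >= spike_time) & (t <= spike_time + search_window)
    if not win.any():
        raise ValueError("no samples inside the post-spike search window")
    return float(v[win].max() - v[base].mean())


def _baseline_stats(sweeps: SweepSet, spike_time: float):
    t = sweeps.time
    base = (t >= spike_time - _BASELINE_MS) & (t < spike_time)
    if not base.any():
        raise InsufficientDataError("sweeps lack a 2 ms pre-spike baseline window")
    seg = sweeps.data[:, base]
    means = seg.mean(axis=1)
    noise_sd = float((seg - means[:, None]).std())
    return means, noise_sd


def classify_failures(
    sweeps: SweepSet,
    chem_window: tuple[float, float] = DEFAULT_CHEM_WINDOW,
    criterion_sd: float = DEFAULT_FAILURE_CRITERION_SD,
) -> tuple[np.ndarray, float]:
    """Flag chemical-failure sweeps and return the failure rate in percent.

    A sweep is a failure when its baseline-subtracted deflection inside the
    chemical window (default 1.5-8 ms after the presynaptic spike) stays
    below ``criterion_sd`` times the sweep-set baseline noise SD. Sweeps are
    lightly smoothed (0.3 ms boxcar) before peak picking. Because the tail
    of the electrical component can intrude into the window, the
    classification is refined iteratively: the mean of the currently flagged
    failures estimates the electrical template, deflections are re-measured
    after subtracting it, and the loop repeats until the flags stop changing.
    Rate = failures / total * 100.
    """
    if sweeps.n_sweeps == 0:
        raise InsufficientDataError("empty sweep set")
    if not 10 <= sweeps.n_sweeps <= 200:
        warnings.warn(
            f"{sweeps.n_sweeps} sweeps is outside the recommended 10-200 range "
            "for failure-rate estimation",
            stacklevel=2,
        )
    if sweeps.spike_time is None:
        raise ValueError("sweep set lacks a presynaptic spike time")
    t0 = sweeps.spike_time
    means, noise_sd = _baseline_stats(sweeps, t0)

    k = max(1, int(round(_CLASSIFY_SMOOTH_MS / sweeps.dt)))
    kernel = np.ones(k) / k
    smooth = np.apply_along_axis(lambda s: np.convolve(s, kernel, mode="same"), 1, sweeps.data)

    t = sweeps.time
    win = (t >= t0 + chem_window[0]) & (t <= t0 + chem_window[1])
    if not win.any():
        raise ValueError("chemical window contains no samples")
    criterion = criterion_sd * noise_sd

    deflection = smooth[:, win].max(axis=1) - means
    flags = deflection < criterion
    for _ in range(10):
        if not flags.any():
            break
        template = smooth[flags].mean(axis=0) - means[flags].mean()
        corrected = (smooth - template[None, :])[:, win].max(axis=1) - means
        new_flags = corrected < criterion
        if np.array_equal(new_flags, flags):
            break
        flags = new_flags
    rate = 100.0 * flags.sum() / sweeps.n_sweeps
    return flags, float(rate)


def isolate_chemical_component(sweeps: SweepSet, failure_flags: np.ndarray) -> SweepSet:
    """Subtract the failure-averaged electrical template from every sweep.

    The average of failure sweeps (chemical component absent) estimates the
    pure electrical response; subtracting it from all sweeps leaves the
    chemical component, measurable on the successes. Undefined without
    failures. The template is stored in ``meta['electrical_template']`` so
    re-adding it reconstructs the originals exactly.
    """
    flags = np.asarray(failure_flags, dtype=bool)
    if flags.shape[0] != sweeps.n_sweeps:
        raise ValueError("failure flags length does not match the sweep count")
    if not flags.any():
        raise CannotIsolateError(
            "no failure sweeps: the electrical template cannot be estimated"
        )
    template = sweeps.data[flags].mean(axis=0)
    out = SweepSet(
        time=sweeps.time,
        data=sweeps.data - template[None, :],
        units=sweeps.units,
        spike_time=sweeps.spike_time,
        ground_truth=sweeps.ground_truth,
        meta={**sweeps.meta, "electrical_template": template},
    )
    return out


def psp_decay_tau(
    time: np.ndarray,
    values: np.ndarray,
    spike_time: float | None = None,
    min_amplitude_fraction: float = 0.05,
) -> float:
    """Decay time constant (ms) of a PSP: fast constant of a double-exponential
    fit restricted to [peak, first crossing of 20% of peak].

    The fast constant is reported because slow electrical events can
    contaminate the tail; components contributing less than
    ``min_amplitude_fraction`` of the total amplitude are ignored when
    selecting it (a pure single exponential then returns its own tau).
    """
    t = np.asarray(time, dtype=float)
    v = np.asarray(values, dtype=float)
    if spike_time is not None:
        sel = t >= spike_time
        base = (t >= spike_time - _BASELINE_MS) & (t < spike_time)
        offset = v[base].mean() if base.any() else 0.0
        t, v = t[sel], v[sel] - offset
    ipk = int(np.argmax(np.abs(v)))
    peak = v[ipk]
    if peak == 0:
        raise FitFailureError("no peak deflection in segment")
    tail = v[ipk:]
    below = np.flatnonzero(np.abs(tail) <= 0.2 * abs(peak))
    if below.size == 0:
        raise WindowTruncationError(
            "decay never reaches 20% of peak within the record"
        )
    stop = ipk + below[0] + 1
    fit = fit_double_exponential(t[ipk:stop], v[ipk:stop])
    total = abs(fit.a) + abs(fit.b)
    taus = [
        tau
        for amp, tau in ((fit.a, fit.tau1), (fit.b, fit.tau2))
        if abs(amp) / total >= min_amplitude_fraction
    ]
    return float(min(taus))


def ohmic_current(amplitude: float, rin: float) -> float:
    """Synaptic current (pA) inferred from a PSP amplitude via Ohm's law.

    I = V/R with V in mV and R in MOhm gives nA; multiplied by 1000 for pA.
    """
    if rin <= 0:
        raise ValueError(f"input resistance must be positive, got {rin}")
    return amplitude / rin * 1e3


def percent_control(pre: float, post: float) -> float:
    """Post value as percent of the pre (control) value, control = 100%."""
    if pre <= 0:
        raise ValueError(f"control value must be positive, got {pre}")
    return 100.0 * post / pre


def peak_swim_current(
    time: np.ndarray,
    current: np.ndarray,
    bouts: list[tuple[float, float]],
    baseline_window: tuple[float, float] | None = None,
) -> SwimPeaks:
    """Peak inward (excitatory) current per fictive-swim bout, from baseline.

    ``bouts`` is a list of (start, end) times in ms. Baseline is the mean
    current over ``baseline_window`` (defaults to everything before the first
    bout). Each bout contributes the magnitude of its largest inward (negative)
    deflection from baseline; the per-bout vector and its mean are returned.
    """
    t = np.asarray(time, dtype=float)
    i = np.asarray(current, dtype=float)
    if len(bouts) == 0:
        raise InsufficientDataError("no swim bouts annotated")
    if len(bouts) < 5:
        warnings.warn(
            f"only {len(bouts)} bouts; at least five are recommended per fish",
            stacklevel=2,
        )
    if baseline_window is None:
        baseline_window = (float(t[0]), float(min(b[0] for b in bouts)))
    bmask = (t >= baseline_window[0]) & (t < baseline_window[1])
    if not bmask.any():
        raise ValueError("baseline window contains no samples")
    baseline = i[bmask].mean()
    peaks = []
    for start, end in bouts:
        m = (t >= start) & (t <= end)
        if not m.any():
            raise ValueError(f"bout ({start}, {end}) contains no samples")
        peaks.append(max(0.0, float(baseline - i[m].min())))
    peaks = np.asarray(peaks)
    return SwimPeaks(peaks=peaks, mean=float(peaks.mean()))
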