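"""Virtual experiments on built networks: Rin/tau steps, single-spike PSPs,
convergence sweeps and the coupling-potential map.

Every protocol is deterministic given the network and integration step. The
measurement conventions mirror the sweep-analysis module: input resistance
from the mean of the last 5 ms of a 50 ms, 5 pA hyperpolarizing pulse; the
time constant from a double-exponential fit of the relaxation after the
pulse; PSP amplitudes from a 2 ms pre-spike baseline to the extremum within
20 ms of the presynaptic spike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ephys_analysis as ea
from .exceptions import ProtocolViolationError
from .model_core import NetworkSpec, SimTrace, StimulusProtocol, StimulusPulse, simulate
from .network_builder import build_size_network, motor_id, shared_afferents
from .sweeps import SweepSet

__all__ = [
    "RinResult",
    "PSPProtocolResult",
    "CouplingMap",
    "run_rin_protocol",
    "run_psp_protocol",
    "run_coupling_map",
    "run_convergence_sweep",
    "run_epsp_size_series",
]

RIN_PULSE_PA = -5.0     # hyperpolarizing step amplitude, pA
RIN_PULSE_MS = 50.0     # step duration, ms
SPIKE_PULSE_MS = 5.0    # presynaptic drive duration, ms
CHEM_PULSE_PA = 10.0    # drive into 5 um chemical interneurons, pA
ELEC_PULSE_PA = 30.0    # drive into 7 um electrical interneurons, pA
PSP_SEARCH_MS = 20.0    # post-spike window for the PSP extremum, ms

_BASELINE_MS = 10.0     # pre-stimulus settling time in every protocol
_TAIL_MS = 30.0         # post-stimulus relaxation recorded for tau fits


@dataclass
class RinResult:
    """Input resistance and weighted time constant of one neuron."""

    target: str
    rin_mohm: float
    tau_ms: float
    fit: ea.FitResult
    trace: SimTrace


@dataclass
class PSPProtocolResult:
    """Aligned postsynaptic traces evoked by a single presynaptic spike."""

    trace: SimTrace
    pre: str
    spike_time: float
    targets: list[str]

    def amplitude(self, neuron_id: str) -> float:
        return ea.psp_amplitude(
            self.trace.time, self.trace.voltage(neuron_id), self.spike_time,
            search_window=PSP_SEARCH_MS,
        )

    def time_to_peak(self, neuron_id: str) -> float:
        t, v = self.trace.time, self.trace.voltage(neuron_id)
        win = (t >= self.spike_time) & (t <= self.spike_time + PSP_SEARCH_MS)
        return float(t[win][np.argmax(v[win])] - self.spike_time)

    def decay_tau(self, neuron_id: str) -> float:
        return ea.psp_decay_tau(
            self.trace.time, self.trace.voltage(neuron_id), spike_time=self.spike_time
        )

    def sweepset(self, ids: list[str] | None = None) -> SweepSet:
        """Postsynaptic traces stacked as one sweep per target neuron."""
        ids = self.targets if ids is None else ids
        return SweepSet(
            time=self.trace.time,
            data=np.vstack([self.trace.voltage(i) for i in ids]),
            spike_time=self.spike_time,
            meta={"neuron_ids": list(ids), "pre": self.pre},
        )


@dataclass
class CouplingMap:
    """Direct cEPSPs (diagonal) and coupling potentials (off-diagonal).

    ``amplitude`` and ``time_to_peak`` are square DataFrames indexed by the
    motor neuron receiving the dedicated chemical input (rows) and the motor
    neuron in which the potential is recorded (columns); ``shared`` holds the
    number of electrical afferents each pair has in common.
    """

    amplitude: pd.DataFrame
    time_to_peak: pd.DataFrame
    shared: pd.DataFrame


def run_rin_protocol(network: NetworkSpec, target: str, dt: float | None = None) -> RinResult:
    """Hyperpolarizing step (-5 pA, 50 ms) into ``target``; Rin and tau.

    Rin is the steady-state deflection (mean of the last 5 ms of the pulse)
    over the injected current; tau is the weighted time constant of a
    double-exponential fit to the relaxation after the pulse.
    """
    network.neuron(target)  # raises KeyError for unknown ids
    proto = StimulusProtocol(
        pulses=(StimulusPulse(target, _BASELINE_MS, RIN_PULSE_MS, RIN_PULSE_PA),),
        duration=_BASELINE_MS + RIN_PULSE_MS + _TAIL_MS,
        **({"dt": dt} if dt is not None else {}),
    )
    trace = simulate(network, proto)
    n_spikes = sum(len(s) for s in trace.spikes.values())
    if n_spikes:
        raise ProtocolViolationError(
            f"hyperpolarizing protocol elicited {n_spikes} spike(s)"
        )
    t = trace.time
    v = trace.voltage(target)
    base = t < _BASELINE_MS
    off = _BASELINE_MS + RIN_PULSE_MS
    steady = (t >= off - 5.0) & (t < off)
    v_rest = v[base].mean()
    dv = v[steady].mean() - v_rest
    rin_mohm = dv / RIN_PULSE_PA * 1e3

    relax = t >= off
    fit = ea.fit_double_exponential(t[relax], v[relax], baseline=v_rest)
    return RinResult(target=target, rin_mohm=float(rin_mohm), tau_ms=fit.weighted_tau,
                     fit=fit, trace=trace)


def _drive_amplitude(network: NetworkSpec, pre: str) -> float:
    role = network.neuron(pre).role
    if role == "chem_interneuron":
        return CHEM_PULSE_PA
    if role == "elec_interneuron":
        return ELEC_PULSE_PA
    raise ProtocolViolationError(f"{pre!r} is not an interneuron (role {role!r})")


def run_psp_protocol(
    network: NetworkSpec,
    pre: str,
    pulse_amplitude: float | None = None,
    pulse_duration: float = SPIKE_PULSE_MS,
    dt: float | None = None,
) -> PSPProtocolResult:
    """Evoke exactly one spike in interneuron ``pre`` and record its targets.

    The drive is the standard 5 ms pulse (10 pA for chemical, 30 pA for
    electrical interneurons, overridable). Zero or multiple presynaptic
    spikes violate the single-PSP contract and raise, reporting the count.
    """
    amp = _drive_amplitude(network, pre) if pulse_amplitude is None else pulse_amplitude
    proto = StimulusProtocol(
        pulses=(StimulusPulse(pre, _BASELINE_MS, pulse_duration, amp),),
        duration=_BASELINE_MS + pulse_duration + PSP_SEARCH_MS + _TAIL_MS,
        **({"dt": dt} if dt is not None else {}),
    )
    trace = simulate(network, proto)
    spikes = trace.spike_times(pre)
    if len(spikes) != 1:
        raise ProtocolViolationError(
            f"single-PSP protocol requires exactly one presynaptic spike in "
            f"{pre!r}, got {len(spikes)}"
        )
    targets = sorted(
        {s.post for s in network.chem_synapses if s.pre == pre}
        | {s.b for s in network.elec_synapses if s.a == pre}
        | {s.a for s in network.elec_synapses if s.b == pre}
    )
    return PSPProtocolResult(
        trace=trace, pre=pre, spike_time=float(spikes[0]), targets=targets
    )


def run_coupling_map(network: NetworkSpec, dt: float | None = None) -> CouplingMap:
    """Spike each dedicated chemical interneuron in turn; map the potentials.

    Requires the dedicated chemical wiring (one chemical interneuron per
    motor neuron) on a convergence network. The direct cEPSP lands on the
    diagonal; the potentials spreading into the other motor neurons through
    shared gap-junction afferents fill the off-diagonal entries, together
    with their times to peak and the shared-afferent counts.
    """
    if network.chem_wiring != "dedicated":
        raise ProtocolViolationError(
            f"coupling map requires dedicated chemical wiring, got {network.chem_wiring!r}"
        )
    mns = [n.id for n in network.neurons if n.role == "motor"]
    amp = pd.DataFrame(0.0, index=mns, columns=mns)
    ttp = pd.DataFrame(0.0, index=mns, columns=mns)
    sh = pd.DataFrame(0, index=mns, columns=mns)
    for mn in mns:
        pre = next(s.pre for s in network.chem_synapses if s.post == mn)
        res = run_psp_protocol(network, pre, dt=dt)
        for other in mns:
            amp.loc[mn, other] = res.amplitude(other)
            ttp.loc[mn, other] = res.time_to_peak(other)
            sh.loc[mn, other] = shared_afferents(network, mn, other)
    return CouplingMap(amplitude=amp, time_to_peak=ttp, shared=sh)


def run_convergence_sweep(
    duplications: list[int] = (0, 1, 5, 10),
    dt: float | None = None,
) -> pd.DataFrame:
    """Full cross of the 10 motor-neuron diameters x duplication levels.

    For every level a shared-wiring network is built; each motor neuron gets
    the hyperpolarizing step protocol (Rin, tau) and the shared chemical
    interneuron is spiked once to measure every cEPSP amplitude and decay.
    Returns a tidy frame with one row per (diameter, duplication).
    """
    rows = []
    for dup in duplications:
        net = build_size_network(dup, chem_wiring="shared")
        psp = run_psp_protocol(net, "chemIN", dt=dt)
        for d in range(1, 11):
            mn = motor_id(d)
            rin = run_rin_protocol(net, mn, dt=dt)
            rows.append(
                {
                    "diameter_um": d,
                    "duplication": dup,
                    "rin_mohm": rin.rin_mohm,
                    "tau_ms": rin.tau_ms,
                    "cepsp_mv": psp.amplitude(mn),
                    "cepsp_decay_ms": psp.decay_tau(mn),
                }
            )
    return pd.DataFrame(rows)


def run_epsp_size_series(
    diameters=range(1, 11),
    pulse_amplitude: float = 300.0,
    pulse_duration: float = 0.5,
    dt: float | None = None,
) -> pd.DataFrame:
    """Electrical PSP amplitude versus target soma size.

    One 7 um electrical interneuron is paired with a single motor neuron of
    each diameter x through a gap junction of 0.01 x^3 nS and driven to a
    single spike; the resulting eEPSP (spikelet) is measured in the motor
    neuron. The cubic conductance weighting outpaces the d^2 growth of
    membrane conductance, so larger somata show larger eEPSPs.

    The drive is a brief, strong pulse (0.5 ms, 300 pA by default) rather
    than the standard 5 ms pulse: in the bare pair a slow approach to
    threshold would pre-depolarize the motor neuron through the gap
    junction and contaminate the 2 ms pre-spike baseline, and any drive
    current outlasting the spike waveform would re-depolarize the
    interneuron and inflate the measured amplitude. A pulse that reaches
    threshold quickly and expires inside the 1 ms spike waveform isolates
    the spikelet itself. Postsynaptic spiking is disabled (see below) so
    the passive spikelet is measured.
    """
    from .model_core import ElecSynapseSpec, NeuronSpec, SpikeParams
    from .network_builder import ELEC_IN_DIAMETER, electrical_conductance

    # the bare two-neuron pair lacks the sibling-synapse shunt of the full
    # network, so the spikelet can exceed the motor neuron's threshold;
    # postsynaptic spiking is disabled to record the passive eEPSP itself
    no_spike = SpikeParams(threshold=1e3, spike_peak=2e3)
    rows = []
    for d in diameters:
        net = NetworkSpec(
            neurons=[
                NeuronSpec("elecIN", "elec_interneuron", ELEC_IN_DIAMETER),
                NeuronSpec(motor_id(d), "motor", float(d), spiking=no_spike),
            ],
            elec_synapses=[
                ElecSynapseSpec("elecIN", motor_id(d), electrical_conductance(d))
            ],
        )
        res = run_psp_protocol(net, "elecIN", pulse_amplitude=pulse_amplitude,
                               pulse_duration=pulse_duration, dt=dt)
        rows.append(
            {
                "diameter_um": d,
                "eepsp_mv": res.amplitude(motor_id(d)),
                "g_ns": electrical_conductance(d),
            }
        )
    return pd.DataFrame(rows)
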