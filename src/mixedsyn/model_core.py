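"""Neuron/synapse data types and the coupled membrane-potential integrator.

Neurons are passive spheres with integrate-and-fire spiking. Somata are
coupled by ohmic, non-rectifying gap junctions (absolute conductances in nS)
and by conductance-based chemical synapses whose specific conductance is
scaled by the postsynaptic surface area. Internally everything runs in a
consistent small-signal unit system:

    voltage mV, time ms, current pA, conductance nS, capacitance pF

(1 pA into 1 pF gives 1 mV/ms; nS x mV = pA; pF / nS = ms), so the per-area
parameters (uF/cm^2, mS/cm^2) are converted exactly once at construction via
the soma surface area in cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import IntegrationError, InvalidGeometryError

__all__ = [
    "MembraneParams",
    "SpikeParams",
    "NeuronSpec",
    "ChemSynapseSpec",
    "ElecSynapseSpec",
    "StimulusPulse",
    "StimulusProtocol",
    "NetworkSpec",
    "SimTrace",
    "PassiveProperties",
    "surface_area",
    "derive_passive",
    "simulate",
]

#: default integration / sampling step, ms
DEFAULT_DT = 0.01


@dataclass(frozen=True)
class MembraneParams:
    """Passive membrane parameters (per unit area).

    c_m : specific capacitance, uF/cm^2
    g_leak : specific leak conductance, mS/cm^2
    E_leak : leak equilibrium potential, mV
    V_rest : resting potential, mV
    """

    c_m: float = 1.0
    g_leak: float = 0.3
    E_leak: float = -60.0
    V_rest: float = -60.0

    def __post_init__(self):
        if self.c_m <= 0 or self.g_leak <= 0:
            raise ValueError("c_m and g_leak must be positive")


@dataclass(frozen=True)
class SpikeParams:
    """Integrate-and-fire spike machinery.

    Repolarisation after a spike is driven by the AHP conductance rather than
    a hard voltage reset; the spike itself is a stylised forced waveform of
    ``spike_duration`` ms (linear rise to ``spike_peak`` and back) during
    which the forced voltage drives gap-junction currents (spikelets).
    """

    threshold: float = -40.0        # mV
    spike_peak: float = 10.0        # mV
    spike_strength: float = 10.0    # dimensionless (display/transmitter scale)
    rel_accommodation: float = 0.3  # dimensionless
    accommodation_tau: float = 10.0  # ms
    ahp_g: float = 0.4              # mS/cm^2
    ahp_tau: float = 3.0            # ms
    ahp_E: float = -70.0            # mV
    refractory: float = 2.0         # ms
    spike_duration: float = 1.0     # ms

    def __post_init__(self):
        if self.threshold >= self.spike_peak:
            raise ValueError("threshold must lie below spike_peak")
        if self.refractory < 0 or self.ahp_g < 0:
            raise ValueError("refractory and conductances must be non-negative")
        if self.spike_duration <= 0 or self.ahp_tau <= 0 or self.accommodation_tau <= 0:
            raise ValueError("durations and time constants must be positive")


@dataclass(frozen=True)
class NeuronSpec:
    """A spherical soma with a role, diameter (um) and its parameter sets."""

    id: str
    role: str  # motor | chem_interneuron | elec_interneuron
    diameter: float
    membrane: MembraneParams = field(default_factory=MembraneParams)
    spiking: SpikeParams = field(default_factory=SpikeParams)

    _ROLES = ("motor", "chem_interneuron", "elec_interneuron")

    def __post_init__(self):
        if self.diameter <= 0:
            raise InvalidGeometryError(
                f"neuron {self.id!r}: diameter must be positive, got {self.diameter}"
            )
        if self.role not in self._ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {self._ROLES}")


@dataclass(frozen=True)
class ChemSynapseSpec:
    """Chemical synapse; specific conductance scaled by postsynaptic area.

    g_norm is in mS/cm^2 and multiplies the postsynaptic sphere surface, so a
    presynaptic spike increments the synaptic conductance by g_norm * A_post
    (in nS after unit conversion), decaying single-exponentially.
    """

    pre: str
    post: str
    g_norm: float = 0.25   # mS/cm^2
    E_rev: float = 0.0     # mV
    decay_tau: float = 1.0  # ms

    def __post_init__(self):
        if self.g_norm < 0:
            raise ValueError("g_norm must be non-negative")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")


@dataclass(frozen=True)
class ElecSynapseSpec:
    """Non-rectifying gap junction with absolute conductance g (nS).

    Current flows down the instantaneous voltage difference; the current into
    ``a`` is exactly minus the current into ``b``.
    """

    a: str
    b: str
    g: float

    def __post_init__(self):
        if self.g < 0:
            raise ValueError("gap-junction conductance must be non-negative")


@dataclass(frozen=True)
class StimulusPulse:
    """A square current pulse into one neuron."""

    target: str
    onset: float      # ms
    duration: float   # ms
    amplitude: float  # pA


@dataclass(frozen=True)
class StimulusProtocol:
    """Pulse list plus run duration and sample step (ms)."""

    pulses: tuple[StimulusPulse, ...]
    duration: float
    dt: float = DEFAULT_DT

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("sample step must be positive")
        object.__setattr__(self, "pulses", tuple(self.pulses))
        for p in self.pulses:
            if p.onset + p.duration > self.duration + 1e-9:
                raise ValueError(
                    f"pulse into {p.target!r} extends past the protocol duration"
                )


@dataclass
class NetworkSpec:
    """Neurons plus chemical and electrical synapse lists.

    ``duplication`` and ``chem_wiring`` are populated by the size-graded
    network builder and default to None for hand-built networks.
    """

    neurons: list[NeuronSpec]
    chem_synapses: list[ChemSynapseSpec] = field(default_factory=list)
    elec_synapses: list[ElecSynapseSpec] = field(default_factory=list)
    duplication: int | None = None
    chem_wiring: str | None = None

    def __post_init__(self):
        ids = [n.id for n in self.neurons]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate neuron ids in network")
        known = set(ids)
        for s in self.chem_synapses:
            if s.pre not in known or s.post not in known:
                raise ValueError(f"chemical synapse references unknown neuron: {s}")
        for s in self.elec_synapses:
            if s.a not in known or s.b not in known:
                raise ValueError(f"electrical synapse references unknown neuron: {s}")

    def neuron(self, neuron_id: str) -> NeuronSpec:
        for n in self.neurons:
            if n.id == neuron_id:
                return n
        raise KeyError(neuron_id)

    def ids(self) -> list[str]:
        return [n.id for n in self.neurons]


@dataclass
class SimTrace:
    """Time-sampled membrane potentials and spike times for one run."""

    time: np.ndarray                 # ms grid, shape (T,)
    ids: list[str]
    v: np.ndarray                    # mV, shape (N, T)
    spikes: dict[str, np.ndarray]    # neuron id -> spike times, ms
    dt: float                        # integration step used, ms

    def voltage(self, neuron_id: str) -> np.ndarray:
        return self.v[self.ids.index(neuron_id)]

    def spike_times(self, neuron_id: str) -> np.ndarray:
        return self.spikes.get(neuron_id, np.empty(0))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_ms": self.time, **{i: self.v[k] for k, i in enumerate(self.ids)}}
        )


@dataclass(frozen=True)
class PassiveProperties:
    """Derived absolute passive properties of an isolated soma."""

    capacitance_pf: float
    conductance_ns: float
    input_resistance_mohm: float
    time_constant_ms: float


def surface_area(diameter: float) -> float:
    """Surface area of a spherical soma, cm^2, from its diameter in um.

    Sphere surface pi*d^2 (== 4*pi*r^2), with d converted to cm.
    """
    if diameter <= 0:
        raise InvalidGeometryError(f"diameter must be positive, got {diameter}")
    d_cm = diameter * 1e-4
    return math.pi * d_cm * d_cm


def derive_passive(spec: NeuronSpec) -> PassiveProperties:
    """Absolute C (pF), G (nS), Rin (MOhm) and tau (ms) of an isolated soma.

    C = c_m * A (uF -> pF via 1e6), G = g_leak * A (mS -> nS via 1e6),
    R = 1/G (1/nS = GOhm -> MOhm via 1e3), tau = C/G = c_m/g_leak in ms
    (independent of size).
    """
    area = surface_area(spec.diameter)
    c_pf = spec.membrane.c_m * area * 1e6
    g_ns = spec.membrane.g_leak * area * 1e6
    return PassiveProperties(
        capacitance_pf=c_pf,
        conductance_ns=g_ns,
        input_resistance_mohm=1e3 / g_ns,
        time_constant_ms=c_pf / g_ns,
    )


def _is_passive(network: NetworkSpec) -> bool:
    return len(network.chem_synapses) == 0


def simulate(
    network: NetworkSpec,
    protocol: StimulusProtocol,
    dt: float | None = None,
) -> SimTrace:
    """Integrate the coupled network under a stimulus protocol.

    Exponential-Euler update per neuron: all conductances (leak, AHP,
    chemical, gap-junction) are frozen over one step and the membrane relaxes
    exactly toward the instantaneous equilibrium

        V_inf = (g_L E_L + g_AHP E_AHP + sum g_chem E_rev
                 + sum_j g_e,ij V_j + I_inj) / g_tot.

    The fixed point of this map is exactly the conductance-matrix steady
    state, so passive steady-state voltages are step-size independent.
    Whenever the network is momentarily purely passive (no AHP or synaptic
    conductance active, no spike waveform in progress) the update instead
    uses the exact matrix-exponential propagator of the linear system,
    precomputed once from the symmetric eigendecomposition of the passive
    conductance matrix — subthreshold step responses and their relaxations
    are therefore exact at any step size, with no first-order eigenvalue
    bias from treating the gap-junction coupling explicitly.
    Spikes: when V crosses the (accommodating) threshold outside the
    refractory period, the soma follows a forced linear rise/fall waveform to
    spike_peak over spike_duration; the AHP conductance increments by
    ahp_g * A and every outgoing chemical synapse by g_norm * A_post.
    """
    dt = float(protocol.dt if dt is None else dt)
    ids = network.ids()
    index = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)

    for p in protocol.pulses:
        if p.target not in index:
            raise KeyError(f"stimulus targets unknown neuron {p.target!r}")

    area = np.array([surface_area(nr.diameter) for nr in network.neurons])
    cap = np.array([nr.membrane.c_m for nr in network.neurons]) * area * 1e6  # pF
    g_leak = np.array([nr.membrane.g_leak for nr in network.neurons]) * area * 1e6  # nS
    e_leak = np.array([nr.membrane.E_leak for nr in network.neurons])
    v_rest = np.array([nr.membrane.V_rest for nr in network.neurons])

    theta0 = np.array([nr.spiking.threshold for nr in network.neurons])
    peak = np.array([nr.spiking.spike_peak for nr in network.neurons])
    rel_acc = np.array([nr.spiking.rel_accommodation for nr in network.neurons])
    acc_decay = np.exp(-dt / np.array([nr.spiking.accommodation_tau for nr in network.neurons]))
    ahp_inc = np.array([nr.spiking.ahp_g for nr in network.neurons]) * area * 1e6  # nS
    ahp_decay = np.exp(-dt / np.array([nr.spiking.ahp_tau for nr in network.neurons]))
    ahp_e = np.array([nr.spiking.ahp_E for nr in network.neurons])
    refractory = np.array([nr.spiking.refractory for nr in network.neurons])
    spike_dur = np.array([nr.spiking.spike_duration for nr in network.neurons])

    # symmetric gap-junction conductance matrix (nS); antisymmetric currents
    # follow structurally from g_ij = g_ji acting on the same voltage difference
    ge = np.zeros((n, n))
    for s in network.elec_synapses:
        i, j = index[s.a], index[s.b]
        if i == j:
            raise ValueError(f"gap junction onto itself: {s.a!r}")
        ge[i, j] += s.g
        ge[j, i] += s.g
    ge_row = ge.sum(axis=1)
    has_elec = bool(network.elec_synapses)

    # chemical synapses: flat per-synapse state with postsynaptic grouping
    n_syn = len(network.chem_synapses)
    syn_pre = np.array([index[s.pre] for s in network.chem_synapses], dtype=np.intp)
    syn_post = np.array([index[s.post] for s in network.chem_synapses], dtype=np.intp)
    syn_g0 = np.array([s.g_norm * area[index[s.post]] * 1e6 for s in network.chem_synapses])
    syn_erev = np.array([s.E_rev for s in network.chem_synapses])
    syn_decay = np.exp(-dt / np.array([s.decay_tau for s in network.chem_synapses])) if n_syn else np.empty(0)
    pre_to_syn: dict[int, np.ndarray] = {}
    if n_syn:
        order = np.argsort(syn_pre, kind="stable")
        for i in np.unique(syn_pre):
            pre_to_syn[int(i)] = order[syn_pre[order] == i]

    # exact propagator of the passive (leak + gap junction) linear system:
    # C dV/dt = -G_pass V + c  with  G_pass = diag(g_leak) + L_gap.
    # Whitening by C^{-1/2} makes it symmetric; eigendecomposition gives
    # V(t+dt) = V_ss + P (V - V_ss) with P = C^{-1/2} U e^{-lam dt} U' C^{1/2}
    g_pass = np.diag(g_leak.astype(float))
    if has_elec:
        g_pass += np.diag(ge_row) - ge
    c_half = np.sqrt(cap)
    lam, u = np.linalg.eigh(g_pass / np.outer(c_half, c_half))
    prop = (u * np.exp(-lam * dt)) @ u.T
    prop = prop * (c_half[None, :] / c_half[:, None])
    g_pass_inv = ((u / lam) @ u.T) / np.outer(c_half, c_half)

    _G_ACTIVE = 1e-12  # nS; below this a conductance is treated as off

    steps = int(round(protocol.duration / dt))
    time = np.arange(steps + 1) * dt

    # per-step injected current, pA — built sparsely from the pulse list
    pulse_spans = []
    for p in protocol.pulses:
        k0 = int(round(p.onset / dt))
        k1 = int(round((p.onset + p.duration) / dt))
        pulse_spans.append((index[p.target], k0, k1, p.amplitude))

    v = v_rest.astype(float).copy()
    theta = theta0.astype(float).copy()
    g_ahp = np.zeros(n)
    g_syn = np.zeros(n_syn)
    last_spike = np.full(n, -np.inf)
    forced_until = np.full(n, -np.inf)
    onset_v = np.zeros(n)

    v_out = np.empty((n, steps + 1))
    v_out[:, 0] = v
    spike_times: dict[str, list[float]] = {nid: [] for nid in ids}

    i_inj = np.zeros(n)
    for k in range(steps):
        t = k * dt
        t_next = t + dt

        i_inj[:] = 0.0
        for tgt, k0, k1, amp in pulse_spans:
            if k0 <= k < k1:
                i_inj[tgt] += amp

        forced = t_next < forced_until
        passive = (
            not forced.any()
            and g_ahp.max(initial=0.0) < _G_ACTIVE
            and (n_syn == 0 or g_syn.max(initial=0.0) < _G_ACTIVE)
        )
        if passive:
            # exact linear-system step
            v_ss = g_pass_inv @ (g_leak * e_leak + i_inj)
            v_new = v_ss + prop @ (v - v_ss)
        else:
            g_tot = g_leak + g_ahp
            num = g_leak * e_leak + g_ahp * ahp_e + i_inj
            if n_syn:
                g_chem = np.bincount(syn_post, weights=g_syn, minlength=n)
                g_tot = g_tot + g_chem
                num = num + np.bincount(syn_post, weights=g_syn * syn_erev, minlength=n)
            if has_elec:
                g_tot = g_tot + ge_row
                num = num + ge @ v
            v_inf = num / g_tot
            v_new = v_inf + (v - v_inf) * np.exp(-dt * g_tot / cap)

        # forced spike waveform overrides the membrane equation
        if forced.any():
            phase = t_next - (forced_until - spike_dur)
            half = spike_dur / 2.0
            rise = phase <= half
            wf = np.where(
                rise,
                onset_v + (peak - onset_v) * phase / half,
                peak + (onset_v - peak) * (phase - half) / half,
            )
            v_new = np.where(forced, wf, v_new)

        if not np.all(np.isfinite(v_new)):
            bad = ids[int(np.argmax(~np.isfinite(v_new)))]
            raise IntegrationError(
                f"non-finite membrane potential in {bad!r} at t={t_next:.3f} ms; "
                f"integration step dt={dt} ms is too large for this network",
                dt=dt,
            )

        # threshold crossing outside refractory and outside a forced waveform
        crossing = (v_new >= theta) & (v < theta) & ~forced & (t_next - last_spike >= refractory)
        if crossing.any():
            for i in np.flatnonzero(crossing):
                spike_times[ids[i]].append(t_next)
            last_spike[crossing] = t_next
            onset_v[crossing] = v[crossing]
            forced_until[crossing] = t_next + spike_dur[crossing]
            g_ahp[crossing] += ahp_inc[crossing]
            if n_syn:
                for i in np.flatnonzero(crossing):
                    sl = pre_to_syn.get(int(i))
                    if sl is not None:
                        g_syn[sl] += syn_g0[sl]

        # conductance decay and threshold accommodation
        g_ahp *= ahp_decay
        if n_syn:
            g_syn *= syn_decay
        # accommodation only raises the threshold above theta0: depolarisation
        # accommodates, hyperpolarisation must not drag the threshold down
        # (a passive rebound would otherwise register as a spike)
        theta_target = theta0 + rel_acc * np.maximum(v - v_rest, 0.0)
        theta = theta_target + (theta - theta_target) * acc_decay

        v = v_new
        v_out[:, k + 1] = v

    return SimTrace(
        time=time,
        ids=ids,
        v=v_out,
        spikes={nid: np.asarray(ts) for nid, ts in spike_times.items()},
        dt=dt,
    )


def passive_steady_state(
    network: NetworkSpec, injections: dict[str, float]
) -> dict[str, float]:
    """Direct conductance-matrix solve for a purely passive network.

    Solves (G_leak + L_gap) V = G_leak E_leak + I for constant injections
    (pA), where L_gap is the gap-junction Laplacian. Used as the linear
    oracle against which the integrator's steady state is checked.
    """
    if network.chem_synapses:
        raise ValueError("steady-state solve is defined for passive networks only")
    ids = network.ids()
    index = {nid: k for k, nid in enumerate(ids)}
    n = len(ids)
    g_l = np.array(
        [nr.membrane.g_leak * surface_area(nr.diameter) * 1e6 for nr in network.neurons]
    )
    e_l = np.array([nr.membrane.E_leak for nr in network.neurons])
    mat = np.diag(g_l.astype(float))
    for s in network.elec_synapses:
        i, j = index[s.a], index[s.b]
        mat[i, i] += s.g
        mat[j, j] += s.g
        mat[i, j] -= s.g
        mat[j, i] -= s.g
    rhs = g_l * e_l
    for nid, amp in injections.items():
        rhs[index[nid]] += amp
    sol = np.linalg.solve(mat, rhs)
    return {nid: float(sol[index[nid]]) for nid in ids}
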