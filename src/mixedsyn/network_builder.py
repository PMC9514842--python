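"""Size-graded convergence networks with diameter-weighted gap junctions.

The canonical circuit has 10 motor neurons with somata of 1..10 um. A pool of
7 um electrical interneurons contacts them with size-graded convergence: in
one "block" of 10 interneurons, interneuron k contacts every motor neuron of
diameter >= k um, so the 10 um cell receives all 10 inputs (100% of the pool)
and the 1 um cell exactly one (10%). The block is duplicated n times
(n = 0..10), giving the 0x/10x/50x/100x convergence conditions with 0, 10,
50 or 100 interneurons. Each gap junction onto a motor neuron of diameter x
carries g = 0.01 x^3 nS, so electrical-synapse density grows steeply with
soma size. Chemical drive comes either from one shared 5 um interneuron
contacting all 10 motor neurons or from one dedicated interneuron per motor
neuron.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import InvalidGeometryError
from .model_core import ChemSynapseSpec, ElecSynapseSpec, NetworkSpec, NeuronSpec

__all__ = [
    "electrical_conductance",
    "build_size_network",
    "network_summary",
    "MOTOR_DIAMETERS",
    "CHEM_IN_DIAMETER",
    "ELEC_IN_DIAMETER",
]

MOTOR_DIAMETERS = tuple(range(1, 11))  # um
CHEM_IN_DIAMETER = 5.0  # um
ELEC_IN_DIAMETER = 7.0  # um

#: duplication level for each convergence label used in the figures
CONVERGENCE_LABELS = {"0x": 0, "10x": 1, "50x": 5, "100x": 10}


def electrical_conductance(diameter: float) -> float:
    """Per-synapse gap-junction conductance (nS) onto a motor neuron.

    y = 0.01 x^3 with x the target soma diameter in um: coupling strength
    grows with the cube of size, outpacing the d^2 growth of membrane
    conductance so larger cells end up proportionally more coupled.
    """
    if diameter <= 0:
        raise InvalidGeometryError(f"diameter must be positive, got {diameter}")
    return 0.01 * diameter**3


def motor_id(diameter: int) -> str:
    return f"MN{diameter:02d}"


def build_size_network(duplication: int, chem_wiring: str = "shared") -> NetworkSpec:
    """Build the 10-motor-neuron convergence network.

    Parameters
    ----------
    duplication : int in [0, 10]
        Number of copies of the nested 10-interneuron block (0x..100x).
    chem_wiring : {"shared", "dedicated"}
        "shared": one chemical interneuron contacts all 10 motor neurons.
        "dedicated": one chemical interneuron per motor neuron.

    The builder is deterministic: identical arguments produce identical,
    stably ordered neuron and synapse lists.
    """
    if not (0 <= duplication <= 10) or int(duplication) != duplication:
        raise ValueError(f"duplication must be an integer in [0, 10], got {duplication}")
    if chem_wiring not in ("shared", "dedicated"):
        raise ValueError(f"chem_wiring must be 'shared' or 'dedicated', got {chem_wiring!r}")
    duplication = int(duplication)

    neurons = [NeuronSpec(motor_id(d), "motor", float(d)) for d in MOTOR_DIAMETERS]
    chem, elec = [], []

    if chem_wiring == "shared":
        neurons.append(NeuronSpec("chemIN", "chem_interneuron", CHEM_IN_DIAMETER))
        chem = [ChemSynapseSpec("chemIN", motor_id(d)) for d in MOTOR_DIAMETERS]
    else:
        for d in MOTOR_DIAMETERS:
            cid = f"chemIN{d:02d}"
            neurons.append(NeuronSpec(cid, "chem_interneuron", CHEM_IN_DIAMETER))
            chem.append(ChemSynapseSpec(cid, motor_id(d)))

    # duplicate blocks of 10 nested interneurons: within a block, interneuron
    # k contacts every motor neuron of diameter >= k um
    for block in range(duplication):
        for k in range(1, 11):
            eid = f"elecIN_b{block:02d}_{k:02d}"
            neurons.append(NeuronSpec(eid, "elec_interneuron", ELEC_IN_DIAMETER))
            for d in range(k, 11):
                elec.append(ElecSynapseSpec(eid, motor_id(d), electrical_conductance(d)))

    return NetworkSpec(
        neurons=neurons,
        chem_synapses=chem,
        elec_synapses=elec,
        duplication=duplication,
        chem_wiring=chem_wiring,
    )


def shared_afferents(network: NetworkSpec, mn_a: str, mn_b: str) -> int:
    """Number of electrical interneurons contacting both motor neurons."""
    partners_a = {s.a for s in network.elec_synapses if s.b == mn_a}
    partners_a |= {s.b for s in network.elec_synapses if s.a == mn_a}
    partners_b = {s.a for s in network.elec_synapses if s.b == mn_b}
    partners_b |= {s.b for s in network.elec_synapses if s.a == mn_b}
    return len(partners_a & partners_b)


def network_summary(network: NetworkSpec) -> pd.DataFrame:
    """Per-neuron synapse counts and summed conductances.

    One row per neuron: role, diameter, number of electrical inputs, summed
    electrical conductance (nS) and number of chemical inputs, followed by
    per-role total rows.
    """
    rows = []
    for nr in network.neurons:
        n_elec = 0
        g_elec = 0.0
        for s in network.elec_synapses:
            if nr.id in (s.a, s.b):
                n_elec += 1
                g_elec += s.g
        n_chem = sum(1 for s in network.chem_synapses if s.post == nr.id)
        rows.append(
            {
                "id": nr.id,
                "role": nr.role,
                "diameter_um": nr.diameter,
                "n_elec_inputs": n_elec,
                "g_elec_total_ns": g_elec,
                "n_chem_inputs": n_chem,
            }
        )
    df = pd.DataFrame(rows)
    totals = (
        df.groupby("role", sort=True)
        .agg(
            n_neurons=("id", "size"),
            n_elec_inputs=("n_elec_inputs", "sum"),
            g_elec_total_ns=("g_elec_total_ns", "sum"),
            n_chem_inputs=("n_chem_inputs", "sum"),
        )
        .reset_index()
    )
    df.attrs["totals"] = totals
    return df
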