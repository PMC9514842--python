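"""Serialisation: network specs to/from YAML or JSON, traces and tables to CSV."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .model_core import (
    ChemSynapseSpec,
    ElecSynapseSpec,
    MembraneParams,
    NetworkSpec,
    NeuronSpec,
    SimTrace,
    SpikeParams,
    StimulusProtocol,
    StimulusPulse,
)

__all__ = [
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
    "protocol_to_dict",
    "protocol_from_dict",
    "trace_to_csv",
    "spikes_to_csv",
]


def network_to_dict(network: NetworkSpec) -> dict:
    return {
        "neurons": [
            {
                "id": n.id,
                "role": n.role,
                "diameter": n.diameter,
                "membrane": asdict(n.membrane),
                "spiking": asdict(n.spiking),
            }
            for n in network.neurons
        ],
        "chem_synapses": [asdict(s) for s in network.chem_synapses],
        "elec_synapses": [asdict(s) for s in network.elec_synapses],
        "duplication": network.duplication,
        "chem_wiring": network.chem_wiring,
    }


def network_from_dict(d: dict) -> NetworkSpec:
    neurons = [
        NeuronSpec(
            id=n["id"],
            role=n["role"],
            diameter=n["diameter"],
            membrane=MembraneParams(**n.get("membrane", {})),
            spiking=SpikeParams(**n.get("spiking", {})),
        )
        for n in d["neurons"]
    ]
    return NetworkSpec(
        neurons=neurons,
        chem_synapses=[ChemSynapseSpec(**s) for s in d.get("chem_synapses", [])],
        elec_synapses=[ElecSynapseSpec(**s) for s in d.get("elec_synapses", [])],
        duplication=d.get("duplication"),
        chem_wiring=d.get("chem_wiring"),
    )


def save_network(network: NetworkSpec, path) -> None:
    path = Path(path)
    d = network_to_dict(network)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_network(path) -> NetworkSpec:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return network_from_dict(d)


def protocol_to_dict(protocol: StimulusProtocol) -> dict:
    return {
        "pulses": [asdict(p) for p in protocol.pulses],
        "duration": protocol.duration,
        "dt": protocol.dt,
    }


def protocol_from_dict(d: dict) -> StimulusProtocol:
    return StimulusProtocol(
        pulses=tuple(StimulusPulse(**p) for p in d.get("pulses", [])),
        duration=d["duration"],
        dt=d.get("dt", 0.01),
    )


def trace_to_csv(trace: SimTrace, path) -> None:
    """Membrane potentials: header ``time_ms`` then one column per neuron id."""
    trace.to_frame().to_csv(path, index=False)


def spikes_to_csv(trace: SimTrace, path) -> None:
    """Spike times as a two-column table (neuron id, time_ms)."""
    rows = [
        {"neuron": nid, "time_ms": t}
        for nid in trace.ids
        for t in trace.spike_times(nid)
    ]
    pd.DataFrame(rows, columns=["neuron", "time_ms"]).to_csv(path, index=False)
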