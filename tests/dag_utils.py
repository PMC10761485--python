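"""Shared toy-DAG builders for engine equivalence tests."""

import random

from mmdt.engine import OperatorRegistry, OperatorSpec
from mmdt.knowledge import EntityDescriptor, EntityNetwork, ValueDomain
from mmdt.values import ClinicalValue

NUM = ValueDomain("numeric", unit="dimensionless")


def entity(eid, etype="observed"):
    return EntityDescriptor(eid, eid.upper(), etype, NUM)


def sum_rule(input_ids, offset=0.0):
    def rule(inputs):
        total = offset
        for eid in input_ids:
            magnitude = inputs[eid].as_number()
            if magnitude is not None:
                total += magnitude
        return ClinicalValue.number(total, "dimensionless")
    return rule


def random_dag(rng: random.Random, n_observed=6, n_operators=20):
    """A random arithmetic operator DAG plus a partial observation map."""
    network = EntityNetwork()
    observed = [f"o{i}" for i in range(n_observed)]
    for eid in observed:
        network.add_entity(entity(eid))
    available = list(observed)
    registry = OperatorRegistry()
    for i in range(n_operators):
        out = f"k{i}"
        network.add_entity(entity(out, "calculated"))
        inputs = tuple(rng.sample(available, k=rng.randint(1, min(3, len(available)))))
        for inp in inputs:
            network.add_edge(inp, out, "derives")
        registry.register(OperatorSpec(f"op_{out}", out, inputs,
                                       sum_rule(list(inputs), offset=float(i))))
        available.append(out)
    observations = {eid: ClinicalValue.number(rng.uniform(-5, 5))
                    for eid in observed if rng.random() > 0.3}
    return network, registry, observations
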