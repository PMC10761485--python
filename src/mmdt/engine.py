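"""Formal-logic layer: recursive operator evaluation with provenance.

Each *operator* is a deterministic rule unit deriving one calculated entity
from precursor entities.  Evaluation is recursive: before an operator runs,
every calculated input is resolved by triggering its own operator first, with
memoization so each operator executes at most once per instantiation.  Absent
observed inputs are passed as UNKNOWN, never raised as errors — the rule set
decides resolvability.  Every execution is recorded in an append-only
:class:`TraceGraph`, the evidence base for the Sankey provenance export.

A value documented directly in the observation map short-circuits derivation
even for calculated entities (a recorded Charlson index is used as-is rather
than re-derived from condition flags); it then counts as an observed factor
in the trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import networkx as nx

from .knowledge import CALCULATED, OBSERVED, EntityNetwork
from .values import ClinicalValue

MANDATORY = "mandatory"
OPTIONAL = "optional"


class UnknownEntityError(KeyError):
    pass


class CycleError(ValueError):
    def __init__(self, cycle: list[str]):
        super().__init__(f"operator dependency cycle: {' -> '.join(cycle)}")
        self.cycle = cycle


class EmptyTraceError(ValueError):
    pass


@dataclass(frozen=True)
class OperatorSpec:
    """One executable rule unit.

    ``rule`` maps input values (keyed by entity id; any may be UNKNOWN) to the
    output value and must be pure.  ``requiredness`` marks inputs whose absence
    makes the output undecidable without running the rule at all.
    """

    id: str
    output_entity: str
    input_entities: tuple[str, ...]
    rule: Callable[[Mapping[str, ClinicalValue]], ClinicalValue]
    requiredness: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.input_entities:
            raise ValueError(f"operator {self.id!r} has no inputs")

    def required(self, entity_id: str) -> str:
        return self.requiredness.get(entity_id, OPTIONAL)


class OperatorRegistry:
    """Operator specs indexed by output entity; dependency graph must be a DAG."""

    def __init__(self, specs: Iterable[OperatorSpec] = ()):  # noqa: D107
        self._specs: list[OperatorSpec] = []
        self._by_output: dict[str, OperatorSpec] = {}
        for spec in specs:
            self.register(spec)

    def register(self, spec: OperatorSpec) -> None:
        if spec.output_entity in self._by_output:
            raise ValueError(f"output entity {spec.output_entity!r} already claimed by "
                             f"{self._by_output[spec.output_entity].id!r}")
        self._by_output[spec.output_entity] = spec
        self._specs.append(spec)

    def specs(self) -> tuple[OperatorSpec, ...]:
        return tuple(self._specs)

    def for_output(self, entity_id: str) -> OperatorSpec | None:
        return self._by_output.get(entity_id)

    def dependency_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for spec in self._specs:
            g.add_node(spec.output_entity)
            for inp in spec.input_entities:
                g.add_edge(inp, spec.output_entity)
        return g

    def check_acyclic(self) -> None:
        g = self.dependency_graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = [u for u, _ in nx.find_cycle(g)]
            raise CycleError(cycle + [cycle[0]])


@dataclass(frozen=True)
class ConsumedInput:
    entity_id: str
    value: ClinicalValue
    origin: str  # "observed" | "calculated"


@dataclass(frozen=True)
class TraceRecord:
    operator_id: str
    consumed: tuple[ConsumedInput, ...]
    missing: tuple[str, ...]
    produced_entity: str
    produced_value: ClinicalValue
    index: int


@dataclass
class TraceGraph:
    """Ordered, immutable evidence of one instantiation."""

    records: list[TraceRecord] = field(default_factory=list)

    def append(self, record: TraceRecord) -> None:
        if self.records and record.index <= self.records[-1].index:
            raise ValueError("trace indices must be strictly increasing")
        self.records.append(record)

    @property
    def observed_used(self) -> set[str]:
        return {c.entity_id for r in self.records for c in r.consumed if c.origin == "observed"}

    @property
    def operators_executed(self) -> set[str]:
        return {r.operator_id for r in self.records}


@dataclass
class EvaluationContext:
    """Observations plus per-instantiation memo and trace."""

    observations: dict[str, ClinicalValue]
    memo: dict[str, ClinicalValue] = field(default_factory=dict)
    trace: TraceGraph = field(default_factory=TraceGraph)
    _stack: list[str] = field(default_factory=list)
    _counter: int = 0

    def next_index(self) -> int:
        self._counter += 1
        return self._counter


def evaluate(target: str, context: EvaluationContext, registry: OperatorRegistry,
             network: EntityNetwork) -> ClinicalValue:
    """Resolve one entity, recursively deriving calculated precursors."""
    if target not in network.entities:
        raise UnknownEntityError(target)
    if target in context.memo:
        return context.memo[target]
    if target in context.observations:
        value = context.observations[target]
        context.memo[target] = value
        return value

    descriptor = network.entities[target]
    if descriptor.entity_type == OBSERVED:
        value = ClinicalValue.unknown()
        context.memo[target] = value
        return value

    spec = registry.for_output(target)
    if spec is None:
        raise UnknownEntityError(f"calculated entity {target!r} has no operator")
    if target in context._stack:
        cycle = context._stack[context._stack.index(target):] + [target]
        raise CycleError(cycle)

    context._stack.append(target)
    try:
        consumed: list[ConsumedInput] = []
        missing: list[str] = []
        inputs: dict[str, ClinicalValue] = {}
        for inp in spec.input_entities:
            value = evaluate(inp, context, registry, network)
            inputs[inp] = value
            if inp in context.observations:
                consumed.append(ConsumedInput(inp, value, "observed"))
            elif network.entities[inp].entity_type == CALCULATED:
                consumed.append(ConsumedInput(inp, value, "calculated"))
            else:
                missing.append(inp)

        mandatory_missing = any(
            spec.required(inp) == MANDATORY and inputs[inp].is_unknown()
            for inp in spec.input_entities
        )
        result = ClinicalValue.unknown() if mandatory_missing else spec.rule(inputs)
    finally:
        context._stack.pop()

    context.trace.append(TraceRecord(
        operator_id=spec.id,
        consumed=tuple(consumed),
        missing=tuple(missing),
        produced_entity=target,
        produced_value=result,
        index=context.next_index(),
    ))
    context.memo[target] = result
    return result


def topological_evaluate(targets: Iterable[str], context: EvaluationContext,
                         registry: OperatorRegistry, network: EntityNetwork) -> dict[str, ClinicalValue]:
    """Brute-force oracle: evaluate all required operators in topological order.

    Deliberately a distinct, non-recursive code path from :func:`evaluate`;
    the two must agree on any acyclic registry.
    """
    targets = list(targets)
    for t in targets:
        if t not in network.entities:
            raise UnknownEntityError(t)
    if not targets:
        return {}
    registry.check_acyclic()

    g = registry.dependency_graph()
    needed: set[str] = set()
    for t in targets:
        needed.add(t)
        if t in g:
            needed |= nx.ancestors(g, t)

    resolved: dict[str, ClinicalValue] = {}
    order = [n for n in nx.topological_sort(g) if n in needed]
    for node in order:
        if node in context.observations:
            resolved[node] = context.observations[node]
            continue
        spec = registry.for_output(node)
        if spec is None:  # observed-type entity with no recorded value
            resolved[node] = ClinicalValue.unknown()
            continue
        inputs = {inp: resolved.get(inp, context.observations.get(inp, ClinicalValue.unknown()))
                  for inp in spec.input_entities}
        mandatory_missing = any(spec.required(i) == MANDATORY and inputs[i].is_unknown()
                                for i in spec.input_entities)
        resolved[node] = ClinicalValue.unknown() if mandatory_missing else spec.rule(inputs)
    for t in targets:
        if t not in resolved:
            resolved[t] = context.observations.get(t, ClinicalValue.unknown())
    return {t: resolved[t] for t in targets}


def trace_summary(trace: TraceGraph) -> tuple[int, int]:
    """(distinct observed factors consumed, distinct operators executed)."""
    return len(trace.observed_used), len(trace.operators_executed)


def export_sankey(trace: TraceGraph) -> dict:
    """Provenance flow as a Sankey-ready JSON document.

    One node per distinct entity/operator; a unit link for every
    consumed-entity→operator and operator→produced-entity flow.
    """
    if not trace.records:
        raise EmptyTraceError("cannot export a Sankey document from an empty trace")
    observed = trace.observed_used
    nodes: dict[str, str] = {}
    links: list[dict] = []
    for record in trace.records:
        nodes[record.operator_id] = "operator"
        for c in record.consumed:
            nodes.setdefault(c.entity_id, "observed" if c.entity_id in observed else "calculated")
            links.append({"source": c.entity_id, "target": record.operator_id, "value": 1})
        nodes[record.produced_entity] = "calculated"
        links.append({"source": record.operator_id, "target": record.produced_entity, "value": 1})
    return {
        "nodes": [{"id": nid, "kind": kind} for nid, kind in sorted(nodes.items())],
        "links": links,
    }
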