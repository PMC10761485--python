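"""Entity-description and entity-network layers of the myeloma knowledge graph.

Clinical parameters are formalized as typed *entities*: "observed" when the
value can be read directly from a patient record (hemoglobin, age, a
cytogenetic marker), "calculated" when it is the output of a rule unit
(anemia, ISS stage, fitness).  Entities are nodes of a directed network whose
edges carry one of four causal relations; the network serializes to TURTLE
(RDF) for expert review and round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import rdflib
from rdflib import RDF, RDFS, Literal, Namespace, URIRef

OBSERVED = "observed"
CALCULATED = "calculated"

RELATIONS = ("derives", "influences", "contains", "treats")

#: Custom namespace for the entity network; relation labels are restricted to
#: the four enumerated predicates so that serialization stays machine-checkable.
MMDT = Namespace("https://mmdt.example.org/kb#")


class RegistrationError(ValueError):
    """Duplicate id or malformed descriptor during network construction."""


class TurtleParseError(ValueError):
    """Malformed or out-of-vocabulary TURTLE content."""


@dataclass(frozen=True)
class CodeBinding:
    """A terminology binding (LOINC / SNOMED-CT / internal) for one entity."""

    system: str
    code: str
    display: str = ""

    def __post_init__(self) -> None:
        if self.system not in ("LOINC", "SNOMED-CT", "internal"):
            raise RegistrationError(f"unknown code system {self.system!r}")
        if not self.code:
            raise RegistrationError("code binding with empty code")


@dataclass(frozen=True)
class ValueDomain:
    """Declared value set of an entity: kind, unit, range or categories."""

    kind: str  # numeric | categorical | boolean | date
    unit: str = ""
    range: tuple[float, float] | None = None
    categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical", "boolean", "date"):
            raise RegistrationError(f"unknown value-domain kind {self.kind!r}")
        if self.kind == "numeric" and not self.unit:
            raise RegistrationError("numeric domain requires a unit or 'dimensionless'")
        if self.kind == "categorical" and len(self.categories) < 2:
            raise RegistrationError("categorical domain requires >= 2 categories")
        if self.range is not None and self.range[0] > self.range[1]:
            raise RegistrationError("value-domain range has min > max")


@dataclass(frozen=True)
class EntityDescriptor:
    id: str
    label: str
    entity_type: str  # observed | calculated
    value_domain: ValueDomain
    code_bindings: tuple[CodeBinding, ...] = ()
    fhir_resource_hint: str = "Observation"

    def __post_init__(self) -> None:
        if not self.id:
            raise RegistrationError("entity with empty id")
        if self.entity_type not in (OBSERVED, CALCULATED):
            raise RegistrationError(f"unknown entity type {self.entity_type!r} for {self.id}")
        seen = set()
        for cb in self.code_bindings:
            key = (cb.system, cb.code)
            if key in seen:
                raise RegistrationError(f"duplicate code binding {key} on {self.id}")
            seen.add(key)


@dataclass
class EntityNetwork:
    """Entities plus their causal edges (source, target, relation)."""

    entities: dict[str, EntityDescriptor] = field(default_factory=dict)
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    def add_entity(self, descriptor: EntityDescriptor) -> "EntityNetwork":
        if descriptor.id in self.entities:
            raise RegistrationError(f"duplicate entity id {descriptor.id!r}")
        self.entities[descriptor.id] = descriptor
        return self

    def add_edge(self, source: str, target: str, relation: str) -> "EntityNetwork":
        if relation not in RELATIONS:
            raise RegistrationError(f"unknown relation {relation!r}")
        for endpoint in (source, target):
            if endpoint not in self.entities:
                raise RegistrationError(f"edge endpoint {endpoint!r} is not a registered entity")
        self.edges.append((source, target, relation))
        return self

    def derives_edges(self) -> list[tuple[str, str]]:
        return [(s, t) for s, t, r in self.edges if r == "derives"]

    def structurally_equal(self, other: "EntityNetwork") -> bool:
        """Equality on ids, types, value domains, bindings and edges.

        Category and binding *order* is not structural content (TURTLE
        multi-valued properties are unordered), so both are compared as sets.
        """
        if set(self.entities) != set(other.entities):
            return False

        def canon(desc: EntityDescriptor) -> EntityDescriptor:
            return replace(
                desc,
                value_domain=replace(desc.value_domain, categories=tuple(sorted(desc.value_domain.categories))),
                code_bindings=tuple(sorted(desc.code_bindings, key=lambda cb: (cb.system, cb.code))),
            )

        for eid, desc in self.entities.items():
            if canon(desc) != canon(other.entities[eid]):
                return False
        return sorted(self.edges) == sorted(other.edges)


def register_entity(descriptor: EntityDescriptor, network: EntityNetwork) -> EntityNetwork:
    """Register one entity; duplicate ids raise naming the colliding id."""
    return network.add_entity(descriptor)


@dataclass(frozen=True)
class Violation:
    kind: str
    message: str


def validate_network(network: EntityNetwork, operators=None) -> list[Violation]:
    """Structural validation report; an empty list means the network is sound.

    With an operator registry supplied, additionally checks that every
    calculated entity is the output of exactly one operator and every entity
    an operator references is registered.
    """
    import networkx as nx

    violations: list[Violation] = []
    for s, t, r in network.edges:
        for endpoint in (s, t):
            if endpoint not in network.entities:
                violations.append(Violation("dangling_edge", f"edge ({s},{t},{r}) references unregistered {endpoint!r}"))

    # derives-subgraph into calculated entities must be acyclic
    g = nx.DiGraph()
    g.add_nodes_from(network.entities)
    g.add_edges_from(network.derives_edges())
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        violations.append(Violation("derives_cycle", f"derives edges contain a cycle: {cycle}"))

    incoming_derives = {t for _, t in network.derives_edges()}
    for eid, desc in network.entities.items():
        if desc.entity_type == CALCULATED and eid not in incoming_derives:
            violations.append(Violation("underived_calculated", f"calculated entity {eid!r} has no incoming derives edge"))

    if operators is not None:
        by_output: dict[str, list[str]] = {}
        for spec in operators.specs():
            by_output.setdefault(spec.output_entity, []).append(spec.id)
            for ent in (spec.output_entity, *spec.input_entities):
                if ent not in network.entities:
                    violations.append(Violation("unregistered_operator_entity", f"operator {spec.id!r} references unregistered entity {ent!r}"))
        for eid, desc in network.entities.items():
            if desc.entity_type != CALCULATED:
                continue
            owners = by_output.get(eid, [])
            if len(owners) == 0:
                violations.append(Violation("missing_derivation", f"calculated entity {eid!r} has no operator"))
            elif len(owners) > 1:
                violations.append(Violation("ambiguous_derivation", f"calculated entity {eid!r} claimed by operators {owners}"))
    return violations


# ---------------------------------------------------------------------------
# TURTLE serialization
# ---------------------------------------------------------------------------

_REL_PREDICATES = {r: MMDT[r] for r in RELATIONS}


def to_turtle(network: EntityNetwork) -> str:
    g = rdflib.Graph()
    g.bind("mmdt", MMDT)
    g.bind("rdfs", RDFS)
    for eid in sorted(network.entities):
        desc = network.entities[eid]
        node = MMDT[eid]
        g.add((node, RDF.type, MMDT.ObservedEntity if desc.entity_type == OBSERVED else MMDT.CalculatedEntity))
        g.add((node, RDFS.label, Literal(desc.label)))
        g.add((node, MMDT.valueKind, Literal(desc.value_domain.kind)))
        if desc.value_domain.unit:
            g.add((node, MMDT.unit, Literal(desc.value_domain.unit)))
        if desc.value_domain.range is not None:
            g.add((node, MMDT.minValue, Literal(float(desc.value_domain.range[0]))))
            g.add((node, MMDT.maxValue, Literal(float(desc.value_domain.range[1]))))
        for cat in desc.value_domain.categories:
            g.add((node, MMDT.categoryValue, Literal(cat)))
        if desc.fhir_resource_hint:
            g.add((node, MMDT.fhirResource, Literal(desc.fhir_resource_hint)))
        for cb in desc.code_bindings:
            bnode = rdflib.BNode()
            g.add((node, MMDT.hasCode, bnode))
            g.add((bnode, MMDT.codeSystem, Literal(cb.system)))
            g.add((bnode, MMDT.codeValue, Literal(cb.code)))
            if cb.display:
                g.add((bnode, MMDT.codeDisplay, Literal(cb.display)))
    for s, t, r in sorted(network.edges):
        g.add((MMDT[s], _REL_PREDICATES[r], MMDT[t]))
    document = g.serialize(format="turtle")
    if "@prefix mmdt:" not in document:  # rdflib drops unused prefixes
        document = f"@prefix mmdt: <{MMDT}> .\n" + document
    return document


_ENTITY_PROPS = {MMDT.valueKind, MMDT.unit, MMDT.minValue, MMDT.maxValue, MMDT.categoryValue, MMDT.fhirResource, MMDT.hasCode}
_CODE_PROPS = {MMDT.codeSystem, MMDT.codeValue, MMDT.codeDisplay}


def _local(uri: URIRef) -> str:
    return str(uri)[len(str(MMDT)):]


def from_turtle(document: str) -> EntityNetwork:
    g = rdflib.Graph()
    try:
        g.parse(data=document, format="turtle")
    except Exception as exc:  # rdflib raises several parser exception types
        raise TurtleParseError(f"malformed TURTLE: {exc}") from exc

    # vocabulary check: every predicate in our namespace must be known
    known = set(_REL_PREDICATES.values()) | _ENTITY_PROPS | _CODE_PROPS
    for _, p, _ in g:
        if str(p).startswith(str(MMDT)) and p not in known:
            raise TurtleParseError(f"unknown relation predicate {p}")

    network = EntityNetwork()
    typed: dict[URIRef, str] = {}
    for s, _, o in g.triples((None, RDF.type, None)):
        if o == MMDT.ObservedEntity:
            typed[s] = OBSERVED
        elif o == MMDT.CalculatedEntity:
            typed[s] = CALCULATED
    for node, etype in sorted(typed.items(), key=lambda kv: str(kv[0])):
        label = str(g.value(node, RDFS.label) or _local(node))
        kind = str(g.value(node, MMDT.valueKind) or "numeric")
        unit = str(g.value(node, MMDT.unit) or "")
        vmin = g.value(node, MMDT.minValue)
        vmax = g.value(node, MMDT.maxValue)
        rng = (float(vmin), float(vmax)) if vmin is not None and vmax is not None else None
        cats = tuple(sorted(str(c) for c in g.objects(node, MMDT.categoryValue)))
        fhir = str(g.value(node, MMDT.fhirResource) or "")
        bindings = []
        for bnode in g.objects(node, MMDT.hasCode):
            bindings.append(CodeBinding(
                system=str(g.value(bnode, MMDT.codeSystem)),
                code=str(g.value(bnode, MMDT.codeValue)),
                display=str(g.value(bnode, MMDT.codeDisplay) or ""),
            ))
        bindings.sort(key=lambda cb: (cb.system, cb.code))
        network.add_entity(EntityDescriptor(
            id=_local(node), label=label, entity_type=etype,
            value_domain=ValueDomain(kind=kind, unit=unit, range=rng, categories=cats),
            code_bindings=tuple(bindings), fhir_resource_hint=fhir,
        ))
    for relation, pred in _REL_PREDICATES.items():
        for s, _, o in g.triples((None, pred, None)):
            network.add_edge(_local(s), _local(o), relation)
    network.edges.sort()
    return network
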