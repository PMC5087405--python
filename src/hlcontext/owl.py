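"""OWL 2 export of the context terminology and instances, and an RDF-level
membership evaluator used as an independent cross-check of the direct
classifier.

The export mirrors the ontology design the package implements: each
high-level context class is an equivalent anonymous class intersecting
existential and universal restrictions on ``hasActivity`` / ``hasLocation`` /
``hasEmotion``.  Because OWL reasoning operates under the open-world
assumption, instance documents carry *closure axioms*: for every present
category a type assertion ``hasX only ({component})`` (a universal restriction
over the nominal class of the component), and for every absent category the
negation of the existential restriction, ``not (hasX some Category)``.

:func:`infer_labels` re-derives class memberships purely from the serialized
graphs — it parses the restrictions and closure axioms back out of the RDF and
evaluates the description-logic fragment they use.  It shares no code with
:mod:`hlcontext.rules`, which makes it a genuinely independent second route
for equivalence testing.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .model import (
    Category,
    HighLevelContext,
    LowLevelContext,
    Vocabulary,
    DEFAULT_VOCABULARY,
    format_timestamp,
)
from .rules import RuleSet

MMC = Namespace("http://hlcontext.example.org/context#")

_CATEGORY_CLASS = {
    Category.ACTIVITY: "Activity",
    Category.LOCATION: "Location",
    Category.EMOTION: "Emotion",
}
_CATEGORY_PROP = {
    Category.ACTIVITY: "hasActivity",
    Category.LOCATION: "hasLocation",
    Category.EMOTION: "hasEmotion",
}


def term_class_name(term: str) -> str:
    """CamelCase OWL class name for a vocabulary term (``lying_down`` → ``LyingDown``)."""
    return "".join(part.capitalize() for part in term.split("_"))


def _union_of(graph: Graph, members: list[URIRef]) -> URIRef | BNode:
    if len(members) == 1:
        return members[0]
    node = BNode()
    graph.add((node, RDF.type, OWL.Class))
    lst = BNode()
    Collection(graph, lst, members)
    graph.add((node, OWL.unionOf, lst))
    return node


def _restriction(graph: Graph, prop: URIRef, kind: URIRef, filler) -> BNode:
    node = BNode()
    graph.add((node, RDF.type, OWL.Restriction))
    graph.add((node, OWL.onProperty, prop))
    graph.add((node, kind, filler))
    return node


def export_terminology(ruleset: RuleSet, vocabulary: Optional[Vocabulary] = None) -> Graph:
    """Emit the terminology (TBox): class hierarchy, properties, and for each
    enabled class definition an equivalent-class expression of restrictions."""
    vocab = vocabulary or ruleset.vocabulary
    g = Graph()
    g.bind("mmc", MMC)
    g.bind("owl", OWL)
    g.add((MMC[""], RDF.type, OWL.Ontology))

    for name in ("Context", "User", "LowLevelContext", "HighLevelContext"):
        g.add((MMC[name], RDF.type, OWL.Class))
    g.add((MMC.LowLevelContext, RDFS.subClassOf, MMC.Context))
    g.add((MMC.HighLevelContext, RDFS.subClassOf, MMC.Context))

    for cat in Category:
        cat_cls = MMC[_CATEGORY_CLASS[cat]]
        g.add((cat_cls, RDF.type, OWL.Class))
        g.add((cat_cls, RDFS.subClassOf, MMC.LowLevelContext))
        for term in sorted(vocab.terms(cat)):
            cls = MMC[term_class_name(term)]
            g.add((cls, RDF.type, OWL.Class))
            g.add((cls, RDFS.subClassOf, cat_cls))

    g.add((MMC.isContextOf, RDF.type, OWL.ObjectProperty))
    g.add((MMC.isContextOf, RDFS.domain, MMC.Context))
    g.add((MMC.isContextOf, RDFS.range, MMC.User))
    for cat in Category:
        prop = MMC[_CATEGORY_PROP[cat]]
        g.add((prop, RDF.type, OWL.ObjectProperty))
        g.add((prop, RDFS.domain, MMC.HighLevelContext))
        g.add((prop, RDFS.range, MMC[_CATEGORY_CLASS[cat]]))
    for prop_name in ("hasStartTime", "hasEndTime"):
        prop = MMC[prop_name]
        g.add((prop, RDF.type, OWL.DatatypeProperty))
        g.add((prop, RDF.type, OWL.FunctionalProperty))
        g.add((prop, RDFS.range, XSD.dateTime))

    for definition in ruleset.definitions:
        cls = MMC[definition.name]
        g.add((cls, RDF.type, OWL.Class))
        g.add((cls, RDFS.subClassOf, MMC.HighLevelContext))
        if not definition.enabled:
            continue
        members: list = []
        for cat in Category:
            rule = definition.rule(cat)
            prop = MMC[_CATEGORY_PROP[cat]]
            term_classes = [MMC[term_class_name(t)] for t in sorted(rule.allowed)]
            if rule.allowed == ruleset.vocabulary.terms(cat):
                filler = MMC[_CATEGORY_CLASS[cat]]
            else:
                filler = _union_of(g, term_classes)
            if rule.required:
                members.append(_restriction(g, prop, OWL.someValuesFrom, filler))
            members.append(_restriction(g, prop, OWL.allValuesFrom, filler))
        expr = BNode()
        g.add((expr, RDF.type, OWL.Class))
        lst = BNode()
        Collection(g, lst, members)
        g.add((expr, OWL.intersectionOf, lst))
        g.add((cls, OWL.equivalentClass, expr))
    return g


def _one_of(graph: Graph, individuals: list[URIRef]) -> BNode:
    node = BNode()
    graph.add((node, RDF.type, OWL.Class))
    lst = BNode()
    Collection(graph, lst, individuals)
    graph.add((node, OWL.oneOf, lst))
    return node


def export_instances(
    records: Iterable[LowLevelContext | HighLevelContext],
    vocabulary: Vocabulary = DEFAULT_VOCABULARY,
) -> Graph:
    """Emit an instance (ABox) document with closure axioms.

    Low-level instances carry their term class, ``isContextOf`` and start/end
    times.  High-level instances additionally carry, per present category, the
    closure ``hasX only ({component})`` and, per absent category, the negated
    existential ``not (hasX some Category)``.
    """
    g = Graph()
    g.bind("mmc", MMC)
    g.bind("owl", OWL)
    ont = MMC["instances"]
    g.add((ont, RDF.type, OWL.Ontology))
    g.add((ont, OWL.imports, MMC[""]))

    def user_node(user: str) -> URIRef:
        node = MMC[f"user_{user}"]
        g.add((node, RDF.type, MMC.User))
        g.add((node, RDF.type, OWL.NamedIndividual))
        return node

    def add_times(node: URIRef, record) -> None:
        g.add((node, MMC.hasStartTime, Literal(format_timestamp(record.start), datatype=XSD.dateTime)))
        if record.end is not None:
            g.add((node, MMC.hasEndTime, Literal(format_timestamp(record.end), datatype=XSD.dateTime)))

    llcs = [r for r in records if isinstance(r, LowLevelContext)]
    hlcs = [r for r in records if isinstance(r, HighLevelContext)]
    seen_llc = {r.id for r in llcs}
    # components referenced by an HLC but not passed explicitly still need assertions
    for hlc in hlcs:
        for comp in hlc.components:
            if comp.id not in seen_llc:
                llcs.append(comp)
                seen_llc.add(comp.id)

    for llc in llcs:
        node = MMC[llc.id]
        g.add((node, RDF.type, OWL.NamedIndividual))
        g.add((node, RDF.type, MMC[term_class_name(llc.type_label)]))
        g.add((node, MMC.isContextOf, user_node(llc.user)))
        add_times(node, llc)

    for hlc in hlcs:
        node = MMC[hlc.id]
        g.add((node, RDF.type, OWL.NamedIndividual))
        g.add((node, RDF.type, MMC.HighLevelContext))
        g.add((node, MMC.isContextOf, user_node(hlc.user)))
        add_times(node, hlc)
        for cat in Category:
            prop = MMC[_CATEGORY_PROP[cat]]
            comp = hlc.component(cat)
            if comp is not None:
                g.add((node, prop, MMC[comp.id]))
                closure = _restriction(g, prop, OWL.allValuesFrom, _one_of(g, [MMC[comp.id]]))
                g.add((node, RDF.type, closure))
            else:
                neg = BNode()
                g.add((neg, RDF.type, OWL.Class))
                g.add(
                    (
                        neg,
                        OWL.complementOf,
                        _restriction(g, prop, OWL.someValuesFrom, MMC[_CATEGORY_CLASS[cat]]),
                    )
                )
                g.add((node, RDF.type, neg))
    return g


# ---------------------------------------------------------------------------
# RDF-level membership evaluation (the independent oracle)
# ---------------------------------------------------------------------------


def _resolve_filler(term_graph: Graph, filler, category_members: Mapping[URIRef, set[URIRef]]) -> set[URIRef]:
    """Resolve a restriction filler to the set of term-class URIs it denotes."""
    if filler in category_members:
        return set(category_members[filler])
    lst = term_graph.value(filler, OWL.unionOf)
    if lst is not None:
        out: set[URIRef] = set()
        for member in Collection(term_graph, lst):
            out |= _resolve_filler(term_graph, member, category_members)
        return out
    return {filler}


def _parse_class_constraints(term_graph: Graph):
    """Parse each equivalent-class expression into per-property constraints.

    Returns ``{class_uri: {prop_uri: {"some": set|None, "all": set|None}}}``.
    """
    category_members: dict[URIRef, set[URIRef]] = {}
    for cat_name in _CATEGORY_CLASS.values():
        cat_cls = MMC[cat_name]
        category_members[cat_cls] = set(term_graph.subjects(RDFS.subClassOf, cat_cls))

    constraints = {}
    for cls in term_graph.subjects(RDFS.subClassOf, MMC.HighLevelContext):
        expr = term_graph.value(cls, OWL.equivalentClass)
        if expr is None:
            continue
        lst = term_graph.value(expr, OWL.intersectionOf)
        members = list(Collection(term_graph, lst)) if lst is not None else [expr]
        per_prop: dict[URIRef, dict[str, Optional[set[URIRef]]]] = {}
        for member in members:
            prop = term_graph.value(member, OWL.onProperty)
            if prop is None:
                continue
            slot = per_prop.setdefault(prop, {"some": None, "all": None})
            some = term_graph.value(member, OWL.someValuesFrom)
            if some is not None:
                slot["some"] = _resolve_filler(term_graph, some, category_members)
            allv = term_graph.value(member, OWL.allValuesFrom)
            if allv is not None:
                slot["all"] = _resolve_filler(term_graph, allv, category_members)
        constraints[cls] = per_prop
    return constraints


def infer_labels(term_graph: Graph, inst_graph: Graph) -> dict[str, set[str]]:
    """Infer class memberships for every high-level context individual.

    Evaluates, for each individual and each class's equivalent expression:
    an existential restriction holds iff an asserted property value has an
    asserted type inside the filler; a universal restriction holds iff the
    property is *closed* for the individual — either by a nominal closure
    axiom whose members' types all fall inside the filler, or by a negated
    existential stating the property has no values.  Unclosed properties
    leave universal restrictions unprovable (open-world behavior).

    Returns a mapping from individual local name (e.g. ``hlc_72``) to the set
    of inferred class local names.
    """
    constraints = _parse_class_constraints(term_graph)

    prefix = str(MMC)

    def local(uri: URIRef) -> str:
        return str(uri)[len(prefix):]

    results: dict[str, set[str]] = {}
    for individual in set(inst_graph.subjects(RDF.type, MMC.HighLevelContext)):
        # asserted values and their asserted term classes
        values: dict[URIRef, list[set[URIRef]]] = {}
        closed: dict[URIRef, Optional[list[URIRef]]] = {}
        for prop_name in _CATEGORY_PROP.values():
            prop = MMC[prop_name]
            vals = list(inst_graph.objects(individual, prop))
            values[prop] = [
                {t for t in inst_graph.objects(v, RDF.type) if isinstance(t, URIRef) and t != OWL.NamedIndividual}
                for v in vals
            ]
        # closure axioms among the individual's anonymous types
        for tnode in inst_graph.objects(individual, RDF.type):
            if not isinstance(tnode, BNode):
                continue
            comp = inst_graph.value(tnode, OWL.complementOf)
            if comp is not None:
                prop = inst_graph.value(comp, OWL.onProperty)
                if prop is not None and inst_graph.value(comp, OWL.someValuesFrom) is not None:
                    closed[prop] = []  # no values at all
                continue
            prop = inst_graph.value(tnode, OWL.onProperty)
            allv = inst_graph.value(tnode, OWL.allValuesFrom)
            if prop is not None and allv is not None:
                lst = inst_graph.value(allv, OWL.oneOf)
                if lst is not None:
                    closed[prop] = list(Collection(inst_graph, lst))

        inferred: set[str] = set()
        for cls, per_prop in constraints.items():
            ok = True
            for prop, slot in per_prop.items():
                some, allv = slot["some"], slot["all"]
                if some is not None:
                    if not any(types & some for types in values[prop]):
                        ok = False
                        break
                if allv is not None:
                    if prop not in closed:
                        ok = False
                        break
                    nominal = closed[prop]
                    member_types = [
                        {
                            t
                            for t in inst_graph.objects(v, RDF.type)
                            if isinstance(t, URIRef) and t != OWL.NamedIndividual
                        }
                        for v in nominal
                    ]
                    if not all(types & allv for types in member_types):
                        ok = False
                        break
            if ok:
                inferred.add(local(cls))
        results[local(individual)] = inferred
    return results
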