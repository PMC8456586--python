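"""Ontology handling: DAG parsing, level assignment, annotation propagation,
and construction of the layer schema / connectivity masks.

The network architecture mirrors a band of ontology levels: each hidden layer
hosts the terms of one level, the level of a term being the length of the
longest path from the root down to it.  A weight is a "GO connection" when it
matches an edge of the ontology between adjacent band levels (or, for the
input layer, an annotation of a probe to a deepest-band term); every other
weight is a "noGO connection" and is the object of the structured penalty.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet

logger = logging.getLogger(__name__)

DEFAULT_RELATIONS = frozenset({"is_a"})
KNOWN_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass(frozen=True)
class OntologyDAG:
    """A rooted DAG of ontology terms.

    Edges are directed child -> parent (the ontology's bottom-up
    orientation), each tagged with its relation type.
    """

    terms: frozenset[str]
    edges: tuple[tuple[str, str, str], ...]  # (child, parent, relation)
    root: str
    names: Mapping[str, str] = field(default_factory=dict)

    def parents_of(self, term: str) -> set[str]:
        return {p for c, p, _ in self.edges if c == term}

    def children_of(self, term: str) -> set[str]:
        return {c for c, p, _ in self.edges if p == term}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, p, _ in self.edges)
        return g


@dataclass
class AnnotationMap:
    """Direct probe->term annotations plus the upward-propagated closure.

    ``propagated[t]`` is the union of the probes directly annotated to *t*
    and to every descendant of *t*: a parent term inherits the probe sets of
    its children.
    """

    direct: dict[str, set[str]]          # probe -> terms
    propagated: dict[str, set[str]]      # term -> probes
    unannotated: set[str] = field(default_factory=set)


@dataclass
class LayerSchema:
    """The selected level band mapped onto network layers.

    ``levels`` is ordered deepest first, so hidden layer 1 hosts the most
    specific terms.  Term order inside a layer is lexicographic and frozen;
    neuron indices in every report refer to this order.
    """

    levels: tuple[int, ...]
    layer_terms: tuple[tuple[str, ...], ...]
    probe_order: tuple[str, ...]
    n_classes: int
    term_names: dict[str, str] = field(default_factory=dict)

    @property
    def n_hidden(self) -> int:
        return len(self.layer_terms)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return tuple(len(t) for t in self.layer_terms)

    @property
    def n_outputs(self) -> int:
        # binary classification uses a single logistic unit
        return 1 if self.n_classes == 2 else self.n_classes

    def to_json(self) -> str:
        return json.dumps(
            {
                "levels": list(self.levels),
                "layer_terms": [list(t) for t in self.layer_terms],
                "probe_order": list(self.probe_order),
                "n_classes": self.n_classes,
                "term_names": dict(self.term_names),
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, payload: str) -> "LayerSchema":
        d = json.loads(payload)
        return cls(
            levels=tuple(d["levels"]),
            layer_terms=tuple(tuple(t) for t in d["layer_terms"]),
            probe_order=tuple(d["probe_order"]),
            n_classes=int(d["n_classes"]),
            term_names=dict(d.get("term_names", {})),
        )


def parse_obo(
    path,
    retained_relations: Iterable[str] = DEFAULT_RELATIONS,
    namespace: str = "biological_process",
) -> OntologyDAG:
    """Parse an OBO file into a rooted child->parent DAG.

    Only terms of ``namespace`` are kept (terms lacking a namespace tag are
    treated as members of the requested namespace, which covers minimal
    hand-written files).  Obsolete terms are dropped.  Unknown relation names
    are ignored with a warning; the root is the unique retained term with no
    outgoing child->parent edge.
    """
    retained = frozenset(retained_relations)
    unknown = retained - KNOWN_RELATIONS
    if unknown:
        raise ValueError(f"unsupported relations requested: {sorted(unknown)}")

    graph = obonet.read_obo(path)

    def in_namespace(node: str) -> bool:
        ns = graph.nodes[node].get("namespace")
        return ns is None or ns == namespace

    terms = {n for n in graph.nodes if in_namespace(n)}
    names = {n: graph.nodes[n].get("name", n) for n in terms}

    edges: list[tuple[str, str, str]] = []
    seen_unknown: set[str] = set()
    for child, parent, rel in graph.edges(keys=True):
        if child not in terms or parent not in terms:
            continue
        if rel not in KNOWN_RELATIONS:
            if rel not in seen_unknown:
                logger.warning("ignoring unknown relation %r", rel)
                seen_unknown.add(rel)
            continue
        if rel in retained:
            edges.append((child, parent, rel))

    g = nx.DiGraph()
    g.add_nodes_from(terms)
    g.add_edges_from((c, p) for c, p, _ in edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology graph is cyclic, e.g. {cycle}")

    roots = sorted(n for n in terms if g.out_degree(n) == 0 and (g.in_degree(n) > 0 or len(terms) == 1))
    if not roots:
        raise ValueError("no root term found (every term has a parent)")
    if len(roots) > 1:
        raise ValueError(f"multiple root candidates: {roots}")

    return OntologyDAG(
        terms=frozenset(terms),
        edges=tuple(sorted(edges)),
        root=roots[0],
        names=names,
    )


def assign_levels(dag: OntologyDAG) -> dict[str, int]:
    """Level of each term = length of the longest root-to-term path.

    The root sits at level 0; every retained edge then satisfies
    level(child) > level(parent).  Terms unreachable from the root are an
    error.
    """
    g = dag.to_networkx()
    # walk parent -> child, i.e. reverse the stored orientation
    rg = g.reverse(copy=False)
    reachable = {dag.root} | nx.descendants(rg, dag.root)
    missing = sorted(set(dag.terms) - reachable)
    if missing:
        raise ValueError(f"terms unreachable from root {dag.root}: {missing}")

    levels = {dag.root: 0}
    for node in nx.topological_sort(rg):
        for child in rg.successors(node):
            cand = levels[node] + 1
            if cand > levels.get(child, -1):
                levels[child] = cand
    return levels


def propagate_annotations(
    dag: OntologyDAG,
    direct_annotations: Mapping[str, Iterable[str]],
    all_probes: Iterable[str] | None = None,
) -> AnnotationMap:
    """Propagate probe annotations upward: each term inherits the probes of
    all its descendants.

    ``direct_annotations`` maps probe -> term(s); annotations to unknown
    terms are logged and skipped.  ``all_probes`` (e.g. the expression
    header) lets probes without any annotation be recorded in
    ``unannotated``.
    """
    direct: dict[str, set[str]] = {}
    term_direct: dict[str, set[str]] = {t: set() for t in dag.terms}
    for probe, terms in direct_annotations.items():
        kept = set()
        for t in terms:
            if t in dag.terms:
                kept.add(t)
                term_direct[t].add(probe)
            else:
                logger.warning("annotation of %s to unknown term %s skipped", probe, t)
        if kept:
            direct[probe] = kept

    g = dag.to_networkx()
    propagated = {t: set(s) for t, s in term_direct.items()}
    # children before parents: child -> parent edges make plain topological
    # order (children first) the correct sweep
    for node in nx.topological_sort(g):
        for parent in g.successors(node):
            propagated[parent] |= propagated[node]

    universe = set(all_probes) if all_probes is not None else set(direct)
    unannotated = {p for p in universe if p not in direct}
    return AnnotationMap(direct=direct, propagated=propagated, unannotated=unannotated)


def build_layer_schema(
    dag: OntologyDAG,
    levels_band: Sequence[int],
    annotation_map: AnnotationMap,
    probe_order: Sequence[str],
    n_classes: int,
) -> tuple[LayerSchema, list[np.ndarray]]:
    """Map a contiguous descending band of levels onto hidden layers and
    build the binary connectivity masks C^(l).

    Hidden layer 1 hosts the deepest selected level.  ``C[0]`` has shape
    (probes, N_1): a probe connects to a first-layer term iff it belongs to
    the term's propagated probe set.  For l >= 2, ``C[l-1]`` has a 1 where
    the layer-l term is a *direct* parent of the layer-(l-1) term; an
    ontology edge that skips a level is not a GO connection.  The output
    layer's all-ones mask is implicit and not stored.
    """
    band = tuple(int(h) for h in levels_band)
    if len(band) == 0 or any(band[i] - 1 != band[i + 1] for i in range(len(band) - 1)):
        raise ValueError(f"levels_band must be contiguous descending, got {band}")

    levels = assign_levels(dag)
    by_level: dict[int, list[str]] = {}
    for t, h in levels.items():
        by_level.setdefault(h, []).append(t)

    layer_terms: list[tuple[str, ...]] = []
    for h in band:
        terms_h = sorted(by_level.get(h, []))
        if not terms_h:
            raise ValueError(f"level {h} of the requested band is empty")
        layer_terms.append(tuple(terms_h))

    probe_order = tuple(probe_order)
    schema = LayerSchema(
        levels=band,
        layer_terms=tuple(layer_terms),
        probe_order=probe_order,
        n_classes=int(n_classes),
        term_names={t: dag.names.get(t, t) for lt in layer_terms for t in lt},
    )

    masks: list[np.ndarray] = []
    first = layer_terms[0]
    c1 = np.zeros((len(probe_order), len(first)))
    probe_idx = {p: j for j, p in enumerate(probe_order)}
    for i, term in enumerate(first):
        for probe in annotation_map.propagated.get(term, ()):
            j = probe_idx.get(probe)
            if j is not None:
                c1[j, i] = 1.0
    masks.append(c1)

    parent_sets = {t: dag.parents_of(t) for t in dag.terms}
    for l in range(1, len(band)):
        below, above = layer_terms[l - 1], layer_terms[l]
        above_idx = {t: i for i, t in enumerate(above)}
        c = np.zeros((len(below), len(above)))
        for j, child in enumerate(below):
            for parent in parent_sets[child]:
                i = above_idx.get(parent)
                if i is not None:
                    c[j, i] = 1.0
        masks.append(c)

    return schema, masks


def to_obo_text(dag: OntologyDAG, namespace: str = "biological_process") -> str:
    """Serialize a DAG back to OBO, one [Term] stanza per term."""
    lines = ["format-version: 1.2", "ontology: exported", ""]
    by_child: dict[str, list[tuple[str, str]]] = {}
    for c, p, rel in dag.edges:
        by_child.setdefault(c, []).append((p, rel))
    for term in sorted(dag.terms):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.names.get(term, term)}")
        lines.append(f"namespace: {namespace}")
        for parent, rel in sorted(by_child.get(term, [])):
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        lines.append("")
    return "\n".join(lines)


def read_annotations(path) -> dict[str, set[str]]:
    """Read probe->term annotations from GAF 2.x (columns 2 and 5) or a
    headerless two-column TSV (probe_id, term_id)."""
    direct: dict[str, set[str]] = {}
    text = Path(path).read_text()
    gaf = text.lstrip().startswith("!")
    for line in text.splitlines():
        if not line.strip() or line.startswith("!"):
            continue
        fields = line.rstrip("\n").split("\t")
        if gaf or len(fields) >= 5:
            probe, term = fields[1], fields[4]
        elif len(fields) >= 2:
            probe, term = fields[0], fields[1]
        else:
            raise ValueError(f"unparseable annotation line: {line!r}")
        direct.setdefault(probe, set()).add(term)
    return direct
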