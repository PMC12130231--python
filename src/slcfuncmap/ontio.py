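"""Chemical-term ontology representation and generic/specific substrate matching.

Metabolites measured by a targeted panel rarely carry the exact term id used in a
pathway database: the panel may report "citrate" while a reaction is annotated with
"citric acid", or a generic class where the annotation is a specific species.  Two
terms are therefore considered to *match* when one is a more generic or a more
specific form of the other in the ontology, walking ``is_a``/``has_role`` edges in a
single generalization direction while freely crossing chemical-equivalence edges
(conjugate acid/base, tautomer, enantiomer) in either direction.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import pandas as pd

from .errors import TermLookupError, ValidationError

logger = logging.getLogger(__name__)

#: Directional generalization relations (specific term -> generic term / role).
DIRECTIONAL_RELATIONS = frozenset({"is_a", "has_role"})

#: Symmetric chemical-equivalence relations, traversable in both directions.
EQUIVALENCE_RELATIONS = frozenset(
    {
        "is_conjugate_base_of",
        "is_conjugate_acid_of",
        "is_tautomer_of",
        "is_enantiomer_of",
    }
)

KNOWN_RELATIONS = DIRECTIONAL_RELATIONS | EQUIVALENCE_RELATIONS


@dataclass(frozen=True)
class MatchPolicy:
    """Controls path semantics of :func:`terms_match`.

    Parameters
    ----------
    max_depth:
        Maximum number of edges in a match path; ``None`` means unbounded.
    allow_mixed_directions:
        When ``True``, generalization edges may be traversed in both directions
        along one path (which lets sibling terms match through their common
        parent).  The default forbids mixing: a match path is generic-ward XOR
        specific-ward, so "more generic or more specific" is taken literally.
    """

    max_depth: int | None = None
    allow_mixed_directions: bool = False


@dataclass
class OntologyGraph:
    """Typed directed graph of chemical terms.

    ``edges`` holds triples ``(source, relation, target)``.  Directional edges
    point from the more specific term to the more generic term (or from a
    chemical to its role); equivalence edges are stored once and traversed
    symmetrically.
    """

    terms: set[str]
    edges: set[tuple[str, str, str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()
        self._build_adjacency()

    def validate(self) -> None:
        for src, rel, tgt in self.edges:
            if src not in self.terms or tgt not in self.terms:
                raise ValidationError(
                    f"edge ({src}, {rel}, {tgt}) has an unregistered endpoint"
                )
            if rel not in KNOWN_RELATIONS:
                raise ValidationError(f"unknown relation type {rel!r}")
        cycle = _find_is_a_cycle(self.edges)
        if cycle is not None:
            raise ValidationError(f"cycle among is_a edges: {' -> '.join(cycle)}")

    def _build_adjacency(self) -> None:
        # _up: traversal toward more generic terms; _down: toward more specific.
        # Equivalence edges appear in both, in both directions.
        up: dict[str, list[tuple[str, str, str, str]]] = {t: [] for t in self.terms}
        down: dict[str, list[tuple[str, str, str, str]]] = {t: [] for t in self.terms}
        for src, rel, tgt in sorted(self.edges):
            if rel in DIRECTIONAL_RELATIONS:
                up[src].append((tgt, src, rel, tgt))
                down[tgt].append((src, src, rel, tgt))
            else:
                up[src].append((tgt, src, rel, tgt))
                up[tgt].append((src, src, rel, tgt))
                down[src].append((tgt, src, rel, tgt))
                down[tgt].append((src, src, rel, tgt))
        self._up = up
        self._down = down
        self._equiv = {
            t: [e for e in up[t] if e[2] in EQUIVALENCE_RELATIONS] for t in self.terms
        }
        self._mixed = {t: up[t] + down[t] for t in self.terms}

    def label(self, term: str) -> str:
        return self.labels.get(term, term)

    def require(self, term: str) -> None:
        if term not in self.terms:
            raise TermLookupError(f"unknown term id: {term!r}")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of a generic/specific match between two terms."""

    query: str
    target: str
    matched: bool
    direction: str | None  # identity | query_more_specific | query_more_generic |
    # equivalence_only | mixed (only under allow_mixed_directions)
    path: tuple[tuple[str, str, str], ...] = ()


def _find_is_a_cycle(edges) -> list[str] | None:
    """Return one cycle among is_a edges (as a node list) or None."""
    adj: dict[str, list[str]] = {}
    for src, rel, tgt in edges:
        if rel == "is_a":
            adj.setdefault(src, []).append(tgt)
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}
    stack_path: list[str] = []

    def dfs(node: str) -> list[str] | None:
        color[node] = GRAY
        stack_path.append(node)
        for nxt in adj.get(node, ()):
            c = color.get(nxt, WHITE)
            if c == GRAY:
                i = stack_path.index(nxt)
                return stack_path[i:] + [nxt]
            if c == WHITE:
                found = dfs(nxt)
                if found:
                    return found
        color[node] = BLACK
        stack_path.pop()
        return None

    for start in sorted(adj):
        if color.get(start, WHITE) == WHITE:
            found = dfs(start)
            if found:
                return found
    return None


def load_ontology(source, dialect: str = "obo_subset") -> OntologyGraph:
    """Read an ontology from ``source`` in the given dialect.

    ``obo_subset`` consumes only ``id``, ``name``, ``is_a`` and ``relationship:``
    lines of OBO 1.2 term stanzas; ``tsv_edges`` expects a headered TSV with
    columns ``source``, ``relation``, ``target``.  Edges with relation types
    outside the supported set are dropped with a logged count.
    """
    if dialect == "obo_subset":
        terms, labels, raw_edges = _read_obo_subset(source)
    elif dialect == "tsv_edges":
        df = pd.read_csv(source, sep="\t", dtype=str)
        expected = {"source", "relation", "target"}
        if not expected.issubset(df.columns):
            raise ValidationError(f"TSV edge list must have columns {sorted(expected)}")
        raw_edges = [tuple(r) for r in df[["source", "relation", "target"]].itertuples(index=False)]
        terms = {e[0] for e in raw_edges} | {e[2] for e in raw_edges}
        labels = {}
    else:
        raise ValidationError(f"unknown ontology dialect {dialect!r}")

    edges: set[tuple[str, str, str]] = set()
    n_ignored = 0
    for src, rel, tgt in raw_edges:
        if rel in KNOWN_RELATIONS:
            edges.add((src, rel, tgt))
        else:
            n_ignored += 1
    if n_ignored:
        logger.warning("ignored %d edges with unsupported relation types", n_ignored)
    return OntologyGraph(terms=terms, edges=edges, labels=labels)


def _read_obo_subset(source):
    """Parse an OBO file via obonet and reduce it to the supported subset."""
    import obonet

    graph = obonet.read_obo(source, ignore_obsolete=True)
    terms = set(graph.nodes)
    labels = {n: d["name"] for n, d in graph.nodes(data=True) if "name" in d}
    raw_edges = []
    for src, tgt, rel in graph.edges(keys=True):
        if src not in terms or tgt not in terms:
            raise ValidationError(f"edge ({src}, {rel}, {tgt}) references an undefined term")
        raw_edges.append((src, rel, tgt))
    return terms, labels, raw_edges


def _bfs(adj, query: str, target: str, max_depth: int | None):
    """Breadth-first search returning the edge path query->target, or None."""
    if query == target:
        return ()
    parent: dict[str, tuple[str, tuple[str, str, str]]] = {query: None}
    frontier = deque([(query, 0)])
    while frontier:
        node, depth = frontier.popleft()
        if max_depth is not None and depth >= max_depth:
            continue
        for nxt, esrc, rel, etgt in adj[node]:
            if nxt in parent:
                continue
            parent[nxt] = (node, (esrc, rel, etgt))
            if nxt == target:
                path = []
                cur = nxt
                while parent[cur] is not None:
                    prev, edge = parent[cur]
                    path.append(edge)
                    cur = prev
                return tuple(reversed(path))
            frontier.append((nxt, depth + 1))
    return None


def terms_match(
    g: OntologyGraph, query: str, target: str, policy: MatchPolicy = MatchPolicy()
) -> MatchResult:
    """Decide whether ``query`` matches ``target`` as a more generic or more
    specific term (or a chemical equivalent), and report the direction."""
    g.require(query)
    g.require(target)
    if query == target:
        return MatchResult(query, target, True, "identity")

    # Equivalence-only connection takes classification precedence: neither term
    # is more generic than the other, they denote the same chemical species.
    path = _bfs(g._equiv, query, target, policy.max_depth)
    if path is not None:
        return MatchResult(query, target, True, "equivalence_only", path)

    path = _bfs(g._up, query, target, policy.max_depth)
    if path is not None:
        return MatchResult(query, target, True, "query_more_specific", path)

    path = _bfs(g._down, query, target, policy.max_depth)
    if path is not None:
        return MatchResult(query, target, True, "query_more_generic", path)

    if policy.allow_mixed_directions:
        path = _bfs(g._mixed, query, target, policy.max_depth)
        if path is not None:
            return MatchResult(query, target, True, "mixed", path)

    return MatchResult(query, target, False, None)


def match_panel(
    g: OntologyGraph,
    panel: set[str],
    compounds: set[str],
    policy: MatchPolicy = MatchPolicy(),
) -> dict[str, set[str]]:
    """All-pairs matching of panel metabolites against annotated compounds."""
    result: dict[str, set[str]] = {}
    for m in sorted(panel):
        matched = {
            c for c in sorted(compounds) if terms_match(g, m, c, policy).matched
        }
        result[m] = matched
    return result
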