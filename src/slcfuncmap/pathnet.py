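"""Pathway hierarchy and reaction mapping.

The pathway universe is a rooted DAG (emulating the "Metabolism" subtree of a
Reactome-style database) whose leaves and internal nodes both carry reactions.
Metabolites are mapped to reactions through ontology matching of educt/product
terms; genes through a user-supplied gene→protein mapping table.  A feature
mapped to a reaction belongs to the reaction's pathways and all their ancestors
up to the root, so per-pathway counts roll up the hierarchy.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import TermLookupError, ValidationError
from .ontio import MatchPolicy, OntologyGraph, terms_match

logger = logging.getLogger(__name__)


@dataclass
class Reaction:
    educts: frozenset[str]
    products: frozenset[str]
    proteins: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()


@dataclass
class PathwayNetwork:
    """Rooted pathway DAG plus reactions with educt/product term sets."""

    root: str
    pathways: set[str]
    parent_edges: dict[str, set[str]]  # child -> parents
    reactions: dict[str, Reaction]

    def __post_init__(self) -> None:
        self.validate()
        children: dict[str, set[str]] = {p: set() for p in self.pathways}
        for child, parents in self.parent_edges.items():
            for p in parents:
                children[p].add(child)
        self._children = children

    def validate(self) -> None:
        if self.root not in self.pathways:
            raise ValidationError(f"root {self.root!r} is not a registered pathway")
        for child, parents in self.parent_edges.items():
            for p in {child} | parents:
                if p not in self.pathways:
                    raise ValidationError(f"parent edge references unknown pathway {p!r}")
        for p in self.pathways:
            if p != self.root and self.root not in self._walk_up(p):
                raise ValidationError(f"pathway {p!r} is not a descendant of the root")
        for rid, rxn in self.reactions.items():
            if not rxn.educts or not rxn.products:
                raise ValidationError(f"reaction {rid!r} has empty educts or products")
            for p in rxn.pathways:
                if p not in self.pathways:
                    raise ValidationError(f"reaction {rid!r} assigned to unknown pathway {p!r}")
            if not rxn.pathways:
                raise ValidationError(f"reaction {rid!r} belongs to no pathway")

    def _walk_up(self, pathway: str) -> set[str]:
        seen: set[str] = set()
        stack = [pathway]
        while stack:
            cur = stack.pop()
            for parent in self.parent_edges.get(cur, ()):
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen

    def ancestors(self, pathway: str, include_self: bool = True) -> set[str]:
        if pathway not in self.pathways:
            raise TermLookupError(f"unknown pathway {pathway!r}")
        up = self._walk_up(pathway)
        return up | {pathway} if include_self else up

    def descendants(self, pathway: str, include_self: bool = True) -> set[str]:
        if pathway not in self.pathways:
            raise TermLookupError(f"unknown pathway {pathway!r}")
        seen: set[str] = set()
        stack = [pathway]
        while stack:
            cur = stack.pop()
            for child in self._children.get(cur, ()):
                if child not in seen:
                    seen.add(child)
                    stack.append(child)
        return seen | {pathway} if include_self else seen

    def reactions_of(self, pathway: str) -> set[str]:
        """Reactions assigned to the pathway or any of its descendants."""
        scope = self.descendants(pathway)
        return {rid for rid, r in self.reactions.items() if r.pathways & scope}

    def children_of_root(self) -> list[str]:
        return sorted(self._children[self.root])


def load_pathway_network(path) -> PathwayNetwork:
    """Read the JSON interchange format.

    Schema: ``{"root": id, "pathways": [{"id", "parents": [...]}],
    "reactions": [{"id", "educts", "products", "proteins", "pathways"}]}``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    pathways = {p["id"] for p in doc["pathways"]}
    parent_edges = {p["id"]: set(p.get("parents", [])) for p in doc["pathways"]}
    reactions = {
        r["id"]: Reaction(
            educts=frozenset(r["educts"]),
            products=frozenset(r["products"]),
            proteins=frozenset(r.get("proteins", [])),
            pathways=frozenset(r.get("pathways", [])),
        )
        for r in doc["reactions"]
    }
    return PathwayNetwork(
        root=doc["root"], pathways=pathways, parent_edges=parent_edges, reactions=reactions
    )


def save_pathway_network(net: PathwayNetwork, path) -> None:
    doc = {
        "root": net.root,
        "pathways": [
            {"id": p, "parents": sorted(net.parent_edges.get(p, ()))}
            for p in sorted(net.pathways)
        ],
        "reactions": [
            {
                "id": rid,
                "educts": sorted(r.educts),
                "products": sorted(r.products),
                "proteins": sorted(r.proteins),
                "pathways": sorted(r.pathways),
            }
            for rid, r in sorted(net.reactions.items())
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_gene_map(path) -> dict[str, set[str]]:
    """Two-column TSV ``gene_id<TAB>protein_id``; one-to-many allowed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_col, prot_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for gene, prot in zip(df[gene_col], df[prot_col]):
        out.setdefault(gene, set()).add(prot)
    return out


def reactions_for_metabolite(
    net: PathwayNetwork,
    g: OntologyGraph,
    metabolite: str,
    policy: MatchPolicy = MatchPolicy(),
) -> set[str]:
    """Reactions whose educts or products the metabolite matches in the ontology."""
    g.require(metabolite)
    hits: set[str] = set()
    for rid, rxn in net.reactions.items():
        for term in rxn.educts | rxn.products:
            if term in g.terms and terms_match(g, metabolite, term, policy).matched:
                hits.add(rid)
                break
    return hits


def pathways_for_feature(
    net: PathwayNetwork,
    feature: str,
    kind: str,
    g: OntologyGraph | None = None,
    gene_map: dict[str, set[str]] | None = None,
    policy: MatchPolicy = MatchPolicy(),
) -> set[str]:
    """All pathways (ancestor-closed) of reactions the feature maps to."""
    if kind == "metabolite":
        if g is None:
            raise ValidationError("an ontology is required to map metabolites")
        rids = reactions_for_metabolite(net, g, feature, policy)
    elif kind == "gene":
        if gene_map is None:
            raise ValidationError("a gene map is required to map genes")
        proteins = gene_map.get(feature)
        if not proteins:
            logger.debug("gene %s absent from gene map; maps to no pathway", feature)
            return set()
        rids = {rid for rid, r in net.reactions.items() if r.proteins & proteins}
    else:
        raise ValidationError(f"unknown feature kind {kind!r}")

    out: set[str] = set()
    for rid in rids:
        for p in net.reactions[rid].pathways:
            out |= net.ancestors(p)
    return out


def build_feature_pathway_map(
    net: PathwayNetwork,
    features,
    kind: str,
    g: OntologyGraph | None = None,
    gene_map: dict[str, set[str]] | None = None,
    policy: MatchPolicy = MatchPolicy(),
) -> dict[str, set[str]]:
    """Map every feature to its (ancestor-closed) pathway set."""
    return {
        f: pathways_for_feature(net, f, kind, g=g, gene_map=gene_map, policy=policy)
        for f in sorted(features)
    }


def mean_pathway_lfc(
    diff: pd.DataFrame, fmap: dict[str, set[str]], pathway: str
) -> float:
    """Mean log2 fold change of all genes mapped to the pathway.

    No significance filter is applied.  Duplicate feature rows are deduplicated
    (first occurrence) before averaging.  With no mapped gene the result is NaN,
    marking the pathway as undefined rather than unchanged.
    """
    dedup = diff.drop_duplicates(subset="feature")
    mask = dedup["feature"].map(lambda f: pathway in fmap.get(f, ()))
    values = dedup.loc[mask, "lfc"]
    if values.empty:
        return math.nan
    return float(values.mean())


def top_level_pathways(
    net: PathwayNetwork, fmap: dict[str, set[str]], k: int = 9
) -> list[str]:
    """The k direct children of the root with the most mapped features.

    Ties break toward the lexicographically smaller pathway id.
    """
    children = net.children_of_root()
    counts = {
        c: sum(1 for pathways in fmap.values() if c in pathways) for c in children
    }
    ranked = sorted(children, key=lambda c: (-counts[c], c))
    if len(ranked) < k:
        logger.warning("root has only %d children; requested top %d", len(ranked), k)
        return ranked
    return ranked[:k]
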