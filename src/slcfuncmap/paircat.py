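"""Categorize significant SLC–metabolite pairs.

Every (transporter, metabolite) pair with a significant abundance change is
placed into exactly one of four categories, in precedence order:

* ``annotated_substrate`` — the metabolite matches a literature-annotated
  substrate of the transporter in the ontology;
* ``metabolic_conversion`` — some reaction connects an annotated substrate and
  the metabolite as educt/product (in either role);
* ``novel_non_orphan`` — neither holds but the transporter has annotated
  substrates;
* ``novel_orphan`` — the transporter has no annotated substrate at all.

Ubiquitous species (hydron, hydroxide, water) are ignored as substrates when
searching for conversions, and a term appearing on both sides of a reaction
cannot anchor a conversion match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .errors import ValidationError
from .ontio import MatchPolicy, OntologyGraph, terms_match
from .pathnet import PathwayNetwork

logger = logging.getLogger(__name__)

CATEGORIES = (
    "annotated_substrate",
    "metabolic_conversion",
    "novel_non_orphan",
    "novel_orphan",
)

#: Substrate annotations too generic to anchor a conversion (by label or id).
DEFAULT_EXCLUDED_SUBSTRATES = frozenset({"hydron", "hydroxide", "water"})

PROPERTY_CLASSES = ("family", "fold", "localization", "substrate_class", "ion_coupling")


@dataclass
class SlcAnnotationTable:
    """Functional annotations per transporter.

    ``substrates`` maps each SLC to its annotated substrate term ids (empty set
    for orphans).  ``properties`` is a long-format frame with columns
    ``slc, prop_class, prop`` holding categorical functional properties
    (family, fold, localization, substrate class, ion coupling).
    """

    substrates: dict[str, frozenset[str]]
    properties: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["slc", "prop_class", "prop"])
    )

    def is_orphan(self, slc: str) -> bool:
        return not self.substrates.get(slc)


def load_annotations(path) -> SlcAnnotationTable:
    """Read an annotation CSV.

    Expected columns: ``slc, family, fold, localization, substrate_class,
    ion_coupling, substrates``; multi-valued fields are semicolon-separated,
    empty substrates mark an orphan.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    if "slc" not in df.columns:
        raise ValidationError("annotation table needs an 'slc' column")
    substrates: dict[str, frozenset[str]] = {}
    prop_rows = []
    for row in df.itertuples():
        substrates[row.slc] = frozenset(
            s for s in str(getattr(row, "substrates", "")).split(";") if s
        )
        for cls in PROPERTY_CLASSES:
            for val in str(getattr(row, cls, "")).split(";"):
                if val:
                    prop_rows.append({"slc": row.slc, "prop_class": cls, "prop": val})
    return SlcAnnotationTable(
        substrates, pd.DataFrame(prop_rows, columns=["slc", "prop_class", "prop"])
    )


def _is_excluded(g: OntologyGraph, term: str, excluded: frozenset[str]) -> bool:
    return term in excluded or g.label(term).lower() in excluded


def conversion_witnesses(
    net: PathwayNetwork,
    g: OntologyGraph,
    substrates: set[str],
    metabolite: str,
    policy: MatchPolicy = MatchPolicy(),
    excluded: frozenset[str] = DEFAULT_EXCLUDED_SUBSTRATES,
    bidirectional: bool = True,
) -> list[tuple[str, str]]:
    """Reactions linking a substrate and the metabolite, with the direction.

    Direction ``substrate_to_metabolite`` means a substrate matched an educt
    and the metabolite a product; ``metabolite_to_substrate`` the converse
    (only searched when ``bidirectional``).  Terms occurring as both educt and
    product of a reaction are disqualified as anchors on either side.
    """
    g.require(metabolite)
    usable = {
        s for s in substrates if s in g.terms and not _is_excluded(g, s, excluded)
    }
    hits: list[tuple[str, str]] = []
    for rid in sorted(net.reactions):
        rxn = net.reactions[rid]
        educt_anchors = {t for t in rxn.educts - rxn.products if t in g.terms}
        product_anchors = {t for t in rxn.products - rxn.educts if t in g.terms}

        def matches(query: str, anchors: set[str]) -> bool:
            return any(terms_match(g, query, t, policy).matched for t in anchors)

        sub_hits_educt = any(matches(s, educt_anchors) for s in usable)
        met_hits_product = matches(metabolite, product_anchors)
        if sub_hits_educt and met_hits_product:
            hits.append((rid, "substrate_to_metabolite"))
            continue
        if bidirectional:
            met_hits_educt = matches(metabolite, educt_anchors)
            sub_hits_product = any(matches(s, product_anchors) for s in usable)
            if met_hits_educt and sub_hits_product:
                hits.append((rid, "metabolite_to_substrate"))
    return hits


def find_conversions(
    net: PathwayNetwork,
    g: OntologyGraph,
    substrates: set[str],
    metabolite: str,
    policy: MatchPolicy = MatchPolicy(),
    excluded: frozenset[str] = DEFAULT_EXCLUDED_SUBSTRATES,
    bidirectional: bool = True,
) -> set[str]:
    """Reaction ids with a substrate-matched educt and a metabolite-matched
    product (or the converse when ``bidirectional``)."""
    return {
        rid
        for rid, _ in conversion_witnesses(
            net, g, substrates, metabolite, policy, excluded, bidirectional
        )
    }


def categorize_pairs(
    diff_tables: dict[str, pd.DataFrame],
    ann: SlcAnnotationTable,
    g: OntologyGraph,
    net: PathwayNetwork,
    policy: MatchPolicy = MatchPolicy(),
    analysis_slc: dict[str, str] | None = None,
    excluded: frozenset[str] = DEFAULT_EXCLUDED_SUBSTRATES,
    bidirectional: bool = True,
) -> pd.DataFrame:
    """Assign a category to every significant SLC–metabolite pair.

    ``diff_tables`` maps analysis id to a DiffTable; each analysis corresponds
    to exactly one SLC (``analysis_slc`` maps ids when they differ).  Returns a
    frame with columns ``slc, metabolite, lfc, padj, category,
    witness_substrate, witness_reaction, direction``.
    """
    records = []
    for analysis_id in sorted(diff_tables):
        table = diff_tables[analysis_id]
        slc = (analysis_slc or {}).get(analysis_id, analysis_id)
        if slc not in ann.substrates:
            logger.warning("SLC %s absent from annotation table; pairs marked orphan", slc)
        substrates = set(ann.substrates.get(slc, frozenset()))
        for row in table.itertuples():
            if not bool(row.significant):
                continue
            met = row.feature
            category = None
            witness_sub = ""
            witness_rxn = ""
            direction = ""
            if met in g.terms:
                for s in sorted(substrates):
                    if s in g.terms and terms_match(g, met, s, policy).matched:
                        category = "annotated_substrate"
                        witness_sub = s
                        break
                if category is None:
                    conv = conversion_witnesses(
                        net, g, substrates, met, policy, excluded, bidirectional
                    )
                    if conv:
                        category = "metabolic_conversion"
                        witness_rxn, direction = conv[0]
            if category is None:
                category = "novel_non_orphan" if substrates else "novel_orphan"
            records.append(
                {
                    "slc": slc,
                    "metabolite": met,
                    "lfc": row.lfc,
                    "padj": row.padj,
                    "category": category,
                    "witness_substrate": witness_sub,
                    "witness_reaction": witness_rxn,
                    "direction": direction,
                }
            )
    return pd.DataFrame(
        records,
        columns=[
            "slc", "metabolite", "lfc", "padj", "category",
            "witness_substrate", "witness_reaction", "direction",
        ],
    )


def category_counts(pairs: pd.DataFrame) -> pd.Series:
    """Number of pairs in each of the four categories (zero-filled)."""
    return pairs["category"].value_counts().reindex(CATEGORIES, fill_value=0)


def category_lfc_test(pairs: pd.DataFrame) -> tuple[float, float]:
    """Kruskal–Wallis test of |log2 fold change| across pair categories."""
    groups = [
        pairs.loc[pairs["category"] == c, "lfc"].abs().to_numpy()
        for c in CATEGORIES
        if (pairs["category"] == c).any()
    ]
    if len(groups) < 2:
        raise ValidationError("need at least two non-empty categories")
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)
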