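"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of the real study inputs — a chemical
ontology with generalization and equivalence relations, a rooted pathway DAG
with educt/product reactions, long-format MRM peak tables with internal
standards, per-run calibration dilution series and multiplicative run effects,
and cohorts of fold-change profiles with planted cluster structure and
cluster-correlated functional properties.  Each generator is a pure function
of its seed and parameters and ships the ground truth an acceptance test
needs (match closures, true internal standards, planted effects, labels).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .ontio import DIRECTIONAL_RELATIONS, EQUIVALENCE_RELATIONS, OntologyGraph
from .paircat import SlcAnnotationTable
from .pathnet import PathwayNetwork, Reaction

_EQ_RELATIONS = tuple(sorted(EQUIVALENCE_RELATIONS))


@dataclass
class SynthTruth:
    """Ground truth accompanying a generated data set."""

    seed: int
    true_is_map: dict[str, str] = field(default_factory=dict)
    planted_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    true_labels: dict[str, int] = field(default_factory=dict)
    true_pair_categories: dict[tuple[str, str], str] = field(default_factory=dict)
    match_closure: dict[str, frozenset[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Ontology


def _brute_force_closure(
    terms: set[str], edges: set[tuple[str, str, str]]
) -> dict[str, frozenset[str]]:
    """Exhaustive-traversal match closure, independent of the ontio machinery.

    Two terms match when one reaches the other along generalization edges
    taken in a single direction, with equivalence edges free in both
    directions.  Implemented as plain BFS up-sets over adjacency dicts.
    """
    up: dict[str, set[str]] = {t: set() for t in terms}
    for src, rel, tgt in edges:
        if rel in DIRECTIONAL_RELATIONS:
            up[src].add(tgt)
        else:
            up[src].add(tgt)
            up[tgt].add(src)
    reach: dict[str, set[str]] = {}
    for t in terms:
        seen = {t}
        queue = deque([t])
        while queue:
            cur = queue.popleft()
            for nxt in up[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        reach[t] = seen
    closure: dict[str, frozenset[str]] = {}
    for a in terms:
        closure[a] = frozenset(
            b for b in terms if b in reach[a] or a in reach[b]
        )
    return closure


def gen_ontology(
    seed: int,
    n_roots: int = 1,
    depth: int = 3,
    branching: int = 2,
    p_equivalence: float = 0.0,
    p_role: float = 0.0,
) -> tuple[OntologyGraph, SynthTruth]:
    """Random is_a forest with optional equivalence twins and role edges.

    Level 0 holds ``n_roots`` roots; each term of level l−1 spawns
    ``branching`` children via is_a edges, down to ``depth`` levels.  Each
    non-root term gains, with probability ``p_equivalence``, a twin term
    linked by a random equivalence relation, and each leaf, with probability
    ``p_role``, a has_role edge to one of a few role terms.  Returns the graph
    and the exhaustively computed match closure as oracle.
    """
    if n_roots < 1 or depth < 1 or branching < 1:
        raise ParameterError("n_roots, depth and branching must be >= 1")
    if not 0.0 <= p_equivalence <= 1.0:
        raise ParameterError("p_equivalence must be a probability")
    rng = np.random.default_rng(seed)

    terms: set[str] = set()
    edges: set[tuple[str, str, str]] = set()
    levels: list[list[str]] = [[f"T0_{i}" for i in range(n_roots)]]
    terms.update(levels[0])
    for level in range(1, depth + 1):
        prev = levels[-1]
        cur: list[str] = []
        for parent in prev:
            for b in range(branching):
                child = f"{parent}.{b}"
                cur.append(child)
                terms.add(child)
                edges.add((child, "is_a", parent))
        levels.append(cur)

    non_roots = [t for lvl in levels[1:] for t in lvl]
    for t in non_roots:
        if rng.random() < p_equivalence:
            twin = f"{t}_eq"
            rel = _EQ_RELATIONS[rng.integers(len(_EQ_RELATIONS))]
            terms.add(twin)
            edges.add((twin, rel, t))

    if p_role > 0:
        roles = [f"ROLE_{i}" for i in range(max(2, n_roots))]
        terms.update(roles)
        # roles must not dangle: tie them under the first root
        for r in roles:
            edges.add((r, "is_a", levels[0][0]))
        for leaf in levels[-1]:
            if rng.random() < p_role:
                edges.add((leaf, "has_role", roles[rng.integers(len(roles))]))

    graph = OntologyGraph(terms=set(terms), edges=set(edges), labels={t: t for t in terms})
    truth = SynthTruth(seed=seed, match_closure=_brute_force_closure(terms, edges))
    return graph, truth


def ontology_leaves(g: OntologyGraph) -> list[str]:
    """Terms that are not the target of any is_a edge (most specific)."""
    parents = {tgt for _, rel, tgt in g.edges if rel == "is_a"}
    return sorted(g.terms - parents)


# ---------------------------------------------------------------------------
# Pathway network


def gen_pathway_network(
    seed: int,
    n_pathways: int = 5,
    n_reactions: int = 8,
    ontology: OntologyGraph | None = None,
    p_shared_side: float = 0.2,
    genes_per_reaction: int = 2,
) -> PathwayNetwork:
    """Rooted pathway tree with reactions drawing terms from ontology leaves.

    The first two non-root pathways are children of the root; later pathways
    attach to a uniformly random earlier pathway.  Each reaction gets 1–2
    educt and 1–2 product leaf terms (with probability ``p_shared_side`` one
    term appears on both sides, exercising the educt-also-product rule), a
    couple of protein ids, and one pathway membership.
    """
    if ontology is None or not ontology.terms:
        raise ParameterError("a non-empty ontology is required")
    if n_reactions < 1:
        raise ParameterError("n_reactions must be >= 1")
    if n_pathways < 1:
        raise ParameterError("n_pathways must be >= 1")
    rng = np.random.default_rng(seed)
    leaves = ontology_leaves(ontology)
    if len(leaves) < 2:
        raise ParameterError("ontology must have at least 2 leaf terms")

    root = "P_root"
    pathway_ids = [root] + [f"P{i}" for i in range(1, n_pathways)]
    parent_edges: dict[str, set[str]] = {root: set()}
    for i, p in enumerate(pathway_ids[1:], start=1):
        if i <= 2:
            parent = root
        else:
            parent = pathway_ids[int(rng.integers(i))]
        parent_edges[p] = {parent}

    assignable = pathway_ids[1:] if n_pathways > 1 else [root]
    reactions: dict[str, Reaction] = {}
    for j in range(n_reactions):
        n_e = int(rng.integers(1, 3))
        n_p = int(rng.integers(1, 3))
        picks = rng.choice(len(leaves), size=min(n_e + n_p, len(leaves)), replace=False)
        chosen = [leaves[i] for i in picks]
        educts = set(chosen[:n_e])
        products = set(chosen[n_e:]) or {chosen[0]}
        if rng.random() < p_shared_side:
            shared = leaves[int(rng.integers(len(leaves)))]
            educts.add(shared)
            products.add(shared)
        reactions[f"R{j}"] = Reaction(
            educts=frozenset(educts),
            products=frozenset(products),
            proteins=frozenset(f"G{j}_{k}" for k in range(genes_per_reaction)),
            pathways=frozenset({assignable[int(rng.integers(len(assignable)))]}),
        )
    return PathwayNetwork(
        root=root, pathways=set(pathway_ids), parent_edges=parent_edges, reactions=reactions
    )


# ---------------------------------------------------------------------------
# Metabolomics experiment


@dataclass
class MetabolomicsDesign:
    """Layout of one synthetic ± doxycycline MRM experiment.

    Defaults mirror the study conditions: four replicates per condition, two
    clones for the two-way (KO-OE) model, two runs, a 6-point calibration
    dilution series per run, and an internal-standard panel whose true
    assignment is known.  ``injection_sd``/``decoy_cal_sd`` are log2-scale
    standard deviations of the shared per-injection factor and of the extra
    calibration scatter of non-matching (decoy) standards.
    """

    analysis_id: str = "SLC_A"
    model: str = "one_way"  # one_way | two_way_clone
    n_replicates: int = 4
    n_clones: int = 2
    metabolites: tuple[str, ...] = tuple(f"M{i:02d}" for i in range(20))
    internal_standards: tuple[str, ...] = ("IS0", "IS1", "IS2", "IS3")
    true_is_map: dict[str, str] | None = None  # default: round-robin
    structure_matched: dict[str, str] = field(default_factory=dict)
    runs: tuple[str, ...] = ("run1", "run2")
    calibration_levels: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0)
    injection_sd: float = 0.1
    matrix_sd: float = 1.2
    clone_sd: float = 0.5

    def resolved_is_map(self) -> dict[str, str]:
        if self.true_is_map is not None:
            return dict(self.true_is_map)
        return {
            m: self.internal_standards[i % len(self.internal_standards)]
            for i, m in enumerate(self.metabolites)
        }


def gen_metabolomics_experiment(
    seed: int,
    design: MetabolomicsDesign | None = None,
    planted: dict[str, float] | None = None,
    noise_sd: float = 0.1,
    batch_effects: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, SynthTruth]:
    """Long-format peak table for one analysis, plus its ground truth.

    Peak areas are exp-scale products of true concentration, per-analyte
    sensitivity, run (batch) multiplier, a shared per-injection factor,
    a per-sample chemical-class matrix factor and lognormal noise
    (``noise_sd`` in log2 units).  Internal standards share the run and
    injection factors, and each metabolite shares its *matrix* factor with its
    chemically similar true internal standard — so the true-standard area
    ratio cancels every systematic factor and its calibration curve is linear,
    while a decoy ratio retains two independent matrix factors
    (``matrix_sd`` each, log2) and fails the adjusted-R² criterion.  Planted
    effects are exact log2 differences of the induced concentration;
    metabolites absent from ``planted`` are null with effect exactly 0.
    """
    design = design or MetabolomicsDesign()
    planted = planted or {}
    batch_effects = batch_effects or {}
    unknown = set(planted) - set(design.metabolites)
    if unknown:
        raise ParameterError(f"planted effects for unknown analytes: {sorted(unknown)}")
    for run in batch_effects:
        if run not in design.runs:
            raise ParameterError(f"batch effect for unknown run {run!r}")
    rng = np.random.default_rng(seed)
    is_map = design.resolved_is_map()
    missing = set(design.metabolites) - set(is_map)
    if missing:
        raise ParameterError(f"metabolites without a true internal standard: {sorted(missing)}")

    mets = list(design.metabolites)
    iss = list(design.internal_standards)
    conc0 = {m: float(rng.uniform(5.0, 50.0)) for m in mets}
    sens = {a: float(10 ** rng.uniform(3.0, 5.0)) for a in mets + iss}
    is_conc = 10.0  # spiked at a fixed nominal concentration
    clones = (
        [f"clone{c+1}" for c in range(design.n_clones)]
        if design.model == "two_way_clone"
        else [""]
    )
    clone_shift = {
        (m, c): (float(rng.normal(0.0, design.clone_sd)) if c else 0.0)
        for m in mets
        for c in clones
    }

    rows: list[dict] = []
    sample_specs = []
    for clone in clones:
        for condition in ("uninduced", "induced"):
            for rep in range(1, design.n_replicates + 1):
                sample_specs.append((clone, condition, rep))
    def matrix_factors() -> dict[str, float]:
        """Per-sample lognormal matrix factor for each chemical class.

        Classes are keyed by internal-standard id; a metabolite belongs to the
        class of its true standard, so the true ratio cancels the factor.
        """
        if not design.matrix_sd:
            return {s: 1.0 for s in iss}
        return {s: 2.0 ** rng.normal(0.0, design.matrix_sd) for s in iss}

    def emit(run, sid, condition, clone, rep, level=None):
        run_mult = batch_effects.get(run, 1.0)
        inj = 2.0 ** rng.normal(0.0, design.injection_sd) if design.injection_sd else 1.0
        w = matrix_factors()
        for m in mets:
            if condition == "calibration":
                conc = level
            else:
                effect = planted.get(m, 0.0) if condition == "induced" else 0.0
                conc = conc0[m] * 2.0 ** (effect + clone_shift[(m, clone)])
            noise = 2.0 ** rng.normal(0.0, noise_sd) if noise_sd else 1.0
            rows.append(
                {
                    "run_id": run, "batch_id": run, "sample_id": sid,
                    "analysis_id": design.analysis_id, "condition": condition,
                    "clone_id": clone, "replicate": rep, "analyte_id": m,
                    "analyte_role": "target",
                    "area": conc * sens[m] * run_mult * inj * w[is_map[m]] * noise,
                    "expected_conc": level if condition == "calibration" else np.nan,
                }
            )
        for s in iss:
            noise = 2.0 ** rng.normal(0.0, noise_sd) if noise_sd else 1.0
            rows.append(
                {
                    "run_id": run, "batch_id": run, "sample_id": sid,
                    "analysis_id": design.analysis_id, "condition": condition,
                    "clone_id": clone, "replicate": rep, "analyte_id": s,
                    "analyte_role": "internal_standard",
                    "area": is_conc * sens[s] * run_mult * inj * w[s] * noise,
                    "expected_conc": level if condition == "calibration" else np.nan,
                }
            )

    for idx, (clone, condition, rep) in enumerate(sample_specs):
        run = design.runs[idx % len(design.runs)]
        sid = f"{design.analysis_id}|{clone or 'wt'}|{condition}|r{rep}"
        emit(run, sid, condition, clone, rep)

    # calibration series: per run, a dilution ladder shared by all metabolites
    for run in design.runs:
        for li, level in enumerate(design.calibration_levels):
            emit(run, f"cal|{run}|L{li}", "calibration", "", li, level=float(level))

    pt = pd.DataFrame(rows)
    truth = SynthTruth(
        seed=seed,
        true_is_map=is_map,
        planted_effects={
            (design.analysis_id, m): float(planted.get(m, 0.0)) for m in mets
        },
    )
    return pt, truth


# ---------------------------------------------------------------------------
# Fold-change cohorts with planted cluster structure


def gen_lfc_cohort(
    seed: int,
    n_items: int = 40,
    n_features: int = 30,
    k_true: int = 4,
    separation: float = 6.0,
    noise_sd: float = 0.5,
    property_fidelity: float = 0.9,
    count_mean: float = 200.0,
    count_dispersion: float = 5.0,
    frac_significant: float = 0.3,
) -> tuple[dict[str, pd.DataFrame], SlcAnnotationTable, SynthTruth]:
    """Cohort of fold-change profiles with known cluster labels.

    Each item's profile is its cluster centroid (centroids pairwise separated
    by ``separation`` in Euclidean norm) plus Gaussian noise.  Each item gets
    one categorical property per class agreeing with its true cluster with
    probability ``property_fidelity``.  Adjusted p values and per-replicate
    negative-binomial read counts are attached so the significance and
    minimum-signal filters downstream are exercisable.
    """
    if n_items < 3 or n_features < 2 or k_true < 1:
        raise ParameterError("degenerate cohort size")
    if k_true > n_items / 3:
        raise ParameterError("k_true must be at most n_items/3")
    rng = np.random.default_rng(seed)

    raw = rng.normal(size=(k_true, n_features))
    raw /= np.linalg.norm(raw, axis=1, keepdims=True)
    centroids = raw * separation / np.sqrt(2.0)

    items = [f"SLC_{i:03d}" for i in range(n_items)]
    labels = {item: (i % k_true) + 1 for i, item in enumerate(items)}
    features = [f"F{j:03d}" for j in range(n_features)]
    nb_n = count_dispersion
    nb_p = nb_n / (nb_n + count_mean)

    tables: dict[str, pd.DataFrame] = {}
    for item in items:
        z = labels[item] - 1
        lfc = centroids[z] + (rng.normal(0.0, noise_sd, n_features) if noise_sd else 0.0)
        padj = np.where(
            rng.random(n_features) < frac_significant,
            rng.uniform(0.0, 0.049, n_features),
            rng.uniform(0.05, 1.0, n_features),
        )
        counts = rng.negative_binomial(nb_n, nb_p, size=(n_features, 4))
        tables[item] = pd.DataFrame(
            {
                "feature": features,
                "lfc": lfc,
                "pvalue": padj,
                "padj": padj,
                "significant": padj < 0.05,
                "count_induced_r1": counts[:, 0],
                "count_induced_r2": counts[:, 1],
                "count_uninduced_r1": counts[:, 2],
                "count_uninduced_r2": counts[:, 3],
            }
        )
        tables[item].attrs["analysis_id"] = item

    prop_rows = []
    substrates: dict[str, frozenset[str]] = {}
    for item in items:
        substrates[item] = frozenset()
        z = labels[item]
        for cls, stem in (
            ("family", "Fam"),
            ("fold", "Fold"),
            ("substrate_class", "Sub"),
        ):
            if rng.random() < property_fidelity:
                val = z
            else:
                val = int(rng.integers(1, k_true + 1))
            prop_rows.append({"slc": item, "prop_class": cls, "prop": f"{stem}{val}"})
    ann = SlcAnnotationTable(
        substrates, pd.DataFrame(prop_rows, columns=["slc", "prop_class", "prop"])
    )
    truth = SynthTruth(seed=seed, true_labels=labels)
    return tables, ann, truth


# ---------------------------------------------------------------------------
# Hand-built pair-categorization scenario


def toy_pair_scenario() -> tuple[
    OntologyGraph, PathwayNetwork, SlcAnnotationTable, dict[str, pd.DataFrame], SynthTruth
]:
    """Small fixed ontology + reactions whose pair categories are hand-derived.

    Covers all four categories plus the two exclusion rules: substrates named
    water cannot anchor a conversion, and a term on both sides of a reaction
    (here ATP) cannot anchor a match.  Deterministic; no randomness involved.
    """
    terms = {
        "amino_acid", "arginine", "ornithine", "taurine", "glucose",
        "citrate", "citric_acid", "water", "atp", "adp",
    }
    edges = {
        ("arginine", "is_a", "amino_acid"),
        ("ornithine", "is_a", "amino_acid"),
        ("citrate", "is_conjugate_base_of", "citric_acid"),
    }
    g = OntologyGraph(terms=terms, edges=edges, labels={t: t for t in terms})

    net = PathwayNetwork(
        root="P_root",
        pathways={"P_root", "P_urea"},
        parent_edges={"P_root": set(), "P_urea": {"P_root"}},
        reactions={
            # arginine -> ornithine (ATP on both sides: cannot anchor)
            "R_arg": Reaction(
                educts=frozenset({"arginine", "atp"}),
                products=frozenset({"ornithine", "atp"}),
                pathways=frozenset({"P_urea"}),
            ),
            # water -> adp: only reachable via the excluded substrate
            "R_wat": Reaction(
                educts=frozenset({"water"}),
                products=frozenset({"adp"}),
                pathways=frozenset({"P_urea"}),
            ),
        },
    )

    ann = SlcAnnotationTable(
        substrates={
            "SLC_ARG": frozenset({"arginine"}),     # substrate + conversion cases
            "SLC_TAU": frozenset({"taurine"}),      # annotated substrate identity
            "SLC_GLC": frozenset({"glucose"}),      # no reaction linkage -> novel
            "SLC_WAT": frozenset({"water"}),        # only excluded substrate
            "SLC_ATP": frozenset({"atp"}),          # both-sides term cannot anchor
            "SLC_CIT": frozenset({"citric_acid"}),  # equivalence-edge substrate match
            "SLC_ORP": frozenset(),                 # orphan
        },
        properties=pd.DataFrame(columns=["slc", "prop_class", "prop"]),
    )

    def table(met: str, lfc: float) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [met],
                "lfc": [lfc],
                "pvalue": [0.001],
                "padj": [0.01],
                "significant": [True],
            }
        )

    diff_tables = {
        "SLC_ARG": table("ornithine", 0.8),
        "SLC_TAU": table("taurine", 2.5),
        "SLC_GLC": table("taurine", -1.2),
        "SLC_WAT": table("adp", 0.6),
        "SLC_ATP": table("ornithine", 1.4),
        "SLC_CIT": table("citrate", 3.1),
        "SLC_ORP": table("glucose", -0.7),
    }
    truth = SynthTruth(
        seed=0,
        true_pair_categories={
            # arginine->ornithine reaction links substrate to metabolite
            ("SLC_ARG", "ornithine"): "metabolic_conversion",
            ("SLC_TAU", "taurine"): "annotated_substrate",
            ("SLC_GLC", "taurine"): "novel_non_orphan",
            # water is excluded as a substrate, so R_wat cannot be used
            ("SLC_WAT", "adp"): "novel_non_orphan",
            # ATP is educt and product of R_arg: disqualified as anchor
            ("SLC_ATP", "ornithine"): "novel_non_orphan",
            # citrate ~ citric_acid via a conjugate-base edge
            ("SLC_CIT", "citrate"): "annotated_substrate",
            ("SLC_ORP", "glucose"): "novel_orphan",
        },
    )
    return g, net, ann, diff_tables, truth
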