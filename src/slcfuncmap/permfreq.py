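"""Pathway hit frequencies and identity-shuffling permutation significance.

For every pathway we count how many analyses contain at least one significant
feature mapped to it (each analysis counts at most once per pathway).  Large or
hub pathways are hit often by chance, so significance is assessed empirically:
each permutation applies one random relabeling of the quantified feature
identities — shared across all analyses and pathways in that iteration — and
the counts are recomputed.  The one-sided enrichment p value uses the add-one
correction, p = (#{permuted ≥ observed} + 1) / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class PathwayHitCounts:
    counts: pd.Series  # pathway id -> number of analyses with >=1 hit
    n_analyses: int


def _significant_features(table: pd.DataFrame) -> set[str]:
    return set(table.loc[table["significant"].fillna(False).astype(bool), "feature"])


def count_pathway_hits(
    diff_tables: dict[str, pd.DataFrame], fmap: dict[str, set[str]]
) -> PathwayHitCounts:
    """Per pathway, the number of analyses with a significant mapped feature."""
    pathways = sorted(set().union(*fmap.values())) if fmap else []
    counts = pd.Series(0, index=pathways, dtype=int)
    for analysis_id in sorted(diff_tables):
        hit: set[str] = set()
        for f in _significant_features(diff_tables[analysis_id]):
            hit |= fmap.get(f, set())
        for p in hit:
            counts[p] += 1
    return PathwayHitCounts(counts, len(diff_tables))


def permutation_pvalues(
    diff_tables: dict[str, pd.DataFrame],
    fmap: dict[str, set[str]],
    B: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical enrichment p values by shuffling feature identities.

    Returns a frame with columns ``pathway_id, observed_count, p_empirical,
    B, seed``, deterministic for a fixed seed.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    universes = [frozenset(t["feature"]) for t in diff_tables.values()]
    universe = sorted(set().union(*universes)) if universes else []
    if len(set(universes)) > 1:
        logger.warning(
            "analyses quantify different feature sets; using their union (%d features)",
            len(universe),
        )
    feat_index = {f: i for i, f in enumerate(universe)}
    pathways = sorted(set().union(*fmap.values())) if fmap else []
    path_index = {p: j for j, p in enumerate(pathways)}
    membership = np.zeros((len(universe), len(pathways)), dtype=bool)
    for f, ps in fmap.items():
        if f in feat_index:
            for p in ps:
                membership[feat_index[f], path_index[p]] = True

    sig_idx = [
        np.array(
            sorted(feat_index[f] for f in _significant_features(t) if f in feat_index),
            dtype=int,
        )
        for _, t in sorted(diff_tables.items())
    ]
    observed = np.zeros(len(pathways), dtype=int)
    for idx in sig_idx:
        if idx.size:
            observed += membership[idx].any(axis=0)

    rng = np.random.default_rng(seed)
    ge = np.zeros(len(pathways), dtype=np.int64)
    for _ in range(B):
        perm = rng.permutation(len(universe))
        counts = np.zeros(len(pathways), dtype=int)
        for idx in sig_idx:
            if idx.size:
                counts += membership[perm[idx]].any(axis=0)
        ge += counts >= observed
    p = (ge + 1) / (B + 1)
    return pd.DataFrame(
        {
            "pathway_id": pathways,
            "observed_count": observed,
            "p_empirical": p,
            "B": B,
            "seed": seed,
        }
    )
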