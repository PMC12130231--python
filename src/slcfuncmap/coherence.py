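"""Cluster-coherence analysis via variation of information.

Two clusterings of the same items (say, metabolomics-profile clusters and
transcriptomics-profile clusters, or groupings by transporter family or
structural fold) are compared through the information they share.  With joint
cluster-pair probabilities p_ij and marginals p_i, p_j:

    MI   = Σ_ij p_ij log(p_ij / (p_i p_j))        (mutual information)
    H12  = −Σ_ij p_ij log p_ij                    (joint entropy)
    VI   = H12 − MI = Σ_ij p_ij log(p_i p_j / p_ij²)
    NVI  = VI / H12                               (normalized; base-invariant)

VI is a metric on clusterings; NVI of 0 means identical groupings, 1 means the
clusterings share no information.  The pairwise term
c_ij = p_ij log(p_i p_j / p_ij²) decomposes VI, and summing c_ij over the
clusters of the other clustering gives each cluster's total contribution.
All entropies use the natural logarithm (nats).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class JointDistribution:
    """Contingency structure of two clusterings on their common items."""

    counts: pd.DataFrame  # rows: clusters of clustering 1, cols: clustering 2
    n_common: int
    n_dropped_1: int
    n_dropped_2: int

    @property
    def joint(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float) / self.n_common


@dataclass
class CoherenceReport:
    H1: float
    H2: float
    H12: float
    MI: float
    VI: float
    NVI: float
    pair_contributions: pd.DataFrame  # c_ij, indexed like the contingency table
    cluster_contributions_1: pd.Series  # per cluster of clustering 1, sums to VI
    cluster_contributions_2: pd.Series
    mi_contributions_1: pd.Series
    mi_contributions_2: pd.Series


def joint_distribution(c1: pd.Series, c2: pd.Series) -> JointDistribution:
    """Contingency counts of two item→label mappings on their common items."""
    common = c1.index.intersection(c2.index)
    if len(common) == 0:
        raise ParameterError(
            f"no common items between clusterings of sizes {len(c1)} and {len(c2)}"
        )
    dropped1 = len(c1) - len(common)
    dropped2 = len(c2) - len(common)
    if dropped1 or dropped2:
        logger.info(
            "dropping items outside the intersection: %d from the first, %d from the second",
            dropped1, dropped2,
        )
    counts = pd.crosstab(c1.loc[common], c2.loc[common])
    return JointDistribution(counts, len(common), dropped1, dropped2)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def coherence_report(jd: JointDistribution) -> CoherenceReport:
    """Entropies, MI, VI, NVI and the per-cluster-pair decomposition."""
    p = jd.joint
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    H1 = _entropy(pi)
    H2 = _entropy(pj)
    H12 = _entropy(p.ravel())
    outer = np.outer(pi, pj)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi_terms = np.where(p > 0, p * np.log(p / outer), 0.0)
        c = np.where(p > 0, p * np.log(outer / p**2), 0.0)
    MI = float(mi_terms.sum())
    VI = float(c.sum())
    NVI = VI / H12 if H12 > 0 else 0.0
    pair = pd.DataFrame(c, index=jd.counts.index, columns=jd.counts.columns)
    mi_df = pd.DataFrame(mi_terms, index=jd.counts.index, columns=jd.counts.columns)
    return CoherenceReport(
        H1=H1,
        H2=H2,
        H12=H12,
        MI=MI,
        VI=VI,
        NVI=NVI,
        pair_contributions=pair,
        cluster_contributions_1=pair.sum(axis=1),
        cluster_contributions_2=pair.sum(axis=0),
        mi_contributions_1=mi_df.sum(axis=1),
        mi_contributions_2=mi_df.sum(axis=0),
    )


def nvi(c1: pd.Series, c2: pd.Series) -> float:
    """Normalized variation of information between two labelings."""
    return coherence_report(joint_distribution(c1, c2)).NVI


def pairwise_nvi_matrix(clusterings: dict[str, pd.Series]) -> pd.DataFrame:
    """Symmetric NVI matrix over named groupings (diagonal 0)."""
    if len(clusterings) < 2:
        raise ParameterError("need at least two clusterings")
    names = sorted(clusterings)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            value = nvi(clusterings[a], clusterings[b])
            mat.loc[a, b] = value
            mat.loc[b, a] = value
    return mat
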