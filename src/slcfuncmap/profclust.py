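"""Profile clustering, functional-property enrichment and uniqueness scoring.

Each analysis contributes a profile of log2 fold changes over the features
measured in *all* analyses.  Profiles are standard-normalized per item (mean 0,
sample SD 1) and grouped by Ward-linkage hierarchical clustering on Euclidean
distances.  The number of clusters is chosen within a band implied by a target
average cluster size of 5–10 items, maximizing the mean silhouette width.
Clusters are then tested for overrepresentation of categorical transporter
properties (family, fold, localization, substrate class, ion coupling) with
one-sided Fisher's exact tests, BH-adjusted per property class at FDR 20%.

Uniqueness scoring identifies genes whose response is specific to one analysis:
the shrunken log2 fold change of a gene is z-scored both across all genes
within the analysis and across all analyses for the gene; hits additionally
require significance and a minimal read-count signal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import fisher_exact
from sklearn.metrics import silhouette_score

from .diffstat import bh_adjust
from .errors import ParameterError
from .paircat import SlcAnnotationTable

logger = logging.getLogger(__name__)

ENRICHMENT_FDR = 0.20


@dataclass
class ProfileMatrix:
    """Item × feature matrix of standardized log2 fold-change profiles."""

    data: pd.DataFrame
    standardized: bool = True


@dataclass
class Clustering:
    """Hierarchical clustering result: labels, linkage tree and cut quality."""

    labels: pd.Series  # item -> cluster label in 1..k
    linkage: np.ndarray
    k: int
    mean_silhouette: float
    candidate_silhouettes: dict[int, float]

    def cut(self, k: int) -> pd.Series:
        return pd.Series(
            fcluster(self.linkage, t=k, criterion="maxclust"), index=self.labels.index
        )


def standardize_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each row to mean 0, sample SD 1 (n−1 denominator)."""
    centered = df.sub(df.mean(axis=1), axis=0)
    sd = df.std(axis=1, ddof=1)
    return centered.div(sd, axis=0)


def build_profile_matrix(diff_tables: dict[str, pd.DataFrame]) -> ProfileMatrix:
    """Stack cohort fold changes, keep features measured in every analysis,
    and standard-normalize each item's profile."""
    if not diff_tables:
        raise ParameterError("cohort is empty")
    wide = pd.DataFrame(
        {
            analysis: table.set_index("feature")["lfc"]
            for analysis, table in sorted(diff_tables.items())
        }
    ).T
    complete = wide.columns[wide.notna().all(axis=0)]
    dropped = wide.shape[1] - len(complete)
    if dropped:
        logger.info("dropped %d features not measured in all analyses", dropped)
    wide = wide[complete]
    sd = wide.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "excluding %d constant profiles that cannot be standardized: %s",
            int(flat.sum()), list(wide.index[flat]),
        )
        wide = wide[~flat]
    return ProfileMatrix(standardize_rows(wide), standardized=True)


def cluster_profiles(
    pm: ProfileMatrix, size_lo: int = 5, size_hi: int = 10
) -> Clustering:
    """Ward clustering with silhouette-guided choice of the cluster count.

    Candidate cuts are k in [ceil(N/size_hi), floor(N/size_lo)] (clamped to
    [2, N−1] when empty); the cut maximizing the mean silhouette width wins,
    ties toward smaller k.
    """
    data = pm.data.sort_index()
    n = len(data)
    if n < 3:
        raise ParameterError("need at least 3 items to cluster")
    X = data.to_numpy(dtype=float)
    Z = linkage(X, method="ward")
    k_lo = int(np.ceil(n / size_hi))
    k_hi = int(np.floor(n / size_lo))
    if k_lo > k_hi:
        logger.warning(
            "empty candidate range for N=%d, sizes %d-%d; clamping to [2, %d]",
            n, size_lo, size_hi, n - 1,
        )
        k_lo, k_hi = 2, n - 1
    k_lo = max(k_lo, 2)
    k_hi = min(k_hi, n - 1)
    silhouettes: dict[int, float] = {}
    for k in range(k_lo, k_hi + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        silhouettes[k] = float(silhouette_score(X, labels, metric="euclidean"))
    best_k = min(
        silhouettes, key=lambda k: (-silhouettes[k], k)
    )  # max silhouette, ties -> smallest k
    labels = pd.Series(
        fcluster(Z, t=best_k, criterion="maxclust"), index=data.index, name="cluster"
    )
    return Clustering(labels, Z, best_k, silhouettes[best_k], silhouettes)


def enrich_properties(
    cl: Clustering,
    ann: SlcAnnotationTable,
    min_annotations: int = 3,
    fdr: float = ENRICHMENT_FDR,
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation of each property in each cluster.

    Only properties carried by at least ``min_annotations`` clustered items are
    tested; BH adjustment runs within each property class separately and
    enrichment is called at the given FDR (default 20%).
    """
    annotated = set(ann.substrates)
    items = [i for i in cl.labels.index if i in annotated]
    skipped = len(cl.labels) - len(items)
    if skipped:
        logger.warning("%d clustered items missing from the annotation table", skipped)
    props = ann.properties[ann.properties["slc"].isin(items)]
    rows = []
    for prop_class, class_props in props.groupby("prop_class"):
        N = len(items)
        for prop, carriers_df in class_props.groupby("prop"):
            carriers = set(carriers_df["slc"])
            K = len(carriers)
            if K < min_annotations:
                continue
            for cluster in sorted(cl.labels.unique()):
                members = {i for i in items if cl.labels[i] == cluster}
                n = len(members)
                k = len(members & carriers)
                table = [[k, n - k], [K - k, N - n - (K - k)]]
                odds, p = fisher_exact(table, alternative="greater")
                rows.append(
                    {
                        "cluster": cluster,
                        "prop_class": prop_class,
                        "prop": prop,
                        "count_in_cluster": k,
                        "cluster_size": n,
                        "count_in_cohort": K,
                        "cohort_size": N,
                        "odds_ratio": odds,
                        "pvalue": p,
                    }
                )
    result = pd.DataFrame(
        rows,
        columns=[
            "cluster", "prop_class", "prop", "count_in_cluster", "cluster_size",
            "count_in_cohort", "cohort_size", "odds_ratio", "pvalue",
        ],
    )
    result["padj"] = np.nan
    for prop_class in result["prop_class"].unique():
        mask = result["prop_class"] == prop_class
        result.loc[mask, "padj"] = bh_adjust(result.loc[mask, "pvalue"])
    result["enriched"] = result["padj"] < fdr
    return result


def _count_columns(table: pd.DataFrame, condition: str) -> list[str]:
    pat = re.compile(rf"^count_{condition}_r\d+$")
    return [c for c in table.columns if pat.match(c)]


def uniqueness_scores(
    diff_tables: dict[str, pd.DataFrame],
    padj_max: float = 0.05,
    min_count: int = 50,
) -> pd.DataFrame:
    """Score how specific each gene's response is to each analysis.

    ``z_within`` standardizes a gene's fold change against all genes of the
    same analysis; ``z_across`` against the same gene over all analyses (needs
    the gene in ≥3 analyses).  A hit requires adjusted p < ``padj_max`` and at
    least ``min_count`` reads in every replicate of at least one condition.
    Rows are sorted by min(|z_within|, |z_across|) descending.
    """
    frames = []
    for analysis_id, table in sorted(diff_tables.items()):
        t = table.copy()
        t["analysis"] = analysis_id
        mean = t["lfc"].mean()
        sd = t["lfc"].std(ddof=1)
        t["z_within"] = (t["lfc"] - mean) / sd if sd > 0 else np.nan
        ind_cols = _count_columns(t, "induced")
        unind_cols = _count_columns(t, "uninduced")
        if not ind_cols or not unind_cols:
            raise ParameterError(
                f"analysis {analysis_id} lacks per-replicate count columns"
            )
        t["min_signal_pass"] = (t[ind_cols].min(axis=1) >= min_count) | (
            t[unind_cols].min(axis=1) >= min_count
        )
        frames.append(
            t[["feature", "analysis", "lfc", "padj", "z_within", "min_signal_pass"]]
        )
    out = pd.concat(frames, ignore_index=True)

    grp = out.groupby("feature")["lfc"]
    gmean = grp.transform("mean")
    gsd = grp.transform(lambda s: s.std(ddof=1))
    gn = grp.transform("size")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (out["lfc"] - gmean) / gsd
    z[gsd == 0] = 0.0  # identical response everywhere: zero deviation
    out["z_across"] = np.where(gn >= 3, z, np.nan)
    few = out.loc[gn < 3, "feature"].unique()
    if len(few):
        logger.debug("%d genes measured in <3 analyses: no z_across", len(few))
    out["hit"] = (
        (out["padj"] < padj_max)
        & out["min_signal_pass"]
        & out["z_across"].notna()
    )
    out["rank_stat"] = np.minimum(out["z_within"].abs(), out["z_across"].abs())
    out = out.sort_values("rank_stat", ascending=False, na_position="last")
    return out.reset_index(drop=True)
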