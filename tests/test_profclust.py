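"""Profile standardization, clustering, enrichment and uniqueness scoring."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from slcfuncmap import (
    ParameterError,
    SlcAnnotationTable,
    build_profile_matrix,
    cluster_profiles,
    enrich_properties,
    gen_lfc_cohort,
    standardize_rows,
    uniqueness_scores,
)


def _diff(features, lfcs, **extra):
    df = pd.DataFrame({"feature": features, "lfc": lfcs})
    for k, v in extra.items():
        df[k] = v
    return df


class TestProfileMatrix:
    def test_feature_missing_in_one_analysis_dropped(self):
        tables = {
            "a": _diff(["f1", "f2"], [1.0, 2.0]),
            "b": _diff(["f1"], [3.0]),
        }
        tables["a"].loc[1, "lfc"] = np.nan
        pm = build_profile_matrix(tables)
        assert list(pm.data.columns) == ["f1"]

    def test_hand_standardization(self):
        tables = {
            "a": _diff(["f1", "f2", "f3"], [1.0, 2.0, 3.0]),
            "b": _diff(["f1", "f2", "f3"], [5.0, 0.0, 1.0]),
        }
        pm = build_profile_matrix(tables)
        np.testing.assert_allclose(pm.data.loc["a"], [-1.0, 0.0, 1.0])

    def test_constant_row_excluded(self, caplog):
        tables = {
            "a": _diff(["f1", "f2"], [2.0, 2.0]),
            "b": _diff(["f1", "f2"], [1.0, 3.0]),
        }
        with caplog.at_level("WARNING"):
            pm = build_profile_matrix(tables)
        assert "a" not in pm.data.index

    def test_standardization_idempotent(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(5, 8)))
        once = standardize_rows(df)
        twice = standardize_rows(once)
        assert np.abs(once - twice).to_numpy().max() < 1e-9
        assert np.abs(once.mean(axis=1)).max() < 1e-9
        np.testing.assert_allclose(once.std(axis=1, ddof=1), 1.0)


class TestClusterProfiles:
    def test_recovers_planted_clusters(self):
        tables, _, truth = gen_lfc_cohort(
            3, n_items=40, n_features=30, k_true=6, separation=10.0, noise_sd=0.1
        )
        cl = cluster_profiles(build_profile_matrix(tables))
        assert cl.k == 6
        truth_labels = pd.Series(truth.true_labels)[cl.labels.index]
        assert adjusted_rand_score(truth_labels, cl.labels) > 0.9

    def test_identical_items_share_cluster(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=10)
        tables = {
            f"i{j}": _diff([f"f{k}" for k in range(10)], rng.normal(size=10))
            for j in range(8)
        }
        tables["twin1"] = _diff([f"f{k}" for k in range(10)], base)
        tables["twin2"] = _diff([f"f{k}" for k in range(10)], base)
        cl = cluster_profiles(build_profile_matrix(tables), size_lo=2, size_hi=5)
        assert cl.labels["twin1"] == cl.labels["twin2"]

    def test_chosen_cut_maximizes_silhouette(self):
        tables, _, _ = gen_lfc_cohort(9, n_items=30, n_features=20, k_true=4)
        pm = build_profile_matrix(tables)
        cl = cluster_profiles(pm)
        X = pm.data.sort_index().to_numpy()
        for k, s in cl.candidate_silhouettes.items():
            # recompute by definition
            ref = silhouette_score(X, cl.cut(k).to_numpy(), metric="euclidean")
            assert s == pytest.approx(ref, abs=1e-12)
            assert cl.mean_silhouette >= s - 1e-12

    def test_cut_reproduces_labels(self):
        tables, _, _ = gen_lfc_cohort(2, n_items=24, n_features=15, k_true=3)
        cl = cluster_profiles(build_profile_matrix(tables))
        pd.testing.assert_series_equal(
            cl.cut(cl.k), cl.labels, check_names=False
        )

    def test_item_order_invariance(self):
        tables, _, _ = gen_lfc_cohort(7, n_items=21, n_features=12, k_true=3)
        cl1 = cluster_profiles(build_profile_matrix(tables))
        reordered = dict(reversed(list(tables.items())))
        cl2 = cluster_profiles(build_profile_matrix(reordered))
        pd.testing.assert_series_equal(cl1.labels, cl2.labels)

    def test_too_few_items_rejected(self):
        tables = {"a": _diff(["f1", "f2"], [1.0, 2.0]), "b": _diff(["f1", "f2"], [2.0, 1.0])}
        with pytest.raises(ParameterError):
            cluster_profiles(build_profile_matrix(tables))


def _hypergeom_tail(k, K, n, N):
    """Independent exact one-sided tail: P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return sum(
        comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)
    ) / comb(N, n)


class TestEnrichment:
    def _clustering(self, labels: dict):
        from slcfuncmap import Clustering

        s = pd.Series(labels)
        return Clustering(s, np.empty((0, 4)), s.nunique(), 0.0, {})

    def test_universal_property_not_enriched(self):
        items = [f"i{j}" for j in range(20)]
        ann = SlcAnnotationTable(
            {i: frozenset() for i in items},
            pd.DataFrame({"slc": items, "prop_class": "family", "prop": "FamX"}),
        )
        cl = self._clustering({i: 1 + (j % 4) for j, i in enumerate(items)})
        out = enrich_properties(cl, ann)
        assert (out["pvalue"] == 1.0).all()

    def test_exact_tail_probability(self):
        """Fisher p equals the hand hypergeometric tail for N=50,K=6,n=5,k=4."""
        items = [f"i{j:02d}" for j in range(50)]
        carriers = set(items[:4]) | set(items[5:7])  # 6 carriers, 4 in cluster 1
        labels = {i: (1 if j < 5 else 2 + (j - 5) % 9) for j, i in enumerate(items)}
        ann = SlcAnnotationTable(
            {i: frozenset() for i in items},
            pd.DataFrame(
                {"slc": sorted(carriers), "prop_class": "family", "prop": "FamA"}
            ),
        )
        out = enrich_properties(self._clustering(labels), ann)
        row = out[(out["cluster"] == 1) & (out["prop"] == "FamA")].iloc[0]
        expected = _hypergeom_tail(4, 6, 5, 50)
        assert expected == pytest.approx(666 / 2_118_760)
        assert row["pvalue"] == pytest.approx(expected, abs=1e-12)

    def test_min_annotations_rule(self):
        items = [f"i{j}" for j in range(10)]
        ann = SlcAnnotationTable(
            {i: frozenset() for i in items},
            pd.DataFrame(
                {"slc": items[:2], "prop_class": "family", "prop": "Rare"}
            ),
        )
        out = enrich_properties(self._clustering({i: 1 + (j % 2) for j, i in enumerate(items)}), ann)
        assert out.empty

    def test_planted_properties_all_flagged(self):
        tables, ann, truth = gen_lfc_cohort(
            4, n_items=40, n_features=30, k_true=4, separation=10.0,
            noise_sd=0.1, property_fidelity=1.0,
        )
        cl = cluster_profiles(build_profile_matrix(tables))
        out = enrich_properties(cl, ann)
        # map each true cluster to its silhouette-cut cluster via majority
        truth_labels = pd.Series(truth.true_labels)
        for z in sorted(set(truth_labels)):
            members = truth_labels[truth_labels == z].index
            cut_cluster = cl.labels[members].mode()[0]
            for stem in ("Fam", "Fold", "Sub"):
                hit = out[
                    (out["cluster"] == cut_cluster) & (out["prop"] == f"{stem}{z}")
                ]
                assert not hit.empty and bool(hit["enriched"].iloc[0])


class TestUniqueness:
    def _tables(self, lfc_map, counts=(100, 100, 100, 100), padj=0.01):
        tables = {}
        for analysis, lfcs in lfc_map.items():
            tables[analysis] = _diff(
                [f"g{i}" for i in range(len(lfcs))],
                lfcs,
                padj=padj,
                count_induced_r1=counts[0],
                count_induced_r2=counts[1],
                count_uninduced_r1=counts[2],
                count_uninduced_r2=counts[3],
            )
        return tables

    def test_constant_gene_has_zero_across_z(self):
        lfc_map = {f"a{k}": [1.0, float(k)] for k in range(5)}
        out = uniqueness_scores(self._tables(lfc_map))
        g0 = out[out["feature"] == "g0"]
        assert np.allclose(g0["z_across"], 0.0)

    def test_planted_spike_top_ranked(self):
        n_analyses = 30
        lfc_map = {
            f"a{k:02d}": [10.0 if k == 0 else 0.0, 0.1 * k, -0.1 * k]
            for k in range(n_analyses)
        }
        out = uniqueness_scores(self._tables(lfc_map))
        top = out.iloc[0]
        assert top["feature"] == "g0" and top["analysis"] == "a00"
        # hand oracle for the across-analyses z-score of the spike
        vals = np.array([10.0] + [0.0] * (n_analyses - 1))
        expected = (10.0 - vals.mean()) / vals.std(ddof=1)
        assert top["z_across"] == pytest.approx(expected)

    def test_min_signal_requires_both_replicates(self):
        lfc_map = {f"a{k}": [1.0, 2.0, 3.0] for k in range(4)}
        out = uniqueness_scores(self._tables(lfc_map, counts=(60, 40, 30, 20)))
        assert not out["min_signal_pass"].any()
        assert not out["hit"].any()

    def test_few_analyses_excluded_from_hits(self):
        lfc_map = {"a1": [5.0, 1.0], "a2": [0.0, 1.0]}
        out = uniqueness_scores(self._tables(lfc_map))
        assert out["z_across"].isna().all()
        assert not out["hit"].any()
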