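import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

import episig as ep
from episig.episignature import DataError, SelectionError

from conftest import toy_beta


class TestScoreProbes:
    def _stats(self, delta, p_adj):
        return pd.DataFrame({"delta_beta": delta, "p_adjusted": p_adj},
                            index=[f"p{i}" for i in range(len(delta))])

    def test_arithmetic(self):
        s = ep.score_probes(self._stats([0.10], [1e-5]))
        assert s.iloc[0] == pytest.approx(0.5)

    def test_p_one_gives_zero(self):
        s = ep.score_probes(self._stats([0.3], [1.0]))
        assert s.iloc[0] == 0.0

    def test_monotone_in_p(self):
        p = np.logspace(-1, -10, 10)
        s = ep.score_probes(self._stats([0.1] * 10, p))
        assert (np.diff(s.to_numpy()) > 0).all()

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            s = ep.score_probes(self._stats([0.1], [0.0]))
        assert np.isfinite(s.iloc[0])


class TestProbeAuc:
    def test_perfect_separation(self):
        row = pd.Series([0.9, 0.8, 0.85, 0.1, 0.2, 0.15],
                        index=[f"s{i}" for i in range(6)])
        assert ep.probe_auc(row, ["s0", "s1", "s2"],
                            ["s3", "s4", "s5"]) == 1.0

    def test_identical_values_half(self):
        row = pd.Series([0.5] * 6, index=[f"s{i}" for i in range(6)])
        assert ep.probe_auc(row, ["s0", "s1", "s2"],
                            ["s3", "s4", "s5"]) == 0.5

    def test_matches_pairwise_counting_oracle(self):
        """3 cases vs 3 controls: AUC equals the brute-force count over all
        9 (case, control) pairs with ties worth 1/2, folded to >= 0.5."""
        rng = np.random.default_rng(8)
        for _ in range(25):
            vals = np.round(rng.uniform(0, 1, size=6), 1)  # force some ties
            row = pd.Series(vals, index=[f"s{i}" for i in range(6)])
            cases, ctrls = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
            wins = sum(
                1.0 if row[c] > row[k] else 0.5 if row[c] == row[k] else 0.0
                for c, k in itertools.product(cases, ctrls))
            expected = max(wins / 9.0, 1 - wins / 9.0)
            assert ep.probe_auc(row, cases, ctrls) == pytest.approx(expected)

    def test_vectorized_matches_rowwise(self, discovery):
        beta = discovery["study"].beta.iloc[:50]
        cases, ctrls = discovery["cases"], discovery["controls"]
        vec = ep.probe_auc_matrix(beta, cases, ctrls)
        for pid in beta.index[:10]:
            assert vec[pid] == pytest.approx(
                ep.probe_auc(beta.loc[pid], cases, ctrls))


class TestSelectProbes:
    def test_duplicate_probes_pruned_keeping_higher_score(self):
        base = np.array([0.9, 0.9, 0.9, 0.1, 0.1, 0.1])
        beta = toy_beta(np.vstack([base, base, 1 - base]))
        stats = pd.DataFrame(
            {"delta_beta": [0.3, 0.2, 0.3], "p_adjusted": [1e-6, 1e-4, 1e-6],
             "auc": [1.0, 1.0, 1.0]}, index=beta.index)
        stats["score"] = ep.score_probes(stats)
        sel = ep.select_probes(stats, beta,
                               ep.SelectionParams(top_k=10, auc_min=0.5))
        # p0 and p1 are perfectly correlated; p2 anti-correlated (|r|=1)
        assert sel == ["p0"]

    def test_auc_floor_excludes(self):
        rng = np.random.default_rng(9)
        beta = toy_beta(rng.uniform(size=(2, 10)))
        stats = pd.DataFrame(
            {"delta_beta": [0.3, 0.3], "p_adjusted": [1e-6, 1e-6],
             "auc": [0.6, 0.95]}, index=beta.index)
        stats["score"] = ep.score_probes(stats)
        sel = ep.select_probes(stats, beta,
                               ep.SelectionParams(auc_min=0.9, top_k=10))
        assert sel == ["p1"]

    def test_empty_selection_raises(self):
        beta = toy_beta([[0.5, 0.5]])
        stats = pd.DataFrame({"delta_beta": [0.0], "p_adjusted": [1.0],
                              "auc": [0.5], "score": [0.0]},
                             index=beta.index)
        with pytest.raises(SelectionError):
            ep.select_probes(stats, beta, ep.SelectionParams(auc_min=0.9))
        assert ep.select_probes(stats, beta,
                                ep.SelectionParams(auc_min=0.9),
                                allow_empty=True) == []

    def test_recovers_implanted_signature(self, discovery):
        study = discovery["study"]
        sel = ep.select_probes(
            discovery["stats"],
            study.beta[discovery["cases"] + discovery["controls"]])
        truth = set(study.truth_signature)
        hits = len(set(sel) & truth)
        assert hits / len(sel) >= 0.8

    def test_deterministic(self, discovery):
        beta = discovery["study"].beta[discovery["cases"]
                                       + discovery["controls"]]
        s1 = ep.select_probes(discovery["stats"], beta)
        s2 = ep.select_probes(discovery["stats"], beta)
        assert s1 == s2


class TestHierarchicalCluster:
    def test_identical_samples_merge_at_zero(self):
        x = np.array([[0.1, 0.1, 0.9], [0.2, 0.2, 0.8]])
        newick, _ = ep.hierarchical_cluster(toy_beta(x))
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        # s0 and s1 are identical: their common ancestor spans zero height
        heights = [tree.find_node_with_taxon_label(t).edge.length
                   for t in ["s0", "s1"]]
        assert all(h == 0 for h in heights)

    def test_newick_contains_all_leaves(self, discovery):
        study = discovery["study"]
        beta = study.beta.loc[study.truth_signature,
                              discovery["cases"] + discovery["controls"]]
        newick, leaves = ep.hierarchical_cluster(beta)
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        labels = {t.label for t in tree.taxon_namespace}
        assert labels == set(beta.columns) == set(leaves)

    def test_cases_and_controls_form_disjoint_subtrees(self, discovery):
        study = discovery["study"]
        cases, ctrls = discovery["cases"], discovery["controls"]
        beta = study.beta.loc[study.truth_signature, cases + ctrls]
        newick, _ = ep.hierarchical_cluster(beta)
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        tree.is_rooted = True
        mrca = tree.mrca(taxon_labels=cases)
        case_clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
        assert case_clade == set(cases)


class TestMdsEmbedding:
    def test_reproduces_2d_realizable_distances(self):
        # three planar points embedded in a 2-probe space
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
        beta = toy_beta(pts.T)
        coords = ep.mds_embedding(beta)
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(coords.to_numpy()), pdist(pts), atol=1e-8)

    def test_duplicate_sample_identical_coordinates(self):
        rng = np.random.default_rng(10)
        x = rng.uniform(size=(20, 4))
        beta = toy_beta(np.hstack([x, x[:, :1]]))
        coords = ep.mds_embedding(beta)
        assert np.allclose(coords.loc["s0"], coords.loc["s4"], atol=1e-10)

    def test_degenerate_all_equal_gives_zeros(self):
        beta = toy_beta(np.full((10, 4), 0.5))
        coords = ep.mds_embedding(beta)
        assert np.allclose(coords.to_numpy(), 0.0, atol=1e-10)

    def test_signal_separates_groups_on_first_coordinate(self, discovery):
        from sklearn.metrics import silhouette_score
        study = discovery["study"]
        cases, ctrls = discovery["cases"], discovery["controls"]
        beta = study.beta.loc[study.truth_signature, cases + ctrls]
        coords = ep.mds_embedding(beta)
        labels = [1 if s in cases else 0 for s in coords.index]
        assert silhouette_score(coords[["dim1"]], labels) > 0


class TestLooCrossvalidation:
    @pytest.fixture(scope="class")
    def rounds(self, discovery):
        return ep.loo_crossvalidate(
            discovery["study"].beta, discovery["m"],
            discovery["study"].samples, discovery["cases"],
            discovery["controls"])

    def test_one_round_per_case(self, rounds, discovery):
        assert len(rounds) == len(discovery["cases"]) == 12

    def test_each_case_held_out_once(self, rounds, discovery):
        assert {r["held_out"] for r in rounds} == set(discovery["cases"])

    def test_strong_signal_places_all_cases_with_cases(self, rounds):
        assert all(r["placement"] == "case" for r in rounds)


class TestClassifier:
    @pytest.fixture(scope="class")
    def trained(self, discovery):
        study = discovery["study"]
        selected = ep.select_probes(
            discovery["stats"],
            study.beta[discovery["cases"] + discovery["controls"]])
        model, report = ep.train_classifier(
            study.beta.loc[selected], discovery["cases"],
            discovery["controls"], seed=13)
        return selected, model, report

    def test_training_cases_above_boundary(self, trained):
        _, _, report = trained
        cases = report[report["role"] == "training_case"]
        assert (cases["mvp"] > 0.5).all()

    def test_controls_below_boundary(self, trained):
        _, _, report = trained
        ctrls = report[report["role"] == "training_control"]
        assert (ctrls["mvp"] < 0.5).all()

    def test_fold_accounting(self, trained):
        """Each control is a test sample exactly once; each case is scored
        in all four fold models."""
        _, _, report = trained
        assert (report.loc[report["role"] == "training_case",
                           "n_folds_averaged"] == 4).all()
        assert (report.loc[report["role"] == "training_control",
                           "n_folds_averaged"] == 1).all()

    def test_scores_in_unit_interval(self, trained):
        _, _, report = trained
        assert report["mvp"].between(0, 1).all()

    def test_reclassification_reproduces_stored_scores(self, trained,
                                                       discovery):
        selected, model, _ = trained
        beta = discovery["study"].beta.loc[selected, discovery["cases"]]
        out = ep.classify_samples(model, beta)
        for s in discovery["cases"]:
            assert out.loc[s, "mvp"] == pytest.approx(
                model.training_scores[s], abs=1e-6)

    def test_signature_free_sample_scores_low(self, trained, discovery):
        selected, model, _ = trained
        study = discovery["study"]
        unused = [s for s in study.control_pool_ids
                  if s not in discovery["controls"]]
        assert unused, "pool should exceed the matched set"
        out = ep.classify_samples(model, study.beta.loc[selected, unused])
        assert (out["mvp"] < 0.5).all()

    def test_missing_model_probe_is_data_error(self, trained, discovery):
        selected, model, _ = trained
        beta = discovery["study"].beta.loc[selected[1:],
                                           discovery["cases"]]
        with pytest.raises(DataError):
            ep.classify_samples(model, beta)

    def test_model_json_round_trip(self, trained, tmp_path):
        selected, model, _ = trained
        path = tmp_path / "model.json"
        model.save(path)
        loaded = ep.EpisignatureModel.load(path)
        assert loaded.probe_ids == model.probe_ids
        assert np.allclose(loaded.weights, model.weights)
        assert loaded.calibration == pytest.approx(model.calibration)
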