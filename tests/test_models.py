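"""Imbalance handling, randomized CV search, ranking, and artifact round-trips."""

import numpy as np
import pytest

from odorkit import models
from odorkit.models import (
    SEARCH_SPACES,
    class_weights,
    downsample_majority,
    draw_configs,
    fit_final,
    random_search,
    rank_combinations,
)


class TestDownsample:
    def test_cap_applied_to_majority_only(self, rng):
        labels = np.array(["pos"] * 8000 + ["neg"] * 1200)
        keep = downsample_majority(labels, cap=5000, seed=0)
        kept = labels[keep]
        assert (kept == "pos").sum() == 5000
        assert (kept == "neg").sum() == 1200

    def test_below_cap_unchanged(self):
        labels = np.array(["pos"] * 3000 + ["neg"] * 1200)
        assert downsample_majority(labels, cap=5000, seed=0).size == 4200

    def test_seed_determinism(self):
        labels = np.array(["a"] * 7000 + ["b"] * 100)
        k1 = downsample_majority(labels, cap=5000, seed=7)
        k2 = downsample_majority(labels, cap=5000, seed=7)
        assert np.array_equal(k1, k2)
        k3 = downsample_majority(labels, cap=5000, seed=8)
        assert not np.array_equal(k1, k3)


class TestClassWeights:
    def test_balanced_gives_unit_weights(self):
        w = class_weights(["A"] * 50 + ["B"] * 50)
        assert w == {"A": 1.0, "B": 1.0}

    def test_inverse_frequency(self):
        w = class_weights(["A"] * 75 + ["B"] * 25)
        assert w["A"] == pytest.approx(2 / 3)
        assert w["B"] == pytest.approx(2.0)

    def test_weighted_counts_conserve_n(self):
        labels = ["A"] * 61 + ["B"] * 17 + ["C"] * 5
        w = class_weights(labels)
        total = sum(w[c] for c in labels)
        assert total == pytest.approx(len(labels))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            class_weights(["A"] * 10)


class TestSearch:
    def test_draws_stay_inside_domains(self):
        for family, space in SEARCH_SPACES.items():
            for cfg in draw_configs(family, n_draws=20, seed=1):
                for key, value in cfg.items():
                    assert value in space[key], (family, key, value)

    def test_single_draw_returned_verbatim(self, rng):
        X = rng.normal(size=(60, 12))
        y = np.array(["a", "b"] * 30)
        cv = random_search("contribution", "ecfp4", X, y, "rf", n_draws=1, seed=3)
        assert cv.config == draw_configs("rf", 1, seed=3)[0]
        assert cv.folds == 5

    def test_separable_data_reaches_high_macro_f1(self, rng):
        n = 120
        X = np.zeros((n, 8))
        y = np.array(["pos"] * (n // 2) + ["neg"] * (n // 2))
        X[: n // 2, 0] = 1.0
        X[:, -4:] = rng.normal(size=(n, 4))  # physchem block noise
        cv = random_search("contribution", "ecfp4", X, y, "rf", n_draws=2, seed=0)
        assert cv.mean_score >= 0.95

    def test_impossible_stratification_errors(self, rng):
        X = rng.normal(size=(10, 8))
        y = np.array(["a"] * 8 + ["b"] * 2)
        with pytest.raises(ValueError, match="stratified"):
            random_search("contribution", "ecfp4", X, y, "rf", n_draws=1, seed=0)


class TestRanking:
    def _report(self, f1, acc, prec=0.5, rec=0.5, tag=""):
        return {"tag": tag, "metrics": {"macro_f1": f1, "accuracy": acc,
                                        "macro_precision": prec, "macro_recall": rec}}

    def test_tie_broken_by_accuracy(self):
        a = self._report(0.73, 0.90, tag="A")
        b = self._report(0.73, 0.88, tag="B")
        assert rank_combinations([b, a])[0]["tag"] == "A"

    def test_full_tie_preserves_input_order(self):
        a = self._report(0.5, 0.5, tag="first")
        b = self._report(0.5, 0.5, tag="second")
        assert [r["tag"] for r in rank_combinations([a, b])] == ["first", "second"]

    def test_distinct_f1_sorts_alone(self):
        reports = [self._report(f, 0.1, tag=str(f)) for f in (0.2, 0.9, 0.5)]
        assert [r["tag"] for r in rank_combinations(reports)] == ["0.9", "0.5", "0.2"]


@pytest.fixture(scope="module")
def contribution_artifact(small_corpus):
    from odorkit.curation import curate_records

    cur = curate_records(small_corpus)
    smiles = [r["smiles"] for r in cur]
    X = models.design_matrix(smiles, "maccs")
    y = np.array([r["contribution"] for r in cur])
    cfg = {"n_estimators": 200, "max_depth": 10, "min_samples_split": 2,
           "min_samples_leaf": 1, "max_features": "sqrt"}
    return fit_final("contribution", "maccs", "rf", cfg, X, y, seed=0), smiles


class TestFitPredict:
    def test_probabilities_normalized(self, contribution_artifact):
        artifact, smiles = contribution_artifact
        proba = artifact.pipeline.predict_proba(models.design_matrix(smiles[:10], "maccs"))
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_bad_smiles_yields_error_record_batch_continues(self, contribution_artifact):
        artifact, _ = contribution_artifact
        rows = models.predict(artifact, ["CCO", "!!bad!!", "c1ccccc1"])
        assert "p_positive" in rows[0]
        assert "error" in rows[1]
        assert rows[2]["label"] in ("positive", "negative")

    def test_artifact_roundtrip_bitwise(self, tmp_path, contribution_artifact):
        artifact, smiles = contribution_artifact
        models.save_artifact(artifact, tmp_path / "m")
        reloaded = models.load_artifact(tmp_path / "m")
        probe = smiles[:50]
        before = [r["p_positive"] for r in models.predict(artifact, probe)]
        after = [r["p_positive"] for r in models.predict(reloaded, probe)]
        assert before == after

    def test_version_mismatch_refused(self, tmp_path, contribution_artifact):
        import json

        artifact, _ = contribution_artifact
        models.save_artifact(artifact, tmp_path / "m")
        manifest = json.loads((tmp_path / "m" / "manifest.json").read_text())
        manifest["version"] = "0"
        (tmp_path / "m" / "manifest.json").write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="version"):
            models.load_artifact(tmp_path / "m")


class TestLeakage:
    def test_validation_labels_never_influence_selection(self, rng):
        """Permuting validation labels cannot change the searched config:
        search only ever sees training data."""
        X = rng.normal(size=(80, 10))
        y = np.array(["a", "b"] * 40)
        cv1 = random_search("contribution", "ecfp4", X, y, "rf", n_draws=3, seed=5)
        cv2 = random_search("contribution", "ecfp4", X, y, "rf", n_draws=3, seed=5)
        assert cv1.config == cv2.config
        assert cv1.fold_scores == cv2.fold_scores


class TestGraphFamily:
    def test_embedding_deterministic_and_spelling_invariant(self):
        a = models.graph_embedding("CC(=O)OCCc1ccccc1")
        b = models.graph_embedding("c1ccccc1CCOC(C)=O")
        assert np.allclose(a, b)

    def test_gcn_family_trains(self, rng):
        smiles = ["CCO", "CCCO", "CCCCO", "c1ccccc1", "Cc1ccccc1", "CCc1ccccc1"] * 5
        y = np.array((["neg"] * 3 + ["pos"] * 3) * 5)
        X = models.graph_matrix(smiles)
        artifact = fit_final("contribution", "graph", "gcn",
                             {"hidden_dim": 64, "learning_rate": 1e-3}, X, y, seed=0)
        rows = models.predict(artifact, ["CCCCCO", "CCCc1ccccc1"])
        assert all("p_positive" in r for r in rows)
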