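"""Synthetic generators: determinism, ground-truth recovery, corpus shape."""

import numpy as np
import pytest
from scipy.stats import skew

from odorkit import models
from odorkit.curation import curate_records
from odorkit.panel import CENSORED, group_threshold
from odorkit.split import murcko
from odorkit.synthetic import (
    SynthSpec,
    gen_corpus,
    gen_labels,
    gen_molecules,
    gen_panel,
    gen_thresholds,
    is_positive_structure,
)


class TestGenMolecules:
    def test_small_custom_library_enumerates_fully(self):
        spec = SynthSpec(
            n_molecules=12,
            aromatic_templates=("{0}c1ccccc1", "{0}c1ccncc1", "{0}c1ccc2ccccc2c1"),
            plain_templates=(),
            substituents=("C", "CC", "CCC", "CCCC"),
            positive_fraction=1.0,
            seed=0,
        )
        mols = gen_molecules(spec)
        assert len(mols) == len(set(mols)) == 12
        assert len({murcko(s) for s in mols}) == 3

    def test_seed_determinism(self):
        a = gen_molecules(SynthSpec(n_molecules=100, seed=5))
        b = gen_molecules(SynthSpec(n_molecules=100, seed=5))
        assert a == b
        assert a != gen_molecules(SynthSpec(n_molecules=100, seed=6))

    def test_oversized_request_errors(self):
        spec = SynthSpec(
            n_molecules=50,
            aromatic_templates=("{0}c1ccccc1",),
            plain_templates=(),
            substituents=("C", "CC"),
        )
        with pytest.raises(ValueError, match="template space"):
            gen_molecules(spec)

    def test_scaffolds_come_from_the_library(self):
        spec = SynthSpec(n_molecules=150, seed=2)
        keys = {murcko(s) for s in gen_molecules(spec)}
        # every scaffold is a ring system from a template or the acyclic ""
        assert all(k == "" or k for k in keys)
        assert len(keys) > 5


class TestGenLabels:
    def test_noiseless_labels_follow_structure(self):
        spec = SynthSpec(n_molecules=200, seed=1, flip_noise=0.0)
        mols = gen_molecules(spec)
        labels = gen_labels(mols, spec)
        for s, lab in zip(mols, labels):
            assert (lab == "positive") == is_positive_structure(s)

    def test_target_prevalence_hit(self):
        spec = SynthSpec(n_molecules=2000, seed=3, positive_fraction=0.93)
        labels = gen_labels(gen_molecules(spec), spec)
        prev = labels.count("positive") / len(labels)
        assert prev == pytest.approx(0.93, abs=0.02)

    def test_full_flip_noise_destroys_signal(self):
        spec = SynthSpec(n_molecules=300, seed=4, flip_noise=0.5)
        mols = gen_molecules(spec)
        labels = gen_labels(mols, spec)
        agree = np.mean(
            [(l == "positive") == is_positive_structure(s) for s, l in zip(mols, labels)]
        )
        assert 0.4 < agree < 0.6


class TestGenThresholds:
    def test_noiseless_is_deterministic_linear_in_physchem(self):
        spec = SynthSpec(n_molecules=50, seed=5, threshold_noise_sd=0.0)
        mols = gen_molecules(spec)
        a = gen_thresholds(mols, spec)
        b = gen_thresholds(mols, spec)
        assert np.array_equal(a, b)
        from odorkit.features import physchem

        beta = np.asarray(spec.threshold_beta)
        manual = spec.threshold_intercept + np.stack(
            [physchem(s) for s in mols]
        ) @ beta
        assert np.allclose(a, manual)

    def test_distribution_roughly_normal(self):
        spec = SynthSpec(n_molecules=2000, seed=11)
        y = gen_thresholds(gen_molecules(spec), spec)
        assert abs(float(skew(y))) < 0.3

    def test_heavy_noise_drowns_signal(self):
        spec = SynthSpec(n_molecules=200, seed=6, threshold_noise_sd=50.0)
        mols = gen_molecules(spec)
        y = gen_thresholds(mols, spec)
        clean = gen_thresholds(mols, SynthSpec(n_molecules=200, seed=6, threshold_noise_sd=0.0))
        assert float(np.corrcoef(y, clean)[0, 1]) ** 2 < 0.3


class TestGenPanel:
    def test_step_function_limit(self):
        sess = gen_panel(1.0, slope=float("inf"), n_panelists=20, seed=0)
        assert group_threshold(sess) == 1.0

    def test_recovery_within_one_dilution_step(self):
        hits = 0
        for seed in range(200):
            sess = gen_panel(1.0, slope=2.0, n_panelists=20, seed=seed)
            t = group_threshold(sess)
            if t != CENSORED and 0.1 <= t <= 10.0:
                hits += 1
        assert hits / 200 >= 0.90

    def test_profiles_monotone(self):
        sess = gen_panel(0.5, slope=1.0, n_panelists=20, seed=3)
        assert (np.diff(sess.detection, axis=1) >= 0).all()


class TestEndToEnd:
    def test_corpus_passes_registry_and_curation_unmodified(self, small_corpus):
        from odorkit.registry import dedupe

        assert [r.smiles_canonical for r in dedupe(small_corpus)] == sorted(
            r.smiles_canonical for r in small_corpus
        )
        cur = curate_records(small_corpus)
        assert len(cur) == len(small_corpus)
        assert all(r["y_neglog10_mg_L"] is not None for r in cur)

    def test_curation_recovers_generated_labels(self, small_corpus):
        spec = SynthSpec(n_molecules=120, seed=42)
        cur = curate_records(small_corpus)
        truth = gen_labels([r["smiles"] for r in cur], spec)
        assert [r["contribution"] for r in cur] == truth

    def test_noiseless_labels_recoverable_by_gbdt(self):
        """A GBDT trained on structure-determined labels separates them."""
        spec = SynthSpec(n_molecules=300, seed=9, flip_noise=0.0, positive_fraction=0.7)
        mols = gen_molecules(spec)
        y = np.array(gen_labels(mols, spec))
        X = models.design_matrix(mols, "ecfp4")
        cfg = {"n_estimators": 300, "max_depth": 4, "learning_rate": 0.1}
        cut = 240
        art = models.fit_final("contribution", "ecfp4", "gbdt", cfg, X[:cut], y[:cut])
        from sklearn.metrics import f1_score

        pred = art.pipeline.predict(X[cut:])
        assert f1_score(y[cut:], pred, average="macro", zero_division=0) >= 0.95
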