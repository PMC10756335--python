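"""Estimator contracts: head, training determinism, CV protocol, ablations."""

import numpy as np
import pytest
from sklearn.base import clone

from cdrlearn.exceptions import ConfigError, TrainingError, ValidationError
from cdrlearn.model import DrugResponseClassifier, _MlpHead, cross_validate, predict_pair, run_ablation


class TestPredictionHead:
    def test_zero_weights_give_half(self, rng):
        head = _MlpHead(f=3, rng=rng)
        for p in head.parameters():
            p.data = np.zeros_like(p.data)
        assert predict_pair(np.ones(6), np.ones(6), head) == 0.5

    def test_probability_in_open_interval(self, rng):
        head = _MlpHead(f=4, rng=rng)
        for _ in range(20):
            p = predict_pair(rng.standard_normal(8), rng.standard_normal(8), head)
            assert 0.0 < p < 1.0

    def test_input_width_is_4f(self, rng):
        head = _MlpHead(f=18, rng=rng)
        assert head.W1.shape[0] == 72
        with pytest.raises(ValidationError):
            predict_pair(np.ones(10), np.ones(10), head)


def small_model(dataset, **kw):
    defaults = dict(dataset=dataset, f=6, epochs=15, seed=3)
    defaults.update(kw)
    return DrugResponseClassifier(**defaults)


class TestFitContracts:
    def test_same_seed_bit_identical(self, small_synthetic):
        _, ds = small_synthetic
        X, y = ds.pairs()
        m1 = small_model(ds).fit(X, y)
        m2 = small_model(ds).fit(X, y)
        np.testing.assert_array_equal(m1.cell_embedding_, m2.cell_embedding_)
        np.testing.assert_array_equal(m1.drug_embedding_, m2.drug_embedding_)
        np.testing.assert_array_equal(
            m1.predict_proba(X[:20]), m2.predict_proba(X[:20])
        )

    def test_loss_descends_on_planted_signal(self, small_synthetic):
        _, ds = small_synthetic
        X, y = ds.pairs()
        m = small_model(ds, epochs=60).fit(X, y)
        assert m.history_.loss.iloc[-1] < m.history_.loss.iloc[0]

    def test_no_cl_logs_but_does_not_backprop_contrastive(self, small_synthetic):
        _, ds = small_synthetic
        X, y = ds.pairs()
        m_a = small_model(ds, ablation=("no_cl",), gamma=0.01).fit(X, y)
        m_b = small_model(ds, ablation=("no_cl",), gamma=1.0).fit(X, y)
        # contrastive is still logged ...
        assert (m_a.history_.loss_cl > 0).any()
        # ... but gradients (hence all parameters) are independent of gamma
        np.testing.assert_array_equal(m_a.cell_embedding_, m_b.cell_embedding_)

    def test_alpha_beta_must_sum_to_one(self, small_synthetic):
        _, ds = small_synthetic
        X, y = ds.pairs()
        with pytest.raises(ConfigError):
            small_model(ds, alpha=0.9, beta=0.5).fit(X, y)

    def test_unknown_ablation_listed(self, small_synthetic):
        _, ds = small_synthetic
        X, y = ds.pairs()
        with pytest.raises(ConfigError, match="no_image"):
            small_model(ds, ablation=("bogus",)).fit(X, y)

    def test_sklearn_clone_roundtrip(self, small_synthetic):
        _, ds = small_synthetic
        m = small_model(ds, alpha=0.7, beta=0.3)
        c = clone(m)
        assert c.get_params()["alpha"] == 0.7
        assert c.get_params()["dataset"].cell_ids == ds.cell_ids

    def test_checkpoint_roundtrip(self, small_synthetic, tmp_path):
        _, ds = small_synthetic
        X, y = ds.pairs()
        m = small_model(ds).fit(X, y)
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = small_model(ds).load(path)
        np.testing.assert_array_equal(m.predict_proba(X[:30]), m2.predict_proba(X[:30]))
        with pytest.raises(ConfigError):
            small_model(ds, alpha=1.0, beta=0.0).load(path)

    def test_ablation_widths_stay_4f(self, small_synthetic):
        # disabled branches are zero-padded so the head keeps one layout
        _, ds = small_synthetic
        X, y = ds.pairs()
        m = small_model(ds, ablation=("no_image",)).fit(X, y)
        f = m.f
        np.testing.assert_array_equal(m.cell_embedding_[:, f:], 0.0)
        m2 = small_model(ds, ablation=("no_rnaseq", "no_cnv")).fit(X, y)
        np.testing.assert_array_equal(m2.cell_embedding_[:, :f], 0.0)


class TestCrossValidate:
    def test_partition_properties(self, small_synthetic):
        _, ds = small_synthetic
        X, y = ds.pairs()
        report = cross_validate(ds, n_splits=4, seed=5, f=6, epochs=5)
        preds = report.predictions
        # every labeled pair appears in exactly one test fold
        assert len(preds) == len(X)
        key = preds["cell_line"] + "|" + preds["drug"]
        assert key.nunique() == len(X)
        sizes = preds.groupby("fold").size()
        assert sizes.max() - sizes.min() <= 1
        assert len(report.fold_auc) == 4

    def test_same_seed_same_folds(self, small_synthetic):
        _, ds = small_synthetic
        r1 = cross_validate(ds, n_splits=3, seed=9, f=6, epochs=3)
        r2 = cross_validate(ds, n_splits=3, seed=9, f=6, epochs=3)
        assert (
            r1.predictions[["cell_line", "drug", "fold"]]
            .equals(r2.predictions[["cell_line", "drug", "fold"]])
        )
        assert r1.fold_auc == r2.fold_auc

    def test_too_few_pairs_rejected(self, small_synthetic):
        _, ds = small_synthetic
        with pytest.raises(ValidationError):
            cross_validate(ds, n_splits=10**6)


class TestRunAblation:
    def test_reports_share_folds_and_names(self, small_synthetic):
        _, ds = small_synthetic
        reports = run_ablation(ds, variants=("no_cl",), n_splits=3, seed=2, f=6, epochs=3)
        assert set(reports) == {"full", "no_cl"}
        a = reports["full"].predictions[["cell_line", "drug", "fold"]]
        b = reports["no_cl"].predictions[["cell_line", "drug", "fold"]]
        assert a.equals(b)

    def test_unknown_variant_rejected(self, small_synthetic):
        _, ds = small_synthetic
        with pytest.raises(ConfigError):
            run_ablation(ds, variants=("nonsense",), n_splits=3, epochs=1)
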