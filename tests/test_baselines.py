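"""Collaborative filtering, boosted trees, and the attention baseline."""

import numpy as np
import pytest

from promptsyn import baselines
from promptsyn.data import LabeledExample, label_records
from promptsyn.kshot import SplitSpec, split_tissue
from promptsyn.metrics import auroc
from promptsyn.simulate import SimConfig, TissueSpec, generate

from .conftest import make_record, random_examples


def signal_examples(n_per_tissue=1000, mechanism="additive", seed=0, **kw):
    cfg = SimConfig(
        n_drugs=20,
        latent_dim=4,
        alpha=2.5,
        sigma=0.1,
        mechanism=mechanism,
        tissues={"lung": TissueSpec(5, n_per_tissue), "breast": TissueSpec(5, n_per_tissue)},
        seed=seed,
        **kw,
    )
    return label_records(generate(cfg))


class TestCollaborativeFiltering:
    def test_prediction_symmetric_under_drug_swap(self):
        examples = random_examples(200, prevalence=0.4, seed=0)
        model = baselines.fit_cf(examples, d=8, seed=0, epochs=50)
        records = [ex.record for ex in examples[:20]]
        fwd = model.predict_proba(records)
        rev = model.predict_proba([r.swapped() for r in records])
        np.testing.assert_array_equal(fwd, rev)

    def test_latent_recovery_on_matching_form(self):
        examples = signal_examples(1000)
        train, test = split_tissue(examples, SplitSpec(0.2, seed=0))
        model = baselines.fit_cf(train, d=16, seed=0, epochs=300)
        score = auroc([ex.y for ex in test], model.predict_proba([ex.record for ex in test]))
        assert score > 0.85

    def test_all_unseen_query_uses_population_fallback(self):
        examples = random_examples(100, prevalence=0.4, seed=1)
        model = baselines.fit_cf(examples, d=8, seed=0, epochs=50)
        unseen = make_record(drug1="NEW-1", drug2="NEW-2", cell_line="NEW-C")
        p = model.predict_proba([unseen, unseen])
        mean_u = model.U.mean(axis=0)
        z = 2 * mean_u @ model.V.mean(axis=0) + 2 * model.b_drug.mean() + model.b_cell.mean() + model.b0
        expected = 1.0 / (1.0 + np.exp(-z))
        np.testing.assert_allclose(p, expected, rtol=1e-10)

    def test_single_class_rejected(self):
        ones = [LabeledExample(make_record(drug1=f"D{i}"), 1) for i in range(10)]
        with pytest.raises(ValueError):
            baselines.fit_cf(ones)

    def test_kshot_warm_start_changes_predictions(self):
        examples = random_examples(300, prevalence=0.4, seed=2)
        base = baselines.fit_cf(examples, d=8, seed=0, epochs=100)
        shots = random_examples(16, prevalence=0.5, seed=9, tissue="liver")
        adapted = baselines.cf_kshot(base, shots, epochs=50)
        records = [ex.record for ex in shots]
        assert not np.allclose(base.predict_proba(records), adapted.predict_proba(records))


class TestGradientBoosting:
    def test_feature_vector_length(self):
        examples = random_examples(50, prevalence=0.4, seed=0)
        space = baselines.FeatureSpace.from_examples(examples)
        assert space.n_features == 2 * len(space.drugs) + len(space.cells) + 2
        X = space.transform([ex.record for ex in examples])
        assert X.shape == (50, space.n_features)

    def test_tissue_absent_from_features(self):
        assert "tissue" not in baselines.FEATURE_FIELDS
        examples = random_examples(40, prevalence=0.4, seed=0, tissue="bone")
        relabeled = [
            LabeledExample(ex.record.__class__(**{**ex.record.__dict__, "tissue": "XXXX"}), ex.y)
            for ex in examples
        ]
        space = baselines.FeatureSpace.from_examples(examples)
        a = space.transform([ex.record for ex in examples]).toarray()
        b = space.transform([ex.record for ex in relabeled]).toarray()
        np.testing.assert_array_equal(a, b)

    def test_deterministic_single_thread(self):
        examples = random_examples(120, prevalence=0.4, seed=3)
        cfg = baselines.GBTConfig(n_trees=30, max_depth=4)
        a = baselines.fit_gbt(examples, cfg, seed=0)
        b = baselines.fit_gbt(examples, cfg, seed=0)
        records = [ex.record for ex in examples[:20]]
        np.testing.assert_array_equal(a.predict_proba(records), b.predict_proba(records))

    def test_recovers_planted_sensitivity_rule(self):
        examples = signal_examples(1000, mechanism="ri_linear")
        train, test = split_tissue(examples, SplitSpec(0.2, seed=0))
        model = baselines.fit_gbt(train, baselines.GBTConfig(n_trees=200, max_depth=6), seed=0)
        scores = model.predict_proba([ex.record for ex in test])
        accuracy = np.mean((scores > 0.5).astype(int) == [ex.y for ex in test])
        assert accuracy > 0.9

    def test_kshot_is_boosting_continuation(self):
        examples = random_examples(200, prevalence=0.4, seed=5)
        base = baselines.fit_gbt(examples, baselines.GBTConfig(n_trees=20, max_depth=4), seed=0)
        shots = random_examples(16, prevalence=0.5, seed=6)
        adapted = baselines.gbt_kshot(base, shots, extra_rounds=10)
        assert adapted.booster.num_boosted_rounds() == 30
        assert base.booster.num_boosted_rounds() == 20

    def test_config_validation(self):
        with pytest.raises(ValueError):
            baselines.GBTConfig(n_trees=0)


class TestTabTransformer:
    CONFIG = baselines.TabConfig(
        embed_dim=16, n_layers=2, n_heads=4, epochs=5, learning_rate=1e-3, seed=0
    )

    def _fit(self, seed=0):
        examples = signal_examples(400, seed=seed)
        train, val = split_tissue(examples, SplitSpec(0.2, seed=seed))
        model, trace = baselines.fit_tab(train, val, self.CONFIG)
        return model, trace, examples

    def test_best_checkpoint_rule(self):
        model, trace, examples = self._fit()
        best = max(row["val_auprc"] for row in trace)
        val_records = [ex.record for ex in examples[:50]]
        assert len(trace) == self.CONFIG.epochs
        # the restored checkpoint reproduces the best epoch's metric
        train, val = split_tissue(examples, SplitSpec(0.2, seed=0))
        from promptsyn.metrics import auprc

        restored = auprc([ex.y for ex in val], model.predict_proba([ex.record for ex in val]))
        assert abs(restored - best) < 1e-9

    def test_one_epoch_kshot_changes_parameters(self):
        model, _, _ = self._fit()
        shots = random_examples(16, prevalence=0.5, seed=2)
        adapted = baselines.tab_kshot(model, shots, seed=0)
        assert adapted.checksum() != model.checksum()
        assert model.checksum() == model.checksum()  # base untouched

    def test_unseen_cell_gets_mean_slot(self, caplog):
        model, _, _ = self._fit()
        before = model.params["cell_emb"].data.mean(axis=0).copy()
        new = make_record(cell_line="CELL-NEW")
        with caplog.at_level("INFO"):
            model.predict_proba([new])
        assert "CELL-NEW" in model.cell_index
        row = model.params["cell_emb"].data[model.cell_index["CELL-NEW"]]
        np.testing.assert_allclose(row, before, rtol=1e-6)

    def test_standardization_frozen_from_training(self):
        model, _, _ = self._fit()
        mu = model.ri_mean.copy()
        model.predict_proba([make_record(ri1=999.0, ri2=-999.0)])
        np.testing.assert_array_equal(model.ri_mean, mu)

    def test_single_class_rejected(self):
        ones = [LabeledExample(make_record(drug1=f"D{i}"), 1) for i in range(10)]
        with pytest.raises(ValueError):
            baselines.fit_tab(ones, ones, self.CONFIG)
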