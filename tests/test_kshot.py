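"""Few-shot protocol: stratified splits, nested shot sets, grid runner."""

import numpy as np
import pytest

from promptsyn.data import LabeledExample
from promptsyn.kshot import (
    ProtocolError,
    ShotSchedule,
    ShotSet,
    SplitSpec,
    fingerprint,
    run_grid,
    sample_nested_shots,
    split_tissue,
)

from .conftest import make_record, random_examples


class TestSplitTissue:
    def test_stratification_arithmetic(self):
        examples = random_examples(100, prevalence=0.0)
        examples = [
            LabeledExample(ex.record, 1) if i < 30 else LabeledExample(ex.record, 0)
            for i, ex in enumerate(examples)
        ]
        train, test = split_tissue(examples, SplitSpec(0.2, seed=0))
        assert sum(ex.y for ex in test) == 6
        assert len(test) == 20 and len(train) == 80

    def test_seed_determinism(self):
        examples = random_examples(60, seed=1)
        a = split_tissue(examples, SplitSpec(0.2, seed=5))
        b = split_tissue(examples, SplitSpec(0.2, seed=5))
        c = split_tissue(examples, SplitSpec(0.2, seed=6))
        assert a == b and a != c

    @pytest.mark.parametrize("seed", range(5))
    def test_union_and_disjointness(self, seed):
        examples = random_examples(50, prevalence=0.4, seed=seed)
        train, test = split_tissue(examples, SplitSpec(0.25, seed=seed))
        assert len(train) + len(test) == len(examples)
        assert not (set(train) & set(test))
        assert set(train) | set(test) == set(examples)

    def test_scarce_class_raises(self):
        examples = random_examples(10, prevalence=0.0)
        examples[0] = LabeledExample(examples[0].record, 1)
        with pytest.raises(ProtocolError):
            split_tissue(examples, SplitSpec(0.2, seed=0))


class TestShotSchedule:
    def test_default_schedule(self):
        assert ShotSchedule().ks == (0, 2, 4, 8, 16, 32, 64, 128)

    @pytest.mark.parametrize("bad", [(2, 2), (4, 2), (2, 3), (2, 0), (0, 0)])
    def test_invalid_schedules(self, bad):
        with pytest.raises(ValueError):
            ShotSchedule(bad)

    def test_zero_only_first(self):
        assert ShotSchedule((0, 2)).nonzero == (2,)


class TestShotSet:
    def test_invariants(self):
        pos = [LabeledExample(make_record(drug1=f"P{i}", loewe=30.0), 1) for i in range(2)]
        neg = [LabeledExample(make_record(drug1=f"N{i}", loewe=-10.0), 0) for i in range(2)]
        s2 = ShotSet(2, (pos[0], neg[0]))
        s4 = ShotSet(4, (pos[0], neg[0], pos[1], neg[1]), parent=s2)
        assert s4.parent is s2
        with pytest.raises(ValueError):
            ShotSet(2, (pos[0], pos[1]))  # single class at k >= 2
        with pytest.raises(ValueError):
            ShotSet(3, (pos[0], neg[0]))  # size mismatch
        with pytest.raises(ValueError):
            ShotSet(2, (pos[1], neg[1]), parent=s2)  # not nested


class TestSampleNestedShots:
    def test_k2_has_one_of_each(self):
        train = random_examples(40, prevalence=0.3, seed=0)
        sets = sample_nested_shots(train, ShotSchedule((0, 2)), seed=1)
        assert sets[0].k == 2
        assert sorted(ex.y for ex in sets[0].examples) == [0, 1]

    def test_quota_arithmetic_imbalanced(self):
        # 90 negatives, 10 positives; k=8 -> round(8 * 0.1) = 1 positive
        records = [make_record(drug1=f"D{i}") for i in range(100)]
        train = [LabeledExample(r, 1 if i < 10 else 0) for i, r in enumerate(records)]
        sets = sample_nested_shots(train, ShotSchedule((8,)), seed=0)
        ys = [ex.y for ex in sets[0].examples]
        assert sum(ys) == 1 and len(ys) == 8

    @pytest.mark.parametrize("seed", range(6))
    def test_nesting_chain_and_proportions(self, seed):
        train = random_examples(200, prevalence=0.35, seed=seed)
        schedule = ShotSchedule((0, 2, 4, 8, 16, 32, 64, 128))
        sets = sample_nested_shots(train, schedule, seed=seed)
        assert [s.k for s in sets] == [2, 4, 8, 16, 32, 64, 128]
        for smaller, larger in zip(sets, sets[1:]):
            assert set(smaller.examples) < set(larger.examples)
        for s in sets:
            ys = [ex.y for ex in s.examples]
            assert 0 < sum(ys) < len(ys)

    def test_oversized_k_dropped_with_warning(self, caplog):
        train = random_examples(20, prevalence=0.4, seed=2)
        with caplog.at_level("WARNING"):
            sets = sample_nested_shots(train, ShotSchedule((0, 2, 16, 32)), seed=0)
        assert [s.k for s in sets] == [2, 16]
        assert "dropping k=32" in caplog.text

    def test_single_class_train_raises(self):
        train = [LabeledExample(make_record(drug1=f"D{i}"), 0) for i in range(10)]
        with pytest.raises(ProtocolError):
            sample_nested_shots(train, ShotSchedule((2,)), seed=0)

    def test_seed_determinism(self):
        train = random_examples(80, prevalence=0.4, seed=4)
        a = sample_nested_shots(train, ShotSchedule((2, 8)), seed=9)
        b = sample_nested_shots(train, ShotSchedule((2, 8)), seed=9)
        assert [s.examples for s in a] == [s.examples for s in b]


class _ConstantArm:
    """Protocol stub: scores by the record's ri1 feature."""

    def __init__(self, name, zero_shot_available=True):
        self.name = name
        self._zero = zero_shot_available

    def fit_shots(self, shots, seed):
        return None

    def score(self, fitted, examples):
        return np.array([ex.record.ri1 for ex in examples])

    def zero_shot(self, examples):
        if not self._zero:
            return None
        return self.score(None, examples)


class TestRunGrid:
    def _tissues(self):
        return {
            "bone": random_examples(60, prevalence=0.4, seed=0, tissue="bone"),
            "liver": random_examples(60, prevalence=0.4, seed=1, tissue="liver"),
        }

    def test_grid_cardinality(self):
        arms = [_ConstantArm("a"), _ConstantArm("b")]
        table = run_grid(arms, self._tissues(), ShotSchedule((0, 2, 4, 8)), seeds=[0])
        assert len(table) == 2 * 2 * 4

    def test_test_set_fixed_across_k(self):
        examples = self._tissues()["bone"]
        train, test = split_tissue(examples, SplitSpec(0.2, seed=7))
        fp = fingerprint(test)
        for _ in range(3):
            train2, test2 = split_tissue(examples, SplitSpec(0.2, seed=7))
            assert fingerprint(test2) == fp

    def test_missing_zero_shot_recorded_as_na(self):
        arms = [_ConstantArm("nozero", zero_shot_available=False)]
        table = run_grid(arms, self._tissues(), ShotSchedule((0, 2)), seeds=[0])
        zero_rows = table[table.k == 0]
        assert zero_rows.auprc.isna().all()
        assert len(table[table.k == 2]) == 2

    def test_metrics_in_range(self):
        table = run_grid([_ConstantArm("a")], self._tissues(), ShotSchedule((2, 8)), seeds=[0, 1])
        assert ((table.auprc >= 0) & (table.auprc <= 1)).all()
        assert ((table.auroc >= 0) & (table.auroc <= 1)).all()
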