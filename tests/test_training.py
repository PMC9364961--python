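"""Subject splits, resampling caps, SGD schedule, convergence, folds."""

import dataclasses

import numpy as np
import pytest

import somnostage as ss
from somnostage.stages import STAGE_ORDER, StageLabel


def make_records(subject_counts, fs=10.0):
    """subject_counts: {subject_id: [(night_id, stage, n_epochs), ...]}."""
    gen = np.random.default_rng(0)
    records = []
    for subject, nights in subject_counts.items():
        index = {}
        for night, stage, n in nights:
            for _ in range(n):
                i = index.get(night, 0)
                index[night] = i + 1
                records.append(ss.EpochRecord(
                    samples=gen.normal(0, 10, (int(fs * 30), 2)), fs_hz=fs,
                    stage=stage, subject_id=subject, night_id=night,
                    epoch_index=i,
                ))
    return records


class TestSplitBySubject:
    def test_cohort_partition_by_reference_numbers(self):
        records = make_records({
            f"S{i:02d}": [(f"S{i:02d}_n1", StageLabel.N2, 2)]
            for i in range(1, 31)
        })
        plan = ss.SplitPlan(
            train_subjects=tuple(f"S{i:02d}" for i in range(7, 31)),
            test_subjects=tuple(f"S{i:02d}" for i in range(1, 7)),
        )
        train, test = ss.split_by_subject(records, plan)
        assert len({r.subject_id for r in train}) == 24
        assert len({r.subject_id for r in test}) == 6
        assert not ({r.subject_id for r in train}
                    & {r.subject_id for r in test})

    def test_empty_test_list_keeps_everything_in_train(self):
        records = make_records({"S01": [("S01_n1", StageLabel.W, 3)]})
        plan = ss.SplitPlan(train_subjects=("S01",), test_subjects=())
        train, test = ss.split_by_subject(records, plan)
        assert len(train) == 3 and len(test) == 0

    def test_temporal_order_preserved(self):
        records = make_records(
            {"S01": [("S01_n1", StageLabel.W, 5)],
             "S02": [("S02_n1", StageLabel.N2, 5)]})
        plan = ss.SplitPlan(train_subjects=("S01", "S02"), test_subjects=())
        train, _ = ss.split_by_subject(records, plan)
        for subject in ("S01", "S02"):
            indices = [r.epoch_index for r in train if r.subject_id == subject]
            assert indices == sorted(indices)

    def test_uncovered_subject_rejected(self):
        records = make_records({"S99": [("S99_n1", StageLabel.W, 1)]})
        plan = ss.SplitPlan(train_subjects=("S01",), test_subjects=("S02",))
        with pytest.raises(ValueError, match="S99"):
            ss.split_by_subject(records, plan)

    def test_overlapping_plan_rejected(self):
        with pytest.raises(ValueError):
            ss.SplitPlan(train_subjects=("S01",), test_subjects=("S01",))


class TestResample:
    def test_oversized_group_capped_without_duplicates(self, rng):
        records = make_records({"S01": [("S01_n1", StageLabel.N2, 500)]})
        out = ss.resample(records, ss.ResamplePolicy(), rng)
        assert len(out) == 200
        assert len({id(r) for r in out}) == 200

    def test_minority_stage_oversampled_to_cap_from_originals(self, rng):
        records = make_records({"S01": [("S01_n1", StageLabel.N1, 50)]})
        out = ss.resample(records, ss.ResamplePolicy(), rng)
        assert len(out) == 200
        originals = {id(r) for r in records}
        assert all(id(r) in originals for r in out)
        assert originals <= {id(r) for r in out}  # every original retained

    def test_unit_cap_keeps_one_per_group(self, rng):
        records = make_records({
            "S01": [("S01_n1", StageLabel.W, 5), ("S01_n1", StageLabel.N2, 7),
                    ("S01_n2", StageLabel.W, 3)]
        })
        out = ss.resample(records,
                          ss.ResamplePolicy(cap_per_stage_per_night=1), rng)
        groups = {(r.night_id, r.stage) for r in out}
        assert len(out) == len(groups) == 3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cap_never_exceeded(self, seed):
        gen = np.random.default_rng(seed)
        counts = {s: int(gen.integers(1, 80)) for s in STAGE_ORDER}
        records = make_records(
            {"S01": [("S01_n1", s, n) for s, n in counts.items()]})
        policy = ss.ResamplePolicy(cap_per_stage_per_night=30)
        out = ss.resample(records, policy, np.random.default_rng(seed))
        from collections import Counter
        tally = Counter((r.night_id, r.stage) for r in out)
        assert max(tally.values()) <= 30

    def test_deterministic_given_seed(self):
        records = make_records({"S01": [("S01_n1", StageLabel.N2, 40)]})
        policy = ss.ResamplePolicy(cap_per_stage_per_night=10)
        a = ss.resample(records, policy, np.random.default_rng(3))
        b = ss.resample(records, policy, np.random.default_rng(3))
        assert [id(r) for r in a] == [id(r) for r in b]


class TestSchedule:
    def test_decay_closed_form(self):
        sched = ss.TrainSchedule()
        expected = {0: 0.015, 20: 0.0015, 40: 0.00015}
        for epoch, lr in expected.items():
            assert ss.learning_rate_at(sched, epoch) == pytest.approx(
                lr, rel=1e-12)

    def test_rate_constant_within_decay_window(self):
        sched = ss.TrainSchedule()
        assert ss.learning_rate_at(sched, 19) == pytest.approx(0.015)
        assert ss.learning_rate_at(sched, 21) == pytest.approx(0.0015)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            ss.TrainSchedule(lr_decay_factor=1.5)


class TestValidationFolds:
    def _nights(self, n_subjects, nights_each):
        return make_records({
            f"S{i:02d}": [(f"S{i:02d}_n{j}", StageLabel.N2, 2)
                          for j in range(1, nights_each + 1)]
            for i in range(1, n_subjects + 1)
        })

    def test_48_nights_make_12_folds_of_4(self):
        records = self._nights(24, 2)
        folds = ss.validation_folds(records, 12)
        assert len(folds) == 12
        for _, holdout in folds:
            assert len({(r.subject_id, r.night_id) for r in holdout}) == 4

    def test_folds_disjoint_and_covering(self):
        records = self._nights(5, 2)
        folds = ss.validation_folds(records, 5)
        seen = []
        for fit, holdout in folds:
            keys = {(r.subject_id, r.night_id) for r in holdout}
            fit_keys = {(r.subject_id, r.night_id) for r in fit}
            assert not keys & fit_keys
            seen.append(keys)
        union = set().union(*seen)
        assert union == {(r.subject_id, r.night_id) for r in records}
        assert sum(len(k) for k in seen) == len(union)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            ss.validation_folds(self._nights(2, 1), 1)

    def test_more_folds_than_nights_rejected(self):
        with pytest.raises(ValueError):
            ss.validation_folds(self._nights(2, 1), 5)


def toy_separable_records(n_per_class=40, fs=1.0):
    """Two trivially separable 'stages': slow large wave vs fast small wave."""
    gen = np.random.default_rng(8)
    t = np.arange(int(fs * 30)) / fs
    records = []
    for k, stage in enumerate((StageLabel.W, StageLabel.N3)):
        for i in range(n_per_class):
            phase = gen.uniform(0, 2 * np.pi)
            base = (80.0 * np.sin(2 * np.pi * 0.05 * t + phase) if k
                    else 15.0 * np.sin(2 * np.pi * 0.4 * t + phase))
            samples = np.stack([base, base * 0.5], axis=1)
            samples += gen.normal(0, 2.0, samples.shape)
            records.append(ss.EpochRecord(
                samples=samples, fs_hz=fs, stage=stage, subject_id="S01",
                night_id="S01_n1", epoch_index=len(records),
            ))
    return records


class TestTrainLoop:
    CFG = ss.ModelConfig(
        input_len=30, input_channels=2, lstm_units=8, lstm_layers=2,
        conv_specs=((8, 3), (4, 3)), pool_size=2, fc_sizes=(16,),
        n_classes=5, dropout_conv=0.0, dropout_fc=0.0,
    )

    def test_zero_epochs_is_identity(self):
        model = ss.build_model(self.CFG, seed=0)
        before = [layer.params[n].copy() for layer, n in model.parameters()]
        result = ss.train(model, toy_separable_records(4),
                          ss.TrainSchedule(epochs=0))
        assert result.model is model
        for (layer, n), prev in zip(model.parameters(), before):
            np.testing.assert_array_equal(layer.params[n], prev)

    def test_converges_on_separable_toy_problem(self):
        records = toy_separable_records()
        model = ss.build_model(self.CFG, seed=0)
        schedule = ss.TrainSchedule(epochs=30, batch_size=16, lr_init=0.05,
                                    seed=0)
        result = ss.train(model, records, schedule)
        # loss strictly decreases over the first 5 epochs and the fit ends
        # essentially perfect
        assert all(np.diff(result.train_loss[:5]) < 0)
        assert result.train_acc[-1] > 0.95

    def test_training_is_bit_reproducible(self):
        records = toy_separable_records(10)
        schedule = ss.TrainSchedule(epochs=2, batch_size=8, seed=5)
        runs = []
        for _ in range(2):
            model = ss.build_model(self.CFG, seed=5)
            runs.append(ss.train(model, records, schedule).train_loss)
        assert runs[0] == runs[1]

    def test_learning_rates_recorded_match_schedule(self):
        records = toy_separable_records(5)
        schedule = ss.TrainSchedule(epochs=3, batch_size=8, lr_decay_every=2,
                                    seed=0)
        result = ss.train(ss.build_model(self.CFG, seed=0), records, schedule)
        assert result.learning_rates == [
            ss.learning_rate_at(schedule, e) for e in range(3)]

    def test_non_finite_loss_aborts_with_diagnostic(self):
        records = toy_separable_records(5)
        model = ss.build_model(self.CFG, seed=0)
        model.out_layer.params["W"][0, 0] = np.nan
        with pytest.raises(ss.TrainingDiverged, match="epoch 0"):
            ss.train(model, records, ss.TrainSchedule(epochs=1, batch_size=8))

    def test_validation_curves_recorded(self):
        records = toy_separable_records(8)
        result = ss.train(
            ss.build_model(self.CFG, seed=0), records,
            ss.TrainSchedule(epochs=2, batch_size=8, seed=0),
            validation=records[:6],
        )
        assert len(result.val_acc) == 2
        assert all(np.isfinite(result.val_acc))
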