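"""Architecture audit, inference contracts, and training-loop behavior."""

import numpy as np
import pytest

import ecgfusion as ef
from ecgfusion.models import DemographicScaler, architecture_summary
from ecgfusion.records import ECGRecord
from ecgfusion.scenarios import LabeledDataset


def _tiny_dataset(scenario, n=8, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        sig = rng.normal(0, 0.1, size=(1000, 12))
        rec = ECGRecord(
            record_id=f"r{i}", signal=sig, fs=100,
            age=50.0 + i, sex="male" if i % 2 else "female", fold=1,
        )
        records.append((rec, i % 2))
    return LabeledDataset(records=records, partition="train", scenario=scenario)


class TestArchitectureAudit:
    def test_custom_cnn_structure(self):
        model = ef.build_model(
            ef.ModelConfig("custom_cnn", input_length=1000, num_classes=5)
        )
        s = architecture_summary(model)
        ecg = s["ecg_branch"]
        assert ecg["conv_filters"] == [32, 64, 128, 256, 512]
        assert ecg["kernel_sizes"] == [3] * 5
        assert ecg["pool_sizes"] == [2] * 5
        assert ecg["batch_norm_after_pool"] == [True] * 5
        assert ecg["dense_units"] == [100, 32]
        assert ecg["dropout_rates"] == [0.4, 0.4]
        demo = s["demo_branch"]
        assert demo["dense_units"] == [100, 64, 32, 16]
        assert demo["dropout_rates"] == [0.4]
        assert demo["n_weights"] == 9372
        head = s["head"]
        assert head["dense_units"] == [10, 10, 5]
        assert head["dropout_rates"] == [0.2, 0.2]

    def test_vgg_structure(self):
        model = ef.build_model(
            ef.ModelConfig("vgg_style", input_length=1000, num_classes=10)
        )
        s = architecture_summary(model)
        ecg = s["ecg_branch"]
        assert ecg["conv_filters"] == [64, 64, 128, 128, 256, 256, 512, 512]
        assert ecg["kernel_sizes"] == [3] * 8
        assert ecg["pool_sizes"] == [2] * 8
        assert ecg["dense_units"] == [512, 512]
        assert ecg["dropout_rates"] == [0.5, 0.5]
        assert ecg["global_pool"] is True
        assert s["head"]["dense_units"] == [10, 10, 10]

    def test_demographic_branch_weight_count_arithmetic(self):
        # 2*100+100 + 100*64+64 + 64*32+32 + 32*16+16 = 9372
        model = ef.build_model(
            ef.ModelConfig("custom_cnn", input_length=1000, num_classes=2)
        )
        assert architecture_summary(model)["demo_branch"]["n_weights"] == (
            2 * 100 + 100 + 100 * 64 + 64 + 64 * 32 + 32 + 32 * 16 + 16
        )

    def test_input_too_short_for_pooling_depth(self):
        with pytest.raises(ValueError, match="too short"):
            ef.ModelConfig("vgg_style", input_length=100, num_classes=2)

    def test_no_demographics_omits_branch(self):
        model = ef.build_model(
            ef.ModelConfig("custom_cnn", input_length=1000, num_classes=2,
                           use_demographics=False)
        )
        assert model.demo_branch is None
        assert "demo_branch" not in architecture_summary(model)


@pytest.fixture(scope="module")
def model_and_records():
    model = ef.build_model(
        ef.ModelConfig("custom_cnn", input_length=1000, num_classes=5, seed=3)
    )
    rng = np.random.default_rng(5)
    records = [
        ECGRecord(f"p{i}", rng.normal(size=(1000, 12)), 100,
                  age=60.0, sex="male", fold=1)
        for i in range(4)
    ]
    model.demo_scaler = DemographicScaler().fit(records)
    return model, records


class TestPredictProba:
    def test_rows_sum_to_one(self, model_and_records):
        model, records = model_and_records
        p = ef.predict_proba(model, records)
        assert p.shape == (4, 5)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_duplicated_inputs_give_identical_rows(self, model_and_records):
        model, records = model_and_records
        p = ef.predict_proba(model, [records[0], records[0]])
        assert np.allclose(p[0], p[1], atol=1e-7)

    def test_empty_batch(self, model_and_records):
        model, _ = model_and_records
        assert ef.predict_proba(model, []).shape == (0, 5)

    def test_length_mismatch_rejected(self, model_and_records):
        model, _ = model_and_records
        bad = ECGRecord("b", np.zeros((5000, 12)), 500, age=50.0,
                        sex="male", fold=1)
        with pytest.raises(ValueError, match="input_length"):
            ef.predict_proba(model, [bad])


class TestTrain:
    def test_empty_training_set_rejected(self):
        sc = ef.binary_superclass("MI")
        empty = LabeledDataset(records=[], partition="train", scenario=sc)
        model = ef.build_model(ef.ModelConfig("custom_cnn", 1000, 2))
        with pytest.raises(ValueError, match="empty"):
            ef.train(model, empty, empty, ef.TrainConfig(max_epochs=1))

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError, match="max_epochs"):
            ef.TrainConfig(max_epochs=0)

    def test_scenario_mismatch_rejected(self):
        a = _tiny_dataset(ef.binary_superclass("MI"))
        b = _tiny_dataset(ef.binary_superclass("CD"))
        model = ef.build_model(ef.ModelConfig("custom_cnn", 1000, 2))
        with pytest.raises(ValueError, match="share a scenario"):
            ef.train(model, a, b, ef.TrainConfig(max_epochs=1))

    def test_missing_class_logs_warning(self, caplog):
        sc = ef.binary_superclass("MI")
        ds = _tiny_dataset(sc)
        ds = LabeledDataset(
            records=[(r, 0) for r, _ in ds.records],
            partition="train", scenario=sc,
        )
        model = ef.build_model(ef.ModelConfig("custom_cnn", 1000, 2, seed=1))
        with caplog.at_level("WARNING"):
            ef.train(model, ds, ds, ef.TrainConfig(max_epochs=1, seed=1))
        assert "absent" in caplog.text

    def test_seeded_training_is_deterministic(self):
        sc = ef.binary_superclass("MI")
        ds = _tiny_dataset(sc)
        losses = []
        for _ in range(2):
            model = ef.build_model(
                ef.ModelConfig("custom_cnn", 1000, 2, seed=7)
            )
            h = ef.train(model, ds, ds, ef.TrainConfig(max_epochs=2, seed=7))
            losses.append(h["val_loss"][-1])
        assert losses[0] == losses[1]

    def test_checkpoint_is_minimum_validation_loss(self, overfit_binary_model):
        model, _, history = overfit_binary_model
        assert model.best_val_loss <= min(history["val_loss"]) + 1e-12
        assert len(history["epoch"]) <= 60


class TestDemographicScaler:
    def test_zscore_and_sex_encoding(self):
        recs = [
            ECGRecord(f"s{i}", np.zeros((1000, 12)), 100, age=a, sex=s, fold=1)
            for i, (a, s) in enumerate([(40.0, "male"), (60.0, "female")])
        ]
        X = DemographicScaler().fit(recs).transform(recs)
        assert X[:, 0] == pytest.approx([-1.0, 1.0])
        assert X[:, 1].tolist() == [0.0, 1.0]

    def test_missing_demographics_rejected_by_default(self):
        recs = [ECGRecord("m", np.zeros((1000, 12)), 100, age=50.0,
                          sex="male", fold=1)]
        scaler = DemographicScaler().fit(recs)
        missing = [ECGRecord("x", np.zeros((1000, 12)), 100, fold=1)]
        with pytest.raises(ValueError, match="demographics"):
            scaler.transform(missing)

    def test_missing_demographics_imputed_when_allowed(self):
        recs = [
            ECGRecord(f"s{i}", np.zeros((1000, 12)), 100, age=a, sex="male",
                      fold=1)
            for i, a in enumerate([40.0, 50.0, 60.0])
        ]
        scaler = DemographicScaler(impute_missing=True).fit(recs)
        X = scaler.transform([ECGRecord("x", np.zeros((1000, 12)), 100, fold=1)])
        assert X[0, 0] == pytest.approx(0.0, abs=1e-9)  # median == mean here
        assert X[0, 1] == 0.5
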