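import numpy as np
import pytest

from enacp.ensemble import (
    DEFAULT_SVM_GRID,
    EncoderBank,
    StackedModel,
    build_encoder_bank,
    cross_val_scores,
    encode_bank_matrices,
    fit_stage1,
    fit_stage2,
    predict_enacp,
    train_enacp,
)
from enacp.evaluation import roc_auc
from enacp.seqio import LabeledDataset, PeptideRecord
from enacp.synthetic_data import SyntheticSpec, generate_peptide_dataset, generate_pssm_set

from conftest import random_records

SMALL_BANK = ["kmer", "pc_pseaac"]


@pytest.fixture(scope="module")
def small_dataset():
    spec = SyntheticSpec(n_pos=40, n_neg=40, effect=0.5, seed=21,
                         length_range=(8, 30))
    dataset, _ = generate_peptide_dataset(spec)
    return dataset


class TestEncoderBank:
    def test_default_bank_is_19_partitioned_3_4_4_8(self):
        bank = build_encoder_bank()
        assert bank.k == 19
        assert bank.family_counts() == {
            "composition": 3, "autocorrelation": 4, "pseaac": 4, "profile": 8,
        }

    def test_without_profiles_drops_to_11(self, caplog):
        with caplog.at_level("WARNING"):
            bank = build_encoder_bank(profiles_available=False)
        assert bank.k == 11
        assert "profile" not in bank.family_counts()
        assert any("dropping profile encoders" in r.message for r in caplog.records)

    def test_duplicate_encoder_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            EncoderBank(encoders=(("kmer", {}), ("kmer", {"k": 3})))

    def test_unknown_encoder_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_encoder_bank(["kmer", "quux"])


class TestStage1:
    def test_separable_classes_meta_auc_one(self):
        # cationic-only positives vs acidic-only negatives: every encoder
        # separates the classes perfectly, so in-sample meta columns must too
        rng = np.random.default_rng(20)
        records, labels = [], []
        for i in range(40):
            L = int(rng.integers(10, 25))
            pos_seq = "".join(rng.choice(list("KR"), L))
            neg_seq = "".join(rng.choice(list("DE"), L))
            records += [PeptideRecord(f"p{i}", pos_seq),
                        PeptideRecord(f"n{i}", neg_seq)]
            labels += [1, 0]
        dataset = LabeledDataset(records, np.array(labels))
        bank = build_encoder_bank(SMALL_BANK)
        mats = encode_bank_matrices(bank, dataset.records)
        _, meta = fit_stage1(mats, dataset.labels, mode="in_sample", seed=0)
        assert meta.shape == (80, 2)
        assert np.all((meta >= 0) & (meta <= 1))
        for m in range(meta.shape[1]):
            assert roc_auc(meta[:, m], dataset.labels) == 1.0

    def test_permuted_labels_out_of_fold_auc_near_half(self):
        records = random_records(200, lmin=10, lmax=30, seed=22)
        rng = np.random.default_rng(23)
        labels = rng.permutation(np.repeat([0, 1], 100))
        bank = build_encoder_bank(SMALL_BANK)
        mats = encode_bank_matrices(bank, records)
        _, meta = fit_stage1(mats, labels, mode="out_of_fold", seed=0)
        for m in range(meta.shape[1]):
            assert abs(roc_auc(meta[:, m], labels) - 0.5) < 0.1

    def test_fixed_seed_reproduces_meta(self, small_dataset):
        bank = build_encoder_bank(SMALL_BANK)
        mats = encode_bank_matrices(bank, small_dataset.records)
        _, meta1 = fit_stage1(mats, small_dataset.labels, seed=5)
        _, meta2 = fit_stage1(mats, small_dataset.labels, seed=5)
        np.testing.assert_array_equal(meta1, meta2)

    def test_single_class_rejected(self, small_dataset):
        bank = build_encoder_bank(["kmer"])
        mats = encode_bank_matrices(bank, small_dataset.records)
        with pytest.raises(ValueError, match="both classes"):
            fit_stage1(mats, np.ones(len(small_dataset), dtype=int))


class TestStage2:
    def test_leaked_label_column_fits_perfectly(self, rng):
        labels = rng.integers(0, 2, 60)
        meta = np.column_stack([labels.astype(float),
                                rng.random(60)])
        model, _ = fit_stage2(meta, labels, seed=0)
        assert (model.predict(meta) == labels).mean() == 1.0

    def test_singleton_grid_recorded(self, rng):
        labels = np.repeat([0, 1], 30)
        meta = rng.random((60, 2)) + labels[:, None]
        _, fitted = fit_stage2(meta, labels, grid={"C": [4.0], "gamma": [0.25]},
                               seed=0)
        assert fitted["C"] == 4.0 and fitted["gamma"] == 0.25

    def test_grid_choice_matches_direct_exhaustive_evaluation(self, rng):
        from sklearn.model_selection import StratifiedKFold, cross_val_score
        from sklearn.svm import SVC

        labels = np.repeat([0, 1], 40)
        meta = rng.normal(size=(80, 3)) + 0.8 * labels[:, None]
        _, fitted = fit_stage2(meta, labels, seed=3)
        best_direct = -1.0
        for c in DEFAULT_SVM_GRID["C"]:
            for g in DEFAULT_SVM_GRID["gamma"]:
                cv = StratifiedKFold(5, shuffle=True, random_state=3)
                acc = cross_val_score(SVC(C=c, gamma=g), meta, labels,
                                      cv=cv, scoring="accuracy").mean()
                best_direct = max(best_direct, acc)
        assert fitted["cv_accuracy"] == pytest.approx(best_direct, abs=0.02)

    def test_constant_meta_warns_but_trains(self):
        labels = np.repeat([0, 1], 10)
        meta = np.full((20, 3), 0.5)
        with pytest.warns(UserWarning, match="constant"):
            model, _ = fit_stage2(meta, labels, grid={"C": [1.0], "gamma": [0.1]})
        assert model is not None

    @pytest.mark.parametrize("learner", ["adaboost", "decision_tree",
                                         "logistic_regression", "naive_bayes",
                                         "random_forest"])
    def test_alternate_second_layer_learners(self, learner, rng):
        labels = np.repeat([0, 1], 25)
        meta = rng.random((50, 2)) + labels[:, None]
        model, fitted = fit_stage2(meta, labels, learner=learner, seed=0)
        assert fitted["learner"] == learner
        assert (model.predict(meta) == labels).mean() > 0.9


class TestTrainPredict:
    CONFIG = {"encoders": SMALL_BANK,
              "svm_grid": {"C": [1.0, 32.0], "gamma": [0.01, 1.0]}}

    def test_minimal_two_peptide_dataset(self):
        ds = LabeledDataset(
            [PeptideRecord("a", "KKKKKKKKKK"), PeptideRecord("b", "DEDEDEDEDE")],
            np.array([1, 0]),
        )
        with pytest.warns(UserWarning, match="constant"):
            # 2-sample boosting yields constant stage-1 outputs
            model = train_enacp(
                ds, config={"encoders": ["kmer"],
                            "svm_grid": {"C": [1.0], "gamma": [0.1]}},
                seed=0)
        results = predict_enacp(model, ds.records)
        assert all(r.error is None for r in results)

    def test_same_seed_identical_predictions(self, small_dataset):
        probe = random_records(20, lmin=10, lmax=30, seed=30, prefix="probe")
        m1 = train_enacp(small_dataset, config=self.CONFIG, seed=11)
        m2 = train_enacp(small_dataset, config=self.CONFIG, seed=11)
        s1 = [r.score for r in predict_enacp(m1, probe)]
        s2 = [r.score for r in predict_enacp(m2, probe)]
        assert s1 == s2
        assert m1.fitted_params == m2.fitted_params

    def test_serialization_roundtrip_and_version_gate(self, small_dataset, tmp_path):
        probe = random_records(10, lmin=10, lmax=30, seed=31, prefix="probe")
        model = train_enacp(small_dataset, config=self.CONFIG, seed=2)
        path = tmp_path / "model.bin"
        model.save(path)
        loaded = StackedModel.load(path)
        assert ([r.score for r in predict_enacp(model, probe)]
                == [r.score for r in predict_enacp(loaded, probe)])
        import joblib

        joblib.dump({"format_version": 999, "model": model}, path)
        with pytest.raises(ValueError, match="version"):
            StackedModel.load(path)

    def test_training_row_meta_consistency_in_sample(self, small_dataset):
        from enacp.ensemble import stage1_meta

        bank = build_encoder_bank(SMALL_BANK)
        mats = encode_bank_matrices(bank, small_dataset.records)
        models, meta_train = fit_stage1(mats, small_dataset.labels,
                                        mode="in_sample", seed=4)
        np.testing.assert_array_equal(stage1_meta(models, mats), meta_train)

    def test_batch_invariance(self, small_dataset):
        model = train_enacp(small_dataset, config=self.CONFIG, seed=1)
        probe = random_records(5, lmin=10, lmax=30, seed=32, prefix="probe")
        batch = predict_enacp(model, probe)
        singles = [predict_enacp(model, [r])[0] for r in probe]
        for rb, rs in zip(batch, singles):
            assert rb.score == pytest.approx(rs.score, abs=1e-12)

    def test_too_short_record_yields_error_entry_and_run_continues(self, small_dataset):
        model = train_enacp(small_dataset, config=self.CONFIG, seed=1)
        probe = [PeptideRecord("ok", "ACDKFWYLMP"),
                 PeptideRecord("short", "ACD"),  # L <= lambda for PseAAC
                 PeptideRecord("ok2", "KKKKKKKKKK")]
        results = predict_enacp(model, probe)
        assert [r.id for r in results] == ["ok", "short", "ok2"]
        assert results[1].error is not None and results[1].score is None
        assert results[0].score is not None and results[2].score is not None

    def test_profile_bank_requires_matching_pssms(self, small_dataset):
        pssms = generate_pssm_set(small_dataset, seed=3)
        config = {"encoders": ["kmer", "top_n_gram"],
                  "svm_grid": {"C": [1.0], "gamma": [0.1]}}
        model = train_enacp(small_dataset, config=config, seed=0,
                            pssms=pssms)
        assert model.bank.k == 2
        probe = small_dataset.records[:3]
        results = predict_enacp(model, probe, pssms)
        assert all(r.error is None for r in results)
        # without profiles every record errors out
        results = predict_enacp(model, probe, None)
        assert all(r.error is not None for r in results)


class TestStackingProperties:
    def test_stacking_preserves_a_good_channel(self, small_dataset):
        # with one informative encoder, the stack's CV AUC must not fall
        # more than 0.02 below that encoder's own CV AUC
        bank = build_encoder_bank(["kmer"])
        mats = encode_bank_matrices(bank, small_dataset.records)
        single = cross_val_scores(small_dataset, bank, matrices=mats, seed=9,
                                  svm_grid={"C": [1.0], "gamma": [0.25]})
        auc_single = roc_auc(single, small_dataset.labels)
        bank2 = build_encoder_bank(["kmer", "ac"])
        mats2 = encode_bank_matrices(bank2, small_dataset.records)
        stacked = cross_val_scores(small_dataset, bank2, matrices=mats2, seed=9,
                                   svm_grid={"C": [1.0], "gamma": [0.25]})
        auc_stacked = roc_auc(stacked, small_dataset.labels)
        assert auc_stacked >= auc_single - 0.02
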