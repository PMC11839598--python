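"""Selection strategies, synthetic-patient composition, dataset assembly."""

import dataclasses

import numpy as np
import pytest

from metaug.augment import (
    KFMFConfig,
    assemble_augmented_dataset,
    compose_synthetic_patients,
    generated_sample_count,
    kfmf_folds,
    replicate_minority_patient,
    select_by_kfmf,
    select_by_length,
    select_minority,
    select_vanilla,
)
from metaug.corpus import Corpus, Patient
from metaug.errors import ConfigurationError, InputError, IntegrityError
from metaug.paraphrase import SyntheticReportSet

from conftest import make_patient, make_report


def words(n: int) -> str:
    return " ".join(["word"] * n)


def variant_set(report, n: int) -> SyntheticReportSet:
    variants = [
        dataclasses.replace(
            report,
            report_id=f"{report.report_id}::syn{k}",
            impression=f"{report.impression} variant {k}",
            provenance="synthetic",
            source_report_id=report.report_id,
        )
        for k in range(n)
    ]
    return SyntheticReportSet(report.report_id, variants)


class TestVanillaAndLength:
    def test_vanilla_selects_everything(self):
        p = make_patient("x-p1", [(words(3), 0), (words(30), 1)])
        sel = select_vanilla(p.reports)
        assert sel.selected_report_ids == {r.report_id for r in p.reports}
        assert sel.strategy == "vanilla"

    def test_length_threshold_inclusive_at_20(self):
        lengths = [5, 10, 15, 19, 20, 21, 40, 60, 80, 120]
        reports = [
            make_report("x-p1", i, words(n), 0) for i, n in enumerate(lengths)
        ]
        sel = select_by_length(reports)
        # [DERIVED by hand: lengths >= 20 are {20, 21, 40, 60, 80, 120}]
        assert len(sel) == 6
        chosen_lengths = sorted(
            r.word_count for r in reports if r.report_id in sel.selected_report_ids
        )
        assert chosen_lengths == [20, 21, 40, 60, 80, 120]

    def test_length_custom_threshold(self):
        reports = [make_report("x-p1", i, words(n), 0) for i, n in enumerate([4, 5, 6])]
        sel = select_by_length(reports, min_words=5)
        assert len(sel) == 2

    def test_length_invalid_threshold(self):
        with pytest.raises(ConfigurationError):
            select_by_length([], min_words=0)


class TestKFMF:
    def _corpus(self, n=12):
        patients = [
            make_patient(f"x-p{i:03d}", [(words(6), i % 2), (words(6), 0)])
            for i in range(n)
        ]
        return Corpus(patients)

    def test_folds_partition_patients(self):
        corpus = self._corpus(11)
        folds = kfmf_folds(corpus.patients, k=5, seed=3)
        assert len(folds) == 5
        ids = [p.patient_id for f in folds for p in f]
        assert sorted(ids) == sorted(p.patient_id for p in corpus.patients)
        sizes = sorted(len(f) for f in folds)
        assert sizes == [2, 2, 2, 2, 3]

    def test_folds_deterministic(self):
        corpus = self._corpus(10)
        a = kfmf_folds(corpus.patients, 5, seed=1)
        b = kfmf_folds(corpus.patients, 5, seed=1)
        assert [[p.patient_id for p in f] for f in a] == [
            [p.patient_id for p in f] for f in b
        ]

    def test_k_larger_than_patients_rejected(self):
        corpus = self._corpus(3)
        with pytest.raises(ConfigurationError):
            kfmf_folds(corpus.patients, 5, seed=0)

    def test_always_negative_stub_selects_exactly_positive_reports(self):
        corpus = self._corpus(10)

        def trainer(_rest, _seed):
            return lambda patient: np.zeros(len(patient.reports))

        sel = select_by_kfmf(corpus, KFMFConfig(seed=0), trainer)
        expected = {r.report_id for r in corpus.reports() if r.label == 1}
        assert sel.selected_report_ids == expected
        assert sum(sel.diagnostics["misclassified_per_fold"]) == len(expected)

    def test_oracle_stub_selects_nothing(self):
        corpus = self._corpus(10)

        def trainer(_rest, _seed):
            return lambda patient: np.array([float(lab) for lab in patient.labels])

        sel = select_by_kfmf(corpus, KFMFConfig(seed=0), trainer)
        assert sel.selected_report_ids == set()

    def test_brute_force_fold_oracle(self):
        """Recompute the selection independently from the fold partition and a
        deterministic hash-based stub predictor."""
        corpus = self._corpus(13)
        cfg = KFMFConfig(k=4, seed=9)

        def prob(report_id: str) -> float:
            return (hash(report_id) % 1000) / 1000.0

        def trainer(_rest, _seed):
            return lambda patient: np.array([prob(r.report_id) for r in patient.reports])

        sel = select_by_kfmf(corpus, cfg, trainer)

        expected = set()
        for fold in kfmf_folds(corpus.patients, cfg.k, cfg.seed):
            for p in fold:
                for r in p.reports:
                    if int(prob(r.report_id) >= 0.5) != r.label:
                        expected.add(r.report_id)
        assert sel.selected_report_ids == expected

    def test_wrong_length_predictor_rejected(self):
        corpus = self._corpus(10)

        def trainer(_rest, _seed):
            return lambda patient: np.zeros(1)

        with pytest.raises(InputError):
            select_by_kfmf(corpus, KFMFConfig(seed=0), trainer)


class TestMinority:
    def test_replication_factor_frozen_example(self):
        # [DERIVED by hand: 930 negative / 70 positive reports ->
        #  round(930/70) - 1 = round(13.286) - 1 = 13 - 1 = 12]
        patients = [
            make_patient(f"n-p{i:03d}", [(words(4), 0)] * 10) for i in range(93)
        ] + [make_patient(f"y-p{i:03d}", [(words(4), 1)] * 10) for i in range(7)]
        sel = select_minority(Corpus(patients))
        assert sel.replication_factor == 12
        assert sel.diagnostics == {"n_positive": 70, "n_negative": 930}

    def test_majority_positive_patients_selected_inclusive_half(self):
        half = make_patient("h-p1", [(words(4), 1), (words(4), 0)])
        minor = make_patient("m-p1", [(words(4), 0), (words(4), 0), (words(4), 1)])
        sel = select_minority(Corpus([half, minor]))
        assert sel.selected_report_ids == {r.report_id for r in half.reports}

    def test_balanced_corpus_factor_zero(self):
        patients = [make_patient("b-p1", [(words(4), 0), (words(4), 1)])]
        sel = select_minority(Corpus(patients))
        assert sel.replication_factor == 0


class TestGeneratedSampleCount:
    def test_vanilla_count(self):
        sel = select_vanilla(
            [make_report("x-p1", i, words(3), 0) for i in range(7)]
        )
        assert generated_sample_count(sel, n_variants=10) == 70

    def test_minority_includes_replicas(self):
        patients = [
            make_patient("n-p1", [(words(4), 0)] * 6),
            make_patient("y-p1", [(words(4), 1)] * 2),
        ]
        sel = select_minority(Corpus(patients))
        # [DERIVED by hand: round(6/2) - 1 = 2 replicas; 2 selected reports;
        #  N=3 variants -> 3*2 + 2*2 = 10]
        assert sel.replication_factor == 2
        assert generated_sample_count(sel, n_variants=3) == 10


class TestCompose:
    def _patient(self):
        return make_patient(
            "liver-p00007",
            [(words(25), 0), (words(25), 1), (words(25), 0)],
        )

    def test_uniform_sets_use_every_variant_exactly_once(self):
        patient = self._patient()
        sets = {i: variant_set(r, 2) for i, r in enumerate(patient.reports)}
        out = compose_synthetic_patients(patient, sets, seed=0)
        assert len(out) == 2
        placed_sources = [
            r.report_id.split("@")[0] for p in out for r in p.reports
        ]
        all_variants = [v.report_id for s in sets.values() for v in s.variants]
        assert sorted(placed_sources) == sorted(all_variants)
        for j, p in enumerate(out):
            assert p.patient_id == f"liver-p00007::syn{j}"
            assert [r.position for r in p.reports] == [0, 1, 2]
            assert [r.label for r in p.reports] == [0, 1, 0]
            assert [r.date for r in p.reports] == [
                r.date for r in patient.reports
            ]

    def test_ragged_sets_fall_back_to_copy_and_replacement(self):
        patient = self._patient()
        sets = {
            0: variant_set(patient.reports[0], 2),
            1: SyntheticReportSet(patient.reports[1].report_id, []),
            2: variant_set(patient.reports[2], 3),
        }
        out = compose_synthetic_patients(patient, sets, seed=1)
        assert len(out) == 3
        for p in out:
            # empty slot 1 -> verbatim original copy
            mid = p.reports[1]
            assert mid.provenance == "original"
            assert mid.impression == patient.reports[1].impression
            assert mid.report_id.split("@")[0] == patient.reports[1].report_id
        # slot 0 has only 2 variants for 3 patients: the first two synthetic
        # patients take the permutation, the third a draw with replacement
        slot0_sources = [p.reports[0].report_id.split("@")[0] for p in out]
        pool0 = {v.report_id for v in sets[0].variants}
        assert set(slot0_sources[:2]) == pool0
        assert slot0_sources[2] in pool0
        # slot 2 uses each of its 3 variants exactly once
        slot2_sources = sorted(p.reports[2].report_id.split("@")[0] for p in out)
        assert slot2_sources == sorted(v.report_id for v in sets[2].variants)

    def test_all_empty_sets_yield_no_patients(self):
        patient = self._patient()
        sets = {
            i: SyntheticReportSet(r.report_id, []) for i, r in enumerate(patient.reports)
        }
        assert compose_synthetic_patients(patient, sets, seed=0) == []

    def test_missing_position_rejected(self):
        patient = self._patient()
        sets = {0: variant_set(patient.reports[0], 2)}
        with pytest.raises(InputError):
            compose_synthetic_patients(patient, sets, seed=0)

    def test_deterministic_in_seed(self):
        patient = self._patient()
        sets = {i: variant_set(r, 4) for i, r in enumerate(patient.reports)}
        a = compose_synthetic_patients(patient, sets, seed=5)
        b = compose_synthetic_patients(patient, sets, seed=5)
        assert [[r.report_id for r in p.reports] for p in a] == [
            [r.report_id for r in p.reports] for p in b
        ]


class TestReplicateMinority:
    def test_round_robin_over_variants(self):
        patient = make_patient("y-p1", [(words(25), 1), (words(25), 1)])
        sets = {
            0: variant_set(patient.reports[0], 2),
            1: SyntheticReportSet(patient.reports[1].report_id, []),
        }
        out = replicate_minority_patient(patient, sets, n_replicas=3)
        assert [p.patient_id for p in out] == [
            "y-p1::rep0",
            "y-p1::rep1",
            "y-p1::rep2",
        ]
        v0, v1 = (v.report_id for v in sets[0].variants)
        slot0 = [p.reports[0].report_id.split("@")[0] for p in out]
        assert slot0 == [v0, v1, v0]
        for p in out:
            assert p.reports[1].provenance == "original"

    def test_zero_replicas(self):
        patient = make_patient("y-p1", [(words(5), 1)])
        assert replicate_minority_patient(patient, {}, 0) == []


class TestAssemble:
    def test_provenance_index_traces_to_train(self):
        patient = make_patient("liver-p00001", [(words(25), 0), (words(25), 1)])
        train = Corpus([patient])
        sets = {i: variant_set(r, 2) for i, r in enumerate(patient.reports)}
        syn = compose_synthetic_patients(patient, sets, seed=0)
        ds = assemble_augmented_dataset(train, syn)
        assert ds.n_patients == 3
        train_ids = {r.report_id for r in patient.reports}
        assert set(ds.provenance_index.values()) <= train_ids
        assert len(ds.provenance_index) == sum(len(p.reports) for p in syn)

    def test_foreign_synthetic_report_rejected(self):
        patient = make_patient("liver-p00001", [(words(25), 0)])
        stray = make_patient("other-p9", [(words(25), 1)])
        stray_syn = compose_synthetic_patients(
            stray, {0: variant_set(stray.reports[0], 1)}, seed=0
        )
        with pytest.raises(IntegrityError):
            assemble_augmented_dataset(Corpus([patient]), stray_syn)
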