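import numpy as np
import pytest

from tcmrules import synth
from tcmrules.preprocess import remove_shared_symptoms
from tcmrules.records import CONSTITUTIONS, Role
from tcmrules.synth import GeneratorConfig, generate, plant_check, preset_config


class TestGeneratorConfig:
    def test_defaults_valid(self):
        GeneratorConfig(n_records=10).validate()

    def test_bad_prevalence_listed(self):
        config = GeneratorConfig(n_records=1, prevalence=(0.5, 0.5))
        with pytest.raises(ValueError, match="prevalence"):
            config.validate()

    def test_prevalence_must_sum_to_one(self):
        config = GeneratorConfig(n_records=1, prevalence=tuple([0.2] * 9))
        with pytest.raises(ValueError, match="sum to 1"):
            config.validate()

    def test_bad_rate_listed(self):
        config = GeneratorConfig(n_records=1, shared_symptom_rate=1.5)
        with pytest.raises(ValueError, match="shared_symptom_rate"):
            config.validate()

    def test_multiple_violations_all_reported(self):
        config = GeneratorConfig(n_records=-1, stopword_rate=-0.5)
        with pytest.raises(ValueError) as err:
            config.validate()
        assert "n_records" in str(err.value) and "stopword_rate" in str(err.value)


class TestGenerate:
    def test_zero_records(self):
        records, truth = generate(GeneratorConfig(n_records=0))
        assert records == []
        assert len(truth.planted_rules) == 9

    def test_degenerate_prevalence_single_class(self):
        prevalence = tuple([1.0] + [0.0] * 8)
        records, _ = generate(GeneratorConfig(n_records=50, prevalence=prevalence,
                                              label_noise_rate=0.0))
        assert all(rec.primary_constitution.token == "BC" for rec in records)

    def test_record_count(self):
        records, _ = generate(GeneratorConfig(n_records=137, seed=2))
        assert len(records) == 137
        assert len({rec.record_id for rec in records}) == 137

    def test_deterministic_from_seed(self):
        config = GeneratorConfig(n_records=100, seed=42)
        r1, t1 = generate(config)
        r2, t2 = generate(config)
        assert r1 == r2
        assert t1 == t2

    def test_different_seed_different_corpus(self):
        r1, _ = generate(GeneratorConfig(n_records=100, seed=1))
        r2, _ = generate(GeneratorConfig(n_records=100, seed=2))
        assert r1 != r2

    def test_class_frequencies_within_three_standard_errors(self):
        n = 10_000
        records, _ = generate(GeneratorConfig(n_records=n, seed=0))
        p = 1.0 / 9
        se = (p * (1 - p) / n) ** 0.5
        for label in CONSTITUTIONS:
            freq = sum(rec.primary_constitution.token == label
                       for rec in records) / n
            assert abs(freq - p) <= 3 * se

    def test_cores_always_present_in_class(self):
        records, truth = generate(preset_config("noise_free", 300, seed=4))
        for rec in records:
            label = rec.primary_constitution.token
            tokens = {s.token for s in rec.symptoms}
            assert set(truth.core_symptoms[label]) <= tokens

    def test_typical_sets_disjoint_outside_shared_pool(self):
        _, truth = generate(GeneratorConfig(n_records=1))
        seen: dict[str, str] = {}
        for label, symptoms in truth.typical_symptoms.items():
            for token in symptoms:
                assert token not in truth.shared_pool
                assert token not in seen, f"{token} in both {seen.get(token)} and {label}"
                seen[token] = label

    def test_regimen_follows_label(self):
        records, truth = generate(GeneratorConfig(n_records=80, seed=6))
        for rec in records:
            expected = set(truth.regimen_map[rec.primary_constitution.token])
            assert {i.token for i in rec.regimen} == expected

    def test_invalid_config_raises_on_generate(self):
        with pytest.raises(ValueError):
            generate(GeneratorConfig(n_records=-3))


class TestPlantCheck:
    def test_noise_free_confidence_one(self):
        records, truth = generate(preset_config("noise_free", 500, seed=8))
        report = plant_check(records, truth, min_support_count=10, min_confidence=0.9)
        for entry in report["rules"]:
            assert entry["confidence"] == 1.0
            assert entry["clears_thresholds"]

    def test_below_threshold_flagged(self):
        records, truth = generate(preset_config("noise_free", 30, seed=8))
        report = plant_check(records, truth, min_support_count=10_000,
                             min_confidence=0.9)
        assert not any(entry["clears_thresholds"] for entry in report["rules"])

    def test_support_matches_brute_scan(self):
        records, truth = generate(GeneratorConfig(n_records=200, seed=10,
                                                  label_noise_rate=0.1))
        report = plant_check(records, truth, 1, 0.0)
        for entry in report["rules"]:
            ant = set(entry["antecedent"])
            expected = sum(
                1 for rec in records
                if ant <= {s.token for s in rec.symptoms}
                and rec.primary_constitution.token == entry["constitution"])
            assert entry["support_count"] == expected


def test_shared_pool_removed_exactly_by_preprocess():
    config = GeneratorConfig(n_records=2000, seed=12, shared_symptom_rate=0.4,
                             stopword_rate=0.0, label_noise_rate=0.0)
    records, truth = generate(config)
    filtered, report = remove_shared_symptoms(records, min_discriminability=0.8,
                                              min_occurrences=2)
    removed = {d["symptom"] for d in report["removed"]}
    assert removed == set(truth.shared_pool)
    for rec in filtered:
        assert not ({s.token for s in rec.symptoms} & set(truth.shared_pool))


def test_paper_like_preset_concentrates_three_classes():
    config = preset_config("paper_like", 2000, seed=1)
    config.validate()
    records, _ = generate(config)
    labels = {rec.primary_constitution.token for rec in records}
    assert labels <= {"BC", "DHC", "ISC"}


def test_unknown_preset_errors():
    with pytest.raises(ValueError, match="preset"):
        preset_config("bogus", 10)


def test_noise_free_perfect_recovery_end_to_end():
    from tcmrules.evaluate import cross_validate
    records, truth = generate(preset_config("noise_free", 450, seed=13))
    report = plant_check(records, truth, min_support_count=5, min_confidence=0.6)
    assert all(e["clears_thresholds"] for e in report["rules"])
    result = cross_validate(records, k=3, seed=0,
                            min_support_count=5, min_confidence=0.6)
    assert result.mean_precision == 1.0
    assert result.mean_recall == 1.0
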