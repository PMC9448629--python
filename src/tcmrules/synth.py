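"""Seeded generator of constitution-labeled record corpora with planted
symptom⇒constitution⇒regimen structure.

Each constitution owns a typical-symptom vocabulary (seeded from published
symptom phrasing, padded with systematic tokens); the first ``n_core_symptoms``
of each vocabulary are planted in every record of that class, so the
(core symptoms) ⇒ constitution rule is recoverable by design.  Noise knobs:
a cross-constitution shared-symptom pool, stop-word contamination, and label
noise.  Identical configs produce bit-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from .records import CONSTITUTIONS, Item, MedicalRecord, Role

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PlantedRule",
    "generate",
    "plant_check",
    "preset_config",
    "PRESETS",
]

# Per-class typical symptom phrases (class-unique by construction; phrases
# that recur across classes in the source vocabulary live in the shared pool).
_TYPICAL_PHRASES: dict[str, tuple[str, ...]] = {
    "BC": ("thin white moss", "ruddy complexion", "dense and shiny hair", "energetic"),
    "YADC": ("fat and tender tongue", "dark lips", "thin hair", "fat and soft muscle", "chilly"),
    "YIDC": ("red tongue", "flushed face", "dry mouth and throat", "pulse breakdown"),
    "QDC": ("pulse weak", "pale face", "easy fatigue"),
    "QSC": ("unstable introversion", "sensitive and anxious", "depressed", "insomniac"),
    "PDC": ("sticky mouth and greasy moss", "oil and sweet skin", "somnolent and lethargic",
            "fat and soft belly", "edema eyes"),
    "DHC": ("easily upset and irritable", "lethargic", "prone to acne"),
    "BSC": ("blue and purple lip", "rough and dark skin", "irritability and forgetfulness",
            "easy itchy and achy", "yellow hair"),
    "ISC": ("prone to be allergic", "poor immunity", "easy to urticaria",
            "easy to allergic rhinitis", "easy to asthma", "easy to skin desquamation"),
}

#: Symptoms deliberately shared across constitutions (the designed "noise").
SHARED_POOL: tuple[str, ...] = ("pale red tongue", "black eyes", "fat or thin")

_STOPWORD_SAMPLE: tuple[str, ...] = ("this", "and", "or", "very", "the", "he/she/it")

#: One hand-written regimen per class (first regimen item); extras are systematic.
_REGIMEN_SEED: dict[str, str] = {
    "BC": "maintain balanced diet and exercise",
    "YADC": "warm the yang and avoid cold food",
    "YIDC": "nourish yin and reduce dryness",
    "QDC": "tonify qi and rest adequately",
    "QSC": "soothe the liver and regulate qi",
    "PDC": "eliminate phlegm and remove dampness",
    "DHC": "clear heat and drain dampness",
    "BSC": "promote blood circulation and remove stasis",
    "ISC": "avoid allergens and strengthen immunity",
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_records: int
    prevalence: tuple = tuple([1.0 / 9] * 9)  # aligned with CONSTITUTIONS
    symptoms_per_constitution: int = 20
    symptoms_per_record: tuple = (3, 8)
    shared_symptom_rate: float = 0.1
    stopword_rate: float = 0.1
    regimen_items_per_constitution: int = 2
    label_noise_rate: float = 0.0
    n_core_symptoms: int = 2
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` listing every violated invariant."""
        problems = []
        if self.n_records < 0:
            problems.append("n_records must be >= 0")
        if len(self.prevalence) != len(CONSTITUTIONS):
            problems.append(f"prevalence must have {len(CONSTITUTIONS)} entries")
        elif any(p < 0 for p in self.prevalence):
            problems.append("prevalence entries must be >= 0")
        elif abs(sum(self.prevalence) - 1.0) > 1e-9:
            problems.append("prevalence must sum to 1 within 1e-9")
        for name in ("shared_symptom_rate", "stopword_rate", "label_noise_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{name} must lie in [0, 1]")
        lo, hi = self.symptoms_per_record
        if not (1 <= lo <= hi):
            problems.append("symptoms_per_record must be a range 1 <= lo <= hi")
        if self.symptoms_per_constitution < 1:
            problems.append("symptoms_per_constitution must be >= 1")
        if self.regimen_items_per_constitution < 1:
            problems.append("regimen_items_per_constitution must be >= 1")
        if not (1 <= self.n_core_symptoms <= self.symptoms_per_constitution):
            problems.append("n_core_symptoms must lie in [1, symptoms_per_constitution]")
        if problems:
            raise ValueError("invalid generator config: " + "; ".join(problems))


class PlantedRule(NamedTuple):
    antecedent: tuple  # symptom tokens
    constitution: str
    regimen: tuple  # regimen tokens
    design_confidence: float


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted — the oracle for recovery experiments."""

    typical_symptoms: dict  # label -> tuple of tokens
    core_symptoms: dict  # label -> tuple of tokens (always present in-class)
    shared_pool: tuple
    regimen_map: dict  # label -> tuple of tokens
    planted_rules: tuple  # tuple[PlantedRule, ...]
    config: GeneratorConfig


def _build_vocabulary(config: GeneratorConfig) -> dict:
    vocab = {}
    for label in CONSTITUTIONS:
        phrases = list(_TYPICAL_PHRASES[label])
        k = 0
        while len(phrases) < config.symptoms_per_constitution:
            phrases.append(f"s_{label.lower()}_{k}")
            k += 1
        vocab[label] = tuple(phrases[: config.symptoms_per_constitution])
    return vocab


def _build_regimens(config: GeneratorConfig) -> dict:
    out = {}
    for label in CONSTITUTIONS:
        items = [_REGIMEN_SEED[label]]
        for k in range(1, config.regimen_items_per_constitution):
            items.append(f"regimen_{label.lower()}_{k}")
        out[label] = tuple(items)
    return out


def generate(config: GeneratorConfig) -> tuple[list[MedicalRecord], GroundTruth]:
    """Draw a corpus from the config; fully reproducible from its seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    vocab = _build_vocabulary(config)
    regimens = _build_regimens(config)
    cores = {label: v[: config.n_core_symptoms] for label, v in vocab.items()}
    planted = tuple(
        PlantedRule(cores[label], label, regimens[label],
                    1.0 - config.label_noise_rate)
        for label in CONSTITUTIONS
    )
    truth = GroundTruth(vocab, cores, SHARED_POOL, regimens, planted, config)

    prevalence = np.asarray(config.prevalence, dtype=float)
    prevalence = prevalence / prevalence.sum()
    lo, hi = config.symptoms_per_record
    records: list[MedicalRecord] = []
    for i in range(config.n_records):
        ci = int(rng.choice(len(CONSTITUTIONS), p=prevalence))
        true_label = CONSTITUTIONS[ci]
        label = true_label
        if config.label_noise_rate > 0 and rng.random() < config.label_noise_rate:
            others = [c for c in CONSTITUTIONS if c != true_label]
            label = others[int(rng.integers(len(others)))]
        n_sym = max(int(rng.integers(lo, hi + 1)), config.n_core_symptoms)
        tokens = list(cores[true_label])
        pool = [t for t in vocab[true_label] if t not in tokens]
        n_extra = min(n_sym - len(tokens), len(pool))
        if n_extra > 0:
            tokens.extend(rng.choice(pool, size=n_extra, replace=False))
        if SHARED_POOL and rng.random() < config.shared_symptom_rate:
            tokens.append(SHARED_POOL[int(rng.integers(len(SHARED_POOL)))])
        if rng.random() < config.stopword_rate:
            tokens.append(_STOPWORD_SAMPLE[int(rng.integers(len(_STOPWORD_SAMPLE)))])
        records.append(MedicalRecord(
            record_id=f"r{i:06d}",
            symptoms=frozenset(Item(t, Role.SYMPTOM) for t in tokens),
            primary_constitution=Item(label, Role.CONSTITUTION),
            regimen=frozenset(Item(t, Role.REGIMEN) for t in regimens[label]),
        ))
    return records, truth


def plant_check(records: Sequence[MedicalRecord], ground_truth: GroundTruth,
                min_support_count: int, min_confidence: float) -> dict:
    """Empirical support/confidence of every planted rule, by brute scan.

    Reports whether each symptom⇒constitution rule clears the thresholds —
    used to calibrate recovery experiments before running the miner.
    """
    report = {"rules": [], "min_support_count": min_support_count,
              "min_confidence": min_confidence}
    for rule in ground_truth.planted_rules:
        ant = frozenset(Item(t, Role.SYMPTOM) for t in rule.antecedent)
        ant_support = sum(1 for rec in records if ant <= rec.symptoms)
        joint = sum(1 for rec in records
                    if ant <= rec.symptoms
                    and rec.primary_constitution.token == rule.constitution)
        confidence = joint / ant_support if ant_support else 0.0
        report["rules"].append({
            "antecedent": list(rule.antecedent),
            "constitution": rule.constitution,
            "support_count": joint,
            "antecedent_support": ant_support,
            "confidence": confidence,
            "design_confidence": rule.design_confidence,
            "clears_thresholds": joint >= min_support_count and confidence >= min_confidence,
        })
    return report


def _paper_like_prevalence() -> tuple:
    # mass concentrated on three classes, normalized to sum to 1
    weights = {"BC": 42.3, "DHC": 31.3, "ISC": 26.2}
    total = sum(weights.values())
    return tuple(weights.get(label, 0.0) / total for label in CONSTITUTIONS)


PRESETS = ("uniform", "paper_like", "noise_free")


def preset_config(name: str, n_records: int, seed: int = 0) -> GeneratorConfig:
    """Named configurations: ``uniform`` (default rates), ``noise_free``
    (all contamination rates zero), ``paper_like`` (prevalence concentrated
    on three classes)."""
    base = GeneratorConfig(n_records=n_records, seed=seed)
    if name == "uniform":
        return base
    if name == "noise_free":
        return replace(base, shared_symptom_rate=0.0, stopword_rate=0.0,
                       label_noise_rate=0.0)
    if name == "paper_like":
        return replace(base, prevalence=_paper_like_prevalence())
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESETS}")
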