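"""The two-stage training/classification pipeline.

Stage 1 mines two rule bases from the corpus: symptom-set ⇒ constitution and
constitution ⇒ regimen-item.  Stage 2 links them on the shared constitution,
with a chain score equal to the product of the two confidences.  New symptom
sets are classified by summing the confidences of every symptom-rule whose
antecedent is contained in the query (monotone, auditable); regimens are
recommended from the constitution-rule base by confidence then support.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import preprocess
from .parallel import mine_parallel
from .records import CONSTITUTIONS, Item, MedicalRecord, Role, to_transactions
from .rules import AssociationRule, generate_rules

__all__ = [
    "RuleBase",
    "LinkedRule",
    "Prediction",
    "train",
    "link",
    "classify",
    "recommend",
    "save_rulebase",
    "load_rulebase",
]

SCORING_MODES = ("confidence_sum", "max_confidence", "support_weighted")


@dataclass
class RuleBase:
    """Stage-1 rule stores plus the parameters they were trained under."""

    stage1_sc: list  # symptom-only antecedent ⇒ single constitution
    stage1_cr: list  # single constitution ⇒ single regimen item
    parameters: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LinkedRule:
    """symptoms ⇒ constitution ⇒ regimen item, scored by confidence product."""

    symptoms: frozenset
    constitution: Item
    regimen_item: Item
    chain_score: float


@dataclass
class Prediction:
    """Constitutions ranked by score; ``predicted`` holds top-1 plus every
    label scoring at least ``multi_label_fraction`` of the top score."""

    scores: list  # [(label token, score)] sorted score desc, token asc
    predicted: list  # label tokens

    @property
    def top1(self) -> str | None:
        return self.scores[0][0] if self.scores else None


def train(records: Sequence[MedicalRecord],
          min_support_count: int = 20,
          min_confidence: float = 0.6,
          *,
          stoplist: preprocess.StopList | None = None,
          min_discriminability: float = 0.8,
          min_occurrences: int = 2,
          remove_shared: bool = True,
          n_shards: int = 1,
          n_groups: int = 9,
          executor: str = "serial",
          include_secondary: bool = False) -> RuleBase:
    """Preprocess, mine both projections, and build the stage-1 rule bases.

    Raises on an empty corpus; empty rule bases (thresholds excluding
    everything) produce a warning, not an error.
    """
    if not records:
        raise ValueError("cannot train on an empty corpus")
    cleaned = preprocess.remove_stopword_symptoms(records, stoplist)
    noise_report: dict = {}
    if remove_shared:
        cleaned, noise_report = preprocess.remove_shared_symptoms(
            cleaned, min_discriminability, min_occurrences)

    sc_tx = to_transactions(cleaned, "symptom_constitution",
                            include_secondary=include_secondary)
    cr_tx = to_transactions(cleaned, "constitution_regimen",
                            include_secondary=include_secondary)

    sc_itemsets = mine_parallel(sc_tx, min_support_count, n_shards, n_groups, executor)
    cr_itemsets = mine_parallel(cr_tx, min_support_count, n_shards, n_groups, executor)

    sc_rules = [
        r for r in generate_rules(sc_itemsets, min_confidence,
                                  consequent_role=Role.CONSTITUTION,
                                  n_transactions=len(sc_tx))
        if len(r.consequent) == 1
        and all(i.role is Role.SYMPTOM for i in r.antecedent)
    ]
    cr_rules = [
        r for r in generate_rules(cr_itemsets, min_confidence,
                                  consequent_role=Role.REGIMEN,
                                  n_transactions=len(cr_tx))
        if len(r.consequent) == 1
        and len(r.antecedent) == 1
        and next(iter(r.antecedent)).role is Role.CONSTITUTION
    ]
    if not sc_rules:
        warnings.warn("stage-1 symptom⇒constitution rule base is empty at these thresholds")
    if not cr_rules:
        warnings.warn("stage-1 constitution⇒regimen rule base is empty at these thresholds")

    params = {
        "min_support_count": min_support_count,
        "min_confidence": min_confidence,
        "min_discriminability": min_discriminability,
        "min_occurrences": min_occurrences,
        "remove_shared": remove_shared,
        "n_shards": n_shards,
        "n_groups": n_groups,
        "executor": executor,
        "include_secondary": include_secondary,
        "n_records": len(records),
        "removed_shared_symptoms": [d["symptom"] for d in noise_report.get("removed", [])],
        "vocabulary_hash": _vocabulary_hash(cleaned),
    }
    return RuleBase(sc_rules, cr_rules, params)


def _vocabulary_hash(records: Iterable[MedicalRecord]) -> str:
    vocab = sorted({i.token for rec in records for i in rec.symptoms}
                   | {rec.primary_constitution.token for rec in records})
    return hashlib.sha256("\n".join(vocab).encode()).hexdigest()[:16]


def link(rulebase: RuleBase) -> list[LinkedRule]:
    """Cross-join the two stage-1 bases on the shared constitution."""
    by_constitution: dict[Item, list[AssociationRule]] = {}
    for r in rulebase.stage1_cr:
        (c,) = r.antecedent
        by_constitution.setdefault(c, []).append(r)
    linked = []
    for sc in rulebase.stage1_sc:
        (c,) = sc.consequent
        for cr in by_constitution.get(c, ()):
            (reg,) = cr.consequent
            linked.append(LinkedRule(sc.antecedent, c, reg,
                                     sc.confidence * cr.confidence))
    linked.sort(key=lambda lr: (-lr.chain_score, lr.constitution.token,
                                lr.regimen_item.token,
                                tuple(sorted(i.token for i in lr.symptoms))))
    return linked


def classify(symptoms: Iterable[Item], rulebase: RuleBase,
             multi_label_fraction: float = 0.5,
             scoring: str = "confidence_sum") -> Prediction:
    """Score each constitution over the matching symptom-rules and rank.

    ``confidence_sum`` (default) sums rule confidences; ``max_confidence``
    takes the best matching rule; ``support_weighted`` weights confidence by
    the rule's support fraction.  No matching rule ⇒ empty prediction.
    """
    if scoring not in SCORING_MODES:
        raise ValueError(f"unknown scoring {scoring!r}; expected one of {SCORING_MODES}")
    query = frozenset(symptoms)
    scores: dict[str, float] = {}
    for r in rulebase.stage1_sc:
        if r.antecedent <= query:
            (c,) = r.consequent
            if scoring == "confidence_sum":
                scores[c.token] = scores.get(c.token, 0.0) + r.confidence
            elif scoring == "max_confidence":
                scores[c.token] = max(scores.get(c.token, 0.0), r.confidence)
            else:
                w = r.confidence * (r.support_fraction or 0.0)
                scores[c.token] = scores.get(c.token, 0.0) + w
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if not ranked:
        return Prediction([], [])
    cutoff = multi_label_fraction * ranked[0][1]
    predicted = [tok for tok, s in ranked if s >= cutoff]
    return Prediction(ranked, predicted)


def recommend(constitution: Item | str, rulebase: RuleBase,
              top_k: int = 3) -> list[AssociationRule]:
    """Top-k regimen rules for a constitution, by confidence then support."""
    if isinstance(constitution, str):
        constitution = Item(constitution, Role.CONSTITUTION)
    if constitution.token not in CONSTITUTIONS:  # pragma: no cover - Item validates
        raise ValueError(f"unknown constitution label {constitution.token!r}")
    matching = [r for r in rulebase.stage1_cr if constitution in r.antecedent]
    matching.sort(key=lambda r: (-r.confidence, -r.support_count,
                                 next(iter(r.consequent)).token))
    return matching[:max(0, top_k)]


def _rule_to_obj(rule: AssociationRule) -> dict:
    return {
        "antecedent": sorted([i.token, i.role.value] for i in rule.antecedent),
        "consequent": sorted([i.token, i.role.value] for i in rule.consequent),
        "support_count": rule.support_count,
        "confidence": rule.confidence,
        "lift": rule.lift,
        "support_fraction": rule.support_fraction,
    }


def _rule_from_obj(obj: dict) -> AssociationRule:
    return AssociationRule(
        antecedent=frozenset(Item(t, Role(role)) for t, role in obj["antecedent"]),
        consequent=frozenset(Item(t, Role(role)) for t, role in obj["consequent"]),
        support_count=obj["support_count"],
        confidence=obj["confidence"],
        lift=obj.get("lift"),
        support_fraction=obj.get("support_fraction"),
    )


def save_rulebase(rulebase: RuleBase, path) -> None:
    """Serialize a trained rule base (rules + parameters) as one JSON document."""
    doc = {
        "parameters": rulebase.parameters,
        "stage1_sc": [_rule_to_obj(r) for r in rulebase.stage1_sc],
        "stage1_cr": [_rule_to_obj(r) for r in rulebase.stage1_cr],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_rulebase(path) -> RuleBase:
    with open(path) as fh:
        doc = json.load(fh)
    return RuleBase(
        [_rule_from_obj(o) for o in doc["stage1_sc"]],
        [_rule_from_obj(o) for o in doc["stage1_cr"]],
        doc.get("parameters", {}),
    )
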