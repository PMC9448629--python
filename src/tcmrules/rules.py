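"""Association-rule generation from a downward-closed frequent-itemset table.

Confidence is support(antecedent ∪ consequent) / support(antecedent).  Lift
is computed for reporting when the transaction count is known, but is never
used for filtering (support and confidence only).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

from .records import Item, Role

__all__ = ["AssociationRule", "generate_rules", "rules_to_csv", "rules_to_json"]


@dataclass(frozen=True)
class AssociationRule:
    """antecedent ⇒ consequent with the joint support count and confidence."""

    antecedent: frozenset
    consequent: frozenset
    support_count: int
    confidence: float
    lift: float | None = None
    support_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.antecedent or not self.consequent:
            raise ValueError("antecedent and consequent must be non-empty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must lie in [0, 1]")

    def sort_key(self):
        return (
            -self.confidence,
            -self.support_count,
            tuple(sorted(i.token for i in self.antecedent)),
            tuple(sorted(i.token for i in self.consequent)),
        )


def generate_rules(frequent_itemsets: Mapping[frozenset, int],
                   min_confidence: float,
                   consequent_role: Role | str | None = None,
                   n_transactions: int | None = None) -> list[AssociationRule]:
    """Emit every rule from every non-empty proper split of every itemset of
    size >= 2 whose confidence clears ``min_confidence``.

    ``consequent_role`` restricts output to rules whose consequent items all
    carry that role.  The itemset table must be downward-closed (as produced
    by the miners); a missing antecedent support raises ``ValueError``.
    Output is deterministically ordered (confidence desc, support desc,
    then token order).
    """
    if not (0.0 <= min_confidence <= 1.0):
        raise ValueError("min_confidence must lie in [0, 1]")
    if consequent_role is not None:
        consequent_role = Role(consequent_role)
    out: list[AssociationRule] = []
    for itemset, support in frequent_itemsets.items():
        if len(itemset) < 2:
            continue
        members = sorted(itemset)
        for k in range(1, len(members)):
            for consequent in combinations(members, k):
                cons = frozenset(consequent)
                if consequent_role is not None and any(
                        i.role is not consequent_role for i in cons):
                    continue
                ant = itemset - cons
                try:
                    ant_support = frequent_itemsets[ant]
                except KeyError:
                    raise ValueError(
                        f"itemset table is not downward-closed: missing support for "
                        f"{sorted(i.token for i in ant)}") from None
                confidence = support / ant_support
                if confidence < min_confidence:
                    continue
                lift = sf = None
                if n_transactions:
                    cons_support = frequent_itemsets.get(cons)
                    if cons_support:
                        lift = confidence / (cons_support / n_transactions)
                    sf = support / n_transactions
                out.append(AssociationRule(ant, cons, support, confidence, lift, sf))
    out.sort(key=AssociationRule.sort_key)
    return out


def _rule_row(rule: AssociationRule) -> dict:
    return {
        "antecedent": "|".join(sorted(i.token for i in rule.antecedent)),
        "consequent": "|".join(sorted(i.token for i in rule.consequent)),
        "support_count": rule.support_count,
        "support_fraction": rule.support_fraction,
        "confidence": rule.confidence,
        "lift": rule.lift,
    }


def rules_to_csv(rules: Sequence[AssociationRule], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(_rule_row(rules[0]).keys())
                                if rules else ["antecedent", "consequent",
                                               "support_count", "support_fraction",
                                               "confidence", "lift"])
        writer.writeheader()
        for rule in rules:
            writer.writerow(_rule_row(rule))


def rules_to_json(rules: Sequence[AssociationRule], path) -> None:
    with open(path, "w") as fh:
        json.dump([_rule_row(r) for r in rules], fh, indent=1)
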