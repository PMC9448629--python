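"""Independent oracles used across the suite.

These deliberately avoid the package's mining code paths: frequent itemsets
are found by exhaustive subset enumeration, supports and confidences by raw
scans over the transaction list.
"""

from __future__ import annotations

from itertools import combinations

from tcmrules.records import Item, Role


def brute_force_itemsets(transactions, min_support_count):
    """All itemsets with support >= threshold, by enumerating every subset of
    the observed item universe and counting containment per transaction."""
    universe = sorted(set().union(*transactions)) if transactions else []
    out = {}
    for k in range(1, len(universe) + 1):
        any_frequent = False
        for combo in combinations(universe, k):
            fs = frozenset(combo)
            support = sum(1 for t in transactions if fs <= t)
            if support >= min_support_count:
                out[fs] = support
                any_frequent = True
        if not any_frequent:
            break  # downward closure: no larger itemset can be frequent
    return out


def support_of(transactions, itemset):
    itemset = frozenset(itemset)
    return sum(1 for t in transactions if itemset <= t)


def confidence_of(transactions, antecedent, consequent):
    ant = support_of(transactions, antecedent)
    joint = support_of(transactions, frozenset(antecedent) | frozenset(consequent))
    return joint / ant if ant else 0.0


def random_db(rng, max_items=8, max_transactions=30):
    """A random small transaction database over single-letter symptom items."""
    n_items = int(rng.integers(1, max_items + 1))
    n_tx = int(rng.integers(1, max_transactions + 1))
    alphabet = [Item(chr(ord("a") + i), Role.SYMPTOM) for i in range(n_items)]
    db = []
    for _ in range(n_tx):
        size = int(rng.integers(1, n_items + 1))
        picks = rng.choice(n_items, size=size, replace=False)
        db.append(frozenset(alphabet[int(i)] for i in picks))
    return db
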