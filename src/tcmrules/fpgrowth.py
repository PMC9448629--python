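"""Single-machine FP-growth: F-list, FP-tree, conditional pattern bases and
recursive mining.

Support is an absolute transaction count.  The F-list orders frequent items
by descending support with ties broken by ascending token; transactions are
filtered and sorted by that order before insertion.  Mining recurses over
header items least-frequent-first, with the single-path shortcut enumerating
sub-combinations.  Internals work on integer F-list ranks for speed; the
public functions take and return :class:`~tcmrules.records.Item` sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, NamedTuple, Sequence

from .records import Item

__all__ = [
    "FList",
    "FPNode",
    "FPTree",
    "FrequentItemset",
    "build_flist",
    "build_tree",
    "conditional_pattern_base",
    "fp_growth",
    "min_support_from_fraction",
    "itemsets_to_csv",
]


class FrequentItemset(NamedTuple):
    items: frozenset
    support_count: int


def _sort_key(item: Item):
    # descending count is applied separately; token asc, then role, for ties
    return (item.token, item.role.value)


@dataclass(frozen=True)
class FList:
    """Frequent single items, ordered by (support desc, token asc)."""

    entries: tuple  # tuple[(Item, int), ...]

    def __post_init__(self) -> None:
        counts = [c for _, c in self.entries]
        if any(c2 > c1 for c1, c2 in zip(counts, counts[1:])):
            raise ValueError("F-list counts must be non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def items(self) -> tuple:
        return tuple(it for it, _ in self.entries)

    def rank(self) -> dict:
        """item -> position (0 = most frequent)."""
        return {it: r for r, (it, _) in enumerate(self.entries)}

    def support(self, item: Item) -> int:
        for it, c in self.entries:
            if it == item:
                return c
        raise KeyError(item)


def _tally(transactions: Iterable[frozenset]) -> dict:
    counts: dict[Item, int] = {}
    for t in transactions:
        for it in t:
            counts[it] = counts.get(it, 0) + 1
    return counts


def build_flist(transactions: Sequence[frozenset], min_support_count: int) -> FList:
    """Scan once, keep items with support >= threshold, order them."""
    if min_support_count < 1:
        raise ValueError("min_support_count must be >= 1")
    counts = _tally(transactions)
    kept = [(it, c) for it, c in counts.items() if c >= min_support_count]
    kept.sort(key=lambda e: (-e[1], _sort_key(e[0])))
    return FList(tuple(kept))


class FPNode:
    """Prefix-tree node; ``node_link`` chains nodes of the same item."""

    __slots__ = ("item", "count", "parent", "children", "node_link")

    def __init__(self, item, parent=None):
        self.item = item          # F-list rank (int) or None for the root
        self.count = 0
        self.parent = parent
        self.children: dict = {}
        self.node_link = None


class FPTree:
    """FP-tree over rank-encoded transactions with per-item header chains.

    ``flist`` is attached by :func:`build_tree` so item-level accessors
    (e.g. :func:`conditional_pattern_base`) can translate ranks back.
    """

    def __init__(self, n_items: int, flist: "FList | None" = None):
        self.root = FPNode(None)
        self.header: list[FPNode | None] = [None] * n_items
        self._tails: list[FPNode | None] = [None] * n_items
        self.flist = flist

    def insert(self, ranked: Sequence[int], count: int = 1) -> None:
        """Insert a rank-sorted transaction, accumulating shared-prefix counts."""
        node = self.root
        for r in ranked:
            child = node.children.get(r)
            if child is None:
                child = FPNode(r, parent=node)
                node.children[r] = child
                if self.header[r] is None:
                    self.header[r] = child
                else:
                    self._tails[r].node_link = child  # type: ignore[union-attr]
                self._tails[r] = child
            child.count += count
            node = child

    def chain(self, rank: int):
        node = self.header[rank]
        while node is not None:
            yield node
            node = node.node_link

    def chain_support(self, rank: int) -> int:
        return sum(node.count for node in self.chain(rank))

    def single_path(self) -> list | None:
        """The root-to-leaf path if the tree is one branch, else None."""
        path = []
        node = self.root
        while node.children:
            if len(node.children) > 1:
                return None
            (node,) = node.children.values()
            path.append((node.item, node.count))
        return path


def _ranked_transactions(transactions: Iterable[frozenset], rank: Mapping[Item, int]):
    for t in transactions:
        ranked = sorted(rank[it] for it in t if it in rank)
        if ranked:
            yield ranked


def build_tree(transactions: Sequence[frozenset], flist: FList) -> FPTree:
    """Filter each transaction to F-list items, sort in F-list order, insert."""
    rank = flist.rank()
    tree = FPTree(len(flist), flist=flist)
    for ranked in _ranked_transactions(transactions, rank):
        tree.insert(ranked)
    return tree


def _conditional_base(tree: FPTree, item_rank: int) -> list:
    """Prefix paths ending just above each node of ``item_rank``, weighted by
    that node's count.  Raises ``KeyError`` if the item has no header entry."""
    if item_rank >= len(tree.header) or tree.header[item_rank] is None:
        raise KeyError(f"item rank {item_rank} absent from tree header")
    base = []
    for node in tree.chain(item_rank):
        path = []
        up = node.parent
        while up is not None and up.item is not None:
            path.append(up.item)
            up = up.parent
        path.reverse()
        base.append((path, node.count))
    return base


def conditional_pattern_base(tree: FPTree, item: Item) -> list:
    """Conditional pattern base for ``item``: ``[(prefix Item list, count), ...]``,
    one entry per node in the item's header chain."""
    if tree.flist is None:
        raise ValueError("tree was not built with build_tree (no F-list attached)")
    rank = tree.flist.rank()
    if item not in rank:
        raise KeyError(f"item {item} absent from tree header")
    items = tree.flist.items
    return [([items[r] for r in prefix], c)
            for prefix, c in _conditional_base(tree, rank[item])]


def _mine(tree: FPTree, order: Sequence[int], suffix: tuple, min_support: int,
          out: dict, top_ranks=None) -> None:
    # order: header ranks present in this tree, most-frequent first
    path = tree.single_path()
    if path is not None and top_ranks is None:
        # every combination of path nodes; support = deepest selected count
        for k in range(1, len(path) + 1):
            for combo in combinations(path, k):
                sup = combo[-1][1]
                if sup >= min_support:
                    out[frozenset(r for r, _ in combo) | frozenset(suffix)] = sup
        return
    for r in reversed(order):  # least-frequent first
        if top_ranks is not None and r not in top_ranks:
            continue
        sup = tree.chain_support(r)
        if sup < min_support:
            continue
        new_suffix = suffix + (r,)
        out[frozenset(new_suffix)] = sup
        base = _conditional_base(tree, r)
        # conditional F-list: tally prefix items under this suffix
        counts: dict[int, int] = {}
        for prefix, c in base:
            for p in prefix:
                counts[p] = counts.get(p, 0) + c
        cond_order = sorted(r2 for r2, c in counts.items() if c >= min_support)
        if not cond_order:
            continue
        keep = set(cond_order)
        cond = FPTree(len(tree.header))
        for prefix, c in base:
            ranked = [p for p in prefix if p in keep]
            if ranked:
                cond.insert(ranked, c)
        _mine(cond, cond_order, new_suffix, min_support, out)


def mine_tree(transactions: Sequence[frozenset], flist: FList, min_support_count: int,
              top_items: frozenset | None = None) -> dict:
    """Mine frequent itemsets from transactions under a given (possibly global)
    F-list.  ``top_items`` restricts the rightmost (least-frequent) item of
    every reported itemset to the given set — the group-filter hook used by
    the partitioned miner.  Returns ``{frozenset[Item]: support_count}``.
    """
    rank = flist.rank()
    tree = FPTree(len(flist))
    for ranked in _ranked_transactions(transactions, rank):
        tree.insert(ranked)
    top_ranks = None
    if top_items is not None:
        top_ranks = frozenset(rank[it] for it in top_items if it in rank)
    ranked_out: dict = {}
    _mine(tree, range(len(flist)), (), min_support_count, ranked_out, top_ranks)
    items = flist.items
    return {frozenset(items[r] for r in fs): c for fs, c in ranked_out.items()}


def fp_growth(transactions: Sequence[frozenset], min_support_count: int) -> dict:
    """All itemsets with support >= ``min_support_count``, with exact supports.

    Returns ``{frozenset[Item]: support_count}``.
    """
    flist = build_flist(transactions, min_support_count)
    return mine_tree(transactions, flist, min_support_count)


def min_support_from_fraction(fraction: float, n_transactions: int) -> int:
    """Convenience: fractional support -> absolute count (ceil, at least 1)."""
    import math

    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    return max(1, math.ceil(fraction * n_transactions - 1e-12))


def itemsets_to_csv(itemsets: Mapping[frozenset, int], path) -> None:
    """Export mined itemsets as CSV: items joined by '|', support column."""
    import csv

    rows = sorted(
        (("|".join(sorted(i.token for i in fs)), c) for fs, c in itemsets.items()),
        key=lambda r: (-r[1], r[0]),
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["items", "support_count"])
        writer.writerows(rows)
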