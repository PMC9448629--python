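"""Partitioned frequent-itemset mining: horizontal sharding, per-shard local
FP-trees mined without cross-shard communication, balanced item grouping, and
a merge step that sums local supports before applying the global threshold.

The distributed runtime is abstracted behind an executor contract — tasks are
pure functions over (shard, group) pairs.  ``serial`` runs them in-process
and is the reference; ``process_pool`` fans them out to worker processes.
Results are executor- and shard-count-invariant by construction: local mining
keeps every local itemset (local support 1) so that merge-then-threshold is
exact.
"""

from __future__ import annotations

import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .fpgrowth import FList, build_flist, mine_tree
from .records import Item

__all__ = [
    "Shard",
    "GroupAssignment",
    "LocalResult",
    "EXECUTORS",
    "shard",
    "global_flist",
    "assign_groups",
    "mine_shard",
    "merge",
    "mine_parallel",
]

EXECUTORS = ("serial", "process_pool")


@dataclass(frozen=True)
class Shard:
    shard_id: int
    transactions: tuple  # tuple[frozenset[Item], ...]


@dataclass(frozen=True)
class GroupAssignment:
    """Round-robin mapping of F-list items to ``n_groups`` balanced groups."""

    n_groups: int
    mapping: Mapping  # Item -> group id

    def items_in(self, group_id: int) -> frozenset:
        return frozenset(it for it, g in self.mapping.items() if g == group_id)


@dataclass
class LocalResult:
    """Itemsets mined from one shard with LOCAL supports, unthresholded."""

    shard_id: int
    n_transactions: int
    itemsets: dict = field(default_factory=dict)  # frozenset[Item] -> local count


def shard(transactions: Sequence[frozenset], n_shards: int) -> list[Shard]:
    """Contiguous horizontal split; shard sizes differ by at most one."""
    if n_shards < 1:
        raise ValueError("n_shards must be >= 1")
    n = len(transactions)
    base, extra = divmod(n, n_shards)
    shards = []
    start = 0
    for i in range(n_shards):
        size = base + (1 if i < extra else 0)
        shards.append(Shard(i, tuple(transactions[start:start + size])))
        start += size
    return shards


def global_flist(shards: Sequence[Shard], min_support_count: int) -> FList:
    """Sum per-shard item tallies, threshold and order; identical to
    ``build_flist`` on the unsharded corpus."""
    all_transactions = [t for s in shards for t in s.transactions]
    return build_flist(all_transactions, min_support_count)


def assign_groups(flist: FList, n_groups: int = 9) -> GroupAssignment:
    """Item at F-list rank r goes to group r mod n_groups (balanced by rank)."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    mapping = {it: r % n_groups for r, (it, _) in enumerate(flist.entries)}
    return GroupAssignment(n_groups, mapping)


def mine_shard(shard: Shard, flist: FList,
               assignment: GroupAssignment | None = None,
               group_filter: int | None = None,
               min_local_support: int = 1) -> LocalResult:
    """Build and mine the shard's local FP-tree under the global F-list.

    Local counts are kept down to ``min_local_support`` (default 1, i.e.
    nothing below the global threshold is discarded locally).  When
    ``group_filter`` is given, only itemsets whose rightmost (F-list-last)
    item belongs to that group are mined.
    """
    top_items = None
    if group_filter is not None:
        if assignment is None:
            raise ValueError("group_filter requires a GroupAssignment")
        top_items = assignment.items_in(group_filter)
    itemsets = mine_tree(shard.transactions, flist, min_local_support, top_items=top_items)
    return LocalResult(shard.shard_id, len(shard.transactions), itemsets)


def merge(local_results: Sequence[LocalResult], min_support_count: int,
          n_transactions: int | None = None) -> dict:
    """Sum local supports per itemset, then apply the global threshold.

    ``local_results`` must cover a full contiguous set of shard ids; when
    ``n_transactions`` is given the shard sizes must add up to it.
    """
    by_shard: dict[int, int] = {}
    for lr in local_results:
        if lr.shard_id in by_shard:
            raise ValueError(f"duplicate local result for shard {lr.shard_id}")
        by_shard[lr.shard_id] = lr.n_transactions
    ids = sorted(by_shard)
    if ids != list(range(len(ids))):
        raise ValueError(f"local results do not cover shards contiguously: {ids}")
    if n_transactions is not None:
        total = sum(by_shard.values())
        if total != n_transactions:
            raise ValueError(
                f"shard sizes sum to {total}, expected {n_transactions} transactions")
    totals: dict = {}
    for lr in local_results:
        for fs, c in lr.itemsets.items():
            totals[fs] = totals.get(fs, 0) + c
    return {fs: c for fs, c in totals.items() if c >= min_support_count}


def _mine_task(shard_obj: Shard, flist: FList, assignment: GroupAssignment | None,
               group_filter: int | None) -> LocalResult:
    return mine_shard(shard_obj, flist, assignment, group_filter)


def mine_parallel(transactions: Sequence[frozenset], min_support_count: int,
                  n_shards: int = 1, n_groups: int = 9,
                  executor: str = "serial") -> dict:
    """Shard, mine locally per (shard, group) task, merge globally.

    Returns ``{frozenset[Item]: global support count}``, identical for every
    shard count and executor.  With a single shard the global threshold is
    applied directly during local mining (the merge is then a no-op), since
    local and global supports coincide.
    """
    if executor not in EXECUTORS:
        raise ValueError(f"unknown executor {executor!r}; expected one of {EXECUTORS}")
    if min_support_count < 1:
        raise ValueError("min_support_count must be >= 1")
    shards = shard(transactions, n_shards)
    flist = global_flist(shards, min_support_count)
    if not len(flist):
        return {}
    assignment = assign_groups(flist, n_groups)
    local_min = min_support_count if n_shards == 1 else 1
    tasks = [(s, g) for s in shards for g in range(n_groups)]
    if executor == "serial":
        partials = [
            mine_shard(s, flist, assignment, g, min_local_support=local_min)
            for s, g in tasks
        ]
    else:
        workers = min(4, os.cpu_count() or 1, len(tasks)) or 1
        with ProcessPoolExecutor(max_workers=workers) as pool:
            futures = [
                pool.submit(mine_shard, s, flist, assignment, g, local_min)
                for s, g in tasks
            ]
            partials = [f.result() for f in futures]
    # fold the per-group partials of each shard into one LocalResult
    per_shard: dict[int, LocalResult] = {}
    for part in partials:
        lr = per_shard.get(part.shard_id)
        if lr is None:
            per_shard[part.shard_id] = LocalResult(
                part.shard_id, part.n_transactions, dict(part.itemsets))
        else:
            lr.itemsets.update(part.itemsets)  # groups partition the itemset space
    return merge(list(per_shard.values()), min_support_count, len(transactions))
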