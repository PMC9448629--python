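import numpy as np
import pytest

from tcmrules.fpgrowth import build_flist, fp_growth
from tcmrules.parallel import (
    LocalResult,
    assign_groups,
    global_flist,
    merge,
    mine_parallel,
    mine_shard,
    shard,
)
from tcmrules.records import Item, Role

from conftest import sym
from oracles import brute_force_itemsets, random_db


class TestShard:
    def test_balanced_sizes(self):
        tx = [sym(f"s{i}") for i in range(10)]
        sizes = [len(s.transactions) for s in shard(tx, 3)]
        assert sizes == [4, 3, 3]

    def test_single_shard_is_identity(self, toy_transactions):
        (s,) = shard(toy_transactions, 1)
        assert list(s.transactions) == toy_transactions

    def test_concatenation_preserves_order(self):
        rng = np.random.default_rng(0)
        tx = random_db(rng, max_items=5, max_transactions=25)
        for n in (1, 2, 3, 7, 40):
            shards = shard(tx, n)
            flat = [t for s in shards for t in s.transactions]
            assert flat == tx
            assert [s.shard_id for s in shards] == list(range(n))
            sizes = [len(s.transactions) for s in shards]
            assert max(sizes) - min(sizes) <= 1

    def test_invalid_shard_count(self, toy_transactions):
        with pytest.raises(ValueError):
            shard(toy_transactions, 0)

    def test_more_shards_than_transactions_allowed(self, toy_transactions):
        shards = shard(toy_transactions, 10)
        assert len(shards) == 10
        assert sum(len(s.transactions) for s in shards) == 3


class TestGlobalFlist:
    @pytest.mark.parametrize("n_shards", [1, 2, 3, 5])
    def test_equals_unsharded_build_flist(self, n_shards):
        rng = np.random.default_rng(7)
        tx = random_db(rng)
        assert global_flist(shard(tx, n_shards), 2) == build_flist(tx, 2)

    def test_all_empty_shards(self):
        assert global_flist(shard([], 3), 1).entries == ()


class TestAssignGroups:
    def _flist(self, n):
        tx = [sym(*[f"s{i}" for i in range(n)])]
        return build_flist(tx, 1)

    def test_nine_items_nine_groups_bijection(self):
        assignment = assign_groups(self._flist(9), 9)
        assert sorted(assignment.mapping.values()) == list(range(9))

    def test_ten_items_nine_groups_pigeonhole(self):
        assignment = assign_groups(self._flist(10), 9)
        sizes = [len(assignment.items_in(g)) for g in range(9)]
        assert sorted(sizes, reverse=True) == [2] + [1] * 8

    @pytest.mark.parametrize("n_items,n_groups", [(1, 9), (5, 3), (20, 9), (9, 1)])
    def test_group_sizes_within_one(self, n_items, n_groups):
        assignment = assign_groups(self._flist(n_items), n_groups)
        sizes = [len(assignment.items_in(g)) for g in range(n_groups)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == n_items

    def test_round_robin_by_rank(self):
        flist = self._flist(5)
        assignment = assign_groups(flist, 2)
        for r, (item, _) in enumerate(flist.entries):
            assert assignment.mapping[item] == r % 2


class TestMineShard:
    def test_whole_corpus_no_filter_equals_support1_mining(self, toy_transactions):
        flist = build_flist(toy_transactions, 2)
        (s,) = shard(toy_transactions, 1)
        local = mine_shard(s, flist)
        # restricted to F-list items, every itemset with support >= 1
        oracle = {fs: c for fs, c in brute_force_itemsets(toy_transactions, 1).items()
                  if fs <= frozenset(flist.items)}
        assert local.itemsets == oracle

    def test_empty_shard_empty_result(self, toy_transactions):
        flist = build_flist(toy_transactions, 2)
        empty = shard(toy_transactions, 10)[-1]
        assert mine_shard(empty, flist).itemsets == {}

    def test_group_filters_partition_the_work(self, toy_transactions):
        flist = build_flist(toy_transactions, 2)
        assignment = assign_groups(flist, 9)
        (s,) = shard(toy_transactions, 1)
        unfiltered = mine_shard(s, flist).itemsets
        union = {}
        total = 0
        for g in range(9):
            part = mine_shard(s, flist, assignment, g).itemsets
            total += len(part)
            union.update(part)
        assert union == unfiltered
        assert total == len(unfiltered)  # disjoint: a partition, not a cover

    def test_group_filter_requires_assignment(self, toy_transactions):
        flist = build_flist(toy_transactions, 2)
        (s,) = shard(toy_transactions, 1)
        with pytest.raises(ValueError):
            mine_shard(s, flist, None, 3)


class TestMerge:
    def test_two_shards_match_sequential(self, toy_transactions):
        flist = build_flist(toy_transactions, 2)
        locals_ = [mine_shard(s, flist) for s in shard(toy_transactions, 2)]
        merged = merge(locals_, 2, len(toy_transactions))
        assert merged == fp_growth(toy_transactions, 2)

    def test_single_shard_pass_through(self, toy_transactions):
        flist = build_flist(toy_transactions, 2)
        locals_ = [mine_shard(s, flist) for s in shard(toy_transactions, 1)]
        assert merge(locals_, 2) == fp_growth(toy_transactions, 2)

    def test_merge_conservation(self, toy_transactions):
        flist = build_flist(toy_transactions, 2)
        locals_ = [mine_shard(s, flist) for s in shard(toy_transactions, 3)]
        merged = merge(locals_, 1, len(toy_transactions))
        for fs, c in merged.items():
            assert c == sum(lr.itemsets.get(fs, 0) for lr in locals_)

    def test_missing_shard_errors(self, toy_transactions):
        flist = build_flist(toy_transactions, 2)
        locals_ = [mine_shard(s, flist) for s in shard(toy_transactions, 2)]
        with pytest.raises(ValueError, match="contiguous"):
            merge(locals_[1:], 2)

    def test_duplicate_shard_errors(self):
        lr = LocalResult(0, 1, {})
        with pytest.raises(ValueError, match="duplicate"):
            merge([lr, lr], 1)

    def test_wrong_total_errors(self, toy_transactions):
        flist = build_flist(toy_transactions, 2)
        locals_ = [mine_shard(s, flist) for s in shard(toy_transactions, 2)]
        with pytest.raises(ValueError, match="sum"):
            merge(locals_, 2, n_transactions=99)


class TestMineParallel:
    @pytest.mark.parametrize("n_shards", [1, 2, 4])
    @pytest.mark.parametrize("executor", ["serial"])
    def test_toy_example_all_configurations(self, toy_transactions, n_shards, executor):
        result = mine_parallel(toy_transactions, 2, n_shards=n_shards,
                               n_groups=9, executor=executor)
        assert result == fp_growth(toy_transactions, 2)

    def test_process_pool_matches_serial(self, toy_transactions):
        serial = mine_parallel(toy_transactions, 2, n_shards=2, executor="serial")
        pooled = mine_parallel(toy_transactions, 2, n_shards=2, executor="process_pool")
        assert pooled == serial

    def test_degenerate_config_equals_fp_growth(self, toy_transactions):
        assert mine_parallel(toy_transactions, 2) == fp_growth(toy_transactions, 2)

    @pytest.mark.parametrize("seed", range(8))
    def test_shard_invariance_on_random_dbs(self, seed):
        rng = np.random.default_rng(seed)
        db = random_db(rng)
        min_sup = int(rng.integers(1, 5))
        oracle = brute_force_itemsets(db, min_sup)
        for n_shards in (1, 2, 4, 8):
            for n_groups in (1, 9):
                assert mine_parallel(db, min_sup, n_shards, n_groups) == oracle

    def test_unknown_executor(self, toy_transactions):
        with pytest.raises(ValueError, match="executor"):
            mine_parallel(toy_transactions, 2, executor="mapreduce")

    def test_empty_corpus(self):
        assert mine_parallel([], 1) == {}
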