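import itertools

import numpy as np
import pandas as pd
import pytest

import dtibridge as dtb
from dtibridge.batch_adjust import MergePlan, MergeStep


def make_meta(rows):
    return dtb.InstanceTable(
        pd.DataFrame(rows, columns=["instance_id", "batch_id", "compound_id"])
    )


def make_expr(columns, genes=("g1", "g2", "g3")):
    return dtb.ExpressionMatrix(
        pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"), dtype=float)
    )


class TestBatchGraph:
    def test_all_cross_batch_pairs_per_shared_compound(self):
        # drug B assayed twice in X and once in Y -> 2 bridge pairs
        meta = make_meta(
            [("i1", "X", "B"), ("i2", "X", "B"), ("i3", "Y", "B"), ("i4", "Y", "C")]
        )
        g = dtb.build_batch_graph(meta)
        assert sorted(g.bridge_pairs("X", "Y")) == [("i1", "i3"), ("i2", "i3")]

    def test_two_by_two_gives_four_pairs(self):
        meta = make_meta(
            [("i1", "X", "B"), ("i2", "X", "B"), ("i3", "Y", "B"), ("i4", "Y", "B")]
        )
        g = dtb.build_batch_graph(meta)
        assert len(g.bridge_pairs("X", "Y")) == 4

    def test_no_shared_compound_no_edge(self):
        meta = make_meta([("i1", "X", "B"), ("i2", "Y", "C")])
        g = dtb.build_batch_graph(meta)
        assert g.edges == {}
        assert g.bridge_pairs("X", "Y") == []

    def test_matches_brute_force_enumeration(self, rng):
        """Edge pairs equal brute force over all instance pairs on random metadata."""
        n = 40
        rows = [
            (f"i{k}", f"B{rng.integers(4)}", f"D{rng.integers(8)}") for k in range(n)
        ]
        meta = make_meta(rows)
        g = dtb.build_batch_graph(meta)
        expected = {}
        for (ia, ba, ca), (ib, bb, cb) in itertools.combinations(rows, 2):
            if ca == cb and ba != bb:
                key = (min(ba, bb), max(ba, bb))
                pair = (ia, ib) if ba == key[0] else (ib, ia)
                expected.setdefault(key, set()).add(pair)
        assert {k: set(v) for k, v in g.edges.items()} == expected


class TestShift:
    def test_single_pair_log2_ratio(self):
        expr = make_expr({"a": [2, 2, 2], "b": [1, 1, 1]})
        shift = dtb.estimate_shift(expr, [("a", "b")])
        assert np.allclose(shift.delta, [1, 1, 1])

    def test_mean_over_two_pairs(self):
        # per-gene log2 ratios (1, 0) and (0, 1) -> delta (0.5, 0.5)
        expr = make_expr(
            {"a1": [2, 1], "b1": [1, 1], "a2": [1, 2], "b2": [1, 1]},
            genes=("g1", "g2"),
        )
        shift = dtb.estimate_shift(expr, [("a1", "b1"), ("a2", "b2")])
        assert np.allclose(shift.delta, [0.5, 0.5])
        assert shift.n_bridge_pairs == 2

    def test_identical_profiles_zero_delta(self):
        expr = make_expr({"a": [3, 5, 7], "b": [3, 5, 7]})
        shift = dtb.estimate_shift(expr, [("a", "b")])
        assert np.allclose(shift.delta, 0)

    def test_antisymmetric_orientation(self):
        expr = make_expr({"a": [2, 8, 1], "b": [1, 2, 4]})
        fwd = dtb.estimate_shift(expr, [("a", "b")])
        rev = dtb.estimate_shift(expr, [("b", "a")])
        assert np.allclose(fwd.delta, -rev.delta)

    def test_missing_instance_raises(self):
        expr = make_expr({"a": [1, 1, 1]})
        with pytest.raises(KeyError, match="ghost"):
            dtb.estimate_shift(expr, [("a", "ghost")])

    def test_apply_moves_whole_absorbed_batch_only(self, tiny_expr, tiny_meta):
        shift = dtb.BatchShift(
            from_batch="Y", to_batch="X",
            delta=pd.Series([1.0, 1.0, 1.0], index=["g1", "g2", "g3"]),
            n_bridge_pairs=1,
        )
        out = dtb.apply_shift(tiny_expr, shift, tiny_meta)
        # i4 in batch Y: (8, 2, 2) -> (16, 4, 4); i3 too; X untouched
        assert np.allclose(out.data["i4"], [16, 4, 4])
        assert np.allclose(out.data["i3"], [2, 1, 0.5])
        assert np.allclose(out.data["i1"], tiny_expr.data["i1"])
        assert np.allclose(out.data["i2"], tiny_expr.data["i2"])

    def test_zero_delta_is_identity(self, tiny_expr, tiny_meta):
        shift = dtb.BatchShift(
            from_batch="Y", to_batch="X",
            delta=pd.Series(0.0, index=["g1", "g2", "g3"]), n_bridge_pairs=1,
        )
        out = dtb.apply_shift(tiny_expr, shift, tiny_meta)
        assert out.equals(tiny_expr)


class TestMergePlan:
    def chain_meta(self):
        # A - B - C chain, bridged by drugs ab and bc
        return make_meta(
            [
                ("a1", "A", "ab"), ("a2", "A", "x1"), ("a3", "A", "x2"),
                ("b1", "B", "ab"), ("b2", "B", "bc"),
                ("c1", "C", "bc"),
            ]
        )

    def test_chain_merges_in_order(self):
        g = dtb.build_batch_graph(self.chain_meta())
        plan = dtb.build_merge_plan(g, big_batch_min=3)
        assert plan.seed_set == ["A"]
        assert [s.absorbed for s in plan.steps] == ["B", "C"]
        assert plan.unadjustable == []

    def test_isolated_batch_reported_unadjustable(self):
        rows = self.chain_meta().data.values.tolist() + [["d1", "D", "solo"]]
        g = dtb.build_batch_graph(make_meta(rows))
        plan = dtb.build_merge_plan(g, big_batch_min=3)
        assert plan.unadjustable == ["D"]
        assert "D" not in [s.absorbed for s in plan.steps]

    def test_star_leaves_absorbed_by_bridge_pair_count(self):
        # center Z largest; leaves share 3, 2, 1 bridge pairs respectively
        rows = [("z%d" % k, "Z", "drug%d" % k) for k in range(6)]
        rows += [("p1", "P", "drug0"), ("p2", "P", "drug1"), ("p3", "P", "drug2")]
        rows += [("q1", "Q", "drug0"), ("q2", "Q", "drug1")]
        rows += [("r1", "R", "drug0")]
        g = dtb.build_batch_graph(make_meta(rows))
        plan = dtb.build_merge_plan(g, big_batch_min=4)
        assert plan.seed_set == ["Z"]
        assert [s.absorbed for s in plan.steps] == ["P", "Q", "R"]
        # counts are against the growing component: P->Z 3; Q->Z 2 plus Q->P 2;
        # R->Z 1 plus one pair each to P and Q
        assert [s.n_bridge_pairs for s in plan.steps] == [3, 4, 3]

    def test_fallback_seeds_largest_batch_when_none_big(self):
        g = dtb.build_batch_graph(self.chain_meta())
        plan = dtb.build_merge_plan(g, big_batch_min=30)
        assert plan.seed_set == ["A"]  # largest batch
        assert len(plan.steps) == 2

    def test_unknown_batch_in_plan_rejected(self, tiny_expr, tiny_meta):
        bogus = MergePlan(
            seed_set=["X"], steps=[MergeStep("X", "Z", 1)], unadjustable=[]
        )
        with pytest.raises(KeyError, match="Z"):
            dtb.adjust(tiny_expr, tiny_meta, plan=bogus)


class TestAdjust:
    def test_exact_multiplicative_batch_effect_removed(self):
        """One bridge drug, batch effect an exact per-gene factor: after
        adjustment the bridge instances coincide."""
        factor = np.array([4.0, 0.25, 2.0])
        base_bridge = np.array([2.0, 1.0, 0.5])
        base_other = np.array([1.0, 3.0, 1.0])
        expr = make_expr(
            {
                "x1": base_bridge, "x2": base_other, "x3": base_bridge * 3,
                "y1": base_bridge * factor, "y2": base_other * 2 * factor,
            }
        )
        # X is larger, so it seeds and Y is absorbed onto X's scale
        meta = make_meta(
            [("x1", "X", "B"), ("x2", "X", "C"), ("x3", "X", "E"),
             ("y1", "Y", "B"), ("y2", "Y", "D")]
        )
        adjusted, report = dtb.adjust(expr, meta, big_batch_min=2)
        assert np.allclose(adjusted.data["y1"], adjusted.data["x1"])
        # the whole batch moved by the same factor
        assert np.allclose(adjusted.data["y2"], base_other * 2)
        assert report["n_batches_merged"] == 2

    def test_single_batch_is_identity(self, tiny_expr):
        meta = make_meta(
            [("i1", "X", "a"), ("i2", "X", "b"), ("i3", "X", "c"), ("i4", "X", "d")]
        )
        adjusted, report = dtb.adjust(tiny_expr, meta)
        assert adjusted.equals(tiny_expr)
        assert report["steps"] == []

    def test_chain_recovers_planted_shifts(self):
        """Zero-noise simulation: adjustment makes same-drug instances from
        different batches identical to 1e-9 and recovers planted offsets."""
        cfg = dtb.SimConfig(
            n_genes=80, n_batches=4, n_compounds=20, n_targets=2,
            ligands_per_target=4, module_size=10, noise_sd=0.0,
            batch_sd=1.5, bridge_density=0.9, seed=7,
        )
        expr, meta, _, truth = dtb.simulate(cfg)
        adjusted, report = dtb.adjust(expr, meta, big_batch_min=2)
        assert report["unadjustable"] == []
        log2 = adjusted.log2()
        batch_of = meta.batch_of()
        seed_batch = report["seed_set"][0]
        for compound in meta.compound_ids:
            insts = meta.instances_of_compound(compound)
            for ia, ib in itertools.combinations(insts, 2):
                np.testing.assert_allclose(
                    log2[ia], log2[ib], atol=1e-9,
                    err_msg=f"{compound}: {ia} vs {ib}",
                )
        # recovered shift of each merged batch equals the planted offset delta
        offsets = truth.batch_offsets
        for inst in meta.instance_ids:
            b = batch_of[inst]
            raw = np.log2(expr.data[inst].to_numpy())
            adj = log2[inst].to_numpy()
            expected = offsets[seed_batch].to_numpy() - offsets[b].to_numpy()
            np.testing.assert_allclose(adj - raw, expected, atol=1e-9)

    def test_within_batch_structure_preserved(self, default_screen):
        raw = default_screen["expr"].log2()
        adj = default_screen["adjusted"].log2()
        table = default_screen["meta"]
        for batch in table.batch_ids[:3]:
            insts = table.instances_in_batch(batch)[:3]
            for ia, ib in itertools.combinations(insts, 2):
                np.testing.assert_allclose(
                    raw[ia] - raw[ib], adj[ia] - adj[ib], atol=1e-9
                )

    def test_seed_component_instances_never_move(self, default_screen):
        report = default_screen["adjust_report"]
        seed_batch = report["seed_set"][0]
        meta = default_screen["meta"]
        insts = meta.instances_in_batch(seed_batch)
        raw = default_screen["expr"].data[insts]
        adj = default_screen["adjusted"].data[insts]
        assert np.allclose(raw, adj)

    def test_bridge_log_difference_zeroed_on_used_edges(self, default_screen):
        """After adjustment the mean per-gene log2 gap across every merge
        edge's bridge pairs is numerically zero."""
        meta = default_screen["meta"]
        adj = default_screen["adjusted"].log2()
        graph = dtb.build_batch_graph(meta)
        report = default_screen["adjust_report"]
        merged = [report["seed_set"][0]] + [s["absorbed"] for s in report["steps"]]
        for k, absorbed in enumerate(merged[1:], start=1):
            pairs = []
            for prior in merged[:k]:
                pairs.extend(graph.bridge_pairs(prior, absorbed))
            gaps = np.stack([adj[ia] - adj[ib] for ia, ib in pairs])
            np.testing.assert_allclose(gaps.mean(axis=0), 0, atol=1e-9)

    def test_noise_adjustment_raises_same_drug_correlation(self):
        """Mean Pearson correlation between same-drug cross-batch instance
        pairs strictly increases after adjustment, across seeds."""
        improved = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = dtb.SimConfig(
                n_genes=300, n_batches=5, n_compounds=40, n_targets=3,
                ligands_per_target=5, module_size=15, batch_sd=1.0,
                noise_sd=0.3, bridge_density=0.8, seed=1000 + seed,
            )
            expr, meta, _, _ = dtb.simulate(cfg)
            adjusted, _ = dtb.adjust(expr, meta, big_batch_min=2)
            before = _mean_same_drug_cross_batch_corr(expr, meta)
            after = _mean_same_drug_cross_batch_corr(adjusted, meta)
            if after > before:
                improved += 1
        assert improved == n_seeds


def _mean_same_drug_cross_batch_corr(expr, meta):
    log2 = expr.log2()
    batch_of = meta.batch_of()
    cors = []
    for compound in meta.compound_ids:
        insts = meta.instances_of_compound(compound)
        for ia, ib in itertools.combinations(insts, 2):
            if batch_of[ia] != batch_of[ib]:
                cors.append(np.corrcoef(log2[ia], log2[ib])[0, 1])
    return float(np.mean(cors))
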