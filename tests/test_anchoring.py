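"""Scaffold divergence, ordering/orientation and the optimization round."""

import itertools

import numpy as np
import pytest

from chromoforge import synth
from chromoforge.anchoring import (
    MarkerMap,
    ScaffoldLayout,
    anchor,
    build_marker_map,
    canonicalize,
    export_linkage_heatmap,
    junction_cost,
    layout_accuracy,
    optimize_layout,
    scaffold_divergence,
    upgma_order,
)
from chromoforge.linkage import (
    RecombinationMatrix,
    assign_linkage_groups,
    build_rf_matrix,
)

from _oracles import exhaustive_best_layout


def _rm_from_rf(rf):
    """RecombinationMatrix with uniform high LOD and full support."""
    rf = np.asarray(rf, dtype=float)
    m = rf.shape[0]
    return RecombinationMatrix(
        [f"M{k:03d}" for k in range(m)],
        rf,
        np.where(np.isnan(rf), 0.0, 10.0),
        np.where(np.isnan(rf), 0, 100).astype(np.int64),
    )


def _instance_from_cm(scaffold_cms, n_progeny=None, seed=None):
    """Build (rm, marker_map) from per-scaffold marker cM positions.

    rf between markers follows the Haldane map of their cM distance; with
    ``n_progeny`` the rf is resampled binomially to emulate estimation noise.
    """
    cms = np.concatenate(scaffold_cms)
    d = np.abs(np.subtract.outer(cms, cms))
    rf = np.asarray(synth.haldane(d))
    if n_progeny is not None:
        rng = np.random.default_rng(seed)
        noisy = rng.binomial(n_progeny, np.clip(rf, 0, 0.5)) / n_progeny
        rf = np.where(~np.eye(len(cms), dtype=bool), noisy, 0.0)
        rf = (rf + rf.T) / 2
    order = {}
    pos = 0
    for k, cm in enumerate(scaffold_cms):
        order[f"s{k:02d}"] = list(range(pos, pos + len(cm)))
        pos += len(cm)
    mm = MarkerMap(order, {s: len(v) for s, v in order.items()})
    return _rm_from_rf(rf), mm


class TestDivergence:
    def test_single_marker_pair(self):
        rm, mm = _instance_from_cm([[0.0], [12.0]])
        sd = scaffold_divergence(rm, mm, ["s00", "s01"])
        assert sd.d[0, 1] == pytest.approx(float(synth.haldane(12.0)))
        assert sd.support[0, 1] == 1

    def test_mean_of_six_rf_values(self):
        rm, mm = _instance_from_cm([[0.0, 5.0], [20.0, 25.0, 30.0]])
        sd = scaffold_divergence(rm, mm, ["s00", "s01"])
        pairs = [(a, b) for a in (0.0, 5.0) for b in (20.0, 25.0, 30.0)]
        expected = np.mean([synth.haldane(abs(a - b)) for a, b in pairs])
        assert sd.d[0, 1] == pytest.approx(expected)
        assert sd.support[0, 1] == 6

    def test_symmetry_and_nan_diagonal(self):
        rm, mm = _instance_from_cm([[0.0, 2.0], [10.0], [30.0, 31.0]])
        sd = scaffold_divergence(rm, mm, ["s00", "s01", "s02"])
        assert np.allclose(sd.d, sd.d.T, equal_nan=True)
        assert np.all(np.isnan(np.diagonal(sd.d)))


class TestJunctionCost:
    def test_two_single_marker_scaffolds_cost_is_their_rf(self):
        rm, mm = _instance_from_cm([[0.0], [15.0]])
        expected = float(synth.haldane(15.0))
        for o1 in "+-":
            for o2 in "+-":
                cost = junction_cost([("s00", o1), ("s01", o2)], rm, mm)
                assert cost == pytest.approx(expected)

    def test_three_scaffold_cost_equals_manual_sum(self):
        rm, mm = _instance_from_cm(
            [[0.0, 1.0, 2.0, 3.0], [10.0, 11.0, 12.0], [20.0, 21.0]]
        )
        order = [("s00", "+"), ("s01", "+"), ("s02", "+")]
        # junction 1: markers 1,2,3 vs 4,5,6 ; junction 2: 4,5,6 vs 7,8
        j1 = np.mean([rm.rf[a, b] for a in (1, 2, 3) for b in (4, 5, 6)])
        j2 = np.mean([rm.rf[a, b] for a in (4, 5, 6) for b in (7, 8)])
        assert junction_cost(order, rm, mm, k_terminal=3) == pytest.approx(j1 + j2)

    def test_whole_chromosome_reflection_preserves_cost(self):
        rm, mm = _instance_from_cm([[0.0, 4.0], [10.0, 14.0], [25.0, 29.0]])
        order = [("s00", "+"), ("s01", "-"), ("s02", "+")]
        reflected = [("s02", "-"), ("s01", "+"), ("s00", "-")]
        assert junction_cost(order, rm, mm) == pytest.approx(
            junction_cost(reflected, rm, mm)
        )


class TestUpgmaOrder:
    def test_single_scaffold_returned_as_is(self):
        rm, mm = _instance_from_cm([[0.0, 5.0]])
        sd = scaffold_divergence(rm, mm, ["s00"])
        assert upgma_order(sd, rm, mm) == [[("s00", "+")]]

    def test_three_scaffolds_recover_truth_and_bruteforce_optimum(self):
        # 5 markers per scaffold so the k=3 terminal windows sense orientation
        rm, mm = _instance_from_cm(
            [
                [0.0, 2.0, 4.0, 6.0, 8.0],
                [14.0, 16.0, 18.0, 20.0, 22.0],
                [28.0, 30.0, 32.0, 34.0, 36.0],
            ]
        )
        sd = scaffold_divergence(rm, mm, sorted(mm.order))
        (block,) = upgma_order(sd, rm, mm)
        final = optimize_layout(block, rm, mm)
        assert [s for s, _ in final] == ["s00", "s01", "s02"]
        assert [o for _, o in final] == ["+", "+", "+"]
        best_cost, _ = exhaustive_best_layout(sorted(mm.order), rm, mm)
        assert junction_cost(final, rm, mm) == pytest.approx(best_cost)

    def test_tied_divergences_resolve_deterministically(self):
        rf = np.full((4, 4), 0.25)
        np.fill_diagonal(rf, 0.0)
        rm = _rm_from_rf(rf)
        mm = MarkerMap({f"s{k}": [k] for k in range(4)},
                       {f"s{k}": 1 for k in range(4)})
        sd = scaffold_divergence(rm, mm, sorted(mm.order))
        results = {tuple(map(tuple, upgma_order(sd, rm, mm))) for _ in range(5)}
        assert len(results) == 1

    def test_disconnected_divergence_graph_returns_blocks(self):
        rf = np.full((4, 4), np.nan)
        np.fill_diagonal(rf, 0.0)
        rf[0, 1] = rf[1, 0] = 0.05
        rf[2, 3] = rf[3, 2] = 0.05
        rm = _rm_from_rf(rf)
        mm = MarkerMap({f"s{k}": [k] for k in range(4)},
                       {f"s{k}": 1 for k in range(4)})
        sd = scaffold_divergence(rm, mm, sorted(mm.order))
        blocks = upgma_order(sd, rm, mm)
        assert sorted(sorted(s for s, _ in b) for b in blocks) == [
            ["s0", "s1"], ["s2", "s3"]
        ]


class TestOptimize:
    CMS = [
        [0.0, 2.0, 4.0, 6.0, 8.0],
        [14.0, 16.0, 18.0, 20.0, 22.0],
        [28.0, 30.0, 32.0, 34.0, 36.0],
    ]

    def test_fixed_point_left_unchanged(self):
        rm, mm = _instance_from_cm(self.CMS)
        order = [("s00", "+"), ("s01", "+"), ("s02", "+")]
        assert optimize_layout(order, rm, mm) == order

    def test_deliberate_flip_reverted_in_one_round(self):
        rm, mm = _instance_from_cm(self.CMS)
        broken = [("s00", "+"), ("s01", "-"), ("s02", "+")]
        assert optimize_layout(broken, rm, mm, max_rounds=1) == [
            ("s00", "+"), ("s01", "+"), ("s02", "+")
        ]

    @pytest.mark.parametrize("seed", range(5))
    def test_cost_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        n_scaf = int(rng.integers(2, 6))
        cms, pos = [], 0.0
        for _ in range(n_scaf):
            k = int(rng.integers(1, 4))
            cms.append(sorted(pos + rng.uniform(0, 8, k)))
            pos += 15.0
        rm, mm = _instance_from_cm(cms, n_progeny=100, seed=seed)
        sids = sorted(mm.order)
        start = [(s, rng.choice(["+", "-"])) for s in rng.permutation(sids)]
        before = junction_cost(start, rm, mm)
        after = junction_cost(optimize_layout(start, rm, mm), rm, mm)
        assert after <= before + 1e-12


class TestAnchorEndToEnd:
    def test_layout_invariant_to_marker_input_order(self, tiny_genome, tiny_cross):
        def run(gm):
            rm = build_rf_matrix(gm)
            lga = assign_linkage_groups(rm)
            return anchor(
                rm, lga,
                {m.marker_id: m.scaffold_id for m in gm.markers},
                {m.marker_id: m.position for m in gm.markers},
            )

        base = run(tiny_cross)
        rng = np.random.default_rng(5)
        shuffled = run(tiny_cross.subset(rng.permutation(tiny_cross.n_markers)))
        assert list(base.groups.values()) == list(shuffled.groups.values())

    def test_error_free_recovery_with_orientation_flags(
        self, tiny_genome, tiny_cross
    ):
        rm = build_rf_matrix(tiny_cross)
        lga = assign_linkage_groups(rm)
        layout = anchor(
            rm, lga,
            {m.marker_id: m.scaffold_id for m in tiny_cross.markers},
            {m.marker_id: m.position for m in tiny_cross.markers},
        )
        acc = layout_accuracy(
            layout.groups, tiny_genome.true_layout(),
            orientable={s for s, k in layout.orientation_known.items() if k},
        )
        assert acc["adjacency_recall"] == 1.0
        assert acc["orientation_accuracy"] >= 0.8

    def test_single_position_scaffold_flagged_unknown(self):
        rf = np.array([[0.0, 0.1], [0.1, 0.0]])
        rm = _rm_from_rf(rf)
        from chromoforge.linkage import LinkageGroupAssignment

        lga = LinkageGroupAssignment({"M000": 1, "M001": 1}, {1: 2})
        layout = anchor(rm, lga, {"M000": "sA", "M001": "sB"},
                        {"M000": 5, "M001": 9})
        assert layout.orientation_known == {"sA": False, "sB": False}
        for order in layout.groups.values():
            assert all(o == "+" for _, o in order)


class TestHeatmap:
    def test_ordered_layout_concentrates_low_rf_near_diagonal(
        self, tiny_genome, tiny_cross
    ):
        rm = build_rf_matrix(tiny_cross)
        lga = assign_linkage_groups(rm)
        scaffold_of = {m.marker_id: m.scaffold_id for m in tiny_cross.markers}
        pos_of = {m.marker_id: m.position for m in tiny_cross.markers}
        layout = anchor(rm, lga, scaffold_of, pos_of)
        mm = build_marker_map(rm, scaffold_of, pos_of)
        g = next(iter(layout.groups))
        ids, mat, bounds = export_linkage_heatmap(rm, layout.groups[g], mm)
        adjacent = np.array([mat[k, k + 1] for k in range(len(ids) - 1)])
        off = mat[np.triu_indices(len(ids), k=1)]
        assert np.nanmean(adjacent) < np.nanmean(off)

    def test_single_scaffold_boundaries(self):
        rm, mm = _instance_from_cm([[0.0, 1.0, 2.0]])
        ids, mat, bounds = export_linkage_heatmap(rm, [("s00", "+")], mm)
        assert bounds == [0, 3]
        assert mat.shape == (3, 3)

    def test_row_order_is_permutation_of_group_markers(self):
        rm, mm = _instance_from_cm([[0.0, 1.0], [8.0, 9.0]])
        ids, _, _ = export_linkage_heatmap(
            rm, [("s01", "-"), ("s00", "+")], mm
        )
        assert sorted(ids) == sorted(rm.marker_ids)
        assert ids[:2] == ["M003", "M002"]  # '-' scaffold reversed


class TestLayoutRoundTrip:
    def test_frame_round_trip(self, tiny_genome, tiny_cross):
        rm = build_rf_matrix(tiny_cross)
        lga = assign_linkage_groups(rm)
        layout = anchor(
            rm, lga,
            {m.marker_id: m.scaffold_id for m in tiny_cross.markers},
            {m.marker_id: m.position for m in tiny_cross.markers},
        )
        back = ScaffoldLayout.from_frame(layout.to_frame())
        assert back.groups == {str(k): v for k, v in layout.groups.items()} or \
            back.groups == layout.groups
        assert back.orientation_known == layout.orientation_known


@pytest.mark.parametrize("seed", range(20))
def test_small_instances_reach_bruteforce_optimum(seed):
    """UPGMA + one optimization round matches exhaustive search (<=4 blocks)."""
    rng = np.random.default_rng(1000 + seed)
    n_scaf = int(rng.integers(2, 5))
    cms, pos = [], 0.0
    for _ in range(n_scaf):
        k = int(rng.integers(2, 4))
        cms.append(sorted(pos + rng.uniform(0, 8, k)))
        pos += 12.0
    rm, mm = _instance_from_cm(cms, n_progeny=200, seed=seed)
    sids = sorted(mm.order)
    sd = scaffold_divergence(rm, mm, sids)
    blocks = upgma_order(sd, rm, mm)
    final = optimize_layout(blocks[0], rm, mm)
    best_cost, _ = exhaustive_best_layout(sids, rm, mm)
    assert junction_cost(final, rm, mm) <= best_cost + 1e-9


def test_canonicalize_puts_smaller_end_left():
    order = [("s2", "+"), ("s1", "-")]
    assert canonicalize(order) == [("s1", "+"), ("s2", "-")]
    assert canonicalize([("s1", "+"), ("s2", "-")]) == [("s1", "+"), ("s2", "-")]
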