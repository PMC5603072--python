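"""Two-point rf/LOD estimation, grouping and scaffold consistency."""

import dataclasses

import numpy as np
import pytest

from chromoforge import synth
from chromoforge.linkage import (
    RecombinationMatrix,
    _pair_models,
    _rf_em_pairs,
    assign_linkage_groups,
    build_rf_matrix,
    check_scaffold_consistency,
    estimate_rf,
)
from chromoforge.qc import MISSING, GenotypeMatrix, MarkerMeta

from _oracles import rf_count_testcross
from conftest import make_testcross_genome


def _simulate_pair(rf, n, type_i, type_j, seed):
    """Directly simulate one marker pair at true rf (coupling phases)."""
    rng = np.random.default_rng(seed)
    code_i = np.zeros(n, dtype=np.int8)
    code_j = np.zeros(n, dtype=np.int8)
    for parent, (het_i, het_j) in enumerate(
        [
            (type_i in ("lmxll", "hkxhk"), type_j in ("lmxll", "hkxhk")),
            (type_i in ("nnxnp", "hkxhk"), type_j in ("nnxnp", "hkxhk")),
        ]
    ):
        a_i = rng.integers(0, 2, n).astype(np.int8)
        rec = (rng.random(n) < rf).astype(np.int8)
        a_j = a_i ^ rec
        if het_i:
            code_i += a_i
        if het_j:
            code_j += a_j
    return code_i, code_j


class TestEstimateRf:
    def test_identical_testcross_vectors_fully_linked(self):
        calls = np.array([0, 1] * 50, dtype=np.int8)
        rf, lod, n = estimate_rf(calls, calls, "lmxll", "lmxll")
        assert rf == 0.0 and lod > 0 and n == 100

    def test_two_of_ten_recombinants(self):
        a = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=np.int8)
        b = np.array([0, 0, 0, 0, 0, 1, 1, 1, 0, 0], dtype=np.int8)
        rf, lod, n = estimate_rf(a, b, "lmxll", "lmxll")
        assert rf == pytest.approx(0.2) and n == 10

    def test_phase_flip_gives_same_rf(self):
        a = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], dtype=np.int8)
        b = np.array([1, 1, 1, 1, 1, 0, 0, 0, 1, 1], dtype=np.int8)  # repulsion
        rf, _, _ = estimate_rf(a, b, "lmxll", "lmxll")
        assert rf == pytest.approx(0.2)

    def test_independent_markers_near_half(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 10_000).astype(np.int8)
        b = rng.integers(0, 2, 10_000).astype(np.int8)
        rf, lod, _ = estimate_rf(a, b, "lmxll", "lmxll")
        assert abs(rf - 0.5) < 3 * np.sqrt(0.25 / 10_000)
        assert lod < 1.0

    def test_cross_parent_testcross_pair_unusable(self):
        a = np.zeros(50, dtype=np.int8)
        b = np.ones(50, dtype=np.int8)
        rf, lod, n = estimate_rf(a, b, "lmxll", "nnxnp")
        assert np.isnan(rf) and lod == 0.0 and n == 0

    def test_no_overlap_gives_unusable_entry(self):
        a = np.array([0, 1, MISSING, MISSING], dtype=np.int8)
        b = np.array([MISSING, MISSING, 0, 1], dtype=np.int8)
        rf, lod, n = estimate_rf(a, b, "lmxll", "lmxll")
        assert np.isnan(rf) and n == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_testcross_rf_equals_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 500))
        a = rng.integers(0, 2, n).astype(np.int8)
        b = rng.integers(0, 2, n).astype(np.int8)
        a[rng.random(n) < 0.2] = MISSING
        b[rng.random(n) < 0.2] = MISSING
        rf, _, n_inf = estimate_rf(a, b, "nnxnp", "nnxnp")
        expected, n_expected = rf_count_testcross(a, b)
        assert n_inf == n_expected
        if expected is None:
            assert np.isnan(rf)
        else:
            assert rf == pytest.approx(expected)

    def test_em_agrees_with_closed_form_on_testcross_counts(self):
        # the generic EM on an unambiguous 2x2 table must reproduce count/n
        counts = np.array([[40.0, 8.0, 12.0, 40.0]])  # 20/100 mismatches
        rf, _ = _rf_em_pairs(counts, "lmxll", "lmxll")
        assert rf[0] == pytest.approx(0.2, abs=1e-9)

    @pytest.mark.parametrize("pair", [
        ("hkxhk", "hkxhk"), ("lmxll", "hkxhk"), ("nnxnp", "hkxhk"),
    ])
    def test_em_recovers_true_rf(self, pair):
        ci, cj = _simulate_pair(0.2, 2000, pair[0], pair[1], seed=42)
        rf, lod, n = estimate_rf(ci, cj, *pair)
        assert rf == pytest.approx(0.2, abs=0.05)
        assert lod > 3 and n == 2000

    def test_class_probabilities_normalize(self):
        for pair in [("hkxhk", "hkxhk"), ("lmxll", "hkxhk"),
                     ("lmxll", "lmxll"), ("nnxnp", "hkxhk")]:
            g, models = _pair_models(*pair)
            for k_mat in models:
                for r in (0.0, 0.1, 0.37, 0.5):
                    powers = np.array(
                        [r ** k * (1 - r) ** (g - k) for k in range(g + 1)]
                    )
                    assert (k_mat @ powers).sum() == pytest.approx(1.0)

    def test_lod_zero_at_half_and_monotone_to_half(self):
        # fixed testcross data with rf_hat < 0.5: the LOD curve decreases
        # from rf_hat toward 0.5 and is exactly 0 at 0.5
        n, rec = 100, 10
        def log_lr(r):
            return rec * np.log10(2 * r) + (n - rec) * np.log10(2 * (1 - r))
        grid = np.linspace(rec / n, 0.5, 50)
        vals = log_lr(grid)
        assert np.all(np.diff(vals) < 0)
        assert log_lr(0.5) == pytest.approx(0.0, abs=1e-12)


@pytest.fixture(scope="module")
def mixed_gm():
    rng = np.random.default_rng(7)
    metas, rows = [], []
    segs = ["lmxll", "nnxnp", "hkxhk"] * 5
    for i, seg in enumerate(segs):
        metas.append(MarkerMeta(f"m{i:02d}", f"s{i % 4}", i, seg))
        ncat = 3 if seg == "hkxhk" else 2
        row = rng.integers(0, ncat, 80).astype(np.int8)
        row[rng.random(80) < 0.1] = MISSING
        rows.append(row)
    return GenotypeMatrix(metas, [f"p{j}" for j in range(80)],
                          np.vstack(rows))


class TestRfMatrix:
    def test_matrix_entries_equal_pairwise_estimates(self, mixed_gm):
        rm = build_rf_matrix(mixed_gm)
        for i in range(0, mixed_gm.n_markers, 3):
            for j in range(i + 1, mixed_gm.n_markers, 4):
                rf, lod, n = estimate_rf(
                    mixed_gm.calls[i], mixed_gm.calls[j],
                    mixed_gm.markers[i].segregation_type,
                    mixed_gm.markers[j].segregation_type,
                )
                if np.isnan(rf):
                    assert np.isnan(rm.rf[i, j])
                else:
                    assert rm.rf[i, j] == pytest.approx(rf, abs=5e-6)
                    assert rm.lod[i, j] == pytest.approx(lod, abs=1e-6)
                assert rm.n_inf[i, j] == n

    def test_matrix_symmetric_with_zero_diagonal(self, mixed_gm):
        rm = build_rf_matrix(mixed_gm)
        assert np.array_equal(np.isnan(rm.rf), np.isnan(rm.rf.T))
        finite = ~np.isnan(rm.rf)
        assert np.allclose(rm.rf[finite], rm.rf.T[finite])
        assert np.all(np.diagonal(rm.rf) == 0)
        assert np.all(rm.lod[rm.usable()] >= 0)

    def test_estimation_error_shrinks_with_progeny(self):
        g = make_testcross_genome(
            cm_positions=tuple(np.linspace(0, 40, 12)), length=900_000
        )
        errs = {}
        for n in (50, 400):
            cfg = synth.SimConfig(
                n_chromosomes=1, chromosome_length=900_000,
                n_scaffolds_per_chromosome=1, n_markers=12, n_progeny=n,
                seed=13,
            )
            gm = synth.simulate_cross(g, cfg)
            rm = build_rf_matrix(gm)
            true_rf = synth.haldane(
                np.abs(np.subtract.outer(
                    [mt.cm for mt in g.marker_truth],
                    [mt.cm for mt in g.marker_truth],
                ))
            )
            mask = rm.usable() & ~np.eye(12, dtype=bool)
            errs[n] = np.abs(rm.rf - true_rf)[mask].mean()
        assert errs[400] < errs[50]


class TestGrouping:
    def test_two_chromosomes_give_two_groups_matching_truth(
        self, tiny_genome, tiny_cross
    ):
        rm = build_rf_matrix(tiny_cross)
        lga = assign_linkage_groups(rm)
        big = [g for g, n in lga.sizes.items() if n >= 2]
        assert len(big) == 2
        truth = tiny_genome.marker_chromosome()
        for members in lga.members(min_size=2).values():
            assert len({truth[mid] for mid in members}) == 1

    def test_infinite_lod_threshold_gives_all_singletons(self, tiny_cross):
        rm = build_rf_matrix(tiny_cross)
        lga = assign_linkage_groups(rm, lod_min=np.inf)
        assert all(n == 1 for n in lga.sizes.values())

    def test_grouping_invariant_to_marker_order(self, tiny_cross):
        rm = build_rf_matrix(tiny_cross)
        lga = assign_linkage_groups(rm)
        rng = np.random.default_rng(3)
        perm = rng.permutation(tiny_cross.n_markers)
        shuffled = tiny_cross.subset(perm)
        lga2 = assign_linkage_groups(build_rf_matrix(shuffled))
        assert lga2.groups == lga.groups
        assert lga2.sizes == lga.sizes


class TestScaffoldConsistency:
    def test_error_free_data_has_no_conflicts(self, tiny_cross):
        rm = build_rf_matrix(tiny_cross)
        lga = assign_linkage_groups(rm)
        scaffold_of = {m.marker_id: m.scaffold_id for m in tiny_cross.markers}
        assert check_scaffold_consistency(lga, scaffold_of) == []

    def test_cross_chromosome_scaffold_is_reported(self, tiny_cross):
        rm = build_rf_matrix(tiny_cross)
        lga = assign_linkage_groups(rm)
        # deliberately merge a scaffold from each chromosome into one id
        scaffold_of = {m.marker_id: m.scaffold_id for m in tiny_cross.markers}
        groups_present = {lga.groups[m] for m in scaffold_of}
        by_group = lga.members(min_size=2)
        g1, g2 = sorted(by_group)[:2]
        for mid in by_group[g1][:3] + by_group[g2][:3]:
            scaffold_of[mid] = "franken_scaffold"
        conflicts = check_scaffold_consistency(lga, scaffold_of)
        assert [c.scaffold_id for c in conflicts] == ["franken_scaffold"]
        assert dict(conflicts[0].groups) == {g1: 3, g2: 3}

    def test_single_marker_scaffold_never_conflicts(self):
        lga_groups = {"m1": 1, "m2": 1}
        from chromoforge.linkage import LinkageGroupAssignment

        lga = LinkageGroupAssignment(lga_groups, {1: 2})
        assert check_scaffold_consistency(lga, {"m1": "sA", "m2": "sB"}) == []
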