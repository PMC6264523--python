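"""Distance matrices, restriction rules, Edmonds, ISA resolution, iteration."""

import itertools

import numpy as np
import pytest

from laftree.distance import AlleleProfile
from laftree.model import AlleleCombination, ModelConfig
from laftree.tstep import (
    DistanceMatrices,
    InfeasibleTreeError,
    Tree,
    build_distance_matrices,
    detect_isa_violations,
    edmonds_arborescence,
    loh_runs,
    resolve_isa,
    run_inference,
    snv_presence,
)
from tests.conftest import make_bundle

A = AlleleCombination
AB = A(1, 1)
B = A(0, 1)


def profiles_from_strings(columns, arm_starts=(0,)):
    return [
        AlleleProfile(tuple(A.from_string(s) for s in col), arm_starts)
        for col in columns
    ]


class TestTreeInvariants:
    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            Tree(parent={"r": None, "a": "b", "b": "a"}, root="r", edge_weights={})

    def test_unreachable_rejected(self):
        with pytest.raises(ValueError):
            Tree(parent={"r": None, "a": "ghost"}, root="r", edge_weights={})

    def test_total_distance_and_ancestry(self):
        t = Tree(
            parent={"r": None, "a": "r", "b": "a"},
            root="r",
            edge_weights={("r", "a"): 2.0, ("a", "b"): 3.0},
        )
        assert t.total_distance == 5.0
        assert t.ancestry_pairs() == {("r", "a"), ("r", "b"), ("a", "b")}
        assert t.topological_order() == ["r", "a", "b"]


class TestLohRules:
    def _bundle_profiles(self, parent_laf, child_laf):
        n = len(parent_laf)
        af = np.column_stack(
            [np.full(n, 0.5), np.asarray(parent_laf), np.full(n, child_laf)]
        )
        bundle = make_bundle(af)
        prof = profiles_from_strings(
            [["AB"] * n, ["B"] * n, ["AB"] * n]
        )
        return bundle, prof

    def test_confident_loh_restricts_edge(self):
        bundle, prof = self._bundle_profiles([0.05] * 12, 0.5)
        mats = build_distance_matrices(prof, bundle, ModelConfig())
        assert mats.restricted[1, 2]  # LOH sample cannot parent a balanced one
        assert not mats.restricted[2, 1]

    def test_unsupported_loh_penalizes_instead(self):
        config = ModelConfig()
        bundle, prof = self._bundle_profiles([0.35] * 12, 0.5)
        mats = build_distance_matrices(prof, bundle, config)
        assert not mats.restricted[1, 2]
        base = np.sum(
            [12]
        )  # 12 positionwise B-vs-AB losses collapse to 1 event horizontally
        assert mats.d_allele[1, 2] == pytest.approx(1 + config.penalty_pa)

    def test_no_loh_leaves_matrices_unchanged(self):
        n = 12
        af = np.column_stack([np.full(n, 0.5)] * 3)
        bundle = make_bundle(af)
        prof = profiles_from_strings([["AB"] * n] * 3)
        config = ModelConfig()
        mats = build_distance_matrices(prof, bundle, config)
        off_diag = ~np.eye(3, dtype=bool)[1:, 1:]
        assert not mats.restricted[1:, 1:][off_diag].any()
        assert (mats.d_allele[1:, 1:] == 0).all()

    def test_runs_span_arm_boundaries(self):
        # an arm-level loss covers consecutive measurements on both arms
        config = ModelConfig()
        laf = np.full(12, 0.05)
        prof = AlleleProfile((B,) * 12, arm_starts=(0, 6))
        runs = loh_runs(prof, laf, config)
        assert [(r.start, r.end, r.confident) for r in runs] == [(0, 12, True)]


class TestParentalAlleleRule:
    def test_opposite_extreme_af_mutually_restricts(self):
        n = 12
        af = np.column_stack([np.full(n, 0.5), np.full(n, 0.02), np.full(n, 0.97)])
        bundle = make_bundle(af)
        prof = profiles_from_strings([["AB"] * n, ["B"] * n, ["B"] * n])
        mats = build_distance_matrices(prof, bundle, ModelConfig())
        assert mats.restricted[1, 2] and mats.restricted[2, 1]

    def test_same_lost_allele_not_restricted(self):
        n = 12
        af = np.column_stack([np.full(n, 0.5), np.full(n, 0.02), np.full(n, 0.03)])
        bundle = make_bundle(af)
        prof = profiles_from_strings([["AB"] * n, ["B"] * n, ["B"] * n])
        mats = build_distance_matrices(prof, bundle, ModelConfig())
        assert not mats.restricted[1, 2] and not mats.restricted[2, 1]

    def test_intermediate_af_not_restricted(self):
        n = 12
        af = np.column_stack([np.full(n, 0.5), np.full(n, 0.2), np.full(n, 0.8)])
        bundle = make_bundle(af)
        prof = profiles_from_strings([["AB"] * n, ["B"] * n, ["B"] * n])
        mats = build_distance_matrices(prof, bundle, ModelConfig())
        assert not mats.restricted[1, 2] and not mats.restricted[2, 1]


class TestSnvRule:
    def _setup(self, child_col, child_laf=0.5):
        n = 12
        af = np.column_stack(
            [np.full(n, 0.5), np.full(n, 0.35), np.full(n, child_laf)]
        )
        snv = np.array([[0.0, 0.4, 0.0]])
        bundle = make_bundle(af, snv_af=snv)
        prof = profiles_from_strings([["AB"] * n, ["AB"] * n, [child_col] * n])
        return bundle, prof

    def test_unexplained_snv_loss_penalized(self):
        config = ModelConfig()
        bundle, prof = self._setup("AB")
        mats = build_distance_matrices(prof, bundle, config)
        assert mats.d_snv[1, 2] == pytest.approx(1 + config.penalty_ps)
        assert mats.d_snv[2, 1] == pytest.approx(1.0)

    def test_allele_loss_exempts_the_edge(self):
        bundle, prof = self._setup("B", child_laf=0.35)
        mats = build_distance_matrices(prof, bundle, ModelConfig())
        assert mats.d_snv[1, 2] == pytest.approx(1.0)

    def test_identical_snv_sets_neutral(self):
        n = 12
        af = np.column_stack([np.full(n, 0.5)] * 3)
        snv = np.array([[0.0, 0.4, 0.4]])
        bundle = make_bundle(af, snv_af=snv)
        prof = profiles_from_strings([["AB"] * n] * 3)
        mats = build_distance_matrices(prof, bundle, ModelConfig())
        assert (mats.d_snv[1:, 1:] == 1).all()


def _matrices(weights, restricted=None, names=None):
    m = len(weights)
    names = names or [f"n{i}" for i in range(m)]
    r = np.zeros((m, m), dtype=bool)
    np.fill_diagonal(r, True)
    r[:, 0] = True
    if restricted:
        for p, c in restricted:
            r[p, c] = True
    return DistanceMatrices(
        d_allele=np.asarray(weights, dtype=float),
        d_snv=np.ones((m, m)),
        restricted=r,
        sample_names=names,
        root_index=0,
    )


def _brute_force_msa(mats):
    """Enumerate all arborescences rooted at index 0; return the minimum weight."""
    m = len(mats.sample_names)
    best = None
    for parents in itertools.product(range(m), repeat=m - 1):
        total = 0.0
        ok = True
        parent_map = {0: None}
        for child, par in enumerate(parents, start=1):
            if mats.restricted[par, child]:
                ok = False
                break
            parent_map[child] = par
            total += mats.d_final[par, child]
        if not ok:
            continue
        # acyclicity: every node must reach the root
        for node in range(1, m):
            seen = set()
            cur = node
            while cur is not None and cur not in seen:
                seen.add(cur)
                cur = parent_map[cur]
            if 0 not in seen:
                ok = False
                break
        if ok and (best is None or total < best):
            best = total
    return best


class TestEdmonds:
    def test_unique_cheapest_parents(self):
        w = np.array(
            [
                [0, 1.0, 5.0, 5.0],
                [9, 0.0, 1.0, 5.0],
                [9, 9.0, 0.0, 1.0],
                [9, 9.0, 9.0, 0.0],
            ]
        )
        tree = edmonds_arborescence(_matrices(w))
        assert tree.parent == {"n0": None, "n1": "n0", "n2": "n1", "n3": "n2"}
        assert tree.total_distance == 3.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            m = int(rng.integers(3, 6))
            w = rng.integers(1, 9, size=(m, m)).astype(float)
            mats = _matrices(w.tolist())
            tree = edmonds_arborescence(mats)
            assert tree.total_distance == pytest.approx(_brute_force_msa(mats))

    def test_infeasible_names_unreachable(self):
        w = np.zeros((3, 3))
        mats = _matrices(w, restricted=[(0, 2), (1, 2)])
        with pytest.raises(InfeasibleTreeError) as exc:
            edmonds_arborescence(mats)
        assert "n2" in str(exc.value)


class TestIsaViolations:
    def test_nested_snvs_clean(self):
        t = Tree(
            parent={"h": None, "a": "h", "b": "a"},
            root="h",
            edge_weights={},
        )
        present = np.array([[False, True, True], [False, False, True]])
        assert detect_isa_violations(t, present, ["h", "a", "b"]) == {}

    def test_sibling_gain_flagged(self):
        t = Tree(
            parent={"h": None, "a": "h", "b": "h"},
            root="h",
            edge_weights={},
        )
        present = np.array([[False, True, True]])
        viols = detect_isa_violations(t, present, ["h", "a", "b"])
        assert viols == {0: [("h", "a"), ("h", "b")]}


class TestResolveIsa:
    def test_violation_free_tree_unchanged(self):
        config = ModelConfig()
        w = np.array([[0, 1.0, 2.0], [9, 0, 1.0], [9, 9, 0]])
        mats = _matrices(w)
        start = edmonds_arborescence(mats)
        present = np.array([[False, True, True]])
        best, cands = resolve_isa(
            start, mats, present, config, np.random.default_rng(0)
        )
        assert best.edges() == start.edges()

    def test_single_violation_repaired(self):
        config = ModelConfig()
        # star is cheapest but puts the shared SNV on two edges; the chain
        # through n1 is the cheapest violation-free alternative
        w = np.array(
            [
                [0, 1.0, 1.0, 1.0],
                [9, 0.0, 1.5, 9.0],
                [9, 9.0, 0.0, 9.0],
                [9, 9.0, 9.0, 0.0],
            ]
        )
        mats = _matrices(w)
        start = edmonds_arborescence(mats)
        present = np.array([[False, True, True, False]])
        best, _ = resolve_isa(start, mats, present, config, np.random.default_rng(0))
        assert detect_isa_violations(best, present, mats.sample_names) == {}
        assert ("n1", "n2") in best.edges()

    def test_never_more_violations_than_start(self):
        config = ModelConfig(isa_tree_count=10)
        rng_w = np.random.default_rng(2)
        for _ in range(10):
            w = rng_w.integers(1, 6, size=(4, 4)).astype(float)
            mats = _matrices(w.tolist())
            present = rng_w.random((3, 4)) < 0.4
            present[:, 0] = False
            start = edmonds_arborescence(mats)
            best, _ = resolve_isa(
                start, mats, present, config, np.random.default_rng(1)
            )
            n = lambda t: len(detect_isa_violations(t, present, mats.sample_names))
            assert n(best) <= n(start)

    def test_seed_stable_selection(self):
        config = ModelConfig(isa_tree_count=20)
        w = np.array(
            [
                [0, 1.0, 1.0, 1.0],
                [9, 0.0, 1.0, 1.0],
                [9, 1.0, 0.0, 1.0],
                [9, 9.0, 9.0, 0.0],
            ]
        )
        mats = _matrices(w)
        present = np.array([[False, True, True, True]])
        start = edmonds_arborescence(mats)
        a, _ = resolve_isa(start, mats, present, config, np.random.default_rng(7))
        b, _ = resolve_isa(start, mats, present, config, np.random.default_rng(7))
        assert a.edges() == b.edges()


class TestRunInference:
    def test_single_tumor_sample_converges(self, config):
        rng = np.random.default_rng(0)
        n = 20
        af = np.column_stack(
            [
                np.clip(0.5 + rng.normal(0, 0.02, n), 0, 1),
                np.clip(0.35 + rng.normal(0, 0.02, n), 0, 1),
            ]
        )
        bundle = make_bundle(af)
        result = run_inference(bundle, config)
        assert result.tree.edges() == frozenset({("healthy", "S1")})
        assert result.converged
        assert len(result.iterations) == 2

    def test_end_to_end_seed_determinism(self, small_dataset):
        bundle, truth, _ = small_dataset
        a = run_inference(bundle, ModelConfig(rng_seed=5))
        b = run_inference(bundle, ModelConfig(rng_seed=5))
        assert a.tree.signature() == b.tree.signature()
        for name in truth.sample_names:
            assert a.estimates[name].mu == b.estimates[name].mu
            assert np.array_equal(
                a.estimates[name].copy_numbers, b.estimates[name].copy_numbers
            )
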