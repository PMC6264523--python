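"""Tree reconstruction from inferred alleles and somatic SNVs.

Pairwise allele event distances (with horizontal dependency) define a
directed distance matrix over samples.  Biological constraints prune or
penalize edges: a subclone with a confidently lost allele region (LOH)
cannot be the parent of a subclone that still has both alleles there;
samples that lost *different* parental alleles over the same region cannot
be related in either direction; a parent whose somatic SNV is absent in a
child without any allele-loss evidence is penalized.  Edmonds' algorithm
then yields the minimum spanning arborescence rooted at the healthy or
precursor sample, and an edit loop removes edges until the infinite sites
assumption (each SNV gained once) is satisfied, keeping the best of a
configurable number of randomized repair passes.

The outer loop alternates this T-step with the per-sample C-step until the
tree (edge set and total distance) recurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cstep import SampleEstimate, infer_sample
from .distance import AlleleProfile, fst_event_distance
from .model import MeasurementBundle, ModelConfig


class InfeasibleTreeError(RuntimeError):
    """No spanning arborescence exists under the current restrictions."""

    def __init__(self, unreachable: list[str]):
        self.unreachable = unreachable
        super().__init__(
            "no feasible arborescence: unreachable samples " + ", ".join(unreachable)
        )


@dataclass(frozen=True)
class Tree:
    """Rooted arborescence over samples (every non-root has one parent)."""

    parent: dict[str, str | None]
    root: str
    edge_weights: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        if self.parent.get(self.root, "missing") is not None:
            raise ValueError("root must map to parent None")
        for child, par in self.parent.items():
            if child == self.root:
                continue
            if par is None or par not in self.parent:
                raise ValueError(f"node {child} lacks a valid parent")
        # acyclicity / reachability from root
        for node in self.parent:
            seen = set()
            cur: str | None = node
            while cur is not None:
                if cur in seen:
                    raise ValueError("parent map contains a cycle")
                seen.add(cur)
                cur = self.parent[cur]
            if self.root not in seen:
                raise ValueError(f"node {node} not reachable from root")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.parent)

    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (par, child) for child, par in self.parent.items() if par is not None
        )

    @property
    def total_distance(self) -> float:
        return float(sum(self.edge_weights.get(e, 0.0) for e in self.edges()))

    def children(self, node: str) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p == node)

    def topological_order(self) -> list[str]:
        order = [self.root]
        stack = [self.root]
        while stack:
            node = stack.pop(0)
            kids = self.children(node)
            order.extend(kids)
            stack.extend(kids)
        return order

    def descendants(self, node: str) -> set[str]:
        out: set[str] = set()
        stack = [node]
        while stack:
            for kid in self.children(stack.pop()):
                out.add(kid)
                stack.append(kid)
        return out

    def ancestry_pairs(self) -> set[tuple[str, str]]:
        """All ordered (ancestor, descendant) pairs implied by the tree."""
        return {
            (anc, desc) for anc in self.parent for desc in self.descendants(anc)
        }

    def signature(self) -> tuple[frozenset[tuple[str, str]], float]:
        return (self.edges(), round(self.total_distance, 6))

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "nodes": self.nodes,
            "parent": {c: p for c, p in sorted(self.parent.items())},
            "edges": [
                {"parent": p, "child": c, "weight": self.edge_weights.get((p, c), 0.0)}
                for p, c in sorted(self.edges())
            ],
            "total_distance": self.total_distance,
        }

    @classmethod
    def star(cls, root: str, leaves: list[str]) -> "Tree":
        parent: dict[str, str | None] = {root: None}
        parent.update({leaf: root for leaf in leaves})
        return cls(parent=parent, root=root, edge_weights={(root, l): 0.0 for l in leaves})


@dataclass
class DistanceMatrices:
    """Directed distances D_A (alleles), D_S (SNVs), their product D_F, and restrictions."""

    d_allele: np.ndarray
    d_snv: np.ndarray
    restricted: np.ndarray
    sample_names: list[str]
    root_index: int

    @property
    def d_final(self) -> np.ndarray:
        return self.d_allele * self.d_snv

    def index(self, name: str) -> int:
        return self.sample_names.index(name)


# ---------------------------------------------------------------------------
# LOH bookkeeping


@dataclass(frozen=True)
class LohRun:
    """A maximal run of consecutive positions with a lost allele."""

    start: int
    end: int  # exclusive
    confident: bool  # True when supported by a long-enough low-LAF run

    def indices(self) -> range:
        return range(self.start, self.end)


def _runs_of(mask: np.ndarray, start: int, end: int) -> list[tuple[int, int]]:
    runs = []
    i = start
    while i < end:
        if mask[i]:
            j = i
            while j < end and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def loh_runs(
    profile: AlleleProfile, laf_column: np.ndarray, config: ModelConfig
) -> list[LohRun]:
    """Allele-loss runs of at least ``loh_run_length`` positions.

    A run is *confident* when it contains at least ``loh_run_length``
    consecutive LAF measurements below ``loh_laf_threshold``; otherwise the
    allele estimate alone claims the LOH and the run is only penalizing.
    Runs are maximal over consecutive measurements in genome order (an
    arm-level loss spans every SNP of the arm, and adjacent lost arms merge).
    """
    n = len(profile)
    alleles = profile.alleles
    lost = np.array(
        [al.a_count == 0 or al.b_count == 0 for al in alleles], dtype=bool
    )
    laf = np.asarray(laf_column, dtype=float)
    low_laf = np.where(np.isfinite(laf), laf < config.loh_laf_threshold, False) & lost
    L = config.loh_run_length
    out: list[LohRun] = []
    for rs, re in _runs_of(lost, 0, n):
        if re - rs < L:
            continue
        confident = any(ce - cs >= L for cs, ce in _runs_of(low_laf, rs, re))
        out.append(LohRun(rs, re, confident))
    return out


# ---------------------------------------------------------------------------
# Distance matrix construction


def build_distance_matrices(
    profiles: list[AlleleProfile],
    bundle: MeasurementBundle,
    config: ModelConfig,
) -> DistanceMatrices:
    """Pairwise allele distances with LOH / parental-allele / SNV rules applied."""
    m = len(profiles)
    if m != bundle.n_samples:
        raise ValueError("one profile per sample required")
    d_allele = np.zeros((m, m))
    for p in range(m):
        for c in range(m):
            if p != c:
                d_allele[p, c] = fst_event_distance(profiles[p], profiles[c])
    d_snv = np.ones((m, m))
    restricted = np.zeros((m, m), dtype=bool)
    np.fill_diagonal(restricted, True)
    restricted[:, bundle.normal_index] = True  # the precursor has no parent
    mats = DistanceMatrices(
        d_allele=d_allele,
        d_snv=d_snv,
        restricted=restricted,
        sample_names=list(bundle.sample_names),
        root_index=bundle.normal_index,
    )
    runs = {j: loh_runs(profiles[j], bundle.laf[:, j], config) for j in range(m)}
    apply_loh_rules(mats, profiles, runs, config)
    apply_parental_allele_rules(mats, bundle, runs, config)
    apply_snv_rules(mats, bundle, profiles, config)
    return mats


def apply_loh_rules(
    mats: DistanceMatrices,
    profiles: list[AlleleProfile],
    runs: dict[int, list[LohRun]],
    config: ModelConfig,
) -> DistanceMatrices:
    """Forbid (or penalize) edges from LOH samples to samples without that LOH.

    Re-gaining a lost allele is highly unlikely: a confident LOH run in a
    candidate parent that the candidate child does not share restricts the
    edge.  If only the allele estimate supports the LOH (no long low-LAF
    run), the edge is penalized by ``penalty_pa`` instead.
    """
    m = len(profiles)
    lost_masks = [
        np.array([al.a_count == 0 or al.b_count == 0 for al in pr.alleles], bool)
        for pr in profiles
    ]
    for p in range(m):
        for run in runs[p]:
            for c in range(m):
                if c == p:
                    continue
                child_shares = bool(lost_masks[c][run.start : run.end].all())
                if child_shares:
                    continue
                if run.confident:
                    mats.restricted[p, c] = True
                else:
                    mats.d_allele[p, c] += config.penalty_pa
    return mats


def apply_parental_allele_rules(
    mats: DistanceMatrices,
    bundle: MeasurementBundle,
    runs: dict[int, list[LohRun]],
    config: ModelConfig,
) -> DistanceMatrices:
    """Mutually forbid samples that lost different parental alleles.

    Where two samples share a confident LOH region, raw AFs near opposite
    extremes (below ``parental_af_low`` in one, above ``parental_af_high`` in
    the other at the same position) show that different parental alleles were
    lost, so neither sample can be an ancestor of the other.
    """
    m = bundle.n_samples
    lo, hi = config.parental_af_low, config.parental_af_high
    for j in range(m):
        for k in range(j + 1, m):
            conflict = False
            for rj in runs[j]:
                if not rj.confident:
                    continue
                for rk in runs[k]:
                    if not rk.confident:
                        continue
                    s = max(rj.start, rk.start)
                    e = min(rj.end, rk.end)
                    if s >= e:
                        continue
                    af_j = bundle.af[s:e, j]
                    af_k = bundle.af[s:e, k]
                    ok = np.isfinite(af_j) & np.isfinite(af_k)
                    opposite = ((af_j < lo) & (af_k > hi)) | (
                        (af_j > hi) & (af_k < lo)
                    )
                    if bool((opposite & ok).any()):
                        conflict = True
            if conflict:
                mats.restricted[j, k] = True
                mats.restricted[k, j] = True
    return mats


def _nearest_snp_index(bundle: MeasurementBundle, snv_pos: tuple[str, str, int]) -> int | None:
    chrom, arm, coord = snv_pos
    best = None
    best_gap = None
    for i, (pc, pa, pcoord) in enumerate(bundle.positions):
        if pc != chrom:
            continue
        gap = abs(pcoord - coord) + (0 if pa == arm else 10**9)
        if best_gap is None or gap < best_gap:
            best, best_gap = i, gap
    return best


def apply_snv_rules(
    mats: DistanceMatrices,
    bundle: MeasurementBundle,
    profiles: list[AlleleProfile],
    config: ModelConfig,
) -> DistanceMatrices:
    """Penalize edges implying an SNV loss without allele-loss evidence.

    A somatic SNV present in a candidate parent but absent in the child is
    only plausible when the carrying allele could have been lost: the child's
    copy number at the nearest measured SNP is below the parent's, or the
    child shows LOH there.  Otherwise ``penalty_ps`` multiplies into D_S.
    """
    if bundle.snv_af.size == 0:
        return mats
    present = snv_presence(bundle, config)
    m = bundle.n_samples
    nearest = [
        _nearest_snp_index(bundle, pos) for pos in bundle.snv_positions
    ]
    for p in range(m):
        for c in range(m):
            if p == c:
                continue
            for s in range(present.shape[0]):
                if not (present[s, p] and not present[s, c]):
                    continue
                idx = nearest[s]
                evidence = False
                if idx is not None:
                    child_al = profiles[c].alleles[idx]
                    parent_al = profiles[p].alleles[idx]
                    evidence = (
                        child_al.copy_number <= parent_al.copy_number - 1
                        or child_al.a_count == 0
                        or child_al.b_count == 0
                    )
                if not evidence:
                    mats.d_snv[p, c] += config.penalty_ps
    return mats


def snv_presence(bundle: MeasurementBundle, config: ModelConfig) -> np.ndarray:
    """Binarized SNV matrix (n_snvs x m); NaN counts as absent."""
    with np.errstate(invalid="ignore"):
        return np.where(
            np.isfinite(bundle.snv_af),
            bundle.snv_af >= config.snv_presence_threshold,
            False,
        )


# ---------------------------------------------------------------------------
# Edmonds and the ISA edit loop


def edmonds_arborescence(
    mats: DistanceMatrices,
    excluded: frozenset[tuple[str, str]] = frozenset(),
) -> Tree:
    """Minimum spanning arborescence over D_F, restricted edges removed."""
    names = mats.sample_names
    root = names[mats.root_index]
    d_final = mats.d_final
    graph = nx.DiGraph()
    graph.add_nodes_from(names)
    for p, pname in enumerate(names):
        for c, cname in enumerate(names):
            if mats.restricted[p, c] or (pname, cname) in excluded:
                continue
            graph.add_edge(pname, cname, weight=float(d_final[p, c]))
    try:
        msa = nx.minimum_spanning_arborescence(graph, attr="weight")
    except nx.NetworkXException:
        reachable = nx.descendants(graph, root) | {root}
        raise InfeasibleTreeError(sorted(set(names) - reachable)) from None
    parent: dict[str, str | None] = {name: None for name in names}
    weights: dict[tuple[str, str], float] = {}
    for p, c in msa.edges:
        parent[c] = p
        weights[(p, c)] = float(graph[p][c]["weight"])
    return Tree(parent=parent, root=root, edge_weights=weights)


def detect_isa_violations(
    tree: Tree, present: np.ndarray, sample_names: list[str]
) -> dict[int, list[tuple[str, str]]]:
    """SNVs gained independently on two or more edges of the tree."""
    col = {name: j for j, name in enumerate(sample_names)}
    gains: dict[int, list[tuple[str, str]]] = {}
    for p, c in sorted(tree.edges()):
        gained = present[:, col[c]] & ~present[:, col[p]]
        for s in np.flatnonzero(gained):
            gains.setdefault(int(s), []).append((p, c))
    return {s: edges for s, edges in gains.items() if len(edges) >= 2}


def _edge_gain_counts(
    tree: Tree, present: np.ndarray, sample_names: list[str]
) -> dict[tuple[str, str], int]:
    col = {name: j for j, name in enumerate(sample_names)}
    return {
        (p, c): int((present[:, col[c]] & ~present[:, col[p]]).sum())
        for p, c in tree.edges()
    }


def _allelic_total(tree: Tree, mats: DistanceMatrices) -> float:
    idx = {name: j for j, name in enumerate(mats.sample_names)}
    return float(sum(mats.d_allele[idx[p], idx[c]] for p, c in tree.edges()))


def resolve_isa(
    start_tree: Tree,
    mats: DistanceMatrices,
    present: np.ndarray,
    config: ModelConfig,
    rng: np.random.Generator,
) -> tuple[Tree, list[Tree]]:
    """Edit the arborescence until the infinite sites assumption holds.

    Randomized passes repeatedly remove the edge introducing the most SNVs
    among edges involved in a violation (ties broken at random) and re-run
    Edmonds; every updated tree generated this way is a candidate, up to a
    budget of ``isa_tree_count`` generated trees.  Returns the best tree
    (fewest violations, then lowest allelic distance, then lowest total
    distance) and the ranked candidate list.
    """
    names = mats.sample_names

    def n_violations(tree: Tree) -> int:
        return len(detect_isa_violations(tree, present, names))

    seen: dict = {start_tree.signature(): start_tree}
    max_edits = max(10, len(names) ** 2)
    generated = 0
    if n_violations(start_tree) > 0:
        while generated < config.isa_tree_count:
            pass_start = generated
            excluded: set[tuple[str, str]] = set()
            tree = start_tree
            for _ in range(max_edits):
                viols = detect_isa_violations(tree, present, names)
                if not viols or generated >= config.isa_tree_count:
                    break
                involved = sorted({e for edges in viols.values() for e in edges})
                counts = _edge_gain_counts(tree, present, names)
                top_count = max(counts[e] for e in involved)
                top = [e for e in involved if counts[e] == top_count]
                pick = top[int(rng.integers(len(top)))]
                excluded.add(pick)
                try:
                    tree = edmonds_arborescence(mats, frozenset(excluded))
                except InfeasibleTreeError:
                    break
                generated += 1
                seen.setdefault(tree.signature(), tree)
            if generated == pass_start:
                break  # pass made no progress; further passes cannot either

    def rank(tree: Tree):
        return (
            n_violations(tree),
            _allelic_total(tree, mats),
            tree.total_distance,
            tuple(sorted(tree.edges())),
        )

    ranked = sorted(seen.values(), key=rank)
    return ranked[0], ranked


# ---------------------------------------------------------------------------
# The outer T/C iteration


@dataclass
class InferenceResult:
    """Final estimates, tree, candidate trees and per-iteration log."""

    estimates: dict[str, SampleEstimate]
    tree: Tree
    candidates: list[Tree]
    iterations: list[dict] = field(default_factory=list)
    converged: bool = False


def precursor_profile(bundle: MeasurementBundle, config: ModelConfig) -> AlleleProfile:
    return AlleleProfile(
        tuple([config.precursor_alleles] * bundle.n_positions), bundle.arm_starts
    )


def run_inference(
    bundle: MeasurementBundle,
    config: ModelConfig,
    initial_tree: Tree | None = None,
) -> InferenceResult:
    """Alternate C- and T-steps until the tree recurs.

    The initial tree places every tumor sample as a child of the healthy or
    precursor sample.  Convergence: the current tree's edge set and total
    distance match a tree from any previous iteration.
    """
    names = list(bundle.sample_names)
    root = names[bundle.normal_index]
    rng = np.random.default_rng(config.rng_seed)
    present = snv_presence(bundle, config)

    root_profile = precursor_profile(bundle, config)
    root_estimate = SampleEstimate(
        copy_numbers=np.full(bundle.n_positions, config.precursor_alleles.copy_number),
        alleles=root_profile,
        mu=0.0,
        log_score=0.0,
    )
    tree = initial_tree or Tree.star(root, [n for n in names if n != root])
    estimates: dict[str, SampleEstimate] = {root: root_estimate}
    candidates: list[Tree] = [tree]
    history: list = []
    iterations: list[dict] = []
    converged = False

    for it in range(config.max_iterations):
        # C-step in topological order so children see fresh parent estimates.
        for name in tree.topological_order():
            if name == root:
                continue
            parent_name = tree.parent[name]
            parent_alleles = estimates[parent_name].alleles
            j = names.index(name)
            estimates[name] = infer_sample(bundle.laf[:, j], parent_alleles, config)
        profiles = [estimates[name].alleles for name in names]
        mats = build_distance_matrices(profiles, bundle, config)
        start = edmonds_arborescence(mats)
        tree, candidates = resolve_isa(start, mats, present, config, rng)
        iterations.append(
            {
                "iteration": it + 1,
                "total_distance": tree.total_distance,
                "violations": len(detect_isa_violations(tree, present, names)),
                "mu": {n: estimates[n].mu for n in names if n != root},
            }
        )
        sig = tree.signature()
        if sig in history:
            converged = True
            break
        history.append(sig)

    return InferenceResult(
        estimates=estimates,
        tree=tree,
        candidates=candidates[:10],
        iterations=iterations,
        converged=converged,
    )
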