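"""Error metrics for closed-loop simulation studies.

Four errors compare inference output with simulator ground truth: copy
numbers (mean absolute deviation), alleles (mean positionwise event
distance), tumor fraction (mean absolute error over tumor samples) and the
tree (ancestor-descendant pairs missed or invented, normalized by the number
of sample pairs).  The ambiguity report quantifies how many ground-truth
positions admit more than one allele explanation at the true tumor fraction,
and how often inference nevertheless recovers the right one.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np

from .cstep import SampleEstimate
from .model import (
    AlleleCombination,
    enumerate_allele_combinations,
    expected_laf,
    positionwise_event_distance,
)
from .simulate import SimulationTruth
from .tstep import Tree


@dataclass
class ErrorReport:
    """One dataset's errors."""

    e_c: float
    e_a: float
    e_mu: float
    e_t: float
    fp_count: int
    fn_count: int
    pair_count: int


def error_copy_numbers(c_true: np.ndarray, c_est: np.ndarray) -> float:
    """Mean absolute copy-number deviation over all matrix entries."""
    c_true = np.asarray(c_true, dtype=float)
    c_est = np.asarray(c_est, dtype=float)
    if c_true.shape != c_est.shape:
        raise ValueError("shapes must match")
    return float(np.abs(c_est - c_true).mean())


def error_alleles(
    a_true, a_est, mirror_forgiving: bool = False
) -> float:
    """Mean positionwise allele event distance (horizontal dependency ignored).

    With ``mirror_forgiving`` the smaller of the distances to the truth and
    to its A<->B mirror is scored, acknowledging that phase is unobservable.
    """
    rows_t = list(a_true)
    rows_e = list(a_est)
    if len(rows_t) != len(rows_e):
        raise ValueError("shapes must match")
    total = 0.0
    count = 0
    for row_t, row_e in zip(rows_t, rows_e):
        if len(row_t) != len(row_e):
            raise ValueError("shapes must match")
        for x, y in zip(row_t, row_e):
            d = positionwise_event_distance(x, y)
            if mirror_forgiving:
                d = min(d, positionwise_event_distance(x.mirror(), y))
            total += d
            count += 1
    return total / count if count else 0.0


def error_mu(mu_true, mu_est) -> float:
    """Mean absolute tumor-fraction error over tumor samples."""
    mu_true = np.asarray(mu_true, dtype=float)
    mu_est = np.asarray(mu_est, dtype=float)
    if mu_true.shape != mu_est.shape:
        raise ValueError("shapes must match")
    return float(np.abs(mu_est - mu_true).mean())


def error_tree(t_true: Tree, t_est: Tree) -> tuple[float, int, int]:
    """Ancestry-pair tree error: (FP + FN) / C(m, 2).

    A relation is an ordered (ancestor, descendant) sample pair implied by a
    tree.  False negatives are relations present in the truth but absent from
    the estimate; false positives the reverse.  The denominator counts all
    unordered sample pairs.
    """
    if set(t_true.parent) != set(t_est.parent):
        raise ValueError("trees must share the same node set")
    rel_true = t_true.ancestry_pairs()
    rel_est = t_est.ancestry_pairs()
    fn = len(rel_true - rel_est)
    fp = len(rel_est - rel_true)
    pairs = comb(len(t_true.parent), 2)
    return (fp + fn) / pairs, fp, fn


def evaluate_run(
    truth: SimulationTruth,
    estimates: dict[str, SampleEstimate],
    tree: Tree,
    mirror_forgiving: bool = False,
) -> ErrorReport:
    """All four errors for one inference run against its simulation truth."""
    if truth.c_matrix is None or truth.a_matrix is None:
        raise ValueError("truth lacks measurement-aligned matrices")
    tumor = truth.tumor_names()
    names = truth.sample_names
    n = truth.c_matrix.shape[0]
    col = {name: j for j, name in enumerate(names)}
    c_true = truth.c_matrix[:, [col[t] for t in tumor]]
    c_est = np.column_stack([estimates[t].copy_numbers for t in tumor])
    a_true = [[truth.a_matrix[i][col[t]] for t in tumor] for i in range(n)]
    a_est = [[estimates[t].alleles.alleles[i] for t in tumor] for i in range(n)]
    e_c = error_copy_numbers(c_true, c_est)
    e_a = error_alleles(a_true, a_est, mirror_forgiving=mirror_forgiving)
    e_mu = error_mu(
        [truth.mu] * len(tumor), [estimates[t].mu for t in tumor]
    )
    e_t, fp, fn = error_tree(truth.tree, tree)
    return ErrorReport(
        e_c=e_c,
        e_a=e_a,
        e_mu=e_mu,
        e_t=e_t,
        fp_count=fp,
        fn_count=fn,
        pair_count=comb(len(names), 2),
    )


# ---------------------------------------------------------------------------
# Ambiguity analysis


@lru_cache(maxsize=None)
def _canonical_laf_table(mu: float, kmin: int, kmax: int) -> tuple:
    table = []
    for c in range(kmin, kmax + 1):
        for q in enumerate_allele_combinations(c):
            qc = q.canonical()
            if qc != q:
                continue  # one representative per mirror pair
            table.append((qc, expected_laf(qc, mu)))
    return tuple(table)


def is_ambiguous(
    allele: AlleleCombination,
    mu: float,
    kmin: int = 1,
    kmax: int = 6,
    tol: float = 1e-6,
) -> bool:
    """Whether another allele multiset yields the same expected LAF at ``mu``.

    Mirrors (AA vs BB) count as the same explanation; a position is ambiguous
    when a multiset with a *different* canonical form lands within ``tol`` of
    the truth's noise-free LAF.
    """
    target = expected_laf(allele, mu)
    can = allele.canonical()
    for qc, laf in _canonical_laf_table(round(mu, 12), kmin, kmax):
        if qc == can:
            continue
        if abs(laf - target) < tol:
            return True
    return False


def ambiguity_report(
    truth: SimulationTruth,
    estimates: dict[str, SampleEstimate],
    kmin: int = 1,
    kmax: int = 6,
) -> tuple[float, float, int, int]:
    """(fraction ambiguous, fraction of ambiguous resolved, n_ambiguous, n_total).

    A ground-truth position is ambiguous when its expected LAF at the true
    tumor fraction is attainable by more than one canonical allele multiset;
    it is resolved when the inferred allele matches the truth up to mirror.
    """
    if truth.a_matrix is None:
        raise ValueError("truth lacks measurement-aligned matrices")
    tumor = truth.tumor_names()
    names = truth.sample_names
    col = {name: j for j, name in enumerate(names)}
    n = len(truth.a_matrix)
    n_total = 0
    n_amb = 0
    n_resolved = 0
    for t in tumor:
        j = col[t]
        est_profile = estimates[t].alleles.alleles if estimates else None
        for i in range(n):
            al = truth.a_matrix[i][j]
            n_total += 1
            if not is_ambiguous(al, truth.mu, kmin, kmax):
                continue
            n_amb += 1
            if est_profile is not None:
                if est_profile[i].canonical() == al.canonical():
                    n_resolved += 1
    frac_amb = n_amb / n_total if n_total else 0.0
    frac_res = n_resolved / n_amb if n_amb else float("nan")
    return frac_amb, frac_res, n_amb, n_total
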