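"""Per-sample maximization of P(C, mu | LAF, tree).

For one tumor sample the copy-number column C and tumor fraction mu are
found by exhaustive search over a mu grid combined with a left-to-right
chain over adjacent-position windows.  Each window couples two adjacent
positions of the child sample with the corresponding positions of its
parent in the current tree: the objective is the product of the child's two
LAF mixture likelihoods and a copy-number prior 1/(d+1), where d is the
event distance (with horizontal dependency) between the window's assigned
child alleles and the parent alleles.  The chain is solved greedily as
windows shift one position at a time; a Viterbi-style dynamic program over
the same objective is available as an alternative solver and as a test
oracle.

The whole grid (positions x candidate copy numbers x mu values) is
evaluated with vectorized numpy; the scalar functions in
:mod:`laftree.model` define the semantics and serve as the reference path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .distance import AlleleProfile, fst_event_distance
from .model import (
    AlleleCombination,
    MeasurementBundle,
    ModelConfig,
    assign_alleles,
    laf_component_model,
    laf_likelihood,
)

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_LOG_FLOOR = 1e-300
_TIE_TOL = 1e-9


@dataclass
class SampleEstimate:
    """One sample's inferred copy numbers, alleles, tumor fraction and score."""

    copy_numbers: np.ndarray
    alleles: AlleleProfile
    mu: float
    log_score: float

    def __post_init__(self) -> None:
        self.copy_numbers = np.asarray(self.copy_numbers, dtype=int)
        if len(self.alleles) != self.copy_numbers.size:
            raise ValueError("alleles and copy_numbers must align")
        for c, al in zip(self.copy_numbers, self.alleles.alleles):
            if al.copy_number != c:
                raise ValueError("allele copy numbers must match copy_numbers")


@dataclass
class Window:
    """Two adjacent child positions with their parent alleles and LAFs."""

    laf: tuple[float, float]
    child_copies: tuple[int, int]
    parent_alleles: tuple[AlleleCombination, AlleleCombination]


def window_objective(window: Window, mu: float, config: ModelConfig) -> float:
    """Likelihood x prior contribution of one window (parent factors omitted).

    The parent's own likelihood factors are constant under the argmax over
    the child's copy numbers and are left out.  Missing LAFs contribute a
    neutral factor of 1 and inherit the parent allele.
    """
    liks: list[float] = []
    assigned: list[AlleleCombination] = []
    for laf_value, c, parent_allele in zip(
        window.laf, window.child_copies, window.parent_alleles
    ):
        if laf_value is None or (isinstance(laf_value, float) and np.isnan(laf_value)):
            liks.append(1.0)
            assigned.append(parent_allele)
            continue
        if not config.kmin <= c <= config.kmax:
            raise ValueError("window copy numbers must lie within [kmin, kmax]")
        comps = laf_component_model(c, parent_allele, mu, config.sigma)
        liks.append(laf_likelihood(laf_value, comps))
        assigned.append(assign_alleles(laf_value, comps))
    parent_profile = AlleleProfile(tuple(window.parent_alleles), (0,))
    child_profile = AlleleProfile(tuple(assigned), (0,))
    d = fst_event_distance(parent_profile, child_profile)
    return liks[0] * liks[1] / (d + 1.0)


def _window_distance(p1a, p1b, p2a, p2b, c1a, c1b, c2a, c2b):
    """Vectorized two-position event distance (child pair vs parent pair)."""
    d = 0
    for pa1, pa2, ch1, ch2 in (((p1a, p2a, c1a, c2a)), ((p1b, p2b, c1b, c2b))):
        d1 = ch1 - pa1
        d2 = ch2 - pa2
        g1 = np.maximum(d1, 0)
        g2 = np.maximum(d2, 0)
        l1 = np.maximum(-d1, 0)
        l2 = np.maximum(-d2, 0)
        d = d + g1 + np.maximum(g2 - g1, 0) + l1 + np.maximum(l2 - l1, 0)
    return d


def _incremental_distance(p1a, p1b, p2a, p2b, c1a, c1b, c2a, c2b):
    """Events *starting* at the window's right position (left already charged)."""
    d = 0
    for pa1, pa2, ch1, ch2 in (((p1a, p2a, c1a, c2a)), ((p1b, p2b, c1b, c2b))):
        d1 = ch1 - pa1
        d2 = ch2 - pa2
        g1 = np.maximum(d1, 0)
        g2 = np.maximum(d2, 0)
        l1 = np.maximum(-d1, 0)
        l2 = np.maximum(-d2, 0)
        d = d + np.maximum(g2 - g1, 0) + np.maximum(l2 - l1, 0)
    return d


class _Grid:
    """Precomputed likelihoods and nearest-mean allele assignments.

    Shapes are (n positions, K candidate copies, M mu values); ``Aass`` and
    ``Bass`` hold the allele counts a hard assignment of the measured LAF
    would produce under each (copy, mu) candidate.
    """

    def __init__(
        self, laf: np.ndarray, parent: AlleleProfile, config: ModelConfig
    ) -> None:
        n = laf.size
        mus = config.mu_grid()
        M = mus.size
        copies = np.arange(config.kmin, config.kmax + 1)
        K = copies.size
        sigma = config.sigma
        pa = parent.a_counts()
        pb = parent.b_counts()
        observed = np.isfinite(laf)

        self.mus = mus
        self.copies = copies
        self.observed = observed
        self.logL = np.zeros((n, K, M))
        self.Aass = np.zeros((n, K, M), dtype=np.int16)
        self.Bass = np.zeros((n, K, M), dtype=np.int16)

        # Group observed positions by their parent allele: the prior weights
        # depend only on (parent allele, candidate copy).
        groups: dict[tuple[int, int], np.ndarray] = {}
        obs_idx = np.flatnonzero(observed)
        for key in {(int(pa[i]), int(pb[i])) for i in obs_idx}:
            rows = obs_idx[(pa[obs_idx] == key[0]) & (pb[obs_idx] == key[1])]
            groups[key] = rows

        safe_laf = np.where(observed, laf, 0.25)
        folded = config.likelihood_mode == "folded"
        for ki, c in enumerate(copies):
            b = np.arange(c + 1)
            a = c - b
            with np.errstate(divide="ignore", invalid="ignore"):
                af = (mus[None, :] * b[:, None] + (1.0 - mus)[None, :]) / (
                    mus * c + 2.0 * (1.0 - mus)
                )[None, :]
            mean = np.minimum(af, 1.0 - af)  # (c+1, M)
            z_mass = norm.cdf((0.5 - mean) / sigma) - norm.cdf((0.0 - mean) / sigma)
            for (paa, pab), rows in groups.items():
                ed = np.abs(a - paa) + np.abs(b - pab)
                w = 1.0 / (ed + 1.0)
                w = w / w.sum()
                z = (laf[rows, None, None] - mean[None, :, :]) / sigma
                pdf = np.exp(-0.5 * z * z) / (sigma * _SQRT_2PI)
                if folded:
                    zr = (laf[rows, None, None] - (1.0 - mean[None, :, :])) / sigma
                    pdf = pdf + np.exp(-0.5 * zr * zr) / (sigma * _SQRT_2PI)
                else:
                    pdf = pdf / z_mass[None, :, :]
                lik = (w[None, :, None] * pdf).sum(axis=1)
                self.logL[rows, ki, :] = np.log(np.maximum(lik, _LOG_FLOOR))
            # Nearest-mean hard assignment with the tie rules of assign_alleles:
            # on equal distance prefer the higher mean, then more B alleles.
            dist = np.abs(safe_laf[:, None, None] - mean[None, :, :])  # (n, c+1, M)
            best_d = dist[:, 0, :].copy()
            best_m = np.broadcast_to(mean[0], best_d.shape).copy()
            best_a = np.full(best_d.shape, a[0], dtype=np.int16)
            best_b = np.full(best_d.shape, b[0], dtype=np.int16)
            for q in range(1, c + 1):
                dq = dist[:, q, :]
                mq = np.broadcast_to(mean[q], dq.shape)
                eq_d = np.abs(dq - best_d) <= 1e-12
                eq_m = np.abs(mq - best_m) <= 1e-9
                better = (
                    (dq < best_d - 1e-12)
                    | (eq_d & ~eq_m & (mq > best_m))
                    | (eq_d & eq_m & (b[q] > best_b))
                )
                best_d = np.where(better, dq, best_d)
                best_m = np.where(better, mq, best_m)
                best_a = np.where(better, np.int16(a[q]), best_a)
                best_b = np.where(better, np.int16(b[q]), best_b)
            self.Aass[:, ki, :] = best_a
            self.Bass[:, ki, :] = best_b

        # Missing measurements inherit the parent allele and contribute
        # a neutral likelihood factor.
        miss = ~observed
        if miss.any():
            self.logL[miss, :, :] = 0.0
            self.Aass[miss, :, :] = pa[miss, None, None]
            self.Bass[miss, :, :] = pb[miss, None, None]


def _update_choice(best_obj, best_key, best_k, obj_k, key_k, k):
    eq = np.abs(obj_k - best_obj) <= _TIE_TOL
    better = (obj_k > best_obj + _TIE_TOL) | (eq & (key_k < best_key))
    return (
        np.where(better, obj_k, best_obj),
        np.where(better, key_k, best_key),
        np.where(better, k, best_k),
        better,
    )


def _arm_segments(n: int, arm_starts) -> list[tuple[int, int]]:
    starts = sorted(set(arm_starts) | {0})
    return [
        (s, (starts[i + 1] if i + 1 < len(starts) else n))
        for i, s in enumerate(starts)
    ]


def _greedy_chain(grid: _Grid, parent: AlleleProfile, config: ModelConfig):
    """Greedy left-to-right chain, vectorized over the mu grid.

    Returns (choices (n, M) copy-index per position, total log score (M,)).
    """
    n, K, M = grid.logL.shape
    pa, pb = parent.a_counts(), parent.b_counts()
    idxM = np.arange(M)
    choices = np.zeros((n, M), dtype=np.int16)
    total = np.zeros(M)
    for s, e in _arm_segments(n, parent.arm_starts):
        # First position of the arm: marginal likelihood; ties broken toward
        # smaller event distance to the parent, then smaller copy number.
        ed0 = np.abs(grid.Aass[s] - pa[s]) + np.abs(grid.Bass[s] - pb[s])  # (K, M)
        best_obj = grid.logL[s, 0, :].copy()
        best_key = ed0[0].astype(float)
        best_k = np.zeros(M, dtype=np.int16)
        for k in range(1, K):
            best_obj, best_key, best_k, _ = _update_choice(
                best_obj, best_key, best_k, grid.logL[s, k, :], ed0[k].astype(float), k
            )
        choices[s] = best_k
        if e - s == 1:
            total += best_obj
            continue
        prev = best_k
        for i in range(s + 1, e):
            dist_fn = (
                _window_distance
                if config.prior_mode == "window" or i == s + 1
                else _incremental_distance
            )
            c1a = grid.Aass[i - 1, prev, idxM]
            c1b = grid.Bass[i - 1, prev, idxM]
            lprev = grid.logL[i - 1, prev, idxM]
            best_obj = None
            for k in range(K):
                d = dist_fn(
                    pa[i - 1], pb[i - 1], pa[i], pb[i],
                    c1a, c1b, grid.Aass[i, k, :], grid.Bass[i, k, :],
                )
                obj = lprev + grid.logL[i, k, :] - np.log1p(d)
                if best_obj is None:
                    best_obj, best_key, best_k = obj, d.astype(float), np.full(
                        M, k, dtype=np.int16
                    )
                else:
                    best_obj, best_key, best_k, _ = _update_choice(
                        best_obj, best_key, best_k, obj, d.astype(float), k
                    )
            choices[i] = best_k
            total += best_obj
            prev = best_k
    return choices, total


def _dp_chain(grid: _Grid, parent: AlleleProfile, config: ModelConfig):
    """Viterbi-style chain optimum over the same window objective."""
    n, K, M = grid.logL.shape
    pa, pb = parent.a_counts(), parent.b_counts()
    choices = np.zeros((n, M), dtype=np.int16)
    total = np.zeros(M)
    for s, e in _arm_segments(n, parent.arm_starts):
        if e - s == 1:
            best_k = np.argmax(grid.logL[s], axis=0)
            choices[s] = best_k
            total += np.max(grid.logL[s], axis=0)
            continue
        dp = np.zeros((K, M))
        back = np.zeros((e - s, K, M), dtype=np.int16)
        for i in range(s + 1, e):
            dist_fn = (
                _window_distance
                if config.prior_mode == "window" or i == s + 1
                else _incremental_distance
            )
            # transition scores (K_prev, K_next, M)
            d = dist_fn(
                pa[i - 1], pb[i - 1], pa[i], pb[i],
                grid.Aass[i - 1, :, None, :], grid.Bass[i - 1, :, None, :],
                grid.Aass[i, None, :, :], grid.Bass[i, None, :, :],
            )
            step = (
                dp[:, None, :]
                + grid.logL[i - 1, :, None, :]
                + grid.logL[i, None, :, :]
                - np.log1p(d)
            )
            back[i - s] = np.argmax(step, axis=0)
            dp = np.max(step, axis=0)
        last = np.argmax(dp, axis=0)
        total += np.max(dp, axis=0)
        idxM = np.arange(M)
        choices[e - 1] = last
        for i in range(e - 1, s, -1):
            last = back[i - s][last, idxM]
            choices[i - 1] = last
    return choices, total


def infer_sample(
    laf_column: np.ndarray,
    parent_profile: AlleleProfile,
    config: ModelConfig,
) -> SampleEstimate:
    """Infer one sample's copy numbers, alleles, and tumor fraction.

    Exhaustively evaluates mu on a grid from 0 to 1 (step ``mu_step``); for
    each mu, copy numbers are chained over adjacent-position windows; the
    (C, mu) with maximal total score wins, ties broken toward larger mu.
    """
    laf = np.asarray(laf_column, dtype=float)
    if laf.size != len(parent_profile):
        raise ValueError("laf_column and parent profile must align")
    if not np.isfinite(laf).any():
        raise ValueError("uninformative sample: all LAF measurements are missing")
    grid = _Grid(laf, parent_profile, config)
    solver = _dp_chain if config.solver == "dp" else _greedy_chain
    choices, total = solver(grid, parent_profile, config)
    # Best mu; exact ties go to the larger mu (near-pure solutions are the
    # more interpretable ones).
    M = total.size
    rev_best = int(np.argmax(np.round(total[::-1], 9)))
    mu_idx = M - 1 - rev_best
    mu = float(grid.mus[mu_idx])

    n = laf.size
    ks = choices[:, mu_idx]
    a_fin = grid.Aass[np.arange(n), ks, mu_idx]
    b_fin = grid.Bass[np.arange(n), ks, mu_idx]
    alleles = tuple(
        AlleleCombination(int(a), int(b)) for a, b in zip(a_fin, b_fin)
    )
    profile = AlleleProfile(alleles, parent_profile.arm_starts)
    copy_numbers = (a_fin + b_fin).astype(int)
    return SampleEstimate(
        copy_numbers=copy_numbers,
        alleles=profile,
        mu=mu,
        log_score=float(total[mu_idx]),
    )


def derive_allele_matrix(
    copy_numbers: np.ndarray,
    mu: float,
    parent_profile: AlleleProfile,
    laf_column: np.ndarray,
    config: ModelConfig,
) -> AlleleProfile:
    """Hard-assign alleles per position from (C, mu) via the mixture means."""
    laf = np.asarray(laf_column, dtype=float)
    copy_numbers = np.asarray(copy_numbers, dtype=int)
    if not laf.size == copy_numbers.size == len(parent_profile):
        raise ValueError("inputs must align")
    out: list[AlleleCombination] = []
    for i, (c, laf_value) in enumerate(zip(copy_numbers, laf)):
        parent_allele = parent_profile.alleles[i]
        if not np.isfinite(laf_value):
            out.append(parent_allele)
            continue
        comps = laf_component_model(int(c), parent_allele, mu, config.sigma)
        out.append(assign_alleles(float(laf_value), comps))
    return AlleleProfile(tuple(out), parent_profile.arm_starts)


def infer_all_samples(
    bundle: MeasurementBundle,
    parent_profiles: dict[int, AlleleProfile],
    config: ModelConfig,
) -> dict[int, SampleEstimate]:
    """C-step over all tumor columns given each column's parent profile."""
    return {
        j: infer_sample(bundle.laf[:, j], parent_profiles[j], config)
        for j in parent_profiles
    }
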