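"""Whole-genome allele event distance with horizontal dependency.

Adjacent genomic positions tend to be altered by the same copy-number event,
so a gain or loss spanning a run of consecutive positions should be counted
as one event, not one per position.  The distance implemented here is the
minimum number of contiguous single-allele +/-1 interval operations that
transform one allele profile into another, computed in closed form from
prefix differences of the per-position gain/loss requirements (the same
quantity a finite-state transducer over the profile computes).  Events never
span chromosome-arm boundaries.

A breadth-first brute-force oracle over explicit interval-operation
sequences is provided for validation on tiny instances.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import AlleleCombination


@dataclass(frozen=True)
class AlleleProfile:
    """An ordered allele multiset per measured position (one sample column)."""

    alleles: tuple[AlleleCombination, ...]
    arm_starts: tuple[int, ...] = (0,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(self.alleles))
        starts = tuple(sorted(set(self.arm_starts) | {0}))
        object.__setattr__(self, "arm_starts", starts)
        n = len(self.alleles)
        if any(s < 0 or s >= max(n, 1) for s in starts):
            raise ValueError("arm_starts out of range")

    def __len__(self) -> int:
        return len(self.alleles)

    def a_counts(self) -> np.ndarray:
        return np.array([al.a_count for al in self.alleles], dtype=np.int64)

    def b_counts(self) -> np.ndarray:
        return np.array([al.b_count for al in self.alleles], dtype=np.int64)


def _check_compatible(parent: AlleleProfile, child: AlleleProfile) -> None:
    if len(parent) != len(child):
        raise ValueError("profiles must have equal length")
    if parent.arm_starts != child.arm_starts:
        raise ValueError("profiles must share arm boundaries")


def _interval_events(delta: np.ndarray, arm_starts: Sequence[int]) -> int:
    """Minimal contiguous +/-1 interval operations realizing per-position deltas."""
    total = 0
    for sign in (1, -1):
        req = np.maximum(sign * delta, 0)
        prev = np.zeros_like(req)
        prev[1:] = req[:-1]
        for s in arm_starts:
            prev[s] = 0  # events reset at each arm start
        total += int(np.maximum(req - prev, 0).sum())
    return total


def fst_event_distance(parent: AlleleProfile, child: AlleleProfile) -> int:
    """Event distance between two allele profiles with horizontal dependency.

    Each single-allele gain or loss spanning any run of adjacent positions
    (within one chromosome arm) counts one event.
    """
    _check_compatible(parent, child)
    if len(parent) == 0:
        return 0
    da = child.a_counts() - parent.a_counts()
    db = child.b_counts() - parent.b_counts()
    starts = parent.arm_starts
    return _interval_events(da, starts) + _interval_events(db, starts)


def copy_number_prior(parent: AlleleProfile, child: AlleleProfile) -> float:
    """Reciprocal pseudocounted event distance, P(C | tree) for one profile pair."""
    return 1.0 / (fst_event_distance(parent, child) + 1.0)


def brute_force_event_distance(
    parent: AlleleProfile,
    child: AlleleProfile,
    max_positions: int = 6,
    max_copy: int = 4,
) -> int:
    """BFS oracle over explicit interval-operation sequences (tests only).

    Explores sequences of single-allele +/-1 operations applied to contiguous
    position intervals within one arm.  Intermediate per-position counts are
    confined to the bounding box of parent and child (plus one unit of
    slack), which cannot exclude an optimal sequence for monotone interval
    operations.  Refuses instances that are too large.
    """
    _check_compatible(parent, child)
    n = len(parent)
    if n == 0:
        return 0
    if n > max_positions:
        raise ValueError(f"instance too large: {n} positions (max {max_positions})")
    pa, pb = parent.a_counts(), parent.b_counts()
    ca, cb = child.a_counts(), child.b_counts()
    if max(pa.max(initial=0) + pb.max(initial=0), ca.max(initial=0) + cb.max(initial=0)) > 2 * max_copy:
        raise ValueError("instance too large: copy numbers exceed oracle bound")
    lo_a = np.maximum(np.minimum(pa, ca) - 1, 0)
    hi_a = np.maximum(pa, ca) + 1
    lo_b = np.maximum(np.minimum(pb, cb) - 1, 0)
    hi_b = np.maximum(pb, cb) + 1

    arm_of = np.zeros(n, dtype=int)
    for k, s in enumerate(parent.arm_starts):
        arm_of[s:] = k
    intervals = [
        (i, j)
        for i in range(n)
        for j in range(i, n)
        if arm_of[i] == arm_of[j]
    ]

    start = tuple(zip(pa.tolist(), pb.tolist()))
    goal = tuple(zip(ca.tolist(), cb.tolist()))
    if start == goal:
        return 0
    seen = {start}
    queue: deque[tuple[tuple[tuple[int, int], ...], int]] = deque([(start, 0)])
    while queue:
        state, dist = queue.popleft()
        for i, j in intervals:
            for which in (0, 1):
                for sign in (1, -1):
                    nxt = list(state)
                    ok = True
                    for p in range(i, j + 1):
                        a, b = nxt[p]
                        if which == 0:
                            a += sign
                            if not lo_a[p] <= a <= hi_a[p]:
                                ok = False
                                break
                        else:
                            b += sign
                            if not lo_b[p] <= b <= hi_b[p]:
                                ok = False
                                break
                        nxt[p] = (a, b)
                    if not ok:
                        continue
                    nxt_t = tuple(nxt)
                    if nxt_t == goal:
                        return dist + 1
                    if nxt_t not in seen:
                        seen.add(nxt_t)
                        queue.append((nxt_t, dist + 1))
    raise RuntimeError("unreachable: interval operations connect all profiles")
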