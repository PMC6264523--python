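"""Single-position probability model for lesser-allele-frequency (LAF) data.

A tumor sample is modeled as a two-population mixture: one dominant tumor
subclone (cell fraction ``mu``) and healthy diploid cells (fraction
``1 - mu``).  At a heterozygous germline SNP the healthy cells carry alleles
AB; the tumor subclone carries some multiset of A (reference) and B (variant)
copies.  The expected variant allele frequency of such a mixture is

    AF = (mu * b + (1 - mu) * 1) / (mu * c + (1 - mu) * 2)

where ``b`` is the number of B copies and ``c`` the tumor copy number at the
position.  The lesser allele frequency LAF = min(AF, 1 - AF) folds away the
unknown phase, so the model lives on [0, 0.5] and cannot distinguish an
allele multiset from its A<->B mirror.

Measured LAFs are modeled as a Gaussian mixture: one component per allele
multiset compatible with a candidate copy number (the set Q), each truncated
to [0, 0.5], with means given by the expected LAF and weights given by a
parent-conditioned prior that favors small allele event distances between a
subclone and its parent in the current tree estimate.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True, order=True)
class AlleleCombination:
    """An unphased multiset of A (reference) and B (variant) allele copies."""

    a_count: int
    b_count: int

    def __post_init__(self) -> None:
        if self.a_count < 0 or self.b_count < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def copy_number(self) -> int:
        return self.a_count + self.b_count

    def __str__(self) -> str:
        return "A" * self.a_count + "B" * self.b_count

    @classmethod
    def from_string(cls, text: str) -> "AlleleCombination":
        """Parse a canonical allele string such as ``"ABB"`` (``"-"`` = empty)."""
        text = text.strip()
        if text in ("", "-"):
            return cls(0, 0)
        if set(text) - {"A", "B"}:
            raise ValueError(f"invalid allele string: {text!r}")
        return cls(text.count("A"), text.count("B"))

    def mirror(self) -> "AlleleCombination":
        """Swap A and B counts (the phase-indistinguishable twin)."""
        return AlleleCombination(self.b_count, self.a_count)

    def canonical(self) -> "AlleleCombination":
        """The mirror representative with the most B alleles (e.g. AA -> BB)."""
        return self if self.b_count >= self.a_count else self.mirror()

    @property
    def is_balanced(self) -> bool:
        return self.a_count == self.b_count


def positionwise_event_distance(x: AlleleCombination, y: AlleleCombination) -> int:
    """Number of single-allele gains/losses separating two allele multisets."""
    return abs(x.a_count - y.a_count) + abs(x.b_count - y.b_count)


def enumerate_allele_combinations(copy_number: int) -> list[AlleleCombination]:
    """All allele multisets of a given total copy number (the set Q).

    Ordered deterministically by ascending B count, so downstream
    most-B tie-breaks are reproducible.
    """
    if copy_number < 0:
        raise ValueError("copy number must be non-negative")
    return [AlleleCombination(copy_number - b, b) for b in range(copy_number + 1)]


def expected_laf(allele: AlleleCombination, mu: float) -> float:
    """Noise-free LAF of a tumor/healthy mixture carrying ``allele`` at fraction ``mu``."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must lie in [0, 1]")
    c = allele.copy_number
    if c == 0 and mu == 1.0:
        raise ValueError("undefined measurement: copy number 0 in a pure tumor sample")
    af = (mu * allele.b_count + (1.0 - mu)) / (mu * c + 2.0 * (1.0 - mu))
    return min(af, 1.0 - af)


def allele_prior(
    child: AlleleCombination,
    parent: AlleleCombination,
    q_set: Sequence[AlleleCombination],
) -> float:
    """Parent-conditioned prior over a candidate set Q.

    P(child | parent) is proportional to 1 / (ED(child, parent) + 1), where ED
    is the positionwise allele event distance and the pseudocount of one
    avoids division by zero; normalized over ``q_set``.
    """
    q_list = list(q_set)
    if not q_list:
        raise ValueError("q_set must be nonempty")
    if child not in q_list:
        raise ValueError(f"child {child} not in candidate set")
    weights = [1.0 / (positionwise_event_distance(q, parent) + 1.0) for q in q_list]
    total = sum(weights)
    return (1.0 / (positionwise_event_distance(child, parent) + 1.0)) / total


@dataclass(frozen=True)
class MixtureComponent:
    """One truncated-Gaussian component of the LAF mixture."""

    allele: AlleleCombination
    mean: float
    weight: float
    sigma: float


def _truncnorm_pdf(x: float, mean: float, sigma: float) -> float:
    # Gaussian truncated to the LAF support [0, 0.5], renormalized.
    z_mass = norm.cdf((0.5 - mean) / sigma) - norm.cdf((0.0 - mean) / sigma)
    u = (x - mean) / sigma
    return math.exp(-0.5 * u * u) / (sigma * _SQRT_2PI) / z_mass


def laf_component_model(
    copy_number: int,
    parent: AlleleCombination,
    mu: float,
    sigma: float,
) -> list[MixtureComponent]:
    """Mixture components for one position under a candidate copy number.

    One component per element of Q(copy_number); means are the expected LAFs
    and weights the parent-conditioned allele priors (sum to 1).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    q_set = enumerate_allele_combinations(copy_number)
    return [
        MixtureComponent(q, expected_laf(q, mu), allele_prior(q, parent, q_set), sigma)
        for q in q_set
    ]


def laf_likelihood(laf_value: float, components: Sequence[MixtureComponent]) -> float:
    """Mixture density of a measured LAF under the components."""
    if not 0.0 <= laf_value <= 0.5:
        raise ValueError("LAF must lie in [0, 0.5]")
    return sum(c.weight * _truncnorm_pdf(laf_value, c.mean, c.sigma) for c in components)


def assign_alleles(
    laf_value: float, components: Sequence[MixtureComponent]
) -> AlleleCombination:
    """Hard-assign a measured LAF to the allele multiset of the nearest component.

    Decision boundaries sit at the midpoints between adjacent distinct
    component means; a value exactly on a boundary goes to the higher-mean
    (more balanced) side.  Components with identical means (the AA/BB
    ambiguity) collapse to the one with the most B alleles.
    """
    if not components:
        raise ValueError("components must be nonempty")
    # Collapse (near-)equal means, preferring more B alleles.
    ordered: list[MixtureComponent] = []
    for comp in sorted(components, key=lambda c: (c.mean, c.allele.b_count)):
        if ordered and abs(comp.mean - ordered[-1].mean) <= 1e-9:
            if comp.allele.b_count > ordered[-1].allele.b_count:
                ordered[-1] = comp  # higher-B entry wins the mirror tie
        else:
            ordered.append(comp)
    if len(ordered) == 1:
        return ordered[0].allele
    boundaries = [
        0.5 * (ordered[i].mean + ordered[i + 1].mean) for i in range(len(ordered) - 1)
    ]
    idx = bisect_right(boundaries, laf_value)
    return ordered[idx].allele


@dataclass
class ModelConfig:
    """Tunable parameters of the inference model.

    Defaults reflect targeted sequencing at >1000x depth, where the LAF noise
    is approximately Gaussian with standard deviation 0.02.
    """

    sigma: float = 0.02
    kmin: int = 1
    kmax: int = 6
    mu_step: float = 0.01
    loh_run_length: int = 10
    loh_laf_threshold: float = 0.3
    parental_af_low: float = 0.1
    parental_af_high: float = 0.9
    penalty_pa: float = 10.0
    penalty_ps: float = 10.0
    snv_presence_threshold: float = 0.05
    isa_tree_count: int = 50
    max_iterations: int = 10
    precursor_alleles: AlleleCombination = field(
        default_factory=lambda: AlleleCombination(1, 1)
    )
    rng_seed: int = 0
    solver: str = "greedy"  # "greedy" (default) or "dp"
    # How the copy-number prior charges events along the chain:
    #   "window"      - every window pays 1/(d_w + 1) with d_w the full
    #                   two-position event distance of the window;
    #   "incremental" - an event spanning several adjacent positions is
    #                   charged only in the window where it starts, so the
    #                   product over windows tracks the reciprocal of the
    #                   total event distance of the column.
    prior_mode: str = "window"
    # Density model for the measured LAF given a component mean:
    #   "truncated" - Gaussian truncated to [0, 0.5] and renormalized;
    #   "folded"    - Gaussian reflected at the 0.5 boundary (the exact
    #                 density of min(AF, 1-AF) for Gaussian AF noise).
    likelihood_mode: str = "truncated"

    def __post_init__(self) -> None:
        if not 0 < self.mu_step <= 1:
            raise ValueError("mu_step must lie in (0, 1]")
        if self.kmin > self.kmax or self.kmin < 0:
            raise ValueError("need 0 <= kmin <= kmax")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.loh_laf_threshold <= 0.5:
            raise ValueError("loh_laf_threshold must lie in [0, 0.5]")
        if not 0 <= self.parental_af_low < self.parental_af_high <= 1:
            raise ValueError("parental AF thresholds must satisfy 0 <= low < high <= 1")
        if self.penalty_pa < 0 or self.penalty_ps < 0:
            raise ValueError("penalties must be non-negative")
        if self.loh_run_length < 1 or self.isa_tree_count < 1 or self.max_iterations < 1:
            raise ValueError("counts must be positive")
        if self.solver not in ("greedy", "dp"):
            raise ValueError("solver must be 'greedy' or 'dp'")
        if self.prior_mode not in ("window", "incremental"):
            raise ValueError("prior_mode must be 'window' or 'incremental'")
        if self.likelihood_mode not in ("truncated", "folded"):
            raise ValueError("likelihood_mode must be 'truncated' or 'folded'")

    def mu_grid(self) -> np.ndarray:
        n_steps = int(round(1.0 / self.mu_step))
        return np.round(np.linspace(0.0, 1.0, n_steps + 1), 10)


@dataclass
class MeasurementBundle:
    """Input measurements for one tumor: AF/LAF matrices plus somatic SNVs.

    ``af`` is n_positions x m_samples with values in [0, 1]; NaN marks a
    missing (uninformative) measurement.  ``positions`` are (chromosome, arm,
    coordinate) tuples ordered along the genome.  ``snv_af`` holds the variant
    allele frequencies of somatic SNVs in the same sample order.  The column
    ``normal_index`` is the healthy/precursor reference sample.
    """

    af: np.ndarray
    positions: list[tuple[str, str, int]]
    snv_af: np.ndarray
    snv_positions: list[tuple[str, str, int]]
    sample_names: list[str]
    normal_index: int = 0
    laf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.af = np.asarray(self.af, dtype=float)
        self.snv_af = np.asarray(self.snv_af, dtype=float)
        if self.af.ndim != 2 or self.af.shape[0] != len(self.positions):
            raise ValueError("af must be n_positions x m_samples")
        if self.af.shape[1] != len(self.sample_names):
            raise ValueError("af columns must match sample_names")
        if self.snv_af.size and self.snv_af.shape[1] != len(self.sample_names):
            raise ValueError("snv_af columns must match sample_names")
        if not 0 <= self.normal_index < len(self.sample_names):
            raise ValueError("normal_index out of range")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.af, initial=0.0) < 0 or np.nanmax(self.af, initial=0.0) > 1:
                raise ValueError("AF values must lie in [0, 1]")
        self._check_position_order()
        self.laf = np.where(self.af > 0.5, 1.0 - self.af, self.af)

    def _check_position_order(self) -> None:
        seen_arms: list[tuple[str, str]] = []
        prev_key: tuple[str, str] | None = None
        prev_coord = -1
        for chrom, arm, coord in self.positions:
            key = (chrom, arm)
            if key != prev_key:
                if key in seen_arms:
                    raise ValueError(f"positions for arm {key} are not contiguous")
                seen_arms.append(key)
                prev_key = key
                prev_coord = coord
            else:
                if coord <= prev_coord:
                    raise ValueError(
                        f"positions not strictly increasing within arm {key}"
                    )
                prev_coord = coord

    @property
    def n_positions(self) -> int:
        return self.af.shape[0]

    @property
    def n_samples(self) -> int:
        return self.af.shape[1]

    @property
    def arm_starts(self) -> tuple[int, ...]:
        """Indices at which a new chromosome arm begins (always includes 0)."""
        starts = [0]
        for i in range(1, len(self.positions)):
            if self.positions[i][:2] != self.positions[i - 1][:2]:
                starts.append(i)
        return tuple(starts)

    def tumor_indices(self) -> list[int]:
        return [j for j in range(self.n_samples) if j != self.normal_index]
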