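"""Clonal-evolution simulator with ground truth for closed-loop evaluation.

Starting from a healthy diploid cell, subclones are formed over a fixed
number of division rounds.  Each child subclone copies its parent's
arm-level allele profile and acquires copy-number events (single-arm
gains/losses of one allele copy, occasional whole-chromosome gains) plus a
batch of new somatic SNVs.  A somatic SNV rides on one specific allele copy
and can be lost when that copy is lost.  Unviable subclones (any arm at
copy number 0 or above the viability ceiling) do not continue and are not
sampled.  All surviving subclones and precursors are sampled, sharing one
tumor fraction, and noisy AF/SNV measurements are emitted at SNP positions
spread evenly over the 44 autosome arms.

The per-round event rates default to values calibrated so that runs average
about five samples (including the healthy cell) and about three quarters of
ground-truth allele positions are ambiguous (their expected LAF is attainable
by more than one allele multiset at the dataset's tumor fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AlleleCombination, MeasurementBundle
from .tstep import Tree

CHROMOSOMES = [str(i) for i in range(1, 23)]
ARMS: list[tuple[str, str]] = [(c, a) for c in CHROMOSOMES for a in ("p", "q")]
N_ARMS = len(ARMS)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated tumor."""

    rounds: int = 4
    n_snps: int = 500
    n_snvs: int = 50
    noise_sigma: float = 0.02
    mu: float | None = None  # shared by all samples; None -> Uniform(0, 1)
    p_divide: float = 0.9
    p_second_child: float = 0.3
    p_arm_gain: float = 0.075
    p_arm_loss: float = 0.075
    p_chrom_gain: float = 0.02
    snv_min: int = 10
    snv_max: int = 15
    kmax_viable: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.p_divide,
            self.p_second_child,
            self.p_arm_gain,
            self.p_arm_loss,
            self.p_chrom_gain,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rounds < 0 or self.n_snps < 1 or self.n_snvs < 0:
            raise ValueError("invalid sizes")
        if self.mu is not None and not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")


@dataclass
class SimulationTruth:
    """Ground truth emitted by the simulator.

    Arm-level allele counts per subclone, the true tree, the SNV catalog
    (which arm and which allele each SNV rides on) and per-subclone presence.
    Measurement-aligned matrices (``c_matrix``, ``a_matrix``,
    ``snv_presence``) are filled in by :func:`generate_measurements`.
    """

    sample_names: list[str]
    tree: Tree
    arm_a: dict[str, np.ndarray]
    arm_b: dict[str, np.ndarray]
    snv_catalog: list[tuple[int, str]]
    snv_sets: dict[str, set[int]]
    mu: float
    positions: list[tuple[str, str, int]] = field(default_factory=list)
    snp_arm_idx: np.ndarray | None = None
    c_matrix: np.ndarray | None = None
    a_matrix: list[list[AlleleCombination]] | None = None
    measured_snv_ids: list[int] = field(default_factory=list)
    snv_positions: list[tuple[str, str, int]] = field(default_factory=list)
    snv_presence: np.ndarray | None = None

    @property
    def healthy(self) -> str:
        return self.tree.root

    def tumor_names(self) -> list[str]:
        return [n for n in self.sample_names if n != self.healthy]


def _viable(a: np.ndarray, b: np.ndarray, kmax: int) -> bool:
    total = a + b
    return bool((total >= 1).all() and (total <= kmax).all())


def _sample_allele_type(rng: np.random.Generator, a: int, b: int) -> str:
    """Pick one existing allele copy uniformly; returns its type."""
    total = a + b
    if total == 0:
        return "A" if rng.random() < 0.5 else "B"
    return "A" if rng.integers(total) < a else "B"


def simulate_tumor(config: SimulationConfig, rng: np.random.Generator | None = None) -> SimulationTruth:
    """Evolve a tumor lineage and return its ground truth.

    Runs ``config.rounds`` division rounds; if a run leaves no viable tumor
    subclone at all, it is resampled with an incremented seed (bounded
    retries).
    """
    base_seed = config.seed
    for attempt in range(25):
        local = rng if (rng is not None and attempt == 0) else np.random.default_rng(
            (base_seed + 1_000_003 * attempt) % 2**31
        )
        truth = _simulate_once(config, local)
        if config.rounds == 0 or truth.tumor_names():
            return truth
    raise RuntimeError("simulation produced no viable subclones after retries")


def _simulate_once(config: SimulationConfig, rng: np.random.Generator) -> SimulationTruth:
    healthy = "healthy"
    arm_a = {healthy: np.ones(N_ARMS, dtype=int)}
    arm_b = {healthy: np.ones(N_ARMS, dtype=int)}
    snv_sets: dict[str, set[int]] = {healthy: set()}
    catalog: list[tuple[int, str]] = []
    parent: dict[str, str | None] = {healthy: None}
    order = [healthy]
    current = [healthy]
    counter = 0

    for _ in range(config.rounds):
        nxt: list[str] = []
        for name in current:
            if rng.random() >= config.p_divide:
                continue
            n_children = 1 + (1 if rng.random() < config.p_second_child else 0)
            for _ in range(n_children):
                a = arm_a[name].copy()
                b = arm_b[name].copy()
                snvs = set(snv_sets[name])
                # whole-chromosome gains (one extra homolog on both arms)
                for ci in range(len(CHROMOSOMES)):
                    if rng.random() < config.p_chrom_gain:
                        for arm_idx in (2 * ci, 2 * ci + 1):
                            t = _sample_allele_type(rng, a[arm_idx], b[arm_idx])
                            if t == "A":
                                a[arm_idx] += 1
                            else:
                                b[arm_idx] += 1
                # single-arm gains and losses
                for arm_idx in range(N_ARMS):
                    if rng.random() < config.p_arm_gain:
                        t = _sample_allele_type(rng, a[arm_idx], b[arm_idx])
                        if t == "A":
                            a[arm_idx] += 1
                        else:
                            b[arm_idx] += 1
                    if rng.random() < config.p_arm_loss:
                        t = _sample_allele_type(rng, a[arm_idx], b[arm_idx])
                        count_before = a[arm_idx] if t == "A" else b[arm_idx]
                        if count_before > 0:
                            if t == "A":
                                a[arm_idx] -= 1
                            else:
                                b[arm_idx] -= 1
                            # an SNV riding the removed copy is lost with it
                            for s in sorted(snvs):
                                s_arm, s_type = catalog[s]
                                if s_arm == arm_idx and s_type == t:
                                    if rng.random() < 1.0 / count_before:
                                        snvs.discard(s)
                if not _viable(a, b, config.kmax_viable):
                    continue
                counter += 1
                child = f"S{counter}"
                # new somatic SNVs after the CNV events of this division
                for _ in range(int(rng.integers(config.snv_min, config.snv_max + 1))):
                    arm_idx = int(rng.integers(N_ARMS))
                    t = _sample_allele_type(rng, a[arm_idx], b[arm_idx])
                    catalog.append((arm_idx, t))
                    snvs.add(len(catalog) - 1)
                arm_a[child] = a
                arm_b[child] = b
                snv_sets[child] = snvs
                parent[child] = name
                order.append(child)
                nxt.append(child)
        current = nxt
        if not current:
            break

    tree = Tree(
        parent=parent,
        root=healthy,
        edge_weights={(p, c): 0.0 for c, p in parent.items() if p is not None},
    )
    mu = config.mu if config.mu is not None else float(rng.uniform(0.0, 1.0))
    return SimulationTruth(
        sample_names=order,
        tree=tree,
        arm_a=arm_a,
        arm_b=arm_b,
        snv_catalog=catalog,
        snv_sets=snv_sets,
        mu=mu,
    )


def _mixture_af(b: float, c: float, mu: float) -> float:
    return (mu * b + (1.0 - mu)) / (mu * c + 2.0 * (1.0 - mu))


def _draw_coords(rng: np.random.Generator, k: int) -> np.ndarray:
    coords = np.sort(rng.integers(1, 10**8, size=k))
    return coords + np.arange(k)  # enforce strict increase


def generate_measurements(
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> MeasurementBundle:
    """Emit noisy AF and SNV measurements, filling aligned truth matrices.

    SNPs are assigned to chromosome arms uniformly at random (equal expected
    count per arm); expected AFs follow the tumor/healthy mixture formula
    with the shared tumor fraction; Gaussian noise is added and values are
    clipped to [0, 1].
    """
    names = truth.sample_names
    m = len(names)
    mu = truth.mu
    sigma = config.noise_sigma

    snp_arms = rng.integers(N_ARMS, size=config.n_snps)
    arm_counts = np.bincount(snp_arms, minlength=N_ARMS)
    positions: list[tuple[str, str, int]] = []
    snp_arm_idx: list[int] = []
    for arm_idx, (chrom, arm) in enumerate(ARMS):
        k = int(arm_counts[arm_idx])
        if k == 0:
            continue
        for coord in _draw_coords(rng, k):
            positions.append((chrom, arm, int(coord)))
            snp_arm_idx.append(arm_idx)
    snp_arm_idx_arr = np.array(snp_arm_idx, dtype=int)
    n = len(positions)

    c_matrix = np.zeros((n, m), dtype=int)
    a_matrix: list[list[AlleleCombination]] = [[None] * m for _ in range(n)]  # type: ignore[list-item]
    af = np.zeros((n, m))
    for j, name in enumerate(names):
        a_arm = truth.arm_a[name][snp_arm_idx_arr]
        b_arm = truth.arm_b[name][snp_arm_idx_arr]
        c_matrix[:, j] = a_arm + b_arm
        for i in range(n):
            a_matrix[i][j] = AlleleCombination(int(a_arm[i]), int(b_arm[i]))
        mu_j = 0.0 if name == truth.healthy else mu
        af[:, j] = _mixture_af(
            b_arm.astype(float), (a_arm + b_arm).astype(float), mu_j
        )
    af = np.clip(af + rng.normal(0.0, sigma, size=af.shape), 0.0, 1.0)

    # measured subset of the SNV catalog, laid out in genome order
    total_snvs = len(truth.snv_catalog)
    if total_snvs > config.n_snvs:
        measured = sorted(
            rng.choice(total_snvs, size=config.n_snvs, replace=False).tolist()
        )
    else:
        measured = list(range(total_snvs))
    by_arm: dict[int, list[int]] = {}
    for s in measured:
        by_arm.setdefault(truth.snv_catalog[s][0], []).append(s)
    located: list[tuple[int, int, int]] = []  # (arm_idx, coord, snv_id)
    for arm_idx in sorted(by_arm):
        for s, coord in zip(by_arm[arm_idx], _draw_coords(rng, len(by_arm[arm_idx]))):
            located.append((arm_idx, int(coord), s))
    located.sort()
    snv_positions = [
        (ARMS[arm_idx][0], ARMS[arm_idx][1], coord) for arm_idx, coord, _ in located
    ]
    measured_sorted = [s for _, _, s in located]
    snv_af = np.zeros((len(located), m))
    presence = np.zeros((len(located), m), dtype=bool)
    for row, (arm_idx, _, s) in enumerate(located):
        for j, name in enumerate(names):
            carrier = s in truth.snv_sets[name]
            presence[row, j] = carrier
            if name == truth.healthy or not carrier:
                continue
            c = float(truth.arm_a[name][arm_idx] + truth.arm_b[name][arm_idx])
            snv_af[row, j] = mu * 1.0 / (mu * c + 2.0 * (1.0 - mu))
    snv_af = np.clip(snv_af + rng.normal(0.0, sigma, size=snv_af.shape), 0.0, 1.0)

    bundle = MeasurementBundle(
        af=af,
        positions=positions,
        snv_af=snv_af,
        snv_positions=snv_positions,
        sample_names=list(names),
        normal_index=0,
    )
    truth.positions = positions
    truth.snp_arm_idx = snp_arm_idx_arr
    truth.c_matrix = c_matrix
    truth.a_matrix = a_matrix
    truth.measured_snv_ids = measured_sorted
    truth.snv_positions = snv_positions
    truth.snv_presence = presence
    return bundle


def simulate_dataset(config: SimulationConfig) -> tuple[MeasurementBundle, SimulationTruth]:
    """Convenience wrapper: one seeded truth plus its measurement bundle."""
    rng = np.random.default_rng(config.seed % 2**31)
    truth = simulate_tumor(config, rng)
    bundle = generate_measurements(truth, config, rng)
    return bundle, truth


def generate_random_dataset(
    template: MeasurementBundle, seed: int
) -> MeasurementBundle:
    """Uniform-random AF/SNV measurements at the template's positions.

    Tumor columns are replaced by Uniform(0, 1) draws (the healthy column is
    kept); running inference on such data yields the chance-level reference
    error band.
    """
    rng = np.random.default_rng(seed % 2**31)
    af = template.af.copy()
    snv_af = template.snv_af.copy()
    for j in template.tumor_indices():
        af[:, j] = rng.uniform(0.0, 1.0, size=af.shape[0])
        if snv_af.size:
            snv_af[:, j] = rng.uniform(0.0, 1.0, size=snv_af.shape[0])
    return MeasurementBundle(
        af=af,
        positions=list(template.positions),
        snv_af=snv_af,
        snv_positions=list(template.snv_positions),
        sample_names=list(template.sample_names),
        normal_index=template.normal_index,
    )


def mix_contamination(
    truth: SimulationTruth,
    config: SimulationConfig,
    contamination: float,
    n_minors: int,
    rng: np.random.Generator,
) -> MeasurementBundle:
    """Measurements for polyclonal samples: major subclone plus minor contaminants.

    Each tumor sample mixes its own (major) subclone at tumor-content
    fraction ``1 - contamination`` with ``n_minors`` other subclones sharing
    the remaining tumor content equally, plus healthy cells at ``1 - mu``.
    The major subclone must keep at least half of the tumor content.
    """
    if not 0.0 <= contamination <= 0.5:
        raise ValueError("major subclone must hold at least 50% of tumor content")
    if truth.snp_arm_idx is None:
        raise ValueError("call generate_measurements on the truth first")
    names = truth.sample_names
    tumor = truth.tumor_names()
    mu = truth.mu
    sigma = config.noise_sigma
    arm_idx = truth.snp_arm_idx
    n = len(truth.positions)
    af = np.zeros((n, len(names)))
    snv_af = np.zeros((len(truth.measured_snv_ids), len(names)))
    for j, name in enumerate(names):
        if name == truth.healthy:
            af[:, j] = 0.5
            continue
        others = [t for t in tumor if t != name]
        k = min(n_minors, len(others))
        minors = (
            [others[i] for i in rng.choice(len(others), size=k, replace=False)]
            if k
            else []
        )
        parts = [(name, mu * (1.0 - contamination))]
        parts += [(mn, mu * contamination / k) for mn in minors] if k else []
        b_tot = np.zeros(n)
        c_tot = np.zeros(n)
        for sub, frac in parts:
            b_tot += frac * truth.arm_b[sub][arm_idx]
            c_tot += frac * (truth.arm_a[sub][arm_idx] + truth.arm_b[sub][arm_idx])
        af[:, j] = (b_tot + (1.0 - mu)) / (c_tot + 2.0 * (1.0 - mu))
        for row, s in enumerate(truth.measured_snv_ids):
            s_arm = truth.snv_catalog[s][0]
            num = 0.0
            den = 2.0 * (1.0 - mu)
            for sub, frac in parts:
                c_sub = truth.arm_a[sub][s_arm] + truth.arm_b[sub][s_arm]
                den += frac * c_sub
                if s in truth.snv_sets[sub]:
                    num += frac * 1.0
            snv_af[row, j] = num / den if den > 0 else 0.0
    af = np.clip(af + rng.normal(0.0, sigma, size=af.shape), 0.0, 1.0)
    if snv_af.size:
        snv_af = np.clip(snv_af + rng.normal(0.0, sigma, size=snv_af.shape), 0.0, 1.0)
    return MeasurementBundle(
        af=af,
        positions=list(truth.positions),
        snv_af=snv_af,
        snv_positions=list(truth.snv_positions),
        sample_names=list(names),
        normal_index=0,
    )
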