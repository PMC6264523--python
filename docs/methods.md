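# Methods

## Problem and data model

laftree reconstructs the subclonal evolution tree of a tumor from two kinds
of measurements taken in `m` purified samples (e.g. microdissections): the
allele frequency (AF) of the non-reference allele at `n` heterozygous
germline SNPs, and the variant allele frequencies of somatic SNVs.  Each
sample is assumed to be dominated by one tumor subclone mixed with healthy
diploid cells; the tumor cell fraction of sample `j` is the scalar `mu_j`.
No read-depth information is used, which makes the method applicable to
targeted sequencing, where depth is biased and uninformative for copy
number.

AFs are folded into lesser allele frequencies, `LAF = min(AF, 1 - AF) in
[0, 0.5]`, which discards phase: an allele multiset (written `A...B...`,
e.g. `ABB`) is indistinguishable from its A<->B mirror.  Whenever a mirror
choice must be made the method reports the variant with the most B alleles.

For a tumor multiset with `b` variant copies out of `c` total, mixed with
healthy `AB` cells, the expected AF is

    AF = (mu * b + (1 - mu)) / (mu * c + 2 * (1 - mu)),

and the expected LAF is the folded value.  This single formula reproduces
all the familiar anchor points: balanced multisets read 0.5 at every `mu`;
a hemizygous `A` or `B` reads (1 - mu)/(2 - mu), about 0.09 at `mu` = 0.9;
`ABBB` reads 1/3 at `mu` = 0.5.

## Per-position mixture

Given a candidate copy number `c`, the possible multisets form the set
`Q(c)` (`c`+1 elements).  The measured LAF is modeled as a Gaussian mixture
with one component per element of `Q(c)`: the means are the expected LAFs,
the standard deviation `sigma` (default 0.02, appropriate for >1000x
depth) is shared, and each component is truncated to [0, 0.5] and
renormalized.  A folded-Gaussian variant (`likelihood_mode="folded"`),
which is the exact density of `min(AF, 1 - AF)` for Gaussian AF noise, is
available; the two differ only for component means within a few `sigma` of
the 0.5 boundary, and the truncated form is the default.

Component weights implement the vertical dependency: a subclone differs
minimally from its parent in the current tree, so

    P(child multiset | parent multiset) ∝ 1 / (ED + 1),

normalized over `Q(c)`, where ED is the number of single-allele gains and
losses separating the multisets and the pseudocount avoids division by
zero.  Hard allele assignment places decision boundaries at midpoints
between adjacent distinct component means; a value exactly on a boundary
goes to the higher-mean side, and mirror-degenerate means collapse to the
most-B variant.

## Horizontal dependency and the event distance

Adjacent positions tend to be hit by the same copy-number event.  The
event distance between two whole-genome allele profiles is therefore the
minimum number of contiguous single-allele +/-1 interval operations
transforming one into the other, computed in closed form from prefix
differences of per-position gain/loss requirements; events never span
chromosome-arm boundaries.  A breadth-first brute-force oracle over
explicit operation sequences validates the closed form on small instances
in the test suite.  The copy-number prior for a profile (or a two-position
window of it) is the pseudocounted reciprocal `1 / (distance + 1)`; for a
single event spanning two adjacent positions this gives 0.5.

## C-step: per-sample maximization

For each sample the method maximizes P(C, mu | LAF, tree) by exhaustive
search over `mu` in {0, 0.01, ..., 1} combined with a chain over
two-position windows.  A window couples adjacent child positions with the
parent's (fixed) alleles there; its objective is the product of the child's
two mixture likelihoods and the window's copy-number prior.  The total
score is the product over all windows, so interior positions contribute
twice — a deliberate property of the window-product formulation that
strengthens the horizontal coupling.  The chain is solved greedily left to
right (the first position of each arm by its marginal likelihood, ties
toward smaller event distance then smaller copy number); a Viterbi-style
dynamic program over the identical objective is available
(`solver="dp"`) and agrees with the greedy pass on clean chains.  Exact
score ties across `mu` resolve toward larger `mu` (the near-pure,
more interpretable solution).  Missing LAF values contribute a neutral
factor and inherit the parent allele.  The whole grid is evaluated with
vectorized numpy; the scalar functions define the semantics and back the
tests.

An alternative event charging mode (`prior_mode="incremental"`) charges
each event only in the window where it starts, tracking the reciprocal of
the total event distance; the default window mode charges every window its
full two-position distance, which penalizes noise-driven isolated changes
about twice as strongly — the stronger regularization is why it is the
default.

Identifiability caveat: when a sample's ground truth contains no allelic
imbalance, `mu` is unidentifiable (every value explains LAF = 0.5); with a
single imbalance level, distinct (copy, `mu`) pairs remain observationally
equivalent.  Tumor fractions in the mid-range are hardest because many
component means then crowd toward 0.5.

## T-step: tree reconstruction

Pairwise event distances between the inferred profiles fill the directed
matrix `D_A`; `D_S` starts at 1 everywhere.  Three rules edit them:

- **LOH restriction.**  A sample has a confident loss-of-heterozygosity
  region when at least 10 consecutive measurements (in genome order; an
  arm-level loss spans all SNPs of the arm) have LAF < 0.3 and the
  inferred alleles there lack one parental allele.  Because re-gaining a
  lost allele is implausible, an edge from such a sample to one without
  the loss is forbidden.  If the alleles claim LOH but the LAF run does
  not support it, the edge is penalized by `P_A` (default 10, in allelic
  distance units) instead.
- **Parental-allele restriction.**  Where two samples share a confident
  LOH region but their raw AFs sit at opposite extremes (< 0.1 in one,
  > 0.9 in the other at the same position), different parental alleles
  were lost and neither sample can be ancestral to the other.
- **SNV loss penalty.**  SNVs are binarized at AF >= 0.05.  A parent
  carrying an SNV that a candidate child lacks is penalized by `P_S`
  (default 10, multiplicative on `D_S`, once per such SNV) unless the
  child shows allele-loss evidence at the nearest measured SNP (lower
  copy number than the parent, or LOH).

The final matrix `D_F = D_A * D_S` feeds Edmonds' minimum spanning
arborescence rooted at the healthy (or tetraploid precursor) sample.
Arborescences that gain the same SNV on two or more edges violate the
infinite sites assumption; an edit loop repeatedly removes the involved
edge introducing the most SNVs (ties broken uniformly at random from a
seeded generator) and re-runs Edmonds, collecting every updated tree up to
a budget of 50.  The tree with the fewest remaining violations, then the
lowest allelic distance, then the lowest total distance wins; recording
intermediate trees matters because the edit loop can pass through the best
tree before over-editing into infeasibility.

The C- and T-steps alternate — samples are re-estimated in topological
order so children see fresh parent profiles — until the tree's edge set
and total distance match any earlier iteration, or `max_iterations`
(default 10) is reached.  All randomness flows from one seed.

## Simulator

A healthy diploid cell evolves for 4 division rounds.  Each dividing
subclone (division probability 0.9, a second child with probability 0.3)
copies its parent and acquires: whole-chromosome gains (probability 0.02
per chromosome), single-arm gains and losses of one allele copy
(probability 0.075 each per arm), and 10–15 new somatic SNVs, each riding
one specific allele copy of a uniformly chosen arm (and lost with it, with
probability 1/copies, when that copy is lost).  Subclones with any arm at
copy number 0 or above 6 are unviable and terminate.  All surviving
subclones plus the healthy cell are sampled at one shared tumor fraction.

Measurements: 500 SNPs by default (the studies here use a reduced 200-SNP
variant; the methods are per-position, so this only widens confidence
intervals), assigned uniformly to the 44 autosome arms, with Gaussian
noise (sigma from 0 to 0.1, default 0.02) added to the expected AFs and
values clipped to [0, 1]; 50 SNV measurements generated the same way from
presence and local copy number.  The division and event rates were chosen
once so that runs average about five samples including the healthy cell
and about 75% of ground-truth positions are ambiguous (see below); they
are exposed in `SimulationConfig`.

What the simulator does not emulate: read-depth variation, allelic
mapping bias, subclonal (fractional) copy number within one sample,
SNP-density variation along the genome, and sub-arm (focal) events.
Passing tests therefore demonstrate correctness of the machinery under
arm-level clonal evolution with Gaussian measurement noise, not
performance on any particular real dataset.

A random-measurement generator (uniform AF and SNV values at the same
positions) provides the chance-level error band, and a contamination mixer
blends each sample's major subclone with minor subclones at a configurable
total fraction (the major subclone keeps at least half the tumor content).

## Error metrics and ambiguity

- `E_C`: mean absolute copy-number difference over all entries.
- `E_A`: mean per-position allele event distance (horizontal dependency
  deliberately ignored); an optional mirror-forgiving mode scores the
  smaller of the distances to the truth and to its mirror.  The default
  strict mode counts a mirror miss (true `AA`, reported `BB`) at full
  distance, so `E_A` carries an irreducible phase component at LOH runs.
- `E_mu`: mean absolute error of the tumor fraction over tumor samples
  (the healthy sample, fixed at `mu` = 0, is excluded).
- `E_T`: ancestor–descendant relations missed (false negatives) plus
  invented (false positives), divided by the number of unordered sample
  pairs.  This ancestry-pair accounting makes a ten-sample tree with two
  missed and six invented relations score 8/45 ≈ 0.18.

A ground-truth position is *ambiguous* when its noise-free expected LAF at
the dataset's true tumor fraction is attainable (within 1e-6) by an allele
multiset with a different canonical (most-B) form and copy number within
[kmin, kmax]; mirrors do not count as different.  All balanced positions
are ambiguous (`AB` vs `AABB` both read 0.5); imbalanced ones only at
special tumor fractions.  A position is *resolved* when the inferred
multiset equals the truth up to mirror.

## Numerical and design choices

- Copy-number bounds kmin = 1, kmax = 6; copy 0 is excluded from the
  search (a viable clone retains at least one copy) but representable.
- The mu grid includes both endpoints; 0 means pure healthy, where every
  multiset reads 0.5.
- Mixture components with means within 1e-9 are treated as degenerate
  (mirror pairs); likelihood floors at 1e-300 before logs.
- Tie-breaking is deterministic everywhere except the documented random
  choice among equally spurious edges in the ISA loop, which consumes the
  run's single seeded generator.
- The precursor defaults to diploid `AB`; a tetraploid `AABB` precursor
  (germ cell tumors) is one configuration switch.
- Penalty magnitudes `P_A` = `P_S` = 10 are large enough to dominate
  typical inter-sample distances without acting as hard restrictions.

## Known limitations

- Mid-range tumor fractions (roughly 0.3–0.6) are intrinsically hard:
  component means crowd toward 0.5 and whole (copy, mu) columns can be
  re-explained at a lower `mu`, which inflates `E_C`/`E_mu` there.  The
  tree is more robust than the point estimates because consistent
  distortions cancel in pairwise distances.
- The strict `E_A` mode mixes true errors with unobservable phase misses.
- Scaling is linear in positions but the method estimates every SNP
  individually; whole-exome scale would require pre-segmentation, which
  is out of scope.
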