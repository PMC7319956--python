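# Methods

## Filtration convention and persistence computation

The package computes Vietoris–Rips persistent homology of the atomic point
cloud on the **distance** scale: an edge enters the complex at the
Euclidean distance between its endpoints and a triangle at its longest
edge. The alternative (ball-radius) convention would place H0 deaths at
half the bond length; the distance scale is chosen so that a bond of
length d produces a connected-component death at exactly d, putting C–H
merges at ≈ 1.1 Å and C–C/C–O merges at ≈ 1.4 Å where a chemist expects
them. All lengths are in angstroms throughout.

**H0** uses the single-linkage equivalence: the finite H0 bars of a Rips
filtration are (0, w) for the N−1 edge weights w of a Euclidean minimum
spanning tree. The MST is delegated to `scipy.sparse.csgraph`; each bar is
attributed to the merging atom pair (the MST edge endpoints), which the
image layer needs for its electronegativity rule. The never-dying
component is excluded. Coincident atoms would produce zero-persistence
bars; they are dropped with a warning and the computation proceeds on one
representative per location.

**H1** is computed by the standard boundary-matrix column reduction over
GF(2) on simplices up to dimension 2. Simplices are processed in
(filtration value, dimension, lexicographic vertex) order, which both
respects faces and fixes tie-breaks reproducibly; equal-length edges are
therefore ordered by vertex indices. Zero-persistence pairs
(birth = death, e.g. an equilateral triangle whose cycle and filling
triangle appear together) are discarded. Homology above dimension 1 is out
of scope: the representation uses components and holes only.

The test suite cross-checks H0 against a brute-force O(N³) Prim MST and H1
against both hand-enumerated complexes (unit square, equilateral triangle,
regular hexagon) and first Betti numbers recomputed from scratch by dense
GF(2) Gaussian elimination at every inter-critical probe value — an
algorithm that shares no code path with the paired reduction.

## Chemically-driven persistence images

A diagram point (b, d) is rendered at (birth, persistence) = (b, d − b).
Each point contributes one unit of Gaussian mass — pixel values are the
exact integral of the Gaussian over each cell (products of 1-D CDF
differences), not center samples, so images are robust to resolution
changes. Intensity is additive: k coincident bars are k times as bright.
No persistence weighting and no intensity normalization are applied; mass
falling outside the grid window is truncated (an H0 point sits on the
birth = 0 edge, so about half its birth-axis mass is off-grid by
construction — harmless, since it is the same half for every molecule).

Kernel widths, the chemical channel:

| parameter | default | meaning |
|---|---|---|
| `resolution` | 25 px/axis | grid per homology dimension; feature length 2·25² = 1250 |
| `r_max` | 4.0 Å | axis range; covers bond lengths and ring voids of small organics |
| `sigma0` | 0.10 Å | base width — about the spread of a bond-length class |
| `alpha` | 0.15 Å per Pauling unit | width growth with \|Δχ\| for H0 points |
| `h1_sigma` | 0.10 Å | fixed width for H1 points |

σ(Δχ) is affine, σ₀ + α·|Δχ|: monotone in the electronegativity gap and
strictly positive for homonuclear pairs. α = 0 switches the chemistry off
and reduces to plain persistence images (useful as a control; the HBr/F₂
pair then collapses to identical vectors). H1 points take a fixed width
because a hole has no single atom pair to read a Δχ from. `auto_range`
derives r_max from a *training* set only (max coordinate plus 10%), never
from test molecules.

## Baselines

Coulomb matrix (0.5·Z^2.4 diagonal, Z_iZ_j/d_ij off-diagonal, rows sorted
by norm for permutation invariance, zero-padded to the largest molecule in
the set) and Bag-of-Bonds (the same pair terms, bagged by unordered
element pair, sorted descending, padded to set-wide bag maxima). Distances
are kept in Å for internal consistency; the comparison of interest is the
dimensionality behavior (their vector length grows with the set's largest
molecule, the PI length does not), which the suite tests explicitly.

## Kernel ridge regression

Kernels: laplacian exp(−‖x−x′‖₁/γ), gaussian exp(−‖x−x′‖₂²/2γ²), linear
x·x′ — γ is a length scale, exposed alongside the ridge λ. Features are
always column-centered; labels are centered on the training mean and the
mean is added back at prediction. Together these act as an intercept: an
affine target stays exactly representable under the linear kernel and a
saturated exponential kernel falls back to the mean label rather than to
zero. Centering is invisible to the translation-invariant exponential
kernels. Column *scaling* (standardization) is optional (default on,
recorded in the CV report); the synthetic benchmarks use raw pixel scales,
which preserve the relative weight of bright, informative pixels.
The dual system (K + λI)a = y − ȳ is solved by Cholesky with a
minimum-norm least-squares fallback for rank-deficient kernels; an
inconsistent system (duplicate rows with conflicting labels at λ = 0) is
detected by its residual and raises with advice to set λ > 0.
Cross-validation shuffles with a recorded seed into k near-equal folds and
recomputes preprocessing statistics inside each training fold. Grid search
minimizes mean CV RMSE, breaking ties toward larger λ, then larger γ.

## Synthetic benchmark

The generator emulates GDB-9-like small organics as geometry only: 5–30
atoms from {H, C, N, O} with weights 0.48/0.40/0.06/0.06, grown by
attaching each atom at a bond-like distance from a random existing atom —
the covalent-radius sum of the pair plus N(0, 0.02 Å) jitter, clipped to
1.0–1.6 Å — under a hard 0.9 Å minimum-distance constraint; with
probability 0.3 a planar 5- or 6-ring (side 1.39 Å) seeds the molecule.
Covalent-radius placement matters: it makes bond length carry elemental
identity (N–H ≈ 1.02 Å vs C–H ≈ 1.07 Å), as in real molecules — the only
channel through which a coordinate-only fingerprint can see composition.
The element weights were calibrated once so the oracle population matches
its intended shape (mean between −5 and −3 kcal/mol, bulk in −3..−5, strong
binders beyond −6 a ~10% minority).

The energy oracle is a deterministic caricature of CO₂-philic motifs:
−3.5 kcal/mol base, −0.8 per nitrogen adjacent (≤ 1.5 Å) to an atom that
itself bears a hydrogen (amino/hydroxo cooperativity), −0.6 per H1 feature
with persistence above 0.3 Å (ring-like voids), plus N(0, 0.25²) noise
seeded per molecule, clipped to [−9, 0].

What the generator does *not* emulate: valence rules, bond angles,
conformational ensembles, van-der-Waals packing, or any quantum-chemical
energetics. Passing tests therefore demonstrate the pipeline's
correctness and its ability to rank and enrich on geometry-plus-
composition signal — not accuracy on real interaction energies.

Two empirical properties of the generator are worth knowing. First,
compact random growth produces weak incidental voids (H1 persistence
≈ 0.1–0.3 Å) in a substantial fraction of ring-free molecules; only the
0.3 Å floor separates ring-sized voids from these packing artifacts, and
the oracle and the tests use that floor. Second, the oracle's
nitrogen-count term is only weakly identifiable from persistence images at
n ≈ 150 training molecules: the N-specific signal (slightly shifted bond
lengths and wider kernels) is a small perturbation of an image dominated
by the C/H skeleton, and measured recovery of the count plateaus well
above zero error regardless of hyperparameters. End-to-end learning on
oracle labels therefore beats the mean-label baseline clearly but does not
reach the noise floor; the noise-floor benchmark used for the learning
suite is a smooth property of the fingerprint's two leading principal
modes, which is representable by construction. This mirrors the practical
motivation for active learning: a small static training set cannot pin
down rare composition-driven effects, but iterative selection finds the
strong binders anyway (the enrichment suite measures exactly that).

## Active learning

Acquisition is pure exploitation: rank the pool by predicted energy and
take the `batch` most negative, ties broken by molecule id. No uncertainty
term is used. The canonical campaign is 100 seed molecules + 3 iterations
of 40, giving 220 labels; thresholds −6.0 (strong mark) and −6.5 kcal/mol
(screen threshold) are exposed as configuration. The loop is deterministic
given features, labels and seed, and appends its per-iteration history
(selected ids, model fingerprint, predictions at selection time) to a
line-delimited JSON log. The oracle is pluggable (synthetic function, CSV
lookup via the CLI, or any id → energy callable); an oracle failure aborts
with partial history retained.

## Problem sizes used by the test suite

Persistence oracles run on 200 random clouds (N ≤ 12) for H0 and ~45
clouds (N ≤ 8) for H1. The shared synthetic benchmark is one seeded
300-molecule pool (featurized once; ~8 s). The learning benchmark uses its
first 150 molecules; enrichment compares 20 seeded exploitation campaigns
(30 seed + 3×10) against 20 random-selection controls on the same pool,
and the bookkeeping check runs one full 100 + 3×40 campaign. The whole
suite completes in well under a minute on one core.

## Known limitations

- H0 attribution picks one MST edge per merge; for exactly tied merge
  distances the attributed pair depends on the documented tie-break order.
- The PI truncates off-grid mass; diagrams exceeding `r_max` (very large
  or very dilute structures) need a wider window or `auto_range`.
- The H1 reduction enumerates all O(N³) triangles; fine up to a few
  hundred atoms, not intended for proteins.
- Energies follow the attractive-negative sign convention everywhere;
  screening "exceeding" a threshold means numerically ≤ it.
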