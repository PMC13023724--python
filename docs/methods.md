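# Methods

## The model

`shiftassign` treats chemical-shift assignment as Bayesian inference over
bijections.  An *assignment block* holds n predicted items (quaternary
carbons observed in 1D ¹³C spectra, or bonded ¹³C–¹H pairs observed as 2D
cross-peaks) and n experimental peaks.  Each item i carries a probability
density p_i over shift space:

* **XS mode** (crystal structure known): a single Gaussian centred at the
  shift predicted for that specific site, with standard deviation σ_pred
  equal to the uncertainty of the prediction method.  2D items use the
  product of the carbon and proton marginals.
* **DB mode** (2D structure only): a uniform-weight mixture with one
  Gaussian component per database entry whose rooted fragment motif matches
  the site, each centred at that entry's predicted shift with that entry's
  uncertainty.  For 2D items the carbon and proton components of one
  matched fragment stay **paired**: the mixture is (1/K) Σ_k
  p_k(y_C)·p_k(y_H), not a product of two independent mixtures.

With a uniform prior over assignments, the posterior of a bijection a is

    p(a | y) = Π_i p_i(y_{a(i)}) / Σ_{a'} Π_i p_i(y_{a'(i)})

and the per-site marginal assignment probability sums this over every
permutation that maps site i to peak j.  The marginal matrix is a convex
combination of permutation matrices and hence doubly stochastic — a useful
built-in self-check, asserted to 1e-9 in the test suite.

Normalising each site's conditional distribution over the peaks of its
block (or over any larger peak set) multiplies a likelihood row by a
constant, which cancels between numerator and denominator.  The block-local
convention is therefore used, and a property test certifies that row
rescalings up to 1e±300 leave marginals unchanged to 1e-10.

## Exact computation

Two routes, both exact:

* **Enumeration** (n ≤ 9): all n! permutation scores in log-sum-exp
  arithmetic.  Serves as the oracle for the second route.
* **Permanent** (n ≤ 22): the normaliser Σ_a Π_i L[i, a_i] is the matrix
  permanent of the likelihood matrix, and
  P[i, j] = L[i, j]·perm(minor_ij) / perm(L).  Permanents are computed with
  Ryser's inclusion–exclusion formula with Gray-code subset updates
  (O(2ⁿ·n)), after per-row scaling accumulated in log space.

Blocks larger than 22 are refused with advice to subdivide (by multiplicity
or spectral region); no silent approximation is ever made, and no
Monte-Carlo fallback exists by design.

Numerical choices:

* All probability arithmetic stays in the log domain; marginals are
  exponentiated only at output.  Gaussian tails underflow double precision
  for shifts ~40σ apart, so linear-domain likelihoods would zero out
  otherwise well-defined posteriors.
* Before Ryser, the log likelihood matrix is balanced by ~30 Sinkhorn
  sweeps (row then column log-sum-exp subtraction).  Marginals are invariant
  under any positive row/column rescaling, and balancing compresses the
  dynamic range of the alternating sum, which would otherwise lose
  precision through cancellation when likelihood ratios span many orders of
  magnitude.  The accumulated offsets are added back when the permanent's
  absolute value is reported.
* The MAP permutation is found with the Hungarian algorithm
  (`scipy.optimize.linear_sum_assignment`); among tied optima the
  lexicographically smallest permutation is returned, found by fixing rows
  in order and testing which columns preserve the optimum (tolerance 1e-9
  on the log posterior, so exact symmetric ties are detected and flagged).
* A likelihood row or column that is zero everywhere means an unassignable
  site or peak and raises an error rather than returning NaNs; −inf log
  likelihoods propagate exactly and are never floored.

## Fragment motifs (DB mode)

A depth-w motif is the induced subgraph on all atoms within w bonds of the
root, with element labels, integer bond orders (aromatic encoded as 4), the
root distinguished, and ring closures preserved.  Canonical keys are
computed by iterative colour refinement seeded with (distance-from-root,
element), followed by individualisation–refinement when symmetric colour
classes remain; the lexicographically smallest serialisation of the final
discrete colouring is the key.  This is exact canonicalisation: equal keys
iff root-preserving isomorphism, verified in the tests against a
brute-force `networkx` isomorphism oracle over a library of small
molecules.  Stereochemistry and 3D geometry deliberately do not enter the
key — the database route is 2D-topological.

Depth selection follows the occurrence rule: the deepest motif retaining at
least `min_occurrences` (default 10) database matches is used; if even
depth 1 is rarer, depth 1 is used and a warning flag is set.  Match counts
are provably non-increasing in depth, which the suite asserts.

When indexing a structure into the database, a proton-bearing carbon
produces one entry per attached proton (so a CH₂ contributes two paired
components), quaternary carbons one unpaired entry.  Pairs must come from
the same source structure via an explicit `partner_ref` — matched pairs are
never combined combinatorially across structures.

A deliberate, faithful limitation: graph-equivalent sites receive identical
DB densities.  In particular the two molecules of a Z′ = 2 asymmetric unit
are indistinguishable to DB mode, while XS mode, whose predictions come
from the 3D structure, can separate them.

## Synthetic benchmark

The generator emulates prediction-accuracy-limited assignment: true shifts
uniform on 0–200 ppm (¹³C) and 0–12 ppm (¹H); predicted = truth +
N(0, σ_pred) with σ_pred = 2.44/0.53 ppm (¹³C/¹H), the reported accuracies
of the shift predictor; experimental = truth + N(0, σ_exp) with σ_exp =
0.05/0.02 ppm, a linewidth-limited read-off precision.  The engine width is
√(σ_pred² + σ_exp²) — the exact standard deviation of (experimental −
predicted) under this model — so the posterior is the true posterior and
its probabilities should be calibrated.  The calibration suite (1000
replicates of 5-site blocks) checks every reliability bin holding ≥ 200
item-peak pairs to within 0.05 of its bin centre.

Uniform placement is a deliberate simplification: real shift distributions
are clustered by functional group, which crowds some spectral regions more
than uniform sampling does, and real peak positions also carry correlated
(e.g. referencing) errors.  Passing tests therefore certify the inference
machinery under a matched generative model, not real-spectrum accuracy
levels.

Mode-specific conditions:

* **DB stand-in densities**: mixtures of 8 components whose centres scatter
  around the true shift with scale 2·σ_pred per nucleus, giving mixtures
  with total width √5·σ_pred ≥ 2σ_pred.  The XS-vs-DB suite reproduces, at
  desk scale, the qualitative ordering that crystal-structure densities
  out-resolve database mixtures.
* **Z′ = 2**: each site is duplicated into copies I/II whose true shifts
  are split by N(0, 3σ_pred) per nucleus — the smallest splitting scale at
  which copies are claimed resolvable.  A 1D-only analysis gives a copy
  accuracy of ½ + arctan(3)/π ≈ 0.90 at this scale; the joint 2D
  (¹³C and ¹H) likelihood raises it to ≈ 0.97, which is what the benchmark
  measures.  DB densities are shared between copies, so copy discrimination
  pins at 0.5 (exact ties count as half).

One pseudo-random stream per run, seeded from the config; draws are
consumed per block in a fixed order (truths, copy splittings, prediction
noise, experimental noise, then DB component offsets), so datasets are
reproducible and structurally comparable across modes at equal seeds.

Problem sizes throughout (5-site blocks, ≤ 1000 replicates, 4-site Z′ = 2
blocks at 300 replicates) are chosen so every suite completes in seconds to
a few tens of seconds on one CPU while keeping Monte-Carlo errors well
below the margins being tested.

## Design choices where the design was open

* **Overlapped resonances**: when two sites share one resonance, the peak
  must be entered as two rows with identical shifts and distinct ids.  This
  keeps the bijection structure (and hence the posterior) well defined
  without introducing an occupancy model; the engine then returns the
  honest 50/50 split.
* **Inequivalent CH₂ protons** are represented as two 2D items sharing the
  carbon density with distinct proton densities — exactly the structure
  that lets XS mode resolve them while DB mode cannot.
* **Default σ_pred** when no sigma column is given: 2.44 ppm (¹³C) and
  0.53 ppm (¹H).
* **Reported precision**: human-readable output prints probabilities to
  0.1%; machine output (marginals.csv, summary.json) keeps full precision.
* **Shieldings vs shifts**: the engine consumes shifts in ppm only; an
  optional per-nucleus affine conversion (slope, intercept) can be applied
  at read time for users starting from computed shieldings.

## Known limitations

* No non-bijective assignment model: missing or extra peaks must be
  resolved at the block-construction stage.
* No approximate marginals above n = 22; the advice is finer blocking,
  which any additional experimental classification (multiplicity, attached
  nitrogen, spectral editing) naturally provides.
* Student-t (DP4-style) likelihoods are not offered; densities are Gaussian
  or Gaussian mixtures.
* DB mode inherits whatever bias the shift database carries; the synthetic
  DB densities here model only its width, not its bias.
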