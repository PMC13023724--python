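# shiftassign

Bayesian probabilistic assignment of solid-state NMR chemical shifts.

Assigning ¹H and ¹³C resonances of polycrystalline organic solids to
specific atomic sites is slow and error-prone when done purely by
connectivity experiments.  `shiftassign` turns predicted chemical shifts
into a posterior probability for *every* possible site-to-peak assignment,
so a spectroscopist sees at a glance which assignments are certain and
which deserve a targeted follow-up experiment.  It supports two sources of
predictions:

* **XS mode** — shifts predicted for a known 3D crystal structure
  (structure validation): each site i gets a Gaussian density
  N(δ_pred,i, σ_pred), and 2D ¹³C–¹H cross-peaks the product of the two
  marginals.  This resolves magnetically inequivalent sites with identical
  2D connectivity — CH₂ protons, or the molecule copies of a Z′ = 2
  crystal.
* **DB mode** — no 3D structure needed: each site's density is a
  uniform-weight Gaussian mixture over database entries whose rooted
  fragment motif (the covalent environment within w bonds) matches the
  site, at the deepest depth w that retains enough occurrences.

Given a block of n predicted items and n experimental peaks, the posterior
of an assignment a (a bijection) under a uniform prior is

    p(a | y) ∝ Π_i p_i(y_{a(i)}),

and the per-site marginal probability that site i belongs to peak j
marginalises over all permutations:

    P[i, j] = Σ_{a : a(i) = j} p(a | y).

Both quantities are computed **exactly**: by enumeration over all n!
permutations for n ≤ 9, or through matrix permanents (Ryser's algorithm,
log-domain, Sinkhorn-balanced) for n ≤ 22, using the identity
P[i, j] = L[i, j]·perm(minor_ij)/perm(L).  The marginal matrix is doubly
stochastic by construction, and all arithmetic stays in log space so
likelihood ratios of hundreds of orders of magnitude remain exact.

See `docs/methods.md` for the model, the numerical choices, and the
synthetic benchmark design.

## Worked example

`examples/` contains a six-site toy (four CH cross-peaks, two quaternary
carbons) whose C1/C5 pair sits 0.25 ppm apart in ¹³C — far below the
2.44 ppm prediction accuracy — but 0.85 ppm apart in ¹H:

```sh
shiftassign assign --mode xs \
    --predicted examples/predicted.csv --peaks examples/peaks.csv --out out
shiftassign report --marginals out/marginals.csv
```

which prints (probabilities in %, peaks labelled in order of decreasing
¹³C shift):

```
Block 13C|quaternary|carbonyl
        q1      q2
C2    97.2     2.8
C3     2.8    97.2

Block 13C-1H|tertiary|aliphatic
           a       b       c       d
C1H1     0.2     8.0    91.9     0.0
C4H4     0.0     0.0     0.0   100.0
C5H5     0.7    91.3     8.0     0.0
C8H8    99.1     0.8     0.1     0.0
```

C4H4 and C8H8 are certain; the close C1/C5 pair is resolved at ~91%
(driven almost entirely by the proton dimension); the carbonyl pair, split
by 4.4 ppm against a 2.44 ppm uncertainty, lands at 97%.  `out/report.txt`
flags every site whose best marginal falls below the confidence threshold
(default 0.90) as a candidate for targeted additional experiments, and
`out/summary.json` carries the MAP assignment and full-precision
probabilities.

Other subcommands: `shiftassign index` builds a fragment-keyed shift
database from a structure (MOL V2000 or atoms/bonds CSV) plus a shift
table; `shiftassign simulate` and `shiftassign benchmark` generate
synthetic datasets with known ground truth and measure assignment accuracy
and calibration.  Exit codes are scriptable: 0 success, 2 validation
error, 3 block too large for exact computation.

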