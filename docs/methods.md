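# Methods

## Scope and model class

The package implements discrete Bayesian-network classification over
fully observed categorical tables. A model is a DAG over the class
variable and the attributes plus one conditional probability table
(CPT) per node; the joint factorizes as
P(x₁,…,xₙ) = ∏ᵢ P(xᵢ | Parents(xᵢ)). Classification evaluates the
class posterior under full attribute evidence; no partial-evidence
inference is provided (all queries the classifiers need are
full-evidence, so exact computation is a product of CPT lookups —
performed in log space and normalized at the end, which keeps
16-attribute products far from underflow).

## Parameter estimation

CPTs use Laplace smoothing:
P(x|g) = (count(x,g) + s) / (count(g) + s·|states|), default s = 1.
The default is deliberately non-zero: with 16 attributes and n ≈ 2000,
unseen (class, parent-state) combinations are common and unsmoothed
estimates would zero out whole posteriors. Parent combinations never
observed fall back to the uniform distribution. The class prior is
smoothed the same way.

Mutual information I(X;Y) and class-conditional mutual information
I(Xᵢ;Xⱼ|C) are computed from *unsmoothed* empirical frequencies in
bits (base-2 logs; the base cancels out of every ranking the
classifiers use). The 0·log 0 ≡ 0 convention applies throughout.

## Classifier construction

* **NB** — star DAG, class → each attribute.
* **TAN** — pairwise CMI weights; maximum-weight spanning tree by
  Kruskal-style sorted greedy selection with cycle rejection; edges
  oriented away from the root; class added as universal parent. The
  default root is the attribute with the highest MI with the class
  (deterministic and informative-first); it is overridable. Edge-sort
  ties break lexicographically by the sorted node pair so results are
  identical across platforms.
* **KDB(k)** — attributes sorted by decreasing MI with the class (ties
  lexicographic); position i takes the min(i−1, k) highest-CMI earlier
  attributes as parents (ties lexicographic). k defaults to 2. KDB(0)
  is structurally identical to NB, which the tests exploit as an
  identity check.
* **Prediction** — argmax of the posterior; exact ties break by class
  state order (first declared state wins), documented and tested.

## Univariate screening

Categorical predictors: Pearson chi-squared on the r×c contingency
table, no continuity correction (the common default for r×c screening).
Ordinal predictors: Mann-Whitney U with midrank tie handling; the exact
null distribution is used when both groups have ≤ 20 observations and
no ties, otherwise the tie-corrected normal approximation. α defaults
to 0.05. Screening is advisory — training accepts any attribute list —
and no multiple-testing correction is applied. Calibration is verified
by a 1000-replicate null simulation in the test suite (type-I error
required to fall in [0.03, 0.07]).

## Constraint-based structure learning

The conditional-independence test is G² (likelihood ratio) on
stratified contingency tables: G² = 2 Σ n_xyz ln(n_xyz·n_z /(n_xz·n_yz)),
df = (|X|−1)(|Y|−1)·∏|Z|, with zero-margin strata contributing 0.
Grow-Shrink runs per node: a grow pass adds any variable dependent on
the target given the current blanket (repeated to a fixed point), a
shrink pass removes members independent given the rest. Variables are
visited in column order; GS output can depend on this ordering, so it
is fixed rather than randomized. Blankets are symmetrized with the AND
rule. Neighbour resolution tests subsets of the smaller blanket;
colliders X→C←B are oriented when the common neighbour is outside the
separating set; edges oriented both ways by conflicting triples revert
to undirected, and no further propagation (Meek rules) is applied —
the output is deliberately a partially directed graph.

Bootstrap averaging resamples the table with replacement B times
(default 1000; B = 200 is used for desk-scale runs) and reports, per
skeleton edge, *strength* (fraction of replicates containing the edge
in either orientation) and *direction confidence* (fraction orienting
it source→target, counting an undirected occurrence as 0.5 toward each
orientation — the convention bnlearn uses). Retention threshold
defaults to 0.5 (majority rule). The arc summary counts an arc as
directed when its majority-direction confidence reaches the direction
cutoff (default 0.9); arcs that flip orientation across replicates
(e.g. 51%/49%) count as undirected.

## Evaluation

Splits are stratified by outcome by default: at 15% prevalence an
unstratified 7:3 split of n ≈ 2000 is noticeably unstable. The
confusion matrix is oriented rows = predicted, columns = measured.
Undefined ratios (zero denominators) are reported as absent (`None`),
never as 0. AUC is the probability-of-concordance estimator
(concordant pairs + half the ties) / (n₊·n₋), computed via midranks;
it is invariant under monotone transforms of the scores and is
cross-checked against an independent implementation in the tests.
Metrics are kept at full precision in the library; only the CLI rounds
for display.

## The synthetic cohort generator

The generator emulates the study conditions of the motivating cohort:
n = 2008 records, binary outcome `np` at exactly 15.2% marginal
prevalence, 12 binary predictors and 4 three-level ordinal grades
(`g`, `afv`, `afc`, `crp`; `age` and `pbg` are three-level bands).
Binary variables use labels "0"/"1", ordinal ones "1"/"2"/"3". The
ground-truth DAG encodes clinically motivated pathways (glucose →
hypertension / macrosomia / membrane rupture → preterm birth;
gravidity → parity and amniotic-fluid volume → cleanliness → CRP), the
outcome depends on (pbg, ptb, afc, p) through a logistic CPT, and the
outcome drives the neonatal sequelae (nrds, nnj, na, ngr, pph) with
`nnj` receiving `afc` as a co-parent (a v-structure, np→nnj←afc).

All CPT constants are frozen literals. The outcome intercept
(−3.7537229) was solved by bisection against exact enumeration of the
outcome's ancestral sub-network so the marginal prevalence is 0.152.
Effect sizes were chosen — and verified once by simulation over 100
cohorts (97/100) — so that univariate screening at α = 0.05 retains
all 16 predictors at n = 2008 with probability above 0.9; seed 42 is
the documented reference cohort used in the tests.

Sampling is ancestral: nodes are drawn in topological order by inverse
CDF from one seeded NumPy generator per call (no global state); output
is byte-identical for fixed (network, n, seed) and distribution-
identical across any valid topological order (tested).

What the generator does **not** emulate: missing data, continuous
measurements (everything is pre-discretized), residual confounding
outside the declared DAG, measurement error, or temporal structure.
Consequently, passing tests demonstrate that the algorithms are
implemented correctly and behave as theory predicts under a faithful
DAG-generated world — not that the fitted clinical-style numbers
would transfer to a real cohort.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, chosen as the
smallest sizes at which each property is statistically decidable:
exact-inference equivalence at ≤ 5 binary attributes (tolerance 1e-9),
spanning-tree optimality on 4-5 nodes × 100 random instances,
Grow-Shrink recovery on 3-node structures at n = 10,000 over 20 seeds,
KDB(2) parent-set recovery at n = 20,000 over 20 seeds (the generating
model's class couplings were solved by exact enumeration so the true
MI ordering is strictly decreasing — 0.52/0.40/0.29/0.20/0.13 bits —
making the attribute order identifiable), screening calibration over
1000 null replicates at n = 500, and bootstrap averaging at B = 200 on
the full 2008 × 17 cohort. CPT rows must sum to 1 within 1e-9;
Monte-Carlo assertions use 3-4 standard-error bands.

## Known limitations

* Grow-Shrink's neighbour-resolution step enumerates subsets of the
  smaller Markov blanket; with very dense graphs or liberal α this is
  exponential in blanket size. At the package's scale (17 variables,
  sparse truth) it is fast.
* G² degrees of freedom use the full conditioning-set state product;
  with large conditioning sets relative to n the test loses power and
  GS stops growing blankets — a conservative failure mode.
* The classifiers require full attribute evidence; records with
  missing cells must be imputed or dropped upstream.
* Attribute states present in test data but unseen in training raise a
  usage error rather than being smoothed in silently.
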