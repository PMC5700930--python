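# Methods

## Trophic levels and incoherence

For a web with prey→predator adjacency matrix **A** and in-degrees
*k<sub>j</sub>* = Σ<sub>i</sub> A<sub>ij</sub>, trophic levels solve

    s_j = 1 + (1/k_j) Σ_i A_ij s_i,    s_j = 1 for basal species.

The system has a unique solution iff (i) at least one species is basal
and (ii) every species is reachable from some basal species;
`validate_trophic_preconditions` reports exactly these two conditions
and every downstream routine raises on violation. The reduced
(N−B)×(N−B) system over non-basal species is solved by direct LU
factorization — dense below 400 unknowns, sparse above — because the
defining equation is exact; no fixed-point iteration is involved.

Summing the defining equation over predators shows Σ links *x* = L, so
the mean trophic distance is identically 1 (asserted at 1e-9 in tests).
The incoherence parameter uses the population form q = √(⟨x²⟩ − 1) over
all L links. A radicand within 1e-12 of zero is clipped to zero: a
perfectly layered web accumulates ~1e-16 of solver noise, and reporting
q = 0 exactly is the correct reading of that number. Self-loops
(cannibalism) make the system ill-posed and are removed on ingest with
a logged count; duplicate edges collapse (the formalism is a binary
adjacency matrix). Node labels are held in lexicographic order so
matrix indexing is reproducible across runs.

## Triad census and significance

The 13 connected triad classes are identified by a 64-entry lookup
table from the 6-bit dyad code of a node triple to its isomorphism
class, built once by exhaustive enumeration and canonicalized over all
six node permutations. The census is induced-subgraph counting: each
unordered triple contributes one count, that of its induced class. The
optimized path vectorizes the per-triple code computation over all
C(N,3) triples (chunked above N = 350); tests check it against a
brute-force per-triple oracle on 200 random digraphs, and the
classifier against networkx's independent 16-type triad taxonomy.

S-class naming follows the field's convention (S1 chain, S2
feed-forward/omnivory, S3 cycle, S4 shared predator, S5 shared prey).
The D1–D8 order is a documented canonical choice — by number of single
links added to the mutual dyads, matching the networkx code order 111D,
111U, 120D, 120U, 120C, 201, 210, 300. Profile correlations are
invariant to any fixed component order, so no cross-profile result
depends on this choice.

The null model preserves every species' in- and out-degree via
attempted double-edge swaps (a→b, c→d ⇒ a→d, c→b), rejecting swaps
that would create a self-loop or duplicate link; `swaps_per_link × L`
swaps are *attempted* per sample, and each ensemble member is an
independent chain started from the original web, avoiding sample
autocorrelation. Defaults are 1000 samples and 10 swaps per link,
chosen for convergence on 50–500-species webs. Two modes exist because
the classical motif literature differs on one point: `plain` randomizes
all links together; `mutual` additionally preserves the number of
mutual-predation dyads by swapping single links (never creating a
dyad) and dyads (as units) within their own pools. The mode is recorded
in `NullEnsembleStats` since it changes z-scores on webs with mutual
links. Ensemble sd uses the sample (n−1) form. A class with zero null
variance gets z = 0 by policy — it is identically distributed under the
null and carries no signal — and an all-zero profile is flagged
`undefined` rather than normalized.

## Profile comparison and families

Profiles are compared by Pearson's r over the 13 components (the
printed (n−1) normalizations cancel), converted to the Euclidean
metric d = √(2(1−r)), and clustered by UPGMA (scipy's average-linkage,
deterministic tie-breaking). Families are the clusters below a cut
distance d_c (default 1.1); `pipeline.classify_families` numbers them
by the minimum q of their members so that family 1 always contains the
most coherent web, making labels stable across runs. For
model-vs-empirical comparison the model ensemble's z vectors are
averaged component-wise before correlating; a flag averages the
unit-normalized vectors instead ("average TSP" reading) — the two agree
closely and both are available.

## The GPPM

Growth: B basal nodes at temporary level ŝ = 1; each of the remaining
N − B nodes picks exactly one prey uniformly among *all* existing nodes
(read literally; basal and non-basal alike) and takes ŝ = ŝ_prey + 1.
Extra links: every ordered pair (i, j) with j non-basal, i ≠ j, not
already a skeleton link, is added independently with probability
min(1, c·w_ij), w_ij = exp(−(x̂_ij−1)²/2T²), where c solves
Σ min(1, c·w_ij) = L − (N − B) exactly (sorted closed form). Capping at
1 keeps probabilities valid at large L; the expected final link count
is L. T = 0 is implemented as the exact limit — only pairs at x̂ = 1
are candidates — avoiding the 0/0 in the Gaussian weight; if too few
such pairs exist to reach L the draw raises as infeasible. Final levels
are recomputed on the finished web; at T = 0 the temporary levels
already solve the level equation, so q = 0 exactly. Reverse-of-skeleton
pairs are allowed, so mutual dyads and long cycles can arise.

Temperature calibration (`fit_temperature`) is stochastic root finding:
bracketing bisection on T, each evaluation a Monte-Carlo ensemble mean
of q (default 200 draws, escalating to 1000 once the bracket is under
0.05), tolerance 0.01 on the mean, all evaluations logged in the
returned fit. The ensemble-mean q is monotone non-decreasing in T,
which keeps bisection consistent under sampling noise; targets above
the large-T plateau raise with the plateau estimate. Master seeds spawn
per-draw child seeds (numpy `SeedSequence`), so all results are
reproducible given one integer.

The S2 transition scan (`s2_transition`) locates, per basal ratio B/N,
the temperature at which the ensemble-mean normalized S2 z-score
changes sign, by linear interpolation between grid points; the critical
incoherence q_c is interpolated the same way. Each draw's profile is
measured against its own null ensemble.

## Synthetic webs

`synthetic_webs` generates inputs with known closed-form properties:
layered webs (all links adjacent-level, q = 0, B = width), the named
toys (omnivory triangle q = √(1/6), diamond q = 0, 3-cycle with no
basal species), and random trophic-valid DAGs with exact (N, B, L).
These emulate the *topological* properties the analysis consumes; they
do not emulate sampling effort, taxonomic aggregation or interaction
strengths of real food-web data, so green tests certify the arithmetic
and the model, not field-data robustness.

## Bundled summary data

`data/food_web_summary.csv` holds published summary statistics (N, B,
L, q, calibrated T, habitat) for 46 empirical food webs, indexed by ID
in order of increasing q. The species-level topologies are not bundled;
analyses that need them (per-web q recomputation, the empirical family
dendrogram) accept a corpus directory of edge lists instead. Regressing
q on B/N over the bundled table gives slope ≈ −1.05, intercept ≈ 0.76,
R² ≈ 0.53 — the small slope difference from the published −1.06 traces
to the table's two-decimal rounding of q.

## Problem sizes used in the test suite

Stochastic checks run at desk scale, chosen to give decisive
Monte-Carlo separation: q(T) monotonicity with 200 draws per grid point
at N = 100, mean non-basal degree 10; calibration checks with 300–600
draws per bisection step; the S2 transition at B/N ∈ {0.1, 0.5} with
100 draws per temperature and 20-sample nulls at 5 swaps per link.
Library defaults remain at the full scale (1000-sample nulls, 10 swaps
per link, 1000-draw fit ensembles).

## Known limitations

- Weighted or signed interaction webs are out of scope; the formalism
  is a binary adjacency matrix.
- Only 3-node motifs are counted; no analytic null approximations are
  provided (the null is always an explicit swap ensemble).
- Family membership of borderline webs depends on the stochastic null
  ensemble; only the family *count* at a given d_c should be treated as
  a stable output.
- The GPPM fits only (B, N, L, q); webs whose structure is not well
  summarized by q will not be reproduced faithfully by the calibrated
  model.
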