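# Methods

This note records the models, conventions and numerical choices behind
`conntopo`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the synthetic benchmark
does and does not establish.

## Connectome model

A functional connectome (FC) is a complete weighted graph on `n` regions
with weights `w_uv = |pearson(x_u, x_v)| ∈ [0, 1]` and unit diagonal.
Taking absolute values folds anti-correlation into coupling strength; the
package deliberately has no signed-network mode. The diagonal is forced to
exactly 1 regardless of floating-point correlation output, and matrices
read from disk are checked symmetric to 1e−8 and then symmetrized by
averaging. Group averaging is the entrywise mean of per-subject matrices;
absolute values are applied per subject (inside FC estimation), so the
average of non-negative matrices needs no second rectification.

Unique off-diagonal weight values define the filtration levels. Uniqueness
is exact floating-point equality; users who want coarser levels should
round the matrix first (no rounding is applied by default). An edge with
`w_uv` exactly equal to the threshold is included.

## Filtration and persistence

The flag (clique) complex of the dissimilarity `d = 1 − w` is filtered by
the Vietoris–Rips rule: a simplex's filtration value is the maximum
pairwise dissimilarity among its vertices (0 for vertices). This is
equivalent to taking clique complexes of the threshold graphs level by
level. Simplices are ordered by (value, dimension, lexicographic vertex
tuple), which guarantees faces precede cofaces; any valid refinement of
this order yields the same diagrams (tested by random vertex relabelling).

Persistence is computed by standard boundary-matrix reduction over the
two-element field, with columns stored as Python big integers (one bit per
simplex) so that a column addition is a single XOR, and with the twist
(clearing) optimization: dimensions are processed from high to low and
paired birth columns are skipped. Coefficients in GF(2) are the standard
choice when the field is otherwise immaterial. `max_dim` defaults to 3 so
that H2 deaths are resolved (measuring `H_p` requires simplices up to
dimension p+1); a vertex cap (default 80 for `max_dim = 3`) guards the
O(n^4) tetrahedron enumeration. The from-scratch path computes a
40-region, `max_dim = 3` complex (~102k simplices) in under two seconds on
one CPU, and `max_dim = 2` (H0/H1) in ~0.04 s.

Conventions:

- Because weights are non-negative, every edge has `d ≤ 1`, so the complex
  at filtration value 1 is the complete flag complex: H1/H2 classes always
  die within the filtration, and the single essential H0 class has its
  death capped at 1.0 (the domain endpoint). This keeps H0 diagrams finite
  multisets, which the Hausdorff metric requires.
- Zero-persistence pairs (birth = death) are recorded and flagged but
  excluded from diagram distances by default: they contribute nothing to
  the Wasserstein optimum and would pollute Hausdorff death sets.
- A brute-force oracle computes Betti numbers directly as
  `dim C_p − rank ∂_p − rank ∂_{p+1}` on the sub-complex at a threshold
  (guarded to n ≤ 14); the acceptance suite checks diagram-derived Betti
  curves against it at every filtration value on 100 random matrices.

## Diagram distances

- **H0 — Hausdorff.** All H0 classes are born at 0, so diagrams reduce to
  death multisets on the real line, compared by the classical max–min
  Hausdorff distance. The capped essential death (1.0) is included on both
  sides, where it contributes 0. The distance is a pseudometric: it is
  insensitive to multiplicity (duplicating a death value changes nothing).
- **H1/H2 — q-Wasserstein.** Partial pairings may match an interval across
  diagrams (max-norm cost) or retire it to the diagonal (cost: half its
  length). All three terms of the objective carry the same exponent `q`,
  and the optimum is found exactly as a square linear-assignment problem
  of size `n_X + n_Y` with one diagonal-projection slot per interval and
  zero-cost slot-to-slot cells; the distance is the q-th root of the
  optimal total. `q` defaults to 2 and is configurable with `q > 1`; an
  exhaustive partial-pairing enumeration serves as the oracle up to 8
  intervals. Essential intervals are rejected in H1/H2 inputs (the
  filtration endpoint should have killed them) and excluded for H0.
- Two empty diagrams are at distance 0; empty vs non-empty costs the
  unmatched total.

The metric is bound to the homological order — Hausdorff for H0,
Wasserstein for H1/H2 — but every analysis function accepts an override,
for methodological comparison.

## Consolidation

The FN partition contracts the connectome to a super-graph: for classes
i ≠ j, `W_ij = Σ_{u∈i, v∈j} w_uv`, normalized by the maximum off-diagonal
`W_ij` so the strongest coupling is exactly 1. The diagonal of the
normalized matrix is set to 1, making the super-graph itself a valid FC so
all homology operations apply unchanged. The normalization denominator
runs over off-diagonal entries only (diagonal blocks are contracted away
in the quotient and are not edges of it). Normalized entries are invariant
under a common positive rescaling of all cross-class weights. If every
cross-class weight is zero the normalized off-diagonal is defined as zero,
with a warning.

## Landscape analyses

- Condition profiles report, per condition, the mean and the *population*
  variance (divide by count) of its distances to the other conditions —
  the variance is descriptive, with no inferential claim.
- The most distinct pair is the argmax over unordered pairs; ties break to
  the lexicographically smallest label pair, making consensus voting
  deterministic.
- Consensus voting increments one unordered pair per subject, so counts
  always sum to the number of subjects.
- Per-subject analyses use each subject's own FC (hence that FC's own
  weight levels); there is no shared group threshold grid.
- Mesoscopic (FN-level) diagrams are computed on induced-subnetwork FCs —
  the principal submatrix per FN — not on masked whole-brain matrices.
- KL divergence between two FNs' all-to-REST distance samples uses
  shared-grid histograms spanning the pooled range (default 10 bins), a
  pseudocount of 1 per bin before normalization (finite on disjoint
  supports), and the natural logarithm. KL is directional; the pipeline
  emits both directions, and top-k rankings run over ordered FN pairs.
  A degenerate pooled range returns 0.
- Top-k strengths are normalized by the largest selected divergence (top
  entry = 1); an all-zero selection reports uniform strength 1.

## Synthetic cohort generator

The generator emulates the *structure* of a multi-condition fMRI cohort —
subjects × conditions with one resting condition, regions grouped into FNs
with stronger within- than between-FN coupling, condition-specific
coupling perturbations, subject heterogeneity — at desk scale, with
analytic correlations for testing.

Regions within an FN sit on a ring, and signals follow a linear factor
model (see `conntopo/synthetic.py` for the formula): an FN factor whose
ring share `ρ` (default 0.5) lives on the first circular harmonic, a
global factor with loading `β` (default 0.2), and unit residual noise.
Population correlations are
`λ_u λ_v [(1 − ρ) + ρ cos(θ_u − θ_v)] + β²` within an FN and `β²` across
FNs. The ring emulates spatially organized within-FN gradients (somatotopy,
retinotopy): it gives each FN one genuinely persistent H1 loop — neighbours
couple strongly, antipodes only through the shared component — whose
persistence scales with the FN's loading `λ`. This matters for
identifiability: in a homogeneous block model, changing within-FN coupling
only relocates near-diagonal noise bars, which optimal partial matching
ignores, so no within-FN effect is visible to H1 no matter how large; the
ring gives within-FN coupling a topological signature.

Default study conditions: 20 subjects, 40 regions, 5 FNs (sizes
10/10/8/6/6, named VIS/SM/DA/LIM/DMN), 300 time points, conditions REST,
EMOT, WM, MOT. Baseline loading λ = 0.7 for every FN; task effects act on
the SM loading: +0.06 (EMOT), +0.10 (WM), +0.22 (MOT), so MOT vs REST is
the planted most-distinct contrast and the other tasks are intermediate
states along the same axis (tasks engaging the same network to different
degrees). A seed is required; there is no default stream. Subject
heterogeneity jitters each subject's FN loadings once (sd 0.02), shared
across conditions, and jittered loadings are clipped into the
unit-variance region.

The baseline/effect sizes were calibrated analytically, from two
requirements, before the acceptance suite was frozen: (i) the matched
route of the Wasserstein optimum must beat retiring both loops to the
diagonal for the (MOT, REST) pair — this requires the REST-state loop to
be persistent already, hence the λ = 0.7 baseline — because when loops go
unmatched the distance is governed by the partner's own loop gap and no
longer discriminates partners correctly; and (ii) the matched-cost margin
of (MOT, REST) over the nearest competitor (≈ 2λ·0.06·0.9 ≈ 0.08) must be
commensurate with the per-subject birth noise (se(r) ≈ (1 − r²)/√T ≈ 0.04
at T = 300), so individual votes are correct in expectation and the
20-subject modal vote concentrates. The perturbed loading 0.92 keeps
λ² + β² < 1.

What the generator does **not** emulate: hemodynamics and autocorrelated
BOLD noise (samples are iid in time, so correlation standard errors are
optimistic), head motion and other artifacts, negative-correlation
structure beyond what absolute values fold in, heterogeneous within-FN
loadings, realistic parcellation sizes (374-region atlases are an order of
magnitude larger), or empirical rest/task effect profiles. Passing the
recovery tests therefore shows the *pipeline* is sensitive and unbiased
under a controlled, identifiable effect — not that any particular
real-data finding would replicate.

## Pipeline and problem sizes

The `run` pipeline chains five levels (group macroscopic, consolidated,
mesoscopic at rest, individual consensus, all-to-REST KL). Group-level
complexes use `max_dim = 3` by default; the per-subject whole-brain
complexes, which dominate runtime (subjects × conditions reductions), use
`individual_max_dim = 2` (H0/H1) by default — at the default cohort scale
this keeps a full run around ten seconds while the group level still
resolves H2. Both are configurable up to 3. All randomness flows from the
single run seed; reruns are byte-identical. Logs record the parameter
values actually used (q, bins, pseudocount, tie rule) so runs are
auditable. Tests and the acceptance suite run the generator at its default
scale and the oracle sweeps at n ≤ 12–15, sizes chosen so the whole suite
completes in a couple of minutes on one CPU.

## Known limitations

- Exact reduction is O(m³) worst case in the number of simplices; the
  package targets desk-scale connectomes (n ≲ 80 for H2, larger for
  H0/H1). No cohomology, zigzag, or approximate backends.
- No bottleneck distance (q = ∞) and no persistence landscapes/images.
- The histogram KL estimator is simple and biased for small samples; it is
  used comparatively (same estimator both directions, same grid), not as
  an absolute divergence estimate.
- Consolidated graphs with k super-nodes can only support homology up to
  dimension k − 2; for small k the pipeline reports empty or absent
  diagrams rather than inventing structure.
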