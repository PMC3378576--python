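# Methods

## Model

The predictor assumes that a protein domain's position in a
4-dimensional "structural space" is a linear function of a
440-dimensional descriptor of its evolutionary profile. The four
coordinates (x, y₁, y₂, z) are constructed so that each of the four
major structural classes occupies its own sign region:

| coordinate | separates | required signs |
|---|---|---|
| x  | all-α vs all-β | α: +, β: − |
| y₁ | all-α vs mixed αβ | α: −, mixed: + |
| y₂ | all-β vs mixed αβ | β: −, mixed: + |
| z  | α/β vs α+β | α/β: +, α+β: − |

Classification combines two of the four discriminations: x > 0 with
y₁ < 0 is all-α; x ≤ 0 with y₂ < 0 is all-β; anything else is mixed and
z decides between α/β (z > 0) and α+β (z ≤ 0). Exact zeros are resolved
by a fixed total ordering — x = 0 routes to the β side, y = 0 to mixed,
z = 0 to α+β — so the rule is total over all of ℝ⁴.

## Structural targets

Training targets come from per-residue secondary-structure strings over
{H, A, P, C} (helix, anti-parallel sheet, parallel sheet, coil). A
window of length k slides along the string; averaging each window's
fractional content of element i over all L−k+1 windows gives the
composition profile f̄ᵢ(k). At k = L this reduces exactly to the
whole-sequence content of element i, which anchors the construction.

Raw scores are then

- x = f̄_H − (f̄_A + f̄_P)
- y₁ = (f̄_A + f̄_P) − θ
- y₂ = f̄_H − θ
- z = (f̄_P − f̄_A) / (f̄_P + f̄_A + δ)

with defaults k₀ = 8 (capped at L; roughly two helical turns or two
strands plus a turn), θ = 0.1 (an "all-" class tolerates up to ~10 %
content of the other element type), and δ = 1e−6 (keeps z finite for
sheet-free domains). z contrasts parallel against anti-parallel sheet
content because the α/β architecture carries mostly parallel sheets and
α+β mostly anti-parallel ones.

For a training domain of known class, each coordinate whose sign the
class dictates is clamped to at least a margin ε = 0.05 on the required
side (a per-domain clamp, idempotent by construction); coordinates the
class leaves free, and coordinates already well placed, keep their raw
score. This is the minimal mechanism that guarantees the sign
constraints without distorting well-separated domains. All four
constants are exposed in `TargetParams` and the `targets:` section of
the YAML config.

## The 440 sequence features

Group sizes 20/40/20/20/140/120/80 fix the lag ranges (10 for the
property autocorrelations, 7 for the profile autocorrelation) and the
positive/negative score split. Positive and negative log-odds parts are
processed separately throughout (P⁺ = max(P,0), P⁻ = min(P,0)) because
they carry different information: enrichment versus depletion relative
to the background. The three segment lengths {4, 8, 16} bracket the
typical strand / helix / supersecondary-element scale, and the four
position-preference statistics (weighted mean relative position, spread,
N/C-terminal bias, edge preference) summarise where along the backbone a
residue type's positive substitution mass sits. Hydrophobicity uses the
Kyte–Doolittle scale and side-chain masses are average masses in
daltons; both tables are replaceable via `FeatureParams`.

Raw integer PSSM scores are used without rescaling — the regression's
feature standardization absorbs scale differences between groups.
Domains too short for a lag or segment length get zeros in the affected
entries (with a log warning) so the vector length is always exactly 440;
the fixed dimensionality is required by the 4×441 coefficient matrix.
Non-standard residues such as X keep their PSSM row but contribute to no
composition count, since composition is defined over the 20 standard
types.

## Regression

Features are standardized (mean 0, population SD 1, zero-variance
columns pinned to scale 1) once on the full training set, so a single
transform serves all four dimensions at predict time. Each dimension is
fitted on its class-union subset by SVD-backed least squares with an
intercept; a rank-deficient design (inevitable when a subset has fewer
rows than 441 columns, as in small fixtures) falls back to a λ = 1e−8
ridge solve, logged whenever it triggers.

The two-round procedure refits once with refined targets: where the
round-1 fitted value already lies on the class-required side with
magnitude ≥ ε, the target becomes the fitted value itself (the domain
relaxes to its natural score); elsewhere the target is pulled to
±ε. Self-consistent fits are a fixed point of this update. The refit is
deterministic and, on separable problems with margin-clamped targets,
does not degrade training sign agreement (verified empirically over 20
seeds in the test suite).

Sequential forward stepwise selection picks the first feature by
absolute Pearson correlation with the target and each later feature by
the residual-sum-of-squares reduction of the refit model, ties broken to
the lowest index. It is implemented as orthogonal greedy selection
(Gram–Schmidt residualization of the remaining columns), which computes
the identical criterion at a fraction of the cost of literal refitting;
equivalence to a naive refit oracle is asserted in the tests. Selection
runs per dimension; the chosen sets need not agree across dimensions.

## Evaluation

Per-class sensitivity TP/(TP+FN), specificity TN/(TN+FP) and MCC are
one-vs-rest on a fixed-order 4×4 confusion matrix; an MCC denominator
with a zero factor yields MCC = 0, and a class absent from the truth
yields NaN sensitivity with a warning. Multi-class agreement uses the
generalized squared correlation GC² = χ²/(N·(K−1)) with K = 4 and
expected counts from the row/column marginals (cells with zero
expectation are skipped); GC² is 1 for any perfect — or perfectly
permuted — classification, i.e. it measures association, not accuracy.
Specificity (not precision) is reported because the per-class "Sp"
figures this family of predictors quotes are consistent with the
one-vs-rest true-negative rate.

Cross-validation uses stratified folds (scikit-learn, shuffled with a
caller-supplied seed, default 1); the jackknife is leave-one-out. Both
retrain the complete pipeline per split and pool held-out predictions
into a single confusion matrix.

## Synthetic data

The generator emulates the study conditions end to end: 200 domains per
class by default, lengths uniform on [60, 300] residues (never below the
conventional 30-residue cutoff), an 80/20 stratified split, and full
reproducibility from one seed. Secondary structure comes from
class-specific block grammars (helix blocks of 6–20 residues for all-α;
anti-parallel strands of 3–10 for all-β; alternating helix/parallel
strand for α/β; a helical region followed by an anti-parallel region for
α+β). Sequences are drawn from element-conditioned residue propensities,
with distinct groups for parallel (V, I, C, L, F) and anti-parallel
(T, Y, W, S, F) strands so the sheet topologies leave a linearly
recoverable sequence signal. Profiles score the drawn residue ≈ +4, the
element's propensity group mildly positive, everything else negative,
plus Gaussian noise (SD 1.0 by default), rounded and clipped to
[−10, 13] like real PSI-BLAST output.

What this emulates — and what it does not: the generator reproduces the
file formats, the integer score range, own-residue dominance and a
composition-linked class signal, but not PSI-BLAST iteration effects,
realistic substitution structure, fold-level diversity within a class,
or the label noise of real structural-class assignments. Passing the
end-to-end tests therefore demonstrates that the pipeline recovers a
planted linear signal through the full feature/regression/decision
stack — not that real-data accuracies are reproduced, which would
require the external benchmark datasets and NR-database PSI-BLAST runs.

## Problem sizes and numerical choices

The end-to-end recovery check runs at the default study condition
(200/class, seed 1; held-out accuracy must reach ≥ 0.90). The
jackknife-vs-10-fold agreement check runs on 40 training domains per
class with a 20-feature budget over 2 seeds, and the row-permutation
invariance check uses 280 domains per class so every subset is
over-determined and the least-squares solution unique — sizes chosen to
keep each property cleanly testable at desk scale. Oracle-equivalence
tests use tolerance 1e−10 (relative); least-squares is compared to the
normal-equations oracle at 1e−8 absolute.

## Known limitations

- The structural-score constants (k₀, θ, δ, ε) and the concrete
  segment lengths and position statistics are this package's choices
  within the documented group-size constraints; alternatives fitting the
  same constraints exist.
- The round-2 target update is one concrete realization of a two-step
  iterative least-squares scheme; schemes that reweight samples or prune
  outliers instead would satisfy the same outer description.
- Secondary-structure input must already distinguish parallel from
  anti-parallel sheets; deriving that annotation from 3D coordinates is
  out of scope.
- Real-data performance is untested here by design; only the synthetic
  benchmark is exercised.
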