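# Methods

## The problem and the model

Given a prochiral ketone and a fixed panel of eight commercial transaminases
(four typically *S*-selective, four *R*-selective), the task is to decide,
from substrate information alone, which enzyme to run. Commercial variants
ship without sequences, so each enzyme is a separate single-task model over
substrate features; nothing is shared across enzymes except the feature
table.

**Stage 1 — conversion gate.** Reaction success is binarized at 25%
conversion (strict `>`), the level at which a micro-scale reaction reliably
yields enough product for ee determination and onward chemistry. Each
enzyme's gate is a random-forest classifier (500 trees, √p features per
split, unlimited depth, fixed seed, 0.5 probability cut-off). Random forests
are a deliberate choice for small-n tabular data with unknown interaction
structure; no hyperparameter search is performed.

**Stage 2 — selectivity ranking.** Measured ee is transformed to the
activation free-energy difference

ΔΔG‡ = *RT* ln((1 + *x*)/(1 − *x*)), *x* = min(ee, 99.9)/100,

with *R* = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and *T* = 308.15 K (the 35 °C
reaction temperature). The transform spreads the heavily top-skewed ee
distribution (most measured values ≥95%) and is strictly monotone, so
enzyme rankings on predicted ΔΔG‡ and predicted ee are identical. ΔΔG‡ is
kept as an unsigned magnitude; the enantiomer identity is carried by the
enzyme's selectivity class. The 99.9% clip keeps ee = 100% finite; reactions
whose ee could not be measured are dropped from selectivity training (never
imputed), mirroring the analytical reality that low-conversion wells rarely
yield an ee.

Per enzyme, a forward stepwise multivariate linear regression is fit on
z-scored features: step 0 commits the feature with the largest |Pearson r|
against ΔΔG‡ (so exactly one feature is always selected, even under pure
noise); each later step evaluates every remaining feature and adds the one
whose enlarged OLS model has the highest leave-one-out cross-validated R²,
stopping as soon as the best candidate is not strictly better, with a hard
cap of min(9, n−3) features. Ties (step-0 correlation or candidate R²)
break deterministically by column order. Final coefficients are refit on all
rows; the model stores feature names, standardization parameters,
coefficients and its LOOCV R², and is fully human-readable when serialized.

**Connected workflow.** For a new substrate, every (optionally
S-only/R-only constrained) enzyme is gated; gate-positive enzymes are ranked
by predicted ΔΔG‡ descending (predictions clamped at 0 from below, ranking
ties broken by enzyme id); the rank-1 enzyme is the recommendation, and a
substrate with no positive gate is predicted non-reactive. Against
experimental data, outcomes classify as:

- reactive branch (some enzyme experimentally `>25%` conversion): *ideal* if
  the rank-1 enzyme exceeded the gate with `<1%` ee regret; *acceptable* if
  rank-2 did when rank-1 did not; *poor* otherwise (including the
  never-yet-observed case of a reactive substrate with all-negative gates,
  which we label poor as a false-negative gate);
- unsuccessful branch: *ideal* with 0 positive gates, *acceptable* with 1 or
  2, *poor* with more than 2. The count-2 case is not pinned down by the
  verbal rules; we place it with acceptable, between the stated anchors.

Regret is substrate-level: best measured ee minus the rank-1 enzyme's
measured ee, undefined (and excluded from aggregates) when the rank-1
enzyme's ee was unmeasured; rank-2 regret uses the same observed maximum.

## Cross-validation discipline

All evaluation is leave-one-ketone-out. The outer `loocv` literally refits
the entire trainer — including standardization and feature selection — on
every n−1 subset, so a held-out label cannot influence its own prediction
(verified by mutation tests). Inside the forward search, candidate feature
sets are scored with the exact PRESS identity for OLS (residual/(1−h_ii)),
which is mathematically identical to refitting every fold for a fixed
feature set — OLS predictions are invariant to per-fold affine
standardization — and keeps the search O(folds) cheaper. LOOCV R² is
1 − PRESS/SST; near-singular candidate designs score −∞ and are never
selected.

For ranking evaluation, substrates inside an enzyme's training set use their
held-out fold prediction; substrates the enzyme never saw (censored ee) use
the full model, which was trained without them by construction.

## Steric descriptors

Descriptors are computed from conformer ensembles (≤20 conformers, energies
re-referenced to the minimum) and Boltzmann-averaged with weights
∝ exp(−E/RT) at 298.15 K — averaging temperature and reaction temperature
are deliberately separate knobs. Per-conformer values are averaged, not
values of an averaged geometry.

**Sterimol.** Axis = carbonyl C → α-C unit vector; substituent = atoms
reachable from the α-carbon without crossing the carbonyl (connectivity
inferred from covalent radii, bond if d < 1.3(rᵢ+rⱼ)). L is the maximal
projection onto the axis measured from the carbonyl atom plus the atom's
Bondi vdW radius; B5 the maximal perpendicular extent; B1 minimizes the
maximal extent over perpendicular directions scanned at 1° resolution. The
scan frame is anchored to the molecule (the B5 atom's perpendicular
direction), so B1 is rigid-motion invariant to machine precision instead of
scan-grid precision.

**Buried volume.** Fraction of a 3.5 Å probe sphere at a center atom
occupied by surrounding vdW spheres (Bondi × 1.17, H included), integrated
on a uniform 0.05 Å grid (cross-checked against closed form and Monte-Carlo
to <0.5% absolute). For α-role assignment, the sphere at each α-carbon
counts only that carbon's own substituent atoms — the center and the
carbonyl side are excluded — and the ensemble-averaged values label the
bulkier side "large" (ties break to the lower atom index, with a warning).
Only the relative ordering is consumed downstream; the absolute
parameterization is conventional catalysis practice. Relabelling by role
makes descriptor columns comparable across unsymmetrical ketones and makes
the table invariant to the raw order of the two α-atoms.

Quantum-chemical descriptors are *ingested*, not computed: a documented CSV
contract (molecule-level plus atom-level rows keyed by substrate and atom
index) replaces any electronic-structure dependency. Constant and
non-finite descriptor columns are dropped at table assembly and the drop is
logged.

## The synthetic generator

The generator emulates the statistical structure of a real micro-scale
screen so every stage is testable without data downloads. Defaults are the
study conditions: 42 substrates × 8 enzymes (336 reactions; held-out preset
24 × 8 = 192), 60 standard-normal features, per-enzyme 4-sparse linear
models for both responses.

- ΔΔG‡ = βₑ·x + εₑ (σ = 0.2 kcal/mol), truncated at 0, mapped to ee at
  308.15 K; per-enzyme intercepts are calibrated so ~88% of measured ee are
  ≥95%.
- conversion = 100·logistic(γₑ·x + s·x + cₑ) + noise (σ = 3%), clamped to
  [0,100], where s is a panel-shared sparse "difficulty" component: hindered
  substrates convert poorly across every enzyme, which is what makes fully
  non-reactive substrates (the unsuccessful branch of the outcome rules)
  occur at realistic rates. cₑ is calibrated to a 56% positive rate at the
  25% gate.
- ee is censored (MISSING) below 15% conversion, and measured ee is recorded
  at 0.1% precision, emulating chromatographic reporting; recorded-precision
  ties are exactly what the tie-aware top-k scoring is defined over.
- Every draw is regenerable bit-exactly from (config, seed), and the stored
  ground truth (supports, coefficients, noiseless responses) serves as the
  oracle for parameter-recovery and workflow-soundness tests.

What the generator does **not** emulate: real chemical feature
distributions and correlations (DFT descriptor ranges, fingerprint
sparsity), enzyme-family structure beyond the shared difficulty axis,
heteroscedastic analytical error, or plate/batch effects. Passing tests
therefore demonstrate the correctness and internal soundness of the
workflow machinery and its qualitative behaviour (model ranking beats the
frequency baseline; labels are noise-stable), not quantitative performance
on laboratory data.

For the workflow-soundness check the generator is run in an
oracle-consistency configuration: zero noise on both responses and the
censoring threshold raised to the conversion gate (25%), so every measured
ee belongs to a gate-positive enzyme. Under the default censoring (15%), an
enzyme below the gate can legitimately hold the best measured ee, so
nonzero regret there reflects the data regime, not a workflow defect. With
oracle (truth-derived) models in that configuration, 100% of substrates
classify ideal — the selection logic itself introduces no loss.

## Numerical choices and degenerate inputs

- Gas constant 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ everywhere; energies kcal/mol.
- ee = 100% → clip at 99.9% (finite transform); negative ΔΔG‡ predictions
  clamp to 0 with a warning.
- Single-class conversion labels → explicit degenerate-training error;
  callers fall back to a constant gate with a warning.
- Constant-y selectivity training sets are rejected; enzymes with fewer than
  5 measured ee are skipped with a warning.
- PRESS denominators below 1e−10 or rank-deficient designs score −∞.
- Fingerprints: Morgan radius 2, 2048 bits. Boltzmann weights require the
  minimum relative energy to be exactly 0 (±1e−9).
- CSV reading uses round-trip float precision so write→read is lossless.

## Problem sizes used in the shipped checks

Panel-level checks run on default-size screens (42×8); the model-vs-baseline
top-k comparison averages 20 independently seeded screens; support recovery
uses 50 replicates of n=30, p=20, 4-sparse signals at R² ≈ 0.8; the
leakage check runs 100 randomized trials at n ∈ [8,15). These sizes were
chosen to make each claim statistically stable while keeping a full run in
the minutes range on a single CPU.

## Known limitations

- The forward-search addition criterion (greedy LOOCV R²) and the exact
  tie-scoring convention are choices among reasonable readings of standard
  stepwise practice; an in-sample-R² addition rule would differ on some
  datasets.
- OHE models cannot generalize to unseen substrates by construction (all-zero
  row); they exist as the baseline featurization.
- V_bur and Sterimol parameterizations (sphere radius, radii scaling, grid,
  1° scan) follow common practice but are not fit to any reference data;
  only relative orderings feed the workflow.
- The outcome rules extrapolate in two places (reactive substrate with
  all-negative gates → poor; unsuccessful substrate with exactly 2 positive
  gates → acceptable); both are flagged in code comments and above.
- No bootstrap confidence intervals or calibration curves; the evaluation
  module is an extension point.
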