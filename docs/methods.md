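# Methods

## Forward model

Protection factors are linear in two per-frame amide observables:
`ln P_i = ⟨β_C N_C,i + β_H N_H,i⟩`. `N_C,i` counts non-hydrogen atoms
strictly within 6.5 Å of the amide N of residue i, excluding all atoms of
residues i−2…i+2 (window clamped at chain termini); `N_H,i` counts O/N atoms
strictly within 2.4 Å of the amide H. Both cutoffs use strict inequality —
"within" is ambiguous at the boundary, and fixing strictness keeps counts
reproducible across platforms. Hydrogens are identified by element rather
than name prefix, so naming dialects ("H", "HN", "1HB2") are handled. The
amide's own backbone N (≈1 Å from H) is always excluded from the acceptor
set; whether the rest of the i−2…i+2 window should also be excluded from the
H-bond count is not determined by the model definition, so we count it by
default and expose `exclude_neighbor_window` as a switch.

Peptide deuteration under EX2 kinetics averages
`1 − exp(−k_int,i · t · e^{−lnP_i})` over the segment's residues excluding
the segment's first residue (its amine back-exchanges during analysis) and
prolines (no amide hydrogen). The denominator is the number of residues
actually averaged, so D → 1 as t → ∞; a `literal_denominator` flag divides
by `end − start` instead for compatibility with the alternative convention.
The protein's first residue is excluded globally. Times are minutes
throughout; intrinsic rates are consumed from a user-supplied two-column
table (sequence- and condition-dependent reference values are inputs, not
re-derived).

Measured data can be corrected for D2O fraction and back-exchange by
element-wise normalization against a maximally deuterated control
(`normalize_experimental`).

## Reweighting

Frame weights are exponentially tilted in the same observables
(`Ω_k ∝ exp{Σ_i λ_i b_ik}`, computed with a log-sum-exp shift), the
maximum-entropy correction for matching ensemble-averaged `ln P`. λ is
found by the damped fixed-point iteration
`λ ← λ(1−ε) + ε ∂ln ρ_err/∂lnP`, whose stationary point minimizes
`L = W_app/k_BT − ln ρ_err`; we verified on exhaustively searchable problems
(≤3 frames) that the converged λ agrees with dense grid minimization of L to
better than 1e-4.

Numerical choices:

- **λ starts at 0** (the maximum-entropy prior); γ scans warm-start λ and β
  from the previous γ, which keeps the decision curve monotone.
- **Adaptive damping.** A fixed ε is unstable at large γ (the first steps
  overshoot and collapse the weights), so the update rate backtracks: a step
  that would increase L is rejected and ε halved; after 20 consecutive
  accepted steps ε doubles (capped at 1). L is therefore non-increasing over
  accepted iterations, and a `ConvergenceError` is raised if ε falls below
  1e-9 without progress. Default initial ε = 0.01.
- **Convergence** is declared when the fixed-point residual, scaled by the
  *nominal* rate (`0.01 · max|∂ln ρ_err/∂lnP − λ|`), drops below `tol`
  (default 1e-8) — measuring the raw step `|Δλ|` would let a temporarily
  tiny adaptive ε fake convergence. Iteration cap 50,000. Near machine
  precision the likelihood comparison itself limits the achievable residual
  to ≈1e-7 in λ.
- **W_app** is evaluated by the work integral over the corrected ensemble
  and must equal `k_B T (Σ Ω ln Ω + ln N)`; both forms are computed and the
  identity is asserted to 1e-8 relative in the tests. Temperature defaults
  to 300 K (k_BT ≈ 2.494 kJ/mol) and only scales the reported work.
- **η is fixed at 1** by convention so that γ alone sets the effective
  precision; it is exposed but rarely worth touching. The λ-independent
  normalization constant of ρ_err is dropped.
- **β optimization** (off by default in the library; the CLI exposes
  `--optimize-betas`) proposes joint uniform perturbations with maximum
  steps Δβ_C = 0.15, Δβ_H = 1.6 (10% of the explored ranges [0, 1.5] ×
  [0, 16]), clips to bounds, and greedily accepts only strictly MSD-lowering
  moves; 100 trials per update, every iteration by default with an interval
  knob. Acceptance uses the γ-free MSD. One-at-a-time proposals are a
  switch.

### β identifiability

When the target is *consistent with the unweighted ensemble* (a
self-consistent target), MC optimization started off-target at (0.30, 3.0)
recovers the generative (0.35, 2.0) within ±0.02/±0.2. When the target
encodes a different state mixture, β and λ are jointly under-determined:
the weights can absorb moderate β errors while the MSD still reaches ~1e-9,
and the recovered β then drifts (we observe β_C ≈ 0.40 on the mixture
benchmark) with a correlated distortion of the recovered populations. This
degeneracy is inherent to fitting nuisance parameters inside a reweighting
that can match the data exactly; population-recovery benchmarks therefore
fix β at the generative values.

## Synthetic benchmark

`TwoStateSpec` emulates a protein interconverting between a compact state A
(per-residue contact means drawn from U(8, 16), H-bond probabilities
U(0.6, 1.0)) and an open state B (U(2, 6), U(0, 0.4)); counts are Poisson /
Bernoulli per frame. Defaults: 1000 frames × 30 residues, equal prior state
populations, no decoys, uniform intrinsic rates of 1/min, labeling times
0.167, 1, 10, 60, 120 min — a full pipeline runs in seconds. Targets mix
the two subensembles' protection factors (e.g. 0.6 lnP_A + 0.4 lnP_B) at
residue resolution (two-residue segments (i−1, i), so the first-residue
exclusion isolates residue i) or on overlapping peptide segmentations.

What the fixture does and does not share with real data: it reproduces the
count statistics, state separation and target construction of a two-state
benchmark, but it has no conformational correlation between residues, no
realistic intrinsic-rate variation, and its optional decoy frames are exact
linear interpolants of the two states in feature space. Such interpolants
are *unidentifiable* under the linear-observable maximum-entropy model —
reweighting can satisfy residue-level targets while leaving weight on them —
whereas real decoy conformations carry feature signatures that
residue-resolution data can discriminate. Decoy-rich fixtures
(`decoy_fraction = 0.6`, mirroring a reference ensemble that is mostly
unassigned frames) are therefore used for the information-degradation
experiments, where they supply the resolution-dependent workload that makes
`W_app` at fixed MSD fall as segments coarsen or coverage drops, while the
population-recovery benchmarks use the decoy-free default. Passing tests
show the estimator recovers known mixtures under these conditions; they do
not certify accuracy on force-field ensembles of real proteins.

Peptide segmentation follows the one-residue-overlap rule (1–10, 10–19, …):
segments are generated while they fit entirely within the sequence and the
last one is extended to the C-terminus — for a 310-residue protein and
10-residue segments this yields exactly 34 peptides. Coverage reduction
removes the most buried peptides first (burial proxy: mean contact count of
the segment's exchange-competent residues; ties broken by lower start) until
the retained residue coverage (union of kept segment spans / protein length)
first reaches the requested fraction. Gaussian noise is applied after
segment averaging and is deliberately not clamped to [0, 1]; out-of-range
values are flagged, matching how real noisy fractions behave.

## Ensemble analysis

Frames are assigned to reference states by Cα RMSD after Kabsch
superposition (cutoff 1.0 Å; nearer reference wins, exact ties stay
unassigned). Pairwise RMSD matrices superpose every frame once onto frame 0
by default (O(F) fits; per-pair Kabsch available but O(F²)). Clustering is
DBSCAN on the precomputed RMSD matrix in which a frame's contribution to the
core-point count is its reweighted weight times the ensemble size; the
minimum cluster population defaults to 10% of the total weight, and the
neighborhood radius (default 0.20 Å pairwise RMSD) can be selected by
maximizing the weighted mean silhouette over clustered frames across a
radius scan (ties prefer the smaller radius). With uniform weights the
procedure reduces exactly to standard DBSCAN.

## Scale of the shipped experiments

Tests and the acceptance script run the benchmark at 1000 frames ×
30 residues with 145 residue-level observables — the package's chosen
desk-scale study conditions; each reweighting converges in roughly 10³
iterations. Mixture-recovery checks span generative fractions 0.95–0.05
over multiple seeds and recover populations within ±5 percentage points
(typically ±1). Full-scale trajectory ensembles (10⁴–10⁵ frames) are
supported by the same code paths; the distance-matrix step is the O(F²)
bottleneck there.

## Known limitations

- EX2 kinetics only; no EX1, no isotope-envelope simulation, no
  temperature/pD correction of intrinsic rates beyond the input table.
- The initial ensemble is assumed to be an equally weighted sample of its
  generating distribution; the original potential is never evaluated.
- Regional β overrides apply to target generation and prediction only; the
  optimizer fits a single global (β_C, β_H), so regionally heterogeneous
  exchange mechanisms surface as an MSD floor rather than being fitted.
- Single chain per run; altloc handling keeps the highest-occupancy
  conformer.
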