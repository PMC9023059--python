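# Methods

## Scope and model of the problem

A structure-prediction network fed a deep multiple sequence alignment (MSA)
returns essentially one conformation of a protein. Restricting the depth of
the stochastically subsampled MSA handed to the network — down to tens of
sequences — together with a single recycle and no post-prediction
relaxation, diversifies the output enough that alternative conformations
(e.g. the inward- and outward-facing states of a transporter, or inactive
vs. active GPCR states) appear among an ensemble of ~50 models per depth.
`altconf` implements (a) the run-specification side of that protocol and
(b) the complete analysis of the resulting ensembles. The network inference
itself is an external interface: `altconf.protocol` emits JSON manifests
and command lines for a ColabFold-compatible runner and never imports
network weights, so the whole package is testable without a GPU.

## Protocol generation

* **Subsampling** (`altconf.msa`): uniform draws without replacement from
  the A3M rows, query always retained as row 0 and counted toward the
  reported depth. The engine's `max_extra_msa` is the row budget; its
  `max_msa_clusters` companion defaults to half the budget, except 512 at a
  budget of 5120. Sampling is seeded and byte-reproducible; cluster-aware
  stratification is *not* emulated — the cluster count is carried as run
  metadata only.
* **Run specifications** (`altconf.protocol`): one recycle, no relaxation;
  without templates 5 networks × 10 predictions, with templates the 2
  template-capable networks × 25 predictions (always 50 models per depth),
  template similarity cutoff 1 %, template subsampling enabled. Per-model
  subsample seeds are derived as base seed + model ordinal, and every seed
  is recorded in the manifest. The default depth grid is powers of two from
  16 to 512 plus 1024 and 5120; the endpoints are protocol constants, the
  intermediate rungs a package choice overridable per run.
* **Template vetting** (`vet_templates`): conformation labels are a human
  judgement supplied by the caller; the function filters by label and
  *reports* Needleman–Wunsch identity to the query (BLOSUM62, gap open 11
  / extend 1, identity over alignment length including gaps) without ever
  applying an identity cutoff automatically.

## Ensemble analysis

* **Correspondence** is always by global sequence alignment (same scoring
  as above), never by structural alignment search: all comparisons are
  same-protein or near-identical homologs, and per-residue statistics are
  computed on the intersection of resolved, mapped residues, which is
  reported alongside every statistic.
* **Kabsch superposition**: closed-form SVD solution with the determinant
  sign flip, so reflections are excluded by construction.
* **TM-score**: TM = (1/L_ref) Σ 1/(1+(d_i/d0)²) with
  d0 = max(0.5, 1.24 (L_ref−15)^⅓ − 1.8), maximized over rigid
  superpositions by fragment seeding (full / halves / quarters, minimum
  seed 4) and alternating inlier re-superposition under a distance cutoff
  shrinking from d0 to d0/2 (4 levels, ≤20 inner iterations, cutoff floor
  1 Å for very short references). Normalization length is the reference's
  mapped residue count by default (`normalize_by="model"` is exposed, since
  TM is asymmetric). Ties between seeds go to the earliest seed. On ≤30
  residue toys this matches a dense random-restart maximization oracle to
  1e-3.
* **Misfold exclusion**: average-linkage agglomerative clustering of the
  pairwise Cα-RMSD matrix (per-pair Kabsch on shared residues), cut at 5 Å;
  clusters smaller than 3 models are excluded. The algorithm, metric and
  cutoffs are package choices (simple and deterministic); 1−TM is
  available as an alternative metric. Excluded models do not enter PCA.
* **Ensemble alignment**: iterative mean-structure superposition (fit on
  shared residues, apply to all; stop when the mean moves <1e-6 Å, cap
  100 rounds). A single-model reference policy is available; the iterative
  mean never leaves more total variance than any single-model reference.
* **Flexibility comparison**: per-residue Cα displacement between the two
  mutually superposed experimental references vs. RMSF over the aligned
  ensemble; both filtered to residues with mean pLDDT > 75 (inclusive
  exclusion at ≤75; the filter can be disabled), then squared Pearson
  correlation. The ensemble-mean pLDDT is used because the filter operates
  on a single per-residue profile.
* **Landscape**: PCA by SVD of the centred 3N coordinate matrix of masked
  Cα positions, models only; experimental references are projected
  afterwards (superposed onto the ensemble mean over masked residues
  first), so they never influence the basis. "Loop" residues are excluded
  by a Cα-geometry heuristic (helix: d(i,i+3) ∈ [4.5, 6.5] Å and
  d(i,i+4) ∈ [4.2, 7.3] Å; strand: d(i,i+2) ∈ [6.0, 7.5] Å and
  d(i,i+3) ∈ [9.0, 11.0] Å); user masks override, and the mask used is
  recorded in every output. Component signs are fixed deterministically
  (largest-magnitude loading positive), then PC1 is re-oriented so the
  first reference projects negative. Extreme-model selection takes the k
  most extreme PC1 models per side, outermost first, ties broken by model
  id.

## Synthetic fixtures

The generator (`altconf.fixtures`) emulates the study's inputs at desk
scale: a 60-residue idealized Cα coil (exact 3.8 Å virtual bonds, 30° turn
and 1.5 Å rise per residue — wide enough that a 10 Å hinge displacement is
geometrically reachable, which a thin ideal α-helix is not), with residues
18–47 rotated rigidly about the chord through the flanking anchors to form
end state B. The hinge angle is solved by bisection so the *post-
superposition* peak Cα displacement equals `hinge_amplitude` (default
10 Å), and both end states are symmetrized about their midpoint by
iterated Kabsch fits so the conformational mode carries no net rigid
motion on either side; without this, ensemble alignment bends the
interpolated path and PC1 cannot recover the injected mode.

Ensembles (default 50 models) draw an interpolation coordinate t per model
— end-state draws at t = 0.1 / 0.9 per the state weights, 20 %
intermediates uniform in [0.1, 0.9] — and add isotropic Gaussian noise
(default σ = 0.5 Å). Confining t to [inset, 1−inset] reflects the observed
geometry that predicted models fall *inside* the bracket spanned by the
experimental structures; the inset of 0.1 is calibrated so the PC1 margin
(~4.7 Å) dominates both the residual rigid-motion absorption when
references are superposed onto the ensemble mean (~2.4 Å) and the noise
projection (σ). Misfolded decoys (default 2) are self-avoiding random
walks with native bond lengths. Emulated pLDDT drops linearly from 95 with
absolute positional error, reaching 55 at ≥4 Å; decoys carry a flat 40.
All outputs are deterministic in the seed and round-trip through the
package's PDB/A3M writers.

What the fixtures do *not* emulate: real protein packing and secondary-
structure physics, sequence–structure covariation, network-specific error
modes, or any empirical relation between confidence and flexibility.
Passing the recovery tests therefore demonstrates correctness of the
analysis machinery under a known ground truth, not predictive performance
on real proteins.

## Numerical choices and degenerate inputs

* Displacement for a single mapped pair is 0 (centred exactly); for two
  pairs it is the residual of the optimal segment superposition; Kabsch
  requires ≥3 points.
* RMSF requires ≥2 models, clustering ≥3, PCA ≥3; correlations require ≥3
  shared residues and raise on zero variance.
* PCA retains all components above a 1e-12 relative-variance floor, so
  reconstruction from the full basis is exact to 1e-6 Å and variance
  fractions sum to 1.
* TM-score iterations that would drop below 4 inliers fall back to the 4
  closest pairs so refinement can continue.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the spec objects; workflow reruns are byte-identical (CSV floats written
  at fixed precision).

## Problem sizes

The test and acceptance workloads use 60-residue toys, 50-model ensembles,
500-model noise ensembles for the RMSF expectation, 1000-row alignments ×
100 seeds for the subsampler statistic, and ≤30-residue structures for the
brute-force superposition oracles — sizes at which the exhaustive oracles
remain exact and the whole suite runs in about a minute on one core.

## Known limitations

* The displacement–RMSF correlation degrades toward r² ≈ 0.7 as noise
  approaches amplitude/4, because RMSF carries an additive isotropic noise
  floor σ√3 that compresses profile contrast
  (RMSF_i ≈ sqrt(3σ² + Var(t)·d_i²)); the r² > 0.75 recovery regime is
  comfortably met at the default σ = amplitude/20.
* TM-scores here use sequence-derived correspondences; they can differ
  from structure-alignment tools on remote homologs, which are out of
  scope.
* The secondary-structure heuristic is a coarse Cα-geometry filter meant
  for masking flexible loops out of PCA, not an assignment tool.
* Single chains only; no side chains; experimental structures with
  unresolved residues simply shrink the reported shared-residue set.
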