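# Methods

This note documents the models, parameter choices and known limitations of
the `h1ub` pipeline: what each stage assumes, which knobs matter, and what
the synthetic-data generators do and do not emulate.

## Coarse-grained representation

Residues resolved in a crystal structure are one-residue beads (radius
2.3 Å, roughly the Cα–Cα spacing scale) constrained into rigid bodies;
unresolved regions are chains of flexible beads covering up to 20 residues
each, with radius scaling as the cube root of the residue count (volume
conservation relative to the one-residue bead). Chain topology connects
sequence-adjacent beads, including rigid–flexible junctions. For
lysine-conjugated ubiquitin constructs an extra bond-like edge ties the
ubiquitin C-terminal residue (76) to the acceptor lysine of the histone;
the conjugation chemistry (a triazole linkage mimicking the isopeptide
bond) is short and rigidly couples the two chains, so a connectivity edge
is the physically sensible representation. PDB input is read with biotite;
only the first MODEL of multi-model files is used, and chains are
selectable per rigid body.

## Score

The score is the negative logarithm of likelihood × priors.

* **Crosslink likelihood.** Each weighted crosslink contributes
  `w · log[ψ_c + (1 − ψ_c) f(d)]` with `f(d) = 1/(1 + exp((d − d₀)/λ))`.
  Defaults: `d₀ = 25 Å` (BS3: 11.4 Å spacer plus two lysine side chains),
  `λ = 2.5 Å`. The positional uncertainty σ is folded into λ rather than
  sampled; ψ defaults to (0.30, 0.10, 0.05) for the three ld-score classes,
  so low-confidence links are allowed to be violated at bounded cost. All
  of these are configurable; the sigmoidal form is the common choice for
  amine-reactive crosslinkers.
* **Connectivity prior.** Upper harmonic `k(d − cap)²` per topology edge,
  zero below the cap; `cap = r_i + r_j + 4 Å · √(residues spanned)`
  (random-coil scaling), `k = 1` score-unit/Å².
* **Excluded volume.** Soft sphere `k(r_i + r_j − d)²` over non-bonded,
  non-intra-rigid pairs, `k = 1` score-unit/Å².

A vectorized evaluator (`sampler.CompiledScore`) precomputes link bead
indices and pair lists; a unit test pins it to an independent naive
re-implementation at 1e-9.

## Sampling

Replica-exchange Metropolis Monte Carlo. One sweep proposes, per mobile
rigid body, a translation (uniform direction, magnitude uniform up to
10 Å) plus a rotation about a random axis through the body centroid (angle
uniform up to 1 rad), and per flexible bead an individual translation.
Acceptance is min(1, exp(−ΔS/T)). The temperature ladder is geometric
between 1.0 and 2.5 (technical units, 32 replicas in production); a random
adjacent pair attempts a swap every 10 sweeps with the standard criterion
min(1, exp((1/T_i − 1/T_j)(S_i − S_j))). Ladder spacing and swap frequency
are implementation choices; the production frame/replica counts and move
maxima are the protocol parameters. Retention ("25% best-scoring saved") is
applied to all frames of a run pooled across replicas, which reproduces the
production bookkeeping 0.25 × 32 × 15000 = 120000 models per run; a
per-replica mode exists behind a flag. Each replica draws from an
independent RNG stream spawned from the master seed, so runs are bitwise
reproducible.

Desk-scale protocol used by the tests and the acceptance script: 4 replicas
× 2000 frames × 3 runs on a ~110-bead complex (about 7 s on one CPU). These
sizes are the package's default demonstration scale; the production-scale
constants remain the config defaults.

## Ensemble analysis

Pairwise RMSD is computed over the mobile proteins in the shared frame —
no superposition, because the reference body is fixed during sampling (a
Kabsch mode exists for non-fixed setups). Clustering is greedy leader
clustering: seed at the unassigned model with the most unassigned
neighbors within the cutoff (10 Å default), assign those neighbors,
recompute the center as the member minimizing mean RMSD to the members;
deterministic given the matrix. Precision is the per-protein RMSF about
the center. Localization densities count, per voxel (5 Å default), the
fraction of members whose bead spheres reach the voxel center; they are
written as MRC. Convergence across independent runs is reported as the
best Jaccard overlap between each run's clusters and the pooled clusters.

## Synthetic data: what it emulates, and what it does not

* **Toy complex.** A large receptor (beads on an open concave shell,
  radius 26 Å) with a compact mobile protein seated in the cleft at
  van-der-Waals contact. The seated-contact geometry matters: crosslink
  restraints are one-sided (they penalize long distances only), so the
  score minimum always presses the mobile body against the receptor along
  the link pull. A truth pose chosen at contact inside a concave interface
  makes that minimum coincide with the truth — which is exactly the
  situation of a real bound complex — and is what makes pose recovery to
  within a bead diameter achievable. A convex two-blob geometry leaves a
  feasible region many Å wide and is not identifiable at that precision.
* **Crosslink tables.** True links are drawn from residue pairs within the
  crosslinker reach (25 Å), round-robin across mobile-side residues the
  way reactive lysines cover a surface; decoys are uniform over all pairs.
  ld scores are drawn from shifted normals (means 38 vs 24, SD 5) so that
  the plotting/modeling threshold policies separate the populations;
  deltaS and FDR columns are drawn in the passing range. Defaults: 100
  unique site pairs, 3 replicates, 90% per-replicate detection, 5% decoys.
  Not emulated: spectra, retention times, heavy/light isotope pairs.
* **AP-MS matrices.** 500 proteins × 6 conditions × (3 biological × 2
  technical) columns at log2 scale; 10% of proteins are planted "enriched"
  with a 4σ mean shift in 1–3 conditions. Dropout (10%) is
  missing-not-at-random: censoring probability decays exponentially with
  intensity rank, the below-detection-limit regime the imputation model
  assumes. Uniform (random) missingness of high-intensity values is *not*
  simulated; with such contamination the down-shifted imputation would
  create spurious within-group variance and sensitivity would drop — a
  known limitation of this imputation strategy, not of the test.
* **Images.** Disks of constant intensity (100) on constant background
  (10) with additive Gaussian noise; droplets never touch the border. No
  PSF, no shading, no out-of-focus light.
* **FRAP.** The bleached ROI follows y(t) = y∞ + (y0 − y∞)e^(−kt) (defaults
  k = 0.05 s⁻¹, y0 = 0.2, y∞ = 0.8) multiplied by a shared acquisition
  photobleaching decay e^(−bt) (b = 0.002 s⁻¹); ten 1-s pre-bleach frames
  precede the bleach. The correction factor
  f_t = I_Ref_pre/(I_Bleach_pre · I_Ref,t) inverts the decay exactly by
  construction, which the tests assert at 1e-9.

Passing tests on these generators show the estimators are correct under
their stated model; they do not establish robustness to real-data artifacts
(uneven illumination, partial-volume droplets, ratio compression,
peptide-level interference).

## Enrichment statistics

The moderated statistic is `sqrt(Σ_g n_g (x̄_g − x̄)²) / (s_pooled·√(k−1) + S0)`
(SAM convention); at S0 = 0 it is a strictly monotone transform of the
classical one-way F, which a unit test asserts. The null is built from 250
(tests: 200) group-label permutations; a protein's q-value is the expected
false-positive count above its statistic divided by its rank, with
monotonicity enforced down the ranking. The valid-value rule ("5 of 6")
is applied per condition by default (at least one condition must satisfy
it); a total-matrix mode exists because the design wording is ambiguous.
Repeated-measures Tukey comparisons are computed as Tukey HSD on
subject-demeaned values after an AnovaRM omnibus — a documented
approximation, as the exact pairing convention of commercial packages is
not public.

## Condensate quantification

The local threshold is Phansalkar's: on the [0,1]-normalized image,
`t = m·(1 + p·e^(−q·m) + k·(s/r − 1))` with fixed p = 2, q = 10 and shape
parameters k = 0.25, r = 0.5 (the method's canonical defaults), window
radius 15 px. The noise filter is a 3×3 median on the binary mask (the
protocol names a noise filter without specifying it). Circularity uses the
region-perimeter convention compatible with Fiji and is clamped at 1 for
small objects where the discrete perimeter underestimates. The FRAP
baseline subtraction ("mean intensity of the bleached ROI subtracted") is
implemented as an off-by-default toggle that subtracts the first
post-bleach value; the default pipeline relies on Eq.-1-style
normalization only, since applying both changes the meaning of y0.

Numerical notes: the threshold comparison includes a 1e-9 epsilon because
box-filter arithmetic produces ±1e-17 noise on constant regions, which
would otherwise binarize flat background. The FRAP fit parametrizes
k = exp(lrc) to keep it positive, initializes y∞ from the last 10% of
points and lrc from a log-linear fit, and flags flat curves as
unidentifiable instead of fitting them.

## Known limitations

* The Bayesian nuisance parameters ψ are fixed per class, not Gibbs-sampled.
* Localization densities use voxel-center inclusion, not exact
  sphere–voxel overlap volumes; at 5 Å spacing the difference is below the
  bead scale.
* Pose recovery accuracy is guaranteed only for cleft-like (concave)
  interfaces with links spread over the mobile protein; shallow convex
  interfaces are fundamentally under-determined by upper-bound restraints.
* The permutation FDR needs `n_permutations × n_proteins` null statistics
  large relative to 1/FDR; the implementation warns when the resolution is
  insufficient.
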