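# h1ub

Analysis toolkit for studying site-specifically ubiquitylated linker histone
H1.2 and its complexes: crosslink-guided Bayesian integrative structural
modeling, crosslinking-MS (XL-MS) filtering and weighting, AP-MS interactome
enrichment statistics, and quantification of phase-separated condensates and
FRAP kinetics. Every stage can run on synthetic inputs with known ground
truth, so the whole pipeline is testable on a laptop without any raw
mass-spectrometry or imaging data.

## Who this is for

Structural and chemical biologists who combine chemical crosslinking (BS3)
with coarse-grained modeling to place a small protein (here: the H1 globular
domain, or H1 conjugated to ubiquitin at a specific lysine) onto a large
binding partner (here: the deacetylase SIRT1), and who quantify the
downstream biology with label-free AP-MS, droplet microscopy and FRAP.

## The models at the core

**Bayesian crosslink score.** A complex is represented as beads — one residue
per bead inside crystal-structure rigid bodies, 20 residues per bead in
flexible chains. Models are ranked by

    S(X) = − Σᵢ wᵢ log[ ψ_cᵢ + (1 − ψ_cᵢ) f(dᵢ(X)) ] + U_conn(X) + U_ev(X)

where `dᵢ` is the model distance of crosslink *i*, `f(d) = 1/(1+exp((d−d₀)/λ))`
is the forward model of crosslink formation (`d₀` = 25 Å, the BS3 Cα–Cα
reach; `λ` = 2.5 Å), `ψ_c` is a per-confidence-class false-positive rate,
`wᵢ ∈ {1,2,3}` counts the biological replicates supporting the link, and the
priors are an upper-harmonic sequence-connectivity term and a soft-sphere
excluded-volume term. Sampling is replica-exchange Metropolis Monte Carlo
(32 replicas × 15000 frames at temperatures 1.0–2.5 in production; rigid-body
moves of at most 10 Å and 1 rad), the best 25% of frames are retained, the
pooled 500 best models are clustered at a 10 Å RMSD cutoff, and per-protein
precision is the RMSF about the cluster center.

**Enrichment statistics.** AP-MS intensity matrices are filtered (5 of 6
valid values), imputed from a down-shifted normal (width 0.3, shift 1.8 SD,
total-matrix scope), and tested with an S0-moderated one-way statistic
(S0 = 2) against a permutation null at FDR 0.001; significant proteins are
Z-scored, replicate-averaged, clustered (Euclidean), and assigned to bait
groups at Z ≥ 0.3.

**Condensates and FRAP.** Droplets are segmented with a Phansalkar local
threshold (radius 15 px), a median noise filter, and size (≥ 4 px) and
circularity (4πA/P² ≥ 0.85) gates; the partition coefficient is
I_droplet/I_outside over integrated intensities. FRAP curves are normalized
and bleach-corrected with f_t = I_Ref_pre/(I_Bleach_pre · I_Ref,t) and fitted
to the asymptotic regression y(t) = y∞ + (y0 − y∞)e^(−kt).

## Worked example

Run the fully synthetic, desk-scaled pipeline:

```bash
h1ub demo --seed 1 --out demo_run
```

which prints (abridged):

```json
{
  "crosslinks":  {"n_rows": 270},
  "modeling":    {"n_models": 500, "n_clusters": 1, "best_score": 55.02},
  "enrichment":  {"n_proteins": 478, "n_significant": 48},
  "condensates": {"n_droplets": 10, "partition_coefficient": 0.412},
  "frap":        {"k": 0.05, "y_inf": 0.8},
  "array":       {"length_bp": 2484, "paci_sites": 12}
}
```

Reading the numbers: 270 simulated crosslink identifications (100 unique
site pairs over 3 replicates with 90% per-replicate detection) collapse to
weighted restraints; scaled sampling (4 replicas × 2000 frames × 2 runs)
converges to a single cluster of the 500 best-scoring models. Of 500
synthetic proteins, 478 pass the valid-value filter and 48 are significantly
enriched at FDR 0.001 (the generator planted 10% enriched proteins at a
4σ effect). The 10 rendered droplets partition 41% of the integrated
intensity into the condensed phase, the FRAP fit recovers the generating
kinetics (k = 0.05 s⁻¹, y∞ = 0.8) exactly on a noiseless trace, and the
12-mer nucleosome-positioning array is 2484 bp with one PacI site per
207 bp repeat.

Individual stages are available both as library functions
(`h1ub.ms_filters.filter_crosslinks`, `h1ub.condensate.frap_fit`, …), as
sklearn-style estimators where the operation is fit/transform-shaped
(`FrapRecoveryModel`, `ModeratedAnovaFDR`, `ThresholdClustering`,
`DropletSegmenter`), and as CLI subcommands (`h1ub mass`, `h1ub synth`,
`h1ub quantify`, `h1ub frap`, `h1ub filter-links`, `h1ub array`).

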