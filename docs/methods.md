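# Methods

This note documents the modeling and numerical choices behind
`graphscreen`: what the pipeline computes, which knobs matter, what the
synthetic data generator does and does not emulate, and where the design
was genuinely open.

## Curation model

Raw records are (compound, endpoint, value, unit) tuples. The pipeline is a
fixed composition: standardize → convert to μM → threshold-label →
deduplicate → druggability-filter. Decisions a maintainer should know:

* **Standardization.** The kept structure is the largest carbon-containing
  fragment (ties broken by lexicographic canonical SMILES), neutralized by
  RDKit's Uncharger, which reverses protonation-state charges
  (carboxylate→acid, ammonium→amine) but leaves true quaternary centers
  charged. Stereochemistry is preserved. Canonical strings are whatever the
  pinned RDKit version emits; the test fixtures pin the dialect, and the
  strings should not be assumed portable across toolkit versions.
* **Labels.** Active is IC₅₀ ≤ 10 μM (closed boundary), inactive is
  strictly > 30 μM, and (10, 30] is excluded as label noise. Ki and Kd are
  treated as IC₅₀-equivalent after unit conversion; `ic50_only` restricts
  to IC₅₀ when that equivalence is not acceptable. No Ki→IC₅₀ conversion
  factor is applied — none is defensible without assay context.
* **Deduplication** keys on canonical SMILES (stereo included; a flag can
  strip it) and keeps the minimum μM value, i.e. the most potent
  measurement. It runs after gray-zone exclusion, so a molecule survives if
  *any* of its measurements is outside the gray zone.
* **Druggability.** Molecular weight window 150–800 Da on the desalted
  parent (average atomic masses), plus a blacklist of ~10 reactive SMARTS
  (acyl halides, aldehydes, enones, epoxides, isocyanates, azides,
  activated alkyl halides, peroxides, nitroso, anhydrides). The list is a
  deliberate, documented default; it is configurable because no canonical
  list exists.

The curation report records survivors after every stage and every removal
reason; conservation (final = parsed − Σ removals) is test-enforced.

## Featurization

Atom vectors are 78-dimensional: element one-hot over {C,N,O,S,F,Cl,Br,I,P}
(9), degree 0–10 (11), formal charge −3…+3 clipped (7), chirality (4),
total hydrogens 0–10 (11), hybridization (8), aromatic flag, mass/100,
ring flag, ring-size flags 3–8 (6), implicit and explicit valence 0–6
(7+7), radical electrons 0–4 (5). Every one-hot block has exactly one
nonzero entry; out-of-range categoricals clip into the last bucket, but an
element outside the vocabulary rejects the whole molecule with a counted
reason — silently dropping atoms would corrupt the graph. Bond vectors are
12-dimensional (order, conjugation, ring, stereo); each undirected bond
becomes two directed edges with identical features. Hydrogens are implicit.

The 50 global descriptors are a frozen ordered list of standard RDKit 2D
descriptors, the first six being MW, LogP, HBD, HBA, TPSA and rotatable
bonds; the remainder are ring counts and the usual topological families
(χ, κ, Balaban J, Bertz CT, Labute ASA, QED, …). Descriptors are z-scored
with moments fit **on the training split only**; a descriptor constant on
the training set gets unit variance (its scaled column is zero), with a
warning. This happens routinely on small sets (e.g. radical electrons,
spiro atoms) and is harmless.

## Network

Defaults: 3 attention layers, 8 heads, per-head width 256, head outputs
**averaged** (hidden space stays 256), batch norm + ELU + dropout 0.2
between layers; dual pooling (GAP‖GMP → 512); descriptor branch 50→64→32
(ReLU, dropout); fusion head 544→512→1 with batch norm, ReLU, dropout and a
sigmoid. Two attention modes are configuration switches:

* `gatv2` (default): score = aᵀ LeakyReLU(W_t h_i + W_s h_j + W_e e_ij).
* `gat` (ablation): score = LeakyReLU(aᵀ [W_t h_i ‖ W_s h_j ‖ W_e e_ij]).

Design points worth recording:

* **Two transforms per head** (W_s for sources/messages, W_t for targets).
  With a single shared W the dynamic mode degenerates toward static
  behavior; the split is required for the context-dependent ranking that
  distinguishes GATv2. The package's test for this is exact: under static
  attention the neighbor ranking is provably independent of the center atom
  (the score is monotone in a center-constant plus a neighbor term), while
  the dynamic mode re-ranks; this replaces a noisy trained "lookup task"
  comparison with a deterministic property.
* **Self-loops** with zero bond features are added to every node at batch
  construction, so single-atom molecules (a legal edgeless graph) and
  isolated atoms have defined neighborhoods. A node with no in-edges is an
  error, not a NaN.
* **Bond features** enter attention additively inside the nonlinearity
  (dynamic mode) or concatenated into the scored vector (static mode); they
  do not alter the message content, only its weighting.
* **Head aggregation mean vs concat.** Mean is the default: it keeps the
  hidden space at 256 and puts the default parameter count at 2,783,969,
  i.e. within 1 % of 2.8 M; concat is available as a switch (it multiplies
  widths by the head count). Batch-norm running statistics are frozen in
  eval mode and dropout is disabled, which is what makes the permutation-
  and spelling-invariance guarantees exact rather than approximate.
* **Numerics.** All math is float64 on a small tape-based reverse-mode
  autodiff (`graphscreen.nn`). The attention softmax subtracts a detached
  per-neighborhood maximum (exact for softmax, numerically safe). The
  max-pool and segment-max subgradient splits ties equally —
  deterministic and valid. Probabilities are clamped to [1e−7, 1−1e−7]
  inside the loss.

## Training

AdamW (base LR 1e−3, weight decay 1e−5) — adopted for the main model for
consistency with the baselines it is compared against. Loss is
label-smoothed BCE, ỹ = y(1−ε)+ε/2 with ε = 0.1 (targets 0.05/0.95); an
optional positive-class weight exists but defaults off, because the
weighted sampler already equalizes class exposure and stacking both would
double-correct. Sampling is with replacement under class-inverse weights;
gradients are averaged over 2 consecutive batches of 64 (effective 128) and
clipped at global norm 3.0 per optimizer step. The cosine warm-restart
schedule is stepped per epoch (restarts at cumulative epochs 10, 30, 70).
Early stopping watches validation AUC with patience 20 and min-delta 0.001;
the best weights are snapshotted whenever validation AUC improves at all,
so the returned model always attains the maximum recorded validation AUC.
Augmentation (randomized SMILES, probability 0.3 per molecule, ≤3 distinct
variants sharing the parent label) is resampled once before training as a
static expanded dataset — simpler and exactly reproducible — and applied to
the training split only, so augmented spellings can never leak across
splits. Runs are bit-reproducible for a fixed seed.

## Scaffold splitting and auditing

Bemis–Murcko scaffold groups are assigned whole. Groups are ordered by
descending size, then scaffold string, and each group goes to the split
with the largest remaining deficit against its target count (ties:
train > valid > test). This deterministic rule honors the requested
fractions and — unlike a strict "fill train, then valid, then test"
sweep — cannot leave the test split empty while the validation split
overflows. Acyclic molecules form a single (empty-scaffold) group. The
audit computes, per test compound, the maximum Tanimoto similarity to any
training compound on 2048-bit radius-2 Morgan fingerprints (ECFP4 — the
"4" is a diameter); summaries use linear-interpolation percentiles.

## Uncertainty

Predictive entropy is base-2, H(p) = −p log₂ p − (1−p) log₂ (1−p) ∈ [0,1]
bits. Base 2 is deliberate: useful flagging thresholds sit near 1 bit,
above the natural-log maximum of ln 2 ≈ 0.693. The screening report flags
the top 10 % of calls by entropy (stable tie-break: entropy descending,
then index) and reports per-bin accuracy/F1 for H < 0.3, 0.3 ≤ H < 0.6,
H ≥ 0.6. The flagging threshold is therefore a data-dependent quantile,
not a constant. Hard-decision metrics use threshold 0.5 unless overridden.

## Synthetic data generator

The generator emulates the *statistical* structure of public bioactivity
extracts, not their chemistry. Molecules are assembled from a grammar of 22
ring scaffolds × substituents chosen so every product parses and sits in
150–800 Da. Activity is planted on a sulfonamide substituent
(S(=O)(=O)N) — deliberately a substituent and not a scaffold, so
Bemis–Murcko splitting cannot separate the signal and held-out recovery
measures learning, not memorization. Potencies are log-normal in log10
space (sd 0.5) with medians 1 μM (motif) and 100 μM (decoy): the two
distributions overlap the 10–30 μM gray zone (≈2 % and ≈12 % of draws), so
the exclusion rule is exercised; draws crossing the *opposite* label
boundary are resampled, so at zero label noise curation recovers the motif
labeling exactly, minus gray-zone exclusions. On top of the clean signal
the generator injects duplicates (rate 0.1), counterion/salt forms (rate
0.1), mixed nM/μM/M units and IC₅₀/Ki/Kd endpoint types; motif prevalence
0.3 gives the class imbalance the weighted sampler exists for. Everything
is deterministic per seed.

What it does **not** emulate: real scaffold-activity correlations, assay
noise heterogeneity, activity cliffs, tautomers, or ChEMBL's element and
size distributions. Passing the recovery experiment therefore shows the
pipeline and model are correct and can learn a substituent-level rule
under scaffold shift — it does not certify performance on real screens.

The end-to-end recovery experiment at its default size (600 molecules →
~527 curated → ~43 in the test split) estimates held-out AUC from few
compounds: under a signal-free null the AUC estimate has standard deviation
≈ 0.09 at that size, a caveat to keep in mind when reading near-chance
results from single runs.

## Problem sizes

Default test and experiment sizes were chosen so the whole suite runs on
one CPU core in a couple of minutes: recovery uses a small model (hidden
64, 4 heads, 2 layers, ≤40 epochs with early stopping) on 600 molecules;
property suites use 1000 random graphs or instances. The full-size default
model (≈2.8 M parameters) is instantiated and exercised forward, but not
trained, in the tests.

## Known limitations

* No tautomer canonicalization, pChEMBL handling, or assay-confidence
  scoring during curation.
* Ki/Kd are pooled with IC₅₀ by default (no conversion factor).
* The element vocabulary is fixed at 9 organics; boron- or
  selenium-containing molecules are rejected, by design, with a counted
  reason.
* Single-process CPU training only; no mini-batch-level scheduling, no
  mixed precision, no hyperparameter search.
* The model gives no calibration guarantee; entropy flags relative, not
  absolute, unreliability.
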