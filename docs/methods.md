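# Methods

## Model

A docking ensemble for one protein pair is an ordered set of rigid-body
decoys with per-decoy interaction energies
`E_int = E(complex) − Σ E(components)` in kcal/mol. Energies are inputs:
the package consumes score tables (TSV/CSV or Rosetta-style whitespace
tables keyed by a `description` column) and never evaluates a force field.

All positional analysis is referenced to the strongest-interacting decoy
(minimum `E_int`; ties broken by ensemble order). This replaces the native
complex, which does not exist in a prospective screen. Consequences worth
keeping in mind: the reference is itself a random draw from the ensemble,
and for pairs without an energetic funnel it is an arbitrary pose; all
scores then measure dispersion around an arbitrary orientation, which is
exactly the behavior that separates the two classes.

### Interface and iRMS

Interface residues are detected on the reference only: a residue belongs to
the interface if any of its heavy atoms lies within `cutoff` (default 10 Å,
inclusive) of any heavy atom of the opposite side. Backbone atoms
(N, CA, C, O) of interface residues, in deterministic (chain, residue,
atom-name) order, form the iRMS atom set. iRMS is the *minimized* RMSD of
that atom set after proper-rotation Kabsch superposition — the convention
of interface-RMSD tools — rather than a fixed-frame RMSD; this makes iRMS
invariant to whole-complex rigid motion, which any sensible pose distance
must be. Atoms missing from either structure are skipped in both; fewer
than three shared atoms is an error.

### TM-score family

`tm_score` uses the standard kernel `(1/L_norm) Σ 1/(1+(d_i/d0)²)` on CA
atoms with `d0(L) = 1.24 (L−15)^⅓ − 1.8`, floored at 0.5 Å (the printed
formula is non-positive for short lengths; the floor and the CA convention
follow the reference implementations). The maximizing superposition is
searched heuristically: seeds from sliding windows of the full length,
halves, and quarters (minimum 4 residues, stride half a window), each
refined by re-superposing on residues within a cutoff that shrinks from
8 Å to max(d0, 4.5 Å) until the included set is stable; the best score over
all visited superpositions is kept. The search can only under-estimate the
true maximum; a dedicated test checks it beats the single-superposition
plug-in score when outliers are planted.

* **rTM** is the harmonic mean of per-chain TM-scores measured in one
  common frame — the superposition maximizing the whole-complex TM-score.
  With rigid decoys, per-chain re-superposition would always return 1, so
  the common frame is what makes the score informative. The frame choice is
  a design decision (the score's verbal definition does not fix it).
* **iTM** restricts the kernel to interface-residue CAs, normalized by the
  total interface residue count; per-side scores are normalized by each
  side's own interface count (a design decision; the per-side
  normalization keeps small interfaces comparable). Its superposition
  starts from the iRMS interface-backbone frame — a free TM search is
  under-determined on tiny interfaces — and is refined on interface CAs;
  the frame with the best whole-interface score also evaluates the
  per-side scores. **riTM** is the harmonic mean of the per-side values.

Harmonic averaging (`N / Σ 1/s_i`) is used for both composite scores so a
single well-recovered large protein or interface side cannot dominate.

### Narrow-funnel statistic and criteria search

The narrow-funnel fraction is the percentage of decoys with
`E ≤ e_max` **and** `iRMS ≤ irms_max`; a pair is classified narrow-funnel
when the fraction is `≥ fraction_min`. All three comparisons are inclusive.
The criteria triple is chosen by maximizing TP−FP over a grid; defaults:
energy from the pooled 1st percentile to 0 kcal/mol in 20 steps, iRMS
1–30 Å in 1 Å steps, fraction ∈ {0.1, 0.2, 0.5, 1, 2, 5, 10} %. Argmax ties
resolve to the lexicographically first (fraction, energy, iRMS) cell.
Group comparisons of per-ensemble means use the classic pooled-variance
two-sample Student's t (not Welch), with the star convention * p<0.05,
** p<0.01, *** p<0.0005.

### Recurrent partner classifier

`RecurrentPairClassifier` is a scikit-learn-style estimator: a single
Elman recurrent block (tanh) consumes one decoy row per timestep, and the
final hidden state passes through a dense stack ending in a 2-way softmax
trained with cross-entropy. The network, backpropagation through time, and
the optimizer rules (Adam, SGD, RMSprop, Adadelta, Adamax, Adagrad, Nadam,
Ftrl — family-default learning rates, overridable) are implemented directly
on numpy; gradients are clipped to global norm 5.

Input representation (a design decision; nothing canonical exists): rows
sorted by ascending energy (ties by decoy id), truncated/zero-padded to
`sequence_length`, standardized per column with training-set statistics.
The recurrent layer reads the sequence *backwards* by default
(`reverse_sequence=True`): a plain recurrent block forgets inputs hundreds
of steps back, so the informative low-energy head must sit adjacent to the
read-out — forward reading trains unstably, backward reading is stable.
Historical layer structures (1024-2, 1024-64-2, 1024-128-2, 2048-128-2,
2048-512-128-32-8-2; first width = recurrent units) are available as
`LAYER_CANDIDATES` for `model_search`; the estimator's own defaults
(32 recurrent units, direct 2-way read-out, 30 epochs, batch 16, Adam) are
sized for the desk-scale benchmarks below.

Cross-validation is stratified k-fold (default 10) after a seeded shuffle
— stratification is a stability choice at small n — with per-fold ROC by
threshold sweep, trapezoidal AUC, and pooled accuracy at p ≥ 0.5. Constant
score vectors report AUC 0.5 by convention. Determinism: identical data,
parameters and seeds reproduce identical weights and predictions (each CV
fold derives its seed as `seed + fold`).

## Synthetic generator

`funnelscan.synthetic` emulates rigid-body docking output. Chains are
self-avoiding persistent CA random walks (3.8 Å steps, non-consecutive CAs
≥ 4.0 Å) with idealized N/C/O offsets; ligand poses are uniform rotations
(quaternion sampling) slid into contact along a random direction by
bisection until the minimum heavy-atom gap equals `contact_gap`
(4.5 Å ± 0.05, a van-der-Waals contact distance).

Three ensemble modes:

* **funnel** — a fixed native pose; `ceil(funnel_fraction · n)` decoys
  perturb it (half-normal rotation jitter `rot_sigma`, lateral contact
  jitter `trans_sigma`) with energies `−depth + slope·iRMS + N(0, noise)`
  (iRMS measured post hoc against the native); the rest are uniform contact
  poses with `N(0, noise)` energies.
* **scattered** — only uniform contact poses with noise energies.
* **broad** — a broad funnel-like landscape: energies produced by the exact
  funnel pipeline (hidden native, jittered poses, post-hoc iRMS), but every
  stored pose is an independent uniform contact pose. Energy marginals
  match funnel mode decoy-for-decoy while the energy–position coupling is
  severed — the archetype of a strong-scoring non-interactor.

Defaults are the study conditions: n_decoys 1000, chains 30+30 residues,
funnel_fraction 0.15, rot_sigma 10°, trans_sigma 2 Å, depth 20 kcal/mol,
slope 1 kcal/mol/Å, noise 2 kcal/mol. Energies follow a stated generative
law, not a force field: the object of study is the joint (energy, iRMS)
distribution, and that law is what the two hypotheses (one dominant
orientation vs none) predict qualitatively. What the generator does *not*
emulate: flexible backbones, side chains, real energy ruggedness,
multi-site binding, >2 chains. Tests passing on it demonstrate the
*machinery* (scores, statistics, training) and the qualitative
distributional directions — not performance on real docking output.

## Benchmarks and problem sizes

Tests and the acceptance script scale the conditions down to run on one
CPU in minutes; sizes are stated with each result.

* **Matched funnel/scattered benchmark** (group direction, criteria
  search): 20 pairs × 200 decoys, chains 20+20. Each funnel/scattered pair
  shares a seed, hence identical chain geometry — an all-else-equal design;
  with independently drawn chains, between-ensemble chain-shape variance in
  mean iRMS is on the order of the funnel shift itself and masks it at
  n=20. The pooled (unpaired) t-test is still what is reported.
* **Separable benchmark** (classifier sanity): 50+50 ensembles × 150
  decoys, chains 14+14, default depth.
* **Weak-funnel benchmark** (feature ablation): 20+20, funnel depth reduced
  to 8 kcal/mol for positives, **broad** negatives. Reducing depth alone
  cannot make energy uninformative while keeping the positional signal: as
  depth approaches the noise scale the minimum-energy reference decouples
  from the funnel cluster and the iRMS column degrades with the energy
  column. Matching the energy marginals via broad negatives isolates the
  energy–position coupling as the only class difference, which is the
  phenomenon the ablation is meant to probe (energy-only near chance,
  energy+iRMS far better).

## Numerical choices and degenerate inputs

Kabsch superposition goes through `scipy`'s proper-rotation alignment
(reflections excluded — protein chirality); an independently implemented
Horn quaternion method serves as a cross-check oracle only. Fewer than 3
points or collinear point sets are errors. Distance queries are exact
(kd-tree, no cutoff approximation). Quality filtering follows strict
inequalities: a side fails with > 700 residues, or when the fraction of
residues with confidence strictly above 90 (pLDDT, B-factor column) is
below 0.70; both cutoffs configurable. PDB reading keeps the
highest-occupancy altloc (ties → first), drops hydrogens and HETATM.
Metric TSVs are written with fixed 6-decimal formatting and a
`# reference_id=` header line, so reruns are byte-identical.

## Known limitations

Single-binding-site assumption (one reference pose); two-chain partitions
are exercised throughout (multi-chain sides are supported by the data
model but not benchmarked); the recurrent classifier is deliberately
simple and sized for hundreds of decoys, not a tuned architecture; the
synthetic generator's realism limits are listed above.
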