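# Methods

## The problem

Lead optimization asks for the strongest-binding members of a chemical
library that is far too large to evaluate compound by compound with an
accurate but expensive oracle — an alchemical free-energy calculation, or
an experimental assay. `alchemspace` implements an active-learning (AL)
answer: evaluate a small batch, train a regression model on everything
evaluated so far, let a selection strategy use the model's predictions and
uncertainties to pick the next batch, and repeat. After a handful of
iterations most of the library's top binders have been found while only a
small fraction of it was ever evaluated.

## The cycle

Iteration 0 draws a diversity-weighted random batch: ligands are sampled
with probability inversely proportional to the number of library members
sharing their unit-square bin in a 2-D t-SNE embedding of cheap 2-D
descriptors (perplexity 30, seeded; the embedding is cached in the
checkpoint directory because stochastic-neighbor embeddings vary between
runs). Every later iteration trains on the accumulated
(ligand, ΔG) records, predicts the whole library, and selects the next
batch of `batch_size` ligands (default 100) from the unevaluated pool.
After each batch the state — evaluated records, batches, predictions,
metrics — is checkpointed as JSON; a run resumes deterministically because
every per-iteration seed (oracle noise, fold splits, network
initialization, random selection) is derived from the run seed and the
iteration index.

The default budget is 6 iterations after initialization. An optional
plateau rule can halt earlier when the best ΔG found stops improving for a
configured number of consecutive iterations, reflecting the observation
that late iterations mostly backfill weaker binders once the strong pool
is exhausted.

## Oracles

* **Lookup** (retrospective mode): measured affinities are read from a
  table; missing ligands are a hard error.
* **Synthetic emulator**: each ligand receives `n_replicates` (default 5)
  i.i.d. Gaussian perturbations of its true ΔG with standard deviation
  `sigma` (default 1.1 kcal/mol, the typical discrepancy between
  nonequilibrium alchemical calculations and experiment); the replicate
  mean and standard error are reported. The noise is i.i.d. on ΔG — no
  ligand-size dependence — because only an aggregate error magnitude is
  available to calibrate against; an optional per-cluster systematic bias
  is exposed for robustness probes and defaults to 0.
* **Manifest adapter**: writes per-iteration CSV manifests for an external
  engine that computes relative free energies against a reference ligand,
  reads back (ligand, ΔΔG, stderr) rows, converts to absolute ΔG via
  ΔG = ΔG_ref + ΔΔG with errors propagated in quadrature, and reports
  ligands still pending so a run can resume when the engine finishes.

## Regression model

The model is an ensemble of small multilayer perceptrons (ReLU hidden
layers, linear scalar output). Each member is trained on a k-fold split of
the training records (default k = 5), leaving one fold out for validation;
`n_repeats` independent re-splits multiply the ensemble (5 × 5 = 25
members when repeats are raised to 5, configurable per iteration). The
ensemble prediction is the arithmetic member mean; the uncertainty is the
standard error of the member values by default, switchable to the standard
deviation — both views appear in practice and the selection strategies
consume whichever is configured.

Training follows a fixed protocol: L1 loss with per-example
inverse-frequency weights, plain SGD with momentum 0.9, mini-batches of up
to 500 examples, and the exponentially decaying learning rate
lr(epoch) = 0.005 · 0.1^(epoch/10000). Targets are affinely mapped by
t = (ΔG − bias)/scale before fitting (defaults: bias −10 kcal/mol,
scale 3) and predictions are always reported back in kcal/mol. Early
stopping watches the held-fold L1 loss with a patience of 10% of the epoch
budget and restores the best checkpoint.

The inverse-frequency weights counter the over-representation of medium
affinities in AL training sets: a Gaussian KDE of the training ΔG values
is evaluated at each target, weights are proportional to the reciprocal
density and renormalized to mean 1. The kernel bandwidth is an absolute
width in kcal/mol; the default is Scott's rule on the training targets.
Feature standardization (zero mean, unit variance per column) and the
weights are always fitted on training records only — never on the library
— so no information leaks from unevaluated ligands. Columns whose standard
deviation sits at rounding-noise level are treated as constant: centered,
left unscaled.

Numerical choices: weights use He initialization except the output layer,
which starts at 10% scale so the initial function is nearly flat — the
optimizer grows complexity instead of having to iron out large random
initial structure, which the sign-based L1 gradient does poorly.
Single-threaded training with a fixed seed is bit-reproducible; every
member gets a distinct seed spawned from the ensemble seed.

Feature selection uses Integrated Gradients: attribution is the path
integral of the input gradient from an all-zeros baseline (the mean ligand
in standardized feature space) to the input, approximated with a 256-step
Riemann sum; a feature's importance is the mean absolute attribution over
members and a probe set, and features below the threshold (default 0.02)
are dropped. For a linear model the attribution reduces exactly to
weight × (input − baseline), which the tests exploit as a closed form.

## Selection strategies

All strategies return batches disjoint from everything already evaluated
and break ties lexicographically by ligand id, making them deterministic
given the prediction table.

* **random** — uniform over the unevaluated pool.
* **greedy** — most negative predicted ΔG.
* **uncertain** — largest prediction uncertainty.
* **mixed** — the most uncertain among the top `pool_factor × batch_size`
  predicted binders (default ratio 3:1). At 1:1 the pool *is* the greedy
  batch; when the pool covers all candidates the result is the uncertainty
  batch. These identities hold exactly and are asserted for arbitrary
  prediction tables. Because each strategy orders its output by its own
  ranking criterion, the identities are identities of batch membership;
  the oracle consumes a batch as a set.
* **narrowing** — for the first `switch_iteration` rounds (default 3), one
  model is trained per available ligand representation, the `n_models`
  (default 5) with the lowest cross-validation RMSE are kept, and each
  nominates its `per_model_top` (default 20) best predicted binders.
  Duplicate nominations are resolved by round-robin in cv-RMSE order, each
  model contributing its next-best unclaimed ligand until the batch is
  full — the tie-break rule is this package's own choice, since "use the
  next best ligand from one of the representations" admits several
  readings. After the switch the policy is plain greedy on the best
  representation.
* **random2greedy** — random for the first rounds, then greedy; a cheap
  stand-in for narrowing when computing many representations is
  impractical.

## Metrics

Per iteration, against ground truth where available: RMSE and Kendall τ of
the library predictions, the fraction of the true top-N binders already
evaluated (N = 50 by default), and the true-positive rate at a ΔG
threshold — among ligands truly at or below the threshold, the fraction
also predicted at or below it. The shipped default threshold of
−13.29 kcal/mol matches the strongest experimentally measured binder of a
PDE2 inhibitor validation series and suits PDE2-style runs;
synthetic-landscape runs use the landscape's own strong-binder threshold.

## Fragment library builder

A congeneric series sharing a core is decomposed by removing the core
match from each ligand and cutting the remainder at BRICS bonds, keeping
track of which atom bonded to the core. Fragments that retain a
core-facing attachment are **linkers**; the rest are **termini** (they
bond to linkers). Fragments are deduplicated by canonical SMILES, keeping
the first origin ligand. Enumeration reattaches each linker to the core at
its recorded anchor atom and decorates every subset of the linker's open
sites with up to `max_termini` termini (repetition allowed, all site
subsets enumerated — the source protocol does not state how sites are
chosen when fewer termini than sites are placed, so all subsets is this
package's reading). Products are canonicalized and deduplicated, which
also collapses symmetric site permutations; valence violations are skipped
and counted. All attachments are single bonds, which covers the
R-group-on-scaffold series this targets. A terminus with several open
sites attaches through its first and has the rest hydrogen-capped.

## Featurization

The `2D_3D` block is defined by an explicit, versioned descriptor
catalogue (constitutional, topological, electrotopological and
surface-area descriptors; MACCS keys; Morgan fingerprints folded to 1024
bits; BCUT2D), not by reflection over the toolkit, so the representation
is stable across toolkit versions. Shape descriptors are added when every
ligand carries 3-D coordinates. Columns that are non-finite for any ligand
are dropped and logged. R-group-only blocks run the same pipeline on the
annotated substructures.

The `atom_hot` encoding counts atoms of each element per cubic voxel
(default 2 Å edge) and flattens the element × voxel tensor. Binning uses
half-open intervals [origin + i·edge, origin + (i+1)·edge) — an atom
exactly on a face belongs to the higher-index cell — chosen for
determinism. Atoms outside the grid go to a per-element overflow bin and
elements missing from the grid's channel list pool into an "other"
channel, so per-element counts are conserved, never silently dropped. A
surface variant restricts voxel columns to a user-supplied boolean mask;
computing a van-der-Waals pocket surface requires a protein structure and
is out of scope. Protein–ligand interaction blocks (PLEC fingerprints,
force-field interaction energies) likewise require a protein structure and
an MD stack; they are ingested as precomputed per-ligand CSV matrices and
aligned to library order.

## Synthetic landscapes

The generator emulates the statistical shape of a real lead-optimization
series: 2,000 ligands in 8 isotropic Gaussian clusters in a 12-dimensional
latent space, ΔG a smooth per-cluster function (base level plus a linear
term in the offset from the cluster center, plus mild sinusoidal
ruggedness unless disabled), free energies spanning −17 to −6 kcal/mol,
and exactly ⌈2.5%·n⌉ = 50 strong binders confined to 3 designated strong
clusters. Strong-cluster base levels sit around −14 kcal/mol and weak ones
around −9.5, with within-cluster spread near 0.8 kcal/mol, so the strong
threshold lands well clear of the weak clusters; the generator raises an
error if the designated strong set ever leaks outside the strong clusters.
The latent features are consumed directly as a feature block, so the
AL/model/selection logic is tested independently of the chemistry toolkit;
a packaged 20-molecule congeneric pyridine series with deterministic 3-D
embeddings covers the chemistry-dependent paths.

What the landscape does **not** emulate: discrete chemical structure,
activity cliffs, assay-specific error structure, or the exact
structure–activity relationships of any real target. Passing the
landscape experiments shows the machinery ranks, selects and converges as
designed on a smooth clustered ground truth — not that any particular real
library would yield the same recovery rates.

Alternative representations for narrowing experiments are built as random
orthogonal rotations of the latent block with view-specific feature noise
(scales 0.1–0.5), so the cross-validation ranking the strategy relies on
has genuine signal.

## Reference experiment and problem sizes

The strategy-comparison experiment runs greedy, narrowing, uncertain and
random on the default landscape with batches of 100 for 6 iterations —
700 ligands evaluated, 35% of the library — over 5 paired seeds (shared
landscape, embedding, initial batch and oracle noise per seed), with the
synthetic oracle at σ = 1.1 kcal/mol and 5 replicates. Experiment runs use
a scaled training protocol (400 epochs, hidden layers 32 and 16) as the
package's desk-scale default; the full-protocol defaults (2,000 epochs,
hidden layers 64 and 32) are used in the learnability tests. Under these
conditions greedy and narrowing recover nearly all of the top-50, random
sits near the 35% evaluation fraction, and uncertainty selection yields
the lowest whole-library RMSE while finding fewer top binders — the
description-versus-optimization trade-off the strategies are designed
around.

## Known limitations

* The MLP is a NumPy implementation; it is single-threaded and sized for
  10²–10⁴ training ligands with 10¹–10³ features, not for deep
  architectures or voxel tensors over large grids.
* Binding-pose generation, PLEC/force-field feature computation, and the
  alchemical simulation protocol itself are out of scope; they enter only
  through ingested matrices and the oracle interfaces.
* Enumeration forms single bonds only and does not score synthetic
  accessibility or enumerate tautomers/protomers (ligands are treated as a
  single neutral tautomer).
* The per-iteration hyper-parameter schedules of the original protocol
  (manual target scale/bias per iteration, architecture per iteration) are
  exposed through configuration but the shipped defaults are this
  package's own.
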