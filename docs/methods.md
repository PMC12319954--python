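# Methods

## Model

`parcelfuse` learns a probabilistic brain parcellation jointly from several
functional-imaging sessions or datasets.  The generative model has two
levels:

**Arrangement model (group level).**  Each of P brain locations carries a
latent one-hot assignment u_i to one of K parcels.  Locations are treated as
independent; the group prior is parameterized by unnormalized
log-probabilities η (K × P), so p(u_i = k) = softmax(η_i)_k.  The softmax of
η *is* the probabilistic group atlas.  Spatially coupled priors (Potts /
deep-Boltzmann arrangements) are out of scope.

**Emission models (session level).**  Given the assignment, a location's
unit-normalized functional profile y_i (N conditions) follows a von
Mises–Fisher (vMF) distribution with parcel mean direction v_k (‖v_k‖ = 1)
and concentration κ: log-density log c_N(κ) + κ v_kᵀ y_i.  Directional
modeling deliberately discards profile amplitude, which varies between
voxels and scanners without carrying parcellation information.  Three
sharing schemes for κ are supported:

* **Type 1** — sessions of the same subjects are concatenated along the
  condition axis (profiles re-normalized) and fitted as one emission model
  with a single κ;
* **Type 2** — one emission model and one κ per session;
* **Type 3** — one κ per session *and* parcel.

κ is the weight a session's evidence receives in the posterior, so Types
2/3 implement adaptive signal-to-noise weighting across sessions (Type 3:
per region).

**Inference.**  EM with message passing.  Per iteration: each emission
model computes data log-likelihoods ℓ (K × P) per subject; log-likelihoods
are summed across a subject's sessions; the arrangement E-step forms the
posterior ⟨u⟩ = softmax(ℓ + η) per location; the expected complete
log-likelihood ℒ = ℒ_A + Σ_n ℒ_E,n is tracked; the arrangement M-step is
closed-form (η ← log Σ_s ⟨u⟩, so softmax(η) is the mean posterior); the
emission M-steps are the standard weighted vMF maximum-likelihood updates
(v_k ∝ posterior-weighted data mean; κ solves A_N(κ) = r̄ by Newton
iteration from the Banerjee starting point κ₀ = r̄(N − r̄²)/(1 − r̄²), with
r̄ the weighted mean resultant length, pooled over parcels for Types 1/2
and per-parcel for Type 3).

## Numerical choices

* Bessel terms use exponentially scaled functions (`scipy.special.ive`);
  log I_ν falls back to the small-argument series term where the scaled
  value underflows.  At κ = 0 the normalizer is the exact uniform density
  on the sphere.
* κ estimates are clamped to [1e-3, 1e5]; a degenerate resultant length
  r̄ = 1 maps to the upper clamp.  Realistic fMRI regimes sit far inside
  this range (initialization draws κ from U(10, 150)).
* All posterior computations are log-space softmaxes with max-subtraction;
  probability-simplex checks use a 1e-10 tolerance.
* A parcel receiving zero posterior mass keeps its previous emission
  parameters (with a warning); zero summed mass in the arrangement M-step
  is floored at 1e-10 before the log so η stays finite.
* All-zero location profiles are flagged missing rather than normalized;
  their emission log-likelihood is 0 for every parcel, so the posterior
  there falls back to the group map.
* Argmax ties in the winner-take-all map resolve to the lowest parcel
  index, keeping hard maps deterministic.

## Optimization protocol

The first EM iteration is a *down pass*: emission log-likelihoods are set
to zero so every randomly initialized emission model is first fitted to the
same arrangement draw, aligning parcel labels across sessions.  Because the
tracked objective ℒ omits the posterior-entropy term of the ELBO, it rises
strictly through every M-step but can in principle dip at an E-step; with
the stopping rule ℒ(t) − ℒ(t−1) < Δ any dip ends the run, so returned
traces are non-decreasing in their interior.  The convergence comparison
starts after the pretraining pass, whose ℒ lacks emission terms and is not
commensurable with later iterations.

Defaults follow the full protocol: Δ = 0.01, at most 200 iterations, 50
random starts warmed up for 30 steps with the best continued to
convergence, the whole procedure repeated ≥ 50 times until the top solution
(|ℒ₁ − ℒ₂| < 10Δ) recurs 10 times.  `FitConfig.desk()` is the
reduced-restart profile used by the tests and the bundled simulation
scripts: 10 starts × 10 warmup steps, one repeat.  Restart RNG streams are
spawned from the master seed, so every run is reproducible.

## Individual parcellations

For a new subject, three estimates are available: the group map
softmax(η); the data-only map softmax(ℓ); and the integrated map
softmax(ℓ + η), a product of experts that tends to the group map as the
data weaken (κ → 0, or missing locations) and to the data-only map as data
accumulate.  `fit_new_emission` adapts an emission model to new data with η
frozen (Type 2 by default; Type 3 by flag), reusing the main convergence
tolerance.

## Synthetic data

The generator emulates functional-imaging studies on a rectangular grid
with 4-neighbor connectivity (default 50 × 50, K = 20, 10 subjects).
Ground-truth maps come from a Potts model: a group prototype is seeded by a
Voronoi partition of K random centers (guaranteeing K contiguous regions)
and roughened by 30 checkerboard Gibbs sweeps at coupling J; each subject's
map is then Gibbs-sampled (50 sweeps from a random start) under the same
coupling plus an external field of strength γ toward the prototype, so
individual maps vary around a shared group organization.  Defaults J = 2.5
and γ = 0.75 were fixed once: J = 2.5 sits above the ordering threshold of
the 20-state Potts model (log(1 + √20) ≈ 1.70), producing smooth maps
(≈ 0.9 neighbor-pair agreement) without the domain coarsening that
eliminates labels at stronger coupling, and γ = 0.75 yields ≈ 0.87
agreement between a subject's map and the prototype — substantial but
incomplete individual overlap with the group.

Session data per location are y_i = λ_k v_k + ε with ε ~ N(0, σ²_k I),
then normalized to unit length.  Signal strength λ_k and noise variance
σ²_k are per-region dials.  In the high-SNR regime (λ² ≫ Nσ²) the
normalized data are vMF-distributed with κ = λ²/σ²; at lower SNR the data
follow a projected-normal law whose fitted concentration is larger than
λ²/σ² but still increases monotonically with it, so the identity is used
as a qualitative, not quantitative, anchor outside the high-SNR regime.

Two presets mirror the simulation studies: `equal_snr` (session 1: N = 40
conditions, σ² = 0.5; session 2: N = 20, σ² = 0.8; λ = 1.1 everywhere;
test set N = 120, σ² = 0.5 — the test noise level is not dictated by the
study design and was fixed at the session-1 level) and `region_split_snr`
(two symmetric N = 40, σ² = 0.5 sessions; regions randomly halved with
λ = 1.1 / 0.2 swapped between sessions — the split levels are package
choices; equal-strength test set).

What the generator does *not* emulate: hemodynamics, temporal and spatial
noise autocorrelation, inter-subject misregistration, and amplitude
structure beyond a scalar λ per region.  Passing simulation tests therefore
demonstrates correctness of the inference machinery and the qualitative
fusion behavior, not performance on real fMRI.

## Evaluation

**DCBC.**  The distance-controlled boundary coefficient bins location
pairs by Euclidean distance (grid units; default bin width 1, maximum 35)
and compares the mean Pearson correlation of within-parcel pairs with
between-parcel pairs *within each bin*, removing the smoothness bias that
makes plain homogeneity metrics favor fine parcellations.  Bins missing
either pair type are excluded; the summary is the inverse-variance weighted
mean of per-bin differences with weights (1/n_within + 1/n_between)⁻¹, the
reciprocal sampling-variance scale of a difference of two means.
Correlations are computed on mean-centered profiles; zero-variance
locations are excluded from pairs.

**Protocol for model comparison** (`parcelfuse.experiments`): per
simulation repetition, the group DCBC scores the winner-take-all group map
on each subject's held-out test data.  Individual parcellations are
evaluated by splitting the test session's conditions in half, fitting a new
emission model on the first half with η frozen, integrating with the group
map in a single E-step, and scoring the resulting MAP maps on the second
half.  Identical individual data feed every compared model, so the
individual DCBC isolates the quality of the group probability map — the
quantity the fusion models differ in.

**Alignment and reconstruction.**  Parcel indices are arbitrary; maps are
aligned by Hungarian assignment on the K × K confusion matrix.  The
reconstruction error of a posterior against a known truth is 1 minus the
mean aligned posterior probability of the true label (0 for a correct
one-hot posterior, 1 − 1/K for a uniform one).

## Problem sizes in the bundled runs

`scripts/acceptance.py` repeats the equal-SNR study 30 times with the
reduced-restart profile; the test suite uses smaller repetition counts per
study (8–30) and a 30 × 30 grid for the localizer-volume experiment.
These sizes keep paired Monte-Carlo error near 1e-3 DCBC units or below
while keeping full runs desk-scale.

The localizer-volume experiment models scan time as repeated runs of a
fixed task set: averaging R runs divides the per-condition noise variance
by R.  (Adding *conditions* instead would not add information here,
because the region mean directions are unit vectors — signal energy is
fixed while noise energy grows with N.)  The baseline run is deliberately
weak (λ = 1.1, σ² = 1.25 per run) and the group atlas is trained from a
strong session (λ = 1.5, σ² = 0.3) so that integration reflects the value
of the group prior rather than its estimation error — the regime in which
group atlases are actually deployed.

## Known limitations

* The ℒ objective can stall against the 200-iteration cap before meeting
  Δ = 0.01 on large instances; κ keeps sharpening slowly without changing
  the MAP maps materially.
* Fusing near-duplicate sessions sharpens posteriors early, which can
  steer EM into different (occasionally worse) local optima than the
  single-session fit at equal restart budgets; more restarts recover the
  invariance.
* DCBC values depend on the test data's per-condition SNR, so absolute
  values are comparable only within a study design; model comparisons are
  therefore always paired within repetitions.
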