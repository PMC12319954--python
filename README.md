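# parcelfuse

Hierarchical Bayesian fusion of probabilistic functional brain
parcellations across heterogeneous imaging datasets.

## The problem

Functional brain parcellations are usually learned from a single dataset,
yet no single experiment samples every functional state, and datasets
differ widely in signal-to-noise.  `parcelfuse` learns one probabilistic
group atlas from many datasets or sessions at once — even when they cover
different subjects and task sets — and can then tailor that atlas to a new
individual from a short localizer scan.  It is aimed at researchers
building functional atlases (cerebellum, cortex, or any location set with
coordinates) and at methodologists studying data fusion for clustering
models.

## The model

Each brain location i of subject s carries a latent parcel assignment
u_i^s ∈ {1..K}.  A shared **arrangement model** supplies the group prior
p(u_i = k) = softmax(η_i)_k — the probabilistic atlas.  Each session n
contributes an **emission model**: given the assignment, the
unit-normalized activity profile y_i (N conditions) is von Mises–Fisher,

    p(y_i | u_i(k) = 1) = c_N(κ) · exp(κ v_kᵀ y_i),

so the concentration κ weighs each session's evidence.  Type 1 models
concatenate sessions (one κ); Type 2 estimate one κ per session; Type 3
one κ per session and parcel.  EM alternates message passing — summed data
log-likelihoods ℓ go up, group log-probabilities η come down, posteriors
are softmax(ℓ + η) — with closed-form M-steps.  Individual parcellations
for new subjects integrate a fresh emission fit (η frozen) with the atlas.
Parcellations are evaluated with the distance-controlled boundary
coefficient (DCBC): the inverse-variance-weighted mean difference between
within- and between-parcel correlations of location pairs at matched
spatial distances.

A synthetic-data module generates ground-truth individual maps from a
Potts model around a group prototype and session data y = λ_k v_k + ε with
region-wise signal λ and noise σ², reproducing the framework's simulation
studies without any imaging download.  See `docs/methods.md` for modeling
details and design choices.

## Worked example

```bash
parcelfuse simulate --preset equal_snr --seed 0 --out study/
parcelfuse fit --data study/train.h5 --k 20 --model-type type2 \
    --seed 0 --out study/model.h5
parcelfuse evaluate --labels study/model.group_labels.tsv \
    --data study/test.h5 --grid 50 50 --out study/eval
```

The `simulate` call writes a two-session synthetic study (50×50 grid,
K = 20, 10 subjects; session 1: 40 conditions at noise variance 0.5,
session 2: 20 conditions at 0.8).  `fit` prints the fitted model's final
expected complete log-likelihood, e.g.

```
fitted type2 model (K=20), final L=508999.555
```

and stores the atlas (η), the per-session vMF parameters, and the
per-subject posteriors.  The Type 2 fit above estimates a larger
concentration for the cleaner session (κ₁ = 11.45 vs κ₂ = 6.34), which is
the adaptive weighting the fusion relies on.  `evaluate` prints the mean
test DCBC of a hard parcellation — `DCBC = 0.0128 (n=10)` for the group
map fitted above; positive values
mean the map's boundaries separate functionally homogeneous regions better
than distance alone predicts.

The same pipeline is scriptable from Python:

```python
import numpy as np
from parcelfuse import build_study_scenarios, generate_dataset, \
    multi_start_fit, FitConfig

ds = generate_dataset(build_study_scenarios(seed=0)["equal_snr"])
model, posteriors, trace = multi_start_fit(
    ds.train, K=20, model_type="type2",
    config=FitConfig.desk(), rng=np.random.default_rng(0))
```

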