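"""Individual parcellation inference for new subjects.

A trained fusion model carries a probabilistic group atlas (eta).  For a
new subject three parcellations are available:

* ``group`` — softmax(eta): the group map, ignoring the subject's data;
* ``data_only`` — softmax(l): the subject's data likelihood alone;
* ``integrated`` — softmax(l + eta): the Bayesian posterior combining both.

The integrated estimate behaves like a product of experts: with little or
noisy data (small kappa) it falls back to the group map, with abundant data
it approaches the data-only solution, and at missing locations (l = 0) it
reduces exactly to the group map.
"""

from __future__ import annotations

import numpy as np

from .arrangement import arrangement_estep, group_prob
from .emission import DataBundle, EmissionParams, emission_loglik
from .fusion import FitConfig, FusionModel, fit_em

__all__ = [
    "fit_new_emission",
    "infer_individual",
    "hard_parcellation",
    "individual_logliks",
]

MODES = ("group", "data_only", "integrated")


def fit_new_emission(
    model: FusionModel,
    new_data: DataBundle,
    config: FitConfig | None = None,
    model_type: str = "type2",
    rng: np.random.Generator | None = None,
):
    """Fit emission model(s) to a new dataset with the group atlas frozen.

    Runs EM in which only the new emission parameters are updated; the
    arrangement parameters eta stay fixed and keep steering the posteriors.
    Returns a single :class:`EmissionParams` when ``new_data`` holds one
    session, else a list (one per session).
    """
    config = config or FitConfig()
    if new_data.P != model.P:
        raise ValueError(
            f"new data has {new_data.P} locations, model expects {model.P}"
        )
    sub_model, _, _ = fit_em(
        new_data,
        model.K,
        model_type=model_type,
        config=config,
        rng=rng,
        init=_with_fresh_emissions(model, new_data, model_type, rng),
        pretrain=True,  # align the fresh emission parcels to the frozen atlas
        freeze_arrangement=True,
    )
    ems = sub_model.emissions
    return ems[0] if len(ems) == 1 else ems


def _with_fresh_emissions(model, new_data, model_type, rng):
    """Frozen-eta starting point: model's eta, random new emission params."""
    from .fusion import initialize

    data = new_data.normalize()
    if model_type == "type1" and len(data.sessions) > 1:
        data = data.concatenated()
    dims = [(s.session_id, s.subject_ids, s.n_conditions) for s in data.sessions]
    fresh = initialize(model.K, model.P, dims, model_type, rng)
    fresh.arrangement = model.arrangement
    return fresh


def individual_logliks(
    emission: EmissionParams, new_data: DataBundle, session_index: int = 0
) -> np.ndarray:
    """Per-subject data log-likelihoods (S, K, P) for one fitted session."""
    sess = new_data.normalize().sessions[session_index]
    return emission_loglik(emission, sess.Y, missing_mask=sess.missing_mask(),
                           check_norm=False)


def infer_individual(
    model: FusionModel, subject_loglik: np.ndarray | None, mode: str = "integrated"
) -> np.ndarray:
    """Individual probabilistic parcellation under one of three modes.

    ``subject_loglik`` is (K, P) (or (S, K, P) for a batch) and is ignored
    for ``mode="group"``.  Missing locations (all-zero l) under
    ``integrated`` reduce to the group map.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if mode == "group":
        return group_prob(model.arrangement)
    ll = np.asarray(subject_loglik, dtype=float)
    if ll.shape[-2:] != (model.K, model.P):
        raise ValueError("subject_loglik must be (..., K, P)")
    if mode == "data_only":
        from scipy.special import softmax

        return softmax(ll, axis=-2)
    return arrangement_estep(model.arrangement, ll)


def hard_parcellation(posterior: np.ndarray) -> np.ndarray:
    """Winner-take-all labels: argmax parcel per location, shape (..., P).

    Ties resolve to the lowest parcel index (np.argmax convention), making
    the map deterministic.
    """
    posterior = np.asarray(posterior, dtype=float)
    if posterior.ndim < 2:
        raise ValueError("posterior must be (..., K, P)")
    return np.argmax(posterior, axis=-2)
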