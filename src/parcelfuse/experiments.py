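"""Repeated-simulation experiments comparing fusion model variants.

These drivers generate a synthetic study, fit a set of models (single
sessions and/or fusions of different emission types), and score every model
by group DCBC, individual DCBC, and reconstruction error against the known
ground truth.  Repeating this over many independently generated datasets
yields paired model comparisons free of generation noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arrangement import group_prob
from .emission import DataBundle, Session
from .evaluation import DCBCSpec, dcbc, pair_correlations, reconstruction_error
from .fusion import FitConfig, multi_start_fit
from .individual import (
    fit_new_emission,
    hard_parcellation,
    individual_logliks,
    infer_individual,
)
from .synthetic import (
    SimulatedDataset,
    SyntheticScenario,
    build_study_scenarios,
    generate_dataset,
    grid_coordinates,
)

__all__ = [
    "ModelScores",
    "score_model",
    "run_repetition",
    "run_experiment",
    "paired_deltas",
    "summarize",
]

#: model labels -> (which sessions to use, emission model type)
MODEL_RECIPES = {
    "session1": ((0,), "type2"),
    "session2": ((1,), "type2"),
    "type1": (None, "type1"),
    "type2": (None, "type2"),
    "type3": (None, "type3"),
}


@dataclass
class ModelScores:
    """Per-repetition scores of one fitted model."""

    group_dcbc: float
    indiv_dcbc: float
    recon_error: float
    kappas: np.ndarray  # per-session concentration(s) of the fitted model
    parcel_shares: np.ndarray  # fraction of locations per parcel, group map


def _subset_bundle(data: DataBundle, sessions) -> DataBundle:
    if sessions is None:
        return data
    return DataBundle([data.sessions[i] for i in sessions],
                      unit_normalized=data.unit_normalized)


def split_test_session(ds: SimulatedDataset) -> tuple[DataBundle, np.ndarray]:
    """Split the test session's conditions in half.

    The first half becomes the individual-training bundle (profiles
    re-normalized), the second half the held-out test data used for all
    DCBC computations.  Returns ``(individual_bundle, test_half)`` with
    ``test_half`` of shape (S, N/2, P).
    """
    sess = ds.test.sessions[0]
    n = sess.n_conditions // 2
    indiv = DataBundle(
        [Session(sess.session_id + "-indiv", sess.subject_ids, sess.Y[:, :n])]
    ).normalize()
    return indiv, sess.Y[:, n:]


def score_model(
    model,
    ds: SimulatedDataset,
    indiv_bundle: DataBundle,
    test_pc,
    config: FitConfig,
    rng: np.random.Generator,
) -> ModelScores:
    """Evaluate one fitted model's group map and individual parcellations.

    Group DCBC scores the winner-take-all group map on every subject's
    held-out test data.  Individual parcellations follow the evaluation
    protocol for probabilistic atlases: a new emission model is fitted to
    the individual-training data with the group atlas frozen, a single
    E-step integrates the individual data likelihood with the group
    probabilities, and the resulting MAP maps are scored on the held-out
    test half.  Because all compared models see identical individual data,
    individual DCBC isolates the quality of the group probability map.
    """
    group_labels = hard_parcellation(group_prob(model.arrangement))
    em = fit_new_emission(model, indiv_bundle, config, "type2", rng)
    ll = individual_logliks(em, indiv_bundle)
    posteriors = infer_individual(model, ll, "integrated")
    indiv_labels = hard_parcellation(posteriors)
    g_vals, i_vals, r_vals = [], [], []
    for s in range(ds.scenario.n_subjects):
        g_vals.append(dcbc(group_labels, test_pc[s]).value)
        i_vals.append(dcbc(indiv_labels[s], test_pc[s]).value)
        r_vals.append(reconstruction_error(posteriors[s], ds.true_maps[s]))
    counts = np.bincount(group_labels, minlength=model.K)
    return ModelScores(
        group_dcbc=float(np.mean(g_vals)),
        indiv_dcbc=float(np.mean(i_vals)),
        recon_error=float(np.mean(r_vals)),
        kappas=np.array([em.kappa_per_parcel() for em in model.emissions]),
        parcel_shares=counts / counts.sum(),
    )


def run_repetition(
    scenario: SyntheticScenario,
    models: tuple[str, ...],
    K_fit: int,
    config: FitConfig,
    rng: np.random.Generator,
    spec: DCBCSpec | None = None,
) -> dict[str, ModelScores]:
    """One simulated dataset, all requested models fitted and scored."""
    ds = generate_dataset(scenario, rng)
    if spec is None:
        spec = DCBCSpec(grid_coordinates(scenario.grid))
    indiv_bundle, test_half = split_test_session(ds)
    test_pc = [
        pair_correlations(test_half[s], spec) for s in range(scenario.n_subjects)
    ]
    out = {}
    for name in models:
        sessions, model_type = MODEL_RECIPES[name]
        bundle = _subset_bundle(ds.train, sessions)
        model, _, _ = multi_start_fit(bundle, K_fit, model_type, config, rng=rng)
        out[name] = score_model(model, ds, indiv_bundle, test_pc, config, rng)
    return out


def run_experiment(
    scenario_name: str = "equal_snr",
    models: tuple[str, ...] = ("session1", "type1", "type2"),
    n_reps: int = 100,
    K_fit: int | None = None,
    config: FitConfig | None = None,
    seed: int | None = None,
    scenario: SyntheticScenario | None = None,
) -> pd.DataFrame:
    """Repeat a simulation study; returns one row per (repetition, model).

    Columns: ``rep, model, group_dcbc, indiv_dcbc, recon_error,
    min_kappa_share`` (share of group-map locations held by the parcel with
    the smallest fitted concentration — the "residual parcel" diagnostic,
    meaningful for type 3 fits).
    """
    if scenario is None:
        scenario = build_study_scenarios()[scenario_name]
    if K_fit is None:
        K_fit = scenario.K
    config = config or FitConfig.desk()
    rng = np.random.default_rng(seed)
    spec = DCBCSpec(grid_coordinates(scenario.grid))
    rows = []
    for rep in range(n_reps):
        scores = run_repetition(scenario, models, K_fit, config, rng, spec)
        for name, sc in scores.items():
            kappas = sc.kappas.min(axis=0)  # per parcel, worst session
            k_min = int(np.argmin(kappas))
            rows.append(
                {
                    "rep": rep,
                    "model": name,
                    "group_dcbc": sc.group_dcbc,
                    "indiv_dcbc": sc.indiv_dcbc,
                    "recon_error": sc.recon_error,
                    "min_kappa": float(kappas[k_min]),
                    "min_kappa_share": float(sc.parcel_shares[k_min]),
                }
            )
    return pd.DataFrame(rows)


def run_data_volume_experiment(
    volumes: tuple[int, ...] = (2, 4, 8, 16),
    n_reps: int = 20,
    scenario: SyntheticScenario | None = None,
    localizer: "SessionSpec | None" = None,
    config: FitConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Individual parcellation quality as a function of localizer volume.

    Trains a group model once per repetition, then derives individual
    parcellations from per-subject localizer data of increasing volume in
    three modes: the group map alone, the data likelihood alone, and their
    Bayesian integration.  All three are scored by DCBC on held-out test
    data.  ``volumes`` counts repeated runs of the same localizer task set:
    averaging R runs leaves the signal untouched and divides the noise
    variance by R, which is how scan time buys information in
    condition-estimate data.  Returns one row per (repetition, volume,
    mode).
    """
    from .synthetic import SessionSpec, generate_session_data

    if scenario is None:
        # strong training session -> a well-estimated group atlas, so the
        # integration reflects the prior's value rather than its errors
        scenario = SyntheticScenario(
            grid=(30, 30), K=10, n_subjects=8,
            sessions=[SessionSpec(40, 1.5, 0.3)],
            test_session=SessionSpec(60, 1.1, 0.5),
        )
    if localizer is None:
        localizer = SessionSpec(20, 1.1, 1.25)  # a single run is weak
    config = config or FitConfig.desk()
    rng = np.random.default_rng(seed)
    spec = DCBCSpec(grid_coordinates(scenario.grid))
    S, K = scenario.n_subjects, scenario.K
    rows = []
    for rep in range(n_reps):
        ds = generate_dataset(scenario, rng)
        model, _, _ = multi_start_fit(ds.train, K, "type2", config, rng=rng)
        test_pc = [
            pair_correlations(ds.test.sessions[0].Y[s], spec) for s in range(S)
        ]
        group_labels = hard_parcellation(group_prob(model.arrangement))
        group_vals = [dcbc(group_labels, test_pc[s]).value for s in range(S)]
        V = rng.standard_normal((localizer.n_conditions, K))
        V /= np.linalg.norm(V, axis=0, keepdims=True)
        lam = np.broadcast_to(np.asarray(localizer.lam), (K,))
        sig0 = np.broadcast_to(np.asarray(localizer.sigma2), (K,))
        for vol in volumes:
            sig = sig0 / vol  # averaging R runs divides the noise variance
            Y = np.stack(
                [
                    generate_session_data(ds.true_maps[s], V, lam, sig, rng)
                    for s in range(S)
                ]
            )
            indiv = DataBundle(
                [Session(f"loc-{vol}", ds.train.sessions[0].subject_ids, Y)],
                unit_normalized=True,
            )
            em = fit_new_emission(model, indiv, config, "type2", rng)
            ll = individual_logliks(em, indiv)
            scores = {"group": np.mean(group_vals)}
            for mode in ("data_only", "integrated"):
                post = infer_individual(model, ll, mode)
                labels = hard_parcellation(post)
                scores[mode] = np.mean(
                    [dcbc(labels[s], test_pc[s]).value for s in range(S)]
                )
            for mode, val in scores.items():
                rows.append({"rep": rep, "volume": vol, "mode": mode,
                             "dcbc": float(val)})
    return pd.DataFrame(rows)


def paired_deltas(
    results: pd.DataFrame, pairs: dict[str, tuple[str, str]]
) -> pd.DataFrame:
    """Per-repetition paired differences between models.

    ``pairs`` maps an output name to ``(model_plus, model_minus)``; the
    delta is ``model_plus - model_minus`` within each repetition.
    """
    wide_g = results.pivot(index="rep", columns="model", values="group_dcbc")
    wide_i = results.pivot(index="rep", columns="model", values="indiv_dcbc")
    rows = []
    for name, (plus, minus) in pairs.items():
        dg = wide_g[plus] - wide_g[minus]
        di = wide_i[plus] - wide_i[minus]
        rows.append(
            {
                "comparison": name,
                "group_delta_mean": dg.mean(),
                "group_delta_sd": dg.std(ddof=1),
                "indiv_delta_mean": di.mean(),
                "indiv_delta_sd": di.std(ddof=1),
                "group_wins": int((dg > 0).sum()),
                "indiv_wins": int((di > 0).sum()),
                "n": len(dg),
            }
        )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of each score per model, across repetitions."""
    g = results.groupby("model")
    out = g.agg(
        group_dcbc_mean=("group_dcbc", "mean"),
        group_dcbc_sem=("group_dcbc", "sem"),
        indiv_dcbc_mean=("indiv_dcbc", "mean"),
        indiv_dcbc_sem=("indiv_dcbc", "sem"),
        recon_error_mean=("recon_error", "mean"),
        n=("rep", "count"),
    )
    return out.reset_index()
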