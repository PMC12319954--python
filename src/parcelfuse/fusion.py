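"""EM driver fusing multiple sessions through a shared arrangement model.

The fitting loop alternates message passing between the emission models and
the arrangement model:

1. emission E-step per session (data log-likelihoods l_ik),
2. summation of log-likelihoods across a subject's sessions,
3. arrangement E-step (posterior = softmax(l + eta) per location),
4. expected complete log-likelihood L = L_A + sum_n L_En,
5. convergence check on the increase of L,
6. closed-form arrangement M-step and vMF emission M-steps.

The first iteration is a "down pass": emission log-likelihoods are skipped
(set to zero) so that all randomly initialized emission models align their
parcel labels to a single arrangement draw.  A multi-start protocol runs
many short warmup fits, continues the best to convergence, and repeats
until the top solution recurs often enough.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .arrangement import (
    ArrangementParams,
    arrangement_estep,
    arrangement_mstep,
    expected_arrangement_loglik,
)
from .emission import (
    MODEL_TYPES,
    DataBundle,
    EmissionParams,
    emission_loglik,
    emission_mstep,
    expected_emission_loglik,
)

__all__ = [
    "FusionModel",
    "FitConfig",
    "initialize",
    "expected_complete_loglik",
    "fit_em",
    "multi_start_fit",
]

#: concentration initialization range ("medium-sized" directional variance)
KAPPA_INIT_RANGE = (10.0, 150.0)


@dataclass
class FusionModel:
    """A fitted (or initialized) fusion model: group atlas + emission models."""

    arrangement: ArrangementParams
    emissions: list[EmissionParams]
    session_ids: list[str]
    subjects: tuple

    def __post_init__(self) -> None:
        if len(self.emissions) != len(self.session_ids):
            raise ValueError("one emission model per session id required")
        K = self.arrangement.K
        for em in self.emissions:
            if em.K != K:
                raise ValueError("all emission models must share K with eta")
            if any(s not in self.subjects for s in em.subject_ids):
                raise ValueError("emission subjects must lie in the registry")
        self.subjects = tuple(self.subjects)

    @property
    def K(self) -> int:
        return self.arrangement.K

    @property
    def P(self) -> int:
        return self.arrangement.P


@dataclass
class FitConfig:
    """Optimization settings for the EM loop and the multi-start protocol.

    Defaults follow the full protocol: up to 200 iterations, convergence
    when L increases by less than 0.01, 50 random initializations warmed up
    for 30 steps each, the whole procedure repeated at least 50 times and
    until the best solution recurs 10 times.  ``desk()`` is a lighter
    profile for interactive use and tests.
    """

    max_iter: int = 200
    delta_tol: float = 0.01
    n_starts: int = 50
    warmup_steps: int = 30
    n_repeats_min: int = 50
    top_solution_count: int = 10
    hard_max_repeats: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.max_iter, self.n_starts, self.warmup_steps,
               self.n_repeats_min, self.top_solution_count,
               self.hard_max_repeats) < 1 or self.delta_tol <= 0:
            raise ValueError("all FitConfig fields must be positive")

    @classmethod
    def full(cls, **kw) -> "FitConfig":
        """The full multi-restart protocol (the class defaults)."""
        return cls(**kw)

    @classmethod
    def desk(cls, **kw) -> "FitConfig":
        """Reduced-restart profile: 10 starts x 10 warmup steps, 1 repeat."""
        kw.setdefault("n_starts", 10)
        kw.setdefault("warmup_steps", 10)
        kw.setdefault("n_repeats_min", 1)
        kw.setdefault("top_solution_count", 1)
        return cls(**kw)


def initialize(
    K: int,
    P: int,
    session_dims: Sequence[tuple[str, tuple, int]],
    model_type: str = "type2",
    rng: np.random.Generator | None = None,
) -> FusionModel:
    """Random starting point: eta ~ N(0,1), unit-normalized Gaussian mean
    directions, and kappa ~ Uniform(10, 150) (per parcel for type 3).

    ``session_dims`` lists ``(session_id, subject_ids, n_conditions)``.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model_type {model_type!r}")
    rng = np.random.default_rng(rng)
    eta = rng.standard_normal((K, P))
    emissions, ids, subjects = [], [], {}
    for session_id, subject_ids, N in session_dims:
        V = rng.standard_normal((N, K))
        V /= np.linalg.norm(V, axis=0, keepdims=True)
        if model_type == "type3":
            kappa = rng.uniform(*KAPPA_INIT_RANGE, size=K)
        else:
            kappa = rng.uniform(*KAPPA_INIT_RANGE)
        emissions.append(EmissionParams(V, kappa, model_type, tuple(subject_ids)))
        ids.append(session_id)
        for s in subject_ids:
            subjects.setdefault(s, None)
    return FusionModel(ArrangementParams(eta), emissions, ids, tuple(subjects))


def expected_complete_loglik(
    model: FusionModel,
    posteriors: np.ndarray,
    session_logliks: Sequence[tuple[np.ndarray, np.ndarray]],
) -> float:
    """L = L_A + sum_n L_En.

    ``posteriors`` is (S, K, P) in registry order; ``session_logliks`` lists
    ``(registry_rows, loglik)`` per session with ``loglik`` shaped
    (len(rows), K, P).
    """
    L = expected_arrangement_loglik(model.arrangement, posteriors)
    for rows, ll in session_logliks:
        L += expected_emission_loglik(posteriors[rows], ll)
    return L


def _prepare(data: DataBundle, model_type: str) -> DataBundle:
    data = data.normalize()
    if model_type == "type1" and len(data.sessions) > 1:
        data = data.concatenated()
    return data


def fit_em(
    data: DataBundle,
    K: int,
    model_type: str = "type2",
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
    init: FusionModel | None = None,
    pretrain: bool = True,
    max_iter: int | None = None,
    freeze_arrangement: bool = False,
):
    """Run the EM loop once from one starting point.

    Returns ``(model, posteriors, trace)`` where ``posteriors`` is (S, K, P)
    in subject-registry order and ``trace`` the per-iteration expected
    complete log-likelihood.  For ``model_type="type1"`` the sessions are
    concatenated along the condition axis (and re-normalized) before
    fitting, yielding a single emission model with one concentration.

    When ``pretrain`` is true the first iteration skips the emission E-step
    (all l set to zero), aligning every emission model to the same
    arrangement draw; the convergence test only compares iterations that
    both include emission terms.
    """
    config = config or FitConfig()
    data = _prepare(data, model_type)
    subjects = data.subjects
    index = {s: i for i, s in enumerate(subjects)}
    rows = [np.array([index[s] for s in sess.subject_ids]) for sess in data.sessions]
    if init is None:
        dims = [(s.session_id, s.subject_ids, s.n_conditions) for s in data.sessions]
        model = initialize(K, data.P, dims, model_type, rng)
    else:
        model = FusionModel(
            ArrangementParams(init.arrangement.eta.copy()),
            list(init.emissions),
            list(init.session_ids),
            init.subjects,
        )
        if model.P != data.P:
            raise ValueError("init model location count does not match data")
    masks = [s.missing_mask() for s in data.sessions]
    tmax = config.max_iter if max_iter is None else max_iter
    first_check = 2 if pretrain else 1
    trace: list[float] = []
    posteriors = None
    S = len(subjects)
    for t in range(tmax + 1):
        if t == 0 and pretrain:
            lls = [
                np.zeros((len(sess.subject_ids), model.K, data.P))
                for sess in data.sessions
            ]
        else:
            lls = [
                emission_loglik(em, sess.Y, missing_mask=mask, check_norm=False)
                for em, sess, mask in zip(model.emissions, data.sessions, masks)
            ]
        combined = np.zeros((S, model.K, data.P))
        for r, ll in zip(rows, lls):
            combined[r] += ll  # rows unique within a session
        posteriors = arrangement_estep(model.arrangement, combined)
        L = expected_complete_loglik(model, posteriors, list(zip(rows, lls)))
        if not np.isfinite(L):
            raise RuntimeError(
                f"expected complete log-likelihood diverged at iteration {t}"
            )
        trace.append(L)
        if t >= first_check and L - trace[-2] < config.delta_tol:
            return model, posteriors, trace
        if not freeze_arrangement:
            model.arrangement = arrangement_mstep(posteriors)
        new_emissions = []
        for em, sess, r, mask in zip(model.emissions, data.sessions, rows, masks):
            new_emissions.append(
                emission_mstep(
                    sess.Y,
                    posteriors[r],
                    model_type=em.model_type,
                    prev=em,
                    subject_ids=sess.subject_ids,
                    missing_mask=mask,
                )
            )
        model.emissions = new_emissions
    return model, posteriors, trace


def multi_start_fit(
    data: DataBundle,
    K: int,
    model_type: str = "type2",
    config: FitConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Multi-restart protocol around :func:`fit_em`.

    Each repeat runs ``n_starts`` random initializations for
    ``warmup_steps`` iterations, continues the best to convergence, and
    records its final L.  Repeats continue until at least ``n_repeats_min``
    have run *and* the best L has recurred ``top_solution_count`` times
    (two solutions match when their L's differ by less than 10 x
    ``delta_tol``), capped at ``hard_max_repeats``.  Returns
    ``(model, posteriors, trace)`` of the overall best solution.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    data = _prepare(data, model_type)
    finals: list[float] = []
    best = None
    for repeat in range(config.hard_max_repeats):
        streams = rng.spawn(config.n_starts)
        warm = [
            fit_em(
                data, K, model_type, config,
                rng=stream, max_iter=config.warmup_steps,
            )
            for stream in streams
        ]
        best_warm = max(warm, key=lambda res: res[2][-1])
        model, post, trace = fit_em(
            data, K, model_type, config, init=best_warm[0], pretrain=False
        )
        finals.append(trace[-1])
        if best is None or trace[-1] > best[2][-1]:
            best = (model, post, trace)
        top = max(finals)
        n_top = sum(1 for L in finals if abs(L - top) < 10 * config.delta_tol)
        if repeat + 1 >= config.n_repeats_min and n_top >= config.top_solution_count:
            break
    return best
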