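"""Session-specific von Mises-Fisher mixture emission models.

Each session (or dataset) of functional profiles gets its own emission
model: a K-component mixture of von Mises-Fisher (vMF) distributions on the
unit (N-1)-sphere, where N is the number of task conditions.  Three variants
control how the concentration parameter kappa is shared:

* Type 1 — one emission model over the concatenated sessions of the same
  subjects, single kappa;
* Type 2 — one emission model per session, one kappa per session;
* Type 3 — one emission model per session, one kappa per session *and*
  parcel, letting sessions contribute region-specific evidence.

kappa acts as the weight a session's evidence receives when the posterior
integrates data with the group prior, so estimating it per session (or per
parcel) implements adaptive signal-to-noise weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, ive

__all__ = [
    "EmissionParams",
    "Session",
    "DataBundle",
    "vmf_log_norm_const",
    "emission_loglik",
    "combine_session_logliks",
    "emission_mstep",
    "estimate_kappa",
    "bessel_ratio",
]

MODEL_TYPES = ("type1", "type2", "type3")

#: clamp range for estimated concentrations; avoids Bessel overflow and
#: degenerate zero concentrations without touching realistic fMRI regimes
KAPPA_MIN = 1e-3
KAPPA_MAX = 1e5

UNIT_NORM_TOL = 1e-8


@dataclass
class EmissionParams:
    """Parameters of one vMF mixture emission model.

    Parameters
    ----------
    V
        Mean directions, shape (N, K); every column has unit Euclidean norm.
    kappa
        Concentration(s): a scalar for model types 1/2, a length-K vector
        for type 3.  All entries nonnegative.
    model_type
        One of ``"type1"``, ``"type2"``, ``"type3"``.
    subject_ids
        The subjects this session covers.
    """

    V: np.ndarray
    kappa: np.ndarray | float
    model_type: str = "type2"
    subject_ids: tuple = ()

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        if self.V.ndim != 2 or self.V.shape[0] < 2:
            raise ValueError("V must be an N x K matrix with N >= 2")
        norms = np.linalg.norm(self.V, axis=0)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("columns of V must have unit norm")
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"unknown model_type {self.model_type!r}")
        kappa = np.asarray(self.kappa, dtype=float)
        if self.model_type == "type3":
            if kappa.shape != (self.K,):
                raise ValueError("type3 requires one kappa per parcel")
        else:
            if kappa.ndim != 0:
                raise ValueError("types 1/2 use a single scalar kappa")
        if np.any(kappa < 0):
            raise ValueError("kappa must be nonnegative")
        self.kappa = kappa
        self.subject_ids = tuple(self.subject_ids)

    @property
    def N(self) -> int:
        return self.V.shape[0]

    @property
    def K(self) -> int:
        return self.V.shape[1]

    def kappa_per_parcel(self) -> np.ndarray:
        """Concentrations broadcast to a length-K vector."""
        return np.broadcast_to(np.atleast_1d(self.kappa), (self.K,)).astype(float)


@dataclass
class Session:
    """One session's observations for the subjects it covers.

    ``Y`` has shape (n_subjects, N conditions, P locations).  A location
    profile that is entirely zero is treated as missing.
    """

    session_id: str
    subject_ids: tuple
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = tuple(self.subject_ids)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 3:
            raise ValueError("Y must be (subjects, conditions, locations)")
        if self.Y.shape[0] != len(self.subject_ids):
            raise ValueError("Y first axis must match subject_ids")

    @property
    def n_conditions(self) -> int:
        return self.Y.shape[1]

    @property
    def P(self) -> int:
        return self.Y.shape[2]

    def missing_mask(self) -> np.ndarray:
        """Boolean (subjects, locations): True where the profile is missing."""
        return np.linalg.norm(self.Y, axis=1) < UNIT_NORM_TOL


@dataclass
class DataBundle:
    """A collection of sessions with a session-to-subjects map.

    The union of the sessions' subject sets defines the subject registry S;
    posteriors and individual parcellations are indexed in registry order.
    """

    sessions: list[Session] = field(default_factory=list)
    unit_normalized: bool = False

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ValueError("DataBundle needs at least one session")
        P = self.sessions[0].P
        if any(s.P != P for s in self.sessions):
            raise ValueError("all sessions must share the location count P")

    @property
    def P(self) -> int:
        return self.sessions[0].P

    @property
    def subjects(self) -> tuple:
        seen: dict = {}
        for s in self.sessions:
            for sid in s.subject_ids:
                seen.setdefault(sid, None)
        return tuple(seen)

    def normalize(self) -> "DataBundle":
        """Return a bundle with every non-missing profile scaled to unit norm."""
        if self.unit_normalized:
            return self
        sessions = []
        for s in self.sessions:
            norms = np.linalg.norm(s.Y, axis=1, keepdims=True)
            Y = np.divide(s.Y, norms, out=np.zeros_like(s.Y), where=norms > UNIT_NORM_TOL)
            sessions.append(Session(s.session_id, s.subject_ids, Y))
        return DataBundle(sessions, unit_normalized=True)

    def concatenated(self) -> "DataBundle":
        """Concatenate all sessions along the condition axis (Type 1 layout).

        All sessions must cover the same subjects in the same order.  The
        concatenated profiles are re-normalized to unit length.
        """
        subj = self.sessions[0].subject_ids
        if any(s.subject_ids != subj for s in self.sessions):
            raise ValueError("type1 concatenation requires identical subject sets")
        Y = np.concatenate([s.Y for s in self.sessions], axis=1)
        sid = "+".join(s.session_id for s in self.sessions)
        return DataBundle([Session(sid, subj, Y)]).normalize()


# ---------------------------------------------------------------------------
# vMF numerics


def _log_bessel_i(order: float, kappa: np.ndarray) -> np.ndarray:
    """log I_order(kappa), stable for large kappa via the scaled Bessel.

    Falls back to the leading small-argument term
    ``order*log(kappa/2) - lgamma(order+1)`` where the scaled Bessel
    underflows (large order with tiny argument).
    """
    kappa = np.asarray(kappa, dtype=float)
    scaled = ive(order, kappa)
    with np.errstate(divide="ignore"):
        out = np.log(scaled) + kappa
    tiny = np.asarray(scaled <= 0)
    if np.any(tiny):
        with np.errstate(divide="ignore"):
            small = order * np.log(kappa / 2.0) - gammaln(order + 1.0)
        out = np.where(tiny, small, out)
    return out


def vmf_log_norm_const(N: int, kappa) -> np.ndarray | float:
    """Log normalizing constant log c_N(kappa) of the vMF density.

    ``c_N(kappa) = kappa^(N/2-1) / ((2 pi)^(N/2) I_(N/2-1)(kappa))``; at
    kappa -> 0 this tends to the inverse surface area of the unit
    (N-1)-sphere (the uniform density).  Vectorized over kappa.
    """
    if N < 2:
        raise ValueError("vMF requires dimension N >= 2")
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be nonnegative")
    nu = N / 2.0 - 1.0
    log_uniform = gammaln(N / 2.0) - np.log(2.0) - (N / 2.0) * np.log(np.pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        general = (
            nu * np.log(kappa)
            - (N / 2.0) * np.log(2.0 * np.pi)
            - _log_bessel_i(nu, kappa)
        )
    out = np.where(kappa == 0, log_uniform, general)
    return float(out) if out.ndim == 0 else out


def bessel_ratio(N: int, kappa) -> np.ndarray | float:
    """Mean resultant length A_N(kappa) = I_(N/2)(kappa) / I_(N/2-1)(kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    num = ive(N / 2.0, kappa)
    den = ive(N / 2.0 - 1.0, kappa)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
    out = np.where(kappa == 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def estimate_kappa(rbar, N: int, tol: float = 1e-10, max_iter: int = 50):
    """Solve A_N(kappa) = rbar for the ML concentration.

    Newton iteration initialized with the Banerjee approximation
    ``kappa0 = rbar (N - rbar^2) / (1 - rbar^2)``; the result is clamped to
    [KAPPA_MIN, KAPPA_MAX].  Degenerate resultant lengths map to the clamp
    ends (rbar <= 0 -> KAPPA_MIN, rbar >= 1 -> KAPPA_MAX).  Vectorized.
    """
    rbar = np.asarray(rbar, dtype=float)
    scalar = rbar.ndim == 0
    rbar = np.atleast_1d(rbar)
    kappa = np.full_like(rbar, KAPPA_MIN)
    hi = rbar >= 1.0 - 1e-12
    kappa[hi] = KAPPA_MAX
    active = (rbar > 0.0) & ~hi
    if np.any(active):
        r = rbar[active]
        k = r * (N - r**2) / np.maximum(1.0 - r**2, 1e-300)
        k = np.clip(k, KAPPA_MIN, KAPPA_MAX)
        for _ in range(max_iter):
            a = np.asarray(bessel_ratio(N, k))
            # A'(kappa) = 1 - A^2 - (N-1)/kappa * A
            da = 1.0 - a**2 - (N - 1.0) / k * a
            step = np.where(np.abs(da) > 1e-300, (a - r) / da, 0.0)
            k_new = np.clip(k - step, KAPPA_MIN, KAPPA_MAX)
            if np.all(np.abs(k_new - k) <= tol * np.maximum(1.0, k)):
                k = k_new
                break
            k = k_new
        kappa[active] = k
    return float(kappa[0]) if scalar else kappa


# ---------------------------------------------------------------------------
# E-step pieces


def emission_loglik(
    params: EmissionParams,
    Y: np.ndarray,
    missing_mask: np.ndarray | None = None,
    check_norm: bool = True,
) -> np.ndarray:
    """Data log-likelihood l_ik = log c_N(kappa_k) + kappa_k v_k^T y_i.

    ``Y`` is (N, P) for one subject or (S, N, P) for a batch; the output is
    (K, P) or (S, K, P) accordingly.  Missing locations (all-zero profiles,
    or flagged in ``missing_mask``) get l = 0 across all parcels so the
    posterior there falls back to the group prior.
    """
    Y = np.asarray(Y, dtype=float)
    single = Y.ndim == 2
    if single:
        Y = Y[None]
    if Y.ndim != 3 or Y.shape[1] != params.N:
        raise ValueError("Y must be (S, N, P) with N matching the emission model")
    if missing_mask is not None and not check_norm:
        # caller already knows which profiles are missing
        missing = np.asarray(missing_mask, dtype=bool)
    else:
        norms = np.linalg.norm(Y, axis=1)
        missing = norms < UNIT_NORM_TOL
        if missing_mask is not None:
            missing = missing | np.asarray(missing_mask, dtype=bool)
        if check_norm and np.any(np.abs(norms[~missing] - 1.0) > 1e-6):
            raise ValueError("Y rows must be unit-normalized (or flagged missing)")
    kappa = params.kappa_per_parcel()
    logc = vmf_log_norm_const(params.N, kappa)
    # (S, K, P) <- (N, K)^T @ (S, N, P), batched BLAS
    ll = np.matmul(params.V.T[None], Y)
    ll *= kappa[None, :, None]
    ll += np.asarray(logc)[None, :, None]
    if missing.any():
        ll[np.broadcast_to(missing[:, None, :], ll.shape)] = 0.0
    return ll[0] if single else ll


def combine_session_logliks(
    logliks: Sequence[tuple[Sequence, np.ndarray]],
    subjects: Sequence | None = None,
) -> tuple[tuple, np.ndarray]:
    """Sum per-session data log-likelihoods into per-subject totals.

    Parameters
    ----------
    logliks
        Sequence of ``(subject_ids, ll)`` pairs, one per session, where
        ``ll`` is (len(subject_ids), K, P).
    subjects
        Subject registry order for the output; defaults to first-appearance
        order over the sessions.  A subject present in no session raises.

    Returns
    -------
    (subjects, combined) where combined is (S, K, P).
    """
    if not logliks:
        raise ValueError("no session log-likelihoods given")
    if subjects is None:
        seen: dict = {}
        for sids, _ in logliks:
            for sid in sids:
                seen.setdefault(sid, None)
        subjects = tuple(seen)
    else:
        subjects = tuple(subjects)
    K, P = np.asarray(logliks[0][1]).shape[-2:]
    combined = np.zeros((len(subjects), K, P))
    covered = np.zeros(len(subjects), dtype=bool)
    index = {sid: i for i, sid in enumerate(subjects)}
    for sids, ll in logliks:
        ll = np.asarray(ll, dtype=float)
        if ll.shape != (len(sids), K, P):
            raise ValueError("log-likelihood shape mismatch")
        for row, sid in enumerate(sids):
            if sid not in index:
                raise ValueError(f"subject {sid!r} absent from registry")
            combined[index[sid]] += ll[row]
            covered[index[sid]] = True
    if not covered.all():
        miss = [subjects[i] for i in np.flatnonzero(~covered)]
        raise ValueError(f"subjects present in no session: {miss}")
    return subjects, combined


# ---------------------------------------------------------------------------
# M-step


def emission_mstep(
    Y: np.ndarray,
    posteriors: np.ndarray,
    model_type: str = "type2",
    prev: EmissionParams | None = None,
    subject_ids: tuple = (),
    missing_mask: np.ndarray | None = None,
) -> EmissionParams:
    """ML update of the vMF mixture parameters from expected assignments.

    ``Y`` is (S, N, P) unit-normalized data, ``posteriors`` (S, K, P)
    column-stochastic expected assignments.  Mean directions are the
    posterior-weighted data means renormalized to unit length; kappa solves
    A_N(kappa) = rbar with rbar the weighted mean resultant length, pooled
    over parcels for types 1/2 and per-parcel for type 3.  A parcel with
    zero total weight keeps its previous direction (and, for type 3, its
    previous kappa).
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model_type {model_type!r}")
    Y = np.asarray(Y, dtype=float)
    U = np.asarray(posteriors, dtype=float)
    if Y.ndim != 3 or U.ndim != 3 or Y.shape[0] != U.shape[0] or Y.shape[2] != U.shape[2]:
        raise ValueError("Y (S,N,P) and posteriors (S,K,P) must align")
    N, K = Y.shape[1], U.shape[1]
    if missing_mask is None:
        missing_mask = np.linalg.norm(Y, axis=1) < UNIT_NORM_TOL  # (S, P)
    missing = np.asarray(missing_mask, dtype=bool)
    # exclude missing locations from the weighted sums
    W = np.where(missing[:, None, :], 0.0, U) if missing.any() else U
    # resultant vectors r_k = sum_{s,i} <u> y  and weights w_k
    R = np.matmul(Y, W.transpose(0, 2, 1)).sum(axis=0)
    w = W.sum(axis=(0, 2))
    rnorm = np.linalg.norm(R, axis=0)
    dead = (w <= 0) | (rnorm <= 0)
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} parcel(s) received zero posterior mass; "
            "keeping previous parameters for them",
            RuntimeWarning,
            stacklevel=2,
        )
    V = np.empty((N, K))
    live = ~dead
    V[:, live] = R[:, live] / rnorm[live]
    if np.any(dead):
        if prev is not None:
            V[:, dead] = prev.V[:, dead]
        else:
            V[:, dead] = 0.0
            V[0, dead] = 1.0
    if model_type == "type3":
        rbar = np.zeros(K)
        rbar[live] = rnorm[live] / w[live]
        kappa = estimate_kappa(np.clip(rbar, 0.0, 1.0), N)
        kappa = np.atleast_1d(kappa)
        if np.any(dead) and prev is not None:
            kappa[dead] = prev.kappa_per_parcel()[dead]
    else:
        total_w = w[live].sum()
        rbar = rnorm[live].sum() / total_w if total_w > 0 else 0.0
        kappa = estimate_kappa(min(max(rbar, 0.0), 1.0), N)
    return EmissionParams(
        V=V, kappa=kappa, model_type=model_type, subject_ids=tuple(subject_ids)
    )


def expected_emission_loglik(posteriors: np.ndarray, logliks: np.ndarray) -> float:
    """Expected emission log-likelihood sum_{s,i,k} <u> * l for one session."""
    return float(np.einsum("skp,skp->", np.asarray(posteriors), np.asarray(logliks)))
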