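"""Independent spatial arrangement model: the probabilistic group atlas.

The arrangement model places a categorical prior over the parcel assignment
of every brain location, independently across locations.  It is parameterized
by unnormalized log-probabilities ``eta`` (K parcels x P locations); the
group probability map is the per-location softmax of ``eta``.  During EM the
arrangement model receives summed data log-likelihoods from the emission
models ("upward message"), returns per-subject posterior assignments, and is
re-estimated from those posteriors in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

__all__ = [
    "ArrangementParams",
    "group_prob",
    "arrangement_estep",
    "arrangement_mstep",
    "expected_arrangement_loglik",
]

#: floor applied to summed posterior mass before taking the log in the
#: M-step, so parcels with zero mass at a location keep a finite eta
ETA_MASS_FLOOR = 1e-10


@dataclass
class ArrangementParams:
    """Group log-probability parameters of the independent arrangement model.

    Parameters
    ----------
    eta
        Array of shape (K, P) holding the unnormalized log-probability of
        each parcel k at each brain location i.  Softmax over the K entries
        of a location gives the group probability map.
    """

    eta: np.ndarray

    def __post_init__(self) -> None:
        self.eta = np.asarray(self.eta, dtype=float)
        if self.eta.ndim != 2:
            raise ValueError("eta must be a K x P matrix")
        if not np.all(np.isfinite(self.eta)):
            raise ValueError("eta contains non-finite entries")

    @property
    def K(self) -> int:
        return self.eta.shape[0]

    @property
    def P(self) -> int:
        return self.eta.shape[1]

    def normalized(self) -> "ArrangementParams":
        """Return a copy with the per-location log-sum subtracted.

        Softmax is invariant to adding a constant per location, so this is a
        pure numerical-hygiene operation.
        """
        lse = np.logaddexp.reduce(self.eta, axis=0, keepdims=True)
        return ArrangementParams(self.eta - lse)


def group_prob(params: ArrangementParams) -> np.ndarray:
    """Group probability map: per-location softmax of eta, shape (K, P)."""
    if not np.all(np.isfinite(params.eta)):
        raise ValueError("eta contains non-finite entries")
    return softmax(params.eta, axis=0)


def arrangement_estep(
    params: ArrangementParams, combined_loglik: np.ndarray
) -> np.ndarray:
    """Posterior parcel assignment given summed data log-likelihoods.

    Computes ``softmax(loglik + eta)`` per location with max-subtraction for
    stability.  ``combined_loglik`` may be (K, P) for a single subject or
    (S, K, P) for a batch of subjects; the output matches its shape.  Zeros
    in ``combined_loglik`` (missing data, or the pretraining down-pass)
    leave the posterior at the group prior for those locations.
    """
    ll = np.asarray(combined_loglik, dtype=float)
    if ll.shape[-2:] != params.eta.shape:
        raise ValueError(
            f"combined_loglik trailing shape {ll.shape[-2:]} does not match "
            f"eta shape {params.eta.shape}"
        )
    return softmax(ll + params.eta, axis=-2)


def _stack_posteriors(posteriors) -> np.ndarray:
    arr = np.asarray(posteriors, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("posteriors must be (K, P) or a list/array (S, K, P)")
    if arr.shape[0] == 0:
        raise ValueError("need at least one posterior")
    return arr


def arrangement_mstep(posteriors) -> ArrangementParams:
    """Closed-form M-step: ``eta_ik = log sum_s <u_i^s(k)>``.

    Because each posterior column sums to one, the per-location softmax of
    the updated eta equals the across-subject mean posterior.  Zero summed
    mass is floored at a small constant before the log so eta stays finite.
    """
    arr = _stack_posteriors(posteriors)
    mass = arr.sum(axis=0)
    return ArrangementParams(np.log(np.maximum(mass, ETA_MASS_FLOOR)))


def expected_arrangement_loglik(params: ArrangementParams, posteriors) -> float:
    """Expected arrangement log-likelihood: sum_s sum_i sum_k <u> * eta."""
    arr = _stack_posteriors(posteriors)
    if arr.shape[-2:] != params.eta.shape:
        raise ValueError("posterior shape does not match eta")
    return float(np.einsum("skp,kp->", arr, params.eta))
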