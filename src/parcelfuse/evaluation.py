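"""Parcellation evaluation: DCBC, parcel alignment, reconstruction error.

The distance-controlled boundary coefficient (DCBC) asks how much more
similar two nearby brain locations are when a parcellation places them in
the same parcel.  Location pairs are binned by spatial distance; within
each bin the mean Pearson correlation of within-parcel pairs is compared
with that of between-parcel pairs at the *same* distance, which removes the
bias of plain homogeneity metrics toward fine parcellations on spatially
smooth data.  The overall DCBC is the inverse-variance weighted mean of the
per-bin differences, with weights derived from the pair counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist

__all__ = [
    "DCBCSpec",
    "DCBCResult",
    "PairCorrelations",
    "pair_correlations",
    "dcbc",
    "align_parcels",
    "reconstruction_error",
]


@dataclass
class DCBCSpec:
    """Binning scheme for DCBC: coordinates plus distance bins.

    Pairs are binned by Euclidean distance between location centers into
    ``(0, bin_width], (bin_width, 2*bin_width], ...`` up to ``max_dist``;
    farther pairs are ignored.  The pair/bin structure is cached on first
    use so repeated evaluations on the same geometry are cheap.
    """

    coordinates: np.ndarray
    bin_width: float = 1.0
    max_dist: float = 35.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be (P, d)")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        n_bins = self.max_dist / self.bin_width
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValueError("max_dist must be a multiple of bin_width")

    @property
    def P(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_bins(self) -> int:
        return int(round(self.max_dist / self.bin_width))

    def pair_bins(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i_idx, j_idx, bin_id) for all location pairs within max_dist."""
        if "pairs" not in self._cache:
            d = pdist(self.coordinates)
            iu, ju = np.triu_indices(self.P, k=1)
            keep = (d > 0) & (d <= self.max_dist)
            bin_id = np.ceil(d[keep] / self.bin_width).astype(np.int64) - 1
            self._cache["pairs"] = (iu[keep], ju[keep], bin_id)
        return self._cache["pairs"]


@dataclass
class DCBCResult:
    value: float
    table: pd.DataFrame  # per-bin counts, correlations, weight

    def __float__(self) -> float:
        return self.value


def _standardize_profiles(test_data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-center and unit-scale each location's profile.

    Returns (Z, valid) where ``Z`` is (N, P) with zero-variance locations
    zeroed and ``valid`` flags locations usable for correlations.
    """
    X = np.asarray(test_data, dtype=float)
    if X.ndim != 2:
        raise ValueError("test_data must be (conditions, locations)")
    Xc = X - X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Xc, axis=0)
    valid = norms > 1e-12
    Z = np.divide(Xc, norms, out=np.zeros_like(Xc), where=valid)
    return Z, valid


@dataclass
class PairCorrelations:
    """Pearson correlations of all binned location pairs for one test set.

    Computing these once and reusing them across parcellations (group map,
    every subject's individual map, ...) is the evaluation fast path.
    """

    spec: DCBCSpec
    corr: np.ndarray  # correlation per pair, aligned with spec.pair_bins()
    ok: np.ndarray  # pairs where both locations have nonzero variance


def pair_correlations(test_data: np.ndarray, spec: DCBCSpec) -> PairCorrelations:
    """Correlate every binned location pair of ``test_data`` (N, P)."""
    if not np.all(np.isfinite(test_data)):
        raise ValueError("test_data must be finite")
    Z, valid = _standardize_profiles(test_data)
    ii, jj, _ = spec.pair_bins()
    R = Z.T @ Z  # (P, P); P is small enough for the full matrix
    return PairCorrelations(spec=spec, corr=R[ii, jj], ok=valid[ii] & valid[jj])


def dcbc(
    labels: np.ndarray,
    test_data: np.ndarray | PairCorrelations,
    spec: DCBCSpec | None = None,
) -> DCBCResult:
    """DCBC of a hard parcellation evaluated on independent test data.

    ``labels`` is a length-P label vector; ``test_data`` is either a
    (conditions, P) profile matrix or a precomputed
    :class:`PairCorrelations`.  Bins lacking either within- or
    between-parcel pairs are excluded; if every bin is excluded an error is
    raised.  The per-bin weight is ``(1/n_within + 1/n_between)^-1``, the
    reciprocal sampling-variance scale of a difference of two means.
    """
    if isinstance(test_data, PairCorrelations):
        pc = test_data
        spec = pc.spec
    else:
        if spec is None:
            raise ValueError("spec is required when passing raw test data")
        pc = pair_correlations(test_data, spec)
    labels = np.asarray(labels).reshape(-1)
    if labels.shape[0] != spec.P:
        raise ValueError("labels length must match spec coordinates")
    if np.unique(labels).size < 2:
        raise ValueError("DCBC needs at least two parcels present")
    ii, jj, bin_id = spec.pair_bins()
    ii, jj, bin_id = ii[pc.ok], jj[pc.ok], bin_id[pc.ok]
    corr = pc.corr[pc.ok]
    same = labels[ii] == labels[jj]
    B = spec.n_bins
    n_w = np.bincount(bin_id[same], minlength=B).astype(float)
    n_b = np.bincount(bin_id[~same], minlength=B).astype(float)
    s_w = np.bincount(bin_id[same], weights=corr[same], minlength=B)
    s_b = np.bincount(bin_id[~same], weights=corr[~same], minlength=B)
    usable = (n_w > 0) & (n_b > 0)
    if not usable.any():
        raise ValueError("no distance bin has both within- and between-parcel pairs")
    with np.errstate(divide="ignore", invalid="ignore"):
        r_w = np.where(n_w > 0, s_w / np.maximum(n_w, 1), np.nan)
        r_b = np.where(n_b > 0, s_b / np.maximum(n_b, 1), np.nan)
    weight = np.zeros(B)
    weight[usable] = 1.0 / (1.0 / n_w[usable] + 1.0 / n_b[usable])
    diff = np.where(usable, r_w - r_b, np.nan)
    value = float(np.nansum(weight * diff) / weight.sum())
    table = pd.DataFrame(
        {
            "bin_upper": (np.arange(B) + 1) * spec.bin_width,
            "n_within": n_w,
            "n_between": n_b,
            "r_within": r_w,
            "r_between": r_b,
            "weight": weight,
        }
    )
    return DCBCResult(value=value, table=table)


def align_parcels(labels_a: np.ndarray, labels_b: np.ndarray, K: int) -> np.ndarray:
    """Mapping that relabels ``labels_b`` to best match ``labels_a``.

    Solves the optimal assignment on the confusion matrix (Hungarian
    algorithm).  Returns ``perm`` such that ``perm[labels_b]`` maximizes
    agreement with ``labels_a``.  When the two maps use different label
    counts (e.g. a K=10 fit compared with a K=20 truth) the assignment is
    rectangular and ``perm`` maps b-labels into a-labels injectively.
    """
    a = np.asarray(labels_a).reshape(-1)
    b = np.asarray(labels_b).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("label maps must have equal length")
    Ka = max(K, int(a.max()) + 1)
    Kb = max(K, int(b.max()) + 1)
    conf = np.zeros((Ka, Kb))
    np.add.at(conf, (a, b), 1.0)
    rows, cols = linear_sum_assignment(-conf.T)  # rows: b-labels, cols: a-labels
    # b-labels beyond the assignment (only when Kb > Ka) fall back to their
    # best-overlap a-label
    perm = np.argmax(conf.T, axis=1)
    perm[rows] = cols
    return perm


def reconstruction_error(posterior: np.ndarray, true_map: np.ndarray) -> float:
    """1 minus the mean posterior probability of the true label, aligned.

    Parcel indices of the posterior are first matched to the ground-truth
    labels by optimal assignment of its winner-take-all map, making the
    score invariant to label permutations.  0 for a one-hot correct
    posterior; 1 - 1/K for a uniform posterior.
    """
    U = np.asarray(posterior, dtype=float)
    truth = np.asarray(true_map).reshape(-1)
    if U.ndim != 2 or U.shape[1] != truth.shape[0]:
        raise ValueError("posterior must be (K, P) matching true_map")
    K = U.shape[0]
    hard = np.argmax(U, axis=0)
    perm = align_parcels(truth, hard, K)
    n_rows = max(int(perm.max()) + 1, int(truth.max()) + 1)
    aligned = np.zeros((n_rows, truth.size))
    aligned[perm[:K]] = U  # row k of U becomes row perm[k]
    p_true = aligned[truth, np.arange(truth.size)]
    return float(1.0 - p_true.mean())
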