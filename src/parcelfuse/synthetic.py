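"""Synthetic ground truth and session data for simulation studies.

Ground-truth individual parcellations are sampled from a Potts model on a
rectangular grid with 4-neighbor connectivity: neighboring locations prefer
equal labels (coupling ``smoothness``), and a per-subject external field
pulls each map toward a shared group prototype, so individual maps vary
around a common group organization.

Session data are generated per location as ``y_i = lambda_k v_k + eps``
with region-specific signal strength lambda_k and isotropic Gaussian noise
of variance sigma2_k, then normalized to unit length.  The normalized data
approximately follow a von Mises-Fisher distribution with mean v_k and
concentration kappa_k = lambda_k^2 / sigma2_k, which ties the generator's
signal-to-noise dials directly to the emission model's concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .emission import DataBundle, Session

__all__ = [
    "SessionSpec",
    "SyntheticScenario",
    "SimulatedDataset",
    "sample_potts",
    "sample_group_prototype",
    "sample_true_parcellations",
    "generate_session_data",
    "generate_dataset",
    "build_study_scenarios",
    "sample_vmf",
    "grid_coordinates",
    "neighbor_agreement",
]


@dataclass
class SessionSpec:
    """Geometry of one synthetic session: size and per-region signal/noise.

    ``lam`` (signal strength, >= 0) and ``sigma2`` (noise variance, > 0)
    may be scalars or length-K vectors.
    """

    n_conditions: int
    lam: float | np.ndarray = 1.1
    sigma2: float | np.ndarray = 0.5

    def region_params(self, K: int) -> tuple[np.ndarray, np.ndarray]:
        lam = np.broadcast_to(np.asarray(self.lam, dtype=float), (K,)).copy()
        sig = np.broadcast_to(np.asarray(self.sigma2, dtype=float), (K,)).copy()
        if np.any(lam < 0):
            raise ValueError("lambda must be nonnegative")
        if np.any(sig <= 0):
            raise ValueError("sigma2 must be positive")
        return lam, sig


@dataclass
class SyntheticScenario:
    """Full description of a simulation study.

    ``smoothness`` is the Potts coupling J (0 = iid labels);
    ``group_strength`` the weight of the external field toward the group
    prototype, controlling how tightly individual maps track the group.
    ``split_lambdas``, when set to ``(high, low)``, makes
    :func:`generate_dataset` randomly split the K regions into two halves
    and give the first training session high signal on the first half and
    low on the second, with the assignment swapped in the second session.
    """

    grid: tuple[int, int] = (50, 50)
    K: int = 20
    n_subjects: int = 10
    smoothness: float = 2.5
    group_strength: float = 0.75
    gibbs_sweeps: int = 50
    prototype_sweeps: int = 30
    sessions: list[SessionSpec] = field(default_factory=list)
    test_session: SessionSpec | None = None
    split_lambdas: tuple[float, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K > self.grid[0] * self.grid[1]:
            raise ValueError("K cannot exceed the number of grid cells")
        if self.K < 1 or self.n_subjects < 1:
            raise ValueError("K and n_subjects must be positive")

    @property
    def P(self) -> int:
        return self.grid[0] * self.grid[1]


@dataclass
class SimulatedDataset:
    """Output of :func:`generate_dataset`."""

    scenario: SyntheticScenario
    prototype: np.ndarray  # (P,) group prototype labels
    true_maps: np.ndarray  # (S, P) individual ground-truth labels
    train: DataBundle
    test: DataBundle
    directions: list[np.ndarray]  # per training session, (N, K)
    test_directions: np.ndarray
    session_lambdas: list[np.ndarray]  # per training session, (K,)
    region_split: np.ndarray | None = None  # bool (K,), True = group A


def _neighbor_counts(labels: np.ndarray, K: int) -> np.ndarray:
    """Per-label 4-neighbor counts; labels (S, H, W) -> (S, K, H, W)."""
    onehot = (labels[:, None, :, :] == np.arange(K)[None, :, None, None]).astype(
        np.float64
    )
    counts = np.zeros_like(onehot)
    counts[:, :, 1:, :] += onehot[:, :, :-1, :]
    counts[:, :, :-1, :] += onehot[:, :, 1:, :]
    counts[:, :, :, 1:] += onehot[:, :, :, :-1]
    counts[:, :, :, :-1] += onehot[:, :, :, 1:]
    return counts


def sample_potts(
    shape: tuple[int, int],
    K: int,
    coupling: float,
    sweeps: int,
    rng: np.random.Generator,
    n_maps: int = 1,
    external_field: np.ndarray | None = None,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Gibbs-sample K-label Potts maps on a 4-neighbor grid.

    Uses checkerboard (two-phase) sweeps; each cell's conditional is
    ``softmax(coupling * n_k + field_k)`` over the labels, with n_k the
    number of 4-neighbors currently labeled k.  Starts from ``init``
    (shape (H, W), shared across maps) or a uniform random configuration.
    ``external_field`` may be (K, H, W) (shared) or (n_maps, K, H, W).
    Returns labels of shape (n_maps, H, W).
    """
    H, W = shape
    if init is not None:
        labels = np.broadcast_to(
            np.asarray(init, dtype=np.int64), (n_maps, H, W)
        ).copy()
    else:
        labels = rng.integers(0, K, size=(n_maps, H, W))
    if sweeps == 0 or (coupling == 0 and external_field is None):
        return labels
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    phases = [(ii + jj) % 2 == p for p in (0, 1)]
    fld = None
    if external_field is not None:
        fld = np.asarray(external_field, dtype=float)
        if fld.ndim == 3:
            fld = fld[None]
    for _ in range(sweeps):
        for phase in phases:
            logits = coupling * _neighbor_counts(labels, K)
            if fld is not None:
                logits = logits + fld
            gumbel = rng.gumbel(size=logits.shape)
            draw = np.argmax(logits + gumbel, axis=1)
            labels[:, phase] = draw[:, phase]
    return labels


def _voronoi_partition(
    shape: tuple[int, int], K: int, rng: np.random.Generator
) -> np.ndarray:
    """Nearest-center partition of the grid into K contiguous regions."""
    H, W = shape
    centers = rng.uniform([0, 0], [H, W], size=(K, 2))
    pts = grid_coordinates(shape)
    d2 = ((pts[:, None, :] - centers[None]) ** 2).sum(-1)
    return np.argmin(d2, axis=1).reshape(H, W)


def sample_group_prototype(
    scenario: SyntheticScenario, rng: np.random.Generator
) -> np.ndarray:
    """Group prototype map: Voronoi seed refined by Potts Gibbs sweeps.

    Seeding from a nearest-center partition of K random points guarantees
    that all K regions exist and are contiguous; ``prototype_sweeps`` Gibbs
    sweeps at the scenario's coupling then roughen the boundaries into
    irregular, MRF-typical shapes.
    """
    seed_map = _voronoi_partition(scenario.grid, scenario.K, rng)
    return sample_potts(
        scenario.grid,
        scenario.K,
        scenario.smoothness,
        scenario.prototype_sweeps,
        rng,
        init=seed_map,
    )[0]


def sample_true_parcellations(
    scenario: SyntheticScenario,
    rng: np.random.Generator,
    prototype: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the group prototype and per-subject ground-truth label maps.

    Returns ``(true_maps, prototype)`` with ``true_maps`` (S, P) and
    ``prototype`` (P,), both flattened row-major.  When ``prototype`` is
    given it is reused instead of sampled.
    """
    H, W = scenario.grid
    if prototype is None:
        proto = sample_group_prototype(scenario, rng)
    else:
        proto = np.asarray(prototype).reshape(H, W)
    fieldmap = scenario.group_strength * (
        proto[None, :, :] == np.arange(scenario.K)[:, None, None]
    ).astype(float)
    maps = sample_potts(
        scenario.grid,
        scenario.K,
        scenario.smoothness,
        scenario.gibbs_sweeps,
        rng,
        n_maps=scenario.n_subjects,
        external_field=fieldmap,
    )
    return maps.reshape(scenario.n_subjects, -1), proto.reshape(-1)


def generate_session_data(
    true_map: np.ndarray,
    v: np.ndarray,
    lam: np.ndarray,
    sigma2: np.ndarray,
    rng: np.random.Generator,
    normalize: bool = True,
) -> np.ndarray:
    """One subject-session: y_i = lambda_k(i) v_k(i) + eps, shape (N, P).

    ``v`` is (N, K) with unit columns; ``lam``/``sigma2`` length-K.  With
    ``normalize`` every location's N-vector is scaled to unit length.
    """
    true_map = np.asarray(true_map, dtype=int).reshape(-1)
    v = np.asarray(v, dtype=float)
    lam = np.asarray(lam, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    signal = v[:, true_map] * lam[true_map][None, :]
    noise = rng.standard_normal(signal.shape) * np.sqrt(sigma2[true_map])[None, :]
    Y = signal + noise
    if normalize:
        norms = np.linalg.norm(Y, axis=0, keepdims=True)
        Y = np.divide(Y, norms, out=np.zeros_like(Y), where=norms > 0)
    return Y


def _random_directions(N: int, K: int, rng: np.random.Generator) -> np.ndarray:
    V = rng.standard_normal((N, K))
    return V / np.linalg.norm(V, axis=0, keepdims=True)


def generate_dataset(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> SimulatedDataset:
    """Sample a full study: truth maps, training sessions, and test set.

    Each session (and the test set) draws its own random mean directions,
    so sessions share the ground-truth parcellation but not the response
    profiles — emission models must align through the arrangement model.
    """
    if not scenario.sessions or scenario.test_session is None:
        raise ValueError("scenario needs training sessions and a test session")
    rng = np.random.default_rng(rng if rng is not None else scenario.seed)
    true_maps, prototype = sample_true_parcellations(scenario, rng)
    subjects = tuple(f"sub-{i:02d}" for i in range(scenario.n_subjects))

    split = None
    session_lambdas: list[np.ndarray] = []
    session_specs = list(scenario.sessions)
    if scenario.split_lambdas is not None:
        high, low = scenario.split_lambdas
        split = np.zeros(scenario.K, dtype=bool)
        split[rng.permutation(scenario.K)[: scenario.K // 2]] = True
        for j, spec in enumerate(session_specs):
            lam = np.where(split, high, low) if j % 2 == 0 else np.where(split, low, high)
            session_specs[j] = replace(spec, lam=lam)

    train_sessions, directions = [], []
    for j, spec in enumerate(session_specs):
        lam, sig = spec.region_params(scenario.K)
        session_lambdas.append(lam)
        V = _random_directions(spec.n_conditions, scenario.K, rng)
        directions.append(V)
        Y = np.stack(
            [
                generate_session_data(true_maps[s], V, lam, sig, rng)
                for s in range(scenario.n_subjects)
            ]
        )
        train_sessions.append(Session(f"ses-{j + 1:02d}", subjects, Y))

    tspec = scenario.test_session
    lam_t, sig_t = tspec.region_params(scenario.K)
    V_t = _random_directions(tspec.n_conditions, scenario.K, rng)
    Y_t = np.stack(
        [
            generate_session_data(true_maps[s], V_t, lam_t, sig_t, rng)
            for s in range(scenario.n_subjects)
        ]
    )
    return SimulatedDataset(
        scenario=scenario,
        prototype=prototype,
        true_maps=true_maps,
        train=DataBundle(train_sessions, unit_normalized=True),
        test=DataBundle([Session("ses-test", subjects, Y_t)], unit_normalized=True),
        directions=directions,
        test_directions=V_t,
        session_lambdas=session_lambdas,
        region_split=split,
    )


def build_study_scenarios(seed: int | None = None) -> dict[str, SyntheticScenario]:
    """Named presets for the two simulation studies.

    ``equal_snr``: 10 subjects, K=20 on a 50x50 grid; session 1 with N=40
    conditions and noise variance 0.5, session 2 with N=20 and 0.8, equal
    signal strength 1.1 everywhere; test set with N=120 conditions.

    ``region_split_snr``: same geometry, two symmetric N=40 sessions with
    noise variance 0.5, but the regions are randomly split into two halves
    with high/low signal strength (1.1 / 0.2) swapped between the sessions;
    the test set has equal signal strength.
    """
    equal = SyntheticScenario(
        sessions=[SessionSpec(40, 1.1, 0.5), SessionSpec(20, 1.1, 0.8)],
        test_session=SessionSpec(120, 1.1, 0.5),
        seed=seed,
    )
    split = SyntheticScenario(
        sessions=[SessionSpec(40, 1.1, 0.5), SessionSpec(40, 1.1, 0.5)],
        test_session=SessionSpec(120, 1.1, 0.5),
        split_lambdas=(1.1, 0.2),
        seed=seed,
    )
    return {"equal_snr": equal, "region_split_snr": split}


def sample_vmf(
    mu: np.ndarray, kappa: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` samples from a vMF distribution (Wood's method).

    ``mu`` is the unit mean direction of length N; returns (size, N).
    """
    mu = np.asarray(mu, dtype=float)
    N = mu.size
    mu = mu / np.linalg.norm(mu)
    if kappa == 0:
        x = rng.standard_normal((size, N))
        return x / np.linalg.norm(x, axis=1, keepdims=True)
    d = N - 1
    b = (-2 * kappa + np.sqrt(4 * kappa**2 + d**2)) / d
    x0 = (1 - b) / (1 + b)
    c = kappa * x0 + d * np.log(1 - x0**2)
    ws = np.empty(size)
    filled = 0
    while filled < size:
        m = size - filled
        z = rng.beta(d / 2.0, d / 2.0, size=m)
        w = (1 - (1 + b) * z) / (1 - (1 - b) * z)
        accept = kappa * w + d * np.log1p(-x0 * w) - c >= np.log(rng.uniform(size=m))
        n_acc = int(accept.sum())
        ws[filled : filled + n_acc] = w[accept]
        filled += n_acc
    # direction uniform in the orthogonal complement of mu
    xi = rng.standard_normal((size, N))
    xi -= np.outer(xi @ mu, mu)
    xi /= np.linalg.norm(xi, axis=1, keepdims=True)
    return ws[:, None] * mu[None, :] + np.sqrt(1 - ws**2)[:, None] * xi


def grid_coordinates(grid: tuple[int, int]) -> np.ndarray:
    """(P, 2) row-major cell-center coordinates of a rectangular grid."""
    H, W = grid
    ii, jj = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    return np.column_stack([ii.ravel(), jj.ravel()]).astype(float)


def neighbor_agreement(labels: np.ndarray, grid: tuple[int, int]) -> float:
    """Fraction of 4-neighbor pairs sharing a label (smoothness summary)."""
    lab = np.asarray(labels).reshape(grid)
    same = np.concatenate(
        [(lab[1:, :] == lab[:-1, :]).ravel(), (lab[:, 1:] == lab[:, :-1]).ravel()]
    )
    return float(same.mean())
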