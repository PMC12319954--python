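import numpy as np
import pytest

from parcelfuse import (
    FitConfig,
    SessionSpec,
    SyntheticScenario,
    generate_dataset,
    multi_start_fit,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def easy_scenario(seed=None, n_subjects=5):
    """High-SNR small scenario: K=5 on a 20x20 grid, kappa ~ 100."""
    return SyntheticScenario(
        grid=(20, 20),
        K=5,
        n_subjects=n_subjects,
        sessions=[SessionSpec(20, 3.0, 0.09)],
        test_session=SessionSpec(40, 3.0, 0.09),
        seed=seed,
    )


def light_config(**kw):
    kw.setdefault("n_starts", 3)
    kw.setdefault("warmup_steps", 8)
    kw.setdefault("n_repeats_min", 1)
    kw.setdefault("top_solution_count", 1)
    kw.setdefault("max_iter", 100)
    return FitConfig(**kw)


@pytest.fixture(scope="session")
def easy_fit():
    """A dataset that is easy to parcellate, with a converged fitted model."""
    ds = generate_dataset(easy_scenario(seed=7))
    model, post, trace = multi_start_fit(
        ds.train, ds.scenario.K, "type2", light_config(),
        rng=np.random.default_rng(7),
    )
    return ds, model, post, trace
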