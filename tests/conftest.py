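import dataclasses

import numpy as np
import pytest

from lifespan_limit import (
    SWEDEN_LIKE,
    GeneratorSpec,
    StretchedExpFit,
    SurvivalCurve,
    generate_lifetable,
    survival_at,
)


@pytest.fixture(scope="session")
def sweden_spec() -> GeneratorSpec:
    return SWEDEN_LIKE


@pytest.fixture(scope="session")
def sweden_table(sweden_spec):
    """One noise-free synthetic life table from the sweden-like preset."""
    return generate_lifetable(sweden_spec, 2020)


@pytest.fixture(scope="session")
def noisy_spec(sweden_spec):
    return dataclasses.replace(sweden_spec, noise="binomial", seed=11)


def make_fit(alpha=88.0, b0=3.0, b1=0.1871182258609849, b2=-0.0013211822586098492,
             window=(100.0, 110.0)) -> StretchedExpFit:
    return StretchedExpFit(
        alpha=alpha, b0=b0, b1=b1, b2=b2,
        fit_window=window, n_points=10, residual_rms=0.0,
    )


def curve_from_fit(fit: StretchedExpFit, age_max: int = 110,
                   step: float = 1.0) -> SurvivalCurve:
    """Exact model survival on a grid, with s(0) = 1 prepended."""
    ages = np.arange(step, age_max + step / 2, step)
    s = survival_at(fit, ages)
    return SurvivalCurve(
        ages=np.concatenate([[0.0], ages]),
        s=np.concatenate([[1.0], s]),
        source_label="exact model curve",
    )


def random_valid_fits(n: int, seed: int, rng_alpha=(85.0, 93.0),
                      omega_range=(115.0, 135.0)):
    """Sample n stretched fits with a root of beta = gamma placed in
    omega_range, by the linear two-parameter solve given b0 and beta(100).

    beta(omega) - gamma(omega) is linear in (b1, b2), so placing the
    crossover is a 2x2 solve; fits whose exponent dips non-positive on the
    window are rejected and resampled.
    """
    rng = np.random.default_rng(seed)
    fits = []
    while len(fits) < n:
        alpha = rng.uniform(*rng_alpha)
        b0 = rng.uniform(2.0, 4.0)
        beta100 = rng.uniform(7.0, 10.0)
        om = rng.uniform(*omega_range)
        lr = np.log(om / alpha)
        # rows: beta(100) constraint; beta(om) + om*ln(om/alpha)*beta'(om) = 0
        A = np.array([
            [100.0, 100.0**2],
            [om + om * lr, om**2 + 2 * om**2 * lr],
        ])
        rhs = np.array([beta100 - b0, -b0])
        try:
            b1, b2 = np.linalg.solve(A, rhs)
            fit = make_fit(alpha=alpha, b0=b0, b1=b1, b2=b2)
        except (np.linalg.LinAlgError, ValueError):
            continue
        fits.append(fit)
    return fits
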