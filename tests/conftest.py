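import math

import numpy as np
import pytest
from scipy.integrate import quad

import bcrisk as b


@pytest.fixture(scope="session")
def scheme():
    return b.default_scheme()


@pytest.fixture(scope="session")
def region():
    return b.bundled_region()


@pytest.fixture(scope="session")
def baseline(region):
    return region.baseline()


@pytest.fixture(scope="session")
def mortality(region):
    return region.mortality()


def worked_example_measurements():
    """The published worked example: one abortion, first live birth at 27,
    no benign breast disease, BMI 27, positive family history,
    life-satisfaction total 7."""
    return b.RawMeasurements(
        n_abortions=1,
        age_first_live_birth=27,
        benign_breast_disease=False,
        height_m=1.60,
        weight_kg=27.0 * 1.60**2,
        family_history=True,
        satisfaction_items=(1, 1, 1, 1, 1, 2),
    )


def quadrature_risk(a, tau, r, baseline, mortality):
    """Independent numeric oracle for the absolute-risk integral.

    Integrates r·h1*(t)·exp(−Λ(a,t)) by adaptive quadrature band by band,
    with the cumulative hazard Λ evaluated from the rate arrays directly.
    """
    grid = baseline.grid
    edges = grid.edges
    h1 = baseline.rates_array
    h2 = mortality.rates_array

    def cumhaz(t):
        lo = np.minimum(np.maximum(a, edges[:-1]), t)
        hi = np.minimum(edges[1:], t)
        w = np.clip(hi - lo, 0.0, None)
        return float(np.sum((r * h1 + h2) * w))

    def band_rate(t):
        k = min(int((t - edges[0]) // grid.band_width), grid.n_bands - 1)
        return r * h1[k]

    total = 0.0
    cuts = [a] + [float(e) for e in edges if a < e < a + tau] + [a + tau]
    for lo, hi in zip(cuts, cuts[1:]):
        val, _ = quad(
            lambda t: band_rate(0.5 * (lo + hi)) * math.exp(-cumhaz(t)),
            lo,
            hi,
            epsabs=1e-14,
            epsrel=1e-12,
        )
        total += val
    return total


def random_schedules(rng, n_bands=6, start=30, width=5, max_rate=0.05):
    """A random piecewise-constant baseline/mortality pair on one grid."""
    grid = b.AgeBandGrid(band_starts=tuple(range(start, start + width * n_bands, width)),
                         band_width=width)
    base = b.HazardSchedule(
        grid=grid, rates=tuple(rng.uniform(0, max_rate, n_bands)), kind="baseline"
    )
    mort = b.HazardSchedule(
        grid=grid,
        rates=tuple(rng.uniform(0, max_rate, n_bands)),
        kind="competing_mortality",
    )
    return base, mort
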