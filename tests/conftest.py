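import numpy as np
import pytest

from iced import (Design, SimulationSpec, VarianceComponents,
                  simulate_dataset, three_scan_design, two_day_design)


@pytest.fixture
def design4():
    """4 scans over 2 days / 3 sessions: all components identified."""
    return two_day_design()


@pytest.fixture
def design3():
    """3 scans, one day: back-to-back pair plus one repositioned scan."""
    return three_scan_design()


@pytest.fixture
def mwf_theta():
    """Variance components of the worked myelin-water-fraction example."""
    return VarianceComponents(sigma_T2=6.97, facet_variances={"session": 0.59},
                              sigma_E2=0.52)


@pytest.fixture
def theta4():
    return VarianceComponents(sigma_T2=4.0, facet_variances={"day": 1.0, "session": 1.0},
                              sigma_E2=1.0, mu=10.0)


@pytest.fixture
def small_dataset(design4, theta4):
    return simulate_dataset(SimulationSpec(design4, theta4, n_persons=150, seed=11))


def random_theta(rng, facets, low=0.05, high=3.0, mu_scale=5.0):
    """A strictly positive random parameter point for property tests."""
    return VarianceComponents(
        sigma_T2=float(rng.uniform(low, high)),
        facet_variances={f: float(rng.uniform(low, high)) for f in facets},
        sigma_E2=float(rng.uniform(low, high)),
        mu=float(rng.normal(0, mu_scale)),
    )


def random_design(rng, max_occasions=6):
    """A random valid one- or two-facet nested design."""
    n = int(rng.integers(2, max_occasions + 1))
    occasions = [f"o{i}" for i in range(n)]
    facets = ["session"] if rng.random() < 0.5 else ["day", "session"]
    membership = {}
    if "day" in facets:
        cut = int(rng.integers(1, n))
        membership["day"] = {o: ("d1" if i < cut else "d2")
                             for i, o in enumerate(occasions)}
    sess, current = {}, 0
    for i, o in enumerate(occasions):
        if i > 0 and rng.random() < 0.5:
            current += 1
        day = membership.get("day", {}).get(o, "d1")
        sess[o] = f"{day}_s{current}"
    membership["session"] = sess
    return Design(occasions, tuple(facets), membership)
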