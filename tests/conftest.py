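import numpy as np
import pytest

from pcablup import Pedigree, SimulationConfig, simulate_pedigree, simulate_traits


def random_pedigree(n: int, seed: int) -> Pedigree:
    """Random valid pedigree: each individual draws 0-2 parents from the
    earlier individuals (guaranteeing acyclicity)."""
    rng = np.random.default_rng(seed)
    recs = []
    n_founders = max(2, n // 5)
    for i in range(n):
        name = f"I{i}"
        if i < n_founders:
            recs.append((name, None, None))
            continue
        choice = rng.random()
        pool = [f"I{j}" for j in range(i)]
        if choice < 0.1:
            recs.append((name, None, None))
        elif choice < 0.25:
            recs.append((name, str(rng.choice(pool)), None))
        else:
            s, d = rng.choice(pool, size=2, replace=False)
            recs.append((name, str(s), str(d)))
    rng.shuffle(recs)
    return Pedigree.from_records(recs)


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree.from_records(
        [("A", None, None), ("B", None, None), ("C", "A", "B")]
    )


@pytest.fixture
def family_pedigree() -> Pedigree:
    """Two founders, two full sibs, and an inbred full-sib-mating offspring."""
    return Pedigree.from_records(
        [
            ("A", None, None),
            ("B", None, None),
            ("C", "A", "B"),
            ("D", "A", "B"),
            ("X", "C", "D"),
        ]
    )


def small_simulation(m=3, seed=0, h2=None, founders=20, families=20, offspring=6,
                     means=None, missing=0.0):
    """Convenience wrapper building a modest simulated dataset."""
    from pcablup import apply_missingness
    from pcablup.simulate import random_psd_covariance

    if h2 is None:
        h2 = np.full(m, 0.3)
    G0 = random_psd_covariance(m, np.asarray(h2), seed=seed + 50)
    R0 = random_psd_covariance(m, 1 - np.asarray(h2), seed=seed + 60)
    cfg = SimulationConfig(
        founders=founders, generations=2, families_per_generation=families,
        offspring_per_family=offspring,
        trait_means=np.zeros(m) if means is None else np.asarray(means, float),
        G0=G0, R0=R0, seed=seed,
    )
    ped = simulate_pedigree(cfg)
    tm, bv = simulate_traits(ped, cfg)
    if missing > 0:
        tm = apply_missingness(tm, missing, seed=seed + 70)
    return cfg, ped, tm, bv
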