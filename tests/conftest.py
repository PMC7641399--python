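import pytest

from hla_popstruct.simulate import SimParams, sim_cohort


def fast_params(seed: int = 0, **overrides) -> SimParams:
    """A scaled-down study layout that keeps every stage fast in tests."""
    base = dict(
        pops_per_region={"SIB": 1, "NAM": 2, "MEA": 2, "SAA": 2, "SAL": 3},
        n_msat=60,
        n_ref_pops=20,
        individuals_range=(12, 16),
        seed=seed,
    )
    base.update(overrides)
    return SimParams(**base)


@pytest.fixture(scope="session")
def small_bundle():
    """(cohort, msat_panel, reference_panel, truth) for a small synthetic study."""
    return sim_cohort(fast_params(seed=11))
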