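import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trnamod as tm

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_refs() -> tm.ReferenceSet:
    """Three random adapter-flanked references, fixed seed."""
    return tm.simulate_references(3, seed=11)


@pytest.fixture(scope="session")
def tiny_refs() -> tm.ReferenceSet:
    """One handmade reference with known uridine positions."""
    body = "GCGGATTTAGCTCAGTTGGGAGAGCGCCAGACTGAAGATCTGGAGGTCCTGTGTTCGATCCACAGAATTCGCA"
    return tm.build_references({"tRNA-toy": body}, adapter5="AAGGCC", adapter3="TTCCGGA")


@pytest.fixture(scope="session")
def sim_sample(small_refs) -> tm.Sample:
    """One simulated sample pushed through align/filter/extract."""
    ref_id = small_refs.ids()[0]
    ref = small_refs[ref_id]
    u_sites = [p for p in range(1, ref.body_len + 1) if ref.body_base(p) == "T"]
    models = {(ref_id, u_sites[0]): tm.SiteModel(u_sites[0], 0.9)}
    return tm.simulate_sample(small_refs, models, seed=7, depth=60)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
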