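import numpy as np
import pytest

import metacurve as mc


@pytest.fixture(scope="session")
def table1():
    return mc.load_table1()


@pytest.fixture(scope="session")
def fs_independent(table1):
    return mc.resolve_independent(table1, "full_scale")


@pytest.fixture(scope="session")
def fs_healthy(fs_independent):
    return mc.filter_subset(fs_independent, {"sample_type": "healthy"})


@pytest.fixture(scope="session")
def fs_published_healthy(fs_healthy):
    return mc.filter_subset(fs_healthy, {"reporting": "reported"})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_record(r=0.3, n=50, **kw):
    base = dict(
        study_label="Study",
        year=2000,
        sample_type="healthy",
        mean_age=30.0,
        male_ratio=50.0,
        reporting="reported",
        domain_raw="FSIQ",
        test_description="test",
        n=n,
        r=r,
    )
    base.update(kw)
    return mc.EffectRecord(**base)


@pytest.fixture()
def toy_records():
    """Five independent healthy effects with distinct sample keys."""
    return [
        make_record(r=r, n=n, study_label=f"S{i}", mean_age=20.0 + i)
        for i, (r, n) in enumerate([(0.1, 30), (0.2, 50), (0.3, 80), (0.25, 40), (0.15, 60)])
    ]
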