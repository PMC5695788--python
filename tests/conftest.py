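import numpy as np
import pytest

import voxpower as vp


@pytest.fixture(scope="session")
def wd_field() -> vp.EffectField:
    return vp.make_effect_field(vp.ScenarioSpec.weak_diffuse(seed=0))


@pytest.fixture(scope="session")
def sl_field() -> vp.EffectField:
    return vp.make_effect_field(vp.ScenarioSpec.strong_localized(seed=0))


@pytest.fixture(scope="session")
def wd_cohort(wd_field) -> vp.CohortSample:
    """Full Weak Diffuse cohort (n = 10,000), shared across tests."""
    return vp.generate_cohort(wd_field, 10_000, seed=101)


@pytest.fixture(scope="session")
def sl_cohort(sl_field) -> vp.CohortSample:
    """Full Strong Localized cohort (n = 10,000), shared across tests."""
    return vp.generate_cohort(sl_field, 10_000, seed=102)


@pytest.fixture(scope="session")
def small_spec() -> vp.ScenarioSpec:
    """A small-grid scenario for cheap cohort-level checks."""
    return vp.ScenarioSpec.weak_diffuse(seed=7, shape=(20, 16), target_voxels=200)


def make_sigmap(sig, n=30, r=None):
    """Hand-built SignificanceMap (and backing stat map) for metric tests."""
    sig = np.asarray(sig, dtype=bool)
    if r is None:
        r = np.where(sig, 0.6, 0.0)
    r = np.asarray(r, dtype=float)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    from scipy import stats

    p = 2 * stats.t.sf(np.abs(t), n - 2)
    stat = vp.VoxelStatMap(n=n, r=r, t=t, p=p)
    return stat, vp.SignificanceMap(sig=sig, threshold=vp.ThresholdSpec(), source=stat)
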