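import numpy as np
import pytest

import brainstates as bs


@pytest.fixture(scope="session")
def filterbank():
    return bs.build_filterbank()


@pytest.fixture(scope="session")
def small_study():
    """One 10-region volunteer on the default full-length layout."""
    cfg = bs.StudyConfig(n_volunteers=1, n_regions=10, seed=42)
    return cfg, bs.generate_study(cfg)[0]


@pytest.fixture(scope="session")
def small_tvfc(small_study, filterbank):
    _, series = small_study
    return bs.compute_tvfc(series, filterbank)


@pytest.fixture(scope="session")
def mini_features():
    """Six 10-region volunteers on the default layout, node + H0 features.

    The small region count keeps TVFC and distance matrices cheap while the
    full-length scan preserves the trim/balancing arithmetic.
    """
    cfg = bs.StudyConfig(n_volunteers=6, n_regions=10, seed=7)
    study = bs.generate_study(cfg)
    fb = bs.build_filterbank(tr=cfg.tr)
    tvfc = [bs.compute_tvfc(s, fb) for s in study]
    from brainstates import stats
    return cfg, tvfc, stats.prepare_features(tvfc, ["node", "H0"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
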