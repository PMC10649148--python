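import numpy as np
import pytest

from youngbmi import AnalysisConfig, SimConfig, analyze_cohort, simulate_cohort


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig()


def make_config(**overrides) -> SimConfig:
    return SimConfig.from_dict({**SimConfig().to_dict(), **overrides})


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, rounding-free measurement process (default biology)."""
    return make_config(height_noise_sd=0.0, outlier_prob=0.0,
                       bmi_noise_sd=0.0, rounding_enabled=False, seed=7)


@pytest.fixture(scope="session")
def static_config():
    """Zero shrinkage and flat, noise-free BMI: every trajectory constant."""
    return make_config(shrink_rate_f=0.0, shrink_rate_m=0.0, shrink_rate_sd=0.0,
                       bmi_age_drift=0.0, bmi_noise_sd=0.0,
                       height_noise_sd=0.0, outlier_prob=0.0, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = make_config(n_subjects=120, seed=3)
    exams, truth = simulate_cohort(cfg)
    return cfg, exams, truth


@pytest.fixture(scope="session")
def small_results(small_cohort):
    _, exams, _ = small_cohort
    return analyze_cohort(exams)


def tricube_wls_oracle(x, y, frac):
    """Independent direct LOWESS oracle: for each target point, tricube
    weights over the int(frac*n) nearest neighbours, then a weighted
    degree-1 least-squares fit evaluated at the point."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    k = max(2, int(frac * n))
    out = np.empty(n)
    for i, xi in enumerate(x):
        d = np.abs(x - xi)
        nearest = np.argsort(d, kind="stable")[:k]
        dmax = d[nearest].max()
        if dmax == 0:
            w = (d == 0).astype(float)
        else:
            w = np.clip(1.0 - np.clip(d / dmax, 0.0, 1.0) ** 3, 0.0, 1.0) ** 3
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        if sxx <= 1e-12:
            out[i] = ym
        else:
            slope = (w * (x - xm) * (y - ym)).sum() / sxx
            out[i] = ym + slope * (xi - xm)
    return out
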