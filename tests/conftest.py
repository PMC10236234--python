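import numpy as np
import pandas as pd
import pytest

from brainage import SimConfig, generate_cohort, generate_reference_cohort
from brainage.containers import CovariatePanel, ROITable


def small_config(**kw) -> SimConfig:
    base = dict(n_study=150, n_control=60, n_reference=200, n_ad_cases=60,
                n_rois=40, n_scanners=5, seed=7)
    base.update(kw)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return small_config()


@pytest.fixture(scope="session")
def cohort(sim_config):
    return generate_cohort(sim_config)


@pytest.fixture(scope="session")
def reference(sim_config):
    return generate_reference_cohort(sim_config)


def make_linear_age_table(n=200, n_rois=12, age_range=(20.0, 90.0), seed=0,
                          label="reference_control", noise_sd=0.0):
    """ROI volumes that are exact (optionally noisy) linear functions of age."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(*age_range, size=n)
    a = rng.uniform(4000, 9000, size=n_rois)
    b = rng.uniform(-40, -10, size=n_rois)
    vols = a[None, :] + b[None, :] * ages[:, None]
    vols += rng.normal(0, noise_sd, size=vols.shape)
    idx = pd.Index([f"X{i:04d}" for i in range(n)], name="subject_id")
    roi = ROITable(
        pd.DataFrame(vols, index=idx, columns=[f"ROI_{j:03d}" for j in range(n_rois)]),
        pd.Series("SC1", index=idx), pd.Series(label, index=idx))
    frame = pd.DataFrame({
        "age": ages,
        "sex": np.where(rng.random(n) < 0.5, "male", "female"),
        "icv": rng.normal(1.45e6, 1e5, size=n),
        "education": 16.0,
        "group": label,
    }, index=idx)
    return roi, CovariatePanel(frame)
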