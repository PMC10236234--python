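"""Synthetic multi-scanner cohort generator.

Emulates the statistical structure of a multi-site ROI-volume brain-aging
study: a middle-aged/older study arm with an accelerated-aging offset, a
demographically matched control arm, a large lifespan reference cohort with
an additional AD-pattern class, nonlinear (quadratic-with-plateau) ROI
age trends, per-scanner location/scale effects, and longitudinal
risk-factor visit histories.

The generating model for subject *i*, ROI *v* is

    y_iv = b_v + f_v(age_eff) + beta_sex,v male_i + beta_icv,v (icv_i - ICV0)
           [+ cohort_shift_v]  + shift(scanner_i, v) + scale(scanner_i, v) eps_iv

with ``f_v`` a monotone-decreasing quadratic decline past a plateau age for
age-sensitive ROIs (flat for all others), ``age_eff = age +
aging_offset_years`` for study-arm subjects on age-sensitive ROIs only, and
``eps ~ N(0, noise_sd^2)``.  Because the group effect is injected as an *age
shift*, the years-equivalent brain-aging statistic has a known ground truth
equal to ``aging_offset_years``.

Structural parameters (baselines, decline rates, covariate coefficients,
scanner effects) are drawn from a fixed internal generator so that two
configs differing only in ``seed`` share identical deterministic components
and differ only in subject-level draws.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import (
    CONTROL,
    CovariatePanel,
    REFERENCE_AD,
    REFERENCE_CONTROL,
    ROITable,
    STUDY,
)

#: reference intracranial volume about which ICV effects are centered, mm^3
ICV0 = 1.45e6
#: age below which ROI volumes are flat (decline starts here), years
PLATEAU_AGE = 30.0
#: fixed seed of the structural-parameter generator (shared across seeds)
_STRUCTURE_SEED = 202306


def _structure(config: SimConfig) -> dict:
    """Draw per-ROI and per-scanner structural parameters.

    Deterministic given the config's size/magnitude fields; independent of
    ``config.seed`` so that different seeds share the same generating curves.
    """
    rng = np.random.default_rng(_STRUCTURE_SEED)
    v = config.n_rois
    baseline = rng.uniform(4000.0, 12000.0, size=v)
    # per-year decline at age 60 in [10, 30] mm^3/yr  ->  f(a) = -k (a-30)^2
    slope60 = rng.uniform(10.0, 30.0, size=v)
    k = slope60 / (2.0 * (60.0 - PLATEAU_AGE))
    n_aff = int(round(config.affected_roi_fraction * v))
    n_sig = int(round(config.ad_signature_fraction * v))
    age_sensitive = np.zeros(v, dtype=bool)
    age_sensitive[:n_aff] = True
    ad_signature = np.zeros(v, dtype=bool)
    if n_sig:
        ad_signature[-n_sig:] = True
    k = np.where(age_sensitive, k, 0.0)
    beta_sex = 0.02 * baseline                      # males ~2% larger
    beta_icv = 0.3 * baseline / ICV0                # 30% scaling with head size
    shifts = rng.normal(0.0, 1.0, size=(config.n_scanners, v)) * config.site_shift_sd
    scales = np.exp(rng.normal(0.0, 1.0, size=(config.n_scanners, v)) * config.site_scale_sd)
    cohort_shift = rng.normal(0.0, 1.0, size=v) * config.cohort_shift_sd
    return dict(baseline=baseline, k=k, age_sensitive=age_sensitive,
                ad_signature=ad_signature, beta_sex=beta_sex, beta_icv=beta_icv,
                shifts=shifts, scales=scales, cohort_shift=cohort_shift)


def roi_names(n_rois: int) -> list[str]:
    return [f"ROI_{i + 1:03d}" for i in range(n_rois)]


def age_trend(ages: np.ndarray, k: np.ndarray) -> np.ndarray:
    """f_v(age): quadratic monotone decline past the plateau age.

    Returns an (n_subjects, n_rois) matrix of trend contributions (<= 0).
    """
    a = np.maximum(np.asarray(ages, dtype=float)[:, None] - PLATEAU_AGE, 0.0)
    return -(a ** 2) * np.asarray(k)[None, :]


def _draw_demographics(rng, n, age_range, edu_mean, edu_sd):
    ages = rng.uniform(age_range[0], age_range[1], size=n)
    male = rng.random(n) < 0.5
    icv = np.where(male,
                   rng.normal(1.55e6, 1.1e5, size=n),
                   rng.normal(1.35e6, 1.0e5, size=n))
    edu = np.clip(rng.normal(edu_mean, edu_sd, size=n), 8.0, 22.0)
    return ages, male, icv, edu


def _volumes(config, st, rng, ages, male, icv, scanner_idx, *,
             aging_offset_rois=None, in_study_space=False,
             ad_rows=None, site_shifts=None, site_scales=None):
    """Assemble the ROI volume matrix from the generating model."""
    n, v = len(ages), config.n_rois
    shifts = st["shifts"] if site_shifts is None else np.asarray(site_shifts, dtype=float)
    scales = st["scales"] if site_scales is None else np.asarray(site_scales, dtype=float)

    det = (st["baseline"][None, :]
           + st["beta_sex"][None, :] * male[:, None].astype(float)
           + st["beta_icv"][None, :] * (icv[:, None] - ICV0))
    trend = age_trend(ages, st["k"])
    if aging_offset_rois is not None and config.aging_offset_years != 0.0:
        shifted = age_trend(ages + config.aging_offset_years, st["k"])
        mask = np.asarray(aging_offset_rois, dtype=bool)
        trend = np.where(mask[None, :], shifted, trend)
    det = det + trend
    if in_study_space:
        det = det + st["cohort_shift"][None, :]
    det = det + shifts[scanner_idx, :]
    if ad_rows is not None and config.ad_effect_sd != 0.0:
        effect = config.ad_effect_sd * config.noise_sd
        det = det - np.outer(ad_rows.astype(float), st["ad_signature"].astype(float)) * effect
    eps = rng.normal(0.0, 1.0, size=(n, v)) * config.noise_sd
    y = det + scales[scanner_idx, :] * eps
    return np.maximum(y, 1.0)


def _assign_scanners(rng, n, n_scanners):
    """Random membership, balanced counts: every scanner gets subjects from
    every group as long as n >= n_scanners."""
    order = rng.permutation(n)
    idx = np.empty(n, dtype=int)
    idx[order] = np.arange(n) % n_scanners
    return idx


def generate_cohort(config: SimConfig, *, site_shifts=None,
                    site_scales=None) -> tuple[ROITable, CovariatePanel]:
    """Generate the study and control arms on multiple scanners.

    Study-arm subjects receive the configured accelerated-aging offset on
    age-sensitive ROIs only; both arms live in the study acquisition space
    (a per-ROI ``cohort_shift`` relative to the reference space).
    ``site_shifts``/``site_scales`` override the structural per-scanner
    effects with explicit (n_scanners, n_rois)-broadcastable arrays — useful
    for injecting known batch effects.
    """
    st = _structure(config)
    rng = np.random.default_rng([config.seed, 1])
    n_s, n_c = config.n_study, config.n_control

    ages_s, male_s, icv_s, edu_s = _draw_demographics(rng, n_s, config.age_range, 15.6, 1.9)
    ages_c, male_c, icv_c, edu_c = _draw_demographics(rng, n_c, config.age_range, 16.2, 1.5)
    scan_s = _assign_scanners(rng, n_s, config.n_scanners)
    scan_c = _assign_scanners(rng, n_c, config.n_scanners)

    vol_s = _volumes(config, st, rng, ages_s, male_s, icv_s, scan_s,
                     aging_offset_rois=st["age_sensitive"], in_study_space=True,
                     site_shifts=site_shifts, site_scales=site_scales)
    vol_c = _volumes(config, st, rng, ages_c, male_c, icv_c, scan_c,
                     in_study_space=True,
                     site_shifts=site_shifts, site_scales=site_scales)

    ids = ([f"S{i + 1:04d}" for i in range(n_s)] + [f"C{i + 1:04d}" for i in range(n_c)])
    index = pd.Index(ids, name="subject_id")
    vols = pd.DataFrame(np.vstack([vol_s, vol_c]), index=index,
                        columns=roi_names(config.n_rois))
    scanner = pd.Series([f"SC{j + 1:02d}" for j in np.concatenate([scan_s, scan_c])],
                        index=index)
    label = pd.Series([STUDY] * n_s + [CONTROL] * n_c, index=index)

    frame = pd.DataFrame({
        "age": np.concatenate([ages_s, ages_c]),
        "sex": np.where(np.concatenate([male_s, male_c]), "male", "female"),
        "icv": np.concatenate([icv_s, icv_c]),
        "education": np.concatenate([edu_s, edu_c]),
        "group": [STUDY] * n_s + [CONTROL] * n_c,
    }, index=index)
    return ROITable(vols, scanner, label), CovariatePanel(frame)


def generate_reference_cohort(config: SimConfig) -> tuple[ROITable, CovariatePanel]:
    """Generate the pooled reference cohort plus AD-pattern cases.

    Reference subjects span ``reference_age_range`` and carry a single
    pooled batch label (no scanner effects, no cohort shift).  The
    ``n_ad_cases`` AD-pattern subjects are drawn from the same demographic
    distribution with an additional atrophy of ``ad_effect_sd`` noise-SD
    units on the AD-signature ROI subset.
    """
    st = _structure(config)
    rng = np.random.default_rng([config.seed, 2])
    n_r, n_a = config.n_reference, config.n_ad_cases

    ages, male, icv, edu = _draw_demographics(rng, n_r + n_a,
                                              config.reference_age_range, 14.0, 3.0)
    ad_rows = np.zeros(n_r + n_a, dtype=bool)
    ad_rows[n_r:] = True
    scan = np.zeros(n_r + n_a, dtype=int)
    # single pooled batch: no site effects
    vols_arr = _volumes(config, st, rng, ages, male, icv, scan, ad_rows=ad_rows,
                        site_shifts=np.zeros((1, config.n_rois)),
                        site_scales=np.ones((1, config.n_rois)))

    ids = ([f"R{i + 1:04d}" for i in range(n_r)] + [f"A{i + 1:04d}" for i in range(n_a)])
    index = pd.Index(ids, name="subject_id")
    vols = pd.DataFrame(vols_arr, index=index, columns=roi_names(config.n_rois))
    scanner = pd.Series("REF", index=index)
    label = pd.Series([REFERENCE_CONTROL] * n_r + [REFERENCE_AD] * n_a, index=index)
    frame = pd.DataFrame({
        "age": ages,
        "sex": np.where(male, "male", "female"),
        "icv": icv,
        "education": edu,
        "group": label.to_numpy(),
    }, index=index)
    return ROITable(vols, scanner, label), CovariatePanel(frame)


#: quantitative risk factors: (between-subject mean, between-subject SD,
#: within-subject visit-to-visit walk SD)
QUANTITATIVE_RISK_FACTORS = {
    "hba1c": (8.0, 1.0, 0.30),
    "bmi": (26.0, 4.0, 0.50),
    "sbp": (120.0, 10.0, 3.0),
    "dbp": (74.0, 8.0, 2.0),
}
#: binary event reports and their per-visit report probability
EVENT_RISK_FACTORS = {"hypertension": 0.02, "retinopathy": 0.015}
#: expected severe-hypoglycemia events per year among susceptible subjects
_HYPO_RATE, _HYPO_SUSCEPTIBLE = 0.12, 0.35


def generate_risk_histories(panel: CovariatePanel, config: SimConfig, *,
                            walk_sd_scale: float = 1.0) -> CovariatePanel:
    """Attach visit-level longitudinal risk-factor records to a panel.

    Study-arm subjects get irregularly spaced visits (roughly annual with
    jitter) from baseline (t=0) to ``followup_years``; each quantitative
    series is a mean-reverting random walk around a subject-level mean.
    Control subjects get a single cross-sectional visit at the study end.
    ``walk_sd_scale`` scales all within-subject walk SDs (0 gives constant
    series equal to the subject mean).
    """
    rng = np.random.default_rng([config.seed, 3])
    rows: list[tuple] = []
    for sid, row in panel.frame.iterrows():
        if row["group"] == STUDY:
            gaps = rng.uniform(0.5, 1.5, size=int(config.followup_years) + 8)
            times = np.concatenate([[0.0], np.cumsum(gaps)])
            times = times[times <= config.followup_years]
        else:
            times = np.array([config.followup_years])
        for cov, (mu, between_sd, walk_sd) in QUANTITATIVE_RISK_FACTORS.items():
            center = mu + rng.normal(0.0, between_sd)
            vals = np.empty(len(times))
            vals[0] = center
            for j in range(1, len(times)):
                vals[j] = center + 0.7 * (vals[j - 1] - center) \
                    + rng.normal(0.0, walk_sd * walk_sd_scale)
            rows.extend((sid, cov, t, val) for t, val in zip(times, vals))
        susceptible = rng.random() < _HYPO_SUSCEPTIBLE
        dt = np.diff(np.concatenate([[0.0], times]))
        counts = rng.poisson(_HYPO_RATE * dt) if susceptible else np.zeros(len(times), int)
        rows.extend((sid, "severe_hypo", t, float(c)) for t, c in zip(times, counts))
        for cov, p in EVENT_RISK_FACTORS.items():
            reports = rng.random(len(times)) < p
            rows.extend((sid, cov, t, float(r)) for t, r in zip(times, reports))
    visits = pd.DataFrame(rows, columns=["subject_id", "covariate", "time", "value"])
    return CovariatePanel(panel.frame, visits)


# ---------------------------------------------------------------------------
# cognitive test emulation

#: domain -> tests; reference (mean, SD, higher_is_worse) per test
COGNITIVE_DOMAINS = {
    "psychomotor": ["verbal_fluency", "digit_symbol", "trail_making_b", "grooved_pegboard"],
    "immediate_memory": ["logical_memory_imm", "digit_symbol"],
    "delayed_recall": ["logical_memory_del"],
}
COGNITIVE_REFERENCE = {
    "verbal_fluency": (40.0, 10.0, False),
    "digit_symbol": (55.0, 12.0, False),
    "trail_making_b": (70.0, 25.0, True),
    "grooved_pegboard": (65.0, 12.0, True),
    "logical_memory_imm": (27.0, 6.0, False),
    "logical_memory_del": (24.0, 7.0, False),
}


def generate_cognition(panel: CovariatePanel, index_scores: pd.Series,
                       config: SimConfig, *, loading: float = -0.04,
                       noise_sd: float = 0.8) -> pd.DataFrame:
    """Raw cognitive test scores correlated with an atrophy index.

    Each test's z-scale signal is ``loading * index`` plus subject and test
    noise, mapped back to the raw test scale (sign-flipped for timed tests
    where higher raw = worse).  Returns a subjects x tests DataFrame.
    """
    rng = np.random.default_rng([config.seed, 4])
    idx = index_scores.reindex(panel.subjects).to_numpy(dtype=float)
    ability = loading * idx + rng.normal(0.0, noise_sd, size=len(idx))
    out = {}
    for test, (mu, sd, worse) in COGNITIVE_REFERENCE.items():
        z = ability + rng.normal(0.0, 0.5, size=len(idx))
        if worse:
            z = -z
        out[test] = mu + sd * z
    return pd.DataFrame(out, index=panel.subjects)
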