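"""Benchmark routines exercising the pipeline end to end.

Each function regenerates its inputs from the synthetic cohort model, runs
the relevant stages and returns summary numbers: the years-equivalent
worked example, end-to-end recovery of a configured aging offset, removal
of injected batch effects against a direct standardization oracle, the
brain-age/AD-signature dissociation, and the calibration of the
statistical primitives.  Used by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import backward_eliminate, bh_fdr, brain_age_gap_years, covariate_scan
from .cohort import ICV0, _structure, age_trend, generate_cohort, generate_reference_cohort
from .config import SimConfig
from .containers import CONTROL, REFERENCE_CONTROL, STUDY
from .harmonize import apply_combat_gam, fit_combat_gam, two_step_harmonize
from .longitudinal import VisitSeries, time_weighted_mean
from .spare import score_spare, train_spare_ad, train_spare_ba


def _rep_seed(seed: int, k: int) -> int:
    return (seed * 10007 + k) % (2 ** 31 - 1)


def _generating_residuals(cfg: SimConfig, roi, covars) -> np.ndarray:
    """Volumes minus the known covariate curve of the generator."""
    st = _structure(cfg)
    male = (covars.frame["sex"] == "male").to_numpy(dtype=float)
    det = (st["baseline"][None, :]
           + age_trend(covars.frame["age"].to_numpy(), st["k"])
           + st["beta_sex"][None, :] * male[:, None]
           + st["beta_icv"][None, :] * (covars.frame["icv"].to_numpy()[:, None] - ICV0))
    return roi.volumes.to_numpy() - det


# ---------------------------------------------------------------------------

def end_to_end_gap_years(seed: int, n_seeds: int = 20, *,
                         aging_offset_years: float = 6.0) -> list[float]:
    """Recover a configured aging offset through the full pipeline.

    For each replicate: simulate a multi-scanner cohort with the offset and
    a lifespan reference cohort, two-step harmonize, train the brain-age
    model on reference controls, score the study cohort and estimate the
    years-equivalent gap.  Returns the per-replicate estimates.
    """
    gaps = []
    for k in range(n_seeds):
        cfg = SimConfig(n_study=400, n_control=100, n_reference=500,
                        n_ad_cases=100, n_rois=100, n_scanners=10,
                        aging_offset_years=aging_offset_years,
                        seed=_rep_seed(seed, k))
        roi, covars = generate_cohort(cfg)
        ref_roi, ref_covars = generate_reference_cohort(cfg)
        harm, _ = two_step_harmonize(roi, covars, ref_roi, ref_covars)
        ctrl = harm.label == REFERENCE_CONTROL
        model = train_spare_ba(harm.subset(ctrl),
                               ref_covars.subset(ctrl[ctrl].index),
                               seed=_rep_seed(seed, 500 + k))
        scores = score_spare(model, harm.subset(harm.label.isin([STUDY, CONTROL])))
        gaps.append(brain_age_gap_years(scores, covars, roi.scanner).years)
    return gaps


def harmonization_injection_check(seed: int) -> dict:
    """Remove an injected +100 mm^3 / x2 batch effect; compare with the
    direct per-batch standardization oracle.

    Returns the batch-level covariate-adjusted mean difference after
    harmonization (mm^3), the residual SD ratio between batches, and the
    oracle's (exactly zero) mean difference.
    """
    cfg = SimConfig(n_study=500, n_control=100, n_rois=40, n_scanners=2,
                    cohort_shift_sd=0.0, aging_offset_years=0.0,
                    seed=_rep_seed(seed, 3001))
    shifts = np.zeros((2, cfg.n_rois)); shifts[1] = 100.0
    scales = np.ones((2, cfg.n_rois)); scales[1] = 2.0
    roi, covars = generate_cohort(cfg, site_shifts=shifts, site_scales=scales)
    model = fit_combat_gam(roi, covars)
    out = apply_combat_gam(model, roi, covars)

    b = (roi.scanner == "SC02").to_numpy()
    harm_resid = _generating_residuals(cfg, out, covars)
    mean_diff = float((harm_resid[b].mean(axis=0) - harm_resid[~b].mean(axis=0)).mean())
    sd_ratio = float((harm_resid[b].std(axis=0) / harm_resid[~b].std(axis=0)).mean())

    resid = _generating_residuals(cfg, roi, covars)
    oracle = resid.copy()
    for rows in (b, ~b):
        oracle[rows] = (oracle[rows] - oracle[rows].mean(axis=0)) / oracle[rows].std(axis=0)
    oracle_diff = float(np.abs(oracle[b].mean(axis=0) - oracle[~b].mean(axis=0)).max())
    raw_diff = float((resid[b].mean(axis=0) - resid[~b].mean(axis=0)).mean())
    return {"adjusted_mean_diff_mm3": mean_diff, "sd_ratio": sd_ratio,
            "oracle_mean_diff": oracle_diff, "raw_mean_diff_mm3": raw_diff}


def dissociation_check(seed: int, *, aging_offset_years: float = 6.0) -> dict:
    """Pure accelerated aging moves the brain-age gap, not the AD score.

    The aging offset acts on age-sensitive ROIs only (disjoint from the
    AD-signature set), so the study group's brain-age gap should shift by
    about the configured offset while its mean AD score stays within a
    fraction of a control-group SD of the controls'.
    """
    cfg = SimConfig(n_study=400, n_control=100, n_reference=500, n_ad_cases=150,
                    n_rois=100, n_scanners=10,
                    aging_offset_years=aging_offset_years, seed=_rep_seed(seed, 4001))
    roi, covars = generate_cohort(cfg)
    ref_roi, ref_covars = generate_reference_cohort(cfg)
    harm, _ = two_step_harmonize(roi, covars, ref_roi, ref_covars)
    ctrl = harm.label == REFERENCE_CONTROL
    ba = train_spare_ba(harm.subset(ctrl), ref_covars.subset(ctrl[ctrl].index),
                        seed=_rep_seed(seed, 4002))
    ad = train_spare_ad(harm.subset(harm.label.isin([REFERENCE_CONTROL, "reference_ad"])),
                        ref_covars, seed=_rep_seed(seed, 4003))
    study_tab = harm.subset(harm.label.isin([STUDY, CONTROL]))
    ba_scores = score_spare(ba, study_tab)
    ad_scores = score_spare(ad, study_tab)
    study = covars.frame["group"] == STUDY
    gap = ba_scores - covars.frame["age"]
    ad_shift_sd = float((ad_scores[study].mean() - ad_scores[~study].mean())
                        / ad_scores[~study].std())
    gap_years = brain_age_gap_years(ba_scores, covars, roi.scanner).years
    return {"ba_gap_years": float(gap_years),
            "ba_gap_raw_years": float(gap[study].mean() - gap[~study].mean()),
            "ad_shift_sd": ad_shift_sd}


# ---------------------------------------------------------------------------
# statistical primitives

def bh_fdr_brute_force_deviation(seed: int, n_vectors: int = 1000) -> float:
    """Max abs deviation of bh_fdr from the definitional brute force."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 40))
        p = rng.uniform(1e-6, 1.0, m)
        q = bh_fdr(p)
        ranks = np.empty(m, dtype=int)
        ranks[np.argsort(p, kind="stable")] = np.arange(1, m + 1)
        brute = np.array([min(1.0, min(m * pj / rj for pj, rj in zip(p, ranks)
                                       if pj >= pi)) for pi in p])
        worst = max(worst, float(np.abs(q - brute).max()))
    return worst


def covariate_scan_type1_rate(seed: int, n_fits: int = 1000, *,
                              alpha: float = 0.05, n: int = 120) -> float:
    """Fraction of null covariate-scan fits with p < alpha."""
    hits = 0
    for k in range(n_fits):
        rng = np.random.default_rng(_rep_seed(seed, 5000 + k))
        idx = pd.Index([f"P{i:04d}" for i in range(n)])
        data = pd.DataFrame({
            "age": rng.uniform(44, 74, n),
            "male": rng.integers(0, 2, n).astype(float),
            "scanner": [f"SC{j % 4}" for j in range(n)],
            "x": rng.normal(0, 1, n),
        }, index=idx)
        y = pd.Series(0.1 * data["age"] + rng.normal(0, 1, n), index=idx)
        hits += covariate_scan(y, ["x"], data)[0].p < alpha
    return hits / n_fits


def time_weighted_mean_equal_spacing_deviation() -> float:
    """Exact agreement with the arithmetic mean under equal visit spacing."""
    values = [3.0, 7.0, 5.0, 9.0]
    s = VisitSeries("s", "hba1c", (2.0, 4.0, 6.0, 8.0), tuple(values))
    return abs(time_weighted_mean(s) - float(np.mean(values)))


def backward_elimination_rates(seed: int, n_runs: int = 100) -> dict:
    """Retention of a 0.5-SD candidate and drop rates of three nulls."""
    strong_kept, null_kept = 0, 0
    for k in range(n_runs):
        rng = np.random.default_rng(_rep_seed(seed, 6000 + k))
        n = 500
        idx = pd.Index([f"P{i:04d}" for i in range(n)])
        data = pd.DataFrame({
            "age": rng.uniform(44, 74, n),
            "male": rng.integers(0, 2, n).astype(float),
            "scanner": [f"SC{j % 4}" for j in range(n)],
        }, index=idx)
        for c in ("c1", "c2", "c3", "c4"):
            data[c] = rng.normal(0, 1, n)
        y = pd.Series(0.5 * data["c1"] + rng.normal(0, 1, n), index=idx)
        kept, _ = backward_eliminate(y, ["c1", "c2", "c3", "c4"], data)
        strong_kept += "c1" in kept
        null_kept += len(set(kept) - {"c1"})
    return {"strong_retention_rate": strong_kept / n_runs,
            "null_drop_rate": 1.0 - null_kept / (3 * n_runs)}
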