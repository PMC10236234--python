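"""ComBat-GAM location/scale harmonization of multi-site ROI volumes.

Per ROI *v* the observed volume is modelled as

    y_iv = alpha_v + f_v(age_i) + x_i' beta_v + sigma_v (gamma_iv + delta_iv eps_iv)

where ``f_v`` is a penalized cubic B-spline age trend (smoothing chosen by
generalized cross-validation), ``x_i`` are linear covariates (sex, ICV,
diagnosis, ...), and ``gamma_iv`` / ``delta_iv`` are per-batch additive and
multiplicative effects on the standardized residuals.  Batch effects are
shrunk by parametric empirical Bayes — a normal prior on the location
effects and an inverse-gamma prior on the squared scale effects, with prior
moments estimated across ROIs within each batch and posterior estimates
iterated to convergence — and then removed:

    y*_iv = sigma_v ((z_iv - gamma*_iv) / delta*_iv) + alpha_v + f_v(age_i) + x_i' beta_v

With a designated reference batch, effects are expressed relative to that
batch so its data pass through unchanged; this is how study data are mapped
into the space of a fixed reference cohort in the second harmonization
step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .containers import (
    CONTROL,
    CovariatePanel,
    REFERENCE_AD,
    REFERENCE_CONTROL,
    ROITable,
    STUDY,
)
from .errors import BrainageError, ConvergenceError, RosterMismatchError

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1

#: spline settings: cubic basis, 10 basis functions before the
#: partition-of-unity column drop
SPLINE_DEGREE = 3
N_BASIS = 10
#: GCV grid for the smoothing parameter
LAMBDA_GRID = tuple(10.0 ** k for k in np.linspace(-2, 8, 11))
#: empirical-Bayes iteration controls
EB_TOL = 1e-4
EB_MAX_ITER = 100


# ---------------------------------------------------------------------------
# spline basis

def _spline_knots(age: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo, hi = float(np.min(age)), float(np.max(age))
    n_interior = N_BASIS - SPLINE_DEGREE - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(age, qs)
    return interior, lo, hi


def _basis_matrix(age: np.ndarray, interior: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Cubic B-spline design rows, linearly extrapolated outside [lo, hi]."""
    t = np.concatenate([[lo] * (SPLINE_DEGREE + 1), interior, [hi] * (SPLINE_DEGREE + 1)])
    n_basis = len(t) - SPLINE_DEGREE - 1
    age = np.asarray(age, dtype=float)
    inside = np.clip(age, lo, hi)
    B = np.empty((len(age), n_basis))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        sp = BSpline(t, c, SPLINE_DEGREE, extrapolate=False)
        B[:, j] = sp(inside)
        out_lo, out_hi = age < lo, age > hi
        if out_lo.any():
            B[out_lo, j] = sp(lo) + sp.derivative()(lo) * (age[out_lo] - lo)
        if out_hi.any():
            B[out_hi, j] = sp(hi) + sp.derivative()(hi) * (age[out_hi] - hi)
    np.nan_to_num(B, copy=False)
    return B


def _second_diff_penalty(q: int) -> np.ndarray:
    D = np.diff(np.eye(q), n=2, axis=0)
    return D.T @ D


# ---------------------------------------------------------------------------
# linear covariate design

#: cohort label -> clinical diagnosis used as harmonization covariate.
#: Controls from either cohort share one level so diagnosis is not
#: confounded with the cohort batch in the second harmonization step.
DIAGNOSIS_OF_GROUP = {STUDY: "case", CONTROL: "control",
                      REFERENCE_CONTROL: "control", REFERENCE_AD: "ad"}


def _diagnosis_series(groups: pd.Series) -> pd.Series:
    return groups.map(lambda g: DIAGNOSIS_OF_GROUP.get(g, g))


def _diagnosis_levels(diag: pd.Series) -> list[str]:
    levels = sorted(diag.unique())
    if "control" in levels:
        levels.remove("control")
        levels.insert(0, "control")
    return levels


def _linear_design(frame: pd.DataFrame, roster: list[str],
                   diagnosis_levels: list[str] | None,
                   scalers: dict[str, tuple[float, float]] | None):
    """Expand the covariate roster (minus age) into a numeric design matrix.

    Numeric covariates are standardized by fit-time mean/SD (stored in
    ``scalers``); ``sex`` becomes a male indicator; ``diagnosis`` a one-hot
    over group levels with the control level as reference.
    """
    cols, names = [], []
    fit_mode = scalers is None
    scalers = {} if fit_mode else scalers
    for cov in roster:
        if cov == "age":
            continue
        if cov == "sex":
            if "sex" not in frame:
                raise RosterMismatchError("covariate 'sex' missing from panel")
            cols.append((frame["sex"] == "male").to_numpy(dtype=float))
            names.append("sex[male]")
        elif cov == "diagnosis":
            diag = _diagnosis_series(frame["group"])
            if diagnosis_levels is None:
                diagnosis_levels = _diagnosis_levels(diag)
            unseen = set(diag.unique()) - set(diagnosis_levels)
            if unseen:
                raise RosterMismatchError(f"diagnosis levels not seen at fit: {sorted(unseen)}")
            for lev in diagnosis_levels[1:]:
                cols.append((diag == lev).to_numpy(dtype=float))
                names.append(f"diagnosis[{lev}]")
        else:
            if cov not in frame:
                raise RosterMismatchError(f"covariate '{cov}' missing from panel")
            x = frame[cov].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise BrainageError(f"covariate '{cov}' has missing values")
            if fit_mode:
                m, s = float(x.mean()), float(x.std())
                scalers[cov] = (m, s if s > 0 else 1.0)
            m, s = scalers[cov]
            cols.append((x - m) / s)
            names.append(cov)
    X = np.column_stack(cols) if cols else np.empty((len(frame), 0))
    return X, names, diagnosis_levels, scalers


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by pivoted QR
        from scipy.linalg import qr
        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [names[piv[j]] for j in range(len(diag))
               if diag[j] < 1e-8 * max(diag[0], 1.0)] or [names[piv[-1]]]
        raise BrainageError(f"rank-deficient design; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# empirical Bayes

def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (2 * s2 + m ** 2) / s2 if s2 > 0 else 2.0

def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (m * s2 + m ** 3) / s2 if s2 > 0 else m


def _eb_batch(z_batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shrink one batch's per-ROI location/scale estimates across ROIs.

    ``z_batch`` is the (n_i x V) block of standardized residuals.  Returns
    (gamma_star, delta2_star) after iterating the posterior-mean equations
    to convergence.
    """
    n = z_batch.shape[0]
    g_hat = z_batch.mean(axis=0)
    d2_hat = z_batch.var(axis=0, ddof=1)
    g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
    a, b = _aprior(d2_hat), _bprior(d2_hat)
    g_old, d2_old = g_hat.copy(), d2_hat.copy()
    change = np.inf
    for _ in range(EB_MAX_ITER):
        if t2 > 0:
            g_new = (t2 * n * g_hat + d2_old * g_bar) / (t2 * n + d2_old)
        else:
            g_new = np.full_like(g_hat, g_bar)
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d2_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
            np.max(np.abs(d2_new - d2_old) / (np.abs(d2_old) + 1e-12)),
        )
        g_old, d2_old = g_new, d2_new
        if change < EB_TOL:
            return g_new, d2_new
    raise ConvergenceError(
        f"empirical-Bayes iterations did not converge after {EB_MAX_ITER} steps "
        f"(last relative change {change:.3e})")


# ---------------------------------------------------------------------------
# model container

@dataclass
class HarmonizationModel:
    """Fitted ComBat-GAM model: covariate effects + per-batch EB effects."""

    roi_names: list[str]
    batch_levels: list[str]
    batch_sizes: list[int]
    covariate_roster: list[str]
    linear_names: list[str]
    diagnosis_levels: list[str] | None
    scalers: dict[str, tuple[float, float]]
    alpha: np.ndarray            # (V,) grand intercept, mm^3
    linear_coefs: np.ndarray     # (p_lin, V)
    spline_coefs: np.ndarray     # (q, V)
    spline_interior: np.ndarray
    spline_lo: float
    spline_hi: float
    spline_col_means: np.ndarray  # (q,)
    sigma: np.ndarray            # (V,) pooled residual SD
    gamma_star: np.ndarray       # (I, V) additive effects, standardized units
    delta_star: np.ndarray       # (I, V) multiplicative effects (> 0)
    reference_batch: str | None = None
    schema_version: int = MODEL_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if np.any(self.delta_star <= 0):
            raise BrainageError("delta* must be strictly positive")

    # -- prediction of the covariate part -----------------------------------
    def stand_mean(self, covars: CovariatePanel) -> np.ndarray:
        """alpha + f(age) + X beta for every subject (n x V)."""
        frame = covars.frame
        age = frame["age"].to_numpy(dtype=float)
        if (age < self.spline_lo).any() or (age > self.spline_hi).any():
            n_out = int(((age < self.spline_lo) | (age > self.spline_hi)).sum())
            logger.warning(
                "%d subject(s) outside fitted age range [%.1f, %.1f]; "
                "linear extrapolation of the age trend", n_out, self.spline_lo, self.spline_hi)
        B = _basis_matrix(age, self.spline_interior, self.spline_lo, self.spline_hi)
        B = B[:, 1:] - self.spline_col_means[None, :]
        X, names, _, _ = _linear_design(frame, self.covariate_roster,
                                        self.diagnosis_levels, self.scalers)
        if names != self.linear_names:
            raise RosterMismatchError(
                f"covariate roster mismatch: fitted {self.linear_names}, got {names}")
        return self.alpha[None, :] + B @ self.spline_coefs + X @ self.linear_coefs

    # -- serialization -------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        d = {
            "schema_version": self.schema_version,
            "roi_names": self.roi_names,
            "batch_levels": self.batch_levels,
            "batch_sizes": self.batch_sizes,
            "covariate_roster": self.covariate_roster,
            "linear_names": self.linear_names,
            "diagnosis_levels": self.diagnosis_levels,
            "scalers": {k: list(v) for k, v in self.scalers.items()},
            "alpha": self.alpha.tolist(),
            "linear_coefs": self.linear_coefs.tolist(),
            "spline_coefs": self.spline_coefs.tolist(),
            "spline_interior": self.spline_interior.tolist(),
            "spline_lo": self.spline_lo,
            "spline_hi": self.spline_hi,
            "spline_col_means": self.spline_col_means.tolist(),
            "sigma": self.sigma.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "reference_batch": self.reference_batch,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "HarmonizationModel":
        d = json.loads(Path(path).read_text())
        if d.pop("schema_version") != MODEL_SCHEMA_VERSION:
            raise BrainageError("unsupported harmonization model schema version")
        for key in ("alpha", "linear_coefs", "spline_coefs", "spline_interior",
                    "spline_col_means", "sigma", "gamma_star", "delta_star"):
            d[key] = np.asarray(d[key], dtype=float)
        d["scalers"] = {k: tuple(v) for k, v in d["scalers"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# fitting

def _resolve_batch(roi: ROITable, covars: CovariatePanel, batch_key: str) -> pd.Series:
    if batch_key == "scanner":
        return roi.scanner
    if batch_key in covars.frame.columns:
        return covars.frame[batch_key].reindex(roi.subjects)
    raise BrainageError(f"unknown batch key '{batch_key}'")


def fit_combat_gam(roi: ROITable, covars: CovariatePanel, *,
                   batch_key: str = "scanner",
                   covariate_roster: list[str] = ("age", "sex", "icv", "diagnosis"),
                   reference_batch: str | None = None) -> HarmonizationModel:
    """Fit the ComBat-GAM model on one data set.

    Pools all batches to estimate the covariate model (penalized-spline age
    trend + linear terms), standardizes residuals, and shrinks per-batch
    location/scale estimates by parametric empirical Bayes.  With
    ``reference_batch`` set, effects are expressed relative to that batch.
    """
    covariate_roster = list(covariate_roster)
    frame = covars.frame.reindex(roi.subjects)
    if frame.isna().any().any():
        n_drop = int(frame.isna().any(axis=1).sum())
        logger.warning("dropping %d subject(s) with missing covariates", n_drop)
        keep = frame.index[~frame.isna().any(axis=1)]
        roi = roi.subset(keep)
        frame = frame.loc[keep]
        covars = CovariatePanel(frame, covars.visits)
    batch = _resolve_batch(roi, covars, batch_key).astype(str)
    levels = sorted(batch.unique())
    sizes = [int((batch == b).sum()) for b in levels]
    for b, n_b in zip(levels, sizes):
        if n_b < 3:
            raise BrainageError(f"batch '{b}' has {n_b} subjects; need at least 3")
    if reference_batch is not None and reference_batch not in levels:
        raise BrainageError(f"reference batch '{reference_batch}' not present in data")

    Y = roi.volumes.to_numpy(dtype=float)
    n, V = Y.shape
    age = frame["age"].to_numpy(dtype=float)
    interior, lo, hi = _spline_knots(age)
    B_full = _basis_matrix(age, interior, lo, hi)
    B = B_full[:, 1:]                        # drop 1 column: basis sums to one
    col_means = B.mean(axis=0)
    B = B - col_means[None, :]
    X_lin, lin_names, diag_levels, scalers = _linear_design(
        frame, covariate_roster, None, None)
    onehot = np.column_stack([(batch == b).to_numpy(dtype=float) for b in levels])
    _check_rank(np.column_stack([onehot, X_lin]) if X_lin.size else onehot,
                [f"batch[{b}]" for b in levels] + lin_names)

    q, p_lin, I = B.shape[1], X_lin.shape[1], len(levels)
    D = np.column_stack([onehot, X_lin, B])
    P = np.zeros((D.shape[1], D.shape[1]))
    P[I + p_lin:, I + p_lin:] = _second_diff_penalty(q)

    # per-ROI smoothing via GCV on a shared design (vectorized over ROIs)
    DtD, DtY = D.T @ D, D.T @ Y
    best_gcv = np.full(V, np.inf)
    best_coef = np.zeros((D.shape[1], V))
    for lam in LAMBDA_GRID:
        M = DtD + lam * P
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            continue
        coef = Minv @ DtY
        edf = float(np.trace(Minv @ DtD))
        rss = ((Y - D @ coef) ** 2).sum(axis=0)
        gcv = n * rss / max(n - edf, 1.0) ** 2
        better = gcv < best_gcv
        best_gcv = np.where(better, gcv, best_gcv)
        best_coef[:, better] = coef[:, better]

    gamma_ols = best_coef[:I]                # (I, V) per-batch intercepts
    beta = best_coef[I:I + p_lin]            # (p_lin, V)
    theta = best_coef[I + p_lin:]            # (q, V)

    w = np.asarray(sizes, dtype=float) / n
    if reference_batch is not None:
        alpha = gamma_ols[levels.index(reference_batch)]
    else:
        alpha = w @ gamma_ols
    stand_mean = alpha[None, :] + X_lin @ beta + B @ theta

    resid_full = Y - D @ best_coef           # residuals net of batch intercepts
    if reference_batch is not None:
        ref_rows = (batch == reference_batch).to_numpy()
        sigma2 = (resid_full[ref_rows] ** 2).mean(axis=0)
    else:
        sigma2 = (resid_full ** 2).mean(axis=0)
    sigma = np.sqrt(np.maximum(sigma2, 1e-12))

    if I == 1:
        gamma_star = np.zeros((1, V))
        delta_star = np.ones((1, V))
    else:
        Z = (Y - stand_mean) / sigma[None, :]
        gamma_star = np.empty((I, V))
        delta_star = np.empty((I, V))
        for i, b in enumerate(levels):
            rows = (batch == b).to_numpy()
            g, d2 = _eb_batch(Z[rows])
            gamma_star[i] = g
            delta_star[i] = np.sqrt(np.maximum(d2, 1e-12))
        if reference_batch is not None:
            r = levels.index(reference_batch)
            gamma_star[r] = 0.0
            delta_star[r] = 1.0

    return HarmonizationModel(
        roi_names=roi.roi_names, batch_levels=levels, batch_sizes=sizes,
        covariate_roster=covariate_roster, linear_names=lin_names,
        diagnosis_levels=diag_levels, scalers=scalers,
        alpha=np.asarray(alpha, dtype=float), linear_coefs=beta, spline_coefs=theta,
        spline_interior=np.asarray(interior, dtype=float), spline_lo=lo, spline_hi=hi,
        spline_col_means=col_means, sigma=sigma,
        gamma_star=gamma_star, delta_star=delta_star, reference_batch=reference_batch)


def apply_combat_gam(model: HarmonizationModel, roi: ROITable,
                     covars: CovariatePanel, *, batch_key: str = "scanner") -> ROITable:
    """Remove fitted batch effects from a table; shape and keys preserved.

    Rows belonging to the model's reference batch (if any) are returned
    unchanged.
    """
    if roi.roi_names != model.roi_names:
        missing = set(model.roi_names) - set(roi.roi_names)
        extra = set(roi.roi_names) - set(model.roi_names)
        raise RosterMismatchError(
            f"ROI roster mismatch (missing {sorted(missing)}, extra {sorted(extra)})")
    frame = covars.frame.reindex(roi.subjects)
    batch = _resolve_batch(roi, CovariatePanel(frame, covars.visits), batch_key).astype(str)
    unknown = set(batch.unique()) - set(model.batch_levels)
    if unknown:
        raise BrainageError(f"batch label(s) not seen at fit time: {sorted(unknown)}")

    Y = roi.volumes.to_numpy(dtype=float)
    stand_mean = model.stand_mean(CovariatePanel(frame, covars.visits))
    Z = (Y - stand_mean) / model.sigma[None, :]
    idx = np.array([model.batch_levels.index(b) for b in batch])
    adj = (Z - model.gamma_star[idx]) / model.delta_star[idx]
    out = adj * model.sigma[None, :] + stand_mean
    out = np.maximum(out, 1.0)
    if model.reference_batch is not None:
        ref_rows = (batch == model.reference_batch).to_numpy()
        out[ref_rows] = Y[ref_rows]          # reference maps to itself, bit-identical
    vols = pd.DataFrame(out, index=roi.subjects, columns=roi.roi_names)
    return roi.with_volumes(vols)


COHORT_BATCH = "cohort"


def two_step_harmonize(study_roi: ROITable, study_covars: CovariatePanel,
                       reference_roi: ROITable, reference_covars: CovariatePanel, *,
                       step1_covariates=("age", "sex", "icv", "diagnosis"),
                       step2_covariates=("age", "sex", "diagnosis"),
                       reference_batch_mode: bool = True,
                       ) -> tuple[ROITable, dict[str, HarmonizationModel]]:
    """Two-step harmonization: across study scanners, then into reference space.

    Step 1 removes scanner effects within the study data (covariates: age,
    sex, ICV, diagnosis).  Step 2 treats the pooled study data and the
    reference cohort as two batches (covariates: age, sex, diagnosis) with
    the reference cohort as the reference batch, so study data are mapped
    into the reference space and reference data pass through unchanged.
    Returns the combined harmonized table plus the two fitted models.
    """
    m1 = fit_combat_gam(study_roi, study_covars, batch_key="scanner",
                        covariate_roster=list(step1_covariates))
    step1 = apply_combat_gam(m1, study_roi, study_covars)

    combined_roi = step1.concat(reference_roi)
    combined_frame = pd.concat([study_covars.frame, reference_covars.frame])
    combined_frame = combined_frame.copy()
    combined_frame[COHORT_BATCH] = np.where(
        combined_frame.index.isin(study_covars.subjects), "STUDY_POOL", "REF")
    combined = CovariatePanel(combined_frame)

    m2 = fit_combat_gam(combined_roi, combined, batch_key=COHORT_BATCH,
                        covariate_roster=list(step2_covariates),
                        reference_batch="REF" if reference_batch_mode else None)
    harmonized = apply_combat_gam(m2, combined_roi, combined, batch_key=COHORT_BATCH)
    return harmonized, {"step1": m1, "step2": m2}
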