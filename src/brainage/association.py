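"""Association analyses: group differences, the years-equivalent statistic,
covariate scans, backward elimination, regional FDR scans and cognition.

Group comparisons of the SPARE indices use linear mixed models with a
random intercept per scanner; covariate and cognition scans use ordinary
least squares with scanner fixed effects, always adjusted for age and sex
(plus education for cognition).  The years-equivalent brain-aging statistic
expresses a group difference in an index as additional years of aging by
taking the ratio of the group coefficient to the age coefficient from one
mixed model containing both, with a delta-method standard error.  Regional
scans apply Benjamini–Hochberg FDR control across ROIs.

All p-values are two-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .containers import CONTROL, CovariatePanel, ROITable, STUDY
from .errors import BrainageError

logger = logging.getLogger(__name__)


@dataclass
class AssociationRecord:
    """One covariate-outcome association: beta, SE, t, p (optional FDR q)."""

    outcome: str
    covariate: str
    beta: float
    se: float
    t: float
    p: float
    q: float | None = None
    n: int = 0
    model_roster: tuple[str, ...] = ()
    effect_size: float | None = None
    note: str = ""


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Tidy one-record-per-row table of association results."""
    return pd.DataFrame([{
        "outcome": r.outcome, "covariate": r.covariate, "beta": r.beta,
        "se": r.se, "t": r.t, "p": r.p, "q": r.q, "n": r.n,
        "effect_size": r.effect_size,
        "model": "+".join(r.model_roster), "note": r.note,
    } for r in records])


@dataclass
class GapEstimate:
    """Years-equivalent brain-aging statistic: beta_group / beta_age."""

    years: float
    se_years: float
    beta_group: float
    se_group: float
    beta_age: float
    se_age: float


def years_equivalent(beta_group: float, beta_age: float, *,
                     se_group: float = np.nan, se_age: float = np.nan,
                     cov_group_age: float = 0.0) -> GapEstimate:
    """Ratio-of-coefficients statistic with a delta-method SE.

    ``years = beta_group / beta_age``; the SE propagates the coefficient
    covariance by the first-order delta method (NaN when SEs are unknown,
    e.g. when computing the statistic from printed coefficients alone).
    """
    if beta_age <= 0:
        raise BrainageError(
            f"age coefficient must be positive for a years-equivalent statistic, "
            f"got {beta_age}; the brain-age model is degenerate")
    years = beta_group / beta_age
    var = ((se_group / beta_age) ** 2
           + (beta_group ** 2 / beta_age ** 4) * se_age ** 2
           - 2.0 * (beta_group / beta_age ** 3) * cov_group_age)
    se_years = float(np.sqrt(var)) if np.isfinite(var) else np.nan
    return GapEstimate(float(years), se_years, float(beta_group), float(se_group),
                       float(beta_age), float(se_age))


# ---------------------------------------------------------------------------
# model helpers

def _model_frame(scores: pd.Series, covars: CovariatePanel, scanner: pd.Series,
                 extra: dict[str, pd.Series] | None = None) -> pd.DataFrame:
    frame = covars.frame
    df = pd.DataFrame({
        "score": scores.reindex(frame.index),
        "is_study": (frame["group"] == STUDY).astype(float),
        "age": frame["age"].astype(float),
        "male": (frame["sex"] == "male").astype(float),
        "scanner": scanner.reindex(frame.index).astype(str),
    }, index=frame.index)
    if "icv" in frame:
        df["icv"] = frame["icv"].astype(float)
    if "education" in frame:
        df["education"] = frame["education"].astype(float)
    if extra:
        for k, v in extra.items():
            df[k] = v.reindex(frame.index)
    return df.dropna(subset=["score"])


def _mixed_fit(formula: str, df: pd.DataFrame):
    """Mixed model with a random scanner intercept; OLS fallback for a
    single scanner."""
    if df["scanner"].nunique() < 2:
        logger.warning("single scanner present; falling back to fixed-effects OLS")
        return smf.ols(formula, data=df).fit(), False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.mixedlm(formula, data=df, groups=df["scanner"]).fit(reml=True)
    return res, True


def fit_group_difference(scores: pd.Series, covars: CovariatePanel,
                         scanner: pd.Series, *, outcome: str = "score",
                         ) -> AssociationRecord:
    """Group mean difference in an index, adjusted for age and sex, with a
    random intercept per scanner."""
    df = _model_frame(scores, covars, scanner)
    if df["is_study"].nunique() < 2:
        raise BrainageError("both groups must be present")
    res, _ = _mixed_fit("score ~ is_study + age + male", df)
    return AssociationRecord(
        outcome=outcome, covariate="group[study vs control]",
        beta=float(res.params["is_study"]), se=float(res.bse["is_study"]),
        t=float(res.tvalues["is_study"]), p=float(res.pvalues["is_study"]),
        n=len(df), model_roster=("group", "age", "sex", "scanner(random)"))


def brain_age_gap_years(scores: pd.Series, covars: CovariatePanel,
                        scanner: pd.Series) -> GapEstimate:
    """Years-equivalent group difference from one mixed model.

    Fits ``score ~ group + age + ICV`` with a random scanner intercept and
    returns beta_group / beta_age with a delta-method SE.
    """
    df = _model_frame(scores, covars, scanner)
    res, _ = _mixed_fit("score ~ is_study + age + icv", df)
    cov = res.cov_params()
    return years_equivalent(
        float(res.params["is_study"]), float(res.params["age"]),
        se_group=float(res.bse["is_study"]), se_age=float(res.bse["age"]),
        cov_group_age=float(cov.loc["is_study", "age"]))


# ---------------------------------------------------------------------------
# covariate scans and backward elimination

_FORCED = ("age", "male")


def _design(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Intercept + forced covariates + scanner fixed effects + candidates."""
    X = pd.DataFrame({"Intercept": 1.0}, index=df.index)
    for c in _FORCED:
        X[c] = df[c]
    scanners = sorted(df["scanner"].unique())
    for s in scanners[1:]:
        X[f"scanner[{s}]"] = (df["scanner"] == s).astype(float)
    for c in columns:
        X[c] = df[c]
    return X


def _ols_record(outcome_name: str, y: pd.Series, X: pd.DataFrame,
                term: str, roster: tuple[str, ...]) -> AssociationRecord:
    res = sm.OLS(y, X).fit()
    return AssociationRecord(
        outcome=outcome_name, covariate=term,
        beta=float(res.params[term]), se=float(res.bse[term]),
        t=float(res.tvalues[term]), p=float(res.pvalues[term]),
        n=int(res.nobs), model_roster=roster)


def covariate_scan(outcome: pd.Series, covariates: list[str],
                   data: pd.DataFrame, *, outcome_name: str = "score",
                   ) -> list[AssociationRecord]:
    """One adjusted model per covariate of interest.

    ``data`` must hold the numeric covariate columns plus ``age``, ``male``
    and ``scanner``.  Each covariate is tested in its own OLS model
    adjusted for age, sex and scanner (fixed effects); records are returned
    in input order.  Constant covariates are flagged, not fitted.
    """
    out = []
    roster = ("covariate", "age", "sex", "scanner")
    for cov in covariates:
        x = data[cov]
        sub = data.dropna(subset=[cov])
        y = outcome.reindex(sub.index)
        keep = y.notna()
        sub, y = sub[keep], y[keep]
        if sub[cov].nunique() <= 1:
            out.append(AssociationRecord(
                outcome=outcome_name, covariate=cov, beta=np.nan, se=np.nan,
                t=np.nan, p=np.nan, n=len(sub), model_roster=roster,
                note="constant covariate; not fitted"))
            continue
        X = _design(sub, [cov])
        out.append(_ols_record(outcome_name, y, X, cov, roster))
    return out


def backward_eliminate(outcome: pd.Series, candidates: list[str],
                       data: pd.DataFrame, *, outcome_name: str = "score",
                       retain_p: float = 0.10, final_p: float = 0.05,
                       ) -> tuple[list[str], list[AssociationRecord]]:
    """Backward elimination of candidate covariates.

    Candidates are fitted jointly with the forced covariates (age, sex,
    scanner fixed effects).  At each step the least-significant candidate
    with p >= ``retain_p`` is removed and the model refitted; once all
    remaining candidates have p < ``retain_p``, candidates with
    p >= ``final_p`` are dropped and the model refitted once.  Forced
    covariates are never removed.  Returns the retained candidate names
    and their records from the final model.
    """
    sub = data.dropna(subset=candidates) if candidates else data
    y = outcome.reindex(sub.index)
    keep = y.notna()
    sub, y = sub[keep], y[keep]
    if candidates:
        cand_mat = sub[candidates].to_numpy(dtype=float)
        full = np.column_stack([np.ones(len(sub)), sub[list(_FORCED)].to_numpy(), cand_mat])
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise BrainageError(f"collinear candidate set: {candidates}")

    def fit(cols: list[str]):
        X = _design(sub, cols)
        if len(sub) <= X.shape[1]:
            raise BrainageError("more parameters than observations")
        return sm.OLS(y, X).fit()

    current = list(candidates)
    while current:
        res = fit(current)
        pvals = {c: float(res.pvalues[c]) for c in current}
        # remove the largest p >= retain_p; ties by name for determinism
        worst = max(sorted(current), key=lambda c: pvals[c])
        if pvals[worst] < retain_p:
            break
        current.remove(worst)
    if current:
        res = fit(current)
        current = [c for c in current if float(res.pvalues[c]) < final_p]
    res = fit(current)
    roster = tuple(["age", "sex", "scanner"] + current)
    records = [AssociationRecord(
        outcome=outcome_name, covariate=c,
        beta=float(res.params[c]), se=float(res.bse[c]),
        t=float(res.tvalues[c]), p=float(res.pvalues[c]),
        n=int(res.nobs), model_roster=roster) for c in current]
    return current, records


# ---------------------------------------------------------------------------
# FDR and regional scans

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg q-values.

    q_i = min over j with p_j >= p_i of (m * p_j / rank_j), monotone by
    construction; ties share ranks by stable sort order.  Requires every
    p in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise BrainageError("p-value vector must be one-dimensional and non-empty")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise BrainageError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def roi_group_scan(roi: ROITable, covars: CovariatePanel,
                   ) -> list[AssociationRecord]:
    """Per-ROI group difference scan with BH-FDR across ROIs.

    For every ROI fits ``volume ~ group + age + sex + ICV + scanner`` (all
    fitted at once on the shared design) and reports the group term with a
    standardized effect size (beta / residual SD) and its q-value.
    """
    frame = covars.frame.reindex(roi.subjects)
    df = pd.DataFrame({
        "is_study": (frame["group"] == STUDY).astype(float),
        "age": frame["age"].astype(float),
        "male": (frame["sex"] == "male").astype(float),
        "icv": frame["icv"].astype(float),
        "scanner": roi.scanner.astype(str),
    }, index=roi.subjects)
    scanners = sorted(df["scanner"].unique())
    X = np.column_stack(
        [np.ones(len(df)), df["is_study"], df["age"], df["male"], df["icv"]]
        + [(df["scanner"] == s).to_numpy(dtype=float) for s in scanners[1:]])
    Y = roi.volumes.to_numpy(dtype=float)
    n, k = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ Y                       # (k, V)
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[1, 1])
    b = beta[1]
    t = b / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = bh_fdr(p)
    eff = b / np.sqrt(sigma2)
    roster = ("group", "age", "sex", "icv", "scanner")
    return [AssociationRecord(
        outcome=name, covariate="group[study vs control]",
        beta=float(b[j]), se=float(se[j]), t=float(t[j]), p=float(p[j]),
        q=float(q[j]), n=n, model_roster=roster, effect_size=float(eff[j]))
        for j, name in enumerate(roi.roi_names)]


# ---------------------------------------------------------------------------
# cognition

def cognition_domain_scores(raw_tests: pd.DataFrame,
                            reference_stats: dict[str, tuple[float, float, bool]],
                            domains: dict[str, list[str]]) -> pd.DataFrame:
    """Standardize tests against reference means/SDs and average per domain.

    ``reference_stats`` maps test name to (mean, SD, higher_is_worse);
    z-scores of tests where a higher raw score means worse performance are
    sign-flipped so higher z always means better.  A subject missing some
    tests of a domain gets the mean of the available ones (logged); missing
    all of them gets NaN.
    """
    z = pd.DataFrame(index=raw_tests.index)
    for test, (mu, sd, worse) in reference_stats.items():
        if sd <= 0:
            raise BrainageError(f"reference SD for '{test}' must be positive")
        if test not in raw_tests:
            continue
        zt = (raw_tests[test] - mu) / sd
        z[test] = -zt if worse else zt
    out = pd.DataFrame(index=raw_tests.index)
    for domain, tests in domains.items():
        present = [t for t in tests if t in z.columns]
        if not present:
            raise BrainageError(f"no tests available for domain '{domain}'")
        block = z[present]
        n_partial = int((block.isna().any(axis=1) & block.notna().any(axis=1)).sum())
        if n_partial:
            logger.warning("domain '%s': %d subject(s) missing some tests; "
                           "averaging available tests", domain, n_partial)
        out[domain] = block.mean(axis=1, skipna=True)
    return out


def cognition_association(domain_scores: pd.Series, index_scores: pd.Series,
                          covars: CovariatePanel, scanner: pd.Series, *,
                          outcome_name: str = "cognition",
                          index_name: str = "index") -> AssociationRecord:
    """Association of an MRI index with a cognitive domain score, adjusted
    for age, sex, education and scanner (fixed effects)."""
    if "education" not in covars.frame:
        raise BrainageError("education is required for cognition models")
    df = _model_frame(domain_scores, covars, scanner,
                      extra={index_name: index_scores})
    df = df.dropna(subset=[index_name, "education"])
    X = _design(df, [index_name])
    X["education"] = df["education"]
    return _ols_record(outcome_name, df["score"], X, index_name,
                       (index_name, "age", "sex", "education", "scanner"))
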