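"""Statistical layer: influence filter, outlier scoring, regressions, tests.

Predicted fluxes are log2-transformed and z-scored, then regressed (logistic,
flux as predictor of case/control status) with the standard confounder set:
age (z), sex, six binary lifestyle/medication covariates, and log10+z total
read counts. P-values across metabolites are adjusted by Benjamini-Hochberg.
Cohort description uses Fisher's exact test (binary covariates) and the
Wilcoxon rank-sum test (numeric covariates). Outlier samples are scored by an
alternating-least-squares PCA on z-scored fluxes that tolerates missing cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "RegressionResult",
    "filter_metabolites_by_influence",
    "detect_outliers",
    "transform_fluxes",
    "flux_logistic_regression",
    "bh_fdr",
    "fisher_2x2",
    "wilcoxon_ranksum",
    "cohort_summary",
    "COVARIATES",
]

logger = logging.getLogger(__name__)

#: binary covariates included in every flux regression
BINARY_COVARIATES = ("alcohol", "laxatives", "antihistamines", "mood_meds",
                     "pain_meds", "sleep_aid")
COVARIATES = ("age", "sex") + BINARY_COVARIATES + ("read_count",)


# -- influence filter --------------------------------------------------------


def filter_metabolites_by_influence(
    influenced: pd.DataFrame,
    min_influenced_fraction: float = 0.05,
    valid: pd.DataFrame | None = None,
) -> list[str]:
    """Keep metabolites microbiome-influenced in more than 5% of samples.

    ``influenced`` is the boolean samples x metabolites flag matrix;
    ``valid`` optionally marks cells with a successful flux prediction
    (missing cells are excluded from the denominator). A metabolite
    influenced in exactly the threshold fraction is removed (the removal rule
    is "not influenced in >= 95% of samples").
    """
    flags = influenced.astype(float)
    if valid is not None:
        flags = flags.where(valid)
    frac = flags.mean(axis=0, skipna=True)
    return [m for m in influenced.columns if frac[m] > min_influenced_fraction]


# -- outlier detection --------------------------------------------------------


def _als_pca(X: np.ndarray, k: int, max_iter: int = 200, tol: float = 1e-9):
    """Rank-k PCA by alternating least squares, tolerating missing cells."""
    mask = np.isfinite(X)
    X0 = np.where(mask, X, 0.0)
    U, s, Vt = np.linalg.svd(X0, full_matrices=False)
    U = U[:, :k] * s[:k]
    V = Vt[:k].T
    if mask.all():
        return U, V
    prev = np.inf
    for _ in range(max_iter):
        for i in range(X.shape[0]):
            obs = mask[i]
            if obs.any():
                U[i], *_ = np.linalg.lstsq(V[obs], X[i, obs], rcond=None)
        for j in range(X.shape[1]):
            obs = mask[:, j]
            if obs.any():
                V[j], *_ = np.linalg.lstsq(U[obs], X[obs, j], rcond=None)
        resid = float(np.nansum((X - U @ V.T) ** 2 * mask))
        if abs(prev - resid) <= tol * max(resid, 1.0):
            break
        prev = resid
    return U, V


def detect_outliers(
    flux_matrix: pd.DataFrame,
    k_iqr: float = 3.0,
    n_components: int = 3,
) -> tuple[pd.Series, list[str]]:
    """Robust-PCA outlier scores on z-transformed fluxes.

    Each sample's score is the Euclidean norm of its principal-component
    scores weighted by the explained-variance fraction of each component;
    samples scoring above Q3 + k_iqr * IQR are flagged.
    """
    if flux_matrix.shape[0] < 3 or flux_matrix.shape[1] < 2:
        raise ValueError("need at least 3 samples and 2 metabolites")
    X = flux_matrix.to_numpy(dtype=float)
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        logger.warning("all metabolites constant: no outliers detectable")
        scores = pd.Series(0.0, index=flux_matrix.index)
        return scores, []
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    k = int(min(n_components, Z.shape[0] - 1, Z.shape[1]))
    U, V = _als_pca(Z, k)
    # orthogonalize the fitted subspace and weight by explained variance
    Uo, s, _ = np.linalg.svd(U @ V.T, full_matrices=False)
    T = Uo[:, :k] * s[:k]
    total = float((s ** 2).sum())
    w = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    scores = pd.Series(np.linalg.norm(T * w, axis=1), index=flux_matrix.index)
    q1, q3 = np.percentile(scores, [25, 75])
    cutoff = q3 + k_iqr * (q3 - q1)
    flagged = list(scores.index[scores > cutoff])
    return scores, flagged


# -- flux transformation and regression ---------------------------------------


def transform_fluxes(flux: pd.Series) -> tuple[pd.Series, float | None]:
    """log2 then z-score; zeros get a half-minimum-positive pseudocount.

    Returns the transformed vector and the pseudocount used (None if no
    zeros were present). Missing cells stay missing.
    """
    v = flux.dropna()
    if (v < 0).any():
        raise ValueError("fluxes must be non-negative")
    if (v == 0).all():
        raise ValueError("all-zero flux vector cannot be transformed")
    eps = None
    if (v == 0).any():
        eps = float(v[v > 0].min()) / 2.0
        logger.info("zero fluxes present: log2 pseudocount eps=%g", eps)
        logv = np.log2(v + eps)
    else:
        logv = np.log2(v)
    sd = logv.std(ddof=0)
    if sd == 0:
        raise ValueError("constant flux vector cannot be z-scored")
    z = (logv - logv.mean()) / sd
    return z.reindex(flux.index), eps


@dataclass
class RegressionResult:
    metabolite: str | None
    term: str
    beta: float
    ci_lo: float
    ci_hi: float
    p: float
    q: float | None = None
    n: int = 0
    converged: bool = True


def _design_matrix(metadata: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=metadata.index)
    age = metadata["age"].astype(float)
    X["age_z"] = (age - age.mean()) / age.std(ddof=0)
    X["sex_male"] = (metadata["sex"] == "male").astype(float)
    for cov in BINARY_COVARIATES:
        X[cov] = metadata[cov].astype(float)
    logreads = np.log10(metadata["read_count"].astype(float))
    X["log_reads_z"] = (logreads - logreads.mean()) / logreads.std(ddof=0)
    return X


def flux_logistic_regression(
    flux: pd.Series,
    metadata: pd.DataFrame,
    interaction: str | None = None,
    metabolite: str | None = None,
) -> list[RegressionResult]:
    """Logistic regression of case/control status on a transformed flux.

    Confounders: age (z), sex, the six binary covariates, log10+z read
    counts. ``interaction`` in {"sex", "age"} adds a flux x interactor term
    whose coefficient is reported alongside the flux term. Samples with a
    missing flux are dropped listwise. Perfect separation or non-convergence
    yields a flagged result without finite estimates.
    """
    if interaction not in (None, "none", "sex", "age"):
        raise ValueError("interaction must be None, 'sex' or 'age'")
    keep = flux.dropna().index.intersection(metadata.index)
    y = (metadata.loc[keep, "diagnosis"] == "PD").astype(float)
    X = _design_matrix(metadata.loc[keep])
    X.insert(0, "flux", flux.loc[keep].astype(float))
    terms = ["flux"]
    if interaction in ("sex", "age"):
        col = "sex_male" if interaction == "sex" else "age_z"
        X[f"flux_x_{interaction}"] = X["flux"] * X[col]
        terms.append(f"flux_x_{interaction}")
    X = sm.add_constant(X, has_constant="add")

    def _flagged() -> list[RegressionResult]:
        return [RegressionResult(metabolite, t, np.nan, np.nan, np.nan, np.nan,
                                 n=len(keep), converged=False) for t in terms]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        logger.warning("regression for %s did not converge (separation?)",
                       metabolite)
        return _flagged()
    if not fit.mle_retvals.get("converged", False) or \
            not np.isfinite(fit.bse[terms]).all():
        return _flagged()
    ci = fit.conf_int(alpha=0.05)  # Wald
    return [
        RegressionResult(metabolite, t, float(fit.params[t]),
                         float(ci.loc[t, 0]), float(ci.loc[t, 1]),
                         float(fit.pvalues[t]), n=len(keep))
        for t in terms
    ]


def bh_fdr(p_values: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    ok = np.isfinite(p)
    if ok.any() and (p[ok].min() < 0 or p[ok].max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# -- cohort description --------------------------------------------------------


@dataclass
class FisherResult:
    odds_ratio: float
    p: float
    ci_lo: float
    ci_hi: float
    zero_cell: bool = False


def fisher_2x2(pd_yes: int, pd_no: int, ctrl_yes: int, ctrl_no: int) -> FisherResult:
    """Sample odds ratio, two-sided Fisher exact p, and Wald 95% CI on log OR."""
    cells = (pd_yes, pd_no, ctrl_yes, ctrl_no)
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    if pd_yes + pd_no == 0 or ctrl_yes + ctrl_no == 0 or \
            pd_yes + ctrl_yes == 0 or pd_no + ctrl_no == 0:
        raise ValueError("every margin must be positive")
    _, p = sps.fisher_exact([[pd_yes, pd_no], [ctrl_yes, ctrl_no]],
                            alternative="two-sided")
    zero = any(c == 0 for c in cells)
    if zero:
        logger.warning("zero cell in 2x2 table: OR/CI unstable, exact p valid")
        odds = np.inf if pd_no * ctrl_yes == 0 else 0.0
        return FisherResult(odds, float(p), np.nan, np.nan, zero_cell=True)
    odds = (pd_yes * ctrl_no) / (pd_no * ctrl_yes)
    se = np.sqrt(sum(1.0 / c for c in cells))
    lo, hi = np.exp(np.log(odds) + np.array([-1.96, 1.96]) * se)
    return FisherResult(float(odds), float(p), float(lo), float(hi))


def wilcoxon_ranksum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum p: exact enumeration when both n <= 10 (no ties),
    normal approximation with mid-rank tie handling otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def cohort_summary(metadata: pd.DataFrame) -> pd.DataFrame:
    """Case/control cohort characteristics table.

    Numeric covariates (age, BMI, read counts) get group means +- SD with a
    Wilcoxon rank-sum p; binary covariates get counts (%) with Fisher OR,
    exact p and 95% CI.
    """
    is_pd = metadata["diagnosis"] == "PD"
    pd_meta, ct_meta = metadata[is_pd], metadata[~is_pd]
    rows = []
    male = fisher_2x2(int((pd_meta["sex"] == "male").sum()),
                      int((pd_meta["sex"] != "male").sum()),
                      int((ct_meta["sex"] == "male").sum()),
                      int((ct_meta["sex"] != "male").sum()))
    rows.append({"variable": "male", "n_pd": len(pd_meta), "n_ctrl": len(ct_meta),
                 "pd_value": f"{(pd_meta['sex'] == 'male').mean():.3f}",
                 "ctrl_value": f"{(ct_meta['sex'] == 'male').mean():.3f}",
                 "p": male.p, "odds_ratio": male.odds_ratio,
                 "ci_lo": male.ci_lo, "ci_hi": male.ci_hi})
    for var in ("age", "bmi", "read_count"):
        if var not in metadata.columns:
            continue
        p = wilcoxon_ranksum(pd_meta[var].to_numpy(), ct_meta[var].to_numpy())
        rows.append({"variable": var, "n_pd": len(pd_meta), "n_ctrl": len(ct_meta),
                     "pd_value": f"{pd_meta[var].mean():.2f} ({pd_meta[var].std(ddof=1):.2f})",
                     "ctrl_value": f"{ct_meta[var].mean():.2f} ({ct_meta[var].std(ddof=1):.2f})",
                     "p": p, "odds_ratio": np.nan, "ci_lo": np.nan,
                     "ci_hi": np.nan})
    for var in BINARY_COVARIATES:
        try:
            res = fisher_2x2(int(pd_meta[var].sum()),
                             int((1 - pd_meta[var]).sum()),
                             int(ct_meta[var].sum()),
                             int((1 - ct_meta[var]).sum()))
            p, odds, lo, hi = res.p, res.odds_ratio, res.ci_lo, res.ci_hi
        except ValueError:  # a margin is empty in a small cohort
            logger.warning("covariate %s has an empty margin; test skipped", var)
            p = odds = lo = hi = np.nan
        rows.append({"variable": var, "n_pd": len(pd_meta), "n_ctrl": len(ct_meta),
                     "pd_value": f"{pd_meta[var].mean():.3f}",
                     "ctrl_value": f"{ct_meta[var].mean():.3f}",
                     "p": p, "odds_ratio": odds, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)
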