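"""Psychometric evaluation: reliability, factorability, EFA, correlations.

Implements the evaluation toolchain for slider-test scores:

* internal consistency — Cronbach's alpha and McDonald's omega-total (from a
  single-common-factor minres solution);
* test-retest reproducibility — ICC(A,1), the single-measure two-way random
  intraclass correlation with absolute agreement, plus Pearson/Spearman;
* factorability — the Kaiser-Meyer-Olkin sampling-adequacy index and
  Bartlett's test of sphericity;
* exploratory factor analysis by the minimum-residual (minres) method with
  factor-count selection by the Kaiser criterion and by parallel analysis;
* Spearman correlation tables with Benjamini-Hochberg FDR control.

Minres EFA minimises the sum of squared off-diagonal residuals of
R - LL' over the uniquenesses; given uniquenesses psi, the loadings L are
the scaled top eigenvectors of R - diag(psi).  RMSEA and BIC use the
normal-theory discrepancy F = ln|Sigma| - ln|R| + tr(R Sigma^-1) - p with
chi2 = (n - 1 - (2p + 5)/6 - 2k/3) * F, df = ((p - k)^2 - (p + k)) / 2,
RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1))) and BIC = chi2 - df ln(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateDataError, FactorConvergenceError, ValidationWarning

__all__ = [
    "ReliabilityReport",
    "FactorReport",
    "CorrelationReport",
    "cronbach_alpha",
    "omega_total",
    "icc_absolute",
    "kmo",
    "bartlett_sphericity",
    "minres_factor",
    "parallel_analysis",
    "efa_minres",
    "spearman_bh",
    "reliability_report",
]

_MIN_UNIQUENESS = 1e-3


def _as_matrix(items) -> np.ndarray:
    x = np.asarray(items, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D respondents x items array")
    return x


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/var(total))."""
    x = _as_matrix(items)
    n, k = x.shape
    if k < 2 or n < 3:
        raise DegenerateDataError("alpha needs >= 2 items and >= 3 respondents")
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise DegenerateDataError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def _single_factor_solution(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-factor minres loadings and uniquenesses from a correlation matrix."""
    loadings, psi, _ = _minres_fit(r, 1)
    return loadings[:, 0], psi


def omega_total(items=None, corr=None) -> float:
    """McDonald's omega-total from a single common factor:
    (sum lambda)^2 / ((sum lambda)^2 + sum psi)."""
    if corr is None:
        corr = np.corrcoef(_as_matrix(items), rowvar=False)
    lam, psi = _single_factor_solution(np.asarray(corr, dtype=float))
    gen = lam.sum() ** 2
    return float(gen / (gen + psi.sum()))


def icc_absolute(
    test, retest, *, average_measures: bool = False
) -> tuple[float, int]:
    """ICC for absolute agreement under a two-way random-effects model.

    Returns the single-measure ICC(A,1) (or average-measures ICC(A,k)) and
    its between-subject degrees of freedom n - 1.  Computed from the two-way
    ANOVA mean squares for subjects (MSR), occasions (MSC) and error (MSE):

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    y = np.column_stack([np.asarray(test, float), np.asarray(retest, float)])
    n, k = y.shape
    if n < 3:
        raise DegenerateDataError("ICC needs at least 3 paired observations")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = np.sum((y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0:
        raise DegenerateDataError("zero between-subject variance")
    if average_measures:
        icc = (msr - mse) / (msr + (msc - mse) / n)
    else:
        icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return float(icc), n - 1


def kmo(corr) -> float:
    """Kaiser-Meyer-Olkin overall measure of sampling adequacy.

    Ratio of summed squared correlations to summed squared correlations plus
    summed squared partial correlations (off-diagonals only).
    """
    r = np.asarray(corr, dtype=float)
    inv = np.linalg.inv(r)
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = np.sum(r[off] ** 2)
    a2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + a2))


def bartlett_sphericity(corr, n_obs: int) -> tuple[float, int, float]:
    """Bartlett's test of sphericity against an identity correlation matrix.

    chi2 = -(n - 1 - (2p + 5)/6) ln|R|, df = p (p - 1) / 2.
    """
    r = np.asarray(corr, dtype=float)
    p = r.shape[0]
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix is not positive definite")
    chi2 = -(n_obs - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def _loadings_from_psi(r: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    reduced = r - np.diag(psi)
    vals, vecs = np.linalg.eigh(reduced)
    order = np.argsort(vals)[::-1][:k]
    lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    # orient each factor so its largest-magnitude loading is positive
    for j in range(lam.shape[1]):
        if lam[np.argmax(np.abs(lam[:, j])), j] < 0:
            lam[:, j] = -lam[:, j]
    return lam


def _minres_fit(
    r: np.ndarray, n_factors: int, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray, float]:
    p = r.shape[0]
    off = ~np.eye(p, dtype=bool)

    def objective(psi: np.ndarray) -> float:
        lam = _loadings_from_psi(r, psi, n_factors)
        resid = r - lam @ lam.T
        return float(np.sum(resid[off] ** 2))

    # start at 1 - squared multiple correlation
    inv_diag = np.diag(np.linalg.inv(r))
    psi0 = np.clip(1.0 / inv_diag, _MIN_UNIQUENESS, 1.0)
    res = optimize.minimize(
        objective,
        psi0,
        method="L-BFGS-B",
        bounds=[(_MIN_UNIQUENESS, 1.0)] * p,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and res.status != 2:  # status 2: precision loss at optimum
        raise FactorConvergenceError(f"minres did not converge: {res.message}")
    psi = res.x
    if np.any(psi <= _MIN_UNIQUENESS * (1 + 1e-6)):
        warnings.warn(
            "Heywood case: uniqueness clamped at the lower bound",
            ValidationWarning,
            stacklevel=3,
        )
    lam = _loadings_from_psi(r, psi, n_factors)
    return lam, psi, float(res.fun)


def minres_factor(corr, n_factors: int) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-residual factor loadings and uniquenesses for ``n_factors``."""
    lam, psi, _ = _minres_fit(np.asarray(corr, dtype=float), n_factors)
    return lam, psi


def parallel_analysis(
    eigenvalues,
    n_obs: int,
    n_vars: int,
    n_iter: int = 100,
    percentile: float = 95.0,
    seed: int | None = 0,
) -> int:
    """Factor count by Horn's parallel analysis.

    Compares observed correlation eigenvalues to the given percentile of
    eigenvalues from ``n_iter`` resamples of uncorrelated standard-normal
    data of the same shape; counts leading factors that exceed the bar.
    """
    rng = np.random.default_rng(seed)
    sims = np.empty((n_iter, n_vars))
    for i in range(n_iter):
        z = rng.standard_normal((n_obs, n_vars))
        sims[i] = np.sort(np.linalg.eigvalsh(np.corrcoef(z, rowvar=False)))[::-1]
    bar = np.percentile(sims, percentile, axis=0)
    observed = np.sort(np.asarray(eigenvalues))[::-1]
    count = 0
    for obs, b in zip(observed, bar):
        if obs > b:
            count += 1
        else:
            break
    return count


@dataclass
class FactorReport:
    """Minres EFA solution with selection and fit diagnostics."""

    loadings: pd.DataFrame
    uniquenesses: pd.Series
    eigenvalues: np.ndarray
    n_factors: int
    n_factors_kaiser: int
    n_factors_parallel: int
    variance_explained: float
    rmsea: float
    bic: float
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


def efa_minres(
    data=None,
    corr=None,
    n_obs: int | None = None,
    n_factors: int | None = None,
    *,
    method: str = "spearman",
    pa_iter: int = 100,
    seed: int | None = 0,
) -> FactorReport:
    """Exploratory factor analysis by the minimum-residual method.

    Accepts either raw scores (``data``, respondents x variables) or a
    correlation matrix with its sample size.  When ``n_factors`` is omitted
    the parallel-analysis count is fitted (falling back to 1).
    """
    if data is not None:
        frame = pd.DataFrame(data)
        names = [str(c) for c in frame.columns]
        n_obs = len(frame)
        r = frame.corr(method=method).to_numpy()
    else:
        r = np.asarray(corr, dtype=float)
        names = [f"v{i + 1}" for i in range(r.shape[0])]
        if n_obs is None:
            raise ValueError("n_obs is required when passing a correlation matrix")
    p = r.shape[0]
    eigs = np.sort(np.linalg.eigvalsh(r))[::-1]
    kaiser = int(np.sum(eigs > 1.0))
    pa = parallel_analysis(eigs, n_obs, p, n_iter=pa_iter, seed=seed)
    k = n_factors if n_factors is not None else max(pa, 1)

    lam, psi, _ = _minres_fit(r, k)
    communal = np.sum(lam**2, axis=1)
    variance_explained = float(communal.sum() / p)

    sigma = lam @ lam.T + np.diag(psi)
    sign, logdet_s = np.linalg.slogdet(sigma)
    _, logdet_r = np.linalg.slogdet(r)
    discrepancy = logdet_s - logdet_r + np.trace(r @ np.linalg.inv(sigma)) - p
    df = ((p - k) ** 2 - (p + k)) / 2.0
    scale = n_obs - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0
    chi2 = max(scale * discrepancy, 0.0)
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n_obs - 1)))) if df > 0 else np.nan
    bic = float(chi2 - df * np.log(n_obs)) if df > 0 else np.nan

    b_chi2, b_df, b_p = bartlett_sphericity(r, n_obs)
    return FactorReport(
        loadings=pd.DataFrame(
            lam, index=names, columns=[f"F{j + 1}" for j in range(k)]
        ),
        uniquenesses=pd.Series(psi, index=names),
        eigenvalues=eigs,
        n_factors=k,
        n_factors_kaiser=kaiser,
        n_factors_parallel=pa,
        variance_explained=variance_explained,
        rmsea=rmsea,
        bic=bic,
        kmo=kmo(r),
        bartlett_chi2=b_chi2,
        bartlett_df=b_df,
        bartlett_p=b_p,
    )


@dataclass
class CorrelationReport:
    """Pairwise Spearman correlations with BH-adjusted significance."""

    rho: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame  # BH-adjusted flags at the given FDR level
    fdr_level: float
    excluded: tuple[str, ...] = ()


def _bh_reject(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject p_(i) <= i/m * q for i up to the
    largest index satisfying the bound."""
    m = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order]
    thresholds = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(ranked <= thresholds)
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


def spearman_bh(table, fdr_level: float = 0.05) -> CorrelationReport:
    """Spearman correlation matrix with one BH family per table.

    Constant columns have undefined rank correlations; they are dropped from
    the family and reported in ``excluded``.
    """
    frame = pd.DataFrame(table)
    constant = [c for c in frame.columns if frame[c].nunique(dropna=True) <= 1]
    frame = frame.drop(columns=constant)
    cols = list(frame.columns)
    p = len(cols)
    rho = pd.DataFrame(np.eye(p), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((p, p)), index=cols, columns=cols)
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    flat_p = np.empty(len(pairs))
    for idx, (i, j) in enumerate(pairs):
        paired = frame.iloc[:, [i, j]].dropna()
        if len(paired) < 3:
            raise DegenerateDataError(
                f"fewer than 3 complete pairs for {cols[i]} vs {cols[j]}"
            )
        r, pv = stats.spearmanr(paired.iloc[:, 0], paired.iloc[:, 1])
        rho.iloc[i, j] = rho.iloc[j, i] = r
        pval.iloc[i, j] = pval.iloc[j, i] = pv
        flat_p[idx] = pv
    reject = _bh_reject(flat_p, fdr_level)
    sig = pd.DataFrame(
        np.zeros((p, p), dtype=bool), index=cols, columns=cols
    )
    for idx, (i, j) in enumerate(pairs):
        sig.iloc[i, j] = sig.iloc[j, i] = bool(reject[idx])
    return CorrelationReport(
        rho=rho,
        p_values=pval,
        significant=sig,
        fdr_level=fdr_level,
        excluded=tuple(str(c) for c in constant),
    )


@dataclass
class ReliabilityReport:
    """Internal consistency and (optional) test-retest reproducibility."""

    cronbach_alpha: float
    omega_total: float
    icc: float | None = None
    icc_df: int | None = None
    retest_pearson: float | None = None
    retest_spearman: float | None = None


def reliability_report(
    item_scores, test_totals=None, retest_totals=None
) -> ReliabilityReport:
    """Alpha and omega from item scores; ICC/r/rho when retest totals given."""
    alpha = cronbach_alpha(item_scores)
    omega = omega_total(item_scores)
    if test_totals is None or retest_totals is None:
        return ReliabilityReport(cronbach_alpha=alpha, omega_total=omega)
    icc, df = icc_absolute(test_totals, retest_totals)
    r = float(stats.pearsonr(test_totals, retest_totals)[0])
    rho = float(stats.spearmanr(test_totals, retest_totals)[0])
    return ReliabilityReport(
        cronbach_alpha=alpha,
        omega_total=omega,
        icc=icc,
        icc_df=df,
        retest_pearson=r,
        retest_spearman=rho,
    )
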