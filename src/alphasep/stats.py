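"""Group-level statistics: t-tests, multiple-comparison corrections,
one-way repeated-measures ANOVA, and partial Spearman correlation.

Conventions: one-tailed t-tests test the greater-than direction (used for
decoding accuracy against chance); Benjamini-Hochberg controls the false
discovery rate across a family of tests; Holm adjustment follows a
significant ANOVA; the partial Spearman correlation rank-transforms all
variables (average ranks for ties), residualises on the covariate — a
categorical covariate such as dataset identity is one-hot encoded
(drop-one) — and correlates the residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    tails: str
    df: float
    n: int


def _check_tails(tails: str) -> None:
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")


def one_sample_t(values, mu0: float = 0.0, tails: str = "two") -> TestResult:
    """One-sample t-test of the mean against ``mu0``.

    ``tails='one'`` tests the greater-than direction (mean > mu0).
    """
    _check_tails(tails)
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    t = (x.mean() - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = sps.t.sf(t, df) if tails == "one" else 2 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(p), tails, float(df), n)


def _check_pvalues(p: np.ndarray) -> None:
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject, p_adjusted)`` in the input order: hypotheses with
    sorted rank i are rejected up to the largest i with
    ``p_(i) <= i * q / m``; adjusted p-values are the step-up minima
    ``min_{j >= i} m * p_(j) / j`` capped at 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    _check_pvalues(p)
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    scaled = ranked * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    below = np.flatnonzero(ranked <= np.arange(1, m + 1) * q / m)
    reject_sorted = np.zeros(m, dtype=bool)
    if below.size:
        reject_sorted[: below[-1] + 1] = True
    reject = np.empty(m, dtype=bool)
    adjusted = np.empty(m)
    reject[order] = reject_sorted
    adjusted[order] = adj_sorted
    return reject, adjusted


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=np.float64)
    _check_pvalues(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    stepped = np.maximum.accumulate((m - np.arange(m)) * ranked)
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(1.0, stepped)
    return adjusted


def rm_anova_oneway(values) -> TestResult:
    """One-way repeated-measures ANOVA on a complete subjects x conditions table.

    F = MS_condition / MS_(condition x subject) with degrees of freedom
    (k - 1, (k - 1)(n - 1)).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D table with >= 2 subjects and >= 2 conditions")
    if np.any(~np.isfinite(x)):
        raise ValueError("table must be complete (no missing cells)")
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        f = np.inf if ms_cond > 0 else 0.0
    else:
        f = ms_cond / ms_err
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return TestResult(float(f), p, "two", float(df1), n)


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def partial_spearman(
    x,
    y,
    covariate,
    tails: str = "two",
    categorical: bool | None = None,
) -> TestResult:
    """Spearman correlation of x and y, partialling out a covariate.

    x, y and a numeric covariate are rank-transformed (average ranks); a
    categorical covariate (detected from a non-numeric dtype, or forced via
    ``categorical=True``) is one-hot encoded with one level dropped. Ranked
    x and y are residualised on the covariate design by least squares and
    the Pearson correlation of the residuals is returned, with p from the t
    approximation on ``n - 2 - c`` degrees of freedom (c = covariate
    columns). ``tails='one'`` tests the positive direction.
    """
    _check_tails(tails)
    x = np.asarray(x)
    y = np.asarray(y)
    cov = np.asarray(covariate)
    n = x.size
    if y.size != n or cov.shape[0] != n:
        raise ValueError("x, y and covariate must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    if categorical is None:
        categorical = cov.dtype.kind in "OUSb"
    if categorical:
        levels = np.unique(cov)
        design = np.column_stack(
            [np.ones(n)] + [(cov == lv).astype(float) for lv in levels[1:]]
        )
    elif cov.ndim == 1:
        design = np.column_stack([np.ones(n), _rank(cov.astype(float))])
    else:
        design = np.column_stack(
            [np.ones(n)] + [_rank(cov[:, j].astype(float)) for j in range(cov.shape[1])]
        )
    c = design.shape[1] - 1
    rx, ry = _rank(x.astype(float)), _rank(y.astype(float))
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    if ex.std() == 0 or ey.std() == 0:
        raise ValueError("constant residuals; correlation undefined")
    r = float(np.corrcoef(ex, ey)[0, 1])
    df = n - 2 - c
    if df < 1:
        raise ValueError("not enough observations for the covariate design")
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
    if tails == "one":
        p = float(sps.t.sf(t, df)) if np.isfinite(t) else (0.0 if t > 0 else 1.0)
    else:
        p = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return TestResult(r, p, tails, float(df), n)
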