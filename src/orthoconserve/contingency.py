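"""2x2 contingency testing with the expected-count dispatch rule.

Two proportions are compared throughout the pipeline with the same
convention: the *reference* population is the first row and the focal gene
set the second, columns are (property present, property absent).  Under
this orientation an odds ratio below 1 means the property is *enriched*
in the focal set relative to the reference.

The chi-squared path applies the Yates continuity correction in its
classical clamped form,

    X^2 = sum_ij max(|O_ij - E_ij| - 0.5, 0)^2 / E_ij ,

which is the form used by R's ``chisq.test`` and has the property that
near-identical 2x2 tables (all |O - E| <= 0.5) give a statistic of
exactly zero.  The Fisher path reports the two-sided exact p-value, the
conditional maximum-likelihood odds ratio and its exact 95% interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .exceptions import DegenerateTableError

__all__ = [
    "ContingencyResult",
    "expected_counts",
    "yates_chi2",
    "fisher_exact",
    "select_test",
]


@dataclass(frozen=True)
class ContingencyResult:
    """Outcome of a 2x2 test, tagged with the method that produced it."""

    method: str  # "chi2_yates" | "fisher"
    statistic: Optional[float]
    p_value: float
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    expected_min: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("contingency counts must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("contingency counts must be integers")
    return t


def expected_counts(table) -> np.ndarray:
    """Expected cell counts E_ij = row_i * col_j / N under independence.

    Raises :class:`DegenerateTableError` when a row margin (or the grand
    total) is zero, since no comparison of the two sets is then possible.
    """
    t = _as_table(table)
    n = t.sum()
    rows = t.sum(axis=1)
    if n == 0 or (rows == 0).any():
        raise DegenerateTableError("table has an empty row margin")
    return np.outer(rows, t.sum(axis=0)) / n


def yates_chi2(table) -> ContingencyResult:
    """Yates-corrected chi-squared test on a 2x2 table (1 df).

    The correction is clamped at zero, so tables whose observed counts sit
    within 0.5 of expectation in every cell yield statistic 0 and p = 1.
    Requires all four margins to be positive (a zero column makes E = 0).
    """
    t = _as_table(table)
    e = expected_counts(t)
    if (t.sum(axis=0) == 0).any():
        raise DegenerateTableError("table has an empty column margin")
    diff = np.maximum(np.abs(t - e) - 0.5, 0.0)
    statistic = float((diff**2 / e).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return ContingencyResult(
        method="chi2_yates",
        statistic=statistic,
        p_value=p,
        odds_ratio=None,
        ci_low=None,
        ci_high=None,
        expected_min=float(e.min()),
    )


def fisher_exact(table, compute_ci: bool = True) -> ContingencyResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio.

    The p-value sums hypergeometric probabilities of all margin-preserving
    tables at most as probable as the observed one (with the customary
    1e-7 relative tolerance on the comparison).  The odds ratio is the
    conditional maximum-likelihood estimate; its 95% interval inverts the
    noncentral hypergeometric tail tests.  ``compute_ci=False`` skips the
    (comparatively expensive) estimate/interval inversion.

    Zero *column* margins are permitted (the table carries no information,
    p = 1, odds ratio undefined); zero row margins are degenerate.
    """
    t = _as_table(table)
    expected_min = float(expected_counts(t).min())  # validates row margins
    a, b = t[0]
    c, d = t[1]
    _, p = stats.fisher_exact([[a, b], [c, d]])
    or_hat = ci_low = ci_high = None
    degenerate_col = (t.sum(axis=0) == 0).any()
    if compute_ci and not degenerate_col:
        res = _odds_ratio(t.astype(int), kind="conditional")
        or_hat = float(res.statistic)
        ci = res.confidence_interval(confidence_level=0.95)
        ci_low, ci_high = float(ci.low), float(ci.high)
    return ContingencyResult(
        method="fisher",
        statistic=None,
        p_value=float(p),
        odds_ratio=or_hat,
        ci_low=ci_low,
        ci_high=ci_high,
        expected_min=expected_min,
    )


def select_test(table, threshold: float = 10.0, compute_ci: bool = True) -> ContingencyResult:
    """Dispatch between the chi-squared and Fisher paths.

    Fisher's exact test is used iff any expected cell count falls below
    ``threshold`` (default 10); otherwise the Yates-corrected chi-squared
    test is applied.  The smallest expected count is reported either way.
    """
    e = expected_counts(table)
    if (e < threshold).any():
        return fisher_exact(table, compute_ci=compute_ci)
    return yates_chi2(table)
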