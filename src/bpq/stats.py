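"""Normality-gated two-group comparison and significance star labels.

The comparison procedure: Shapiro–Wilk normality on each group (on the
paired differences for paired data); when normality is not rejected a
two-tailed t test is used (paired or unpaired), otherwise the Wilcoxon
matched-pairs signed-rank test (paired) or the Mann–Whitney test
(unpaired). P-values map to star labels with the "<=" boundary convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "compare", "star_label"]

#: Sample size at or below which rank tests use exact p-values.
EXACT_N_MAX = 25


def star_label(p: float) -> str:
    """Significance label for a p-value.

    ``ns`` for p > 0.05, then ``*`` (p <= 0.05), ``**`` (p <= 0.01),
    ``***`` (p <= 0.001), ``****`` (p <= 0.0001); boundary values take the
    stronger label.
    """
    if not 0.0 <= p <= 1.0 or not np.isfinite(p):
        raise ValueError("p must lie in [0, 1]")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one gated two-group comparison."""

    test_name: str       # paired_t | wilcoxon_signed_rank | unpaired_t | mann_whitney
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    paired: bool
    stars: str
    normality_p: tuple    # Shapiro–Wilk p's the gate was based on

    def to_row(self) -> dict:
        return {"test": self.test_name, "statistic": self.statistic,
                "p_value": self.p_value, "n_a": self.n_a, "n_b": self.n_b,
                "paired": self.paired, "stars": self.stars}


def _shapiro_p(x: np.ndarray, what: str) -> float:
    if np.ptp(x) == 0:
        raise ValueError(f"{what} is constant; Shapiro–Wilk and the "
                         "downstream tests are undefined")
    return float(sps.shapiro(x).pvalue)


def compare(a, b, paired: bool = False,
            alpha_normality: float = 0.05) -> ComparisonResult:
    """Compare two samples with the normality-gated test selection.

    Parameters
    ----------
    a, b
        1D samples (aligned element-wise when ``paired``).
    paired
        Whether observations are matched pairs.
    alpha_normality
        Shapiro–Wilk rejection level for the gate.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise ValueError("samples must be finite")
    if paired and len(a) != len(b):
        raise ValueError("paired samples must have equal length")

    if paired:
        diff = a - b
        if np.ptp(diff) == 0:
            raise ValueError("paired differences are constant; the "
                             "signed-rank test is undefined")
        normality = (_shapiro_p(diff, "paired differences"),)
        normal = normality[0] > alpha_normality
        if normal:
            res = sps.ttest_rel(a, b)
            name = "paired_t"
        else:
            method = ("exact" if len(diff) <= EXACT_N_MAX
                      and not np.any(diff == 0) else "approx")
            res = sps.wilcoxon(a, b, correction=(method == "approx"),
                               method=method)
            name = "wilcoxon_signed_rank"
    else:
        normality = (_shapiro_p(a, "group a"), _shapiro_p(b, "group b"))
        normal = all(p > alpha_normality for p in normality)
        if normal:
            res = sps.ttest_ind(a, b)
            name = "unpaired_t"
        else:
            method = ("exact" if max(len(a), len(b)) <= EXACT_N_MAX
                      else "asymptotic")
            res = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method=method)
            name = "mann_whitney"

    p = float(res.pvalue)
    return ComparisonResult(
        test_name=name, statistic=float(res.statistic), p_value=p,
        n_a=len(a), n_b=len(b), paired=paired, stars=star_label(p),
        normality_p=normality)
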