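"""Statistical kernels: normality-gated paired location tests, exact
Wilcoxon signed-rank, paired t, McNemar, IQR ratio and boxplot summaries.

All tests are two-sided; the default significance level is 0.05.  The
paired-location test applies a Shapiro–Wilk normality gate to the paired
*differences* (the quantity the paired t-test assumes normal): if the
gate p-value is >= alpha the paired t-test runs, otherwise the Wilcoxon
signed-rank test.

Wilcoxon follows the classical convention: zero differences are dropped,
tied absolute differences receive midranks, and the statistic is
``min(W+, W-)``.  For small samples (``n_effective`` <= 25 by default)
the two-sided p-value is exact, computed by dynamic programming over the
``2^n`` equiprobable sign assignments (ties permitting); beyond that, a
normal approximation with tie correction and a continuity correction is
used.

McNemar's test uses only the discordant cells b and c of the paired 2x2
table: exact two-sided ``p = min(1, 2 · Σ_{k<=min(b,c)} C(b+c, k) / 2^{b+c})``
(binomial sign test on the discordant pairs), or the continuity-corrected
chi-square ``(|b−c|−1)^2 / (b+c)`` on 1 df.

Quantiles everywhere use linear interpolation between order statistics:
for a sorted sample ``x_(1..n)`` the quantile at level ``t`` is
``x_(k) + f · (x_(k+1) − x_(k))`` with ``h = (n−1)·t``, ``k = floor(h)+1``,
``f = h − floor(h)`` (numpy's default rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedTestResult",
    "ContingencyTable2x2",
    "BoxplotSummary",
    "shapiro_wilk_p",
    "wilcoxon_signed_rank",
    "paired_t",
    "paired_location_test",
    "mcnemar",
    "iqr_ratio",
    "boxplot_summary",
    "WILCOXON_EXACT_MAX_N",
]

WILCOXON_EXACT_MAX_N = 25
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class PairedTestResult:
    """Outcome of one paired M-vs-AM (or session-vs-session) comparison."""

    test_name: str                      # "paired_t" | "wilcoxon_signed_rank"
    statistic: float
    p_value: float
    n_effective: int
    normality_p: float = float("nan")
    alpha: float = DEFAULT_ALPHA
    label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Paired accept/reject counts; first index is the AM decision, second
    the M decision (``n_ny`` means AM = NO while M = YES)."""

    n_nn: int
    n_ny: int
    n_yn: int
    n_yy: int

    def __post_init__(self) -> None:
        for cell in (self.n_nn, self.n_ny, self.n_yn, self.n_yy):
            if cell < 0:
                raise ValueError("contingency cells must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_nn + self.n_ny + self.n_yn + self.n_yy

    @property
    def discordant(self) -> tuple[int, int]:
        """(b, c) = (AM-no/M-yes, AM-yes/M-no)."""
        return self.n_ny, self.n_yn

    def transposed(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.n_nn, self.n_yn, self.n_ny, self.n_yy)


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number summary with whiskers at the 5th and 95th percentiles;
    points outside the whiskers are listed singly as outliers."""

    median: float
    q1: float
    q3: float
    p5: float
    p95: float
    n: int
    outliers: tuple[float, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Normality gate
# ---------------------------------------------------------------------------

def shapiro_wilk_p(x) -> float:
    """Two-sided p-value of the Shapiro–Wilk normality test."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("Shapiro–Wilk needs a 1D sample with n >= 3")
    if len(x) > 5000:
        raise ValueError("Shapiro–Wilk supports n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk undefined for a constant sample")
    return float(sps.shapiro(x).pvalue)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_midranks(d: np.ndarray) -> np.ndarray:
    """Midranks of |d| after dropping zeros."""
    return sps.rankdata(np.abs(d))


def _exact_wilcoxon_p(ranks: np.ndarray, w_min: float) -> float:
    """Two-sided exact p by enumerating sign assignments.

    Uses dynamic programming on doubled ranks (midranks are half-integers,
    so doubling makes them integers): the number of sign assignments with
    W+ equal to each achievable value is built up one rank at a time.
    The signed-rank distribution is symmetric about ``T/2`` where
    ``T = Σ ranks``, so the two-sided p doubles the lower tail at
    ``w_min = min(W+, W−)``.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n = len(ranks)
    w_doubled = int(np.rint(2 * w_min))
    lower_tail = counts[: w_doubled + 1].sum() / (2.0 ** n)
    return min(1.0, 2.0 * lower_tail)


def _approx_wilcoxon_p(ranks: np.ndarray, w_min: float) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = len(ranks)
    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups of |d|
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    z = (w_min - mean + 0.5) / math.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.cdf(z)))


def wilcoxon_signed_rank(d, exact_max_n: int = WILCOXON_EXACT_MAX_N
                         ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Returns ``(statistic, p_value)`` with statistic = min(W+, W−).
    Exact enumeration for ``n_effective <= exact_max_n``, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]  # Wilcoxon's original zero-drop rule
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; Wilcoxon undefined")
    ranks = _signed_midranks(d)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w_min = min(w_plus, w_minus)
    if n <= exact_max_n:
        p = _exact_wilcoxon_p(ranks, w_min)
    else:
        p = _approx_wilcoxon_p(ranks, w_min)
    return w_min, p


# ---------------------------------------------------------------------------
# Paired t
# ---------------------------------------------------------------------------

def paired_t(d) -> tuple[float, float]:
    """Two-sided one-sample t-test on paired differences:
    ``t = mean(d) / (sd(d)/sqrt(n))`` with n−1 degrees of freedom."""
    d = np.asarray(d, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("paired t-test undefined for zero-variance differences")
    t = d.mean() / (sd / math.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return float(t), p


# ---------------------------------------------------------------------------
# Normality-gated paired location test
# ---------------------------------------------------------------------------

def paired_location_test(x, y, alpha: float = DEFAULT_ALPHA,
                         label: str = "") -> PairedTestResult:
    """Compare paired samples x and y: Shapiro–Wilk on d = x − y chooses
    between the paired t-test (normal differences) and the Wilcoxon
    signed-rank test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D paired samples")
    if len(x) < 3:
        raise ValueError("paired location test needs n >= 3")
    d = x - y
    if np.all(d == 0):
        raise ValueError(
            "all paired differences are zero; location test degenerate"
        )
    normality_p = shapiro_wilk_p(d)
    if normality_p >= alpha:
        stat, p = paired_t(d)
        return PairedTestResult("paired_t", stat, p, len(d), normality_p,
                                alpha, label)
    stat, p = wilcoxon_signed_rank(d)
    n_eff = int(np.count_nonzero(d))
    return PairedTestResult("wilcoxon_signed_rank", stat, p, n_eff,
                            normality_p, alpha, label)


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------

def mcnemar(table: ContingencyTable2x2, method: str = "exact") -> float:
    """Two-sided McNemar p-value from the discordant cells.

    ``method="exact"``: binomial sign test on the discordant pairs.
    ``method="chi2_cc"``: continuity-corrected chi-square on 1 df
    (requires b + c >= 1).
    """
    b, c = table.discordant
    n_disc = b + c
    if method == "exact":
        if n_disc == 0:
            return 1.0
        k_max = min(b, c)
        tail = sum(math.comb(n_disc, k) for k in range(k_max + 1)) / 2.0 ** n_disc
        return min(1.0, 2.0 * tail)
    if method == "chi2_cc":
        if n_disc == 0:
            raise ValueError("chi-square McNemar undefined with no discordant pairs")
        chi2 = (abs(b - c) - 1.0) ** 2 / n_disc
        return float(sps.chi2.sf(chi2, df=1))
    raise ValueError(f"unknown method {method!r}; use 'exact' or 'chi2_cc'")


# ---------------------------------------------------------------------------
# Dispersion and boxplot summaries
# ---------------------------------------------------------------------------

def iqr_ratio(x, y) -> float:
    """IQR(x) / IQR(y), quartiles by linear interpolation.  Used to compare
    dispersions when a location test alone is not informative."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4 or len(y) < 4:
        raise ValueError("IQR ratio needs n >= 4 in both samples")
    iqr_y = float(np.quantile(y, 0.75) - np.quantile(y, 0.25))
    if iqr_y == 0:
        raise ValueError("IQR of the reference sample is zero")
    iqr_x = float(np.quantile(x, 0.75) - np.quantile(x, 0.25))
    return iqr_x / iqr_y


def boxplot_summary(x) -> BoxplotSummary:
    """Median/quartiles with whiskers at the 5th and 95th percentiles;
    values outside the whiskers are reported singly as outliers."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("boxplot summary needs a nonempty 1D sample")
    p5, q1, med, q3, p95 = np.quantile(x, [0.05, 0.25, 0.5, 0.75, 0.95])
    outliers = tuple(float(v) for v in np.sort(x[(x < p5) | (x > p95)]))
    return BoxplotSummary(median=float(med), q1=float(q1), q3=float(q3),
                          p5=float(p5), p95=float(p95), n=len(x),
                          outliers=outliers)
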