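"""Coverage-weighted summary statistics and per-site hypothesis tests.

The group summary used throughout is the coverage-weighted mean methylation

    m_bar = sum_r C_r (mC_r / C_r) / sum_r C_r = sum_r mC_r / sum_r C_r

with C_r the read coverage and mC_r the methylated-read count of replicate
r, and the coverage-weighted variance

    s^2 = sum_r C_r (m_bar - m_r)^2 / (sum_r C_r - 1),   m_r = mC_r / C_r.

Two groups with >= 2 replicates each are compared by a Welch-type statistic

    t = (m_bar_B - m_bar_A) / sqrt(s_A^2 / R_A + s_B^2 / R_B)

with R the replicate count per group and Welch-Satterthwaite degrees of
freedom; when either group has a single replicate the counts are pooled and
a two-sided Fisher's exact test is used instead.

Note the weighting enters through the summaries, not the sample sizes: the
denominator (sum C_r - 1) makes s^2 a shrunk estimate of the replicate-level
variance (factor (R-1)C/(RC-1) at equal coverages C), so the test is mildly
anticonservative at small R.  At unit coverages it coincides exactly with
the textbook Welch test on the replicate fractions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class ZeroCoverageError(ValueError):
    """Total coverage is zero; a methylation fraction is undefined."""


class InsufficientReplicatesError(ValueError):
    """Too few replicates for the requested estimator or test."""


class EmptyTableError(ValueError):
    """A 2x2 contingency table with no observations."""


class InvalidPValueError(ValueError):
    """A p-value outside [0, 1]."""


WEIGHTED_WELCH = "weighted_welch"
FISHER_EXACT = "fisher_exact"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group test at one site (or aggregated region)."""

    statistic: float
    df: float
    p: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise InvalidPValueError(f"p={self.p} outside [0, 1]")


def _as_counts(meth, coverage) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(meth, dtype=float)
    c = np.asarray(coverage, dtype=float)
    if m.shape != c.shape:
        raise ValueError("meth and coverage must have equal length")
    if (m < 0).any() or (c < 0).any():
        raise ValueError("counts must be non-negative")
    if (m > c).any():
        raise ValueError("meth count exceeds coverage")
    return m, c


def weighted_mean(meth, coverage) -> float:
    """Coverage-weighted mean methylation fraction of one replicate group."""
    m, c = _as_counts(meth, coverage)
    total = c.sum()
    if total <= 0:
        raise ZeroCoverageError("total coverage is zero")
    return float(m.sum() / total)


def weighted_variance(meth, coverage) -> float:
    """Coverage-weighted variance of the replicate methylation fractions.

    Requires at least two replicates and total coverage > 1.  With all
    coverages equal to 1 this reduces to the ordinary unbiased sample
    variance of the fractions.
    """
    m, c = _as_counts(meth, coverage)
    if len(m) < 2:
        raise InsufficientReplicatesError("variance needs >= 2 replicates")
    total = c.sum()
    if total <= 1:
        raise ZeroCoverageError("total coverage must exceed 1")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(c > 0, m / np.where(c > 0, c, 1), 0.0)
    mbar = m.sum() / total
    return float((c * (mbar - frac) ** 2).sum() / (total - 1.0))


def _welch_arrays(meth_a, cov_a, meth_b, cov_b):
    """Vectorised weighted Welch test over sites (rows = sites, cols = reps).

    Returns ``(t, df, p)`` arrays.  Degenerate sites (both group variances
    zero) get p = 1 when the means are equal and p = 0 otherwise.
    """
    ma = np.atleast_2d(np.asarray(meth_a, dtype=float))
    ca = np.atleast_2d(np.asarray(cov_a, dtype=float))
    mb = np.atleast_2d(np.asarray(meth_b, dtype=float))
    cb = np.atleast_2d(np.asarray(cov_b, dtype=float))
    r_a, r_b = ma.shape[1], mb.shape[1]
    if r_a < 2 or r_b < 2:
        raise InsufficientReplicatesError(
            "weighted Welch test needs >= 2 replicates per group")

    def group_stats(m, c):
        total = c.sum(axis=1)
        safe_total = np.where(total > 0, total, np.nan)
        mbar = m.sum(axis=1) / safe_total
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(c > 0, m / np.where(c > 0, c, 1), 0.0)
        dev = (c * (mbar[:, None] - frac) ** 2).sum(axis=1)
        denom = np.where(total > 1, total - 1.0, np.nan)
        return mbar, dev / denom

    mean_a, var_a = group_stats(ma, ca)
    mean_b, var_b = group_stats(mb, cb)
    se2 = var_a / r_a + var_b / r_b
    diff = mean_b - mean_a

    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(se2)
        df_num = se2 ** 2
        df_den = (var_a / r_a) ** 2 / (r_a - 1) + (var_b / r_b) ** 2 / (r_b - 1)
        df = df_num / df_den
        p = 2.0 * sps.t.sf(np.abs(t), df)

    degenerate = se2 == 0
    if np.any(degenerate):
        with np.errstate(invalid="ignore"):
            equal = np.isclose(diff, 0.0)
            p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
            t = np.where(degenerate,
                         np.where(equal, 0.0, np.sign(diff) * np.inf), t)
            df = np.where(degenerate, np.nan, df)
    invalid = np.isnan(se2)
    if np.any(invalid):
        p = np.where(invalid, np.nan, p)
    return t, df, p


def weighted_welch_test(meth_a, cov_a, meth_b, cov_b) -> TestResult:
    """Two-sided coverage-weighted Welch test between two replicate groups.

    Antisymmetric in group order: swapping the groups negates the statistic
    and leaves the p-value unchanged.
    """
    ma, ca = _as_counts(meth_a, cov_a)
    mb, cb = _as_counts(meth_b, cov_b)
    t, df, p = _welch_arrays(ma[None, :], ca[None, :], mb[None, :], cb[None, :])
    t0, df0, p0 = float(t[0]), float(df[0]), float(p[0])
    if np.isnan(p0):
        raise ZeroCoverageError("a group has total coverage <= 1")
    if df0 != df0 and p0 in (0.0, 1.0):  # degenerate zero-variance site
        warnings.warn(
            "both group variances are zero; p set by convention",
            RuntimeWarning, stacklevel=2)
    return TestResult(statistic=t0, df=df0, p=p0, method=WEIGHTED_WELCH)


def fisher_exact_test(meth_a: int, unmeth_a: int,
                      meth_b: int, unmeth_b: int) -> TestResult:
    """Two-sided Fisher's exact test on the methylated/unmethylated table.

    The table rows are groups A and B, columns methylated vs unmethylated
    read counts; the p-value sums hypergeometric probabilities of all
    tables (at fixed margins) no more probable than the observed one.
    """
    table = np.array([[meth_a, unmeth_a], [meth_b, unmeth_b]], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise EmptyTableError("empty 2x2 table")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(statistic=float("nan"), df=float("nan"),
                      p=float(min(p, 1.0)), method=FISHER_EXACT)


def site_p_value(meth_a, cov_a, meth_b, cov_b) -> TestResult:
    """Dispatch the appropriate two-group test for one site.

    Uses the weighted Welch test when both groups have >= 2 replicates;
    with a single replicate in either group, Welch's test cannot be used
    and the counts are pooled into a 2x2 table for Fisher's exact test.
    """
    ma, ca = _as_counts(meth_a, cov_a)
    mb, cb = _as_counts(meth_b, cov_b)
    if len(ma) < 1 or len(mb) < 1:
        raise InsufficientReplicatesError("each group needs >= 1 replicate")
    if min(len(ma), len(mb)) == 1:
        pooled_ma, pooled_ca = int(ma.sum()), int(ca.sum())
        pooled_mb, pooled_cb = int(mb.sum()), int(cb.sum())
        return fisher_exact_test(pooled_ma, pooled_ca - pooled_ma,
                                 pooled_mb, pooled_cb - pooled_mb)
    return weighted_welch_test(ma, ca, mb, cb)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InvalidPValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
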