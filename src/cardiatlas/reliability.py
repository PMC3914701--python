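"""Method-agreement and test-retest reliability statistics.

Bland-Altman bias / limits of agreement for paired measurements, and the
single-measure intraclass correlation ICC(2,1) — two-way random effects,
absolute agreement — with its F-based 95% confidence interval
(McGraw & Wong conventions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import f as f_dist


@dataclass
class PairedMeasurements:
    """Two same-unit measurements per subject (two methods or two visits)."""

    subject_ids: list[str]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float).ravel()
        self.b = np.asarray(self.b, dtype=float).ravel()
        if len(self.a) != len(self.b) or len(self.a) != len(self.subject_ids):
            raise ValueError("subject_ids, a and b must have equal length")
        if len(self.a) < 2:
            raise ValueError("need at least 2 paired measurements")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("measurements must be finite")

    @classmethod
    def from_arrays(cls, a, b) -> "PairedMeasurements":
        a = np.asarray(a, dtype=float).ravel()
        return cls([str(i) for i in range(len(a))], a, b)


@dataclass
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    sd_diff: float
    means: np.ndarray
    differences: np.ndarray


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman agreement: bias = mean(A-B), LoA = bias ± 1.96 SD(A-B)."""
    d = pairs.a - pairs.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        sd_diff=sd,
        means=(pairs.a + pairs.b) / 2.0,
        differences=d,
    )


@dataclass
class ICCResult:
    icc: float
    ci_lower: float
    ci_upper: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_raters: int


def icc_absolute_agreement(table: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Single-measure ICC(2,1): two-way random effects, absolute agreement.

    Parameters
    ----------
    table:
        (n_subjects, k_raters) measurement matrix; k is typically 2
        (test / retest).
    alpha:
        1 - confidence level for the F-based interval.

    Notes
    -----
    From the two-way ANOVA mean squares (rows = subjects, columns =
    raters/occasions)::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The confidence interval follows McGraw & Wong's ICC(A,1) construction
    with a Satterthwaite degrees-of-freedom approximation.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("table must be (n_subjects, k>=2)")
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("table must be finite")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if ss_total < 1e-300 or abs(denom) < 1e-300:
        raise ValueError("degenerate ICC: no variance in the table")
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) interval for ICC(A,1)
    a_ = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isinf(a_):
        lower = upper = 1.0
    else:
        b_ = 1 + k * icc * (n - 1) / (n * (1 - icc))
        v = (a_ * msc + b_ * mse) ** 2 / (
            (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_u = f_dist.ppf(1 - alpha / 2, n - 1, v)
        f_l = f_dist.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr
        )
    return ICCResult(
        icc=float(icc),
        ci_lower=float(lower),
        ci_upper=float(upper),
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        n_subjects=n,
        n_raters=k,
    )
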