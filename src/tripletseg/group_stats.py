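"""Group-level statistics: one-sided t-tests, FDR correction, repeated-measures ANOVA."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ElectrodeTestResult",
    "AnovaResult",
    "ttest_one_sided",
    "fdr_correct",
    "electrode_tests",
    "rm_anova",
]

logger = logging.getLogger(__name__)


@dataclass
class ElectrodeTestResult:
    """Per-electrode one-sided tests with FDR decisions."""

    t: np.ndarray
    p: np.ndarray
    rejected: np.ndarray
    q: float

    def to_frame(self, channels=None) -> pd.DataFrame:
        n = len(self.t)
        if channels is None:
            channels = [f"ch{i}" for i in range(n)]
        return pd.DataFrame(
            {"channel": channels, "t": self.t, "p": self.p, "significant": self.rejected}
        )


@dataclass
class AnovaResult:
    """One-way repeated-measures ANOVA with Bonferroni post-hocs."""

    f: float
    df_num: int
    df_den: int
    p: float
    posthoc_p: dict[tuple[int, int], float]


def ttest_one_sided(values: np.ndarray) -> tuple[float, float]:
    """One-sample t-test of ``values`` against zero, upper tail."""
    values = np.asarray(values, float)
    if len(values) < 2:
        raise ValueError("need at least 2 subjects")
    if values.std(ddof=1) == 0:
        # degenerate but directional: all-equal values decide the tail alone
        logger.warning("zero variance in one-sided t-test; p set by sign")
        m = values.mean()
        if m > 0:
            return np.inf, 0.0
        if m < 0:
            return -np.inf, 1.0
        return 0.0, 0.5
    t, p = stats.ttest_1samp(values, 0.0, alternative="greater")
    return float(t), float(p)


def fdr_correct(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions at level ``q``."""
    p_values = np.asarray(p_values, float)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, _, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return rejected


def electrode_tests(values: np.ndarray, q: float = 0.05) -> ElectrodeTestResult:
    """Electrode-wise one-sided t-tests across subjects, FDR corrected.

    ``values`` is (subjects, channels), e.g. SNR scores at one target rate.
    """
    values = np.asarray(values, float)
    t = np.empty(values.shape[1])
    p = np.empty(values.shape[1])
    for c in range(values.shape[1]):
        t[c], p[c] = ttest_one_sided(values[:, c])
    return ElectrodeTestResult(t=t, p=p, rejected=fdr_correct(p, q), q=q)


def rm_anova(matrix: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA (sphericity assumed).

    ``matrix`` is (subjects, conditions), complete (no missing cells).  The F
    statistic follows the two-way subject-by-condition sum-of-squares
    decomposition; post-hoc paired t-tests are Bonferroni corrected by the
    number of pairs (p capped at 1).
    """
    m = np.asarray(matrix, float)
    if m.ndim != 2:
        raise ValueError("matrix must be (subjects, conditions)")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing cells are not supported (no imputation)")
    n_sub, n_cond = m.shape
    if n_sub < 3 or n_cond < 2:
        raise ValueError("need at least 3 subjects and 2 conditions")

    grand = m.mean()
    cond_means = m.mean(axis=0)
    subj_means = m.mean(axis=1)
    ss_cond = n_sub * np.sum((cond_means - grand) ** 2)
    ss_subj = n_cond * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df_num = n_cond - 1
    df_den = (n_cond - 1) * (n_sub - 1)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    f = ms_cond / ms_err if ms_err > 0 else (0.0 if ms_cond == 0 else np.inf)
    p = float(stats.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0

    pairs = [(i, j) for i in range(n_cond) for j in range(i + 1, n_cond)]
    posthoc = {}
    for i, j in pairs:
        _, pp = stats.ttest_rel(m[:, i], m[:, j])
        posthoc[(i, j)] = min(float(pp) * len(pairs), 1.0)
    return AnovaResult(f=float(f), df_num=df_num, df_den=df_den, p=p, posthoc_p=posthoc)
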