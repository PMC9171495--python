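"""Group-level statistics: edgewise rank-sum contrasts, group comparison of
global efficiency, severity classing from FMA scores, and the GE–FMA
Pearson correlation.

The Wilcoxon rank-sum (Mann–Whitney U) test is exact for small tie-free
samples and uses the tie-corrected normal approximation otherwise.  Edge
contrasts report uncorrected p-values by default, with an optional
Benjamini–Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import CohortRecord, EfficiencySeries

__all__ = [
    "ranksum",
    "edgewise_ranksum",
    "EdgeContrast",
    "compare_ge",
    "classify_severity",
    "correlate_ge_fma",
    "SEVERITY_BOUNDS",
]

#: Half-open severity classes on the FMA scale (upper class closed at 60).
SEVERITY_BOUNDS = {"severe": (0.0, 20.0), "moderate": (20.0, 40.0), "mild": (40.0, 60.0)}

EXACT_MAX_N = 10


def ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (statistic, p).

    Exact null distribution when both samples have at most 10 observations
    and no ties; tie-corrected normal approximation otherwise.  Two
    identical constant samples give p = 1 rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= EXACT_MAX_N and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class EdgeContrast:
    """Edgewise group contrast at one time point.

    ``statistic`` and ``p`` are n×n matrices (diagonal zero / one);
    ``sign[i, j]`` is +1 where group A's median edge weight exceeds group
    B's, −1 for the reverse, 0 for equality.  ``significant`` flags edges
    at the chosen alpha (after correction if requested).
    """

    statistic: np.ndarray
    p: np.ndarray
    sign: np.ndarray
    groups: tuple[str, str]
    alpha: float
    corrected: bool
    significant: np.ndarray


def edgewise_ranksum(group_a: list[np.ndarray], group_b: list[np.ndarray],
                     alpha: float = 0.05, groups: tuple[str, str] = ("A", "B"),
                     correct: bool = False) -> EdgeContrast:
    """Rank-sum contrast of every off-diagonal edge between two groups.

    Each group is a list of per-subject connectivity matrices at one time
    point.  With ``correct=True`` p-values are Benjamini–Hochberg adjusted
    across the off-diagonal edges before thresholding at ``alpha``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    A = np.stack([np.asarray(m, dtype=float) for m in group_a])
    B = np.stack([np.asarray(m, dtype=float) for m in group_b])
    n = A.shape[1]
    if A.shape[1:] != (n, n) or B.shape[1:] != (n, n):
        raise ValueError("all matrices must be square and same size")
    stat = np.zeros((n, n))
    p = np.ones((n, n))
    sign = np.zeros((n, n), dtype=int)
    off = [(i, j) for i in range(n) for j in range(n) if i != j]
    for i, j in off:
        s, pv = ranksum(A[:, i, j], B[:, i, j])
        stat[i, j], p[i, j] = s, pv
        diff = np.median(A[:, i, j]) - np.median(B[:, i, j])
        sign[i, j] = 0 if diff == 0 else int(np.sign(diff))
    pvals = np.array([p[i, j] for i, j in off])
    if correct:
        _, p_adj, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        pvals = p_adj
        p_out = np.ones((n, n))
        for (i, j), pv in zip(off, pvals):
            p_out[i, j] = pv
        p = p_out
    significant = np.zeros((n, n), dtype=bool)
    for (i, j), pv in zip(off, pvals):
        significant[i, j] = pv < alpha
    return EdgeContrast(statistic=stat, p=p, sign=sign, groups=groups,
                        alpha=alpha, corrected=correct, significant=significant)


def compare_ge(group_a: list[EfficiencySeries], group_b: list[EfficiencySeries],
               window: tuple[float, float] = (0.0, 6.0)
               ) -> tuple[float, float, int]:
    """Rank-sum comparison of subject-mean task-window GE between groups.

    Series sharing a subject id (e.g. the two imagery conditions) are
    averaged into a single per-subject value first.  Returns
    ``(statistic, p, direction)`` with direction +1 if group A's median
    exceeds group B's, −1 for the reverse, 0 for equality.
    """

    def per_subject(series: list[EfficiencySeries]) -> np.ndarray:
        by_subj: dict[str, list[float]] = {}
        for k, s in enumerate(series):
            key = s.subject or f"#{k}"
            by_subj.setdefault(key, []).append(s.mean_in_window(window))
        return np.array([float(np.mean(v)) for _, v in sorted(by_subj.items())])

    a = per_subject(group_a)
    b = per_subject(group_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 subjects per group")
    stat, p = ranksum(a, b)
    diff = np.median(a) - np.median(b)
    direction = 0 if diff == 0 else int(np.sign(diff))
    return stat, p, direction


def classify_severity(fma: float) -> str:
    """Map an FMA score to a severity class.

    Half-open classes severe [0, 20), moderate [20, 40), mild [40, 60] so
    every valid score maps to exactly one class.
    """
    if not 0 <= fma <= 60:
        raise ValueError(f"FMA score {fma} outside [0, 60]")
    if fma < 20:
        return "severe"
    if fma < 40:
        return "moderate"
    return "mild"


def correlate_ge_fma(cohort: list[CohortRecord],
                     window: tuple[float, float] = (0.0, 6.0),
                     mean_ge: np.ndarray | None = None
                     ) -> tuple[float, float]:
    """Pearson correlation of subject-mean GE against FMA over patients.

    Only records carrying an FMA score (patients) enter; the subject-level
    GE is the mean over the task window and both conditions unless
    ``mean_ge`` supplies precomputed values aligned with the patients.
    """
    patients = [r for r in cohort if r.fma is not None]
    if len(patients) < 3:
        raise ValueError("need at least 3 subjects with FMA scores")
    fma = np.array([r.fma for r in patients], dtype=float)
    if mean_ge is None:
        ge = np.array([r.mean_ge(window) for r in patients])
    else:
        ge = np.asarray(mean_ge, dtype=float)
        if ge.shape != fma.shape:
            raise ValueError("mean_ge must align with the FMA-scored subjects")
    if not (np.all(np.isfinite(ge)) and np.all(np.isfinite(fma))):
        raise ValueError("non-finite GE or FMA values")
    if np.ptp(ge) == 0 or np.ptp(fma) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    r, p = sps.pearsonr(ge, fma)
    return float(r), float(p)
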