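"""Posture-comparison statistics.

The cohort design is repeated-measures: each subject (block) is measured in
every body position (treatment), so comparisons are within-subject and
nonparametric.  The toolbox mirrors that design:

* Anderson-Darling normality check (reported, but the pipeline proceeds
  nonparametrically regardless);
* Friedman omnibus rank test across positions within subjects;
* Conover post-hoc pairwise comparisons on within-block rank sums with
  Holm (or Bonferroni) multiplicity correction, run when the omnibus is
  significant;
* paired Wilcoxon signed-rank (filtered-vs-apnea cardiac amplitudes);
* Pearson correlation (amplitude change vs heart-rate change).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    pairwise: pd.DataFrame | None = None
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _as_block_matrix(table) -> tuple[np.ndarray, list, list]:
    """Validate a subjects x treatments table; no missing cells allowed."""
    if isinstance(table, pd.DataFrame):
        values = table.to_numpy(dtype=float)
        rows, cols = list(table.index), list(table.columns)
    else:
        values = np.asarray(table, dtype=float)
        rows = list(range(values.shape[0]))
        cols = list(range(values.shape[1]))
    if values.ndim != 2:
        raise ValueError("block table must be 2-D (subjects x treatments)")
    if np.isnan(values).any():
        raise ValueError("block table has missing cells; the design must be complete")
    return values, rows, cols


# ---------------------------------------------------------------------------
# normality
# ---------------------------------------------------------------------------

def anderson_darling(sample) -> TestResult:
    """Anderson-Darling test of normality with estimated mean and variance.

    The statistic uses the small-sample correction
    ``A* = A^2 (1 + 0.75/n + 2.25/n^2)`` and the standard approximation for
    the p-value in the estimated-parameters case.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 8:
        raise ValueError(f"need n >= 8 for the normality test, got {n}")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("constant sample: normality test undefined")
    z = (x - x.mean()) / s
    logcdf = sst.norm.logcdf(z)
    logsf = sst.norm.logsf(z)
    i = np.arange(1, n + 1)
    a2 = -n - np.sum((2 * i - 1) * (logcdf + logsf[::-1])) / n
    a_star = a2 * (1 + 0.75 / n + 2.25 / n**2)
    if a_star >= 0.6:
        p = np.exp(1.2937 - 5.709 * a_star + 0.0186 * a_star**2)
    elif a_star > 0.34:
        p = np.exp(0.9177 - 4.279 * a_star - 1.38 * a_star**2)
    elif a_star > 0.2:
        p = 1 - np.exp(-8.318 + 42.796 * a_star - 59.938 * a_star**2)
    else:
        p = 1 - np.exp(-13.436 + 101.14 * a_star - 223.73 * a_star**2)
    return TestResult(float(a_star), float(np.clip(p, 0.0, 1.0)),
                      "Anderson-Darling (normal, estimated parameters)")


# ---------------------------------------------------------------------------
# Friedman omnibus
# ---------------------------------------------------------------------------

def _friedman_ranks(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sst.rankdata, 1, values)


def friedman_statistic(values: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from a blocks x treatments matrix."""
    n, k = values.shape
    r = _friedman_ranks(values)
    col_sums = r.sum(axis=0)
    a1 = float((r**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    denom = a1 - c1
    if denom <= 0:  # every block constant: no information, no effect
        return 0.0
    return float((k - 1) * ((col_sums**2).sum() - n * c1) / denom)


def _friedman_statistic_batch(values: np.ndarray) -> np.ndarray:
    """Vectorized Friedman statistic over a (B, n, k) stack of tables."""
    b, n, k = values.shape
    r = sst.rankdata(values, axis=-1)
    col_sums = r.sum(axis=1)
    a1 = (r**2).sum(axis=(1, 2))
    c1 = n * k * (k + 1) ** 2 / 4.0
    denom = a1 - c1
    num = (k - 1) * ((col_sums**2).sum(axis=1) - n * c1)
    out = np.zeros(b)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


#: below these sizes the chi-square approximation is too coarse; use permutation
_SMALL_BLOCKS, _SMALL_TREATMENTS = 9, 5


def friedman(table, method: str = "auto", n_permutations: int = 20000,
             seed: int = 0) -> TestResult:
    """Friedman repeated-measures rank test (midranks for ties).

    The statistic is the tie-corrected Friedman chi-square.  Its p-value is
    the chi-square tail on k-1 df for larger designs; for small tables
    (<= 9 blocks and <= 5 treatments), where that approximation is coarse,
    the p-value comes from a seeded Monte-Carlo permutation of values within
    blocks (within ~0.004 of the exact enumeration at the default draw count).
    """
    values, _, _ = _as_block_matrix(table)
    n, k = values.shape
    if n < 3 or k < 3:
        raise ValueError("Friedman test needs >= 3 blocks and >= 3 treatments")
    stat = friedman_statistic(values)
    if method == "auto":
        method = ("permutation"
                  if n <= _SMALL_BLOCKS and k <= _SMALL_TREATMENTS else "chi2")
    if method == "chi2":
        p = float(sst.chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        keys = rng.random((n_permutations, n, k))
        order = np.argsort(keys, axis=-1)
        permuted = np.take_along_axis(
            np.broadcast_to(values, (n_permutations, n, k)), order, axis=-1)
        stats = _friedman_statistic_batch(permuted)
        p = float((1 + np.sum(stats >= stat - 1e-12)) / (1 + n_permutations))
    else:
        raise ValueError("method must be 'auto', 'chi2' or 'permutation'")
    return TestResult(stat, p, f"Friedman ({method})")


def friedman_permutation_p(values: np.ndarray) -> float:
    """Exact permutation p-value: all within-block orderings (tiny tables only).

    Enumerates every combination of independent column permutations per
    block (``k!**n`` cases), so it is an oracle for small n and k.
    """
    from itertools import permutations, product

    values = np.asarray(values, dtype=float)
    n, k = values.shape
    observed = friedman_statistic(values)
    perms = list(permutations(range(k)))
    count = total = 0
    for combo in product(perms, repeat=n):
        permuted = np.stack([values[i, list(p)] for i, p in enumerate(combo)])
        total += 1
        if friedman_statistic(permuted) >= observed - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# Conover post-hoc
# ---------------------------------------------------------------------------

def conover_posthoc(table, friedman_result: TestResult | None = None,
                    correction: str = "holm", alpha: float = ALPHA) -> pd.DataFrame:
    """Conover pairwise comparisons after Friedman, multiplicity-corrected.

    The statistic for treatments i, j is
    ``|R_i - R_j| / sqrt(2 n (A1 - B1) / ((n-1)(k-1)))`` with within-block
    rank sums ``R``, ``A1 = sum r^2``, ``B1 = sum R_j^2 / n``, referred to a
    t distribution on (n-1)(k-1) df.  P-values are corrected by Holm's
    step-down (or Bonferroni).  Meant to run after a significant omnibus; a
    non-significant omnibus only triggers a warning.
    """
    if friedman_result is not None and not friedman_result.significant:
        warnings.warn("Conover post-hoc requested although the Friedman omnibus "
                      "is not significant")
    if correction not in ("holm", "bonferroni"):
        raise ValueError("correction must be 'holm' or 'bonferroni'")
    values, _, cols = _as_block_matrix(table)
    n, k = values.shape
    r = _friedman_ranks(values)
    col_sums = r.sum(axis=0)
    a1 = float((r**2).sum())
    b1 = float((col_sums**2).sum()) / n
    df = (n - 1) * (k - 1)
    denom_sq = 2.0 * n * (a1 - b1) / df
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if denom_sq <= 0:
        raw = [0.0 if col_sums[i] == col_sums[j] else np.inf for i, j in pairs]
    else:
        raw = [abs(col_sums[i] - col_sums[j]) / np.sqrt(denom_sq) for i, j in pairs]
    pvals = [2 * float(sst.t.sf(t, df)) for t in raw]
    corrected = multipletests(pvals, alpha=alpha, method=correction)[1]
    mat = pd.DataFrame(np.ones((k, k)), index=cols, columns=cols)
    for (i, j), p in zip(pairs, corrected):
        mat.iloc[i, j] = mat.iloc[j, i] = p
    return mat


# ---------------------------------------------------------------------------
# paired tests and correlation
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(x, y) -> TestResult:
    """Paired Wilcoxon signed-rank test (two-sided).

    Zero differences are dropped; the p-value is exact for n <= 25 without
    ties in the absolute differences, otherwise a tie-corrected normal
    approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    if d.size < 6:
        raise ValueError(f"need >= 6 nonzero paired differences, got {d.size}")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sst.wilcoxon(d, method=method, correction=(method == "approx"))
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"Wilcoxon signed-rank ({method})")


def pearson(x, y) -> TestResult:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sst.pearsonr(x, y)
    return TestResult(float(r), float(p), "Pearson correlation")


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def posture_report(block: pd.DataFrame, correction: str = "holm",
                   alpha: float = ALPHA) -> dict:
    """Friedman omnibus + (if significant) Conover pairwise for one kind."""
    omnibus = friedman(block)
    pairwise = None
    if omnibus.significant:
        pairwise = conover_posthoc(block, omnibus, correction=correction, alpha=alpha)
    flagged = []
    if pairwise is not None:
        cols = list(pairwise.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if pairwise.iloc[i, j] < alpha:
                    flagged.append((cols[i], cols[j]))
    return {"friedman": omnibus, "pairwise": pairwise, "flagged_pairs": flagged}
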