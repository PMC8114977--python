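"""Shared statistical primitives: Welch t, BH adjustment, vectorized Fisher.

The Fisher implementation is the two-sided point-probability method (sum of
hypergeometric point probabilities not exceeding that of the observed table),
the convention used by R's ``fisher.test`` and scipy.  It is vectorized over
tables by grouping on margins so that enrichment scans and exhaustive
table sweeps stay cheap.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["welch_ttest", "bh_adjust", "fisher_exact_2x2", "fisher_exact_batch"]

# relative tie guard on point probabilities, same convention as scipy/R
_TIE_GAMMA = 1 + 1e-7


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sided Welch t-test for features x samples blocks.

    Degenerate rows (zero variance in both groups) get t=0, p=1 when the
    means are equal, and +/-inf t with p=0 when they differ.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        t[degenerate & equal] = 0.0
        p[degenerate & equal] = 1.0
        diff_sign = np.sign(a.mean(axis=1) - b.mean(axis=1))
        t[degenerate & ~equal] = np.inf * diff_sign[degenerate & ~equal]
        p[degenerate & ~equal] = 0.0
    return t, p


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _table_pvalues(n: int, r1: int, c1: int, a_values: np.ndarray) -> np.ndarray:
    """Two-sided Fisher p for tables with margins (r1, n-r1) x (c1, n-c1)
    and top-left counts ``a_values``."""
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    obs = pmf[np.asarray(a_values) - lo]
    # sum point probabilities <= observed (with relative tie guard)
    return np.array([pmf[pmf <= po * _TIE_GAMMA].sum() for po in obs]).clip(0.0, 1.0)


def fisher_exact_batch(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher exact test for a stack of 2x2 tables.

    Parameters
    ----------
    tables
        Integer array of shape (k, 2, 2), rows ``[[a, b], [c, d]]``.

    Returns
    -------
    odds_ratio, p
        Conditional sample odds ratio ``a*d/(b*c)`` (inf when b*c == 0 and
        a*d > 0; nan for fully degenerate tables) and two-sided p-values.
    """
    tables = np.asarray(tables, dtype=np.int64)
    if tables.ndim == 2:
        tables = tables[None]
    if tables.shape[1:] != (2, 2) or (tables < 0).any():
        raise ValueError("tables must be non-negative with shape (k, 2, 2)")
    a = tables[:, 0, 0]
    b = tables[:, 0, 1]
    c = tables[:, 1, 0]
    d = tables[:, 1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        oddsratio = np.where(b * c > 0, a * d / np.maximum(b * c, 1), np.inf)
        oddsratio = np.where((a * d == 0) & (b * c == 0), np.nan, oddsratio)

    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    p = np.ones(len(tables), dtype=float)
    # group tables sharing margins so each hypergeometric pmf is built once
    keys = np.stack([n, r1, c1], axis=1)
    order = np.lexsort(keys.T)
    sorted_keys = keys[order]
    boundaries = np.flatnonzero(
        np.r_[True, (np.diff(sorted_keys, axis=0) != 0).any(axis=1)]
    )
    for start, stop in zip(boundaries, np.r_[boundaries[1:], len(order)]):
        idx = order[start:stop]
        ni, r1i, c1i = keys[idx[0]]
        if ni == 0 or r1i in (0, ni) or c1i in (0, ni):
            continue  # degenerate margins: p = 1
        p[idx] = _table_pvalues(int(ni), int(r1i), int(c1i), a[idx])
    return oddsratio, p


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test for a single 2x2 table."""
    oddsratio, p = fisher_exact_batch(np.asarray(table)[None])
    return float(oddsratio[0]), float(p[0])
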