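"""Differential expression and differential DNA-methylation calling.

Expression probes are quantile normalized, log2 transformed, filtered on
detection p-values, tested with a two-sided t (Welch by default, an
empirical-Bayes moderated t on request), BH corrected and gated at
|logFC| > 0.4 and adjusted p < 0.05.

Methylation beta-values are tested on the M-value scale
(M = log2(beta/(1-beta))) with the moderated t as default — per-probe
variances at n = 6/group are too unstable for a plain t — while the effect
size stays on the beta scale; differentially methylated positions (DMPs)
pass FDR < 0.1 and |dbeta| >= 0.05.  All effects are treated minus control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma

from ._stats import bh_adjust, welch_ttest
from .containers import BetaMatrix, ExpressionMatrix, ValidationError

__all__ = [
    "EXPR_FDR",
    "EXPR_MIN_LOGFC",
    "METH_FDR",
    "METH_MIN_DELTA_BETA",
    "DetectionFilterReport",
    "detection_filter",
    "quantile_normalize",
    "differential_expression",
    "m_transform",
    "m_inverse",
    "call_dmps",
    "moderated_ttest",
]

logger = logging.getLogger(__name__)

EXPR_FDR = 0.05
EXPR_MIN_LOGFC = 0.4
METH_FDR = 0.1
METH_MIN_DELTA_BETA = 0.05

M_CLIP_EPS = 1e-3


@dataclass(frozen=True)
class DetectionFilterReport:
    n_input: int
    n_removed: int
    removed_probes: tuple[str, ...]


def detection_filter(
    matrix: ExpressionMatrix,
    p_threshold: float = 0.05,
    min_samples: int = 6,
    strict: bool = False,
) -> tuple[ExpressionMatrix, DetectionFilterReport]:
    """Drop probes undetected in too many samples.

    A probe is removed when its detection p-value exceeds ``p_threshold``
    in at least ``min_samples`` samples (absolute count).  Without a
    detection table the matrix passes through unchanged (or errors in
    ``strict`` mode).
    """
    if matrix.detection_p is None:
        if strict:
            raise ValidationError("detection p-values required in strict mode")
        logger.warning("no detection p-values supplied; detection filter skipped")
        return matrix, DetectionFilterReport(len(matrix.values), 0, ())
    fails = (matrix.detection_p > p_threshold).sum(axis=1)
    drop = fails >= min_samples
    kept = matrix.values.index[~drop]
    removed = tuple(matrix.values.index[drop])
    logger.info("detection filter: %d/%d probes removed", len(removed), len(matrix.values))
    filtered = ExpressionMatrix(
        matrix.values.loc[kept],
        matrix.groups,
        scale=matrix.scale,
        detection_p=matrix.detection_p.loc[kept],
        probe_gene_map=matrix.probe_gene_map,
    )
    return filtered, DetectionFilterReport(len(matrix.values), len(removed), removed)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization across samples followed by log2 transform.

    Every column is forced onto the common distribution of across-column
    rank means (tied ranks receive the linearly interpolated mean, as in
    limma's normalizeQuantiles), then values are log2 transformed.
    """
    if matrix.scale != "raw":
        raise ValidationError("quantile_normalize expects a raw-scale matrix")
    vals = matrix.values.to_numpy()
    if (vals < 0).any():
        raise ValidationError("negative intensities cannot be quantile normalized")
    sorted_means = np.sort(vals, axis=0).mean(axis=1)
    nrow = vals.shape[0]
    ranks = matrix.values.rank(axis=0, method="average").to_numpy()
    if nrow == 1:
        normalized = np.full_like(vals, sorted_means[0])
    else:
        grid = np.arange(1, nrow + 1, dtype=float)
        normalized = np.interp(ranks, grid, sorted_means)
    if (normalized <= 0).any():
        logger.warning("zero rank-means present; +1 offset applied before log2")
        normalized = normalized + 1.0
    out = pd.DataFrame(np.log2(normalized), index=matrix.values.index,
                       columns=matrix.values.columns)
    return ExpressionMatrix(
        out, matrix.groups, scale="log2",
        detection_p=matrix.detection_p, probe_gene_map=matrix.probe_gene_map,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)  # Newton on 1/trigamma
        y = y + step
        if abs(step) < 1e-8 * y:
            break
    return float(y)


def _fit_fdist(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Empirical-Bayes fit of a scaled inverse-chi-square prior to sample
    variances: returns (prior df d0, prior variance s0^2) by Smyth's
    method of moments on log variances."""
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - polygamma(1, df / 2.0)
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_ttest(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-Bayes moderated pooled-variance t.

    Per-probe pooled variances are shrunk toward a chip-wide prior fitted by
    the scaled-F method of moments; the t statistic then carries
    ``df + d0`` degrees of freedom.  With strongly heteroscedastic probes
    the shrinkage is mild; with near-common variance d0 grows large and the
    test approaches a z-test on the pooled variance.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / df
    d0, s0_2 = _fit_fdist(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=1) - b.mean(axis=1)) / se
    if np.isinf(df_total):
        p = 2 * sps.norm.sf(np.abs(t))
    else:
        p = 2 * sps.t.sf(np.abs(t), df_total)
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    return t, p


def differential_expression(
    matrix: ExpressionMatrix,
    fdr: float = EXPR_FDR,
    min_logfc: float = EXPR_MIN_LOGFC,
    moderated: bool = False,
) -> pd.DataFrame:
    """Per-probe differential expression with BH correction and gates.

    Returns a DataFrame indexed by probe id with ``gene`` (when a
    probe->gene map is attached), ``logfc`` (log2, treated - control),
    ``t``, ``p``, ``p_adj`` and the ``significant`` flag
    (adjusted p < ``fdr`` and |logfc| > ``min_logfc``).
    """
    if matrix.scale != "log2":
        raise ValidationError("differential_expression expects a log2 matrix; "
                              "run quantile_normalize first")
    a, b = matrix.group_arrays()
    t, p = (moderated_ttest if moderated else welch_ttest)(a, b)
    out = pd.DataFrame(
        {"logfc": a.mean(axis=1) - b.mean(axis=1), "t": t, "p": p},
        index=matrix.feature_ids,
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["p_adj"] < fdr) & (out["logfc"].abs() > min_logfc)
    if matrix.probe_gene_map is not None:
        gene = matrix.probe_gene_map.set_index("probe_id")["gene"]
        out.insert(0, "gene", out.index.map(gene))
    return out


def m_transform(beta, eps: float = M_CLIP_EPS):
    """Beta to M-value: M = log2(beta/(1-beta)); out-of-range betas are
    clipped to [eps, 1-eps] with a warning."""
    beta = np.asarray(beta, dtype=float)
    if ((beta <= 0) | (beta >= 1)).any():
        logger.warning("beta-values outside (0,1) clipped to [%g, %g]", eps, 1 - eps)
        beta = np.clip(beta, eps, 1 - eps)
    return np.log2(beta / (1.0 - beta))


def m_inverse(m):
    """M-value back to beta: beta = 2^M / (1 + 2^M)."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


def call_dmps(
    matrix: BetaMatrix,
    fdr: float = METH_FDR,
    min_delta_beta: float = METH_MIN_DELTA_BETA,
    moderated: bool = True,
) -> pd.DataFrame:
    """Differentially methylated position calling.

    t-tests run on M-values; ``delta_beta`` (treated - control) stays on the
    beta scale.  Returns a DataFrame indexed by probe id with group mean
    betas, ``delta_beta``, ``t``, ``p``, ``p_adj`` (BH FDR), ``direction``
    (hyper/hypo) and the ``significant`` flag (FDR < ``fdr`` and
    |delta_beta| >= ``min_delta_beta``).
    """
    a, b = matrix.group_arrays()
    ma, mb = m_transform(a), m_transform(b)
    t, p = (moderated_ttest if moderated else welch_ttest)(ma, mb)
    out = pd.DataFrame(
        {
            "mean_beta_treated": a.mean(axis=1),
            "mean_beta_control": b.mean(axis=1),
            "t": t,
            "p": p,
        },
        index=matrix.feature_ids,
    )
    out["delta_beta"] = out["mean_beta_treated"] - out["mean_beta_control"]
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["direction"] = np.where(out["delta_beta"] > 0, "hyper", "hypo")
    out["significant"] = (out["p_adj"] < fdr) & (
        out["delta_beta"].abs() >= min_delta_beta
    )
    return out
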