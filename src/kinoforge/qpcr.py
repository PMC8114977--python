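"""ddCt relative quantification from triplicate qPCR Ct values.

Per sample the median of the technical triplicate is taken; target Ct is
normalized against a reference (housekeeping) gene to give dCt; treated and
solvent-control replicates are paired by replicate index to give
ddCt = dCt_treated - dCt_solvent, and the log2 fold change is

    logFC = -ddCt

so that fewer cycles (more transcript) under treatment reads as
up-regulation.  Significance is a two-sided paired t-test across replicate
pairs (an unpaired Welch fallback is available).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ValidationError

__all__ = ["validate_ct_table", "quantify", "REFERENCE_GENE"]

logger = logging.getLogger(__name__)

REFERENCE_GENE = "ACTB"
TREATED = "treated"
SOLVENT = "solvent"

_CT_COLUMNS = ["gene_id", "sample_id", "condition", "replicate", "ct1", "ct2", "ct3"]


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format Ct table (one row per gene x sample,
    triplicate Ct readings in ct1..ct3, condition treated/solvent)."""
    missing = [c for c in _CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"Ct table lacks columns {missing}")
    df = table[_CT_COLUMNS].copy()
    bad_cond = set(df["condition"].unique()) - {TREATED, SOLVENT}
    if bad_cond:
        raise ValidationError(
            f"condition must be '{TREATED}' or '{SOLVENT}', got {sorted(bad_cond)}"
        )
    cts = df[["ct1", "ct2", "ct3"]].to_numpy(dtype=float)
    if np.isnan(cts).any() or (cts <= 0).any() or (cts >= 45).any():
        raise ValidationError("Ct values must be finite and inside (0, 45)")
    if df.duplicated(["gene_id", "condition", "replicate"]).any():
        raise ValidationError("duplicate (gene, condition, replicate) rows")
    return df


def quantify(
    table: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    paired: bool = True,
) -> pd.DataFrame:
    """ddCt quantification of every target gene against the reference.

    Returns one row per target gene with the mean log2 fold change
    (treated vs solvent), per-replicate ddCt spread (sd), the number of
    replicate pairs and the paired t-test p-value.  Degenerate cases
    (zero-variance differences, e.g. target identical to reference) are
    reported with p = 1 and ``zero_variance`` flagged.
    """
    df = validate_ct_table(table)
    df["ct_median"] = df[["ct1", "ct2", "ct3"]].median(axis=1)

    ref = df[df["gene_id"] == reference_gene]
    if ref.empty:
        raise ValidationError(f"reference gene {reference_gene!r} absent from table")
    ref_ct = ref.set_index(["condition", "replicate"])["ct_median"]
    samples = df.set_index(["condition", "replicate"]).index.unique()
    no_ref = [s for s in samples if s not in ref_ct.index]
    if no_ref:
        raise ValidationError(f"reference gene missing for samples: {no_ref}")

    results = []
    for gene, sub in df[df["gene_id"] != reference_gene].groupby("gene_id"):
        dct = (
            sub.set_index(["condition", "replicate"])["ct_median"] - ref_ct
        ).dropna()
        try:
            treated = dct.loc[TREATED]
            solvent = dct.loc[SOLVENT]
        except KeyError as err:
            raise ValidationError(f"gene {gene!r} lacks condition {err}") from None
        if paired:
            reps = treated.index.intersection(solvent.index)
            ddct = (treated.loc[reps] - solvent.loc[reps]).to_numpy()
        else:
            ddct = np.array([treated.mean() - solvent.mean()])
        logfc = -ddct
        n_pairs = len(logfc) if paired else min(len(treated), len(solvent))

        p, zero_var = np.nan, False
        if paired:
            if n_pairs < 2:
                logger.warning("gene %s: <2 replicate pairs, t-test skipped", gene)
            elif np.allclose(ddct, ddct[0]):
                zero_var = True
                p = 1.0 if np.allclose(ddct, 0) else 0.0
                if np.allclose(ddct, 0):
                    logger.warning("gene %s: zero-variance zero differences; p set to 1",
                                   gene)
            else:
                p = float(sps.ttest_rel(-ddct, np.zeros_like(ddct)).pvalue)
        else:
            t_arr, s_arr = treated.to_numpy(), solvent.to_numpy()
            if len(t_arr) >= 2 and len(s_arr) >= 2:
                if np.allclose(t_arr, t_arr[0]) and np.allclose(s_arr, s_arr[0]):
                    zero_var = True
                    p = 1.0 if np.isclose(t_arr[0], s_arr[0]) else 0.0
                else:
                    p = float(sps.ttest_ind(-t_arr, -s_arr, equal_var=False).pvalue)
        results.append(
            {
                "gene_id": gene,
                "n_pairs": n_pairs,
                "logfc": float(np.mean(logfc)),
                "logfc_sd": float(np.std(logfc, ddof=1)) if len(logfc) > 1 else np.nan,
                "fold_change": float(2.0 ** np.mean(logfc)),
                "p": p,
                "zero_variance": zero_var,
            }
        )
    return pd.DataFrame(results)
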