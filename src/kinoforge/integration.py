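"""Starburst integration of methylation and expression results.

Every (CpG probe, gene) combination present in both omics becomes a pair
with signed coordinates

    x = sign(logFC)  * -log10(expression FDR)
    y = sign(dbeta)  * -log10(methylation FDR)

and a two-tier class: ``blue`` when expression FDR < 0.05 and methylation
FDR < 0.1; ``red`` when additionally |dbeta| > 0.05 and |logFC| > 0.4.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ValidationError

__all__ = ["pair_probes_to_genes", "classify_pairs", "tier_counts", "common_genes"]

logger = logging.getLogger(__name__)

BLUE_EXPR_FDR = 0.05
BLUE_METH_FDR = 0.1
RED_MIN_DELTA_BETA = 0.05
RED_MIN_LOGFC = 0.4

#: floor on FDRs before -log10 so coordinates stay finite
_FDR_FLOOR = 1e-300


def pair_probes_to_genes(
    dmps: pd.DataFrame,
    expression: pd.DataFrame,
    probe_gene_map: pd.DataFrame,
    collapse: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join methylation and expression results through gene symbols.

    ``probe_gene_map`` maps CpG probes to genes (columns ``probe_id``,
    ``gene``); the expression table must carry a ``gene`` column.  Each
    (CpG probe, expression probe) combination sharing a gene yields one
    pair; ``collapse="min-fdr"`` keeps only the lowest-expression-FDR probe
    per (CpG, gene).  Returns (pairs, unmatched report).
    """
    if "gene" not in expression.columns:
        raise ValidationError("expression table needs a 'gene' column")
    cpg_gene = probe_gene_map.rename(columns={"probe_id": "cpg_probe"})[
        ["cpg_probe", "gene"]
    ].dropna()
    meth = dmps.rename_axis("cpg_probe").reset_index()[
        ["cpg_probe", "delta_beta", "p_adj"]
    ].rename(columns={"p_adj": "meth_fdr"})
    expr = expression.rename_axis("expr_probe").reset_index()[
        ["expr_probe", "gene", "logfc", "p_adj"]
    ].rename(columns={"p_adj": "expr_fdr"})

    pairs = cpg_gene.merge(meth, on="cpg_probe").merge(expr, on="gene")
    if collapse == "min-fdr":
        pairs = (
            pairs.sort_values("expr_fdr", kind="mergesort")
            .drop_duplicates(["cpg_probe", "gene"])
        )
    elif collapse is not None:
        raise ValueError(f"unknown collapse mode {collapse!r}")
    pairs = pairs.sort_values(["cpg_probe", "gene", "expr_probe"],
                              kind="mergesort").reset_index(drop=True)

    matched_cpgs = set(pairs["cpg_probe"])
    matched_genes = set(pairs["gene"])
    unmatched = pd.concat(
        [
            pd.DataFrame({"feature_id": sorted(set(meth["cpg_probe"]) - matched_cpgs),
                          "kind": "cpg"}),
            pd.DataFrame({"feature_id": sorted(set(expr["gene"].dropna()) - matched_genes),
                          "kind": "gene"}),
        ],
        ignore_index=True,
    )
    if pairs.empty:
        logger.warning("no CpG-gene pairs shared between the two omics")
    return pairs, unmatched


def classify_pairs(
    pairs: pd.DataFrame,
    expr_fdr: float = BLUE_EXPR_FDR,
    meth_fdr: float = BLUE_METH_FDR,
    min_delta_beta: float = RED_MIN_DELTA_BETA,
    min_logfc: float = RED_MIN_LOGFC,
) -> pd.DataFrame:
    """Add starburst coordinates and tier labels to a pairs table."""
    out = pairs.copy()
    efdr = out["expr_fdr"].clip(lower=_FDR_FLOOR)
    mfdr = out["meth_fdr"].clip(lower=_FDR_FLOOR)
    out["x"] = np.sign(out["logfc"]) * -np.log10(efdr)
    out["y"] = np.sign(out["delta_beta"]) * -np.log10(mfdr)
    blue = (out["expr_fdr"] < expr_fdr) & (out["meth_fdr"] < meth_fdr)
    red = blue & (out["delta_beta"].abs() > min_delta_beta) & (
        out["logfc"].abs() > min_logfc
    )
    out["tier"] = np.where(red, "red", np.where(blue, "blue", "none"))
    return out


def tier_counts(classified: pd.DataFrame) -> dict[str, int]:
    """Pair counts per tier; red pairs also count as blue (red is a subset)."""
    n_red = int((classified["tier"] == "red").sum())
    n_blue = n_red + int((classified["tier"] == "blue").sum())
    return {"total": len(classified), "blue": n_blue, "red": n_red}


def common_genes(classified: pd.DataFrame, tier: str = "blue") -> list[str]:
    """Genes appearing in pairs at the requested tier or better."""
    wanted = {"red"} if tier == "red" else {"red", "blue"}
    return sorted(classified.loc[classified["tier"].isin(wanted), "gene"].unique())
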