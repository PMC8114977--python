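"""Genomic-context enrichment of differentially methylated positions.

For each level of each annotation axis (gene relation, CpG-island relation,
enhancer flag, repeat class) a 2x2 table DMP/non-DMP x in-level/not-in-level
is tested with the two-sided Fisher exact test; BH adjustment runs within
each axis.  ``repeat_profile`` adds per-repeat-class effect summaries
(mean delta-beta, hyper/hypo counts) on top of the enrichment scan.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_exact_batch
from .containers import ValidationError

__all__ = ["ANNOTATION_AXES", "validate_annotations", "enrich", "repeat_profile"]

logger = logging.getLogger(__name__)

#: axis name -> allowed levels (annotation tables must use these labels)
ANNOTATION_AXES: dict[str, tuple[str, ...]] = {
    "gene_relation": ("promoter", "body", "3'UTR", "intergenic"),
    "cgi_relation": ("island", "shore", "open_sea"),
    "enhancer": ("enhancer", "non_enhancer"),
    "repeat_class": ("LINE", "SINE", "LTR", "none"),
}


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Check the annotation table covers every axis with legal labels.

    Expects columns ``probe_id``, the four axis columns (``enhancer`` may be
    boolean; it is mapped to enhancer/non_enhancer) and optionally ``gene``.
    Returns a copy indexed by probe id.
    """
    df = annotations.copy()
    if "probe_id" in df.columns:
        df = df.set_index("probe_id")
    if not df.index.is_unique:
        raise ValidationError("duplicate probe ids in annotation table")
    if df["enhancer"].dtype == bool or set(df["enhancer"].unique()) <= {True, False}:
        df["enhancer"] = np.where(df["enhancer"].astype(bool), "enhancer", "non_enhancer")
    for axis, levels in ANNOTATION_AXES.items():
        if axis not in df.columns:
            raise ValidationError(f"annotation table lacks column {axis!r}")
        bad = set(df[axis].unique()) - set(levels)
        if bad:
            raise ValidationError(f"illegal {axis} labels: {sorted(bad)}")
    return df


def enrich(
    dmps: pd.DataFrame | pd.Index,
    annotations: pd.DataFrame,
    universe: pd.Index | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of the DMP set across every annotation level.

    Parameters
    ----------
    dmps
        A :func:`~kinoforge.differential.call_dmps` table (its ``significant``
        flag selects the DMP set) or directly an index of DMP probe ids.
    annotations
        Per-probe annotation table (see :func:`validate_annotations`).
    universe
        Background probe set; defaults to all annotated probes.  The
        background choice matters: it should be the QC-surviving probes the
        DMPs were called from, not the full array manifest.

    Returns one row per (axis, level) with the 2x2 counts, odds ratio, fold
    enrichment, two-sided Fisher p and BH-adjusted p within the axis.
    """
    ann = validate_annotations(annotations)
    if isinstance(dmps, pd.DataFrame):
        dmp_ids = pd.Index(dmps.index[dmps["significant"]] if "significant" in dmps
                           else dmps.index)
    else:
        dmp_ids = pd.Index(dmps)
    if universe is None:
        universe = ann.index
    universe = pd.Index(universe).unique()
    missing = universe.difference(ann.index)
    if len(missing):
        raise ValidationError(f"probes missing annotation: {list(missing[:5])}")
    stray = dmp_ids.difference(universe)
    if len(stray):
        raise ValidationError(f"DMP probes outside universe: {list(stray[:5])}")

    ann = ann.loc[universe]
    is_dmp = ann.index.isin(dmp_ids)
    n_dmp, n_tot = int(is_dmp.sum()), len(universe)

    rows, tables = [], []
    for axis, levels in ANNOTATION_AXES.items():
        values = ann[axis].to_numpy()
        for level in levels:
            in_level = values == level
            a = int(np.count_nonzero(is_dmp & in_level))
            b = n_dmp - a
            c = int(np.count_nonzero(~is_dmp & in_level))
            d = (n_tot - n_dmp) - c
            n_level = a + c
            if n_level == 0:
                logger.warning("level %s/%s has no probes in universe; omitted",
                               axis, level)
                continue
            fold = (
                (a / n_dmp) / (n_level / n_tot) if n_dmp and n_level else np.nan
            )
            rows.append({"axis": axis, "level": level, "dmp_in": a, "dmp_out": b,
                         "rest_in": c, "rest_out": d, "fold_enrichment": fold})
            tables.append([[a, b], [c, d]])

    result = pd.DataFrame(rows)
    oddsratio, p = fisher_exact_batch(np.array(tables))
    result["odds_ratio"] = oddsratio
    result["p"] = p
    result["p_adj"] = np.nan
    for axis in result["axis"].unique():
        mask = result["axis"] == axis
        result.loc[mask, "p_adj"] = bh_adjust(result.loc[mask, "p"].to_numpy())
    result["direction"] = np.where(result["odds_ratio"] > 1, "enriched", "depleted")
    return result


def repeat_profile(dmps: pd.DataFrame, annotations: pd.DataFrame,
                   universe: pd.Index | None = None) -> pd.DataFrame:
    """Per-repeat-class methylation summary for a DMP table.

    For each repeat class: probe counts, mean delta-beta over universe
    probes in the class, hyper/hypo DMP counts, and the Fisher enrichment
    row for that class.  Requires a full ``call_dmps`` table (it reads
    ``delta_beta`` and ``direction`` of every tested probe).
    """
    ann = validate_annotations(annotations)
    if universe is None:
        universe = ann.index.intersection(dmps.index)
    universe = pd.Index(universe)
    enr = enrich(dmps.loc[dmps.index.intersection(universe)], ann, universe)
    enr = enr[enr["axis"] == "repeat_class"].set_index("level")

    rows = []
    ann_u = ann.loc[universe]
    dmp_u = dmps.loc[universe]
    sig = dmp_u["significant"]
    for cls in ANNOTATION_AXES["repeat_class"]:
        in_cls = ann_u["repeat_class"] == cls
        if not in_cls.any():
            logger.warning("repeat class %s absent from universe; omitted", cls)
            continue
        sub = dmp_u.loc[in_cls.to_numpy()]
        sub_sig = sub[sig.loc[sub.index]]
        rows.append({
            "repeat_class": cls,
            "n_probes": int(in_cls.sum()),
            "mean_delta_beta": float(sub["delta_beta"].mean()),
            "n_dmp_hyper": int((sub_sig["direction"] == "hyper").sum()),
            "n_dmp_hypo": int((sub_sig["direction"] == "hypo").sum()),
            "odds_ratio": float(enr.loc[cls, "odds_ratio"]) if cls in enr.index else np.nan,
            "p": float(enr.loc[cls, "p"]) if cls in enr.index else np.nan,
            "p_adj": float(enr.loc[cls, "p_adj"]) if cls in enr.index else np.nan,
        })
    return pd.DataFrame(rows)
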