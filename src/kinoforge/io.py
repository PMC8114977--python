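"""TSV readers/writers for every table the pipeline consumes or emits.

The canonical dialect is tab-delimited UTF-8 with a header row and '.'
decimals; ``sep=","`` switches any reader to CSV.  Matrix files carry the
feature id in the first column; the sample sheet maps sample ids to the
two group labels.
"""

from __future__ import annotations

import pandas as pd

from .containers import (
    BetaMatrix,
    ExpressionMatrix,
    IntensityMatrix,
    ValidationError,
)
from .kinome import KinasePeptideMap
from .qpcr import validate_ct_table

__all__ = [
    "read_sample_sheet",
    "read_matrix",
    "read_kinase_map",
    "read_annotations",
    "read_ct_table",
    "read_truth",
    "write_table",
    "write_matrix",
]

_GROUP_ALIASES = {
    "treated": "treated", "treatment": "treated", "case": "treated",
    "control": "control", "solvent": "control", "ctrl": "control",
}


def _read_tsv(path, sep: str = "\t", index_col=None) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, index_col=index_col)
    except FileNotFoundError:
        raise
    except Exception as err:  # surface pandas' line-numbered message
        raise ValidationError(f"malformed table {path}: {err}") from err


def _numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return df.astype(float)
    except (TypeError, ValueError):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValidationError(
                    f"{path}: non-numeric value in column {col!r}, row {bad[0]!r}"
                ) from None
        raise


def read_sample_sheet(path, sep: str = "\t") -> pd.Series:
    """Sample sheet: columns ``sample_id`` and ``group``.  Group labels are
    normalized (treated/treatment/case -> treated; control/solvent/ctrl ->
    control)."""
    df = _read_tsv(path, sep)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path}: sample sheet needs column {col!r}")
    groups = df.set_index("sample_id")["group"].astype(str).str.lower()
    unknown = set(groups.unique()) - set(_GROUP_ALIASES)
    if unknown:
        raise ValidationError(f"{path}: unrecognized group labels {sorted(unknown)}")
    return groups.map(_GROUP_ALIASES)


def read_matrix(
    path,
    kind: str,
    groups: pd.Series,
    sep: str = "\t",
    scale: str = "log2",
    detection_path=None,
    gene_map_path=None,
):
    """Load a feature x sample matrix as the requested container.

    ``kind`` is ``"intensity"``, ``"expression"`` or ``"beta"``.  Duplicate
    feature ids and non-numeric cells are rejected with the offending
    id/column named.
    """
    df = _read_tsv(path, sep, index_col=0)
    if not df.index.is_unique:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate feature ids {dupes}")
    df = _numeric(df, path)
    if kind == "intensity":
        return IntensityMatrix(df, groups, scale=scale)
    if kind == "expression":
        detection = None
        if detection_path is not None:
            detection = _numeric(_read_tsv(detection_path, sep, index_col=0), detection_path)
            detection = detection.loc[df.index, df.columns]
        gene_map = None
        if gene_map_path is not None:
            gene_map = _read_tsv(gene_map_path, sep)
            for col in ("probe_id", "gene"):
                if col not in gene_map.columns:
                    raise ValidationError(f"{gene_map_path}: needs column {col!r}")
        return ExpressionMatrix(df, groups, scale=scale, detection_p=detection,
                                probe_gene_map=gene_map)
    if kind == "beta":
        return BetaMatrix(df, groups)
    raise ValueError(f"unknown matrix kind {kind!r}")


def read_kinase_map(path, sep: str = "\t") -> KinasePeptideMap:
    df = _read_tsv(path, sep)
    for col in ("kinase_id", "peptide_id"):
        if col not in df.columns:
            raise ValidationError(f"{path}: kinase map needs column {col!r}")
    return KinasePeptideMap(df[["kinase_id", "peptide_id"]])


def read_annotations(path, sep: str = "\t") -> pd.DataFrame:
    from .enrichment import validate_annotations

    df = _read_tsv(path, sep)
    if "gene" in df.columns:
        df["gene"] = df["gene"].fillna("")
    validate_annotations(df)
    return df


def read_ct_table(path, sep: str = "\t") -> pd.DataFrame:
    return validate_ct_table(_read_tsv(path, sep))


def read_truth(path, sep: str = "\t") -> pd.DataFrame:
    df = _read_tsv(path, sep)
    for col in ("feature_id", "kind", "effect", "direction"):
        if col not in df.columns:
            raise ValidationError(f"{path}: truth table needs column {col!r}")
    return df


def write_table(df: pd.DataFrame, path, sep: str = "\t", index: bool = False) -> None:
    pd.DataFrame(df).to_csv(path, sep=sep, index=index)


def write_matrix(matrix, path, sep: str = "\t") -> None:
    """Write a container's value matrix with the feature id as first column."""
    matrix.values.rename_axis("feature_id").to_csv(path, sep=sep)
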