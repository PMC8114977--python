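"""In-memory containers for the two-group omics matrices the pipeline consumes.

All matrices are features x samples :class:`pandas.DataFrame` objects wrapped
with a sample->group mapping.  Exactly two groups are supported, canonically
named ``"treated"`` and ``"control"``; every effect size downstream is
oriented treated minus control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATED = "treated"
CONTROL = "control"

__all__ = [
    "TREATED",
    "CONTROL",
    "ValidationError",
    "TwoGroupMatrix",
    "IntensityMatrix",
    "ExpressionMatrix",
    "BetaMatrix",
]


class ValidationError(ValueError):
    """Raised when an input matrix or table fails load-time validation."""


def _check_groups(values: pd.DataFrame, groups: pd.Series) -> pd.Series:
    groups = pd.Series(groups)
    missing = [s for s in values.columns if s not in groups.index]
    if missing:
        raise ValidationError(f"samples without a group label: {missing}")
    groups = groups.loc[values.columns]
    levels = set(groups.unique())
    if levels != {TREATED, CONTROL}:
        raise ValidationError(
            f"exactly two groups '{TREATED}' and '{CONTROL}' required, got {sorted(levels)}"
        )
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ValidationError(
            f"each group needs >= 2 samples, got {counts.to_dict()}"
        )
    return groups


@dataclass
class TwoGroupMatrix:
    """Features x samples matrix with a two-group design.

    Parameters
    ----------
    values
        Numeric matrix, rows indexed by feature id, columns by sample id.
    groups
        Mapping (``pd.Series``) from sample id to ``"treated"``/``"control"``.
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dupes}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()[:5]
            raise ValidationError(f"missing values in features {bad}")
        self.values = self.values.astype(float)
        self.groups = _check_groups(self.values, self.groups)

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def treated_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == TREATED])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == CONTROL])

    def group_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (treated, control) value blocks as float arrays."""
        return (
            self.values[self.treated_samples].to_numpy(),
            self.values[self.control_samples].to_numpy(),
        )

    def swap_groups(self):
        """Return a copy with treated/control labels exchanged."""
        swapped = self.groups.map({TREATED: CONTROL, CONTROL: TREATED})
        return type(self)(self.values.copy(), swapped, **self._extra_kwargs())

    def _extra_kwargs(self) -> dict:
        return {}


@dataclass
class IntensityMatrix(TwoGroupMatrix):
    """Phosphopeptide signal matrix (peptides x samples).

    ``scale`` is ``"raw"`` or ``"log2"``; :meth:`to_log2` converts in place
    semantics-free (returns a new object).
    """

    scale: str = "log2"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.scale == "raw" and (self.values.to_numpy() < 0).any():
            raise ValidationError("raw intensities must be non-negative")

    def to_log2(self) -> "IntensityMatrix":
        if self.scale == "log2":
            return self
        vals = self.values
        if (vals.to_numpy() <= 0).any():
            vals = vals + 1.0  # zero-signal guard
        return IntensityMatrix(np.log2(vals), self.groups, scale="log2")

    def _extra_kwargs(self) -> dict:
        return {"scale": self.scale}


@dataclass
class ExpressionMatrix(TwoGroupMatrix):
    """Expression probe matrix with optional per-cell detection p-values
    and a probe->gene map (``probe_id``, ``gene`` columns)."""

    scale: str = "log2"
    detection_p: pd.DataFrame | None = None
    probe_gene_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.detection_p is not None:
            dp = self.detection_p
            if list(dp.index) != list(self.values.index) or list(dp.columns) != list(
                self.values.columns
            ):
                raise ValidationError("detection p-value table must match matrix shape")

    def _extra_kwargs(self) -> dict:
        return {
            "scale": self.scale,
            "detection_p": self.detection_p,
            "probe_gene_map": self.probe_gene_map,
        }


@dataclass
class BetaMatrix(TwoGroupMatrix):
    """Methylation beta-value matrix; betas are clipped into (0,1) at load.

    ``clip_eps`` is the boundary guard used when a value sits on 0 or 1.
    """

    clip_eps: float = 1e-3

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values.to_numpy()
        if (vals < 0).any() or (vals > 1).any():
            raise ValidationError("beta-values must lie in [0, 1]")
        if (vals <= 0).any() or (vals >= 1).any():
            self.values = self.values.clip(self.clip_eps, 1 - self.clip_eps)

    def _extra_kwargs(self) -> dict:
        return {"clip_eps": self.clip_eps}
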