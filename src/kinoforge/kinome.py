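"""Upstream kinase activity inference from phosphopeptide-array data.

A kinase's activity change is summarized by the normalized kinase statistic

    tau = (1/n) * sum_i (mean_i,treated - mean_i,control) / sqrt(s2_i,treated + s2_i,control)

over the n peptides mapped to that kinase, where means and variances are of
log2 peptide intensities per group.  tau > 0 reads "activated under
treatment".  Two permutation scores accompany each tau:

* significance score: group labels are shuffled across samples M times;
* specificity score: a random peptide set of the same size n is drawn from
  the whole chip M times;

and each is reported as Q = -log10(max(m/M, 1/M)) with m the number of
permutations where |tau_p| strictly exceeds |tau|.  Kinases are ranked by
the sum of the two scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal

import numpy as np
import pandas as pd

from ._stats import bh_adjust, welch_ttest
from .containers import IntensityMatrix, ValidationError

__all__ = [
    "KinasePeptideMap",
    "PermutationScore",
    "peptide_differential",
    "kinase_statistic",
    "permutation_scores",
    "rank_kinases",
    "DEFAULT_PERMUTATIONS",
    "DEFAULT_MIN_PEPTIDES",
    "VARIANCE_FLOOR",
]

logger = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 500
DEFAULT_MIN_PEPTIDES = 3
#: floor on s2_1 + s2_2 so flat peptides cannot divide by zero
VARIANCE_FLOOR = 1e-8


class KinasePeptideMap:
    """Many-to-many kinase -> peptide associations.

    A peptide motif may be a substrate of several kinases, so peptide sets
    overlap freely.  Built from an iterable of (kinase_id, peptide_id) pairs
    or a two-column DataFrame.
    """

    def __init__(self, pairs) -> None:
        if isinstance(pairs, pd.DataFrame):
            df = pairs.iloc[:, :2].copy()
            df.columns = ["kinase_id", "peptide_id"]
        else:
            df = pd.DataFrame(list(pairs), columns=["kinase_id", "peptide_id"])
        if df.empty:
            raise ValidationError("kinase->peptide map is empty")
        df = df.drop_duplicates()
        self.pairs = df.reset_index(drop=True)
        self._sets: dict[str, list[str]] = {
            k: g["peptide_id"].tolist() for k, g in self.pairs.groupby("kinase_id")
        }

    @property
    def kinases(self) -> list[str]:
        return sorted(self._sets)

    def peptides_for(self, kinase: str) -> list[str]:
        try:
            return self._sets[kinase]
        except KeyError:
            raise KeyError(f"kinase {kinase!r} not in map") from None

    def set_size(self, kinase: str) -> int:
        return len(self.peptides_for(kinase))

    def __len__(self) -> int:
        return len(self._sets)


def peptide_differential(matrix: IntensityMatrix) -> pd.DataFrame:
    """Per-peptide two-sided Welch t-test with BH correction across the chip.

    Returns a DataFrame indexed by peptide id with group means/variances
    (log2 units), ``t``, ``p`` and ``p_adj``.  Raw-scale matrices are log2
    transformed first.
    """
    matrix = matrix.to_log2()
    a, b = matrix.group_arrays()
    t, p = welch_ttest(a, b)
    out = pd.DataFrame(
        {
            "mean_treated": a.mean(axis=1),
            "mean_control": b.mean(axis=1),
            "var_treated": a.var(axis=1, ddof=1),
            "var_control": b.var(axis=1, ddof=1),
            "t": t,
            "p": p,
        },
        index=matrix.feature_ids,
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def _standardized_diffs(
    block1: np.ndarray, block2: np.ndarray, variance_floor: float = VARIANCE_FLOOR
) -> np.ndarray:
    """(mean1 - mean2)/sqrt(s2_1 + s2_2) row-wise; works on stacked
    permutation blocks (..., n_samples)."""
    num = block1.mean(axis=-1) - block2.mean(axis=-1)
    denom2 = block1.var(axis=-1, ddof=1) + block2.var(axis=-1, ddof=1)
    floored = denom2 < variance_floor
    if floored.any():
        logger.warning(
            "variance floor %g applied to %d peptide term(s)",
            variance_floor,
            int(floored.sum()),
        )
        denom2 = np.maximum(denom2, variance_floor)
    return num / np.sqrt(denom2)


def kinase_statistic(
    stats: pd.DataFrame,
    kmap: KinasePeptideMap,
    kinase: str,
    min_peptides: int = 1,
    variance_floor: float = VARIANCE_FLOOR,
) -> float:
    """Normalized kinase statistic tau from a peptide_differential table."""
    peptides = [p for p in kmap.peptides_for(kinase) if p in stats.index]
    if len(peptides) < max(min_peptides, 1):
        raise ValidationError(
            f"kinase {kinase!r} has {len(peptides)} mapped peptides in the data, "
            f"needs >= {max(min_peptides, 1)}"
        )
    sub = stats.loc[peptides]
    num = sub["mean_treated"].to_numpy() - sub["mean_control"].to_numpy()
    denom2 = sub["var_treated"].to_numpy() + sub["var_control"].to_numpy()
    floored = denom2 < variance_floor
    if floored.any():
        logger.warning(
            "variance floor %g applied to %d peptide term(s) of kinase %s",
            variance_floor,
            int(floored.sum()),
            kinase,
        )
        denom2 = np.maximum(denom2, variance_floor)
    return float(np.mean(num / np.sqrt(denom2)))


@dataclass(frozen=True)
class PermutationScore:
    """Result of one permutation scan: observed tau, exceedance count m out
    of M permutations, and Q = -log10(max(m/M, 1/M))."""

    tau: float
    m: int
    M: int
    q: float


def _q_score(m: int, M: int) -> float:
    return float(-np.log10(max(m / M, 1.0 / M)))


def _sample_label_splits(
    n_samples: int, n_treated: int, M: int, rng: np.random.Generator
) -> np.ndarray:
    """M random reassignments of which columns form the treated group."""
    u = rng.random((M, n_samples))
    return np.argsort(u, axis=1)


def permutation_scores(
    matrix: IntensityMatrix,
    kmap: KinasePeptideMap,
    kinase: str,
    mode: Literal["samples", "peptides"],
    M: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.SeedSequence = 0,
    exhaustive: bool = False,
    variance_floor: float = VARIANCE_FLOOR,
) -> PermutationScore:
    """Permutation score for one kinase.

    ``mode="samples"`` shuffles group labels across all samples
    (significance score); ``mode="peptides"`` draws random peptide sets of
    the kinase's size from the whole chip (specificity score).  With
    ``exhaustive=True`` and ``mode="samples"`` all distinct label
    assignments are enumerated and M is overridden by their count.
    """
    if M < 1:
        raise ValidationError("permutation count M must be >= 1")
    matrix = matrix.to_log2()
    X = matrix.values.to_numpy()
    peptide_index = matrix.feature_ids
    treated_cols = [matrix.values.columns.get_loc(s) for s in matrix.treated_samples]
    control_cols = [matrix.values.columns.get_loc(s) for s in matrix.control_samples]
    n1, n2 = len(treated_cols), len(control_cols)

    peptides = [p for p in kmap.peptides_for(kinase) if p in peptide_index]
    if not peptides:
        raise ValidationError(f"kinase {kinase!r} has no peptides on the chip")
    rows = peptide_index.get_indexer(peptides)
    n = len(rows)

    d_obs = _standardized_diffs(X[:, treated_cols], X[:, control_cols], variance_floor)
    tau = float(d_obs[rows].mean())

    rng = np.random.default_rng(seed)
    if mode == "samples":
        Xk = X[rows]
        col_order = np.array(treated_cols + control_cols)
        if exhaustive:
            splits = np.array(
                [list(c) + [i for i in range(n1 + n2) if i not in c]
                 for c in combinations(range(n1 + n2), n1)]
            )
            M = comb(n1 + n2, n1)
        else:
            splits = _sample_label_splits(n1 + n2, n1, M, rng)
        perm_cols = col_order[splits]  # (M, n_samples) original column ids
        g1 = Xk[:, perm_cols[:, :n1]]  # (n, M, n1)
        g2 = Xk[:, perm_cols[:, n1:]]
        tau_p = _standardized_diffs(
            np.moveaxis(g1, 0, 1), np.moveaxis(g2, 0, 1), variance_floor
        ).mean(axis=1)
    elif mode == "peptides":
        total = len(peptide_index)
        if n > total:
            raise ValidationError(
                f"kinase set size {n} exceeds chip size {total}"
            )
        u = rng.random((M, total))
        # sort so summation order is canonical: identical sets give bit-equal tau
        subsets = np.sort(np.argpartition(u, n - 1, axis=1)[:, :n], axis=1)
        tau_p = d_obs[subsets].mean(axis=1)
    else:
        raise ValueError("mode must be 'samples' or 'peptides'")

    m = int(np.count_nonzero(np.abs(tau_p) > np.abs(tau)))
    return PermutationScore(tau=tau, m=m, M=M, q=_q_score(m, M))


def rank_kinases(
    matrix: IntensityMatrix,
    kmap: KinasePeptideMap,
    M: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    min_peptides: int = DEFAULT_MIN_PEPTIDES,
    variance_floor: float = VARIANCE_FLOOR,
) -> tuple[pd.DataFrame, list[str]]:
    """Score and rank every kinase in the map.

    Returns the ranked score table (descending combined score; ties broken
    by larger |tau|, then kinase id) and the list of kinases skipped for
    having fewer than ``min_peptides`` peptides present on the chip.
    Each kinase gets its own deterministic permutation stream derived from
    ``seed``, so adding or removing kinases does not perturb the others.
    """
    matrix = matrix.to_log2()
    peptide_index = set(matrix.feature_ids)
    scorable, skipped = [], []
    for kinase in kmap.kinases:
        present = [p for p in kmap.peptides_for(kinase) if p in peptide_index]
        (scorable if len(present) >= min_peptides else skipped).append(kinase)
    if skipped:
        logger.info("skipping %d kinase(s) below min_peptides=%d: %s",
                    len(skipped), min_peptides, skipped)
    if not scorable:
        raise ValidationError(
            f"no kinase has >= {min_peptides} peptides on the chip "
            f"({len(kmap)} kinases in map, {len(peptide_index)} peptides measured)"
        )

    root = np.random.SeedSequence(seed)
    streams = root.spawn(2 * len(scorable))
    records = []
    for i, kinase in enumerate(scorable):
        sig = permutation_scores(
            matrix, kmap, kinase, "samples", M=M, seed=streams[2 * i],
            variance_floor=variance_floor,
        )
        spec = permutation_scores(
            matrix, kmap, kinase, "peptides", M=M, seed=streams[2 * i + 1],
            variance_floor=variance_floor,
        )
        n_present = len([p for p in kmap.peptides_for(kinase) if p in peptide_index])
        records.append(
            {
                "kinase_id": kinase,
                "n_peptides": n_present,
                "tau": sig.tau,
                "significance_q": sig.q,
                "specificity_q": spec.q,
                "combined_score": sig.q + spec.q,
                "direction": "activated" if sig.tau > 0 else "inhibited",
            }
        )
    scores = pd.DataFrame(records)
    scores["_abs_tau"] = scores["tau"].abs()
    scores = scores.sort_values(
        ["combined_score", "_abs_tau", "kinase_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="_abs_tau")
    scores["rank"] = np.arange(1, len(scores) + 1)
    return scores.reset_index(drop=True), skipped
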