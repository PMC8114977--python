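"""Synthetic multi-omics data with planted ground truth.

Every pipeline input — phosphopeptide intensities, methylation betas with
probe annotations, expression probes with detection p-values, and qPCR Ct
triplicates — can be generated here with known planted effects, so each
downstream stage is testable for recovery without any external download.

The planted truth is returned (and written) as a separate table with one
row per planted feature (``feature_id``, ``kind``, ``effect``,
``direction``); it is never embedded in the input files themselves.

Generative model, briefly:

* peptide log2 intensities = per-peptide log-normal baseline + Gaussian
  within-group noise; peptides mapped to a planted kinase get a
  ``delta x noise-SD`` shift in the treated group;
* beta-values are built on the M-value (log2-logit) scale with Gaussian
  probe baselines and noise, so betas land strictly inside (0,1); planted
  probes are shifted by a fixed delta-beta on the beta scale and are drawn
  with elevated probability (relative risk r) from one annotation category;
* expression logFCs can be sign-coupled to planted DMPs through shared gene
  symbols; qPCR Ct triplicates are ddCt-consistent with a planted log2 fold
  change plus technical noise and a per-sample global Ct offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import BetaMatrix, ExpressionMatrix, IntensityMatrix, ValidationError
from .differential import m_inverse, m_transform
from .enrichment import ANNOTATION_AXES
from .kinome import KinasePeptideMap

__all__ = ["SimulationConfig", "InvalidConfigError", "simulate_kinome",
           "simulate_methylome", "simulate_expression_and_qpcr", "simulate_all"]


class InvalidConfigError(ValidationError):
    """Raised when a SimulationConfig fails validation."""


#: marginal probabilities of each annotation level, before enrichment
_ANNOTATION_PROBS = {
    "gene_relation": {"promoter": 0.25, "body": 0.40, "3'UTR": 0.05, "intergenic": 0.30},
    "cgi_relation": {"island": 0.30, "shore": 0.25, "open_sea": 0.45},
    "enhancer": {"enhancer": 0.15, "non_enhancer": 0.85},
    "repeat_class": {"LINE": 0.15, "SINE": 0.12, "LTR": 0.08, "none": 0.65},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe one treated-vs-control in-vitro contrast: a 150-motif
    chip read in 6 samples per group with one strongly activated kinase,
    an EPIC-like slice of 2000 CpG probes with 5% planted DMPs of
    delta-beta +0.10 concentrated in LTR repeats at relative risk 5,
    expression anti-coupled to methylation, and a qPCR panel planted at a
    2-fold induction measured in 3 paired biological replicates.
    """

    seed: int = 0
    # kinome chip
    n_peptides: int = 150
    n_kinases: int = 20
    peptides_per_kinase: int = 8
    n_samples_per_group: int = 6
    planted_kinases: tuple[tuple[str, float], ...] = (("K01", 2.0),)
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    peptide_noise_sd: float = 0.5
    # methylome
    n_probes: int = 2000
    planted_dmp_fraction: float = 0.05
    planted_delta_beta: float = 0.10
    enriched_category: tuple[str, str] = ("repeat_class", "LTR")
    enrichment_relative_risk: float = 5.0
    beta_baseline_m_sd: float = 2.0
    beta_noise_sd: float = 0.3
    # expression
    n_genes: int = 200
    planted_logfc: float = 1.0
    expression_noise_sd: float = 0.3
    coupling: int = -1
    undetected_fraction: float = 0.05
    # qPCR
    qpcr_targets: tuple[str, ...] = ("QT1", "QT2", "QT3")
    qpcr_logfc: float = 1.0
    qpcr_noise_sd: float = 0.1
    n_qpcr_replicates: int = 3
    reference_gene: str = "ACTB"

    def __post_init__(self) -> None:
        counts = {
            "n_peptides": self.n_peptides, "n_kinases": self.n_kinases,
            "peptides_per_kinase": self.peptides_per_kinase,
            "n_samples_per_group": self.n_samples_per_group,
            "n_probes": self.n_probes, "n_genes": self.n_genes,
            "n_qpcr_replicates": self.n_qpcr_replicates,
        }
        for name, value in counts.items():
            if value <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {value}")
        if self.peptides_per_kinase < 2 or self.n_peptides < self.peptides_per_kinase:
            raise InvalidConfigError(
                "need n_peptides >= peptides_per_kinase >= 2"
            )
        if self.n_samples_per_group < 2:
            raise InvalidConfigError("need >= 2 samples per group")
        if not 0 <= self.planted_dmp_fraction <= 1:
            raise InvalidConfigError("planted_dmp_fraction must lie in [0, 1]")
        if abs(self.planted_delta_beta) >= 0.5:
            raise InvalidConfigError("|planted_delta_beta| must be < 0.5")
        if self.enrichment_relative_risk < 1:
            raise InvalidConfigError("enrichment_relative_risk must be >= 1")
        axis, level = self.enriched_category
        if axis not in ANNOTATION_AXES or level not in ANNOTATION_AXES[axis]:
            raise InvalidConfigError(f"unknown annotation category {axis}/{level}")
        for kid, _ in self.planted_kinases:
            if kid not in self.kinase_ids():
                raise InvalidConfigError(f"planted kinase {kid!r} outside K01..K{self.n_kinases:02d}")

    # deterministic id vocabularies -------------------------------------
    def kinase_ids(self) -> list[str]:
        return [f"K{i + 1:02d}" for i in range(self.n_kinases)]

    def peptide_ids(self) -> list[str]:
        return [f"P{i + 1:04d}" for i in range(self.n_peptides)]

    def probe_ids(self) -> list[str]:
        return [f"cg{i + 1:07d}" for i in range(self.n_probes)]

    def gene_ids(self) -> list[str]:
        return [f"GENE{i + 1:04d}" for i in range(self.n_genes)]

    def sample_ids(self) -> tuple[list[str], list[str]]:
        n = self.n_samples_per_group
        return ([f"T{i + 1}" for i in range(n)], [f"C{i + 1}" for i in range(n)])

    def groups(self) -> pd.Series:
        treated, control = self.sample_ids()
        return pd.Series(
            ["treated"] * len(treated) + ["control"] * len(control),
            index=treated + control,
        )

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # one independent child stream per generator, all rooted in config.seed
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def simulate_kinome(
    config: SimulationConfig,
) -> tuple[IntensityMatrix, KinasePeptideMap, pd.DataFrame]:
    """Phosphopeptide chip with planted kinase activations.

    Peptide sets are drawn per kinase without replacement but overlap
    freely across kinases (one site, many kinases).  Each planted kinase's
    peptides receive a ``delta x peptide_noise_sd`` log2 shift in the
    treated group; overlapping planted sets accumulate shifts.
    """
    rng = _rng(config, 0)
    peptides = config.peptide_ids()
    kinases = config.kinase_ids()
    pairs = [
        (k, peptides[i])
        for k in kinases
        for i in sorted(rng.choice(config.n_peptides, config.peptides_per_kinase,
                                   replace=False))
    ]
    kmap = KinasePeptideMap(pairs)

    treated, control = config.sample_ids()
    n1, n2 = len(treated), len(control)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          config.n_peptides)
    X = baseline[:, None] + rng.normal(
        0.0, config.peptide_noise_sd, (config.n_peptides, n1 + n2)
    )
    pep_pos = {p: i for i, p in enumerate(peptides)}
    for kid, delta in config.planted_kinases:
        rows = [pep_pos[p] for p in kmap.peptides_for(kid)]
        X[np.ix_(rows, range(n1))] += delta * config.peptide_noise_sd

    matrix = IntensityMatrix(
        pd.DataFrame(X, index=peptides, columns=treated + control),
        config.groups(), scale="log2",
    )
    truth = pd.DataFrame(
        [
            {"feature_id": kid, "kind": "kinase", "effect": delta,
             "direction": "activated" if delta > 0 else "inhibited"}
            for kid, delta in config.planted_kinases
        ],
        columns=["feature_id", "kind", "effect", "direction"],
    )
    return matrix, kmap, truth


def simulate_methylome(
    config: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame]:
    """EPIC-like beta matrix with planted DMPs and a full annotation table.

    Planted probes are chosen among probes whose baseline beta leaves room
    for the planted shift (both baseline and target inside (0.05, 0.95)),
    with selection probability multiplied by the relative risk for probes
    in the enriched annotation category.
    """
    rng = _rng(config, 1)
    probes = config.probe_ids()
    genes = config.gene_ids()

    ann = pd.DataFrame(index=pd.Index(probes, name="probe_id"))
    for axis, probs in _ANNOTATION_PROBS.items():
        levels = list(probs)
        ann[axis] = rng.choice(levels, size=config.n_probes, p=list(probs.values()))
    gene_assign = np.array(genes)[rng.integers(0, config.n_genes, config.n_probes)]
    ann["gene"] = np.where(ann["gene_relation"] == "intergenic", "", gene_assign)

    base_m = rng.normal(0.0, config.beta_baseline_m_sd, config.n_probes)
    base_beta = m_inverse(base_m)
    delta = config.planted_delta_beta
    n_planted = int(round(config.planted_dmp_fraction * config.n_probes))
    planted_idx = np.array([], dtype=int)
    if n_planted > 0 and delta != 0:
        eligible = (
            (base_beta > 0.05) & (base_beta < 0.95)
            & (base_beta + delta > 0.05) & (base_beta + delta < 0.95)
        )
        axis, level = config.enriched_category
        weights = np.where(ann[axis].to_numpy() == level,
                           config.enrichment_relative_risk, 1.0)
        weights = weights * eligible
        if np.count_nonzero(weights) < n_planted:
            raise InvalidConfigError(
                "not enough probes with headroom for the planted delta-beta"
            )
        planted_idx = rng.choice(config.n_probes, n_planted, replace=False,
                                 p=weights / weights.sum())

    treated, control = config.sample_ids()
    n1 = len(treated)
    m_treated = np.repeat(base_m[:, None], n1, axis=1)
    if len(planted_idx):
        m_treated[planted_idx] = m_transform(base_beta[planted_idx] + delta)[:, None]
    m_control = np.repeat(base_m[:, None], len(control), axis=1)
    M = np.concatenate([m_treated, m_control], axis=1)
    M = M + rng.normal(0.0, config.beta_noise_sd, M.shape)
    beta = m_inverse(M)

    matrix = BetaMatrix(
        pd.DataFrame(beta, index=probes, columns=treated + control), config.groups()
    )
    truth = pd.DataFrame(
        {
            "feature_id": [probes[i] for i in sorted(planted_idx)],
            "kind": "cpg",
            "effect": delta,
            "direction": "hyper" if delta > 0 else "hypo",
        },
        columns=["feature_id", "kind", "effect", "direction"],
    )
    return matrix, ann.reset_index(), truth


def simulate_expression_and_qpcr(
    config: SimulationConfig,
    methylome_truth: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression matrix + probe->gene map + qPCR Ct table + truth.

    When a methylome truth table and annotations are supplied, genes
    harboring a planted DMP get an expression logFC of
    ``coupling x sign(delta_beta) x planted_logfc`` (coupling = -1 puts
    hyper-methylated genes in the down-regulated starburst quadrants);
    otherwise every tenth gene is planted at ``planted_logfc``.
    """
    rng = _rng(config, 2)
    genes = config.gene_ids()

    # ~1.2 probes per gene: every gene one probe, every fifth a second
    probe_rows = [(f"ILMN_{i + 1:06d}", g) for i, g in enumerate(genes)]
    extra = genes[::5]
    probe_rows += [
        (f"ILMN_{len(genes) + j + 1:06d}", g) for j, g in enumerate(extra)
    ]
    probe_gene_map = pd.DataFrame(probe_rows, columns=["probe_id", "gene"])

    gene_logfc = pd.Series(0.0, index=genes)
    if methylome_truth is not None:
        if annotations is None:
            raise InvalidConfigError("coupling to DMPs needs the annotation table")
        ann = annotations.set_index("probe_id") if "probe_id" in annotations.columns \
            else annotations
        planted_cpgs = methylome_truth.loc[methylome_truth["kind"] == "cpg"]
        for _, rec in planted_cpgs.iterrows():
            gene = ann.loc[rec["feature_id"], "gene"]
            if gene:
                sign = 1.0 if rec["direction"] == "hyper" else -1.0
                gene_logfc[gene] = config.coupling * sign * config.planted_logfc
    else:
        for g in genes[::10]:
            gene_logfc[g] = config.planted_logfc

    treated, control = config.sample_ids()
    n1, n2 = len(treated), len(control)
    n_probes = len(probe_gene_map)
    baseline = rng.normal(7.5, 1.5, n_probes)
    X = baseline[:, None] + rng.normal(0.0, config.expression_noise_sd,
                                       (n_probes, n1 + n2))
    probe_logfc = probe_gene_map["gene"].map(gene_logfc).to_numpy()
    X[:, :n1] += probe_logfc[:, None]

    detection = rng.uniform(0.0, 0.04, (n_probes, n1 + n2))
    n_undetected = int(round(config.undetected_fraction * n_probes))
    if n_undetected:
        undetected = rng.choice(n_probes, n_undetected, replace=False)
        detection[undetected] = rng.uniform(0.06, 1.0, (n_undetected, n1 + n2))

    probe_index = pd.Index(probe_gene_map["probe_id"])
    matrix = ExpressionMatrix(
        pd.DataFrame(X, index=probe_index, columns=treated + control),
        config.groups(), scale="log2",
        detection_p=pd.DataFrame(detection, index=probe_index,
                                 columns=treated + control),
        probe_gene_map=probe_gene_map,
    )

    # qPCR: paired treated/solvent replicates, per-sample global Ct offset
    ct_rows = []
    panel = [(config.reference_gene, 0.0)] + [
        (t, config.qpcr_logfc) for t in config.qpcr_targets
    ]
    base_ct = {config.reference_gene: 15.0}
    base_ct.update({t: 24.0 + i for i, t in enumerate(config.qpcr_targets)})
    for rep in range(1, config.n_qpcr_replicates + 1):
        for cond in ("treated", "solvent"):
            sample_offset = rng.normal(0.0, 0.5)
            for gene, logfc in panel:
                mu = base_ct[gene] + sample_offset
                if cond == "treated":
                    mu -= logfc  # more transcript -> fewer cycles
                cts = mu + rng.normal(0.0, config.qpcr_noise_sd, 3)
                ct_rows.append({
                    "gene_id": gene, "sample_id": f"{cond[0].upper()}{rep}",
                    "condition": cond, "replicate": rep,
                    "ct1": cts[0], "ct2": cts[1], "ct3": cts[2],
                })
    ct_table = pd.DataFrame(ct_rows)

    truth_rows = [
        {"feature_id": g, "kind": "gene", "effect": lfc,
         "direction": "up" if lfc > 0 else "down"}
        for g, lfc in gene_logfc.items() if lfc != 0
    ] + [
        {"feature_id": t, "kind": "gene", "effect": config.qpcr_logfc,
         "direction": "up" if config.qpcr_logfc > 0 else "down"}
        for t in config.qpcr_targets
    ]
    truth = pd.DataFrame(truth_rows,
                         columns=["feature_id", "kind", "effect", "direction"])
    return matrix, probe_gene_map, ct_table, truth


def simulate_all(config: SimulationConfig) -> dict:
    """Run all three generators with cross-omics coupling; returns a dict of
    every input object plus the concatenated truth table."""
    intensity, kmap, truth_k = simulate_kinome(config)
    betas, annotations, truth_m = simulate_methylome(config)
    expression, probe_gene_map, ct_table, truth_e = simulate_expression_and_qpcr(
        config, methylome_truth=truth_m, annotations=annotations
    )
    return {
        "intensity": intensity,
        "kinase_map": kmap,
        "betas": betas,
        "annotations": annotations,
        "expression": expression,
        "probe_gene_map": probe_gene_map,
        "ct_table": ct_table,
        "truth": pd.concat([truth_k, truth_m, truth_e], ignore_index=True),
    }
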