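"""End-to-end pipeline orchestration with a reproducibility manifest.

``run_pipeline`` executes the stages in dependency order —
simulate -> kinome -> express -> dmp -> enrich -> integrate -> qpcr —
writing one TSV per stage plus a manifest JSON recording the seed, every
threshold and the SHA-256 of each artifact, so a rerun with the same
config is byte-identical and verifiably so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import differential, enrichment, integration, io, kinome, qpcr, simulate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "kinome", "express", "dmp", "enrich", "integrate", "qpcr")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and cause."""


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Input paths may be left None, in which case the synthetic generators
    supply that stage's input (the usual mode for self-contained runs).
    Thresholds default to the pipeline's standard gates.
    """

    outdir: str = "kinoforge_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # inputs (None -> synthesize)
    intensities: str | None = None
    sample_sheet: str | None = None
    kinase_map: str | None = None
    expression: str | None = None
    detection_p: str | None = None
    probe_gene_map: str | None = None
    betas: str | None = None
    annotations: str | None = None
    ct_table: str | None = None
    # thresholds
    expr_fdr: float = differential.EXPR_FDR
    expr_min_logfc: float = differential.EXPR_MIN_LOGFC
    meth_fdr: float = differential.METH_FDR
    meth_min_delta_beta: float = differential.METH_MIN_DELTA_BETA
    detection_p_threshold: float = 0.05
    detection_min_samples: int = 6
    permutations: int = kinome.DEFAULT_PERMUTATIONS
    min_peptides: int = kinome.DEFAULT_MIN_PEPTIDES
    reference_gene: str = qpcr.REFERENCE_GENE
    strict: bool = False
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("expr_fdr", "expr_min_logfc", "meth_fdr",
                     "meth_min_delta_beta", "detection_p_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dict.

    Raises :class:`PipelineError` (wrapping the cause) if any stage fails;
    missing input paths fail fast before any stage runs.
    """
    for attr in ("intensities", "sample_sheet", "kinase_map", "expression",
                 "detection_p", "probe_gene_map", "betas", "annotations",
                 "ct_table"):
        path = getattr(config, attr)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"input {attr} not found: {path}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = simulate.SimulationConfig(seed=config.seed, **config.simulation)
    artifacts: dict[str, Path] = {}
    data: dict = {}
    groups = (io.read_sample_sheet(config.sample_sheet)
              if config.sample_sheet else None)

    def _write(name: str, df, index=False) -> None:
        path = outdir / f"{name}.tsv"
        io.write_table(df, path, index=index)
        artifacts[name] = path

    for stage in [s for s in STAGES if s in config.stages]:
        logger.info("stage %s", stage)
        try:
            if stage == "simulate":
                sim = simulate.simulate_all(sim_cfg)
                data.update(sim)
                io.write_matrix(sim["intensity"], outdir / "sim_intensities.tsv")
                io.write_matrix(sim["betas"], outdir / "sim_betas.tsv")
                io.write_matrix(sim["expression"], outdir / "sim_expression.tsv")
                for name in ("sim_intensities", "sim_betas", "sim_expression"):
                    artifacts[name] = outdir / f"{name}.tsv"
                _write("sim_kinase_map", sim["kinase_map"].pairs)
                _write("sim_annotations", sim["annotations"])
                _write("sim_ct_table", sim["ct_table"])
                _write("sim_truth", sim["truth"])
            elif stage == "kinome":
                matrix = (io.read_matrix(config.intensities, "intensity", groups)
                          if config.intensities else data["intensity"])
                kmap = (io.read_kinase_map(config.kinase_map)
                        if config.kinase_map else data["kinase_map"])
                scores, skipped = kinome.rank_kinases(
                    matrix, kmap, M=config.permutations, seed=config.seed,
                    min_peptides=config.min_peptides,
                )
                data["kinase_scores"] = scores
                logger.info("kinome: %d scored, %d skipped", len(scores), len(skipped))
                _write("kinase_scores", scores)
            elif stage == "express":
                matrix = (
                    io.read_matrix(config.expression, "expression", groups,
                                   detection_path=config.detection_p,
                                   gene_map_path=config.probe_gene_map)
                    if config.expression else data["expression"]
                )
                matrix, report = differential.detection_filter(
                    matrix, config.detection_p_threshold,
                    config.detection_min_samples, strict=config.strict,
                )
                logger.info("express: %d probes removed by detection filter",
                            report.n_removed)
                if matrix.scale == "raw":
                    matrix = differential.quantile_normalize(matrix)
                data["expression_records"] = differential.differential_expression(
                    matrix, fdr=config.expr_fdr, min_logfc=config.expr_min_logfc
                )
                _write("expression_records", data["expression_records"], index=True)
            elif stage == "dmp":
                matrix = (io.read_matrix(config.betas, "beta", groups)
                          if config.betas else data["betas"])
                data["dmp_records"] = differential.call_dmps(
                    matrix, fdr=config.meth_fdr,
                    min_delta_beta=config.meth_min_delta_beta,
                )
                n_sig = int(data["dmp_records"]["significant"].sum())
                logger.info("dmp: %d significant of %d probes", n_sig,
                            len(data["dmp_records"]))
                _write("dmp_records", data["dmp_records"], index=True)
            elif stage == "enrich":
                ann = (io.read_annotations(config.annotations)
                       if config.annotations else data["annotations"])
                data["enrichment"] = enrichment.enrich(data["dmp_records"], ann)
                data["repeat_profile"] = enrichment.repeat_profile(
                    data["dmp_records"], ann
                )
                _write("enrichment", data["enrichment"])
                _write("repeat_profile", data["repeat_profile"])
            elif stage == "integrate":
                ann = (io.read_annotations(config.annotations)
                       if config.annotations else data["annotations"])
                cpg_gene = ann.loc[ann["gene"] != "", ["probe_id", "gene"]]
                pairs, unmatched = integration.pair_probes_to_genes(
                    data["dmp_records"], data["expression_records"], cpg_gene
                )
                classified = integration.classify_pairs(
                    pairs, expr_fdr=config.expr_fdr, meth_fdr=config.meth_fdr,
                    min_delta_beta=config.meth_min_delta_beta,
                    min_logfc=config.expr_min_logfc,
                )
                data["starburst"] = classified
                counts = integration.tier_counts(classified)
                logger.info("integrate: %s", counts)
                _write("starburst_pairs", classified)
                _write("starburst_unmatched", unmatched)
                (outdir / "starburst_summary.json").write_text(
                    json.dumps(counts, indent=2)
                )
                artifacts["starburst_summary"] = outdir / "starburst_summary.json"
            elif stage == "qpcr":
                table = (io.read_ct_table(config.ct_table)
                         if config.ct_table else data["ct_table"])
                data["qpcr_results"] = qpcr.quantify(
                    table, reference_gene=config.reference_gene
                )
                _write("qpcr_results", data["qpcr_results"])
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err

    manifest = {
        "config": config.to_dict(),
        "stages_run": [s for s in STAGES if s in config.stages],
        "artifacts": {name: {"path": str(path), "sha256": _sha256(path)}
                      for name, path in sorted(artifacts.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["data"] = data
    return manifest
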