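# Methods

This note records the models, parameter choices and numerical conventions
behind each pipeline stage, what the synthetic-data generators do and do
not emulate, and the design decisions taken where more than one reasonable
convention exists.

## Upstream kinase inference

Per-peptide differential phosphorylation uses a two-sided Welch t-test on
log2 intensities with BH correction across the whole chip. The normalized
kinase statistic is the unweighted mean of standardized treated-minus-
control differences over the kinase's mapped peptide set; peptide sets may
overlap across kinases because one phosphosite can be a substrate of many
kinases. Conventions fixed here:

- **Group order.** Group 1 = treated, group 2 = control, so τ > 0 always
  reads "activated by treatment". Every downstream effect (logFC, Δβ,
  qPCR logFC) follows the same orientation.
- **Permutations.** `M = 500` by default (200 in the recovery studies,
  which already saturates the score ceiling), seeded; each kinase gets an
  independent child stream spawned from the global seed so adding or
  removing kinases does not perturb the others. The sample-mode scan
  shuffles which samples form the treated group (group sizes preserved);
  `exhaustive=True` enumerates all `C(n1+n2, n1)` assignments, which is
  exact for small designs. The peptide-mode scan draws `n`-subsets
  uniformly without replacement from all chip peptides. Subset indices are
  sorted before averaging so that identical sets give bit-identical τ_p
  and float summation order can never create spurious strict inequalities.
- **Exceedance count.** `m` uses the strict inequality `|τ_p| > |τ|`;
  ties do not count. `Q = −log10(max(m/M, 1/M))`, so `0 ≤ Q ≤ log10(M)`.
- **Degenerate peptides.** A variance floor `ε = 1e−8` on `s²_1 + s²_2`
  keeps flat peptides from dividing by zero; a warning is logged.
- **Scoring floor.** Kinases with fewer than `min_peptides = 3` peptides
  present on the chip are reported as skipped, not scored.
- **Ties in ranking.** Equal combined scores are broken by larger |τ|,
  then lexicographic kinase id, so ranks are a deterministic permutation.

## Differential expression and methylation

Quantile normalization forces every column onto the distribution of
across-column rank means, with tied ranks receiving linearly interpolated
means (verified against limma's `normalizeQuantiles` to ~1e−14), followed
by log2. The detection filter removes probes whose detection p exceeds
0.05 in at least 6 samples (absolute count; both knobs configurable).

Two test statistics are available for both omics:

- **Welch t** (default for expression): robust to unequal group variances,
  no sharing across probes.
- **Empirical-Bayes moderated t** (default for methylation): pooled
  per-probe variances are shrunk toward a chip-wide prior `s₀²` with
  prior degrees of freedom `d₀`, both estimated by the scaled-F method of
  moments on log variances (Newton inversion of the trigamma function);
  the statistic then has `d₀ + df` degrees of freedom, or is Gaussian when
  the fit degenerates to a common variance. The implementation reproduces
  limma's `lmFit + eBayes` t and p-values to ~1e−14 (tested via Rscript).
  Moderation is the default for methylation because six samples per group
  give per-probe variance estimates too unstable for the joint
  FDR-plus-effect-size gate to reach useful sensitivity; it is optional
  for expression.

Methylation testing happens on M-values `M = log2(β/(1−β))` (boundary
betas clipped to `[1e−3, 1−1e−3]` with a warning); the reported effect Δβ
stays on the beta scale. Gates: expression significant iff adjusted
p < 0.05 and |logFC| > 0.4; DMP iff FDR < 0.1 and |Δβ| ≥ 0.05, with
direction hyper/hypo by the sign of Δβ. Arrays are treated as unpaired
designs throughout.

## Genomic-context enrichment

The probe universe is an explicit argument (default: all annotated
probes); it should be the QC-surviving probes the DMPs were called from,
not the full array manifest — the background choice changes odds ratios
materially. The Fisher test is the conventional two-sided
point-probability method: the p-value sums hypergeometric point
probabilities not exceeding that of the observed table, with the same
relative tie guard (`1 + 1e−7`) R and scipy use. It is implemented as a
margin-grouped vectorized scan so that exhaustive table sweeps (all ~1.4e5
tables with total ≤ 40 in the test suite) run in seconds; agreement with
`scipy.stats.fisher_exact` is ~1e−16 and with brute-force enumeration
≤ 1e−12. Both the sample odds ratio and the fold enrichment
`(a/n_DMP)/(n_level/n_total)` are reported, and BH adjustment runs within
each annotation axis. Sidedness and multiplicity handling are conventions
fixed here; nothing in the underlying contrasts dictates them.

## Starburst integration

Multi-mapping is resolved by emitting every (CpG probe, gene, expression
probe) combination; `collapse="min-fdr"` keeps the best expression probe
per (CpG, gene) instead. FDRs are floored at 1e−300 before −log10 so
coordinates stay finite. Tier logic is a pure function of the four
per-pair statistics, and red ⊆ blue by construction.

## qPCR quantification

The median is taken over technical triplicates (the conventional reading
of replicate-group medians), then ΔCt = target − reference per sample,
ΔΔCt = treated − solvent paired by biological replicate index, and
**logFC = −ΔΔCt**: the sign is fixed so that fewer cycles (more
transcript) under treatment reads as up-regulation. Normalization makes
per-sample global Ct offsets cancel exactly. Significance is a two-sided
paired t across replicate pairs; with fewer than two pairs the test is
skipped (p = NaN), and zero-variance degenerate cases (e.g. target ≡
reference) report p = 1 with a flag. An unpaired Welch fallback is
available for unpaired designs.

## Synthetic data: what it emulates, and what it does not

The generators produce every input shape the pipeline reads, each with a
separate planted-truth table (never embedded in the inputs, so no stage
can leak truth):

- **Kinome chip** (default 150 peptides, 20 kinases, 8 peptides/kinase,
  6 samples/group): per-peptide baselines Normal(10, 1.5) on log2 — a
  realistic array dynamic range — plus Normal noise with SD 0.5; planted
  kinases shift their peptides by `δ × noise SD` in the treated group
  (default one kinase at δ = 2).
- **Methylome** (default 2000 probes, 5% planted at Δβ = +0.10):
  beta-values are built on the M-value scale with probe baselines
  Normal(0, 2) and noise SD 0.3, which keeps betas strictly inside (0,1)
  with a realistically bimodal marginal; planted probes are drawn with
  five-fold relative risk from LTR repeats and only among probes whose
  baseline leaves headroom for the shift (baseline and target inside
  (0.05, 0.95)). Annotation axes are sampled with fixed marginal
  frequencies (e.g. 8% LTR, 15% LINE).
- **Expression + qPCR** (default 200 genes, ~1.2 probes/gene, noise SD
  0.3): planted logFCs are coupled to planted DMPs through shared gene
  symbols with sign `coupling × sign(Δβ)` (default anti-coupling, the
  hyper-methylated/down-regulated configuration); 5% of probes are marked
  undetected. Ct triplicates are ddCt-consistent with the planted logFC
  (1.0) plus technical noise SD 0.1 cycles and per-sample global offsets
  that the reference normalization must remove.

Not emulated: bead-level artifacts, dye and probe-type (BMIQ-correctable)
bias, batch effects, SNP-affected or cross-reactive probes, primer
efficiency differences. Passing recovery tests therefore demonstrates the
correctness and calibration of the statistics under clean Gaussian noise,
not robustness to array-specific artifacts — those are assumed handled by
upstream preprocessing, which is out of scope here.

## Problem sizes and determinism

The recovery studies run at the default study conditions: 50 seeds for
kinase ranking (M = 200) and DMP calling, 100 seeds for enrichment
recovery, 200 seeds for qPCR recovery — sizes at which the Monte-Carlo
rates are stable to a few percent and the whole suite runs in well under a
minute per study. All randomness descends from a single integer seed via
`numpy.random.SeedSequence` spawning; fixed seed means byte-identical
outputs, which the pipeline manifest makes checkable via SHA-256 of every
artifact.

## Known limitations

- The moderated t assumes a single scaled-F variance prior across the
  chip; strongly multimodal variance structure would call for robust
  fitting, which is not implemented.
- The kinase map is taken as given (unweighted); prediction-strength
  weighting of peptide sets is not supported.
- Pathway/network enrichment over external knowledge bases is out of
  scope; the integration stage reports tiered pairs and plain gene-list
  intersections instead.
- The expression stage models unpaired two-group designs only.
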