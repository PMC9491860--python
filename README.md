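# dosagecomp

Proteogenomic analysis of **gene dosage compensation** after somatic
copy-number alteration (SCNA).

In aneuploid tumors, a gained or lost chromosome arm changes the DNA copy
number of thousands of genes at once, but RNA and especially protein
abundance often change *less* than the DNA does — the cell buffers the
dosage change. `dosagecomp` quantifies this buffering from matched DNA /
RNA / protein gene × sample matrices of the kind produced by tumor
proteogenomic consortia (copy-number log2 ratios, RNA-seq abundances, TMT
protein ratios), and relates per-sample aneuploidy burden to expression
changes. It is aimed at computational biologists analyzing multi-omic
tumor cohorts, and ships a synthetic-cohort generator with known ground
truth so every stage can be validated by parameter recovery.

## What it computes

**Compensation score.** For each gene *g* in each sample *s*, log2 fold
changes on every layer are taken relative to that gene's *neutral group*
(samples with DNA log2 ratio in [−0.2, 0.2]; the reference is the median of
that group).  The per-layer compensation score is

```
CS = dna_l2fc − expr_l2fc    if dna_l2fc > 0
CS = expr_l2fc − dna_l2fc    if dna_l2fc < 0
```

so CS > 0 whenever the expression response is attenuated relative to the
DNA change.  Samples are binned by DNA log2FC into five SCNA groups
(deep loss < −0.65 < loss < −0.2 ≤ neutral ≤ 0.2 < gain ≤ 0.65 < high
gain), and group medians are tested against zero by a one-tailed bootstrap
median test (10,000 resamples, basic 95% CI), with protein-complex vs
non-complex contrasts by a two-tailed bootstrap median-difference test and
Benjamini–Hochberg FDR across each analysis family.

**Regulation profiles.** Per gene and tumor type, the DNA–RNA Spearman ρ
(high = RNA tracks dosage = weak RNA-level regulation) and RNA–protein
Spearman ρ (high = protein tracks RNA = weak protein-level regulation),
averaged into a pan-cancer profile.  On top of the profiles: the
gene-level density-slope association (40 DNA–RNA bins, per-bin argmax of
the joint KDE density, OLS slope + Spearman ρ over the representative
points), opposite-tail regulation groups at the 35% quantiles, pathway
medians with a table-level association, gene-class bootstrap contrasts,
and a hypergeometric over-representation test.

**Aneuploidy.** SEG-like segment files are tiled into 100 kb windows
within chromosome-arm boundaries; an arm is called gained when its mean
log2 ratio exceeds +0.2 (strictly) and lost below −0.2, and the per-sample
aneuploidy score is the count of gained plus lost arms.  Each gene's
expression is regressed on the aneuploidy score with covariates
(`expr ~ β0 + β1·aneuploidy + β2·purity + ...`), genes are ranked by the
t-value of β1, and ranked lists feed a preranked gene-set enrichment
(weighted Kolmogorov–Smirnov running sum, gene-label permutation NES/FDR).

## Worked example

```python
import dosagecomp as dc
from dosagecomp.simulate import (SimulationConfig, simulate_dataset,
                                 pathway_gene_sets, default_arm_table)

cfg = SimulationConfig(n_genes=600, n_samples_per_type=90, n_tumor_types=2,
                       n_pathways=30, pathway_coupling=-1.0, seed=1)
dataset, truth, segments = simulate_dataset(cfg)

table = dc.foldchange_pipeline(dataset)
cs = dc.compensation_table(table, dataset.gene_annotation)
summary = dc.summarize_group_cs(cs, n_boot=2000, seed=1)
pan = summary[(summary.tumor_type == "pan") & (summary.test == "median_gt_zero")]
print(pan[pan.scna_group == "gain"][["layer", "gene_class", "median_cs", "fdr"]]
      .to_string(index=False))

profiles = dc.regulation_pipeline(dataset)
assoc = dc.pathway_regulation(profiles, pathway_gene_sets(truth))
print(f"pathway-level association: rho = {assoc.spearman:.2f} "
      f"(p = {assoc.spearman_p:.1e})")

scores = dc.aneuploidy_from_segments(segments, default_arm_table())
print("aneuploidy scores match truth:",
      (scores.aneuploidy_score.reindex(truth.samples.index)
       == truth.samples.true_aneuploidy).all())
```

prints

```
  layer gene_class  median_cs     fdr
protein       True   0.290932 0.00075
protein      False   0.180050 0.00075
    rna       True   0.022266 0.00090
    rna      False   0.117296 0.00090
pathway-level association: rho = -0.93 (p = 2.2e-13)
aneuploidy scores match truth: True
```

Reading the output: in the DNA-gain group, protein-complex genes
(`gene_class True`) have a median protein-layer compensation score of 0.29
— their protein response absorbs about 0.29 of each log2 unit of DNA gain
— versus 0.18 for non-complex genes, while RNA-level compensation is weak
and runs the other way; all four cells are significantly positive at FDR <
0.005.  The generator was run with anti-coupled pathway noise
(`pathway_coupling=-1`), and the pathway-level table recovers the expected
strong negative association between RNA-level and protein-level
regulation.  Arm-level aneuploidy scores recomputed from the segment files
match the simulated ground truth exactly.

## Command line

Each stage is also a CLI subcommand operating on tab-delimited files
(`simulate`, `foldchange`, `compensation`, `regulation`, `aneuploidy`),
each taking `--config` (YAML), `--out-dir`, `--seed` and `--log-level`;
identical config + seed give byte-identical outputs. `dosagecomp simulate`
writes a complete file fixture (matrices, segments, arm table,
annotations, pathway GMT, truth tables) that the other subcommands
consume.

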