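# methoutlier

Outlier-based DNA methylation biomarker discovery and diagnostic-panel
evaluation for tumor/normal cohorts.

The package implements a four-stage pipeline:

1. **Outlier screening** (`methoutlier.screening`) — beta values
   (M/(U+M)) are aggregated probe→gene by per-sample maximum; per gene, a
   baseline cutoff is derived from the normal samples (Tukey fence
   `q75 + k·IQR`, floored at `median + delta_min` so that any called outlier
   differs from a typical normal by at least `delta_min`, default 0.10);
   tumor samples strictly beyond the cutoff are flagged and the gene is
   scored by the normalized rank sum `S = Σ rank/N` over flagged samples
   (joint midranks over all non-missing samples; left-tail outliers are
   ranked on negated values). Genes are ranked by descending score and
   selected by score cutoff or top-k (ties included). An optional
   label-permutation null yields per-gene empirical p-values.
2. **Integration filtering** (`methoutlier.integration`) — candidates are
   retained when promoter methylation anti-correlates with expression
   (Spearman rho < 0, optional p ceiling); Welch t-tests for tumor/normal and
   HPV-stratified contrasts (HPV-positive at ≥1 viral copy/genome/cell); a
   Fisher exact test on outlier presence covers subset-methylated genes.
3. **Diagnostic evaluation** (`methoutlier.diagnostics`) — QMSP Ct values are
   quantified through a fitted standard curve (censored at 38 cycles),
   normalized to the beta-actin loading control (×100), dichotomized at zero,
   and combined with the any-marker panel rule. Reports
   sensitivity/specificity with exact Clopper–Pearson 95% CIs, two-sided
   Fisher exact p (minimum-likelihood method), Cohen's kappa with a
   large-sample CI, percent agreement, paired Spearman correlation, and
   2^-ddCt relative expression. `reconstruct_paired_table` recovers a paired
   2×2 from marginals + percent agreement.
4. **Synthetic cohorts** (`methoutlier.simulate`) — seeded generators for
   discovery cohorts (low, tight normal betas; a heterogeneous tumor subset
   shifted by Δβ, attenuated in HPV+ tumors; expression negatively coupled to
   methylation) and paired tissue/saliva QMSP assays (per-gene tissue
   positivity, saliva positivity conditional on tissue, signal-free controls,
   gene events correlated through a patient-level Gaussian copula factor).

`methoutlier.pipeline.run_pipeline` orchestrates
simulate → screen → integrate → evaluate with eager per-stage outputs and a
summary JSON recording the candidate funnel, seed, and config hash.

## CLI

```bash
# full pipeline on a synthetic bundle
methoutlier run --seed 42 --out run_dir/

# or stage by stage
methoutlier simulate bundle --seed 2 --out bundle/
methoutlier screen --meth bundle/methylation.tsv --annot bundle/annotation.tsv \
    --tail both --delta-min 0.1 --fence-k 1.5 --top-k 50 --out screen.tsv
methoutlier integrate --meth bundle/methylation.tsv --expr bundle/expression.tsv \
    --annot bundle/annotation.tsv --candidates screen.tsv --out candidates.tsv
methoutlier evaluate --qmsp bundle/qmsp_saliva.tsv --qmsp-tissue bundle/qmsp_tissue.tsv \
    --annot bundle/validation_annotation.tsv --out report.json
```

All matrices are tab-delimited (features × samples, first row sample ids,
first column feature ids; missing values as empty cells or `NA`, never 0).
Annotations need columns `sample_id`, `patient_id`, `group` (tumor/normal),
`specimen` (tissue/saliva), with optional `hpv_copy_number`/`hpv_status`.
QMSP tables are long-format TSV with `sample_id`, `gene`, `ct_target`,
`ct_actin` (empty Ct = undetermined / no amplification). Expression matrices
must be one row per gene.

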