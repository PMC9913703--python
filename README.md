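# osap

A tested pipeline for deriving, scoring and refining two-sided gene
expression signatures:

1. **Derivation** — intersect per-contrast log2 fold-change calls across
   multiple case-vs-reference comparisons; a gene enters the core signature
   only if it clears the cutoff in *every* contrast, in the same direction.
2. **ssGSEA scoring** — a from-scratch single-sample GSEA running-sum engine
   (rank-weighted in-set ECDF minus out-of-set ECDF, summed over all
   positions; exponent `alpha`, range normalization, up-minus-down
   combination for two-sided signatures).
3. **Refinement** — per-gene Hodges–Lehmann shift estimates and two-sided
   Wilcoxon rank-sum tests in two independent cohorts; genes are kept only
   when the shift sign agrees in both cohorts (optionally with per-cohort
   significance), and direction labels are reassigned from the cohort data.
4. **Association statistics** — Mann–Whitney (exact enumeration for small
   tie-free samples), Kruskal–Wallis, Spearman correlation, hierarchical
   clustering on correlation distance, and PCA.
5. **Synthetic data** — planted-signal simulators for a cell-line panel
   (parental + derived conditions), heterogeneous patient cohorts with a
   dilution fraction and an inflammation confounder, and flow-sorted pure
   populations with driver genes — each emitting ground truth for recovery
   tests.

Supported formats: GCT 1.2, plain TSV matrices, GMT gene sets (with the
`<stem>_UP` / `<stem>_DN` merging convention for two-sided signatures), and
TSV sample annotations (`sample_id`, `group`, `cohort`, covariates).

## CLI

```sh
# simulate a cell-line panel with planted truth
osap simulate cell-lines --seed 17 --out-prefix sim/

# derive the core signature from contrasts
osap derive --expr sim/matrix.gct --contrasts contrasts.tsv --cutoff 1.5 --out core.gmt

# score signatures per sample
osap score --expr cohort.gct --signatures core.gmt --alpha 0.25 --normalize --out scores.tsv

# refine across two cohorts
osap refine --sig core.gmt --expr-a a.gct --anno-a a.tsv --expr-b b.gct --anno-b b.tsv \
    --case disease --control healthy --p 0.05 --out refined.gmt

# group tests / correlations on a score table
osap associate --scores scores.tsv --anno anno.tsv --test kw --out stats.tsv

# full pipeline (derive -> refine -> score -> associate) from YAML
osap run --config pipeline.yaml
```

`pipeline.yaml` keys: `expression`, `contrasts`, `cohort_a`/`cohort_b`
(each with `expression`, `annotation`, `case`, `control`), `out_dir`,
optional `score_expression`/`score_annotation`, and `params`
(`cutoff`, `alpha`, `normalize`, `p_threshold`, `test`, ...).  The run
directory receives per-stage TSV/GMT outputs, `run.log`, and a
`manifest.json` with the effective config and input/output SHA-256 checksums;
re-running on identical inputs reproduces identical checksums.

The contrasts table is a TSV with columns `name`, `case_ids`, `ref_ids`
(comma-joined sample IDs).

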