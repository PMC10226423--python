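# dropgate

**Gate-based characterization of genes consistently under-detected in
scRNA-seq relative to paired bulk RNA-seq, with 3′ poly(T) motif analysis.**

Single-cell RNA-seq count matrices are dominated by zeros, and part of that
sparsity is technical: some genes are systematically harder to capture during
library preparation than their true expression warrants. `dropgate` asks
whether specific genes are *consistently* under-detected across a cohort of
samples for which both bulk RNA-seq and scRNA-seq were generated from the
same material, and whether those genes share sequence features near their
transcript 3′ ends — where oligo-dT capture acts — such as poly(T) runs that
can base-pair with the mRNA poly(A) tail.

It is written for computational biologists who have (or want to simulate) a
compendium of paired bulk/single-cell samples and want a reproducible,
testable version of this comparison.

## Method

For each sample pair the package builds one dot per gene in the plane

* **x** — pseudo-bulk expression: per-cell library-size normalization to
  10⁴ counts, ln(1 + ·), averaged over all cells of the sample;
* **y** — bulk expression: per-dataset median-of-ratios size factors
  (the DESeq estimator), ln(1 + ·), then quantile normalization across all
  samples jointly.

Three polygonal **gates** select outliers in the pooled dot cloud:
`upper_left` (bulk high, single-cell low: under-detected), `upper_right`
(high in both), and `bottom` (single-cell high, bulk near zero:
over-detected). A gene's **recurrence count** is the number of sample pairs
in which its dot falls inside a gate; genes recurring at least twice form
each gate's candidate set.

Two null models calibrate the counts. The **occupancy null** treats the D
gated dots as falling uniformly on N genes, giving the closed-form
expectation `E[#genes hit ≥ 2] = N[1 − (1−1/N)^D − (D/N)(1−1/N)^(D−1)]`.
The **random-pairing null** redraws the bulk↔single-cell pairing as a
uniform derangement (no sample keeps its own partner) 100 times, re-gating
with frozen gate polygons.

Candidate genes' last 350 bp (longest transcript per gene) are then tested
for poly(T) enrichment with a one-sided hypergeometric test on long T runs,
and scanned with a ZOOPS ("zero or one occurrence per sequence") EM motif
finder whose significance is calibrated by refitting on
composition-preserving per-sequence shuffles (Bonferroni-corrected across
the widths scanned, compared against 0.05).

A synthetic-cohort generator (`dropgate.synthetic`) plants a poly(T) run in
the 3′ tail of a known 5% of genes and lowers their single-cell capture
efficiency as `exp(−β · max(0, run − r0))`, leaving bulk counts untouched —
so every stage of the pipeline can be validated against ground truth.
See `docs/methods.md` for the full model and parameter rationale.

## Worked example

```python
import dropgate as dg

data = dg.simulate_cohort(dg.CohortConfig(seed=1))       # 2,000 genes, 53 pairs
result = dg.run_analysis(data, dg.AnalysisParams(seed=1))
result = dg.run_motif_stage(result, data.sequences, dg.AnalysisParams(seed=1))

s = result.correlation_summary
print(f"Pearson {s['pearson_mean']:.3f}  Spearman {s['spearman_mean']:.3f}")
print("upper-left dots:", result.tables["upper_left"].total_dots,
      "recurrent genes:", len(result.recurrent["upper_left"]))
planted = data.truth.under_detected_genes
rec = result.recurrent["upper_left"]
print("precision:", len(rec & planted) / len(rec),
      " recall:", len(rec & planted) / len(planted))
m = result.motifs["upper_left"][0]
print("top motif:", m.consensus, " significance:", round(m.significance, 3))
```

prints

```
Pearson 0.882  Spearman 0.910
upper-left dots: 2595 recurrent genes: 78
precision: 1.0  recall: 0.78
top motif: TTTTTTTTTTTTTTT  significance: 0.04
```

All 78 genes recurring in the under-detection gate are planted defect
carriers (precision 1.0), 78% of the planted genes are recovered, and their
3′ tails yield a poly(T) consensus that survives shuffle calibration. The
same scan on the `upper_right` gate finds no significant T-run motif, and
the mean per-pair Pearson correlation under the derangement null (0.793)
falls below the paired value (0.882) — matched pairs share real per-sample
biology.

The same pipeline is available from the shell:

```bash
dropgate run-all --seed 1 --outdir runs/demo          # or stage by stage:
dropgate simulate|preprocess|gate|null|motif|report --outdir runs/demo
```

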