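# dmrscan

Sliding-window calling of **differentially methylated regions (DMRs)** for
Illumina 450K-style case-control methylation studies, built for epigenome-wide
analyses of bulk brain tissue (the motivating application is Alzheimer's
disease versus non-demented controls in cortex), together with a fully seeded
synthetic-cohort generator so the whole pipeline can be exercised and
validated without access to any restricted data.

## Who this is for

Epigenetics researchers running case-control EWAS on array beta-values
(methylation fractions in [0, 1]) who want region-level calls rather than
single-CpG hits: clusters of neighboring CpGs moving concordantly are far
more robust than isolated probes at the small effect sizes (|Δβ| ≈ 0.02–0.07)
typical of complex disease.

## The method

1. **Probe QC.** Probes flagged as multimapping or having a common SNP within
   5 bp of the target CpG are removed; analysis is restricted to autosomes.
   Per-sample beta values with detection *p* > 0.01 are masked. Samples are
   quantile-normalized to the across-sample mean quantile curve.
2. **Per-CpG model.** At each CpG *j* with beta vector β<sub>j</sub>:

   β<sub>j</sub> = α + γ₁·AOD + γ₂·gender + γ₃·race + γ₄·array \[+ γ₅·NP\] + δ<sub>j</sub>·disease + ε

   where AOD is age of death (years), NP is the estimated neuronal proportion
   of the bulk sample (included only at CpGs known to differ between neurons
   and glia), and δ<sub>j</sub> is the covariate-adjusted case-minus-control
   effect in beta units. δ<sub>j</sub> > 0 defines hypermethylation. One-sided
   p-values toward each direction come from the t statistic.
3. **Windowed combination.** For every CpG, a 1 kb window [pos, pos + 1 kb)
   collects its neighbors; the one-sided p-values of all members are combined
   with Fisher's method (−2Σln p ~ χ²<sub>2k</sub>) separately toward hyper-
   and hypomethylation, and the window takes the more significant direction.
   Discordant CpGs contribute p ≈ 1 and penalize the window.
4. **FDR and merging.** Window p-values are Benjamini–Hochberg adjusted;
   windows with q < 0.01 are significant, and overlapping same-direction
   windows merge into one DMR spanning its first to last member CpG.
5. **Downstream.** Neuron/glia deconvolution (constrained two-reference
   least squares), promoter/gene-body/intergenic and island/shore/shelf/sea
   annotation, χ² feature enrichment against the array background, one-sided
   Fisher's exact TFBS enrichment (Bonferroni, ≥5 % prevalence filter),
   length-preserving permutation enrichment for histone tracks, GWAS-SNP
   proximity (±2 kb / ±250 kb at SNP p < 10⁻⁶), age-of-death association at
   top DMR-CpGs in controls, and cross-cohort concordance (directional
   replication + Pearson correlation of effects).

## Worked example

```python
import dmrscan as d

model = d.SlidingWindowDMR.from_simulation(seed=1)   # 34 cases + 34 controls
res = model.fit()
print(res.summary())
```

```
Sliding-window DMR analysis
================================================================
Probes: 20000 input, 19006 retained (0 non-autosomal, 479 multimap, 515 SNP-within-5bp)
CpGs fitted: 19006 (skipped: 0)
Window: 1000 bp, min CpGs 2, FDR 0.01
----------------------------------------------------------------
DMRs called: 60
  hypermethylated: 32   hypomethylated: 28
  DMR-CpGs: 358 (309 independently significant)
  mean size: 939 bp   mean CpGs/DMR: 5.97
  mean max |delta-beta|: 0.0471
```

The simulated cohort plants 50 DMR clusters (each ≤ 1 kb) with effects drawn
from 0.02–0.07 on the beta scale; all 50 are recovered here with the correct
direction, at a mean DMR size of ~939 bp and with per-CpG adjusted effects in
the planted range. `res.dmrs` is a DataFrame with one row per region
(coordinates, direction, combined p, q, CpG counts, top CpG):

```
chromosome   start     end  length  n_cpgs direction   combined_p            q
      chr1   37092   37963     871       7     hyper 1.834420e-17 6.352888e-16
      chr1 1186411 1187786    1375       6      hypo 9.485521e-35 5.769429e-33
      ...
```

`res.cpg_results` carries the per-CpG effects and one-sided p-values,
`res.plot_manhattan()` draws the genome-wide picture, and
`res.to_tables(out_dir)` writes the DMR table (TSV + BED) and per-CpG table.

The same analysis is scriptable from the shell:

```bash
dmrscan simulate --out cohort/ --seed 1
dmrscan run-all --out results/ --seed 1          # simulate + full pipeline
dmrscan scan --manifest cohort/manifest.tsv --beta cohort/beta.tsv \
             --sheet cohort/sample_sheet.tsv --out cpg_results.tsv
dmrscan call-dmrs --cpg-results cpg_results.tsv --out dmr_out/
```

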