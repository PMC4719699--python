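# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the limitations of `dmrscan`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The per-CpG model

Methylation is analyzed on the beta scale (fraction methylated, in [0, 1]).
At each CpG an ordinary least-squares model is fitted:

    beta = intercept + AOD + gender + race + array [+ NP] + disease

* **AOD** — age of death in years, numeric.
* **gender, race, array** — treatment-coded against the alphabetically first
  level (a deterministic choice; the reference level is configurable through
  `DesignSpec`). A categorical covariate with a single observed level is
  dropped with a warning; a single-level disease column is an error.
* **NP** — neuronal proportion of the bulk sample, included *only* at CpGs
  carrying the cell-type-differential flag in the manifest. Methylation at
  those CpGs differs between neurons and glia, so between-group differences
  in cellular composition would otherwise masquerade as disease effects.
* **disease** — control = 0, case = 1, always the last column, so its
  coefficient is the covariate-adjusted case-minus-control difference in
  beta units. A positive coefficient is hypermethylation.

Two-sided p-values come from the t distribution on the residual degrees of
freedom; the one-sided values are the upper and lower t tails, so
`p_hyper + p_hypo = 1` and `p_two = 2 * min(p_hyper, p_hypo)` hold exactly.
A CpG is fitted only if at least 10 unmasked samples remain per group
(configurable); CpGs failing this, or with a rank-deficient design after
row deletion, are recorded as skipped rather than aborting the scan.
Modelling beta directly (no M-value or logit transform) keeps effect sizes
interpretable as methylation differences but makes the Gaussian-error
assumption approximate near the [0, 1] boundaries; this is a documented
limitation shared with the regime the pipeline targets (small effects at
mid-range or plateaued CpGs).

## Window combination and DMR calling

One candidate window is anchored at every CpG and holds all CpGs in
[pos, pos + window) with `window = 1000 bp` — chosen because correlation
between neighboring-CpG methylation decays on roughly this scale on the
450K array — and candidates with fewer than `min_cpgs = 2` members are
dropped ("neighboring CpGs" implies plurality). Per-CpG anchoring is
deterministic and step-free; a fixed slide step would add an arbitrary
phase parameter.

For each window, Fisher's method combines the one-sided p-values of **all**
members toward hypermethylation, and separately toward hypomethylation:
`stat = -2 * sum(ln p) ~ chi-square(2k)`. The window's direction is the
smaller combined p (ties, a measure-zero event, break toward hyper).
Combining all members in both directions — rather than pre-filtering to
direction-concordant CpGs — lets discordant members (one-sided p near 1)
penalize the statistic, which operationalizes direction awareness without
an extra concordance threshold.

One p-value per window (the better direction) enters a single
Benjamini–Hochberg adjustment; entering both directions would double-count.
Windows with q < FDR (default 1 %) are significant. Significant windows of
the same direction sharing at least one member CpG (equivalently,
overlapping in span) merge into one DMR running from its first to its last
member CpG; the DMR inherits the combined p and q of its most significant
constituent window. Opposite-direction overlapping DMRs are emitted
separately and flagged. Reported per DMR: CpG count, count of members
independently significant in the DMR direction (one-sided p < 0.05), the
largest absolute *adjusted* disease coefficient (not the raw group
difference — the adjusted value is the model's estimand), and the member
CpG with the smallest one-sided p in the DMR direction.

Zero p-values entering Fisher's method are clamped to the smallest positive
float with a warning. BH adjustment delegates to
`statsmodels.stats.multitest.multipletests`; the test suite checks it
against a hand-rolled step-up implementation.

Because true windows merge many-to-one into DMRs while borderline false
windows stay singletons, FDR control at the window level (as specified) is
diluted at the region level when many true regions exist; null cohorts are
clean (see acceptance tests), and this behaviour is inherent to the
window-level-FDR design rather than an implementation artifact.

## Cell-type deconvolution

Bulk beta at a reference probe is modelled as
`w * neuron + (1 - w) * glia`; the per-sample estimate of w minimizes the
squared residual over shared unmasked probes, solved in closed form as a
scalar projection and clipped to [0, 1]. The estimate is exact for
noise-free mixtures, invariant to probes where the references agree, and
symmetric under swapping the reference labels (w <-> 1 - w). Group
comparison uses Welch's t-test ("t-test" alone under-specifies; Welch is the
robust default and is documented as a choice). Only two cell classes are
supported; reference-free deconvolution is out of scope.

## Quantile normalization

Each sample's observed (unmasked) values are mapped through the
across-sample mean quantile curve. The curve is built on a grid of
plotting positions (i - 0.5)/n by linearly interpolating each sample's
empirical quantile function; a sample's value at average rank r among k
observed maps to the curve at (r - 0.5)/k. For complete data this reduces
exactly to "replace sorted values by the mean of sorted columns"; ties get
averaged ranks and hence the mean of the tied reference quantiles; masked
entries are excluded from both the curve and the ranks and pass through
unchanged. The procedure is idempotent on complete, tie-free data to 1e-12
and never leaves the pooled input range. Missing values are never imputed.
Infinium type-I/II chemistry bias correction is intentionally absent: the
synthetic generator works post-normalization and carries no probe-type
bias; `probe_type` is recorded so users can pre-correct externally.

The pipeline applies masking before normalization. Whether observed-only or
complete data should feed the rank computation is genuinely open; mapping
observed values through interpolated quantile positions keeps per-sample
distributions aligned without imputation, and is recorded as this package's
choice.

## Probe filtering

Removal precedence is fixed for reproducible reports: non-autosomal, then
multimap-flagged, then SNP-within-5bp-flagged, each probe counted once under
the first rule that removes it. Manifest flags are taken as given; remapping
probes or querying variant catalogs is out of scope.

## The synthetic cohort generator

The generator emulates the statistical structure of a 34-case / 34-control
bulk-cortex 450K study; its defaults are the study conditions, not tuning
knobs.

* **Scale** — 20,000 probes on 2 chromosomes of 20 Mb: desk-scale, while
  dense enough (median spacing ~1 kb) that multi-CpG windows are common.
* **Baselines** — a three-component beta mixture, Beta(2,20) : Beta(20,2) :
  Beta(5,5) with weights 0.45/0.45/0.10, giving the bimodal landscape in
  which well over 60 % of probe means fall outside (0.2, 0.8).
* **Planted DMRs** — 50 clusters of 3–8 CpGs, each confined to a 1 kb span
  (so the caller's window matches the truth by construction) in disjoint
  3 kb blocks; effects uniform on [0.02, 0.07] on the beta scale, constant
  within a cluster (within-DMR effect heterogeneity beyond direction
  concordance is not characterized in this regime, so a constant effect is
  the recorded assumption); direction hyper with probability 2/3. Planted
  CpGs get mid-range baselines (0.15–0.85) so effects are not attenuated at
  the boundaries — consistent with DMR-CpGs being less bimodal than
  background. Planted probes never carry exclusion flags.
* **Covariates** — ages of death uniform on 66–95 in both groups; gender,
  race and a 12-samples-per-chip batch assignment; sparse per-probe
  gender/race/batch shifts (sd 0.01 at 5 % of probes). Age slopes of
  ±0.002 beta/year at 5 % of probes (disjoint from planted clusters).
* **Neuronal proportion** — case mean 0.247, control mean 0.303, sd 0.05,
  clipped to [0, 1]. At cell-type-differential-flagged probes (33 % of the
  array, matching the prevalence of neuron/glia-differential CpGs among
  450K autosomal probes) beta gains a ±0.15 slope in NP with random sign.
  Because NP differs between groups by design, the conditional NP
  adjustment in the regression is load-bearing: omitting it inflates
  false positives at flagged probes.
* **Noise** — truncated normal within [0, 1] around the systematic mean,
  sd 0.02, sampled by inverse-CDF so the whole cohort is a pure function of
  one integer seed (named substreams; no global state).
* **Detection failures** — each cell independently fails at rate 0.01;
  failed cells receive detection p uniform on (0.02, 0.5), passing cells
  uniform on (0, 0.005), so the 0.01 threshold separates them crisply.
* **Annotation tracks** — genes (with strand and TSS), CpG islands, two
  histone tracks, a motif-to-promoter incidence map, and a GWAS SNP table;
  half the planted DMRs are deliberately covered by genes/islands/the first
  histone track, and one motif is enriched in DMR-overlapping promoters, so
  enrichment signal exists by construction.

What the generator does **not** emulate: raw array intensities, probe-type
chemistry and color channels, physically clustered batch effects, LD
between SNPs, spatial autocorrelation of background (non-planted) CpGs, and
beta-distributed (heteroskedastic) noise. Passing tests therefore certify
the pipeline's statistical machinery under its own assumptions, not its
robustness to every artifact of real array data.

## Enrichment and downstream choices

* Promoters are ±2 kb around the strand-aware TSS; precedence is promoter >
  gene body > intergenic, and island > shore (±2 kb) > shelf (next ±2 kb) >
  sea. Coordinates are 0-based half-open internally (BED convention); point
  positions are 1-based in tables; the conversion is exactly −1 on start.
* χ² feature enrichment uses Pearson's statistic without Yates correction
  (backgrounds are large); degenerate margins return p = 1 with a flag.
* TFBS enrichment is one-sided toward enrichment (depletion is not
  reported), Bonferroni-corrected over the motifs actually tested after the
  ≥5 %-of-test-promoters prevalence filter.
* Histone-track enrichment re-places each DMR uniformly at random within
  its own chromosome, preserving length, with empirical
  p = (1 + #{null ≥ observed}) / (1 + permutations). This is simpler than
  interval-count-matched permutation schemes and conservative at desk
  scale; it is seedable and exactly reproducible.
* GWAS proximity windows (±2 kb, ±250 kb; SNP p < 10⁻⁶ strictly) measure
  distance from the nearer DMR *edge* (0 inside), inclusive at the
  boundary.
* Cross-cohort concordance: a shared CpG replicates when the screening
  cohort's coefficient matches the reference cohort's sign and the
  one-tailed p toward that sign is < 0.05. The Pearson p-value uses the
  two-sided t-transform t = r·sqrt((n−2)/(1−r²)); two-sided is the recorded
  choice where sidedness is otherwise ambiguous.
* The age-of-death scan runs in controls only, regressing beta on AOD with
  gender, race, array and NP as covariates, and reports the significant
  fraction separately for hyper- and hypo-DMR top CpGs; an empty direction
  reports NaN, not zero.

## Problem sizes and determinism

Default analyses run at 20,000 probes x 68 samples (about 1.5 s per full
fit on one CPU); the acceptance script uses one planted cohort, three null
cohorts, 100 deconvolution replicates and the analytic concordance
computation. All randomness descends from a single integer seed;
re-running any pipeline with the same config and seed reproduces output
tables byte for byte.

## Known limitations

* Linear-on-beta modelling near the [0, 1] boundary is approximate; no
  M-value option is provided.
* Window-level FDR dilutes to region-level FDR when many true regions
  exist (see above).
* Fisher's method assumes independent p-values; neighboring CpGs are
  correlated in real data, making combined p-values anti-conservative
  there. No Stouffer–Liptak/comb-p style correlation correction is
  implemented (deliberately out of scope).
* The two-reference deconvolution cannot represent more than two cell
  populations and inherits any bias in the reference profiles.
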