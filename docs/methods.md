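# Methods

## Model and procedure

The pipeline integrates two omics layers measured on the same tumor/normal
cohort. Methylation is observed as per-cytosine counts (methylated m, total t
reads) from targeted bisulfite sequencing; the estimand at each CpG is the
methylation ratio β = m/t ∈ [0, 1]. Counts from the two strands of a CpG are
summed (the minus-strand cytosine is reported at its own coordinate and
collapsed onto the plus-strand C at pos − 1) before the ratio is formed, so β
uses all reads covering the dinucleotide. The analysis is restricted to CpGs
observed in **every** sample — the intersection is the only site filter the
procedure prescribes; per-CpG minimum coverage is available
(`min_coverage`, default 1) but off by default.

DMR calling is a fixed decision rule, not a statistical test: with group means
β̄_T (tumor) and β̄_N (normal), a CpG is a DMR iff |β̄_T − β̄_N| > 0.4
(strict), then hypomethylated iff β̄_T < 0.3, hypermethylated iff β̄_T > 0.7
(both strict). A "region" here is a single CpG; no window merging is applied
because none is defined for this rule set. Three choices in the rule were
genuinely open and are resolved as follows, each with a config escape hatch:

- the difference is **absolute** by default (both directions count as DMRs;
  `dmr_mode="normal_minus_tumor"` restricts to methylation loss);
- a DMR whose tumor mean lands in [0.3, 0.7] is kept as `indeterminate`
  rather than silently dropped, so gene-level tallies remain complete
  (`count_indeterminate_as_dmr=False` excludes them from fractions);
- ratios are compared at full float precision; no rounding precedes the
  threshold comparisons anywhere in the package.

Gene prioritization consumes an externally produced DE table (the DE fit
itself is out of scope; any tool emitting gene, log2FC, adjusted p, baseMean
works). DEGs satisfy |log2FC| ≥ 2 (inclusive), padj < 0.05 (strict), baseMean
≥ 100 (inclusive); missing padj excludes the gene. Each DEG's score is its DMR
fraction over the intersected CpGs inside its annotated interval (1-based
inclusive; overlapping genes each count a shared CpG). Eligibility is strict
on both axes: n_CpG > 10 and fraction > 1/2. "DMR ratio" for ranking is read
as this fraction; the per-gene median and mean of |β̄_T − β̄_N| are emitted as
companion statistics. Ties break deterministically by mean absolute
difference, then gene id. The gene territory is whatever the supplied map
says — promoter vs body is the annotation's decision, not the package's.

Cohort specificity uses the strongest reading of "differs from the other
tumor classes": the target-class mean must differ from **each** other class
mean by more than the threshold (0.4, strict). A pooled-other-mean mode is
available (`specificity_mode="pooled"`) since the per-class reading is a
choice. Probe variability for the t-SNE panel is population variance (ddof=0)
over available values — the common "most variable probes" convention for
450K-style matrices — with ties broken by probe id. t-SNE runs with random
(non-PCA) initialization, perplexity 30 and a fixed seed; coordinates are
reproducible for a fixed seed and scikit-learn version, and the embedding is
diagnostic only (no downstream quantity depends on it).

The methylation–expression model is simple OLS per linked (probe, gene) pair:
expr = a + b·β, Pearson r, two-sided p from t with n − 2 df, requiring n ≥ 3
and non-constant β. Expression enters as centered log10(FPKM + 1) by default.
The normalization phrase "subtracted from the mean" is implemented as
centering (v − mean), because the literal reading (mean − v) flips every sign
and would invert the negative methylation–expression correlations the
procedure is designed to surface; `fpkm_center_mode="mean_minus_value"`
preserves the literal variant, and raw-log or raw-FPKM scales are selectable
(`expr_scale`). Centering shifts only the intercept of the fit; slope sign, r
and p are unaffected by it. No multiple-testing correction is applied across
probe fits (fits are reported per probe); a BH column can be added downstream.

Companion rules: variant depth cutoff is **inclusive** at 10 (the
conventional reading of a minimum-depth cutoff), population frequencies are
strict at < 0.01, and a frequency missing from ExAC EAS / gnomAD EAS / Korean
passes by default — a variant absent from the databases cannot exceed the
cutoff (`missing_af_passes=False` fails closed). TMB divides coding (exonic)
survivors by a configurable coding length, default 30 Mb. ZRPKM
median-centers against reference samples and divides by their sample SD
(ddof=1), excluding zero-SD features; mean-centering is a config option. CNV
states: deletion ≤ −0.4 (inclusive), amplification > 0.3 (strict). The fusion
filter keeps records with a protein-coding partner and nonzero junction and
spanning reads, then collapses records identical in partners, breakpoints and
both read counts; orientation-swapped pairs are deliberately not merged, as
duplicate identity is defined by the full record.

## Synthetic-data generator

`synthio` emulates the statistical structure the pipeline assumes, not the
sequencing process. Read coverage is Poisson per sample per CpG (a single
interpretable parameter; default mean 30, typical of targeted bisulfite
panels), methylated counts are Binomial(coverage, β_true). Background β_true
is Beta(0.6, 0.4) — U-shaped, mimicking the bimodality of real CpG
methylation — and identical in both groups; planted CpGs take fixed group
means (defaults 0.85 → 0.10 for hypo, 0.15 → 0.90 for hyper). Planting is in
contiguous blocks of 20 CpGs so gene intervals tile the CpG grid and a driver
gene's interval contains planted CpGs only; planted fractions therefore round
to whole blocks. Even-indexed CpGs split their reads across strands
(hypergeometric partition of methylated reads) so the strand-collapse path is
always exercised; odd-indexed CpGs are plus-strand only.

Driver-gene expression is log10-linear in the true group methylation mean
(default slope −1.2, intercept 2.5, Gaussian noise SD 0.1), with
FPKM = 10^v − 1 so the downstream log10(FPKM + 1) transform recovers v
exactly; non-driver genes draw a group-independent log-normal background. The
emitted DE table comes from a Welch t-test on log10(FPKM + 1) with
Benjamini–Hochberg adjustment, declared in the truth manifest — downstream
stages only consume the table's columns, so the producing test does not enter
their contracts. Cohort sample sizes default to 6 tumor / 6 normal: six is
the tumor cohort size the study design describes, and the normal side is a
free parameter (the expression comparison uses an external normal cohort of
unstated size); six gives the two-group DE test enough degrees of freedom
that planted drivers are detectable at the default effect size, which two
normals would not.

The cohort generator plants a class-specific probe block for **every** class,
not only the target: with a signature only for the target class the remaining
classes would be statistically identical and no embedding could separate
them. The truth manifest still records which probes are specific to the
designated target, and per-class specificity recovery is exact either way.
Specific-probe means are constructed at exactly ±delta from the shared
background mean with the base drawn so no clipping occurs; per-sample values
are Gaussian (SD 0.05) clipped to [0, 1]. The auxiliary-table generator emits
hand-written boundary templates first (both sides of every filter cutoff,
exact duplicates, orientation swaps) and fills the requested sizes with random
rows whose expected fate is recorded by the generator's own restatement of the
rules — an intent record, independent of the filter implementations under
test. All draws flow from one root seed through `numpy.random.SeedSequence`
substreams (methylome 0, expression 1, cohort 2, aux 3), so any module can be
regenerated independently and byte-identically.

What the generator does **not** emulate — and what passing tests therefore do
not establish about real data: read-level artifacts (bisulfite conversion
failure, mapping bias, PCR duplicates), spatially correlated methylation along
the genome, covariate structure (age, purity, batch), heavy-tailed or
overdispersed expression noise, and realistic LD between probes. Recovery
results on this generator validate the *rules and their implementation*, not
the biological sensitivity of the thresholds on patient data.

## Problem sizes and numerical choices

The bundled test and acceptance scales were chosen as the smallest sizes at
which the planted effects are unambiguous: 10,000 CpGs with 5% planting for
DMR recovery, 500 genes / 5 drivers for ranking, 200 replicates of n = 30 for
slope recovery, 5 classes × 20 samples × 1,000 probes for the cohort stage.
The end-to-end fixture uses 4,000 CpGs / 200 genes. Degenerate inputs are
contracts, not crashes: empty intersections warn and propagate empty tables;
an empty DMR table yields an empty ranking and a successful run; zero-CpG DEGs
score 0 and are ineligible; zero-SD ZRPKM features are excluded with a flag;
constant-methylation fits raise a dedicated error and are skipped (with a
warning) in batch mode. Reports are byte-deterministic: JSON is written with
sorted keys, no timestamps, and every ordering in the package is explicitly
tied (variance ties by probe id, ranking ties by mean difference then gene id,
fit ordering by p then probe id).

## Known limitations

- Per-CpG DMR calls with a hard threshold ignore coverage uncertainty; a
  low-coverage CpG can cross the 0.4 line by sampling noise. The intersection
  step plus the `min_coverage` knob are the only guards, as in the original
  rule set.
- The specificity rule compares class means only; class variance is ignored.
- t-SNE coordinates are seed- and version-dependent; only their cluster
  structure is meaningful.
- The fusion duplicate rule is exact-match; near-duplicate breakpoints
  (off-by-one) are retained as distinct.
- VCF input is not parsed; variant tables arrive as TSV with the documented
  column names.
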