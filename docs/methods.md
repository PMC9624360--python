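# Methods

This note documents the models, defaults, numerical choices, and known
limitations of each pipeline stage, and what the synthetic-data generator
does and does not emulate.

## Differential miRNA expression (`mirpipe.microarray`)

**Model.** Probeset-summary intensities are treated as linear-scale values
containing an additive array background. Per array (sample) `s`, the
background estimate `b_s` is the mean intensity of the anti-genomic
control probesets on that array — background is an array-level property,
so it is never pooled across arrays. Each mature-miRNA probeset value `x`
becomes `log2(1 + max(x − b_s, 0))`, after first zeroing any value whose
detection (DABG) p-value exceeds `dabg_alpha` (default 0.05). The
pseudo-count of 1 is the only finite-valued convention compatible with a
chain that floors negative background-subtracted values to exactly 0; it
maps 0 to 0 and leaves well-expressed values essentially unchanged.

**Expression filter.** "Expressed above background in both cell lines" is
operationalized as: normalized value > 0 in at least half of each cell
line's samples, required for *every* line. This is symmetric across lines
and introduces no threshold beyond the DABG mask itself. Other readings
(per-condition, per-sample) are defensible; this one is a documented
package choice.

**Test.** For each expressed miRNA the pooled CON vs IK1 contrast is
tested with Tukey's HSD statistic

    q = |mean_IK1 − mean_CON| / sqrt(MSW/2 · (1/n1 + 1/n2)),

where MSW is the within-group mean square of a one-way layout and p comes
from the studentized-range distribution with `k` groups and `N − k` df.
Two layouts are supported. The default, `two_group`, pools all CON vs all
IK1 samples (k = 2, so q = √2·|t|); `four_group` pools the within-group
variance over the cell_line × condition cells (k = 4). The default is
two_group for two reasons: (i) it is the comparison actually performed —
one pooled control group against one pooled induced group; (ii) with
duplicate samples the four-group layout leaves only 4 error df, and the
resulting studentized-range tail is heavy enough that, at an effect of
2.0 log2 units and residual sd 0.3, recovery of planted effects after BH
correction drops to ~86–88%, below the 90% design target the generator's
default conditions are meant to support. Both layouts share the same
contrast and effect estimate; only the error pooling differs.

**Degenerate inputs.** A miRNA with zero within-group variance in every
group (possible after DABG masking zeroes a whole group) gets p = 0 when
the group means differ and p = 1 otherwise, plus a `zero_variance` flag
and a runtime warning — the studentized range is undefined there, and
this convention keeps obviously-different all-zero-vs-constant patterns
callable rather than silently dropped.

**Multiplicity.** Benjamini–Hochberg step-up across all tested miRNAs
(backed by `statsmodels.stats.multitest`). Calls require FDR < 0.05
*and* |difference| > 1 log2 unit, both strict.

## Peak reproducibility and TSS annotation (`mirpipe.peaks`)

Coordinates are 0-based half-open throughout; merging and intersection
require ≥ 1 bp genuine overlap (touching intervals do not merge). The
reproducible set is the per-base intersection of the merged coverage of
every replicate of every cell line — the most conservative reading of
"present in all replicates of all lines"; partial overlaps are reported
as the intersected interval. The interval engine is a sorted two-pointer
sweep, verified in the test suite against per-base brute force on
randomized toy chromosomes.

The peak anchor is the narrowPeak summit when called (summit offset ≥ 0),
otherwise the interval midpoint (integer floor). A gene is linked when
its TSS lies within the closed window [anchor − 50,000, anchor + 50,000];
the boundary is inclusive at exactly ±50,000 and exclusive at 50,001.
Link distance is signed on the gene strand (negative = upstream of the
TSS). TSS is taken as the annotated gene start (+ strand) or end − 1
(− strand). The mapping from miRNA genes to the mature miRNAs they encode
is an explicit two-column table, so polycistronic loci map to several
mature products; a differentially expressed miRNA with no mapping is
counted unbound and listed in a warning. The bound fraction is reported
rounded to a whole percent.

## Target networks and enrichment (`mirpipe.network`)

Gene symbols are upper-cased on both sides of every comparison.
Directional target sets are unions over the interaction table; "unique"
sets are set differences (genes targeted only by one direction). -3p/-5p
arms are distinct identifiers with distinct targetomes and are never
collapsed. Enrichment is the upper-tail hypergeometric probability with
the population size fixed at the interaction database's distinct-target
count (default 17,387) rather than at the genome, keeping the urn
consistent with how the query was drawn; when an explicit background
gene list is supplied, query and gene sets are first restricted to it,
and gene sets that vanish are skipped with a warning. One BH family per
collection per query. By default enrichment queries use the full
directional unions (the unique sets are also available), since the
headline pathway comparisons are run on all targets of each direction.

## Survival (`mirpipe.surv`)

Expression is standardized to cohort z-scores of the values as given
(normalized counts, linear scale); bins are low (z ≤ cut_low), high
(z ≥ cut_high), mid otherwise. Default cuts ±0.43 are the standard-normal
tertile boundaries, chosen to reproduce a three-group high/mid/low design
without asserting any particular study's exact cutoffs; both are
configurable. The log-rank test is the k-group score test over all
occupied bins; Cox regression uses the continuous z-score with Efron tie
handling and Wald intervals (via lifelines). Monotone partial likelihood
(complete separation) is flagged and the CI reported unbounded. The
per-miRNA screen ranks by log-rank p and never aborts on a single
miRNA's failure. Times are in days and are used as-is.

## Synthetic data (`mirpipe.simulate`)

The generator emulates: a two-cell-line, CON/IK1, duplicate-sample array
design with 95 anti-genomic probesets and non-miRNA decoy probesets;
planted up/down effects of `effect_size_log2` (default 2.0) with
log2-normal residual sd 0.3; a planted below-detection fraction (default
20%) realized through the detection p-values; replicate ChIP-seq peak
sets where bound genes get a peak within the 50 kb TSS window in every
replicate set and decoys appear only in strict subsets (plus a few
reproducible intergenic peaks on a gene-free chromosome to exercise the
no-gene path); a many-to-many interaction table whose directional target
pools overlap by a configurable rate (0 ⇒ provably disjoint unions);
gene-set collections with planted enriched sets; and a log-normal
expression cohort with exponential event times whose hazard is
`λ0 · exp(β · z)` with z the cohort-standardized expression — the same
covariate the survival stage computes, so `hazard_beta` is the log hazard
ratio the Cox fit estimates. Censoring is an independent exponential
calibrated to the requested null censoring fraction.

Intensities follow `background_mean + 2^(baseline + effect + noise)`:
the additive background is an array-level constant estimated by the
anti-genomic mean (estimation error ~ background_sd/√95 ≈ 1 intensity
unit), so the realized log2 residual equals the configured
`noise_sd_log2`. Expressed baselines are uniform on [6, 9] log2 units —
comfortably above background, as is typical of miRNAs that pass a
detection filter.

What it does **not** emulate: probe-level sequences or CEL summarization,
probe GC/affinity effects, correlated residuals across samples,
cross-hybridization, read-level peak shapes or fold-enrichment signal,
database annotation errors, or clinical covariates beyond one expression
column per miRNA. Passing tests therefore demonstrate correctness of the
statistical chain under its stated assumptions, not robustness to array
artifacts or cohort confounding.

Default problem sizes (200 miRNAs, 8 arrays, ~150 genes, 500 patients)
are chosen so a full end-to-end run takes seconds while leaving every
statistic well inside its asymptotic regime for the planted effects; all
generators accept larger sizes unchanged.

## Determinism

Every generator draws from a single `numpy.random.default_rng` seeded
from its config; identical seeds give byte-identical output files.
`run_all` re-runs are byte-identical on all result TSVs (the manifest
carries timestamps and is exempt).

## Known limitations

- The HSD p-value relies on scipy's studentized-range distribution;
  extremely large q with tiny df can underflow to 0, which BH handles
  but which loses relative ordering among the most extreme calls.
- The reproducibility filter has no partial-overlap fraction: a 1 bp
  mutual overlap across all sets counts. An overlap-fraction threshold
  would require a different merge semantics and is out of scope.
- The survival screen fits one miRNA at a time; the optional
  multi-covariate Cox fit shares no variable-selection logic.
- The GTF reader consumes gene lines with `gene_id`/`gene_name`/biotype
  attributes only; transcript-level TSS selection is not implemented —
  the annotated gene start/end stands in for the TSS.
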