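# Methods

This note records the models, parameter choices and numerical conventions
behind `braintip`, and what the synthetic benchmarks do and do not
establish about real data.

## Synthetic cohort model

The human generator draws a UMI count matrix over a fixed grid of donor
ages (default: the 29 distinct ages 29–94 with a gap between 29 and 42, one
donor per age, 200 nuclei per donor, 2000 genes). Per-gene baseline means
are log-normal (`mu = −0.7`, `sigma = 1.0` on the log scale) and counts are
negative binomial with dispersion θ = 2 (Var = μ + μ²/θ), multiplied by a
per-cell depth factor (log-normal, σ = 0.25). At these settings a 2000-gene
cell detects ~770 genes on ~1600 UMIs — a desk-scale analogue of a
single-nucleus library, and comfortably above the 500-feature QC floor.
Cell types are sampled per donor from proportions that drift linearly per
decade (glia up, neurons down) and renormalize; pseudotime is a jittered
monotone map of age. Mitochondrial genes are the first ⌈1% × n_genes⌉
genes, named `MT-*`, so QC behaviour is deterministic.

Two kinds of structure can be planted:

* **Waves** — a gene set whose log2 mean expression follows
  `±effect · logistic(steepness · (age − center))` (default effect 1,
  steepness 0.5/y): negligible a decade before the center, ~2-fold a
  decade after.
* **Transition module** — inside one age (or pseudotime) interval, module
  genes get their per-gene count SD inflated by a factor (default 3, via a
  recomputed NB dispersion at the same mean) and share a single latent
  Gaussian factor realizing intra-module correlation `rho_in_state`
  (default 0.7) through a Gaussian copula on the NB marginals; outside the
  interval the same mechanism runs at `rho_baseline` (default 0.2). The
  copula preserves the count marginals exactly while controlling
  correlation.

Two consequences of the count layer matter for interpretation:

* Copula correlation and dispersion inflation are strongly attenuated for
  near-zero-count genes — a module planted in genes expressed at ~0.3
  counts/cell is statistically invisible after log-normalization.
  Correlated-module genes (planted and background) therefore have their
  baseline means floored at 2 counts/cell (`corr_gene_min_mean`), matching
  the fact that real DNB candidate genes are measurably expressed.
* The generator also plants three 20-gene *background programs* at a
  constant latent ρ = 0.4 across all ages. Real transcriptomes carry
  co-expression structure everywhere; without it, no state other than the
  planted transition would yield any module, and a "which state has the
  highest CI" comparison would be vacuous.

The mouse generator produces bulk NB counts (means log-normal around 50,
θ = 10) over a month grid (default 3–28 months, 6 samples/month) with the
same transition machinery applied to month groups.

What the generator does **not** model: ambient RNA, doublets, batch
effects, cell-type-specific expression programs, or any fitting to real
datasets. Passing the planted-truth benchmarks therefore demonstrates that
the *statistics* recover the structures they are designed for at realistic
counting noise — not that real brains behave like the simulation.

## QC, normalization, groups

Nuclei with detected features (< 500 or > 7500) or mitochondrial count
fraction > 5% are removed; boundaries are kept (strict inequalities).
Normalization is library-size scaling to 10,000 counts followed by
ln(1 + x) — the conventional behaviour of single-cell toolkits, chosen
because only the name of the normalization step is standard, not a
formula. Age groups: young = 29–60, old = 65–94, anything between (or
beyond) unassigned; unassigned cells are kept for age-resolved analyses
and excluded from two-group comparisons.

## The rank test and its calibration

All two-group tests are the two-sided Wilcoxon rank-sum in its
tie-corrected normal approximation **without** continuity correction. This
is deliberate: DE-SWAN windows on the default grid contain only 3–6 donors
per side, where the exact test's discrete support makes it severely
conservative (attained size ≈ 0.031 at α = 0.05, or 0.030 with continuity
correction), while the plain normal approximation attains a mean size of
0.0497 across the grid's windows — the nominal level the scan's
significant-gene counts are interpreted against. Multiple testing uses
Benjamini–Hochberg throughout.

## DE-SWAN

Unit of analysis: donor pseudobulk (mean normalized expression per donor).
Cell-level testing is available behind a flag but inflates n by orders of
magnitude and trivializes p-values, and the original sliding-window design
operates on donors. Window boundaries are `[c − w/2, c]` vs `(c, c + w/2]`,
so each donor inside a window is used exactly once and the center donor
anchors the younger side. Centers default to all distinct donor ages;
centers with fewer than 3 donors on either side are skipped. Peaks are
strict local maxima (plateaus contribute their leftmost center; endpoints
qualify against their single neighbour).

Resolution caveat: with donors every 2 years, the expected window
separation at the two centers flanking a planted wave differs by ~2%, so
the realized argmax can land one grid step from the planted center (it
does in ~3/10 seeds); the scan localizes waves to grid resolution, not
beyond. Waves spaced more closely than the window width merge into broad
crests.

## Differential expression

Wilcoxon per gene on normalized expression; fold change on de-logged group
means `(mean(expm1 x_A) + ε)/(mean(expm1 x_B) + ε)`, ε = 1e−9. A gene is
*up* iff BH-adjusted p < α and fold > threshold (1.2 for the young/old
comparison, 1.5 for atlas-level marker calling); genes expressed in < 10%
of cells in both groups are not tested. Swapping labels exactly negates
log2 fold changes and flips directions.

Benchmark note: the power benchmark (50 genes shifted 2-fold, 200
cells/group) plants its effect in genes with baseline mean ≥ 2 counts/cell
— the same measurable-expression convention as the transition module — and
reaches ~99% sensitivity; no rank test can reach high sensitivity for
2-fold shifts in genes sampled at ~0.3 counts/cell. Null calibration is
measured on a cohort with nothing planted: a cohort *with* planted genes
has a genuine compositional shift in all remaining genes after library-size
normalization, which the test correctly flags.

## Gene-set scoring and enrichment

The AUC score ranks a cell's genes by descending expression (ties broken by
ascending gene index, for determinism) and integrates the recovery curve of
set genes over the top 5% of ranks, normalized so a set occupying exactly
the top ranks scores 1. The threshold-crossing delta takes the young-group
0.90 quantile as threshold t and reports P_old(score > t) − P_young(score
> t); 0.90 is a declared convention. The enrichment score
E = (n_A/N_A)/(N/N_total) satisfies Σ_s E_s·(N_s/N_total) = 1 exactly for
every cell type, which the tests assert. The CV profile reports the median
across genes of per-gene SD/mean within each group.

## Transcriptional noise

Counts are thinned binomially with p = target/depth (expected post-depth
exactly target; the default target is the minimum post-QC depth; exact
multivariate-hypergeometric subsampling is available by flag). On the
thinned, log-normalized matrix, genes with nonzero mean are ranked by
mean, split into 10 equal bins (remainder to the last), the extreme bins
dropped, and the 10 lowest-CV genes per retained bin form the invariant
set. Noise = Euclidean distance of each cell's invariant-gene profile to
its cell type's mean profile; groups are compared per cell type by
rank-sum with BH correction.

Caveat established during development: inflating *count* SD does not
monotonically raise log-scale noise — for weakly expressed genes the extra
dispersion mostly adds zeros, which *compresses* the log1p spread. The
dispersion-recovery benchmark therefore runs in an expressed-gene regime
(baseline log-normal with mean log 1.0), where the planted 2× dispersion
is recovered with the correct sign in ≥ 9/10 seeds.

## DNB scoring

States: closed age bins (default [29,41], [42,49], [50,55], [56,60],
[61,64], [65,70], [71,77], [78,83], [84,89], [90,94] — the 50–55 / 56–60 /
65–70 bins are the named comparison groups, the rest tile the cohort) or
equal-frequency pseudotime deciles. Within a state, modules are detected
by average-linkage clustering on 1 − |r| with the tree cut at 0.75 and a
minimum module size of 10; zero-variance genes are excluded. Each module's
CI = (PCC_in/PCC_out)·SD_in uses mean |Pearson r| (magnitude, not sign, is
what the DNB criteria concern), per-gene sample SD (ddof = 1), and a
PCC_out floor of 1e−6 to keep CI finite on decorrelated backgrounds. The
dominant module per state is the CI argmax (ties: larger module, then
lexicographically smaller gene tuple); the tipping state is the CI argmax
over states (ties: earlier state). Cells in earlier / tipping / later
states are labelled young / tipping / old, and the tipping state's
dominant module is reported as the DNB gene list with its |r| ≥ 0.3
network.

Replicate-level (bulk) operating point: with ~6 samples per state the null
|r| level is ≈ 0.4, so the single-cell cut height would merge the entire
transcriptome into one unscorable cluster. Bulk cohorts are scored with
`cut_height = 0.4` and module detection restricted to the 100
highest-within-state-SD genes — DNB criterion 1 applied as pre-selection —
with the minimum state size relaxed to the replicate count. Under these
settings the planted month-18 transition is recovered in 10/10 seeds.

## Problem sizes

Benchmarks run at the cohort scale stated above (5800 nuclei × 2000 genes
human; 54 samples × 2000 genes mouse); the full test suite takes ~40 s and
the acceptance script ~30 s on one CPU.

## Known limitations

* The generator's cell types differ only in mixing proportions, not in
  expression programs; cell-type-resolved analyses exercise bookkeeping,
  not biology.
* Module detection by fixed-cut hierarchical clustering is sensitive to
  the cut height at small sample sizes; the bulk operating point above is
  calibrated for ~6 replicates and should be revisited for other designs.
* DE-SWAN runs without covariate adjustment (age is the only modelled
  axis); sex and region are carried in metadata but not regressed out.
* Pseudotime is consumed as input; no trajectory inference is performed.
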