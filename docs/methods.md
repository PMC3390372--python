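# Methods

This note documents the statistical model behind each stage of the
pipeline, what the synthetic-data generator does and does not emulate,
the numerical choices made where the procedure left room, and known
limitations.

## Read representation and deduplication

A read is reduced to its 5′-most aligned base and strand. The analysis
counts reads per bin rather than per-base coverage, so fragment length is
irrelevant; a read belongs to the bin containing its 5′ position. Reads
mapping to identical positions are collapsed into single reads, where
"identical position" means identical `(chrom, pos5, strand)` — the
standard single-end PCR-duplicate definition. An `ignore_strand` flag
collapses the two strands as well, for libraries where strand is not
informative. Deduplication is idempotent, and the library size `M`
(millions of mapping reads) is always the post-deduplication count.

All internal coordinates are 0-based half-open. GFF3 (1-based closed)
and CX reports (1-based) are converted on read; BED passes through.

## Re-replication caller

With 100-bp bin counts `n_i`, the normalized score is
`(n_i + c) / 0.1 / M` (reads per kb per million mapped), with pseudocount
`c = M/10` guaranteeing strict positivity so the per-bin
`log2(mutant/wild-type)` ratio is finite everywhere. The ratio track is
then tiled into 1-kb windows stepped 500 bp; a window's value is the
arithmetic mean of its ten constituent bin ratios (the ratio is formed
first, then windowed — windows do not re-aggregate raw counts).
Windows are Z-standardized against the mean and standard deviation of
**all** windows, genome-wide by default (`per_chrom=True` standardizes
each chromosome separately); no outlier trimming is applied. Windows
with `Z > 2` become intervals, and intervals separated by at most 500 bp
(including overlapping and adjacent windows) are merged. A TE is
re-replicating iff it overlaps a called region by ≥ 1 bp; half-open
touching does not count.

Numerical guards: partial windows at chromosome ends are dropped so the
Z population is homogeneous; a constant ratio track (standard deviation
zero up to accumulated rounding noise, detected at relative tolerance
1e−12) maps to `Z = 0` everywhere and yields no calls.

Because roughly 12 % of the default simulated genome is elevated
heterochromatin, the genome-wide Z distribution is a mixture; elevated
windows stand 2.5–3 standard deviations above background, comfortably
clearing the cutoff, which is why recovery is near-exact at the default
coverage. At mean coverage well below ~20 reads per bin, or with
heterochromatin fractions approaching half the genome, the mixture
compresses the Z scale and the cutoff loses power — the caller's main
operating constraint.

Coarse chromosomal views use normalized densities
(reads/base/million mapped) in 100-kb bins, smoothed triangularly ten
times; the log2 view pseudocounts both densities with `c = M/10`.

The heterochromatin read-fraction comparison between two libraries is a
two-sided test on the 2×2 table (in/out of heterochromatin × sample):
chi-square with Yates continuity correction, replaced by Fisher's exact
test when any cell is below 5. The result object records which test was
used. Per-TE DNA read densities (reads per kb of TE per million mapped)
are compared with a two-sided Wilcoxon rank-sum test, exact when there
are no ties; the fully tied degenerate case returns p = 1.

## Derepression caller

RPKM is `count / (length/1000) / (lib_size/10^6)` with `lib_size` the
total mapped reads of the replicate. Fisher's exact test is applied to
raw counts — `[[count_mut, lib_mut − count_mut], [count_wt, lib_wt −
count_wt]]` — never to RPKM, since exact tests require counts. The
two-sided p-value sums every outcome on the hypergeometric support (the
feature's total count across both libraries, margins fixed) whose
probability does not exceed the observed table's. The support is
enumerated directly in log space via `gammaln`; outcomes structurally
tied with the observed one (mirror tables) are included using a relative
tie tolerance of 1e−11, which absorbs `gammaln` rounding noise while
remaining far below any genuine probability gap. Benjamini–Hochberg
correction is applied per replicate pair across all features.

The derepression call requires, in **every** replicate pair, fold change
> 4 on zero-replaced RPKM **and** adjusted p < 0.01. Zero replacement
assigns each zero RPKM the smallest non-zero RPKM of the same sample
(counts are never zero-replaced). The p threshold applies to adjusted
values by default; `use_adjusted=False` (CLI `--raw-p`) switches to raw
p-values for the alternative reading. Replicates pair index-to-index
(wild-type i vs mutant i); any explicit pairing can be passed instead.
Setting `p_cut ≥ 1` disables the significance filter entirely (p can
equal 1 exactly, so a strict inequality would otherwise never pass).

Set-overlap enrichment uses the upper-tail hypergeometric probability of
the observed intersection given the two set sizes and the universe.

## Methylation

The fundamental statistic is the pooled, coverage-weighted level
`Σ#C / Σ(#C + #T)` per context over whatever domain is requested; a
per-site-mean mode is available behind a flag. Both strands are pooled.
Zero-coverage bins are missing (NaN), never 0, and are excluded from
cross-feature means rather than imputed. Chromosome profiles smooth each
contiguous covered run independently so missingness cannot bleed into
neighbors. Feature metaplots use fixed-width flank bins (default 2 kb in
20 bins) and length-scaled body bins (default 20): each position maps to
the body bin containing its scaled coordinate; minus-strand features are
mirrored so the TSS is always left.

## Signal operators

The moving average truncates its window at the edges (no invented
values); triangular smoothing convolves interior points with
(0.25, 0.5, 0.25) per iteration and copies the endpoints unchanged, since
the kernel is undefined there. Both are linear, preserve constants, and
keep outputs within the input range. Boundary metaplots aggregate both
edges of every region, mirroring right edges so positive offsets always
point into the region; boundaries snap to the signal's bin grid, regions
shorter than one bin are skipped with a warning, and overlapping flanks
of nearby regions are aggregated unless `exclude_overlapping` is set
(no exclusion is the default because none is required by the
procedure). Size strata are user-configurable, with a quartile helper.

## Flow cytometry

Ploidy peaks are geometrically spaced (2C, 4C, 8C, 16C), so peak
detection runs on **log** intensities, where all peaks have equal width
(the standard deviation of log intensity equals CV/100) and equal
spacing (log 2). A Freedman–Diaconis histogram of log intensities is
smoothed with a 3-bin moving average, the requested number of highest
local maxima is taken, and each center is refined as the mean intensity
of events within ±1.5 bins — recovering component means to well under
5 % at 10,000 events. The CV of a peak is `100·sd/mean` over events
gated in `[center·0.75, center·1.25]`; the gate is explicit
configuration because instrument-software peak regions are not
standardized. The CV is exactly invariant under global intensity
rescaling. Fewer than 50 gated events is an error (unstable estimate).
Replicate CVs are summarized as mean ± SD, and mutant CVs can be
normalized to the wild-type CV.

## Synthetic-data generator

Defaults describe the desk-scale study conditions: two 2.5-Mb
chromosomes; ten heterochromatin patches of 20–100 kb aligned to the
100-bp coverage grid, placed with ≥ 120-kb gaps; TE density 60/Mb inside
patches vs 12/Mb outside (lengths 500–5,000 bp; superfamilies 50 %
LTR/Gypsy, 30 % LTR/Copia, 20 % LINE/L1); wild-type coverage 50 reads
per 100-bp bin; mutant copy factor κ = 2 inside patches (κ is free
configuration — the copy gain is modeled as a uniform per-patch coverage
multiplier, not origin-level re-firing dynamics, because the caller only
sees aggregate coverage); two RNA-seq replicates of 5 million mapped
reads with 50 TEs planted at 8-fold upregulation; methylation means
CG 0.8 / CHG 0.4 / CHH 0.1 in heterochromatin vs 0.2 / 0.05 / 0.02
outside at depth 20; and 10,000 FACS events over peaks at 100/200/400/800
with 5 % CV and weights 0.35/0.30/0.20/0.15.

DNA read counts per 100-bp bin are Poisson with the configured mean
(times κ in mutant heterochromatin); positions within a bin are drawn
uniformly **without replacement** over (position, strand) slots, so the
simulated placements are duplicate-free and deduplication does not
distort the planted coverage (sampling with replacement would silently
shave ~10–20 % off high-coverage bins after dedup and bias the log2
ratio downward). RNA-seq counts are negative binomial
(Poisson–gamma, dispersion 0.05 by default, 0 giving Poisson) with
expected count `baseline_rpkm · length_kb · lib_size/10^6`; baselines
are lognormal with a 30 % silent (zero) fraction, which exercises the
zero-replacement rule. Planted TEs are drawn from TEs with baseline at
or above the median non-zero baseline — an 8-fold gain of a silent TE is
undetectable by construction, so planting is restricted to expressed
elements. Methylation counts are Binomial(depth, mean) at uniformly
placed sites (2/kb per context by default). Every generator is
deterministic given its seed, with an independent stream per stage.

A companion configuration, `expression_study_config`, scales the
annotation (five 10-Mb chromosomes, ~2,000 TEs) for derepression-recovery
studies where the DNA-coverage stage is not simulated.

What the generator does **not** emulate: sequence content (no
FASTA/FASTQ), mappability and GC biases, bisulfite conversion errors,
fragment-length effects, TE nesting structure, batch effects between
replicates, and cell-cycle or origin-firing dynamics. Passing recovery
tests therefore demonstrates correctness of the statistical machinery
under the stated model, not robustness to alignment artifacts or
coverage biases in real libraries — which is why the callers expose
their thresholds rather than hard-coding them.

## Known limitations

- The Z-score segmentation has no explicit multiple-testing control; the
  `Z > 2` cutoff is a fixed operating point whose false-positive window
  rate under the null is the ≈ 2.3 % normal upper tail.
- Fisher's exact test between two libraries ignores biological
  overdispersion; requiring every replicate pair to pass is the guard
  against it, and strongly controls false calls in the null simulations.
- The FACS peak CV is comparable only within this implementation's
  gating convention; instrument-software peak regions differ.
- `window_z` assumes chromosomes are long relative to the window;
  contigs shorter than one window are skipped.
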