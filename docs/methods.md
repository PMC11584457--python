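# Methods

`amplihap` infers amplicon haplotypes from pooled dual-barcoded paired-end
short reads and quantifies their within-sample frequencies. This note
records the models and procedures implemented, the parameters that matter,
the numerical choices made where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## Pipeline model

The data model is a multiplexed amplicon run: each sample carries a unique
(barcode_fwd, barcode_rev) pair and each marker a unique primer pair, so a
read pair's origin is identified by the prefix `barcode + primer` on each
mate. The pipeline is a linear chain of table-to-table stages, each
persisted as TSV:

1. **Demultiplex** — exact prefix match (barcode first, selecting the
   sample; then primer, selecting the marker), both prefixes trimmed.
   Matching is exact by default; `max_mismatch` allows a per-element
   Hamming tolerance. Orientation is fixed (no swap search). Exactness
   makes assignment counts exactly reproducible.
2. **Quality filter** — a pair is kept iff neither mate contains `N` and
   each mate's expected error count `sum 10^(-Q/10)` is at most
   `max_expected_errors` (default 2.0 per read) after any positional
   truncation from a per-marker trim table. Expected-error filtering is
   the sole quality criterion; no quality-tail truncation is applied —
   trimming is positional only.
3. **Downsample** — combinations below `min_read_count` are dropped
   (0 disables); combinations above `n_sample` (default 10,000) are drawn
   without replacement to exactly `n_sample` using a PRNG stream keyed by
   `(seed, sample_id, marker_id)`, so results are independent of table
   order and parallelization.
4. **ASV estimation** — per combination and direction: dereplicate to
   exact-sequence uniques, denoise (below), then let each read pair vote
   for its (forward-center, reverse-center) pair; center pairs with at
   least `min_asv_count` votes are merged (maximal exact suffix/prefix
   overlap of at least `min_overlap` bases, or plain concatenation of the
   reverse complement when `min_overlap = -1` for non-overlapping designs).
5. **Annotation** — per-row global alignment identity against the marker
   reference (`ident`), per-marker z-standardization of identity across
   the dataset (`ident_z`), chimera detection, and a status label.
6. **Sequence filtering** — homopolymer and terminal indel correction,
   dataset-level filters, variant calling and masking, haplotype naming
   and within-sample frequencies, VCF export.
7. **Report** — a single static HTML file with all summary views; every
   number shown is recomputable from the stage TSVs next to it.

## Denoising

Denoising is a greedy pass over uniques in descending abundance. A unique
*u* is absorbed into an accepted center *c* at Levenshtein distance
`d <= d_max` (default 10; indels count, which is what lets the denoiser
tolerate indel errors) when **both** of:

- **skew** — `abundance(u)/abundance(c) <= beta(d) = 1/2^(alpha d + 1)`
  with `alpha = 2`: an error lineage is rare relative to its template;
- **error-model plausibility** — `abundance(u)` is consistent with
  `Poisson(abundance(c) * (eps/3)^d)`, the expected number of reads that
  mutate from *c* into exactly *u*'s sequence at per-base substitution
  rate `eps`; a unique with `P(X >= count) < p_new` (default 0.01) is
  treated as a genuine variant and becomes a center even where the skew
  test alone would absorb it.

plus a small-count floor (default 3): near-singleton uniques within
`d_max` of any center are absorbed into the nearest one unconditionally,
so a low-frequency true haplotype retains its own error tail instead of
shedding it as spurious centers.

The plausibility condition is the load-bearing one. A pure abundance-skew
rule cannot provide minor-clone sensitivity: `beta(1) = 0.125` absorbs any
single-substitution variant below ~12.5% relative abundance, while the
detection regime of interest is ~0.1%. At that frequency the only usable
signal is that a true variant's count (~10 per 10,000 reads) exceeds the
expected count of any specific error child (`n * eps/3`, ~3 at
`eps = 0.1%`); the Poisson test encodes exactly that comparison, in the
spirit of quality-aware partitioning denoisers. `eps` is estimated per
combination and direction from the distance-1 neighborhood of the most
abundant unique (`sum of neighbor abundances / (a_top * L)`); a
co-occurring true variant at distance 1 inflates the estimate slightly,
which errs conservative precisely when that variant is abundant enough
not to need protection. An explicit rate can be passed instead. `p_new =
0.01` is a conventional significance level chosen so the denoiser is not
the binding constraint at the detectability boundary — the abundance
filters below are.

Consequence worth stating: near the statistical limit, the occasional
largest error child is indistinguishable from a real variant, so the
unfiltered ASV table can contain a few spurious low-count rows. They are
removed downstream by `min_asv_count`/`min_asv_freq` and, when they
survive those, by variant masking (their defining allele has dataset MAF
below `var_maf`).

## Annotation

- **Alignment**: end-to-end Needleman–Wunsch with match +1, mismatch −1,
  gap open −2, gap extend −1. Identity is identical columns over the full
  alignment length, gaps in the denominator (a 3-nt deletion against a
  120-nt reference gives 117/120). Global end-to-end alignment fits
  fixed-primer amplicons, where haplotypes are full-length by
  construction.
- **Standardization** is per marker with the sample (n−1) standard
  deviation; a marker with a single row or zero spread gets z = 0 for all
  rows. Per-marker (not global) standardization is the variant that
  reproduces the reference arithmetic exactly.
- **Chimeras**: a row is flagged when two parents exist in the same
  (sample, marker) combination, each with `count >= min_parent_ratio *
  child_count`, whose exact mosaic reproduces the child with 1..
  `max_breakpoints` switch points. All sequences are projected into
  reference coordinates first (insertions dropped), giving a common
  column space; the minimal switch count is found by the greedy
  feasible-set scan, which is optimal for minimal segmentation. Only
  two-parent mosaics are searched; three-parent chimeras are out of scope
  (consistent with the default `max_breakpoints = 3`).
- **Status**: the six fail conditions are evaluated independently; one
  failure gives its label, two or more give `multiple`, none gives
  `pass`. All rows are retained with their status; filtering happens
  downstream. `min_read_count` is assessed on the post-downsampling
  combination total.

## Sequence filtering

Homopolymer correction reverts an insertion or deletion when its bases
all equal the base of a reference homopolymer run of length
`>= min_homo_rep` (default 3) at that position; terminal correction
reverts indel runs lying entirely within `terminal_region_len` (default
5) columns of either alignment end. Both are identity when their
parameter is null, and both are idempotent. They run before variant
calling, so the variant table is substitution-only in the common case;
residual interior deletions are carried as `-` alleles and exported as
anchored indel VCF records (insertions relative to the reference are not
called).

Dataset filters drop non-pass rows, then combinations whose pass total is
below `min_marker_count`, then samples and markers by missingness
(fraction of the full study design's markers/samples with no pass data,
thresholds `max_sm_miss`/`max_marker_miss`; boundaries are inclusive, so
0.5 missing at a 0.5 threshold survives).

Variant calling pools read counts across all passing rows of a marker:
allele frequency is count-weighted, MAF is the frequency of the most
frequent non-major allele, and He = 1 − Σp². A site fails when it has
more than `n_alleles` alleles (always enforced) or MAF < `var_maf` or
He < `var_he` (enforced when masking is active, below). At a failing
site, every allele except the major one is reverted to the reference
base in the haplotypes carrying it (gap alleles are left so masking never
changes sequence length), the affected rows are flagged `masked = TRUE`,
and haplotypes identical after masking merge with counts summed.

`sample_med_He` gates the MAF/He masking: each sample's median per-marker
haplotype heterozygosity is computed from within-sample frequencies, and
masking is active when the median of those medians across samples is at
least `sample_med_He`. The default 0 keeps masking always active; a
mixed-infection run can raise it so that genuinely diverse datasets skip
frequency-based masking. This gating is an interpretation of an
ambiguous knob and is deliberately conservative: the allele-count cap is
never gated.

Haplotypes are named `<marker>-<k>` in descending total dataset
abundance with lexicographic tie-break. The numbering is deterministic
but otherwise arbitrary; no meaning attaches to the index.

## Synthetic data

The generator emulates a defined-mixture amplicon run: per (sample,
marker) it draws each read pair's source haplotype binomially from the
mixture ratio, builds `barcode + primer + insert` fragments (reverse
complement on the mate), and emits fixed-length reads with

- a linear Phred decay (default Q38 → Q20 across the read; the same
  deterministic quality string for every read),
- per-base substitution (default 0.1%) and indel (default 0.01%) errors
  confined to the insert,
- PCR chimeras at a configurable rate (default 0.2%): two-haplotype
  mosaics with one uniformly placed interior breakpoint,
- spurious homopolymer indels at a configurable rate (default 0.1%):
  one base inserted into or deleted from a random homopolymer run.

Every pair is recorded in a truth table (sample, marker, source
haplotype, artifact label), sufficient to score demultiplexing
assignment, denoising recovery, and chimera detection exactly. The
bundled five-sample design mixes two alleles per marker (1–2
substitutions apart, 120-nt amplicons, two markers) at ratios 1:1, 1:10,
1:100, 1:500, 1:1000 with 10,000 pairs per combination by default.

What it does not emulate: errors in technical bases (barcodes/primers are
emitted error-free, so demultiplexing is lossless by construction),
empirical quality-dependent error profiles, PCR-cycle-explicit chimera
formation, or quality strings that reflect the injected error rate.
Passing tests therefore demonstrate the pipeline's contracts under a
clean, fully parameterized error model — not performance on a particular
instrument's error spectrum.

## Detectability at the 0.1% boundary

With 10,000 pairs and default thresholds, a minor clone at frequency
0.1% has expected count 10 — exactly the `min_asv_freq = 0.001` cutoff.
Retention is then approximately `P(X >= E[X])` for a binomial count,
about 0.5–0.6 per replicate; it cannot reach high reliability at this
exact boundary for any method, because the threshold sits on the mean.
The replicated experiment in `amplihap.validate.minor_clone_retention`
measures this directly (typical runs: 100% retention at 1:10 and 1:100,
~55–65% at 1:1000). One mixture step above the boundary (1:500, expected
count 20) retention is near-certain. This is the honest operating
characteristic of threshold-based detection at its nominal limit.

## Numerical and reproducibility choices

- All randomness flows from explicit integer seeds; per-combination
  streams are keyed by `(seed, crc32(sample:marker))` so results do not
  depend on iteration order.
- Gzip outputs pin `mtime = 0`, making stage outputs byte-identical
  across reruns; the HTML report is deterministic except its timestamp
  line.
- Ties are broken lexicographically by sequence everywhere a rank is
  assigned (dereplication order, denoiser center choice, haplotype
  naming).
- Alignments are cached per (sequence, reference) pair; the first optimal
  alignment reported by the aligner is used, which is deterministic for
  fixed inputs.
- Degenerate inputs: empty FASTQ dereplicates to an empty unique set; a
  marker with zero spread standardizes to z = 0; combinations with no
  merged sequences are omitted with a log line; an all-filtered dataset
  raises an error naming the stage that emptied it.
- Default problem sizes in the test suite are scaled (1,200 pairs per
  combination for the end-to-end fixture; 10,000 for the detectability
  experiments), chosen to exercise every stage at depths where the
  binomial expectations being tested are sharp.

## Known limitations

- The denoiser models substitution error lineages; indel error lineages
  are absorbed by distance but not modelled in the plausibility rate
  (conservative: they are rarer than substitutions on short-read data).
- Insertions relative to the reference are preserved in haplotype
  sequences but not called as variants.
- The chimera search considers two parents; higher-order mosaics are not
  detected.
- Frequencies are read-count proportions; no PCR/sequencing bias
  correction is attempted.
- The NJ tree places haplotypes of different markers at fixed distance
  1.0 (distinct loci share no alignment columns), so cross-marker
  branch lengths are nominal.
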