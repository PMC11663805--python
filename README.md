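# cdrscan

Detect hypomethylated dip regions (CDRs) inside centromeric
alpha-satellite higher-order-repeat arrays from long-read CpG methylation
pileups.

Centromeres are typically hypermethylated across the alpha-satellite
array except for a localized hypomethylated window that coincides with
CENP-A chromatin at the kinetochore.  `cdrscan` finds these windows from
three inputs:

1. a per-CpG methylation pileup in **bedMethyl** format (as produced by a
   modified-base pileup tool from a methylation-tagged BAM),
2. a **BED** file of target regions (alpha-satellite HOR array plus
   flanks), and
3. a **repeat annotation** of the target regions, either BED4 (4th column
   = repeat name) or RepeatMasker `.out`, used to locate "ALR/Alpha"
   intervals.

It emits a BED file of dip calls and an optional three-panel diagnostic
figure per region (repeat annotation + call bars, binned methylation with
the regional median, total/methylated read coverage).

## Method

For each target region the pileup is aggregated into sequential 5-kbp
bins (unweighted mean CpG methylation frequency; empty bins excluded),
and bins overlapping an "ALR/Alpha" annotation form the analysis signal.
With regional median *m*:

- **candidates** are alpha bins with mean frequency below
  `m * (1 - depth_fraction)` (default `depth_fraction = 0.34`);
  genomically consecutive candidates form one valley;
- valleys are kept only if their topographic **prominence** (computed at
  the deepest bin on the alpha-bin signal) is at least
  `prominence_fraction * m` (default `0.30`);
- each surviving valley's boundaries are **extended** outward one bin at
  a time while the neighbouring alpha bin stays below
  `mean - edge_sd_multiplier * SD` (default one SD);
- calls separated by at most `merge_gap_bins` bins (default 1) merge.

An `--absolute-thresholds` mode interprets the depth and prominence
cutoffs as raw frequencies instead of median-relative ones.

## CLI

```sh
# call dips
cdrscan call --bedmethyl pileup.bedmethyl --regions regions.bed \
    --repeats repeats.bed --repeat-dialect bed --out outdir \
    [--bin-size 5000] [--depth-fraction 0.34] [--prominence-fraction 0.30] \
    [--edge-sd 1.0] [--merge-gap 1] [--absolute-thresholds] \
    [--combine-strands] [--plot png] [--skip-errors] [--config config.yaml]

# generate a fully synthetic fixture (pileup + repeats + truth + region)
cdrscan simulate --seed 7 --out simdir [--region-length 3000000] \
    [--n-dips 1] [--dip-min 60000] [--dip-max 150000] [--coverage 30]

# score calls against a truth BED
cdrscan evaluate --calls outdir/sample_cdr_calls.bed \
    --truth simdir/truth.bed [--tolerance 5000]

# render diagnostic figures only
cdrscan plot --bedmethyl ... --regions ... --repeats ... --out plots
```

`call` accepts a YAML config whose keys mirror the flags; explicit
command-line flags override the file.  Exit codes: 0 success, 2 usage
error, 3 parse error, 4 empty-region / no-alpha-signal error.

Upstream preprocessing (not reimplemented here): align methylation-tagged
long reads to the assembly, pile up modified bases into bedMethyl, and
run a repeat masker on the region FASTA to obtain the annotation.

## Evaluation semantics

`cdrscan evaluate` classifies each truth dip as *correct* (a call covers
it to within the boundary tolerance at both ends), *partial* (overlapped
but with a larger boundary deficit) or *missed*; calls overlapping no
truth dip are *erroneous*.  Precision is
`(n_calls - erroneous) / n_calls`, recall is
`(correct + partial) / n_truth`.
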