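# Methods

## The scan statistic

At each biallelic SNP the two pools give allele-frequency vectors
`H = (h_ref, h_alt)` and `L = (l_ref, l_alt)`, estimated as read-depth
fractions from the AD field. The per-site statistic is the Euclidean
distance

    ED = sqrt( (H_ref − L_ref)² + (H_alt − L_alt)² ),

bounded by √2 for biallelic sites. ED is a metric on frequency vectors and
is invariant to swapping the two pools, so the scan is direction-agnostic;
the direction of the allele-frequency shift can be read off the per-site
table if needed. A 4-dimensional (A/C/G/T) variant of the statistic is not
implemented: after QC every site is biallelic and the two extra coordinates
would be identically zero.

**ED^x.** Raising ED to a power x ≥ 1 (default x = 2) shrinks background
noise (ED ≪ 1) faster than signal, and is monotone, so site ranking is
unchanged. x is a config/CLI parameter.

**Smoothing.** The raw ED² track is dominated by binomial read-sampling
noise, so it is smoothed per chromosome with a tricube-kernel local
weighted mean over physical distance:

    fitted_i = Σ_j w_ij ed²_j / Σ_j w_ij,
    w_ij = (1 − (|pos_j − pos_i|/b)³)³  for |pos_j − pos_i| < b.

The kernel was chosen because it preserves constants exactly, reproduces
the raw value for isolated sites, has compact support (so an exact O(n²)
oracle exists and is used in the tests at 1e-10 tolerance), and needs a
single parameter. Default bandwidth b = 2 Mb, matching the Mb-scale linkage
blocks of a natural variety panel; a bandwidth below the median marker gap
triggers a warning because the fit then degenerates to the raw track.
A local-linear (loess-like) alternative was considered and rejected: with
positive-valued, peak-shaped input it can overshoot below zero at peak
shoulders, while the weighted mean stays within the window's range.

**Threshold.** Per chromosome, `median(fitted) + 3·SD(fitted)` with sample
SD (ddof = 1). The median (not the mean) anchors the cut-off to the
background level, so a single strong peak inflates only the SD term.
Thresholds are per chromosome rather than genome-wide because chromosomes
carrying a QTL have genuinely heavier-tailed fitted distributions.
Computed on the *fitted* per-chromosome values: the threshold must live on
the same scale as the track it cuts. Fewer than 2 sites on a chromosome is
an error (SD undefined).

**Region calling.** Maximal runs of consecutive sites with
`fitted > threshold` — strict inequality, so boundary ties are excluded —
with runs separated by less than `merge_gap` (default 100 kb) merged.
Region bounds are the first and last above-threshold SNP positions, i.e.
SNP-position bounds, not padded intervals.

## Interval accounting

Cross-year candidate regions are plain interval intersections
(`[max(starts), min(ends)]` per overlapping pair), with source labels
unioned. Reported sizes follow the `end − start` convention (converted to
Mb and rounded half-away-from-zero to 4 decimals); this is the convention
under which the reference interval table's printed sizes are reproduced
exactly, and `end − start + 1` rounds identically for all four reference
rows, so nothing is lost by adopting the half-open count. Gene overlap, by
contrast, treats both region endpoints as inclusive (both are SNPs inside
the region): a gene is assigned on ≥ 1 bp overlap, with a
containment-only mode behind a flag. Strand is ignored for overlap and
carried through to output.

## Variant QC

* A pool's observation is **valid** at ≥ `min_depth` (default 5×) total
  reads; below that it is missing.
* A site is dropped when its missing fraction over pools exceeds
  `max_site_missing` (default 0.5). With only two pools this drops a site
  exactly when both pools are missing; the fraction form is kept so the
  same rule applies to per-variety tables.
* Pooled MAF — computed from the combined ref/alt depths of the valid
  pools — must be ≥ `min_maf` (default 0.20, boundary inclusive).
* Only biallelic SNP records are read at all; indels and multiallelic
  records are dropped with a logged count.

The validity→MAF sequence equals a joint one-pass filter and is idempotent
(both properties are tested). The per-sample missing-rate filter (default
0.3) and the heterozygote calling rule (MAF ≥ 0.2 with ≥ 4 reads per
allele) belong to many-sample array genotyping; they are carried in
`QCParams` for per-variety use but are inert in two-pool mode.

Marker density uses non-overlapping windows (default 500 kb), half-open
`[k·w, (k+1)·w)` on 0-based coordinates — a 1-based position `p` falls in
window `(p−1)//w` — so window counts are bit-exact reproducible. Gap sizes
are successive position differences per chromosome.

## Phenotype suitability

Per year: max, min, mean, sample SD, and bias-corrected (adjusted
Fisher–Pearson) skewness G1 and excess kurtosis G2. A year is flagged
suitable for BSA when |G1| < 1 and |G2| < 1, the usual
approximate-normality screen. The moment (uncorrected) versions are
available via `bias_corrected=False`; which flavor a given published table
used is generally not recoverable, and for n ≈ 85 the difference is small.

## The simulator

`synth_data` emulates the study design end to end, with ground truth
exposed for testing:

* **Panel.** SNPs at uniform-random positions (`snp_density` per Mb,
  default 25 — array-scale density). Per-SNP panel allele frequencies are
  Uniform(0.1, 0.9). Sixteen founder haplotypes are drawn site-wise from
  those frequencies; each individual haplotype is a Markov mosaic of
  founders with per-interval switch probability
  `r = min(0.5, d_bp · 1e-8 · recomb_scale)`. Default `recomb_scale = 40`
  gives an LD persistence length of ~2.5 Mb — linkage blocks of a few Mb,
  as seen in self-pollinating variety panels — so ED peaks are
  Mb-scale rather than chromosome-scale. Because both bulks draw from the
  same founder pool, founder-frequency noise cancels in H − L and the null
  ED level is set by haplotype- and read-sampling alone.
* **Trait.** `y = Σ_q effect_q · dosage_q + e`, with `e` Gaussian, scaled
  so the realized genetic-variance fraction equals the requested h².
  `h2 = 0` produces a pure-noise (null) trait; `h2 = 1` is noise-free.
  Replicate years share genotypes and redraw noise only.
* **Bulks.** Round-half-up of `q·n` individuals per tail (default 15%
  tails of 200 individuals), ties broken by stable individual id, so
  selection is deterministic and permutation-invariant.
* **Reads.** Per site and pool: depth ~ Poisson(mean depth, default 50×);
  alt count ~ Binomial(depth, p′) with
  `p′ = p(1−e) + (1−p)e` folding a symmetric per-base error rate
  (default 1e-3) into the true pooled frequency p.
* **Seeds.** One master seed expands through `numpy.random.SeedSequence`
  into per-stage substreams (panel, per-year reads); the pipeline manifest
  records all derived seeds and the same config reruns bit-identically.

What the simulator does **not** model: coalescent/pedigree structure,
population stratification, genotyping batch effects, reference bias,
mapping artifacts, indel realignment, or read-level errors correlated along
reads. Passing tests therefore demonstrate correctness of the statistics
and plumbing and sane behavior under idealized pooled sampling — not
robustness to every artifact of real resequencing data.

## Default problem sizes

The simulation-backed tests and the acceptance script run the full
two-year pipeline on 200 individuals, 5 chromosomes × 40 Mb, 25 SNPs/Mb
(≈ 5000 SNPs), 15% tails at 50×, across 20 seeds for the recovery rate and
20 for the null rate; smaller panels (2–3 chromosomes) back the
property-style checks. These sizes give stable rates while keeping a full
suite run in tens of seconds.

## Known limitations

* The tricube local mean is one reasonable choice of profile fit among
  several; peak *boundaries* (hence region sizes) shift with bandwidth,
  though peak *coverage* of a true QTL is robust across the tested grid.
* With two pools the missing-site rule has only the degenerate
  both-missing case; the many-sample semantics are untested against a real
  array cohort.
* `median + 3·SD` is a background-interference heuristic, not a calibrated
  genome-wide error rate; the null false-coverage rate is measured by
  simulation instead.
* Interval sizes use the `end − start` convention described above; anyone
  needing inclusive lengths should add 1 bp per region.
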