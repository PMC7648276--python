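# Methods

This note documents the models, algorithmic choices and limitations of
`aneuhic`. It complements the README, which explains what the package is
for; here the emphasis is on *how* each quantity is computed and why the
defaults are what they are.

## Restriction geometry

A chromosome is digested in silico by scanning the forward strand for the
enzyme motif; each occurrence starting at `s` cuts at `s + cut_offset`
(HindIII `A^AGCTT`: offset 1). Only palindromic motifs are accepted, so
the forward scan finds every site; non-palindromic motifs raise an error
rather than silently missing the reverse-strand sites. Coordinates are
0-based half-open throughout, including BED/bedGraph output. Fragments
tile `[0, L)` exactly; cuts that would fall at position 0 or L are
dropped because they would create empty fragments.

**Fragment-end windows.** Each fragment of length ≥ 2·MML carries two
windows of MML bp at its ends; shorter fragments carry a single
whole-fragment window. This guarantees no base belongs to two windows of
the same fragment and no read can be counted twice within a fragment.

**Per-bin covariates.** GC content is the G+C fraction over non-N bases
(all-N bins are flagged missing); mappability defaults to 1.0 and is
otherwise resampled from a bedGraph by length-weighted mean; effective
fragment length is the number of bases of the bin inside the union of
fragment-end windows — a per-bin proxy for restriction-fragment-length
bias, since window-restricted counting makes a fragment's expected count
depend on how much window it offers. Bins where any covariate is ≤ 0 are
masked for all log-linear models.

## Read-pair taxonomy and the MML

The classifier is a total function over loadable pairs (pairs with both
mates unmapped are dropped at load, with a count). With `d(side)` the
distance from a mate's 5′ position to the cut site downstream in its read
orientation (fragment right boundary for `+`, left boundary for `-`):

| geometry                 | condition                  | class              |
|--------------------------|----------------------------|--------------------|
| one mate unmapped        | —                          | single_sided       |
| same fragment            | inward                     | dangling_end       |
| same fragment            | outward                    | self_circle        |
| same fragment            | same strand                | other              |
| different fragments      | inward, span ≤ MML         | extra_dangling_end |
| different fragments      | d(1) ≤ MML and d(2) ≤ MML  | valid_pair         |
| different fragments      | otherwise                  | other              |

The span of an inward pair runs from the leftmost mate's 5′ start to the
rightmost mate's 3′ end (5′ + read length); a pair whose mates map to the
same position on opposite strands is treated as a degenerate inward pair
of span = read length. In 3C-seq mode any inward cis pair of span ≤ MML
is labelled `genomic` first — without biotin enrichment such inserts are
ordinary WGS-like fragments regardless of fragment co-membership — and
only the remainder goes through the table above.

**MML estimation** uses the artifact population identifiable *without*
knowing the MML: inward pairs on the same or adjacent fragments (the
dangling-end / extra-dangling-end inserts). The MML is the smallest
multiple of 100 bp strictly greater than the nearest-rank 99th percentile
of their spans — nearest rank (no interpolation), strict inequality, and
rounding up to hundreds are each deliberate. At least 100 candidate pairs
are required; otherwise the caller must pass an explicit MML. The read
length is taken from configuration; it is not inferred from the data.

## Read-depth signal

*Entire-fragment counting* (Hi-C): each retained read side whose 5′
position falls in a fragment-end window increments that window; a
fragment's count is the sum over its windows; the count is assigned to
every base of the fragment, and the per-bin RD value is the arithmetic
mean of per-base values (terminal bins average over covered bases only).
Means rather than sums keep the RD in reads-per-base and invariant to bin
size. Valid pairs contribute both sides; every other pair contributes a
single count placed at its first mapped side — a non-informative pair is
one physical molecule from one fragment, and counting both of its sides
would double-weight artifacts relative to ligation products. Sides
falling outside every window are simply not counted (the retention rule).
With `use_all_reads=False` only valid pairs are counted; this exists for
comparison, not as the default. Two further comparison baselines are
available behind `rd_baseline(mode=...)` — assigning each retained read
to its fragment's midpoint, or to its exact 5′ coordinate — both of which
concentrate counts on single positions and produce a sparser, noisier
signal than entire-fragment counting; they are provided for benchmarking
only.

*Genomic-pair pileup* (3C-seq): each genomic pair adds 1 to every base of
its insert span; per-bin value is the mean per-base coverage.

Both routes are tested for exact equality against literal per-base
oracles on ≤ 100-kb toys.

**RD bias correction** (on by default before CNV calling): a log-link
Poisson regression of the binned RD on log-GC, log-mappability and
log-effective-length over unmasked bins, followed by median-ratio
rescaling (`corrected = raw · median(fitted)/fitted`), which removes the
multiplicative trend while preserving the overall level. This mirrors the
explicit GLM philosophy of the contact-map model. The per-bin effective
length only partially captures fragment-length variation *within* a bin,
so window-count RD retains more dispersion than a WGS pileup would — one
reason the CNV-recovery tests drive the caller with bin-level RD
simulations rather than window counts.

## Copy-number calling

**Reference estimation.** Peaks are local maxima of a Gaussian KDE
(Scott bandwidth) of the positive unmasked RD values, kept if their
density exceeds 5% of the maximum; at least 500 unmasked bins are
required. Peak weights are mass fractions (share of bins nearest each
peak). Candidate grid spacings `u = peak/k` (k = 1…8) are refined by
weighted least squares and scored by the weighted squared deviation of
`peak/u` from integers. Among grids fitting within tolerance (0.01), the
one whose weight-averaged copy number is closest to `ploidy_hint` wins;
near-ties (within 0.2 copies — e.g. the {1,2} vs {2,4} readings of a
two-level genome) are resolved by the modal peak's distance to the hint,
then by the coarsest grid, so {2,4} beats {3,6}. The reference is
`reference_rd = 2·u`, and per-bin copy number is `2·rd/reference_rd`.
The hint (default 2, set 4 for hypotetraploid lines) resolves a genuine
ambiguity: any grid that fits at spacing u also fits at u/2. When the
modal state occupies less than about two-thirds of the genome the
karyotype reading can remain ambiguous under any rule of this form.

**Large segments.** Change-points minimize squared error with penalty
`3·σ̂²·log n` (PELT-style pruned dynamic programming), where σ̂ is a
MAD-based noise estimate from first differences. Segments shorter than
`min_lcv_size` (default 1 Mb — the conventional boundary between
segmental aneuploidy and focal events) are merged into the neighbour with
the nearest mean; states are the rounded segment means and equal-state
neighbours merge. Masked bins are bridged by interpolation so they cannot
spawn spurious change-points. Segments with state ≠ 2 are LCVs.

**Focal alterations.** Within each segment, maximal single-direction runs
of bins deviating from the segment state by more than
`max(0.5, z_{1−α/2}·σ̂_MAD)` (α = 0.05) and spanning ≥ `min_fa_size`
(default 10 kb = 2 bins) are emitted, with the run's mean CN.

**CNV track.** Per-bin `w` = segment state, overridden by FA copy number
inside FA intervals, floored at 0.5 so `log w` stays finite for
homozygous deletions entering the GLM. Overlapping FAs are an error.

`CopyNumberCaller` packages these stages as a scikit-learn estimator
(`fit` on an `RDProfile`, fitted attributes `distribution_fit_`,
`segments_`, `lcvs_`, `focal_alterations_`, `cnv_track_`); every stage is
also callable as a plain function.

## Contact-map normalization

Counts f_kl are Poisson with
`log λ = α0 + Σ_m α_m · log(feature_m,k · feature_m,l)` over the four
covariates (GC, mappability, effective length, CNV). Fitting is
maximum-likelihood IRLS (statsmodels GLM) with deviance tolerance 1e−8
and ≤ 100 iterations. Only upper-triangle cis cells enter the fit (to
avoid double-weighting symmetric cells); zero cells are retained (the
Poisson likelihood handles them); pairs touching masked bins or any
non-positive covariate are excluded and stay missing in the normalized
map. By default one coefficient vector is pooled over all cis matrices
and one over all trans matrices — genome-wide pooling conditions the fit
far better than per-chromosome fits; per-chromosome scope is available.
The normalized map is `f̂ = f/λ̂`, symmetric whenever the input is.

Genomic distance is deliberately **not** a covariate: `f̂` is a
bias-corrected map, not an observed-over-expected distance-normalized
map. Consequently, when simulations add a power-law distance decay to the
rates, normalization still reduces 1D-signal dispersion but the residual
decay structure remains — and the raw-vs-normalized 1D rank correlation
is only guaranteed non-negative when the simulated biases are purely
multiplicative in the modelled covariates.

Matrices default to 500-kb bins; the 5-kb feature and CNV tracks are
aggregated to matrix bins by length-weighted mean before pairing, keeping
a single source of truth (the constant scale factor this introduces in
effective length is absorbed by the intercept).

## Diagnostics

- CS = Σ W_i·[|S_i − CN_i| ≤ 0.25] / Σ W_i with S_i the nearest
  nonnegative integer state and W_i the bin size; the 0.25 boundary is
  inclusive. ZS (fraction of bins with CN exactly 0) is unweighted.
- The 1D signal is the column sum of a matrix, skipping missing cells;
  dispersion is the sample (n−1) standard deviation per chromosome.
- Bias–frequency correlation pairs each included upper-triangle cell
  f_kl with the product `feature_k · feature_l`, matching the GLM's
  product-form predictors; a constant feature returns NaN with a warning.
  Genome-wide values pool all chromosomes' cells; per-chromosome values
  are reported alongside.

## Synthetic data

The simulator provides the closed loop for every stage: genomes with
motif instances planted at exponential spacings (accidental occurrences
are scrubbed so the digest recovers exactly the planted sites; with
`mean_fragment=None` a pure i.i.d. sequence is returned, where a 6-bp
cutter cuts every 4⁶ = 4096 bp on average); piecewise-constant CNV
truths; read pairs drawn per class according to the classifier's own rule
table, with loci sampled linearly in copy number (the minimal model
consistent with capture probability scaling with template abundance, no
overdispersion); and contact counts drawn Poisson around the GLM rate
form, optionally multiplied by `(|k−l|+1)^(−decay)` — a deliberate
misspecification absent from the fitted model, so decorrelation tests are
honest about what the model does not capture.

What the simulations do *not* emulate: sequencing error, chimeric reads,
PCR duplicates, mappability structure of real genomes, translocations,
and subclonal (non-integer) copy number. Passing tests therefore
demonstrate correctness of the algorithms under their stated model, not
robustness to every artifact of real libraries.

### Problem sizes

Defaults in tests and the acceptance script: 10-Mb genomes for
fragment-length statistics; ≤ 100-kb toys for exact counting oracles;
300-bin matrices over 20 seeds for GLM coefficient recovery; 200–250-bin
matrices at a mean depth of ~20 contacts per cell (typical for 500-kb cis
maps; much sparser maps leave a rank-tie artifact of ~0.05 in Spearman
correlations against planted biases) for decorrelation and dispersion
checks; and 1200-bin RD profiles with 0.2-copy noise over 20 seeds (15
near-diploid, 5 hypotetraploid with a ≥ two-thirds tetraploid backbone)
for CNV recovery.

## Known limitations

- Single-enzyme digests only; palindromic motifs only.
- Duplicate removal and MAPQ filtering are upstream concerns; the loader
  takes mapped-pair tables as given.
- The FA thresholding is a robust-dispersion rule, not a segmentation of
  its own; FAs narrower than two bins at the working resolution are
  invisible by construction.
- Per-chromosome GLM scope is available but unvalidated on small
  chromosomes, where the fit can be poorly conditioned.
- The pipeline caches the RD track (written at full precision, so resumed
  runs are byte-identical); classification is recomputed on resume.
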