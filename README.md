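# aneuhic

Copy-number-aware read-depth analysis and explicit contact-map
normalization for Hi-C and 3C-seq data of karyotypically abnormal (e.g.
cancer) cell lines.

## The problem

Most Hi-C normalization methods assume all genomic bins should be equally
visible. Cancer genomes violate that assumption: amplified regions are
over-represented and deleted regions under-represented in the ligation
library, so copy-number variation (CNV) leaves block artifacts in the
contact map and biases every downstream analysis (TADs, compartments,
loops). Correcting this requires (1) an accurate copy-number profile —
ideally extracted from the Hi-C reads themselves — and (2) a normalization
model in which copy number is an explicit covariate rather than something
a matrix-balancing scheme silently over-compensates.

`aneuhic` implements the full chain:

1. **Entire-fragment read-depth (RD) signal.** Reads whose 5′ ends fall in
   *fragment-end windows* (a region of maximum molecule length, MML,
   adjacent to each restriction cut) are counted per restriction fragment;
   the fragment count is assigned to every base of the fragment and
   averaged into bins (default 5 kb). All read classes contribute — valid
   pairs count both sides, every other (non-informative) pair counts once
   — which raises the resolution of the RD signal well beyond what valid
   pairs alone provide. For 3C-seq data, where most pairs are ordinary
   genomic inserts, the RD signal is a WGS-like fragment pileup instead.
2. **Hierarchical CNV calling.** The RD histogram of an aneuploid genome
   is multimodal — one mode per populated integer copy-number state. Modes
   of a kernel-density estimate are fit to an integer grid, anchoring the
   copy-number reference (CN = 2); penalized least-squares change-point
   segmentation then calls Mb-scale large copy-number variations (LCVs),
   and coverage thresholding inside each segment calls focal
   amplifications/deletions (FAs). LCVs and FAs merge into the per-bin
   copy-number track *w*.
3. **Explicit Poisson GLM normalization.** Contact counts f_kl between
   bins k and l are modelled as Poisson with

       log λ_kl = α0 + α1·log(x_k·x_l) + α2·log(y_k·y_l)
                     + α3·log(z_k·z_l) + α4·log(w_k·w_l)

   where x, y, z, w are per-bin GC content, mappability, effective
   fragment length (bases inside fragment-end windows) and copy number.
   The normalized map is f̂ = f / λ̂. Cis and trans maps get separate
   fits, pooled genome-wide by default. All biases, including CNV, are
   estimated *simultaneously* — nothing is divided out in a second pass.

Two diagnostics quantify the results: the **centralization score** (CS,
size-weighted fraction of bins within 0.25 copies of an integer state)
and **zero score** (ZS, fraction of empty bins) for RD quality, and the
per-chromosome standard deviation of the contact map's 1D signal (column
sums) plus Spearman correlations between contact frequencies and each
bias product for normalization quality.

## Worked example

```python
import numpy as np
from aneuhic import (CopyNumberCaller, PoissonBiasModel, RDProfile,
                     bias_correlation, one_d_signal, pairwise_design,
                     signal_dispersion)
from aneuhic.simulate import simulate_contact_counts

# --- call copy number from a noisy read-depth profile -----------------
rng = np.random.default_rng(0)
states = np.r_[np.full(500, 2.0), np.full(300, 4.0), np.full(400, 2.0)]
rd = RDProfile("chr1", 5000, 40.0 * states + rng.normal(0, 8.0, 1200))
caller = CopyNumberCaller(min_lcv_size=5e5).fit(rd)
print(f"CN reference RD : {caller.distribution_fit_.reference_rd:.1f}")
for seg in caller.segments_:
    print(f"segment {seg.start//1000:>5}-{seg.end//1000:>5} kb  CN={seg.state}  ({seg.cls})")

# --- normalize a contact map carrying the CNV bias --------------------
features = {"gc": rng.uniform(0.3, 0.6, 240), "mappability": np.ones(240),
            "effective_length": rng.uniform(0.2, 1.0, 240),
            "cnv": np.repeat([2.0, 4.0, 2.0], [100, 60, 80])}
mat, _ = simulate_contact_counts(features, [2.0, 0.4, 0.0, -0.5, 0.9], seed=1)
design = pairwise_design(features)
model = PoissonBiasModel(kind="cis").fit([mat], [design])
norm = model.transform(mat, *design)
print(f"fitted coefficients a0..a4 : {np.round(model.coef_, 3)}")
print(f"CNV bias correlation  raw : {bias_correlation(mat, features['cnv']):.3f}"
      f"  normalized : {bias_correlation(norm, features['cnv']):.3f}")
print(f"1D-signal SD          raw : {signal_dispersion(one_d_signal(mat)):.1f}"
      f"  normalized : {signal_dispersion(one_d_signal(norm)):.2f}")
```

prints

```
CN reference RD : 79.8
segment     0- 2500 kb  CN=2  (neutral)
segment  2500- 4000 kb  CN=4  (LCV)
segment  4000- 6000 kb  CN=2  (neutral)
fitted coefficients a0..a4 : [ 1.995  0.4    0.    -0.501  0.901]
CNV bias correlation  raw : 0.664  normalized : 0.008
1D-signal SD          raw : 3431.9  normalized : 2.92
```

The caller recovers the planted tetraploid segment and the CN reference
(truth: RD 80 per two copies); the GLM recovers the planted coefficients
(0.4, 0, −0.5, 0.9), and normalization removes the CNV–contact
correlation (0.66 → 0.01) while collapsing the 1D-signal dispersion.

## Command line

The `aneuhic` entry point wraps the library for end-to-end runs driven by
a YAML config (`aneuhic run-all config.yaml`), with subcommands `digest`,
`classify`, `simulate` and `evaluate` for the individual stages. A run
emits the read-class summary, RD bedGraph, CNV bedGraph + LCV/FA BED
files, raw and normalized matrix triplets, GLM coefficients, a score
report and a log, deterministically for a given config.

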