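"""Binned read-depth (RD) signal computation and bias correction.

Two routes produce the RD signal:

* **Entire-fragment counting** (Hi-C): read 5' ends falling inside
  fragment-end windows are counted per window; a fragment's count is the
  sum over its windows; that count is assigned to every base of the
  fragment and averaged per bin.  Valid pairs contribute both sides; every
  other (non-informative) read pair contributes a single count.
* **Genomic-pair pileup** (3C-seq): each genomic pair adds one to every
  base of its insert span, like ordinary WGS paired-end coverage.

RD units are reads per base, so the signal is invariant to bin size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .restriction import BinFeatureTrack, FragmentEndWindow, RestrictionMap, n_bins

__all__ = [
    "RDProfile",
    "count_window_reads",
    "fragment_counts",
    "rd_from_fragment_counts",
    "rd_from_genomic_pairs",
    "correct_rd_signal",
]

#: classes whose reads contribute to the RD signal alongside valid pairs
NON_INFORMATIVE = ("dangling_end", "extra_dangling_end", "self_circle", "single_sided")


@dataclass
class RDProfile:
    """Binned read-depth signal of one chromosome (default 5-kb bins)."""

    chromosome_name: str
    bin_size: int
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # True = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RD values must be nonnegative")
        if self.mask is None:
            self.mask = np.zeros(len(self.values), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def unmasked(self) -> np.ndarray:
        return self.values[~self.mask]


def _counted_sides(pairs, classes, use_all_reads, chromosome=None):
    """5' positions of read sides retained for entire-fragment counting.

    Valid pairs contribute side1 and side2 separately; each non-informative
    pair contributes one count, placed at its first mapped side.  With
    ``chromosome`` set, only sides mapped to that chromosome are returned.
    """

    def on_chrom(side):
        if chromosome is None:
            return pairs[f"mapped{side}"]
        return pairs[f"mapped{side}"] & (pairs[f"chrom{side}"] == chromosome)

    positions = []
    valid = classes == "valid_pair"
    for side in (1, 2):
        sel = valid & on_chrom(side)
        positions.append(pairs.loc[sel, f"pos{side}"].to_numpy())
    if use_all_reads:
        noninf = classes.isin(NON_INFORMATIVE)
        use1 = noninf & on_chrom(1)
        use2 = noninf & ~pairs["mapped1"] & on_chrom(2)
        positions.append(pairs.loc[use1, "pos1"].to_numpy())
        positions.append(pairs.loc[use2, "pos2"].to_numpy())
    return np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)


def count_window_reads(
    pairs: pd.DataFrame,
    classes: pd.Series,
    windows: list[FragmentEndWindow],
    use_all_reads: bool = True,
    chromosome: str | None = None,
) -> np.ndarray:
    """Count retained read sides falling inside each fragment-end window.

    A side whose 5' position lies in a window increments that window once;
    sides outside every window are discarded (the retention rule).  With
    ``use_all_reads=False`` only valid pairs are counted.
    """
    pos = _counted_sides(pairs, classes, use_all_reads, chromosome)
    starts = np.array([w.start for w in windows], dtype=np.int64)
    ends = np.array([w.end for w in windows], dtype=np.int64)
    order = np.argsort(starts)
    counts = np.zeros(len(windows), dtype=np.int64)
    if len(pos):
        # windows are non-overlapping within a fragment; across fragments they
        # are disjoint too, so a sorted interval lookup suffices
        idx = np.searchsorted(starts[order], pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[order][np.clip(idx, 0, None)])
        np.add.at(counts, order[idx[ok]], 1)
    return counts


def fragment_counts(
    window_counts: np.ndarray, windows: list[FragmentEndWindow], n_fragments: int
) -> np.ndarray:
    """Per-fragment count = sum of its fragment-end window counts."""
    out = np.zeros(n_fragments, dtype=np.int64)
    for c, w in zip(window_counts, windows):
        out[w.fragment_id] += c
    return out


def rd_from_fragment_counts(
    counts: np.ndarray, rmap: RestrictionMap, bin_size: int = 5000
) -> RDProfile:
    """Entire-fragment RD: assign each fragment's count to all its bases,
    then average per bin (terminal bins average over covered bases only)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    counts = np.asarray(counts, dtype=float)
    if len(counts) != rmap.n_fragments:
        raise ValueError("one count per fragment required")
    per_base = np.repeat(counts, rmap.fragment_lengths)
    return RDProfile(rmap.chromosome_name, bin_size, _bin_means(per_base, bin_size))


def _bin_means(per_base: np.ndarray, bin_size: int) -> np.ndarray:
    length = len(per_base)
    nb = n_bins(length, bin_size)
    edges = np.r_[0, np.arange(1, nb) * bin_size].astype(np.intp)
    sums = np.add.reduceat(per_base, edges)
    sizes = np.minimum(np.arange(1, nb + 1) * bin_size, length) - np.arange(nb) * bin_size
    return sums / sizes


def rd_from_genomic_pairs(
    pairs: pd.DataFrame,
    classes: pd.Series,
    chromosome_length: int,
    read_length: int,
    bin_size: int = 5000,
    chromosome_name: str = "chr",
) -> RDProfile:
    """WGS-like pileup RD from 3C-seq genomic pairs.

    Each pair adds one to every base of its insert span (leftmost 5' start
    to rightmost 3' end); per-bin value is the mean per-base coverage.
    """
    if bool((np.asarray(classes) != "genomic").any()):
        raise ValueError("rd_from_genomic_pairs accepts genomic pairs only")
    diff = np.zeros(chromosome_length + 1, dtype=float)
    if len(pairs):
        p1 = pairs["pos1"].to_numpy()
        p2 = pairs["pos2"].to_numpy()
        left = np.minimum(p1, p2)
        right = np.maximum(p1, p2) + read_length
        right = np.minimum(right, chromosome_length)
        np.add.at(diff, left, 1.0)
        np.add.at(diff, right, -1.0)
    per_base = np.cumsum(diff[:-1])
    return RDProfile(chromosome_name, bin_size, _bin_means(per_base, bin_size))


def rd_baseline(
    pairs: pd.DataFrame,
    classes: pd.Series,
    rmap: RestrictionMap,
    bin_size: int = 5000,
    mode: str = "midpoint",
    use_all_reads: bool = True,
) -> RDProfile:
    """Comparison-baseline RD signals (not the default method).

    ``mode="midpoint"`` assigns each retained read side to the midpoint of
    its restriction fragment; ``mode="exact_cut"`` assigns it to its exact
    5' coordinate.  Values are counts per base (count/bin_size), on the
    same scale as the entire-fragment signal.  These exist only as
    baselines: both concentrate counts on single coordinates and yield a
    sparser, noisier signal than entire-fragment counting.
    """
    if mode not in ("midpoint", "exact_cut"):
        raise ValueError(f"unknown baseline mode {mode!r}")
    pos = _counted_sides(pairs, classes, use_all_reads, rmap.chromosome_name)
    if mode == "midpoint":
        frag = rmap.fragment_of(pos) if len(pos) else np.empty(0, dtype=np.int64)
        pos = (rmap.fragments[frag, 0] + rmap.fragments[frag, 1]) // 2
    nb = n_bins(rmap.chromosome_length, bin_size)
    counts = np.bincount(pos // bin_size, minlength=nb).astype(float)
    return RDProfile(rmap.chromosome_name, bin_size, counts / bin_size)


def correct_rd_signal(rd: RDProfile, features: BinFeatureTrack) -> RDProfile:
    """Correct the RD signal for GC, mappability and effective-length bias.

    A log-link Poisson regression of the RD values on log-GC,
    log-mappability and log-effective-length is fit over unmasked bins;
    corrected value = raw * median(fitted) / fitted, which removes the
    multiplicative bias while preserving the overall signal level.  Bins
    with zero mappability or zero effective length are masked.
    """
    if len(features) != len(rd):
        raise ValueError("features not aligned to RD bins")
    mask = rd.mask | features.mask
    if mask.all():
        raise ValueError("all bins masked; cannot fit bias model")
    ok = ~mask
    if rd.values[ok].sum() == 0:  # empty chromosome: nothing to correct
        values = rd.values.copy()
        values[mask] = 0.0
        return RDProfile(rd.chromosome_name, rd.bin_size, values, mask)
    X = np.column_stack(
        [
            np.log(features.gc[ok]),
            np.log(features.mappability[ok]),
            np.log(features.effective_length[ok]),
        ]
    )
    X = sm.add_constant(X, has_constant="add")
    fit = sm.GLM(rd.values[ok], X, family=sm.families.Poisson()).fit()
    fitted = fit.mu
    scale = np.median(fitted) / fitted
    values = rd.values.copy()
    values[ok] = rd.values[ok] * scale
    values[mask] = 0.0
    return RDProfile(rd.chromosome_name, rd.bin_size, values, mask)
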