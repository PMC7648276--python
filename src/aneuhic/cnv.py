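"""Copy-number calling from the multimodal read-depth distribution.

Cancer genomes carry copy-number variation at two scales: Mb-scale
large-scale copy-number variations (LCVs, segmental aneuploidy) and
kb-to-Mb focal alterations (FAs).  Because sequencing coverage is
proportional to copy number, the RD-value histogram of an aneuploid genome
is multimodal, with one mode per populated integer copy-number state.  The
caller proceeds hierarchically:

1. **Copy-number reference** — peaks of a kernel-density estimate of the
   RD values are fit to an integer grid; the spacing of the grid is the RD
   increment per copy and ``reference_rd = 2 * spacing`` anchors CN = 2.
   A ploidy hint resolves the inherent grid ambiguity (a grid that fits at
   spacing u also fits at u/2).
2. **Large segments** — penalized least-squares change-point segmentation
   of the per-bin CN signal, with sub-``min_lcv_size`` segments merged into
   their nearest-mean neighbour.  Segments with integer state != 2 are LCVs.
3. **Focal alterations** — within each segment, runs of bins deviating
   from the segment state beyond ``max(0.5, z * sigma_MAD)`` and at least
   ``min_fa_size`` long are amplification/deletion FAs.

LCVs and FAs merge into the per-bin CNV track ``w`` used by the contact-map
bias GLM (floored at 0.5 so log(w) stays finite for homozygous deletions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .readdepth import RDProfile

__all__ = [
    "CopyNumberDistributionFit",
    "Segment",
    "FocalAlteration",
    "CNVTrack",
    "CopyNumberCaller",
    "fit_copy_number_distribution",
    "to_copy_number",
    "segment_large_events",
    "detect_focal_alterations",
    "merge_cnv_track",
]


@dataclass
class CopyNumberDistributionFit:
    peak_locations: np.ndarray  # RD values of density modes
    peak_weights: np.ndarray  # normalized density mass at each mode
    peak_states: np.ndarray  # integer CN assigned to each mode
    unit_spacing: float  # RD per copy
    reference_rd: float  # RD value anchored at CN = 2

    def __post_init__(self) -> None:
        if not np.isclose(self.reference_rd, 2.0 * self.unit_spacing):
            raise ValueError("reference_rd must equal 2 * unit_spacing")


@dataclass
class Segment:
    start: int  # bp, half-open
    end: int
    mean_cn: float
    state: int

    @property
    def cls(self) -> str:
        return "neutral" if self.state == 2 else "LCV"


@dataclass
class FocalAlteration:
    start: int  # bp, half-open
    end: int
    cn: float
    parent_state: int

    @property
    def kind(self) -> str:
        return "amplification" if self.cn > self.parent_state else "deletion"


@dataclass
class CNVTrack:
    bin_size: int
    values: np.ndarray  # per-bin copy number w > 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("CNV track values must be positive")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# copy-number reference from the multimodal RD distribution


def fit_copy_number_distribution(
    rd: RDProfile,
    ploidy_hint: int = 2,
    max_copy: int = 8,
    min_peak_frac: float = 0.05,
) -> CopyNumberDistributionFit:
    """Fit the RD histogram to an integer copy-number grid.

    Peaks are local maxima of a Gaussian KDE of the unmasked RD values
    whose density exceeds ``min_peak_frac`` of the maximum.  Candidate
    grid spacings (each peak divided by each candidate copy number) are
    scored by the weighted squared deviation of peaks from integers; among
    well-fitting grids the one whose density-weighted mean CN is closest
    to ``ploidy_hint`` wins.
    """
    values = rd.unmasked
    values = values[np.isfinite(values) & (values > 0)]
    if len(values) < 500:
        raise ValueError(f"need >= 500 unmasked bins to fit the RD distribution, got {len(values)}")

    kde = stats.gaussian_kde(values)
    grid = np.linspace(0, values.max() * 1.1, 2048)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]) & (dens[1:-1] > min_peak_frac * dens.max())
    ) + 1
    peaks = grid[interior]
    keep = peaks > 0
    peaks = peaks[keep]
    if len(peaks) == 0:
        raise ValueError("no peak found in the RD distribution")
    # mass-based peak weights: fraction of bins nearest each mode
    nearest = np.argmin(np.abs(values[:, None] - peaks[None, :]), axis=1)
    weights = np.bincount(nearest, minlength=len(peaks)).astype(float)
    weights = weights / weights.sum()
    modal = int(np.argmax(weights))

    best = None
    for p in peaks:
        for k in range(1, max_copy + 1):
            u0 = p / k
            if u0 <= 0:
                continue
            states = np.maximum(1, np.round(peaks / u0)).astype(int)
            if states.max() > 2 * max_copy:
                continue
            # refine spacing by weighted least squares on the assigned grid
            u = float(np.sum(weights * states * peaks) / np.sum(weights * states**2))
            cost = float(np.sum(weights * (peaks / u - states) ** 2))
            mean_cn = float(np.sum(weights * states))
            mode_dist = abs(int(states[modal]) - ploidy_hint)
            cand = (cost, abs(mean_cn - ploidy_hint), u, states, mode_dist)
            if best is None or _better_grid(cand, best):
                best = cand
    cost, _, unit, states, _ = best
    states = np.maximum(1, np.round(peaks / unit)).astype(int)
    return CopyNumberDistributionFit(
        peak_locations=peaks,
        peak_weights=weights,
        peak_states=states,
        unit_spacing=unit,
        reference_rd=2.0 * unit,
    )


def _better_grid(cand, best, tol: float = 0.01, margin: float = 0.2) -> bool:
    """Prefer well-fitting grids; choose among them by the ploidy hint.

    The primary rule is the distance of the weight-averaged CN from the
    hint; when two grids are within ``margin`` of each other (a balanced
    aneuploid genome makes e.g. {1,2} and {2,4} nearly equidistant), the
    near-tie is resolved by the modal peak's state distance to the hint,
    then by the coarsest grid (largest spacing), so {2,4} beats {3,6}.
    """
    cost_c, hint_c, u_c, _, mode_c = cand
    cost_b, hint_b, u_b, _, mode_b = best
    if cost_c <= tol and cost_b <= tol:
        if abs(hint_c - hint_b) > margin:
            return hint_c < hint_b
        return (mode_c, -u_c) < (mode_b, -u_b)
    return (cost_c, hint_c) < (cost_b, hint_b)


def to_copy_number(rd: RDProfile, fit: CopyNumberDistributionFit) -> np.ndarray:
    """Per-bin copy number: cn = 2 * rd / reference_rd."""
    if fit.reference_rd <= 0:
        raise ValueError("reference_rd must be positive")
    return 2.0 * rd.values / fit.reference_rd


# ---------------------------------------------------------------------------
# large-segment change-point detection


def _changepoints_pelt(x: np.ndarray, penalty: float) -> list[int]:
    """PELT-style optimal partitioning under squared-error cost."""
    n = len(x)
    cs = np.r_[0.0, np.cumsum(x)]
    cs2 = np.r_[0.0, np.cumsum(x**2)]

    def seg_cost(i, j):  # cost of x[i:j]
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / (j - i)

    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    candidates = [0]
    for t in range(1, n + 1):
        costs = np.array([F[s] + seg_cost(s, t) + penalty for s in candidates])
        k = int(np.argmin(costs))
        F[t] = costs[k]
        last[t] = candidates[k]
        # pruning: drop candidates that can never be optimal again
        candidates = [s for s, c in zip(candidates, costs) if c - penalty <= F[t]]
        candidates.append(t)
    # backtrack
    bps = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            bps.append(s)
        t = s
    return sorted(bps)


def segment_large_events(
    cn: np.ndarray,
    bin_size: int,
    min_lcv_size: float = 1e6,
    mask: np.ndarray | None = None,
    penalty: float | None = None,
) -> list[Segment]:
    """Piecewise-constant segmentation of the per-bin CN signal.

    Change-points come from penalized least squares (default penalty
    ``3 * sigma^2 * log n`` with a MAD-of-differences noise estimate);
    segments shorter than ``min_lcv_size`` are merged into the neighbour
    with the nearest mean, states are rounded to integers, and adjacent
    equal-state segments are merged.
    """
    cn = np.asarray(cn, dtype=float)
    n = len(cn)
    if mask is None:
        mask = ~np.isfinite(cn)
    work = cn.copy()
    if mask.any():  # masked bins take the running signal level, not zero
        ok = ~mask
        if not ok.any():
            raise ValueError("all bins masked")
        work[mask] = np.interp(np.flatnonzero(mask), np.flatnonzero(ok), cn[ok])

    if penalty is None:
        d = np.diff(work)
        sigma = stats.median_abs_deviation(d, scale="normal") / np.sqrt(2) if len(d) else 0.0
        sigma = max(sigma, 1e-3)
        penalty = 3.0 * sigma**2 * np.log(max(n, 2))

    bps = _changepoints_pelt(work, penalty)
    bounds = [0, *bps, n]
    means = [work[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]

    # merge sub-minimum segments into the neighbour with the nearest mean
    min_bins = max(1, int(round(min_lcv_size / bin_size)))
    segs = [[a, b, m] for a, b, m in zip(bounds[:-1], bounds[1:], means)]
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i, (a, b, m) in enumerate(segs):
            if b - a >= min_bins:
                continue
            neighbours = []
            if i > 0:
                neighbours.append((abs(segs[i - 1][2] - m), i - 1))
            if i < len(segs) - 1:
                neighbours.append((abs(segs[i + 1][2] - m), i + 1))
            _, j = min(neighbours)
            lo, hi = (j, i) if j < i else (i, j)
            a2, b2 = segs[lo][0], segs[hi][1]
            segs[lo] = [a2, b2, work[a2:b2].mean()]
            del segs[hi]
            changed = True
            break

    # round to integer states and merge equal-state neighbours
    out: list[Segment] = []
    for a, b, m in segs:
        state = max(0, int(round(m)))
        if out and out[-1].state == state:
            prev = out[-1]
            a0 = prev.start // bin_size
            merged_mean = work[a0:b].mean()
            out[-1] = Segment(prev.start, b * bin_size, merged_mean, state)
        else:
            out.append(Segment(a * bin_size, b * bin_size, m, state))
    return out


# ---------------------------------------------------------------------------
# focal alterations


def detect_focal_alterations(
    cn: np.ndarray,
    segments: list[Segment],
    bin_size: int,
    min_fa_size: float = 10e3,
    alpha: float = 0.05,
    mask: np.ndarray | None = None,
) -> list[FocalAlteration]:
    """Coverage-thresholded focal amplifications/deletions inside segments.

    Within each segment, maximal runs of consecutive bins deviating from
    the segment state by more than ``max(0.5, z_{1-alpha/2} * sigma_MAD)``
    (all in the same direction) and spanning at least ``min_fa_size`` are
    emitted, with cn = mean CN of the run.
    """
    cn = np.asarray(cn, dtype=float)
    if mask is None:
        mask = ~np.isfinite(cn)
    z = stats.norm.ppf(1 - alpha / 2)
    min_bins = max(1, int(np.ceil(min_fa_size / bin_size)))
    out: list[FocalAlteration] = []
    for seg in segments:
        a, b = seg.start // bin_size, seg.end // bin_size
        vals = cn[a:b]
        ok = ~mask[a:b]
        if ok.sum() < 2:
            continue
        sigma = stats.median_abs_deviation(vals[ok], scale="normal")
        thr = max(0.5, z * sigma)
        dev = np.where(ok, vals - seg.state, 0.0)
        direction = np.where(dev > thr, 1, np.where(dev < -thr, -1, 0))
        i = 0
        while i < len(direction):
            if direction[i] == 0:
                i += 1
                continue
            j = i
            while j < len(direction) and direction[j] == direction[i]:
                j += 1
            if j - i >= min_bins:
                run = vals[i:j][ok[i:j]]
                out.append(
                    FocalAlteration(
                        start=(a + i) * bin_size,
                        end=(a + j) * bin_size,
                        cn=float(run.mean()),
                        parent_state=seg.state,
                    )
                )
            i = j
    return out


def merge_cnv_track(
    segments: list[Segment],
    fas: list[FocalAlteration],
    bin_size: int,
    n_bins: int,
    floor: float = 0.5,
) -> CNVTrack:
    """Merge LCV segment states and FA copy numbers into the per-bin track.

    FA copy numbers override their parent segment's state; values below
    ``floor`` are clipped so the bias GLM can take log(w).
    """
    values = np.full(n_bins, 2.0)
    for seg in segments:
        values[seg.start // bin_size : -(-seg.end // bin_size)] = seg.state
    spans = sorted((fa.start, fa.end) for fa in fas)
    for (s1, e1), (s2, _) in zip(spans[:-1], spans[1:]):
        if s2 < e1:
            raise ValueError("overlapping focal alterations")
    for fa in fas:
        values[fa.start // bin_size : -(-fa.end // bin_size)] = fa.cn
    return CNVTrack(bin_size, np.maximum(values, floor))


# ---------------------------------------------------------------------------
# estimator facade


class CopyNumberCaller(BaseEstimator):
    """Hierarchical copy-number caller over a binned read-depth profile.

    Scikit-learn-style estimator: ``fit(rd_profile)`` runs reference
    estimation, large-segment detection and focal-alteration detection,
    exposing the results as fitted attributes.

    Parameters
    ----------
    ploidy_hint:
        Expected overall ploidy used to resolve the copy-number grid
        ambiguity (2 for near-diploid, 4 for hypotetraploid lines).
    min_lcv_size:
        Minimum span (bp) of a large-scale copy-number segment; shorter
        events are left to the focal-alteration stage.  Default 1 Mb.
    min_fa_size:
        Minimum span (bp) of a focal alteration.  Default 10 kb.
    alpha:
        Two-sided significance level of the FA deviation threshold.
    cn_floor:
        Lower clip for the exported CNV track (keeps log(w) finite).

    Attributes
    ----------
    distribution_fit_ : CopyNumberDistributionFit
    copy_number_ : per-bin CN signal (2 * rd / reference_rd)
    segments_ : list[Segment]
    lcvs_ : segments with state != 2
    focal_alterations_ : list[FocalAlteration]
    cnv_track_ : CNVTrack
    """

    def __init__(
        self,
        ploidy_hint: int = 2,
        min_lcv_size: float = 1e6,
        min_fa_size: float = 10e3,
        alpha: float = 0.05,
        cn_floor: float = 0.5,
    ):
        self.ploidy_hint = ploidy_hint
        self.min_lcv_size = min_lcv_size
        self.min_fa_size = min_fa_size
        self.alpha = alpha
        self.cn_floor = cn_floor

    def fit(self, rd: RDProfile, y=None):
        self.distribution_fit_ = fit_copy_number_distribution(rd, ploidy_hint=self.ploidy_hint)
        self.copy_number_ = to_copy_number(rd, self.distribution_fit_)
        self.segments_ = segment_large_events(
            self.copy_number_, rd.bin_size, min_lcv_size=self.min_lcv_size, mask=rd.mask
        )
        self.lcvs_ = [s for s in self.segments_ if s.cls == "LCV"]
        self.focal_alterations_ = detect_focal_alterations(
            self.copy_number_,
            self.segments_,
            rd.bin_size,
            min_fa_size=self.min_fa_size,
            alpha=self.alpha,
            mask=rd.mask,
        )
        self.cnv_track_ = merge_cnv_track(
            self.segments_,
            self.focal_alterations_,
            rd.bin_size,
            len(rd),
            floor=self.cn_floor,
        )
        return self

    def predict(self, rd: RDProfile) -> np.ndarray:
        """Per-bin CN of a new profile under the fitted reference."""
        return to_copy_number(rd, self.distribution_fit_)
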