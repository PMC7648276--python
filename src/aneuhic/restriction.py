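"""In-silico restriction digestion and per-bin feature tracks.

A reference chromosome is digested into an ordered set of restriction
fragments by scanning the forward strand for a (palindromic) enzyme motif,
e.g. HindIII ``A^AGCTT`` with a cut one base into the motif.  Fragment-end
windows of length MML (maximum molecule length) adjacent to each cut site
define where sequencing reads are retained for read-depth computation, and
three per-bin covariates of the contact-map bias model are derived here:
GC content, mappability and effective fragment length (the number of bases
of a bin lying inside fragment-end windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RestrictionMap",
    "FragmentEndWindow",
    "BinFeatureTrack",
    "digest_genome",
    "build_fragment_end_windows",
    "gc_track",
    "effective_length_track",
    "load_mappability",
    "n_bins",
]

_VALID_MOTIF_BASES = set("ACGT")


def n_bins(chromosome_length: int, bin_size: int) -> int:
    """Number of bins tiling ``[0, chromosome_length)`` at ``bin_size``."""
    return -(-int(chromosome_length) // int(bin_size))


@dataclass(frozen=True)
class FragmentEndWindow:
    """A window adjacent to a restriction cut where reads are retained.

    ``side`` is ``"left"``/``"right"`` for the two MML-length windows of a
    long fragment, or ``"whole"`` for a fragment shorter than 2x MML, which
    gets a single window covering it entirely (so no base is double-counted).
    """

    fragment_id: int
    side: str  # left | right | whole
    start: int
    end: int  # 0-based, half-open

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "whole"):
            raise ValueError(f"invalid window side {self.side!r}")
        if self.end <= self.start:
            raise ValueError("empty fragment-end window")


@dataclass
class RestrictionMap:
    """Ordered restriction fragments of one chromosome.

    Fragments tile ``[0, chromosome_length)`` with no gaps or overlaps;
    internal boundaries sit at ``cut_site + cut_offset`` positions.
    """

    chromosome_name: str
    chromosome_length: int
    fragments: np.ndarray  # (n, 2) int array of half-open intervals
    cut_sites: np.ndarray  # cut positions (already offset), strictly inside
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        self.fragments = np.asarray(self.fragments, dtype=np.int64).reshape(-1, 2)
        self.cut_sites = np.asarray(self.cut_sites, dtype=np.int64)
        starts, ends = self.fragments[:, 0], self.fragments[:, 1]
        if starts[0] != 0 or ends[-1] != self.chromosome_length:
            raise ValueError("fragments do not span the chromosome")
        if np.any(ends[:-1] != starts[1:]) or np.any(ends <= starts):
            raise ValueError("fragments must tile without gaps or overlaps")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def fragment_lengths(self) -> np.ndarray:
        return self.fragments[:, 1] - self.fragments[:, 0]

    def fragment_of(self, positions) -> np.ndarray:
        """Fragment index containing each 0-based position (vectorized)."""
        pos = np.asarray(positions, dtype=np.int64)
        if np.any((pos < 0) | (pos >= self.chromosome_length)):
            raise ValueError("position outside chromosome")
        return np.searchsorted(self.fragments[:, 1], pos, side="right")


def digest_genome(sequence: str, motif: str, cut_offset: int) -> RestrictionMap:
    """Digest ``sequence`` at every forward-strand occurrence of ``motif``.

    Each occurrence starting at position ``s`` yields one cut at
    ``s + cut_offset``.  Only palindromic (reverse-complement-invariant)
    motifs are accepted, so a forward scan finds every site.

    Parameters
    ----------
    sequence:
        Chromosome sequence (case-insensitive; ``N`` allowed).
    motif:
        Recognition sequence, e.g. ``"AAGCTT"`` for HindIII.
    cut_offset:
        Cut position within the motif, ``0 <= cut_offset <= len(motif)``
        (HindIII ``A^AGCTT`` -> 1).
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not motif:
        raise ValueError("empty motif")
    motif = motif.upper()
    if not set(motif) <= _VALID_MOTIF_BASES:
        raise ValueError(f"ambiguous bases in motif {motif!r}")
    if not 0 <= cut_offset <= len(motif):
        raise ValueError("cut_offset outside motif")
    if motif != _revcomp(motif):
        raise ValueError(f"non-palindromic motif {motif!r} not supported")

    seq = sequence.upper()
    length = len(seq)
    cuts = []
    start = seq.find(motif)
    while start != -1:
        cut = start + cut_offset
        if 0 < cut < length:  # cuts at the ends would create empty fragments
            cuts.append(cut)
        start = seq.find(motif, start + 1)  # overlapping occurrences allowed
    cuts = np.unique(np.asarray(cuts, dtype=np.int64))

    boundaries = np.concatenate(([0], cuts, [length]))
    fragments = np.column_stack((boundaries[:-1], boundaries[1:]))
    return RestrictionMap(
        chromosome_name="chr",
        chromosome_length=length,
        fragments=fragments,
        cut_sites=cuts,
        motif=motif,
        cut_offset=cut_offset,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def build_fragment_end_windows(rmap: RestrictionMap, mml: int) -> list[FragmentEndWindow]:
    """Fragment-end windows of length ``mml`` at both ends of each fragment.

    Fragments shorter than ``2 * mml`` yield a single whole-fragment window,
    so no base belongs to two windows of the same fragment.
    """
    if mml <= 0:
        raise ValueError("mml must be positive")
    windows: list[FragmentEndWindow] = []
    for i, (start, end) in enumerate(rmap.fragments):
        start, end = int(start), int(end)
        if end - start < 2 * mml:
            windows.append(FragmentEndWindow(i, "whole", start, end))
        else:
            windows.append(FragmentEndWindow(i, "left", start, start + mml))
            windows.append(FragmentEndWindow(i, "right", end - mml, end))
    return windows


@dataclass
class BinFeatureTrack:
    """Per-bin GC content, mappability and effective fragment length.

    These are the sample-independent covariates ``x`` (GC), ``y``
    (mappability) and ``z`` (effective length, in bp) of the bias GLM.
    ``mask`` flags bins unusable for model fitting (all-N sequence,
    zero mappability or zero effective length).
    """

    bin_size: int
    gc: np.ndarray
    mappability: np.ndarray
    effective_length: np.ndarray
    mask: np.ndarray = field(default=None)  # True = missing / excluded

    def __post_init__(self) -> None:
        self.gc = np.asarray(self.gc, dtype=float)
        self.mappability = np.asarray(self.mappability, dtype=float)
        self.effective_length = np.asarray(self.effective_length, dtype=float)
        if not (len(self.gc) == len(self.mappability) == len(self.effective_length)):
            raise ValueError("feature tracks must have equal length")
        if np.any(self.effective_length > self.bin_size):
            raise ValueError("effective length exceeds bin size")
        # log-model covariates: any nonpositive factor makes the bin unusable
        base = (
            ~np.isfinite(self.gc)
            | (self.gc <= 0)
            | (self.mappability <= 0)
            | (self.effective_length <= 0)
        )
        if self.mask is None:
            self.mask = base
        else:
            self.mask = np.asarray(self.mask, dtype=bool) | base

    def __len__(self) -> int:
        return len(self.gc)


def gc_track(sequence: str, bin_size: int) -> np.ndarray:
    """Per-bin GC fraction, counting G/C over non-N bases.

    All-N bins are returned as NaN (flagged missing downstream).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    seq = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    is_gc = (seq == ord("G")) | (seq == ord("C"))
    is_n = seq == ord("N")
    nb = n_bins(len(seq), bin_size)
    edges = np.arange(1, nb) * bin_size
    gc_counts = np.add.reduceat(is_gc, np.r_[0, edges].astype(np.intp))
    valid = np.add.reduceat(~is_n, np.r_[0, edges].astype(np.intp))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = gc_counts / valid
    out[valid == 0] = np.nan
    return out


def effective_length_track(
    windows: list[FragmentEndWindow], bin_size: int, chromosome_length: int
) -> np.ndarray:
    """Bases of each bin covered by the union of fragment-end windows."""
    nb = n_bins(chromosome_length, bin_size)
    out = np.zeros(nb, dtype=float)
    for w in windows:
        b0 = w.start // bin_size
        b1 = (w.end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(w.start, b * bin_size)
            hi = min(w.end, (b + 1) * bin_size, chromosome_length)
            if hi > lo:
                out[b] += hi - lo
    return out


def load_mappability(
    source,
    bin_size: int,
    chromosome_length: int,
    chromosome_name: str | None = None,
) -> np.ndarray:
    """Per-bin mappability, resampled by length-weighted mean.

    ``source`` may be None (returns all-ones), a path to a bedGraph file, or
    an iterable of ``(start, end, value)`` intervals in bp.  Uncovered bases
    count as mappability 1.0.  Values outside [0, 1] are rejected.
    """
    nb = n_bins(chromosome_length, bin_size)
    if source is None:
        return np.ones(nb, dtype=float)

    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        intervals = _read_bedgraph_intervals(source, chromosome_name)
    else:
        intervals = [(int(s), int(e), float(v)) for s, e, v in source]

    covered = np.zeros(chromosome_length, dtype=float)
    value = np.ones(chromosome_length, dtype=float)
    for start, end, val in intervals:
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"mappability value {val} outside [0, 1]")
        start = max(0, start)
        end = min(chromosome_length, end)
        if end > start:
            value[start:end] = val
            covered[start:end] = 1.0
    edges = np.r_[0, np.arange(1, nb) * bin_size].astype(np.intp)
    sums = np.add.reduceat(value, edges)
    # terminal bin may be short: divide by actual bases per bin
    sizes = np.minimum(np.arange(1, nb + 1) * bin_size, chromosome_length) - np.arange(nb) * bin_size
    return sums / sizes


def _read_bedgraph_intervals(path, chromosome_name):
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, val = line.split()[:4]
            if chromosome_name is not None and chrom != chromosome_name:
                continue
            intervals.append((int(start), int(end), float(val)))
    return intervals
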