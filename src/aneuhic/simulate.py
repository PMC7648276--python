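"""Synthetic genomes, read pairs, CNV profiles and contact matrices.

Every generator is deterministic given its seed and records enough truth
(planted restriction sites, class labels, integer copy numbers, GLM
coefficients, Poisson rates) for closed-loop testing of the rest of the
package: the read classifier must reproduce planted class labels exactly,
the CNV caller must recover planted breakpoints and states, and the bias
GLM must recover planted coefficients.

The simulation model is deliberately minimal and mirrors the assumptions
of the inference code it exercises: coverage is linear in copy number,
contact counts are Poisson around a log-linear rate in the pairwise
feature products, and an optional power-law distance decay can be added
to the simulated rates *without* being part of the fitted model, so
decorrelation tests run under honest misspecification.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .normalization import ContactMatrix
from .cnv import CNVTrack
from .restriction import RestrictionMap

__all__ = [
    "SimulationTruth",
    "random_sequence",
    "generate_genome",
    "simulate_cnv_profile",
    "simulate_read_pairs",
    "simulate_contact_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationTruth:
    """Serializable record of everything that determines a simulation."""

    seed: int
    genome_length: int | None = None
    gc: float | None = None
    motif: str | None = None
    planted_cut_sites: list[int] = field(default_factory=list)
    cnv_segments: list[tuple[int, int, int]] = field(default_factory=list)
    class_proportions: dict[str, float] = field(default_factory=dict)
    glm_coefficients: list[float] = field(default_factory=list)
    decay_exponent: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. DNA with P(G) = P(C) = gc/2."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode()


def generate_genome(
    length: int,
    gc: float = 0.5,
    motif: str = "AAGCTT",
    mean_fragment: float | None = 4096.0,
    seed: int = 0,
) -> tuple[str, SimulationTruth]:
    """Toy chromosome with restriction sites at known positions.

    With ``mean_fragment`` set, accidental motif occurrences in the i.i.d.
    background are scrubbed (one base mutated) and motif copies are planted
    at exponential spacings of that mean, so the digest recovers exactly
    the planted sites.  With ``mean_fragment=None`` the pure i.i.d.
    sequence is returned and sites occur naturally (expected spacing
    4^|motif| on uniform DNA).
    """
    if mean_fragment is not None and mean_fragment < len(motif):
        raise ValueError("mean_fragment must be at least the motif length")
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(random_sequence(length, gc, rng).encode(), dtype=np.uint8).copy()
    truth = SimulationTruth(seed=seed, genome_length=length, gc=gc, motif=motif)
    if mean_fragment is None:
        return seq.tobytes().decode(), truth

    motif_arr = np.frombuffer(motif.encode(), dtype=np.uint8)
    m = len(motif_arr)

    # plant motif instances at exponential spacings
    planted = []
    pos = 0.0
    while True:
        pos += rng.exponential(mean_fragment)
        start = int(pos)
        if start + m > length:
            break
        planted.append(start)
    for s in planted:
        seq[s : s + m] = motif_arr

    # scrub accidental occurrences (repeat until clean: a mutation can in
    # principle create a new site overlapping another)
    planted_set = set(planted)
    while True:
        hits = _find_motif(seq, motif_arr)
        accidental = [h for h in hits if h not in planted_set]
        if not accidental:
            break
        for h in accidental:
            if any(abs(h - p) < m for p in planted_set):
                continue  # overlaps a planted copy; mutating would damage it
            j = h + m // 2
            current = seq[j]
            choices = _BASES[_BASES != current]
            seq[j] = rng.choice(choices)
        hits2 = set(_find_motif(seq, motif_arr))
        if hits2 <= planted_set | {h for h in hits if any(abs(h - p) < m for p in planted_set)}:
            break
    truth.planted_cut_sites = [int(s) for s in sorted(planted)]
    return seq.tobytes().decode(), truth


def _find_motif(seq: np.ndarray, motif: np.ndarray) -> list[int]:
    n, m = len(seq), len(motif)
    if n < m:
        return []
    hit = np.ones(n - m + 1, dtype=bool)
    for j, b in enumerate(motif):
        hit &= seq[j : n - m + 1 + j] == b
    return list(np.flatnonzero(hit))


def simulate_cnv_profile(
    n_bins: int,
    bin_size: int,
    n_segments: int = 5,
    cn_states=(1, 2, 3, 4),
    seed: int = 0,
    min_segment_bins: int = 1,
) -> tuple[CNVTrack, list[tuple[int, int, int]]]:
    """Random piecewise-constant copy-number truth.

    Returns the per-bin track and truth segments as (start_bin, end_bin,
    state) with consecutive segments forced to differ in state.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    rng = np.random.default_rng(seed)
    states = list(cn_states)
    if n_segments == 1:
        bounds = [0, n_bins]
    else:
        interior = np.sort(
            rng.choice(
                np.arange(min_segment_bins, n_bins - min_segment_bins),
                size=n_segments - 1,
                replace=False,
            )
        )
        bounds = [0, *interior.tolist(), n_bins]
    chosen = []
    for _ in range(n_segments):
        opts = [s for s in states if not chosen or s != chosen[-1]] or states
        chosen.append(int(rng.choice(opts)))
    values = np.empty(n_bins)
    segments = []
    for (a, b), s in zip(zip(bounds[:-1], bounds[1:]), chosen):
        values[a:b] = s
        segments.append((int(a), int(b), int(s)))
    return CNVTrack(bin_size, values), segments


def _cn_weighted_bins(cnv: CNVTrack | None, n_bins: int) -> np.ndarray:
    if cnv is None:
        return np.ones(n_bins) / n_bins
    w = cnv.values.astype(float)
    return w / w.sum()


def simulate_read_pairs(
    rmap: RestrictionMap,
    class_proportions: dict[str, float],
    n_pairs: int,
    mml: int,
    read_length: int = 50,
    cnv_truth: CNVTrack | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Read pairs of planted classes obeying the classifier's rule table.

    Loci are sampled proportionally to local copy number (coverage linear
    in CN).  Returns the pair table and the planted class labels; running
    the classifier with the same restriction map and MML reproduces the
    labels exactly (``genomic`` pairs only under ``mode="c3seq"``).
    """
    if abs(sum(class_proportions.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    rng = np.random.default_rng(seed)
    chrom = rmap.chromosome_name
    L = rmap.chromosome_length
    frag = rmap.fragments
    lens = rmap.fragment_lengths

    if cnv_truth is not None:
        mid_bins = ((frag[:, 0] + frag[:, 1]) // 2) // cnv_truth.bin_size
        frag_cn = cnv_truth.values[np.clip(mid_bins, 0, len(cnv_truth) - 1)]
    else:
        frag_cn = np.ones(rmap.n_fragments)
    frag_w = lens * frag_cn
    frag_p = frag_w / frag_w.sum()

    classes = list(class_proportions)
    draws = rng.choice(len(classes), size=n_pairs, p=[class_proportions[c] for c in classes])
    records, labels = [], []

    def pick_fragment(min_len=1):
        while True:
            i = rng.choice(rmap.n_fragments, p=frag_p)
            if lens[i] >= min_len:
                return int(i)

    for d in draws:
        cls = classes[d]
        for _ in range(1000):
            rec = _make_pair(cls, rng, rmap, frag, lens, frag_p, pick_fragment, mml, read_length, L, chrom, cnv_truth)
            if rec is not None:
                break
        else:
            raise RuntimeError(f"could not place a {cls} pair; genome too small?")
        records.append(rec)
        labels.append(cls)

    df = pd.DataFrame(records, columns=["chrom1", "pos1", "strand1", "mapped1", "chrom2", "pos2", "strand2", "mapped2"])
    return df, pd.Series(labels)


def _make_pair(cls, rng, rmap, frag, lens, frag_p, pick_fragment, mml, read_length, L, chrom, cnv_truth):
    rl = read_length

    def span_draw(limit):
        lo = rl
        hi = max(rl, min(mml, limit))
        return int(rng.integers(lo, hi + 1))

    if cls == "dangling_end":
        i = pick_fragment(min_len=rl + 1)
        a, b = int(frag[i, 0]), int(frag[i, 1])
        s = span_draw(b - a)
        p1 = int(rng.integers(a, b - s + 1)) if b - a > s else a
        p2 = p1 + s - rl
        return (chrom, p1, "+", True, chrom, p2, "-", True)

    if cls == "self_circle":
        i = pick_fragment(min_len=2)
        a, b = int(frag[i, 0]), int(frag[i, 1])
        p1, p2 = sorted(rng.choice(np.arange(a, b), size=2, replace=False).tolist())
        return (chrom, int(p1), "-", True, chrom, int(p2), "+", True)

    if cls == "extra_dangling_end":
        if len(rmap.cut_sites) == 0:
            return None
        c_idx = int(rng.integers(0, len(rmap.cut_sites)))
        c = int(rmap.cut_sites[c_idx])
        len_left = lens[c_idx]
        len_right = lens[c_idx + 1]
        s = span_draw(len_left + len_right)
        if s - rl < 1:
            return None
        d1 = int(rng.integers(1, min(s - rl, len_left) + 1))
        p1 = c - d1
        p2 = p1 + s - rl
        if p2 >= int(frag[c_idx + 1, 1]):
            return None
        return (chrom, p1, "+", True, chrom, p2, "-", True)

    if cls == "valid_pair":
        for _ in range(100):
            i, j = pick_fragment(), pick_fragment()
            if i == j:
                continue
            sides = []
            for k in (i, j):
                a, b = int(frag[k, 0]), int(frag[k, 1])
                u = int(rng.integers(1, min(mml, b - a) + 1))
                if rng.random() < 0.5:
                    sides.append((b - u, "+"))  # downstream cut = fragment end
                else:
                    sides.append((a + u - 1, "-"))  # downstream cut = fragment start
            (p1, s1), (p2, s2) = sides
            # avoid geometry that reclassifies as a short inward insert
            if s1 != s2:
                left, right = (p1, p2) if p1 <= p2 else (p2, p1)
                lstr = s1 if p1 <= p2 else s2
                if (lstr == "+" or p1 == p2) and right + rl - left <= mml:
                    continue
            return (chrom, p1, s1, True, chrom, p2, s2, True)
        return None

    if cls == "single_sided":
        i = pick_fragment()
        a, b = int(frag[i, 0]), int(frag[i, 1])
        p1 = int(rng.integers(a, b))
        strand = "+" if rng.random() < 0.5 else "-"
        return (chrom, p1, strand, True, chrom, 0, "+", False)

    if cls == "genomic":
        s = span_draw(L)
        if cnv_truth is not None:
            nb = len(cnv_truth)
            bin_p = _cn_weighted_bins(cnv_truth, nb)
            b0 = int(rng.choice(nb, p=bin_p))
            lo = b0 * cnv_truth.bin_size
            hi = min(L, (b0 + 1) * cnv_truth.bin_size)
            p1 = int(rng.integers(lo, hi))
        else:
            p1 = int(rng.integers(0, L))
        p1 = min(p1, L - s)
        p2 = p1 + s - rl
        return (chrom, p1, "+", True, chrom, p2, "-", True)

    raise ValueError(f"unknown read class {cls!r}")


def simulate_contact_counts(
    features: dict,
    coefficients,
    decay_exponent: float = 0.0,
    seed: int = 0,
    bin_size: int = 500_000,
    chromosome_name: str = "chr",
    features_col: dict | None = None,
    col_chromosome_name: str = "chr2",
) -> tuple[ContactMatrix, np.ndarray]:
    """Contact counts drawn from the log-linear Poisson rate model.

    lambda_kl = exp(a0 + sum_m a_m log(feature_m,k * feature_m,l))
                * (|k - l| + 1) ** (-decay_exponent)

    Cis by default: the upper triangle is drawn ~ Poisson(lambda) and
    mirrored so the matrix is symmetric.  With ``features_col`` a
    rectangular trans matrix between two chromosomes is drawn instead
    (no distance decay applies).  Returns the matrix and the truth rates.
    """
    from .normalization import FEATURE_NAMES, pairwise_design

    coefficients = np.asarray(coefficients, dtype=float)
    if len(coefficients) != 1 + len(FEATURE_NAMES):
        raise ValueError("need intercept + 4 coefficients")
    for feats in (features, features_col) if features_col is not None else (features,):
        for name in FEATURE_NAMES:
            if np.any(np.asarray(feats[name]) <= 0):
                raise ValueError(f"feature {name!r} must be positive everywhere")
    design, include = pairwise_design(features, features_col)
    lam = np.exp(coefficients[0] + design @ coefficients[1:])
    rng = np.random.default_rng(seed)
    if features_col is not None:
        counts = rng.poisson(lam)
        return ContactMatrix(chromosome_name, col_chromosome_name, bin_size, counts), lam
    n = design.shape[0]
    k = np.arange(n)
    dist = np.abs(k[:, None] - k[None, :]) + 1.0
    lam = lam * dist ** (-decay_exponent)
    upper = np.triu(rng.poisson(lam))
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(chromosome_name, chromosome_name, bin_size, counts), lam
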