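"""Read-pair ingestion, maximum-molecule-length estimation, classification.

Mapped Hi-C/3C-seq mates arrive as per-pair records: for each side a
chromosome, a 0-based 5' mapping coordinate, a strand and a mapped flag.
Pairs are classified into the standard conformation-capture taxonomy:

``valid_pair``
    sides on different restriction fragments, each 5' end within MML of its
    downstream cut site — a true ligation product, the sole input to
    contact matrices.
``dangling_end`` / ``self_circle``
    both sides on the same fragment, facing inward / outward.
``extra_dangling_end``
    different fragments but an inward, WGS-like insert of span <= MML.
``single_sided``
    only one mate mapped.
``genomic``
    (3C-seq mode) inward pair of span <= MML regardless of fragment
    co-membership — an ordinary genomic insert.
``other``
    anything else (same-strand same-fragment pairs, valid-pair candidates
    violating the cut-site distance bound).

The MML (maximum molecule length, an upper bound on sonicated molecule
size) is estimated from the inward same/adjacent-fragment pairs as the
smallest multiple of 100 bp strictly greater than the nearest-rank 99th
percentile of their insert spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .restriction import RestrictionMap

__all__ = [
    "READ_CLASSES",
    "PAIR_COLUMNS",
    "LoadResult",
    "load_read_pairs",
    "inward_span",
    "estimate_mml",
    "classify_read_pairs",
    "class_summary",
]

READ_CLASSES = (
    "valid_pair",
    "dangling_end",
    "extra_dangling_end",
    "self_circle",
    "single_sided",
    "genomic",
    "other",
)

PAIR_COLUMNS = [
    "chrom1", "pos1", "strand1", "mapped1",
    "chrom2", "pos2", "strand2", "mapped2",
]


@dataclass
class LoadResult:
    pairs: pd.DataFrame
    n_dropped_unmapped: int


def load_read_pairs(path, columns: dict[str, str] | None = None) -> LoadResult:
    """Load a pair table from tab-delimited text or HDF5.

    Pairs with both mates unmapped are dropped and counted.  ``columns``
    optionally remaps input column names onto the canonical
    ``chrom1/pos1/strand1/mapped1`` (and side-2) schema.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        df = _load_hdf5(path)
    else:
        df = pd.read_csv(path, sep="\t")
    if columns:
        df = df.rename(columns=columns)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pair table missing column(s): {', '.join(missing)}")
    df = df[PAIR_COLUMNS].copy()
    for side in (1, 2):
        df[f"mapped{side}"] = df[f"mapped{side}"].astype(bool)
        df[f"pos{side}"] = df[f"pos{side}"].astype(np.int64)
        df[f"chrom{side}"] = df[f"chrom{side}"].astype(str)
    keep = df["mapped1"] | df["mapped2"]
    dropped = int((~keep).sum())
    return LoadResult(df[keep].reset_index(drop=True), dropped)


def _load_hdf5(path: str) -> pd.DataFrame:
    import h5py

    with h5py.File(path, "r") as fh:
        data = {}
        for name in fh:
            col = fh[name][()]
            if col.dtype.kind in ("S", "O"):
                col = np.char.decode(col.astype("S"), "utf-8")
            data[name] = col
    return pd.DataFrame(data)


def inward_span(pair, read_length: int) -> int:
    """Insert span of an inward-facing cis pair: side1-start to side2-end.

    The span runs from the leftmost mate's 5' start to the rightmost
    mate's 3' end (its 5' coordinate plus the read length).
    """
    chrom1, pos1, strand1 = pair["chrom1"], pair["pos1"], pair["strand1"]
    chrom2, pos2, strand2 = pair["chrom2"], pair["pos2"], pair["strand2"]
    if chrom1 != chrom2:
        raise ValueError("interchromosomal pair has no inward span")
    if strand1 == strand2:
        raise ValueError("same-strand pair has no inward span")
    if pos1 == pos2:  # degenerate overlap: inward by convention
        return int(read_length)
    left, right = (pos1, pos2) if pos1 < pos2 else (pos2, pos1)
    left_strand = strand1 if pos1 < pos2 else strand2
    if left_strand != "+":
        raise ValueError("outward-facing pair has no inward span")
    return int(right) + int(read_length) - int(left)


def _both_mapped(df: pd.DataFrame) -> pd.Series:
    return df["mapped1"] & df["mapped2"]


def _inward_geometry(df: pd.DataFrame, read_length: int):
    """Vectorized inward test + span for both-mapped cis pairs."""
    cis = _both_mapped(df) & (df["chrom1"] == df["chrom2"])
    swap = df["pos2"] < df["pos1"]
    left_pos = np.where(swap, df["pos2"], df["pos1"])
    right_pos = np.where(swap, df["pos1"], df["pos2"])
    left_strand = np.where(swap, df["strand2"], df["strand1"])
    right_strand = np.where(swap, df["strand1"], df["strand2"])
    opposite = (df["strand1"] != df["strand2"]).to_numpy()
    tie = (df["pos1"] == df["pos2"]).to_numpy()
    inward = cis.to_numpy() & (
        ((left_strand == "+") & (right_strand == "-")) | (tie & opposite)
    )
    span = right_pos + read_length - left_pos
    return inward, span


def _as_rmap_dict(rmap) -> dict[str, RestrictionMap]:
    if isinstance(rmap, RestrictionMap):
        return {rmap.chromosome_name: rmap}
    return dict(rmap)


def _fragment_ids(pairs: pd.DataFrame, rmaps: dict[str, RestrictionMap]):
    """Genome-wide fragment ids per side (-1 for unmapped sides).

    Fragments of different chromosomes get disjoint id ranges, so equal
    ids imply the same fragment of the same chromosome, and an id
    difference of 1 within a chromosome means adjacent fragments.
    """
    offsets, total = {}, 0
    for name in sorted(rmaps):
        offsets[name] = total
        total += rmaps[name].n_fragments + 1  # +1 gap: no cross-chrom adjacency
    out = []
    for side in (1, 2):
        ids = np.full(len(pairs), -1, dtype=np.int64)
        mapped = pairs[f"mapped{side}"].to_numpy()
        chroms = pairs[f"chrom{side}"].to_numpy()
        pos = pairs[f"pos{side}"].to_numpy()
        for name, rmap in rmaps.items():
            sel = mapped & (chroms == name)
            if sel.any():
                ids[sel] = offsets[name] + rmap.fragment_of(pos[sel])
        out.append(ids)
    return out[0], out[1]


def estimate_mml(pairs: pd.DataFrame, rmap, read_length: int) -> int:
    """Estimate the MML from artifact-pair insert lengths.

    Candidates are inward pairs whose sides lie on the same or adjacent
    restriction fragments (the dangling-end / extra-dangling-end population,
    identifiable without already knowing the MML).  The MML is the smallest
    multiple of 100 bp strictly greater than the nearest-rank 99th
    percentile of their spans.
    """
    rmaps = _as_rmap_dict(rmap)
    inward, span = _inward_geometry(pairs, read_length)
    idx = np.flatnonzero(inward)
    if len(idx) == 0:
        raise ValueError("no inward pairs; supply MML manually")
    frag1, frag2 = _fragment_ids(pairs.iloc[idx], rmaps)
    near = np.abs(frag1 - frag2) <= 1
    spans = np.sort(span[idx][near])
    if len(spans) < 100:
        raise ValueError(
            f"only {len(spans)} same/adjacent-fragment inward pairs "
            "(need >= 100); supply MML manually"
        )
    rank = int(np.ceil(0.99 * len(spans)))  # nearest-rank percentile
    p99 = int(spans[rank - 1])
    return 100 * (p99 // 100 + 1)


def classify_read_pairs(
    pairs: pd.DataFrame,
    rmap: RestrictionMap,
    mml: int,
    read_length: int,
    mode: str = "hic",
) -> pd.Series:
    """Assign exactly one read class to every loaded pair.

    Returns a Categorical Series aligned with ``pairs``.  The rule table
    (with ``d(side)`` = distance from the 5' position to the cut site
    downstream in read orientation):

    ========================  ==========================  ==================
    geometry                  condition                   class
    ========================  ==========================  ==================
    one side unmapped         —                           single_sided
    same fragment             inward                      dangling_end
    same fragment             outward                     self_circle
    same fragment             same strand                 other
    different fragments       inward and span <= MML      extra_dangling_end
    different fragments       d(side1), d(side2) <= MML   valid_pair
    different fragments       otherwise                   other
    ========================  ==========================  ==================

    In ``mode="c3seq"`` any inward cis pair with span <= MML is labeled
    ``genomic`` first (a WGS-like insert), taking precedence over the
    fragment-based rules.
    """
    if mml <= 0:
        raise ValueError("mml must be positive")
    if mode not in ("hic", "c3seq"):
        raise ValueError(f"unknown mode {mode!r}")
    rmaps = _as_rmap_dict(rmap)
    for side in (1, 2):
        chroms = set(pairs.loc[pairs[f"mapped{side}"], f"chrom{side}"].unique())
        unknown = chroms - set(rmaps)
        if unknown:
            raise ValueError(f"chromosome(s) absent from restriction map: {unknown}")

    n = len(pairs)
    labels = np.full(n, "other", dtype=object)
    both = _both_mapped(pairs).to_numpy()
    labels[~both] = "single_sided"

    inward, span = _inward_geometry(pairs, read_length)
    short_inward = inward & (span <= mml)

    pos1 = pairs["pos1"].to_numpy()
    pos2 = pairs["pos2"].to_numpy()
    frag1, frag2 = _fragment_ids(pairs, rmaps)
    same_frag = both & (frag1 != -1) & (frag1 == frag2)

    cis = both & (pairs["chrom1"] == pairs["chrom2"]).to_numpy()
    swap = pos2 < pos1
    left_strand = np.where(swap, pairs["strand2"], pairs["strand1"])
    right_strand = np.where(swap, pairs["strand1"], pairs["strand2"])
    outward = cis & (left_strand == "-") & (right_strand == "+") & (pos1 != pos2)

    labels[same_frag & inward] = "dangling_end"
    labels[same_frag & outward] = "self_circle"
    # same fragment + same strand stays "other"

    diff_frag = both & ~same_frag
    labels[diff_frag & short_inward] = "extra_dangling_end"

    # valid-pair candidates: different fragments, not a short inward insert
    d1 = _downstream_cut_distance(pairs, rmaps, 1)
    d2 = _downstream_cut_distance(pairs, rmaps, 2)
    candidate = diff_frag & ~short_inward
    labels[candidate & (d1 <= mml) & (d2 <= mml)] = "valid_pair"

    if mode == "c3seq":
        labels[both & short_inward] = "genomic"

    return pd.Series(pd.Categorical(labels, categories=READ_CLASSES), index=pairs.index)


def _downstream_cut_distance(pairs, rmaps, side):
    """Distance from each 5' position to the cut site in read direction:
    the fragment's right boundary for + reads, left boundary for - reads."""
    n = len(pairs)
    out = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    mapped = pairs[f"mapped{side}"].to_numpy()
    chroms = pairs[f"chrom{side}"].to_numpy()
    pos = pairs[f"pos{side}"].to_numpy()
    strand = pairs[f"strand{side}"].to_numpy()
    for name, rmap in rmaps.items():
        sel = mapped & (chroms == name)
        if not sel.any():
            continue
        frag = rmap.fragment_of(pos[sel])
        starts = rmap.fragments[frag, 0]
        ends = rmap.fragments[frag, 1]
        out[sel] = np.where(strand[sel] == "+", ends - pos[sel], pos[sel] - starts + 1)
    return out


def class_summary(classes: pd.Series) -> pd.DataFrame:
    """Tab-friendly per-class counts and fractions."""
    counts = classes.value_counts().reindex(READ_CLASSES, fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "read_class": counts.index,
            "count": counts.to_numpy(),
            "fraction": counts.to_numpy() / total if total else 0.0,
        }
    )
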