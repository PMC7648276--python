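"""Readers and writers for the plain-text genomics formats the tool uses.

bedGraph for per-bin signals, BED for intervals (fragments, LCVs, FAs),
(bin1, bin2, value) triplet text for contact matrices, tab-delimited pair
tables, and a key-value text serialization for GLM fits.  All coordinates
are 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .normalization import BiasModelFit, ContactMatrix, FEATURE_NAMES

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_bedgraph",
    "read_bedgraph_values",
    "write_bed",
    "write_triplets",
    "read_triplets",
    "write_pairs",
    "write_bias_fit",
    "read_bias_fit",
]


def read_fasta(path) -> dict[str, str]:
    """Sequences of a FASTA file keyed by record name (via pyfaidx)."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bedgraph(path, chrom: str, bin_size: int, values, mask=None) -> None:
    """Per-bin values as bedGraph; masked bins are omitted."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if mask is not None and mask[i]:
                continue
            fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.6g}\n")


def read_bedgraph_values(path, chrom: str, bin_size: int, n_bins: int) -> np.ndarray:
    out = np.full(n_bins, np.nan)
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 4 or parts[0] != chrom:
                continue
            out[int(parts[1]) // bin_size] = float(parts[3])
    return out


def write_bed(path, chrom: str, intervals, scores=None, names=None) -> None:
    """Intervals as BED with optional name and score columns."""
    with open(path, "w") as fh:
        for i, (start, end) in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i}"
            score = scores[i] if scores is not None else 0
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{name}\t{score}\n")


def write_triplets(path, matrix, row_chrom=None, col_chrom=None) -> None:
    """Matrix as ``bin1<TAB>bin2<TAB>value`` triplets (nonzero/finite cells)."""
    if isinstance(matrix, ContactMatrix):
        cells, row_chrom, col_chrom = matrix.counts, matrix.row_chrom, matrix.col_chrom
    else:
        cells = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"# rows={row_chrom} cols={col_chrom} shape={cells.shape[0]}x{cells.shape[1]}\n")
        for i, j in zip(*np.nonzero(np.nan_to_num(cells))):
            v = cells[i, j]
            if np.isfinite(v):
                fh.write(f"{i}\t{j}\t{v:.6g}\n")


def read_triplets(path, shape) -> np.ndarray:
    out = np.zeros(shape)
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            i, j, v = line.split()
            out[int(i), int(j)] = float(v)
    return out


def write_pairs(path, pairs: pd.DataFrame) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def write_bias_fit(path, fit: BiasModelFit) -> None:
    with open(path, "w") as fh:
        fh.write(f"kind\t{fit.kind}\n")
        fh.write(f"scope\t{fit.scope}\n")
        fh.write(f"n_pairs\t{fit.n_pairs}\n")
        fh.write(f"alpha0\t{fit.coefficients[0]:.10g}\n")
        for name, c in zip(FEATURE_NAMES, fit.coefficients[1:]):
            fh.write(f"alpha_{name}\t{c:.10g}\n")


def read_bias_fit(path) -> BiasModelFit:
    fields = {}
    with open(path) as fh:
        for line in fh:
            key, val = line.rstrip("\n").split("\t")
            fields[key] = val
    coefs = [float(fields["alpha0"])] + [float(fields[f"alpha_{n}"]) for n in FEATURE_NAMES]
    return BiasModelFit(np.array(coefs), fields["kind"], fields["scope"], int(fields["n_pairs"]))
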