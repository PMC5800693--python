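"""Readers and writers for contact matrices, segmentations and tracks.

Dense whitespace-separated text and COO triplet text are the two supported
contact-matrix exchange formats; results are written as BED3 (TAD intervals)
and bedGraph (per-bin tracks). Coordinates are 0-based half-open throughout,
and BED output maps retained bins back to their *original* genomic intervals
via the matrix's ``bin_index_map`` (filtered gaps are not re-inflated).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np

from .types import (
    ConsistencyError,
    ContactMatrix,
    MatrixFormatError,
    Segmentation,
    Track,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

__all__ = [
    "read_dense_matrix",
    "read_coo_triplets",
    "write_segments_bed",
    "read_segments_bed",
    "write_track_bedgraph",
]


def read_dense_matrix(path: PathLike, bin_size: int, chrom: str = "chr?") -> ContactMatrix:
    """Read a dense whitespace-separated square matrix from text.

    The matrix is symmetrized by averaging with its transpose (a warning is
    logged if the asymmetry exceeds 1e-8). NaN or negative entries are
    rejected with the offending row and column named.
    """
    try:
        raw = np.loadtxt(path, dtype=float, ndmin=2)
    except ValueError as exc:
        raise MatrixFormatError(f"could not parse {path} as a dense matrix: {exc}") from exc
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise MatrixFormatError(
            f"{path}: expected a square matrix, got shape {raw.shape[0]}x{raw.shape[1]}"
        )
    bad = np.argwhere(~np.isfinite(raw))
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"{path}: non-finite entry at row {i}, column {j}")
    bad = np.argwhere(raw < 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(f"{path}: negative entry {raw[i, j]} at row {i}, column {j}")
    if not np.allclose(raw, raw.T, atol=1e-8, rtol=0.0):
        logger.warning("%s: input matrix is asymmetric; symmetrizing by (M + M^T)/2", path)
    return ContactMatrix(raw, bin_size=bin_size, chrom=chrom)


def read_coo_triplets(
    path: PathLike, n_bins: int, bin_size: int, chrom: str = "chr?"
) -> ContactMatrix:
    """Read sparse ``i j value`` triplet text into a dense symmetric matrix.

    Indices are 0-based; unmentioned pairs are zero. Every line contributes
    to both ``(i, j)`` and ``(j, i)`` and duplicate lines are summed, so a
    file listing both orientations of a pair counts each line.
    """
    m = np.zeros((n_bins, n_bins), dtype=float)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected 'i j value', got {line!r}"
                )
            i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise IndexError(
                    f"{path}:{lineno}: bin index ({i}, {j}) outside [0, {n_bins})"
                )
            if v < 0:
                raise ValueError(f"{path}:{lineno}: negative contact value {v}")
            m[i, j] += v
            if i != j:
                m[j, i] += v
    return ContactMatrix(m, bin_size=bin_size, chrom=chrom)


def write_segments_bed(seg: Segmentation, cm: ContactMatrix, path: PathLike) -> None:
    """Write segmentation intervals as BED3 in original genomic coordinates.

    Each interval spans from the original coordinate of its first retained
    bin to the end of its last retained bin's original interval; an empty
    segmentation produces an empty file.
    """
    if seg.intervals and seg.n_bins != cm.n_bins:
        raise ConsistencyError(
            f"segmentation covers {seg.n_bins} bins but matrix has {cm.n_bins}"
        )
    with open(path, "w") as fh:
        for s, e in seg.intervals:
            start_bp = int(cm.bin_index_map[s]) * cm.bin_size
            end_bp = (int(cm.bin_index_map[e - 1]) + 1) * cm.bin_size
            fh.write(f"{cm.chrom}\t{start_bp}\t{end_bp}\n")


def read_segments_bed(path: PathLike, cm: ContactMatrix) -> Segmentation:
    """Read BED3 intervals back into a Segmentation over retained bins.

    Inverse of :func:`write_segments_bed` for the same contact matrix;
    interval ends are looked up against the matrix's bin index map.
    """
    start_of = {int(orig): k for k, orig in enumerate(cm.bin_index_map)}
    end_of = {int(orig) + 1: k + 1 for k, orig in enumerate(cm.bin_index_map)}
    intervals: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, s_bp, e_bp = line.split("\t")[:3]
            s_bp, e_bp = int(s_bp), int(e_bp)
            if s_bp % cm.bin_size or e_bp % cm.bin_size:
                raise MatrixFormatError(
                    f"{path}:{lineno}: coordinates are not bin-size multiples"
                )
            try:
                intervals.append(
                    (start_of[s_bp // cm.bin_size], end_of[e_bp // cm.bin_size])
                )
            except KeyError as exc:
                raise ConsistencyError(
                    f"{path}:{lineno}: coordinate does not map to a retained bin"
                ) from exc
    return Segmentation(intervals)


def write_track_bedgraph(track: Track, cm: ContactMatrix, path: PathLike) -> None:
    """Write a per-bin track as bedGraph, one line per retained bin."""
    if len(track) != cm.n_bins:
        raise ConsistencyError(
            f"track length {len(track)} does not match matrix size {cm.n_bins}"
        )
    if np.any(~np.isfinite(track.values)):
        raise ValueError(f"track {track.name!r} contains non-finite values")
    with open(path, "w") as fh:
        for k, orig in enumerate(cm.bin_index_map):
            start_bp = int(orig) * cm.bin_size
            fh.write(f"{cm.chrom}\t{start_bp}\t{start_bp + cm.bin_size}\t{track.values[k]:g}\n")
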