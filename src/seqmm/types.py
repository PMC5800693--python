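"""Core containers shared across the package.

A chromosome's Hi-C data lives in a :class:`ContactMatrix`: a square,
symmetric, nonnegative matrix of contact counts between fixed-size genomic
bins, together with the bookkeeping needed to map retained matrix rows back
to original genomic coordinates after empty bins have been filtered out.
Segmentations (ordered, contiguous TAD intervals) and per-bin tracks
(principal components, summation profiles) are thin dataclasses with
validation in ``__post_init__``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

__all__ = [
    "ContactMatrix",
    "PointCloud",
    "Segmentation",
    "Track",
    "LaplacianMatrix",
    "Embedding",
    "MatrixFormatError",
    "ConsistencyError",
    "EmptyMatrixError",
    "DegenerateInputError",
]

SYMMETRY_TOL = 1e-8


class MatrixFormatError(ValueError):
    """Raised when an input file does not parse as a square contact matrix."""


class ConsistencyError(ValueError):
    """Raised when two objects that must share a bin universe do not."""


class EmptyMatrixError(ValueError):
    """Raised when filtering removes every bin of a contact matrix."""


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but carries no signal
    (e.g. an all-zero matrix fed to a principal-component analysis)."""


@dataclass
class ContactMatrix:
    """Square symmetric contact map for one chromosome.

    Parameters
    ----------
    values
        ``n x n`` nonnegative real matrix. Symmetrized on construction by
        averaging with its transpose when the asymmetry exceeds 1e-8.
    bin_size
        Genomic bin width in base pairs.
    chrom
        Chromosome label used when writing BED/bedGraph output.
    bin_index_map
        Strictly increasing original bin index for each retained row/column;
        defaults to the identity map. After empty-bin filtering this records
        which original bins survive.
    """

    values: np.ndarray
    bin_size: int
    chrom: str = "chr?"
    bin_index_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise MatrixFormatError(f"contact matrix must be square, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("contact matrix contains NaN or infinite entries")
        if not np.allclose(v, v.T, atol=SYMMETRY_TOL, rtol=0.0):
            v = 0.5 * (v + v.T)
        else:
            v = 0.5 * (v + v.T)  # remove residual round-off asymmetry too
        self.values = v
        if self.bin_size <= 0:
            raise ValueError("bin_size must be a positive number of base pairs")
        if self.bin_index_map is None:
            self.bin_index_map = np.arange(v.shape[0])
        else:
            m = np.asarray(self.bin_index_map, dtype=int)
            if m.shape != (v.shape[0],):
                raise ConsistencyError(
                    f"bin_index_map length {m.shape} does not match matrix size {v.shape[0]}"
                )
            if m.size > 1 and np.any(np.diff(m) <= 0):
                raise ValueError("bin_index_map must be strictly increasing")
            self.bin_index_map = m

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def with_values(self, values: np.ndarray) -> "ContactMatrix":
        """Copy of this matrix with new values but the same bin bookkeeping."""
        return ContactMatrix(values, self.bin_size, self.chrom, self.bin_index_map.copy())


@dataclass
class PointCloud:
    """3D coordinates of sequentially numbered points (atoms or loci)."""

    coords: np.ndarray
    chain_label: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError(f"coords must be an (n, 3) array, got {c.shape}")
        if c.shape[0] < 2:
            raise ValueError("a point cloud needs at least two points")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords contain NaN or infinite values")
        self.coords = c
        if self.chain_label is not None and len(self.chain_label) != c.shape[0]:
            raise ConsistencyError("chain_label length does not match number of points")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


@dataclass
class Segmentation:
    """Ordered, contiguous, non-overlapping intervals over retained bins.

    Intervals are ``(start, end)`` half-open, 0-based, each of length >= 1,
    with every start equal to the previous end so the union covers
    ``[0, n)`` exactly.
    """

    intervals: list[tuple[int, int]]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        iv = [(int(s), int(e)) for s, e in self.intervals]
        for s, e in iv:
            if e <= s:
                raise ValueError(f"interval ({s}, {e}) has non-positive length")
        for (s0, e0), (s1, e1) in zip(iv, iv[1:]):
            if s1 != e0:
                raise ValueError(
                    f"intervals must be contiguous: ({s0},{e0}) followed by ({s1},{e1})"
                )
        if iv and iv[0][0] != 0:
            raise ValueError("first interval must start at bin 0")
        self.intervals = iv

    @property
    def n_bins(self) -> int:
        return self.intervals[-1][1] if self.intervals else 0

    @property
    def n_domains(self) -> int:
        return len(self.intervals)

    def boundaries(self) -> np.ndarray:
        """Internal boundary positions: interval start bins, excluding 0."""
        return np.array([s for s, _ in self.intervals[1:]], dtype=int)


@dataclass
class Track:
    """A per-bin real-valued signal aligned to a contact matrix."""

    values: np.ndarray
    name: str = "track"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()

    def __len__(self) -> int:
        return self.values.size


@dataclass
class LaplacianMatrix:
    """Combinatorial weighted graph Laplacian L = D - W for a banded
    contact graph; rows sum to zero and the matrix is positive semidefinite."""

    values: np.ndarray
    nb: int
    convention: str = "D-W"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Embedding:
    """Eigenvectors of the smallest Laplacian eigenvalues (ascending),
    one column per eigenvalue, including the trivial near-constant vector."""

    vectors: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.vectors.shape[1] != self.eigenvalues.size:
            raise ConsistencyError("number of eigenvectors and eigenvalues differ")
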