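"""Synthetic Hi-C matrices and a toy double helix for offline testing.

:func:`generate_hic` draws Poisson counts around a multiplicative expected
model with the three statistical features the analysis methods assume:

* power-law distance decay ``(1 + |i-j|)^(-alpha)`` of contact frequency;
* planted TADs — contiguous diagonal blocks with uniformly enriched
  internal contacts;
* checkerboard compartments — alternating blocks of ±1 sign, with
  same-sign contacts boosted by ``1 + strength`` and opposite-sign
  contacts damped by its reciprocal (the plaid pattern the first
  principal component picks up).

The planted boundaries and compartment signs come back as a
:class:`SyntheticTruth` so recovery can be scored exactly.

:func:`generate_double_helix` builds two intertwined antiparallel helices
(B-DNA-like proportions) numbered sequentially along chain A then back
down chain B, for demonstrating the local-scale vs global-scale clustering
contrast on a point cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence, Union

import numpy as np

from .types import ContactMatrix, PointCloud

__all__ = [
    "SyntheticTruth",
    "generate_hic",
    "expected_hic",
    "generate_double_helix",
]


@dataclass
class SyntheticTruth:
    """Planted structure of a synthetic matrix: internal TAD boundary bins,
    the per-bin compartment sign vector, and the generator parameters."""

    tad_boundaries: np.ndarray
    compartment_sign: np.ndarray
    params: dict[str, Any] = field(default_factory=dict)


def _resolve_tad_sizes(n_bins: int, tad_sizes: Union[int, Sequence[int], None]) -> list[int]:
    if tad_sizes is None:
        return [n_bins]
    if isinstance(tad_sizes, (int, np.integer)):
        size = int(tad_sizes)
        if size < 1:
            raise ValueError("tad size must be >= 1")
        sizes = [size] * (n_bins // size)
        rem = n_bins - sum(sizes)
        if rem:
            if sizes:
                sizes[-1] += rem
            else:
                sizes = [n_bins]
        return sizes
    sizes = [int(s) for s in tad_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("all tad sizes must be >= 1")
    if sum(sizes) != n_bins:
        raise ValueError(
            f"tad sizes sum to {sum(sizes)} but the matrix has {n_bins} bins"
        )
    return sizes


def _compartment_sign(n_bins: int, compartment_block: int) -> np.ndarray:
    if compartment_block <= 0:
        return np.ones(n_bins, dtype=int)
    block_of = np.arange(n_bins) // compartment_block
    return np.where(block_of % 2 == 0, 1, -1)


def expected_hic(
    n_bins: int = 300,
    tad_sizes: Union[int, Sequence[int], None] = None,
    decay_exponent: float = 1.0,
    tad_enrichment: float = 3.0,
    compartment_block: int = 0,
    compartment_strength: float = 0.0,
    mean_depth: float = 50.0,
    bin_size: int = 100_000,
    chrom: str = "chrS",
) -> tuple[ContactMatrix, SyntheticTruth]:
    """Noise-free expected contact matrix (the Poisson means, no sampling).

    Expected contact between bins i and j:

    ``lambda_ij = depth * (1+|i-j|)^(-alpha) * e_TAD(i,j) * e_comp(i,j)``

    with ``e_TAD = tad_enrichment`` when i and j share a planted TAD (else
    1) and ``e_comp = 1 + strength`` for same compartment sign, its
    reciprocal for opposite signs.
    """
    if decay_exponent <= 0:
        raise ValueError("decay_exponent must be positive")
    if tad_enrichment < 1:
        raise ValueError("tad_enrichment must be >= 1")
    if compartment_strength < 0:
        raise ValueError("compartment_strength must be >= 0")
    if mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    sizes = _resolve_tad_sizes(n_bins, tad_sizes)
    ends = np.cumsum(sizes)
    tad_of = np.repeat(np.arange(len(sizes)), sizes)
    sign = _compartment_sign(n_bins, compartment_block)

    idx = np.arange(n_bins)
    lam = mean_depth * (1.0 + np.abs(idx[:, None] - idx[None, :])) ** (-decay_exponent)
    lam *= np.where(tad_of[:, None] == tad_of[None, :], tad_enrichment, 1.0)
    if compartment_strength > 0:
        comp = np.where(
            sign[:, None] == sign[None, :],
            1.0 + compartment_strength,
            1.0 / (1.0 + compartment_strength),
        )
        lam *= comp
    truth = SyntheticTruth(
        tad_boundaries=ends[:-1].astype(int),
        compartment_sign=sign,
        params={
            "n_bins": n_bins,
            "decay_exponent": decay_exponent,
            "tad_enrichment": tad_enrichment,
            "compartment_block": compartment_block,
            "compartment_strength": compartment_strength,
            "mean_depth": mean_depth,
            "seed": None,
        },
    )
    return ContactMatrix(lam, bin_size=bin_size, chrom=chrom), truth


def generate_hic(
    n_bins: int = 300,
    tad_sizes: Union[int, Sequence[int], None] = None,
    decay_exponent: float = 1.0,
    tad_enrichment: float = 3.0,
    compartment_block: int = 0,
    compartment_strength: float = 0.0,
    mean_depth: float = 50.0,
    seed: int = 0,
    bin_size: int = 100_000,
    chrom: str = "chrS",
) -> tuple[ContactMatrix, SyntheticTruth]:
    """Poisson-sampled synthetic contact matrix with planted truth.

    Counts are drawn independently as ``Poisson(lambda_ij)`` for ``i <= j``
    and mirrored, so the output is a symmetric integer-valued matrix;
    the same seed reproduces the same matrix exactly.
    """
    expected, truth = expected_hic(
        n_bins,
        tad_sizes,
        decay_exponent,
        tad_enrichment,
        compartment_block,
        compartment_strength,
        mean_depth,
        bin_size,
        chrom,
    )
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.poisson(expected.values).astype(float))
    counts = upper + np.triu(upper, 1).T
    truth.params["seed"] = seed
    return ContactMatrix(counts, bin_size=bin_size, chrom=chrom), truth


def generate_double_helix(
    n_per_chain: int = 50,
    radius: float = 4.0,
    pitch: float = 12.0,
    points_per_turn: int = 10,
    phase: float = np.pi,
    jitter: float = 0.0,
    seed: int = 0,
) -> PointCloud:
    """Two intertwined antiparallel helices, sequentially numbered.

    Chain A runs bottom to top (indices ``0 .. n-1``); chain B runs back
    down (indices ``n .. 2n-1``), offset in phase so the chains face each
    other across the helix axis at every height. Sequential neighbors
    within a chain are spatially close, the two chain *ends* meet only at
    the top (where the numbering crosses chains), and points at the same
    height on opposite chains are ``2 * radius`` apart — the geometry that
    makes local-scale (banded) clustering recover the chains while
    global-scale clustering splits the structure across the axis.

    Default proportions echo B-DNA (radius ~ 4 A at base scale, ~10 points
    per turn); ``jitter`` adds isotropic Gaussian noise of that standard
    deviation, seeded.
    """
    if n_per_chain < 10:
        raise ValueError("n_per_chain must be >= 10")
    levels = np.arange(n_per_chain)
    theta = 2.0 * np.pi * levels / points_per_turn
    z = pitch * levels / points_per_turn
    chain_a = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])
    # antiparallel: chain B is numbered from the top level downwards
    rev = levels[::-1]
    theta_b = 2.0 * np.pi * rev / points_per_turn + phase
    chain_b = np.column_stack(
        [radius * np.cos(theta_b), radius * np.sin(theta_b), pitch * rev / points_per_turn]
    )
    coords = np.vstack([chain_a, chain_b])
    if jitter > 0:
        coords = coords + np.random.default_rng(seed).normal(0.0, jitter, coords.shape)
    labels = ["A"] * n_per_chain + ["B"] * n_per_chain
    return PointCloud(coords, chain_label=labels)
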