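"""Contact-matrix preprocessing: empty-bin filtering, log transform,
observed/expected (Toeplitz) normalization, and row-correlation matrices.

Hi-C contact frequency decays roughly as a power law of genomic distance;
dividing each entry by the mean contact at its offset (the "expected"
value) removes this trend so that compartment-scale plaid structure
dominates the principal components.
"""

from __future__ import annotations

import numpy as np

from .types import ContactMatrix, EmptyMatrixError

__all__ = [
    "filter_empty_bins",
    "log_transform",
    "toeplitz_normalize",
    "correlation_matrix",
]


def filter_empty_bins(cm: ContactMatrix, min_row_sum: float = 0.0) -> ContactMatrix:
    """Remove rows/columns whose sum is <= ``min_row_sum``.

    Unmappable or unsequenced genomic bins produce all-zero rows that
    destabilize spectral analysis; they are dropped and the surviving bins'
    original indices recorded in the returned matrix's ``bin_index_map``.
    """
    sums = cm.values.sum(axis=1)
    keep = np.flatnonzero(sums > min_row_sum)
    if keep.size == 0:
        raise EmptyMatrixError(
            f"no bins with row sum > {min_row_sum}; matrix would be empty"
        )
    values = cm.values[np.ix_(keep, keep)]
    return ContactMatrix(values, cm.bin_size, cm.chrom, cm.bin_index_map[keep])


def log_transform(cm: ContactMatrix) -> ContactMatrix:
    """Apply ``x -> log(1 + x)`` (natural log) entrywise.

    Monotone and zero-preserving; compresses the dynamic range of raw
    counts before they are used as graph affinity weights.
    """
    if np.any(cm.values < 0):
        raise ValueError("log transform requires nonnegative entries")
    return cm.with_values(np.log1p(cm.values))


def toeplitz_normalize(cm: ContactMatrix) -> ContactMatrix:
    """Observed/expected normalization against per-offset means.

    Entry (i, j) is divided by the mean of all entries at offset
    ``|i - j|`` (over retained-bin offsets), so each offset-diagonal of the
    output has mean exactly 1 wherever the expected value is positive.
    Offsets with zero expected value are left as zeros.
    """
    n = cm.n_bins
    if n < 2:
        raise ValueError("Toeplitz normalization needs at least 2 bins")
    out = cm.values.copy()
    for d in range(n):
        diag = np.diagonal(cm.values, offset=d)
        mean = diag.mean()
        if mean > 0:
            idx = np.arange(n - d)
            out[idx, idx + d] = diag / mean
            if d > 0:
                out[idx + d, idx] = diag / mean
    return cm.with_values(out)


def correlation_matrix(cm: ContactMatrix) -> ContactMatrix:
    """Pearson correlation of every pair of matrix rows.

    Applied to the normalized matrix this sharpens the compartment plaid
    pattern for display. Zero-variance rows get off-diagonal correlation 0
    by convention so downstream spectral code stays total; the diagonal is 1.
    """
    n = cm.n_bins
    if n < 3:
        raise ValueError("correlation matrix needs at least 3 bins")
    x = cm.values - cm.values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    ok = norms > 0
    xs = np.zeros_like(x)
    xs[ok] = x[ok] / norms[ok, None]
    corr = xs @ xs.T
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    corr = 0.5 * (corr + corr.T)
    return cm.with_values(corr)
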