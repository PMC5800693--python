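"""TAD calling by band-limited spectral clustering, plus scans and baselines.

The pipeline: filter empty bins, log-transform counts to affinity weights,
build the band-limited weighted Laplacian at sequential scale ``nb``, embed
bins in the eigenvectors of the ``n_c`` smallest eigenvalues, K-means into
``n_c`` clusters, then split each cluster into sequentially contiguous runs
— every maximal run becomes one TAD (so the final TAD count is usually
larger than ``n_c``).

Also here:

* :func:`boundary_stability_scan` — how TAD boundaries move as the band
  size varies; boundaries stabilize once ``nb`` exceeds the typical TAD
  size.
* :func:`summation_profile` / :func:`local_minima` — the per-bin sum of
  contacts perpendicular to the diagonal; TAD boundaries fall at its local
  minima.
* :func:`chen_bisection` — the recursive Fiedler-vector bisection baseline:
  split a region at the sign change of its Fiedler vector until every
  region's algebraic connectivity reaches a threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .multiscale import band_laplacian
from .preprocess import filter_empty_bins, log_transform
from .types import (
    ConsistencyError,
    ContactMatrix,
    Embedding,
    LaplacianMatrix,
    Segmentation,
    Track,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityScan",
    "estimate_tad_number",
    "spectral_embedding",
    "cluster_embedding",
    "contiguity_split",
    "call_tads",
    "merge_small_tads",
    "boundary_similarity",
    "boundary_stability_scan",
    "summation_profile",
    "local_minima",
    "chen_bisection",
]

DEFAULT_TAD_BP = 2_000_000  # typical TAD size used to estimate cluster count
KMEANS_RESTARTS = 10


@dataclass
class StabilityScan:
    """Boundary sets per band size and the similarity of adjacent pairs."""

    nb_values: np.ndarray
    boundary_sets: list[Optional[np.ndarray]]
    similarity_to_next: np.ndarray


def estimate_tad_number(
    n_bins: int, bin_size: int, target_tad_bp: int = DEFAULT_TAD_BP
) -> int:
    """Expected cluster count: chromosome length over the typical TAD size
    (default 2 Mb), rounded, and clamped to at least 2."""
    if n_bins < 2:
        raise ValueError("need at least 2 bins to estimate a TAD count")
    est = int(np.floor(n_bins * bin_size / target_tad_bp + 0.5))
    return max(2, est)


def spectral_embedding(lap: LaplacianMatrix, n_c: int) -> Embedding:
    """Eigenvectors of the ``n_c`` smallest Laplacian eigenvalues.

    The trivial near-constant eigenvector is kept: when the banded graph is
    disconnected the component indicators live in the null space and are
    exactly what K-means needs. Column signs are fixed so each column's
    largest-magnitude entry is positive.
    """
    n = lap.n
    if not 2 <= n_c <= n:
        raise ValueError(f"n_c must be in [2, {n}], got {n_c}")
    eigenvalues, vectors = scipy.linalg.eigh(lap.values, subset_by_index=(0, n_c - 1))
    for k in range(vectors.shape[1]):
        if vectors[np.argmax(np.abs(vectors[:, k])), k] < 0:
            vectors[:, k] = -vectors[:, k]
    return Embedding(vectors, eigenvalues)


def cluster_embedding(emb: Embedding, n_c: int, seed: int = 0) -> np.ndarray:
    """K-means on the unit-normalized rows of the spectral embedding.

    Rows are scaled to unit Euclidean norm before clustering (the standard
    spectral-clustering renormalization); this stops low-degree bins at the
    chromosome ends, whose eigenvector entries are disproportionately
    large, from capturing clusters of their own. Fixed seed and a fixed
    restart count (best inertia of 10 runs) make the labels reproducible;
    degenerate inputs that leave clusters empty are handled by
    scikit-learn's re-seeding and logged.
    """
    if n_c > emb.vectors.shape[0]:
        raise ValueError(
            f"cannot form {n_c} clusters from {emb.vectors.shape[0]} bins"
        )
    rows = emb.vectors
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    rows = rows / norms
    km = KMeans(n_clusters=n_c, n_init=KMEANS_RESTARTS, random_state=seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        labels = km.fit_predict(rows)
    for w in caught:
        logger.warning("cluster_embedding: %s", w.message)
    return labels


def contiguity_split(labels: Sequence[int]) -> Segmentation:
    """Split cluster labels into maximal runs of consecutive equal labels.

    Each run becomes one TAD interval, so spatial clusters that are not
    sequentially contiguous contribute several TADs.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        return Segmentation([])
    changes = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], changes])
    ends = np.concatenate([changes, [labels.size]])
    return Segmentation(list(zip(starts.tolist(), ends.tolist())))


def _preprocess(cm: ContactMatrix, min_row_sum: float) -> ContactMatrix:
    return log_transform(filter_empty_bins(cm, min_row_sum))


def call_tads(
    cm: ContactMatrix,
    nb: int,
    n_c: Optional[int] = None,
    seed: int = 0,
    min_row_sum: float = 0.0,
) -> Segmentation:
    """Full band-limited spectral TAD calling pipeline on raw counts.

    ``n_c=None`` estimates the cluster count from the chromosome length and
    a 2 Mb typical TAD size. The returned segmentation records the
    parameters used in its provenance.
    """
    work = _preprocess(cm, min_row_sum)
    n = work.n_bins
    if n == 1:
        return Segmentation(
            [(0, 1)], provenance={"nb": nb, "n_c": 1, "seed": seed, "method": "band-spectral"}
        )
    if n_c is None:
        n_c = estimate_tad_number(n, work.bin_size)
    n_c = min(int(n_c), n)
    lap = band_laplacian(work, nb)
    emb = spectral_embedding(lap, n_c)
    labels = cluster_embedding(emb, n_c, seed=seed)
    seg = contiguity_split(labels)
    seg.provenance = {"nb": nb, "n_c": n_c, "seed": seed, "method": "band-spectral"}
    return seg


def merge_small_tads(
    seg: Segmentation, cm: ContactMatrix, nb: int, min_bins: int
) -> Segmentation:
    """Merge intervals shorter than ``min_bins`` into the neighbor they
    share more band contact with (mean contact within ``|i-j| <= nb``).

    Optional post-filter; off by default in the calling pipeline because
    singleton runs are legitimate output of the contiguity split.
    """
    intervals = list(seg.intervals)
    values = cm.values

    def band_mean(a: tuple[int, int], b: tuple[int, int]) -> float:
        rows = np.arange(a[0], a[1])
        cols = np.arange(b[0], b[1])
        block = values[np.ix_(rows, cols)]
        mask = np.abs(rows[:, None] - cols[None, :]) <= nb
        return float(block[mask].mean()) if mask.any() else 0.0

    changed = True
    while changed and len(intervals) > 1:
        changed = False
        for k, (s, e) in enumerate(intervals):
            if e - s >= min_bins:
                continue
            left = band_mean(intervals[k], intervals[k - 1]) if k > 0 else -np.inf
            right = (
                band_mean(intervals[k], intervals[k + 1])
                if k < len(intervals) - 1
                else -np.inf
            )
            if left >= right:
                intervals[k - 1] = (intervals[k - 1][0], e)
            else:
                intervals[k + 1] = (s, intervals[k + 1][1])
            del intervals[k]
            changed = True
            break
    return Segmentation(intervals, provenance={**seg.provenance, "min_tad_bins": min_bins})


def boundary_similarity(a: Segmentation, b: Segmentation, tol_bins: int = 0) -> float:
    """Jaccard index of two boundary sets after greedy one-to-one matching
    within ``+/- tol_bins``.

    Boundaries are interval start bins excluding 0. Two identical
    segmentations score 1; disjoint boundary sets beyond tolerance score 0.
    If neither segmentation has internal boundaries the similarity is 1.
    """
    if a.n_bins != b.n_bins:
        raise ConsistencyError(
            f"segmentations cover different universes: {a.n_bins} vs {b.n_bins} bins"
        )
    ba, bb = a.boundaries(), b.boundaries()
    if ba.size == 0 and bb.size == 0:
        return 1.0
    matched = 0
    used = np.zeros(bb.size, dtype=bool)
    for x in ba:
        dist = np.abs(bb - x).astype(float)
        dist[used] = np.inf
        if dist.size and dist.min() <= tol_bins:
            used[np.argmin(dist)] = True
            matched += 1
    union = ba.size + bb.size - matched
    return matched / union if union else 1.0


def boundary_stability_scan(
    cm: ContactMatrix,
    nb_values: Sequence[int],
    n_c: Optional[int] = None,
    seed: int = 0,
    tol_bins: int = 1,
) -> StabilityScan:
    """Call TADs at each band size and compare adjacent boundary sets.

    A per-``nb`` failure is recorded as a missing boundary set (similarity
    NaN for the pairs involving it) and logged.
    """
    sets: list[Optional[np.ndarray]] = []
    segs: list[Optional[Segmentation]] = []
    for nb in nb_values:
        try:
            seg = call_tads(cm, int(nb), n_c=n_c, seed=seed)
            segs.append(seg)
            sets.append(seg.boundaries())
        except Exception as exc:  # record and continue the scan
            logger.warning("boundary_stability_scan: nb=%d failed (%s)", nb, exc)
            segs.append(None)
            sets.append(None)
    sims = np.full(max(len(nb_values) - 1, 0), np.nan)
    for k in range(len(nb_values) - 1):
        if segs[k] is not None and segs[k + 1] is not None:
            sims[k] = boundary_similarity(segs[k], segs[k + 1], tol_bins)
    return StabilityScan(np.asarray(nb_values, dtype=int), sets, sims)


def summation_profile(cm: ContactMatrix, nb: int) -> Track:
    """Per-bin contact sum perpendicular to the matrix diagonal.

    ``S(i) = sum_{k=1..w} M[i-k, i+k]`` with half-width ``w = nb // 2`` so
    that every summed pair stays within the ``|i-j| <= nb`` band; edge bins
    use truncated (in-bounds) sums. Within a TAD the anti-diagonal crosses
    enriched contacts, so TAD boundaries appear as local minima of S.
    """
    if nb < 2:
        raise ValueError(f"summation profile needs band size >= 2, got {nb}")
    n = cm.n_bins
    s = np.zeros(n)
    for k in range(1, nb // 2 + 1):
        if 2 * k < n:
            s[k : n - k] += np.diagonal(cm.values, offset=2 * k)
    return Track(s, name=f"summation_nb{nb}")


def local_minima(track: Track) -> np.ndarray:
    """Strict-left / plateau-right local minima of a track.

    A position i qualifies when ``S(i) < S(i-1)`` and the plateau of equal
    values starting at i is followed by a strictly larger value; the
    leftmost point of such a plateau counts once. Endpoints are excluded.
    """
    s = track.values
    if s.size < 3:
        raise ValueError("local minima need a track of length >= 3")
    minima = []
    i = 1
    n = s.size
    while i < n - 1:
        if s[i] < s[i - 1]:
            j = i
            while j + 1 < n and s[j + 1] == s[i]:
                j += 1
            if j + 1 < n and s[j + 1] > s[i]:
                minima.append(i)
            i = j + 1
        else:
            i += 1
    return np.array(minima, dtype=int)


def _fiedler(lap_values: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = scipy.linalg.eigh(lap_values, subset_by_index=(0, 1))
    v = vecs[:, 1]
    # for a disconnected graph the two smallest eigenvectors span the
    # component indicators; projecting out the constant vector gives a
    # sign pattern that separates the components
    return float(vals[1]), v - v.mean()


def _best_sign_cut(v: np.ndarray) -> int:
    """Cut position that best separates positive from non-positive entries."""
    n = v.size
    pos = (v > 0).astype(int)
    left_pos = np.concatenate([[0], np.cumsum(pos)])  # positives in v[:c]
    total_pos = left_pos[-1]
    cuts = np.arange(1, n)
    # agreement if left is the non-positive side, and the mirror orientation
    agree_a = (cuts - left_pos[1:-1]) + (total_pos - left_pos[1:-1])
    agree_b = left_pos[1:-1] + ((n - cuts) - (total_pos - left_pos[1:-1]))
    score = np.maximum(agree_a, agree_b)
    best = score.max()
    candidates = cuts[score == best]
    if candidates.size > 1:
        # degenerate tie: take the candidate closest to the midpoint
        mid = n / 2
        candidates = candidates[np.argsort(np.abs(candidates - mid), kind="stable")]
        if score.min() == best:
            logger.warning("chen_bisection: fully degenerate cut; splitting at midpoint")
    return int(candidates[0])


def chen_bisection(
    cm: ContactMatrix,
    nb: int,
    connectivity_threshold: float = 0.5,
    min_size_bins: int = 3,
    min_row_sum: float = 0.0,
) -> Segmentation:
    """Recursive Fiedler-vector bisection of the banded contact graph.

    Starting from the whole chromosome: build the band-limited Laplacian of
    the current range's submatrix; if its Fiedler value (algebraic
    connectivity) is already >= ``connectivity_threshold`` — the region is
    well connected — or the range is shorter than ``2 * min_size_bins``,
    emit it as one TAD; otherwise cut at the position that best separates
    the signs of the Fiedler vector and recurse on both parts. Raw counts
    are preprocessed exactly as in :func:`call_tads` (filter + log), so the
    two methods are directly comparable.
    """
    work = _preprocess(cm, min_row_sum)
    n = work.n_bins
    intervals: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        size = hi - lo
        if size < 2 * min_size_bins or size < 2:
            intervals.append((lo, hi))
            return
        sub = work.values[lo:hi, lo:hi]
        lap = band_laplacian(sub, min(nb, size - 1))
        fiedler_value, v = _fiedler(lap.values)
        if fiedler_value >= connectivity_threshold:
            intervals.append((lo, hi))
            return
        cut = _best_sign_cut(v)
        cut = min(max(cut, 1), size - 1)
        recurse(lo, lo + cut)
        recurse(lo + cut, hi)

    recurse(0, n)
    return Segmentation(
        sorted(intervals),
        provenance={
            "nb": nb,
            "threshold": connectivity_threshold,
            "min_size_bins": min_size_bins,
            "method": "fiedler-bisection",
        },
    )
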