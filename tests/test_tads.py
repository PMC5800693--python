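import numpy as np
import pytest

from seqmm import (
    ContactMatrix,
    Segmentation,
    Track,
    band_laplacian,
    boundary_similarity,
    boundary_stability_scan,
    call_tads,
    chen_bisection,
    cluster_embedding,
    contiguity_split,
    estimate_tad_number,
    local_minima,
    merge_small_tads,
    spectral_embedding,
    summation_profile,
)
from seqmm.types import ConsistencyError


def _cm(values):
    return ContactMatrix(np.asarray(values, dtype=float), 100_000)


class TestEstimateTadNumber:
    @pytest.mark.parametrize(
        "n_bins,expected",
        [(351, 18), (40, 2), (10, 2)],  # 35.1 Mb / 2 Mb rounds to 18; small cases clamp
    )
    def test_arithmetic_and_clamp(self, n_bins, expected):
        assert estimate_tad_number(n_bins, 100_000, 2_000_000) == expected


class TestSpectralEmbedding:
    def test_two_cliques_separate_in_embedding(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        np.fill_diagonal(w, 0)
        emb = spectral_embedding(band_laplacian(_cm(w), 5), 2)
        rows = emb.vectors
        # rows are constant within a clique and differ across cliques
        assert np.allclose(rows[:3], rows[0], atol=1e-8)
        assert np.allclose(rows[3:], rows[3], atol=1e-8)
        assert not np.allclose(rows[0], rows[3], atol=1e-6)

    def test_connected_graph_first_eigenvector_constant(self, random_cm):
        emb = spectral_embedding(band_laplacian(random_cm, 3), 3)
        assert emb.eigenvalues[0] == pytest.approx(0.0, abs=1e-8)
        v0 = emb.vectors[:, 0]
        assert np.allclose(v0, v0[0], atol=1e-8)

    def test_scaling_spans_same_subspace(self, random_cm):
        lap = band_laplacian(random_cm, 3)
        a = spectral_embedding(lap, 3).vectors
        lap3 = band_laplacian(random_cm.with_values(3 * random_cm.values), 3)
        b = spectral_embedding(lap3, 3).vectors
        # projector onto the span must agree
        assert np.allclose(a @ a.T, b @ b.T, atol=1e-7)

    def test_orthonormal_columns(self, random_cm):
        emb = spectral_embedding(band_laplacian(random_cm, 4), 4)
        assert np.allclose(emb.vectors.T @ emb.vectors, np.eye(4), atol=1e-8)

    def test_too_many_eigenvectors_rejected(self, random_cm):
        with pytest.raises(ValueError):
            spectral_embedding(band_laplacian(random_cm, 3), random_cm.n_bins + 1)


class TestClusterEmbedding:
    def _emb(self, rows):
        from seqmm import Embedding

        rows = np.asarray(rows, dtype=float)
        return Embedding(rows, np.zeros(rows.shape[1]))

    def test_separated_groups_recovered(self):
        rows = np.array([[1.0, 0.0], [1.0, 0.01], [1.0, 1.0], [1.0, 1.01]])
        labels = cluster_embedding(self._emb(rows), 2, seed=0)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_identical_rows_degenerate(self):
        rows = np.ones((5, 2))
        labels = cluster_embedding(self._emb(rows), 2, seed=0)
        assert len(set(labels)) == 1

    def test_same_seed_same_labels(self, random_cm):
        emb = spectral_embedding(band_laplacian(random_cm, 3), 3)
        a = cluster_embedding(emb, 3, seed=5)
        b = cluster_embedding(emb, 3, seed=5)
        assert np.array_equal(a, b)


class TestContiguitySplit:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            ([0, 0, 1, 1, 0, 0], [(0, 2), (2, 4), (4, 6)]),
            ([0, 0, 0], [(0, 3)]),
            ([0, 1, 0, 1], [(0, 1), (1, 2), (2, 3), (3, 4)]),
        ],
    )
    def test_run_splitting(self, labels, expected):
        assert contiguity_split(labels).intervals == expected


class TestCallTads:
    def test_noise_free_two_blocks_exact(self, two_block_cm):
        seg = call_tads(two_block_cm, nb=20, n_c=2, seed=0)
        assert seg.intervals == [(0, 20), (20, 40)]

    def test_single_bin_matrix(self):
        seg = call_tads(_cm([[5.0]]), nb=1, n_c=2, seed=0)
        assert seg.intervals == [(0, 1)]

    def test_segmentation_invariants_and_label_count(self, two_block_cm):
        seg = call_tads(two_block_cm, nb=10, n_c=4, seed=0)
        assert seg.intervals[0][0] == 0
        assert seg.n_bins == two_block_cm.n_bins
        assert seg.n_domains >= 1
        assert seg.provenance["nb"] == 10

    def test_planted_boundaries_recovered(self):
        from seqmm import generate_hic

        cm, truth = generate_hic(
            n_bins=300, tad_sizes=[30] * 10, tad_enrichment=3.0, seed=7
        )
        seg = call_tads(cm, nb=30, n_c=10, seed=0)
        called = seg.boundaries()
        hits = sum(
            1 for t in truth.tad_boundaries if np.min(np.abs(called - t)) <= 1
        )
        assert hits >= 9


class TestMergeSmallTads:
    def test_singleton_absorbed(self, two_block_cm):
        seg = Segmentation([(0, 1), (1, 20), (20, 40)])
        merged = merge_small_tads(seg, two_block_cm, nb=10, min_bins=3)
        assert merged.intervals == [(0, 20), (20, 40)]


class TestBoundarySimilarity:
    def test_identical_segmentations(self):
        a = Segmentation([(0, 5), (5, 10)])
        assert boundary_similarity(a, a, tol_bins=0) == 1.0

    def test_disjoint_beyond_tolerance(self):
        a = Segmentation([(0, 5), (5, 20)])
        b = Segmentation([(0, 15), (15, 20)])
        assert boundary_similarity(a, b, tol_bins=1) == 0.0

    def test_partial_match_hand_enumeration(self):
        # boundaries {10, 20} vs {11, 40}: only 10<->11 matches at tol 1,
        # Jaccard = 1 / (2 + 2 - 1)
        a = Segmentation([(0, 10), (10, 20), (20, 50)])
        b = Segmentation([(0, 11), (11, 40), (40, 50)])
        assert boundary_similarity(a, b, tol_bins=1) == pytest.approx(1 / 3)

    def test_universe_mismatch_rejected(self):
        a = Segmentation([(0, 5)])
        b = Segmentation([(0, 6)])
        with pytest.raises(ConsistencyError):
            boundary_similarity(a, b, 1)


class TestBoundaryStabilityScan:
    def test_constant_nb_list_fully_similar(self, two_block_cm):
        scan = boundary_stability_scan(two_block_cm, [15, 15, 15], n_c=2, seed=0)
        assert np.allclose(scan.similarity_to_next, 1.0)

    def test_empty_list(self, two_block_cm):
        scan = boundary_stability_scan(two_block_cm, [], n_c=2, seed=0)
        assert scan.similarity_to_next.size == 0
        assert scan.boundary_sets == []


class TestSummationProfile:
    def test_all_ones_interior_value(self):
        cm = _cm(np.ones((12, 12)))
        s = summation_profile(cm, nb=6)
        assert s.values[6] == 3  # w = 3 in-bounds pairs

    def test_first_bin_has_no_pairs(self, random_cm):
        s = summation_profile(random_cm, nb=6)
        assert s.values[0] == 0

    def test_single_offdiagonal_entry(self):
        m = np.zeros((5, 5))
        m[1, 3] = m[3, 1] = 7.0
        s = summation_profile(_cm(m), nb=4)
        assert s.values[2] == 7
        assert np.sum(s.values) == 7

    def test_small_band_rejected(self, random_cm):
        with pytest.raises(ValueError):
            summation_profile(random_cm, nb=1)


class TestLocalMinima:
    @pytest.mark.parametrize(
        "track,expected",
        [
            ([3, 1, 3], [1]),
            ([1, 2, 3, 4], []),
            ([5, 2, 2, 5], [1]),  # plateau counts once at its left edge
            ([5, 2, 2, 0, 4], [3]),  # plateau not flanked by larger values
        ],
    )
    def test_minima_rules(self, track, expected):
        assert list(local_minima(Track(track))) == expected

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            local_minima(Track([1, 2]))


class TestChenBisection:
    def test_two_blocks_split_exactly(self, two_block_cm):
        seg = chen_bisection(two_block_cm, nb=20, connectivity_threshold=0.5)
        assert (0, 20) in seg.intervals and (20, 40) in seg.intervals

    def test_uniform_connected_matrix_single_tad(self):
        from seqmm import log_transform

        cm = _cm(np.full((12, 12), 5.0))
        # oracle: algebraic connectivity of the preprocessed (log) graph
        lap = band_laplacian(log_transform(cm), 11)
        fiedler = np.sort(np.linalg.eigvalsh(lap.values))[1]
        seg = chen_bisection(cm, nb=11, connectivity_threshold=fiedler / 2)
        assert seg.intervals == [(0, 12)]

    def test_min_size_guard(self, two_block_cm):
        seg = chen_bisection(
            two_block_cm, nb=20, connectivity_threshold=0.5,
            min_size_bins=two_block_cm.n_bins,
        )
        assert seg.intervals == [(0, 40)]

    def test_agrees_with_band_spectral_on_blocks(self, two_block_cm):
        a = call_tads(two_block_cm, nb=20, n_c=2, seed=0)
        b = chen_bisection(two_block_cm, nb=20, connectivity_threshold=0.5)
        assert a.intervals == b.intervals
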