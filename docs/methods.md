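# Methods

## The two band-parameterized models

Let `M` be an `n × n` symmetric contact matrix for one chromosome at bin
size `b` (bp). The sequential scale parameter `N_b` (bins) corresponds to
a genomic distance `N_b · b`.

**Band removal (compartments).** `M^rm_ij = M_ij` if `|i − j| ≥ N_b`,
else 0. The strict inequality is on the removed side, so `N_b = 0` is the
identity and `N_b = 1` removes only the main diagonal. Compartment calls
are the sign of the first principal component (FPC) of the
observed/expected-normalized matrix: columns are centered and the leading
right singular vector taken, unit-normalized, with the largest-magnitude
entry made positive so results are deterministic. The FPC could
equivalently be taken from the row-correlation matrix
(`correlation_matrix` is provided for that variant and for display);
the direct-PCA route is the default because it is the construction the
robustness scan perturbs.

**Band-limited Laplacian (TADs).** `W_ij = M'_ij` for `0 < |i − j| ≤ N_b`,
else 0, where `M' = log(1 + M)` of raw counts, and `L = D − W` with
`D_ii = Σ_j W_ij`. The main diagonal never enters `W`. Note the two
models' band conventions are intentionally asymmetric (removal zeroes
`< N_b`; the Laplacian keeps `≤ N_b`), so at equal `N_b` they differ on
the `|i − j| = N_b` diagonal. `L` is the *positive semidefinite*
orientation of the weighted Laplacian: eigenvectors of its smallest
eigenvalues are the low-frequency modes of the banded contact graph, and
the second-smallest eigenvalue is the Fiedler value (algebraic
connectivity). An equivalent formulation with the opposite global sign
has the same eigenvectors with the eigenvalue order reversed; the PSD
convention is used because it is the numerically standard one.

## TAD calling pipeline

1. **Filter** rows/columns with sum ≤ `min_row_sum` (default 0 —
   unobserved bins only; the cutoff is user-settable). The surviving
   bins' original indices are kept so output coordinates refer to the
   original genome.
2. **Transform** counts by `log(1 + x)` (natural log; the base only
   rescales all weights uniformly). The transformed values act as
   *affinity* weights — larger contact ⇒ stronger edge — which is what a
   Laplacian needs; the log tames the heavy-tailed count distribution.
3. **Embed** each bin as its row in the eigenvectors of the `N_c`
   smallest eigenvalues of `L`. The trivial near-constant eigenvector is
   kept: it is harmless to K-means and becomes a component indicator
   (hence essential) when the banded graph is disconnected. `N_c`
   defaults to `max(2, round(n · b / 2 Mb))` — chromosome length over a
   typical 2 Mb TAD.
4. **Cluster** with K-means (`k = N_c`, 10 restarts, fixed seed, best
   inertia kept). Embedding rows are scaled to unit Euclidean norm
   first: end-of-chromosome bins have roughly half the band degree of
   interior bins, which makes low eigenvectors spike there; without the
   renormalization K-means spends clusters on those few bins at large
   `N_b` and the boundary calls destabilize in exactly the regime that
   should be stable.
5. **Split** each cluster into maximal runs of consecutive bins; every
   run is one TAD. The final TAD count therefore usually exceeds `N_c`.
   No minimum TAD size is enforced by default; `merge_small_tads`
   (CLI `--min-tad-bins`) optionally absorbs short intervals into the
   neighbor with the larger mean within-band contact.

**Stability scan.** TADs are called per `N_b` with fixed `N_c` and seed;
adjacent boundary sets are compared by a Jaccard index after greedy
one-to-one matching within ± `tol` bins. Similarity is low while
`N_b` is below the typical TAD size (the band then cuts through the
domains that define the boundaries) and high above it.

**Summation profile.** `S(i) = Σ_{k=1..w} M[i−k, i+k]` with
`w = floor(N_b / 2)`, so every summed pair stays inside the
`|i − j| ≤ N_b` band; out-of-range pairs are skipped, so edge bins use
truncated sums (bin 0 gets 0). Local minima are positions with a strict
drop from the left whose plateau of equal values is followed by a strict
rise; the leftmost plateau point counts once and endpoints are excluded.
The perpendicular-sum window arithmetic (`floor(N_b/2)` pairs) is a
declared convention — only the band width itself is canonical.

**Fiedler-bisection baseline.** Recursively: compute the band Laplacian
of the current range's submatrix; if its Fiedler value is at or above
`connectivity_threshold` (the region is internally well connected) or
the range is shorter than `2 · min_size_bins`, emit it as one TAD;
otherwise cut at the position that maximizes sign agreement of the
Fiedler vector on both sides (ties resolve toward the midpoint, logged)
and recurse. For disconnected regions the two smallest eigenvectors span
the component indicators, so the second eigenvector is re-centered
(mean-subtracted) before taking signs; for connected regions this is a
no-op since the Fiedler vector is already orthogonal to the constant
vector. Preprocessing is identical to the main pipeline so the two
methods are directly comparable. The stopping rule — stop when
connectivity is *high* — is the published criterion for this family of
methods; the default threshold 0.5 (on log-count weights) is a
convenience default, and the two-block acceptance check is
threshold-insensitive because a disconnected region has Fiedler value 0.

## Normalizations

**Observed/expected ("Toeplitz") normalization** divides entry `(i, j)`
by the mean of all entries at offset `|i − j|` (offsets measured over
retained bins). Each offset-diagonal of the output has mean exactly 1
where the expected value is positive; all-zero diagonals stay zero.
Compartment analysis always normalizes first (the distance-decay trend
otherwise dominates the first principal component); TAD calling uses
log-transformed raw counts — whether to normalize before the Laplacian
is genuinely open, and the default keeps the decay because it encodes
the sequential locality the local-scale model is built on. Both choices
are overridable (`--normalize`, `--transform` flags).

No ICE/KR balancing is implemented; observed/expected is the only
normalization the methods here require.

## Rigidity weights and the two-scale demonstration

For 3D point data (atoms, reconstructed loci), Gaussian rigidity weights
`W_ij = exp(−(r_ij/η)²)` convert Euclidean distances into affinities;
`η` (default demonstrations use 8 Å, an atomic-scale influence range)
controls the kernel width. On a synthetic double helix — two intertwined
antiparallel chains, numbered up chain A then down chain B, B-DNA-like
proportions (radius 4, pitch 12, 10 points per turn) — 2-way spectral
clustering of the *banded* weight graph recovers the two chains exactly
(the band keeps only along-chain edges plus the top junction where the
numbering crosses), while clustering the *full* weight matrix splits the
structure across the helix axis, mixing both chains in each cluster.
The demonstration band must stay below the points-per-turn scale
(nb = 4 is used); wider bands blur the junction between the chains.

## Synthetic data generator

Expected contact
`λ_ij = depth · (1 + |i−j|)^(−α) · e_TAD(i,j) · e_comp(i,j)`, with
`e_TAD = enrichment` when i, j share a planted TAD (else 1) and
`e_comp = 1 + s` for equal compartment signs, `1/(1 + s)` otherwise.
Counts are independent Poisson draws for `i ≤ j`, mirrored — the
simplest generative model consistent with count data. Defaults:
`n = 300` bins at 100 kb, `α = 1`, `enrichment = 3`, `depth = 50`,
alternating compartment blocks; a desk-scale stand-in for a ~30 Mb
chromosome arm at typical sequencing depth, sized so every test and the
acceptance script run in seconds on one CPU. `expected_hic` returns the
noise-free `λ` matrix for checks that must not depend on sampling.

What the generator does *not* emulate: loop/corner peaks, nested or
hierarchical domains, trans contacts, coverage biases (so no balancing
is needed), and non-Poisson overdispersion. Passing tests therefore show
the pipelines recover block-diagonal enrichment and checkerboard sign
structure under Poisson noise — not that they are robust to every
artifact of real Hi-C libraries.

## Numerical conventions and edge cases

* Matrices are symmetrized on read by `(M + Mᵀ)/2` (logged when the
  asymmetry exceeds 1e-8); negative or NaN inputs are rejected.
* Coordinates are 0-based half-open everywhere (BED convention). BED
  output maps each retained bin to its own original interval; gaps from
  filtered bins are not re-inflated, to avoid claiming domain membership
  for unobserved bins.
* Eigenvector signs are fixed per column (largest-magnitude entry
  positive); principal-component comparisons use absolute PCC, which is
  invariant to the remaining ambiguity.
* Zero-variance rows get correlation 0 off-diagonal (not NaN) so
  spectral code downstream stays total.
* An all-zero matrix raises a degenerate-input error from the FPC; the
  band-size scan records NaN for such scales and continues.
* K-means degenerate cases (identical embedding rows) collapse to fewer
  effective clusters with a logged warning.

## Known limitations

* Single-chromosome, intra-chromosomal analysis only; no genome-wide
  assembly or inter-chromosomal compartments.
* Compartment labels are ±1 sign states; assigning biological A/B
  identity requires external covariates (gene density, expression) that
  are out of scope.
* The combinatorial Laplacian is the only graph operator (no
  random-walk or symmetric normalization), and TAD output is flat —
  no nested domain hierarchy.
* Dense in-memory matrices throughout: fine for per-chromosome maps at
  ≥ 100 kb resolution (n ≲ a few thousand), not for 1 kb genome-wide
  work.
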