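# seqmm — sequence-based multiscale analysis of Hi-C contact maps

`seqmm` analyzes a chromosome's Hi-C contact matrix at a tunable
*sequential* scale: a band size `N_b` (in bins) selects which range of
genomic distances `|i − j| · bin_size` enters the model. Two complementary
constructions cover the two levels of chromosome organization:

* **Band removal (global scale → A/B compartments).** Zero the diagonal
  band `|i − j| < N_b` of the observed/expected-normalized matrix
  `M^Seq_ij = M_ij · 1[|i−j| ≥ N_b]` and take the first principal
  component (FPC) of the result. The sign pattern of the FPC is the A/B
  compartment call. Because compartments are a global spatial feature,
  the FPC is nearly unchanged even when a wide band of short-range
  contacts is removed — `seqmm scan-fpc` quantifies this robustness as
  |PCC| against the full-matrix FPC per band size.
* **Band-limited weighted Laplacian (local scale → TADs).** Keep only the
  band `0 < |i − j| ≤ N_b` as graph weights `W` (after `log(1+x)` of raw
  counts) and build the combinatorial Laplacian `L = D − W`. Topologically
  associating domains (TADs) are called by K-means on the eigenvectors of
  the `N_c` smallest eigenvalues of `L`, followed by splitting each
  cluster into sequentially contiguous runs. Boundary calls stabilize
  once `N_b` exceeds the typical TAD size (`seqmm scan-tads`), and fall
  at local minima of the perpendicular summation profile
  `S(i) = Σ_k M[i−k, i+k]`.

A recursive Fiedler-vector bisection baseline (`seqmm chen`) and a
seeded synthetic-matrix generator with planted TADs and checkerboard
compartments (`seqmm simulate`) round out the toolkit, so everything is
testable offline. Intended users: computational biologists exploring
chromosome architecture from per-chromosome contact matrices at ~100 kb
resolution.

## Worked example

Simulate a 120-bin (12 Mb at 100 kb) chromosome with four planted 30-bin
TADs and call them back:

```sh
$ seqmm simulate --n-bins 120 --tad-size 30 --enrichment 3 --seed 7 \
      --out sim.txt --truth truth.json
simulated 120x120 matrix -> sim.txt
$ seqmm tads --matrix sim.txt --bin-size 100000 --chrom chrS --nb 30 \
      --nc 4 --seed 0 --out tads.bed
called 4 TADs over 120 bins -> tads.bed
$ cat tads.bed
chrS	0	3000000
chrS	3000000	6000000
chrS	6000000	9000000
chrS	9000000	12000000
```

The four BED intervals are the called TADs in genomic coordinates; their
internal boundaries (bins 30, 60, 90) match `truth.json` exactly. The
stability scan shows the boundary calls settling once the band covers a
whole TAD (similarity is the tolerance-1 Jaccard overlap of adjacent
rows' boundary sets):

```sh
$ seqmm scan-tads --matrix sim.txt --nb-min 10 --nb-max 40 --nb-step 10 \
      --nc 4 --out stab.tsv
$ cat stab.tsv
nb	n_tads	boundaries	similarity_to_next
10	4	29,60,92	0.5000
20	4	30,60,90	1.0000
30	4	30,60,90	1.0000
40	4	30,60,90	nan
```

Compartments work the same way from the library or via
`seqmm compartments` / `seqmm scan-fpc`, writing per-bin FPC values as
bedGraph and the robustness curve as TSV.

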