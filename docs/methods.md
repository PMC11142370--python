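# Methods

## Interaction models and tests

Genotypes are coded as minor-allele counts g ∈ {0, 1, 2}.  Two pair
encodings are supported:

* **Cartesian**: code(g₁, g₂) = g₁·g₂, values in {0,…,4}.  The product
  correlates with each genotype, so a Cartesian interaction leaks a
  marginal single-locus signal.
* **XOR**: code(g₁, g₂) = 1[g₁=1] ⊕ 1[g₂=1], the classic symmetric XOR
  penetrance table [[0,1,0],[1,0,1],[0,1,0]] over (g₁, g₂).  At MAF 0.5
  under HWE, the heterozygosity indicator is Bernoulli(½) independent of
  the other locus, so E[code | g₁] = ½ for every g₁: the model has exactly
  zero marginal effect and is invisible to any single-locus analysis.
  The encoding is pluggable (`epinet.synth.PAIR_CODES`), so an alternative
  penetrance table can be substituted without touching the scan.

Three-locus generalizations are the direct parity (1[g₁=1] ⊕ 1[g₂=1] ⊕
1[g₃=1]) and product (g₁·g₂·g₃) forms, consistent with the pair codes.

The pair test fits `y ~ 1 + g₁ + g₂ + code(g₁,g₂)` by ordinary least
squares on pairwise-complete individuals (missing genotype calls and
non-finite phenotypes dropped per pair) and reports the two-sided t-test
p-value of the code coefficient.  The three-way test adds the three main
effects, the three pairwise codes and the three-locus code, and tests the
last.  The OLS solve is a direct normal-equations implementation for scan
throughput; the test suite verifies its p-values against statsmodels OLS
to 1e-8 relative.  Rank-deficient designs (constant column, collinear
code) yield p = 1 with a `degenerate` flag instead of an exception, so a
full scan never aborts on one bad pair.  No covariates are adjusted by
default.

MAF pruning keeps columns with empirical MAF ≥ the threshold (inclusive
boundary; default 0.05).  Benjamini–Hochberg FDR is applied across all
hypotheses of a single scan; pairs and triangle 3-way tests form separate
BH families.  Adjusted p-values are the edge weights used downstream.

## Network construction and threshold selection

The network N = {V, E, τ} admits an edge when its FDR-adjusted p-value
ω(e) ≤ τ (inclusive); V contains exactly the endpoints of admitted edges.
Duplicate entries for an unordered pair collapse to the smallest weight.
Weight–τ comparisons use a 1e-9 *relative* closeness guard: a weight equal
to the printed threshold up to float representation is admitted, but at
τ = 0 only weights exactly 0 pass (an absolute epsilon would silently
admit arbitrarily small positive weights).

Modularity with resolution γ (default 1) is

    Q = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j)

summed over ordered node pairs including i = j with A_ii = 0.  The public
`modularity()` evaluates this definition directly (dense, vectorized); the
community-detection path uses the algebraically identical per-community
form Σ_c [l_c/m − γ(d_c/2m)²], and a property test asserts the two agree
to 1e-12 on random partitions.

Community detection is greedy agglomeration (Clauset–Newman–Moore):
singleton start, repeatedly apply the merge with maximal
ΔQ = l_uv/m − γ d_u d_v / 2m², stop when no merge increases Q (best gain
≤ 1e-12, guarding float noise on gains that are exactly zero in exact
arithmetic).  Tie-breaks take the lexicographically smallest community-id
pair, with initial ids assigned in sorted locus order, so the partition is
deterministic.  Returned community ids are relabeled 0,1,… by descending
size.  Greedy detection is a heuristic: tests verify it attains the
exhaustive-search optimum on the small planted fixtures and never exceeds
it elsewhere, but on general graphs it may return a suboptimal partition.

The τ-sweep runs from 0 in 0.0001 steps up to the first grid point at or
above the maximum observed weight, so the final grid point contains every
input pair.  Each grid point records node/edge/component/triangle counts
and the greedy Q (defined as 0 for an edge-free network); τ* is the
*smallest* grid τ attaining the maximum Q, preferring sparser networks
when Q ties — note that for weight sets whose networks never develop
community structure (e.g. a single edge, or one balanced triangle) Q is 0
everywhere and τ* is therefore 0, an empty network.  Consumers that need
a non-empty network (comparison, enrichment export) should use either the
τ* network when non-empty or the saturated all-pairs network; the
acceptance script uses the saturated convention for its comparison stage.
Metrics are computed with networkx (components, triangle counts); a
brute-force triple enumeration cross-checks triangles in the tests.

## Network comparison

Nodes n₁ = (c₁, p₁) and n₂ = (c₂, p₂) match within tolerance δ iff
c₁ = c₂ and |p₁ − p₂| ≤ δ.  The inclusive inequality is deliberate: δ = 0
then means "exact coordinate", and exact-overlap counts at δ = 0 are
symmetric between the two directions.  Chromosome labels are normalized
("chr1" ≡ "1") before comparison.  Edges match when endpoints match
pairwise in either orientation.  Matching is existential (an element is
matched if any counterpart matches), hence directional: percentages are
against the querying network's own totals, and the a→b and b→a tables
differ in general.

Community similarity from C_a to C_b is Λ(δ) = the number of C_a nodes
with at least one δ-match in C_b; Λ is non-decreasing in δ and bounded by
|C_a|.  Its area under the curve on the grid δ_min + k·s, k = 0…M+1 with
M = (δ_max − δ_min)/s − 1, is

    AUC = Σ_{k=0..M} [Λ(δ_min+ks) + Λ(δ_min+(k+1)s)] / (2(M+1)),

normalized by |C_a|.  This printed form (divisor 2(M+1) with M one less
than the number of steps) is implemented literally rather than replaced by
a conventional trapezoid rule; on the default grid (0…10 Mb, s = 1 Mb) it
averages 10 trapezoid terms over 11 Λ evaluations, and AUC_norm ∈ [0, 1]
with 1 iff Λ saturates at every grid point.  Tolerance queries use
per-chromosome sorted position arrays (binary search); a quadratic
all-pairs oracle confirms the counts in tests.

## Triangle motifs and 3-way testing

Triangles are unordered node triples with all three edges present, each
enumerated once in sorted-locus order.  Each is classified by chromosome
dispersion (`all_same_chromosome` / `two_shared` / `all_different`); a
single-chromosome triangle with span ≤ 2 Mb (configurable) is flagged cis
— co-located triangles are more plausibly linkage-disequilibrium artifacts
than genuine trans epistasis, and the 2 Mb default reflects the ~1.6 Mb
span typical of such LD clusters.  Every triangle is then re-tested with
the explicit three-way model; BH runs across the triangle set only.  The
significant triangles can be exported as a multigraph with one parallel
edge per containing triangle, so shared pairs show their multiplicity.

## Synthetic data: what it emulates, and what it does not

The generator draws each SNP column i.i.d. from HWE proportions
((1−q)², 2q(1−q), q²) and builds the phenotype as a sum of planted
interaction codes times effect sizes β plus Normal(0, σ²) noise.  Defaults
used across the tests and the acceptance script: MAF q = 0.5 (the regime
in which XOR is exactly marginal-null), β = 1.0–1.5 against σ = 0.5–0.6,
cohort sizes n = 300–500 and 12–21 SNPs for the scan-level simulations —
sizes chosen so that a planted effect is comfortably but not trivially
detectable and a full scan remains a few-second computation.  Genotype and
phenotype noise streams are seeded separately from one spec seed;
identical spec + seed reproduce bit-identical data.

The generator deliberately omits several features of real outbred-cohort
data: linkage disequilibrium between loci (columns are independent),
relatedness/population structure, missing genotype calls (readers accept
them; the simulator never emits them), covariates, and main effects other
than the leakage implied by the planted codes.  Passing tests therefore
demonstrate correctness of the statistical machinery and the network
algorithms under the stated model, not robustness to confounding in real
genotype panels — in particular, positional-tolerance matching is
motivated by LD that the simulator itself does not generate.

## Numerical conventions and edge cases

* p-values are validated to [0, 1] at every boundary (readers, BH,
  result types); malformed pair-table rows fail with the line number.
* Locus ordering is numeric-aware on chromosome labels (chr2 < chr10,
  numeric before alphabetic), giving deterministic, byte-identical
  exports.
* Empty networks: metrics are all zero, Q is 0 by convention in sweeps;
  community detection on an empty network is an error.
* Genotype coordinates are 1-based inclusive; enrichment ranges are
  SNP ± flank with the start clamped at 1 and degenerate ranges (flank 0)
  skipped with a warning.
* `pairwise_scan` output is sorted by (p_adj, locus keys); BH ties make
  this a total, reproducible order.

## Limitations

Greedy modularity maximization is order-dependent and resolution-limited;
γ is exposed but only γ = 1 is exercised by the tests.  The sweep
re-detects communities per distinct edge set along the grid (cached), so
very large pair tables with many distinct weights can be slow.  The scan
is O(m²) in SNP count by design (exhaustive testing); genome-scale runs
(10⁴ SNPs, ~5·10⁷ pairs) are feasible only with external parallelization,
which this package does not provide.
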