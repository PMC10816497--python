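# Methods

## The model

`peakmotifs` re-implements an exhaustive de novo motif-discovery scheme for
ChIP-seq peak sequences, together with its two downstream analyses: a linear
model of peak scores on motif presence, and a phi-coefficient co-occurrence
analysis of transcription-factor binding sites with a shuffling null.

A motif is a degenerate consensus of fixed length k written in the 15-letter
IUPAC code. Each letter is encoded as a 4-bit nibble with one bit per
admitted base — bit order (C, G, T, A) from most to least significant, so
A→0001, T→0010, G→0100, C→1000, W→0011, N→1111 — and a motif packs its k
nibbles into one integer, first position most significant. Every length-k
window of an A/C/G/T sequence is packed the same way, and

    match  ⇔  (window AND motif) == window,

one AND and one comparison per window, exactly equivalent to per-position
set membership. Reverse-strand occurrences are found by matching the
reverse-complement motif against the forward encoding, which is identical to
scanning the other strand. A palindromic motif therefore counts each
matching window once per strand; presence (≥ 1 hit), the quantity used by
every downstream stage, is unaffected.

### Selection criterion

Given N sequences of length L, a motif with n containing sequences is
reported when all three conditions hold strictly:

* F = n/N > f₀    (abundance; default f₀ = 0.01),
* Q < q₀          (expected abundance; default q₀ = 0.30),
* P_Bonf(n, N) < p₀ (default p₀ = 0.01),

where P_Bonf is the upper binomial tail P(X ≥ n), X ~ Binomial(N, Q),
multiplied by the number M of candidate motifs that survive the Q filter.
M is computed once per run and kept fixed across greedy iterations.

### Expected abundance Q

The background is an order-m Markov chain (m ∈ 0..3, default 3) fitted on
the forward strands of the input with an additive pseudocount (default 1);
window positions with fewer than m predecessors back off to the lower-order
conditionals. The probability p_w that one window matches the motif is
computed by dynamic programming over positions with the last min(m, i) bases
as state — never by expanding the up-to-4^k word list. Q then treats the
L−k+1 windows as independent:

    single strand:  Q = 1 − (1 − p_w)^(L−k+1)
    both strands:   Q = 1 − [(1 − p_w)(1 − p_rc)]^(L−k+1)

Two caveats of the independence approximation are documented and tested:
overlapping windows are positively dependent (Q is slightly overestimated
for self-overlapping motifs), and on both strands a palindromic motif's two
strand events coincide, roughly doubling its nominal Q.

Both strand conventions are exposed because they serve different purposes.
When occurrences are counted on either strand (the default), the binomial
success probability must be the either-strand Q — using the single-strand Q
there is anticonservative, and with it pure-background data yields dozens of
spurious "significant" motifs. `MotifDiscovery` therefore defaults to
`q_strands="both"`. The single-strand form is retained as the convention
of the original GPU implementation this package re-creates: it reproduces
that tool's published three-fold reduction of the k=8 candidate space at
q₀ = 30% (868,491,264 of 15⁸ ≈ 2.56×10⁹ candidates on uniform 201-bp
sequences — the package computes this count exactly by a small dynamic
program over the per-position degeneracy product, without enumerating the
space).

### Binomial tail at extreme significance

Discovered motifs reach tails around 10⁻¹⁵⁰⁰, far below float underflow.
For n > Nq the tail is accumulated in units of the leading term,
P(X ≥ n) = pmf(n) · Σ Π ratios with pmf ratios r < 1, entirely in log
space; for n ≤ Nq (moderate tails) scipy's survival function is used. The
result is accurate to ~10⁻¹² relative error on the log, validated against
frozen arbitrary-precision reference values down to 10⁻¹⁴⁷².

### Greedy iterative extraction

Each iteration scores all candidates, selects the smallest Bonferroni-
corrected log-probability among those satisfying the criterion, records its
statistics, and masks every window matching the selected motif (both
strands) in every sequence before the next iteration. Q and M are not
recomputed after masking — only the abundance n changes. Ties are broken by
larger n, then the lexicographically smallest motif, making runs fully
deterministic. Because a window's content alone determines whether it
matches, masking is maintained at the level of distinct window words with
per-sequence presence bitsets, which makes rescoring after masking cheap.

Two search strategies:

* **exhaustive** — enumerate all 15^k motifs (lexicographic order), filter
  by Q, score the survivors. Cost grows as 15^k; allowed up to k = 6
  (~1.1×10⁷ candidates) and guarded beyond that (`allow_large=True`). This
  is the reference behaviour, and at k = 3 it is verified motif-for-motif
  against an independent brute-force re-scanner.
* **hillclimb** — the desk-scale strategy for k ≥ 7 on one CPU. Local
  searches are seeded from the most overrepresented exact words observed in
  the data (ranked by their own binomial tails) and move by single-letter
  substitutions accepted when they improve the corrected significance
  subject to Q < q₀. M is the exact uniform-background Q-filter count when
  applicable, otherwise a seeded Monte-Carlo estimate of it. This finds
  strongly enriched consensi without touching all 2.6×10⁹ candidates at
  k = 8; it is a documented approximation, not an exhaustive guarantee, and
  is the honest limit of a CPU implementation of a method designed for
  GPUs. On the synthetic pioneer-factor set it recovers the planted
  degenerate consensus exactly (as its reverse complement, equivalent under
  both-strand scanning), plus the planted partner motifs verbatim.

## Peak-score regression

ln(PS) = B₀ + Σ Bᵢ Xᵢ + e, fitted by OLS (statsmodels behind
`PeakScoreRegression`). Xᵢ is motif presence (0/1, either strand) by
default; per-sequence occurrence counts are available as an alternative
predictor mode — presence is the primary convention, counts are reported to
give slightly different (typically slightly worse) predictions, and the two
coincide whenever no motif occurs more than once. Scores must be positive
and are otherwise treated as opaque (no assumption about the peak caller).
Exact-duplicate and constant columns are dropped with a warning before
fitting; coefficient p-values use the t distribution on N−p−1 df.
Predictive power is summarised by the Pearson correlation r between
observed and predicted ln(PS), with Bonferroni adjustment over the number
of evaluation sets considered together. Calibration is verified by
simulation: 95% CI coverage of true coefficients at N=2000, σ=0.3 (200
replicates) and a ~5% significant-coefficient rate under an all-zero model.

## Co-occurrence and the shuffling null

Motif presence vectors (either strand, no masking) give 2×2 tables per
motif pair; phi = (ad−bc)/√((a+b)(c+d)(a+c)(b+d)), identical to the Pearson
correlation of the binary indicators. The pairwise matrix uses the
chi-square approximation (phi²·N, 1 df) for its significance mask; pairs
with a zero marginal are flagged NaN, not zeroed. TF-level presence is the
union over the motifs annotated to that TF via a user-supplied motif→TF
map (PWM-database annotation is out of scope; the map is an input).

Significance against nucleotide composition uses mononucleotide shuffling:
each replicate permutes the letters within every sequence independently,
preserving each sequence's length and composition exactly. Motifs whose
real abundance does not strictly exceed the shuffled abundance in at least
95% of replicates are discarded; with the retained motifs, the empirical
p-value of a partner TF is the proportion of replicates with
|phi_null| > |phi_real| (strictly greater, following the wording of the
procedure this re-implements; an observed 0 means p < 1/reps, and the
report carries that floor explicitly). Replicates with an undefined phi
never count as exceeding. Default 10,000 replicates; analyses in the test
suite scale this down to 100–500.

A calibration subtlety: under a pure-composition null the abundance filter
(correctly) retains almost nothing, so the uniformity of the empirical p is
verified in the exchangeable configuration — random sequences, filter
bypassed via `filter_motifs=False` — where each sequence is exchangeable
with its own shuffles and the p-values are uniform by construction (KS
check in the test suite). The ~5% null retention rate of the filter is
asserted separately.

## Synthetic data

The generator emulates fixed-width summit windows (default L = 201, the
inclusive [−100, +100] region; the convention "200 vs 201" is not fixed by
the emulated protocol, 201 was chosen and documented). Background sequence
comes from the Markov chain (uniform by default); each plant is carried
with a per-sequence probability, realised as one word drawn uniformly from
the motif's expansion, reverse-complemented with the strand probability
(default 0.5) and written at a uniform position, overwriting the background
so L stays fixed (overlaps between plants are counted and reported; they
are rare at the default densities). Conditional plants (`co_with`)
produce co-occurring sites. Scores follow PS = exp(B₀ + Σ Bᵢ Xᵢ + ε),
ε ~ N(0, σ²), the same linear model the regression stage fits, so σ = 0
recovers the betas exactly.

Named fixtures define the study conditions used by the tests:

* `mini` — N=60, L=30, one planted 3-letter consensus (TGW at 0.6): small
  enough for full brute-force cross-validation at k=3.
* `foxa2_like` — N=500 (a 10× scale-down of the emulated 5000-sequence
  training sets), L=201, a strong forkhead-style plant TRTWKACH at
  probability 0.67 (the abundance the emulated pioneer-factor set shows),
  plus two weaker partner plants (nuclear-receptor-like RGGTCAAR and
  GC-box-like GGGCGGRR) planted conditionally on the target to create
  co-occurrence; betas (3.2, 0.5, 0.25, 0.20), σ = 0.5, giving training
  correlations in the 0.4–0.6 range.
* `null` — N=200, L=50, no plants.

What the generator does **not** emulate: read-level signal, peak calling,
score distributions of any specific caller, positional preference of sites
relative to summits, flanking-sequence heterogeneity, or overlapping/
clustered real binding sites. Passing tests therefore demonstrate that the
machinery is correct and calibrated under the stated generative model, not
that any particular biological dataset will yield particular motifs.

## Numerical and procedural choices

* Strict inequalities throughout the selection criterion, as specified.
* Background fitted on forward strands only; strandedness enters through
  p_rc in Q and through reverse-complement matching in counting.
* Unseen contexts at pseudocount 0 fall back to a uniform conditional.
* Binomial-tail series truncates when the running term falls below 1e-17
  of the accumulated sum; ordering ties on the corrected log-probability
  are resolved by larger n, then lexicographic motif order.
* Score ties at a training/control split boundary keep input order.
* BED input is 0-based half-open; only name and score columns are read.
* Sequences must be pure A/C/G/T (case-folded); records with ambiguity
  letters are excluded at load time with a warning. Ambiguity codes are
  allowed only in motifs.

## Problem sizes

Test-suite and acceptance-script simulations use N = 60–2000 sequences,
L = 30–201, k = 3–8, 100–500 shuffling replicates and 3000–4000
Monte-Carlo samples — scales chosen so the whole suite runs in about a
minute on one CPU while keeping every statistical check at ≥ 3σ
resolution. The corresponding full-scale analyses (N = 5000 training
sequences, 10,000 replicates, exhaustive k = 8) are supported by the same
code paths via their parameters.

## Known limitations

* The hill-climb search can miss the global optimum that the exhaustive
  GPU enumeration guarantees; it is the documented CPU trade-off.
* Q's window-independence approximation biases Q upward for
  self-overlapping motifs and double-counts palindromes on both strands.
* M under a fitted background at k ≥ 7 is a Monte-Carlo estimate (its
  sampling error enters log10 P_Bonf only through log10 M, i.e. weakly).
* The shuffling null preserves mononucleotide composition only — a
  dinucleotide-preserving shuffle would be stricter and is not implemented.
* Empirical p-values are reported as proportions without smoothing; 0
  means "below 1/reps", and the report carries that floor.
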