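# peakmotifs

De novo discovery of degenerate (IUPAC) sequence motifs in ChIP-seq peak
sequences, with two downstream analyses: a multiple-regression model of peak
scores on motif presence, and a phi-coefficient co-occurrence analysis of
transcription-factor binding sites with a within-sequence shuffling null.

It is written for regulatory genomicists who have a set of fixed-width peak
sequences (e.g. the [−100, +100] windows around ChIP-seq peak summits) with
per-peak scores, and who want (a) every significantly overrepresented
consensus of a fixed length k in the 15-letter IUPAC alphabet, (b) how much
of the peak-score variation those motifs explain, and (c) which motifs —
hence which co-binding partner TFs — co-occur in the same peaks.

## The method

A motif of length k (default 8) is a word over {A,C,G,T, R,Y,M,K,W,S,
B,D,H,V, N}. Each letter becomes a 4-bit code with one bit per admitted
base (A→0001, T→0010, G→0100, C→1000, …, N→1111); a motif packs k such
nibbles into one integer, and so does every window of every peak sequence,
so a window matches a motif iff `(window & motif) == window` — one bitwise
AND per comparison. Both strands are scanned by matching the
reverse-complement motif against the forward encoding.

A motif occurring in n of N sequences is significant when, strictly,

* F = n/N > f₀ (default 1%),
* Q < q₀ (default 30%), where Q is the probability that a background
  sequence of the same length contains the motif at least once, under an
  order-m Markov model (m ≤ 3) fitted to the peaks, and
* P_Bonf(n, N) < p₀ (default 0.01), the upper binomial tail P(X ≥ n) with
  X ~ Binomial(N, Q), Bonferroni-multiplied by the number M of candidate
  motifs surviving the Q filter.

Discovery is iterative and greedy: the most significant motif is reported,
every window matching it is masked in every sequence, and the scan repeats
until nothing satisfies the criterion. All 15^k candidates are enumerated
exhaustively up to k = 6; for longer motifs a seeded hill-climb search over
the motif space stands in for the full enumeration (see
`docs/methods.md`). Tails are computed in log space and remain accurate at
the 10⁻¹⁵⁰⁰ scale such data produce.

Downstream, ln(peak score) is regressed on motif presence indicators by
OLS (Y = B₀ + B₁X₁ + … + e), and TF-level co-occurrence is measured by the
phi coefficient of 2×2 presence tables, with empirical p-values from
shuffling the nucleotides within each sequence (composition-preserving).

## Worked example

Everything below is produced by the built-in synthetic generator — no
downloads. The `foxa2_like` fixture emulates a pioneer-factor peak set: 500
sequences of 201 bp with the forkhead-style consensus TRTWKACH planted in
67% of them and two weaker partner motifs planted preferentially in the
same peaks, with scores from the ln-linear model.

```python
import peakmotifs as pm

fx = pm.make_fixture("foxa2_like", seed=1)
disc = pm.MotifDiscovery(k=8, max_iterations=3, random_state=0).fit(fx.sequences)
print(disc.report_)
```

```
   motif   n   N     F      Q  minus_log10_P_Bonf  iteration
DGTMWAYA 337 500 0.674 0.1949            110.3445          0
RGGTCAAR 168 500 0.336 0.0403             94.4470          1
GTMWAYAN 341 500 0.682 0.2448             84.7073          2
```

The top motif DGTMWAYA is exactly the reverse complement of the planted
TRTWKACH (equivalent under both-strand scanning) and is found in 67% of the
peaks at −log₁₀ P_Bonf ≈ 110; iteration 1 recovers the partner motif
RGGTCAAR verbatim; iteration 2 picks up a shifted variant of the target, as
exhaustive enumeration characteristically does.

```python
motifs = [p.motif for p in fx.spec.plants]
fit, X, y = pm.fit_peak_score_model(fx.sequences, fx.scores, motifs)
print(fit.summary_frame())
print(pm.evaluate_correlation(y, fit.predict(X)))
```

```
     term  coefficient  std_error       t  p_value
intercept       3.2117     0.0429 74.9372      0.0
 TRTWKACH       0.4592     0.0524  8.7708      0.0
 RGGTCAAR       0.2673     0.0513  5.2107      0.0
 GGGCGGRR       0.2694     0.0535  5.0400      0.0
training r = 0.519
```

The fitted coefficients recover the generating betas (3.2, 0.5, 0.25,
0.20) within their standard errors, and predicted vs observed ln(PS)
correlate at r = 0.52.

```python
res = pm.shuffle_significance(
    fx.sequences, motifs,
    {motifs[0]: "TARGET", motifs[1]: "PARTNER1", motifs[2]: "PARTNER2"},
    target_tf="TARGET", reps=500, seed=1)
print(res.table())
```

```
partner_tf    phi  empirical_p  p_floor  replicates
  PARTNER1 0.2508          0.0    0.002         500
  PARTNER2 0.1662          0.0    0.002         500
```

Both planted partners co-occur with the target (phi = 0.25 and 0.17), and
no shuffled replicate reaches those values (empirical p below the 1/500
floor).

The same pipeline is available from a shell:

```
peakmotifs simulate --fixture foxa2_like --seed 1 --out-dir sim
peakmotifs discover --fasta sim/peaks.fasta --k 8 --out-dir disc
peakmotifs regress  --fasta sim/peaks.fasta --scores sim/scores.tsv \
                    --motifs disc/motifs.tsv --out-dir reg
peakmotifs cooccur  --fasta sim/peaks.fasta --motifs disc/motifs.tsv \
                    --map map.tsv --target-tf TARGET --out-dir co
peakmotifs split    --fasta sim/peaks.fasta --scores sim/scores.tsv --n-train 250
```

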