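# Methods

This note records the statistical model behind `codonscan`, the design
choices that are this package's own, and their numerical rationale.

## 1. Codon-pair log-odds matrix

Training data are in-frame pairwise alignments of orthologous coding
sequences. Consecutive column triplets are counted as aligned codon pairs;
any gap or ambiguity character in either triplet excludes that column, and a
trailing partial triplet is ignored. Counts are symmetrized,
`q ∝ (c + cᵀ)/2`, because the direction of the genome comparison is
arbitrary, and a pseudocount (default 0.5 per cell, with the normalizer
adjusted so frequencies still sum to 1) keeps unobserved pairs finite.

The score of a codon pair is the natural-log odds

    S(a, b) = ln( q(a, b) / e(a, b) ),   a = x₁x₂x₃, b = y₁y₂y₃,

with the expectation built from the same training columns:

    e(a, b) = p(x₁, y₁) · p(x₂, y₂) · p(x₃, y₃),

where `p` is the 4×4 matrix of observed aligned nucleotide-pair frequencies
pooled (averaged) over the three codon positions, computed directly from `q`.

### Why the expectation is a nucleotide-pair product

The obvious alternative — the product of marginal codon frequencies,
`e = f(a)·f(b)` — makes the method unusable, and we rejected it on
quantitative grounds:

* Under `f(a)·f(b)`, an *identical* codon pair scores
  `ln(P(identity|pair)/f(a)) ≈ +3.5` nats, because training alignments are
  ~75–90 % identical at the codon level while any single codon frequency is
  ~1/61. Score then measures similarity, not coding structure.
* A realistic non-coding null (70 % nucleotide identity → ~34 % codon
  identity) consequently has *positive* expected segment score (measured
  +0.27 nats/codon at a 2-million-codon training volume). Karlin–Altschul
  statistics require negative drift; the exponential score distribution the
  calibration fits does not exist, and no decay constant `a` can satisfy
  `E[exp(a·S)] = 1` (with 34 % of pairs at +3.5 nats,
  `0.34·e^{1.2·3.5} ≫ 1`).

Dividing by the per-site pair expectation instead cancels overall similarity
and base composition exactly, leaving only the *within-codon pattern*: how
the three aligned sites behave jointly relative to sites behaving
independently. Measured on synthetic training data, the expected score is
−1.61 nats/codon under the null and +0.62 nats/codon under the coding
distribution (the latter is `KL(q‖e) > 0` by construction). Identity runs in
diverged non-coding homology are near score-neutral; the third-position-biased
synonymous pattern of real coding alignments is what scores.

Scores are kept in nats as floats; no integer rescaling. The matrix TSV
serializes scores to 17 significant digits together with the codon marginals,
the pooled nucleotide-pair frequencies, the pseudocount and a provenance
string, so a round trip is byte-stable.

## 2. Six-framing segment search

Both rows of a pairwise DNA alignment are read in reading frames 0/1/2 on the
given strand and, after reverse-complementing both rows together, frames
0/1/2 on the opposite strand. Columns containing a gap (`-`, `.`) or
ambiguity code in either row split the alignment into clean blocks; codon
framing restarts at each block boundary, so phase stays defined without gap
penalties and segments never span an indel.

Within one framing the region score is the sum of codon-pair scores, and the
reported objects are all *locally maximal* positive segments — segments whose
score cannot be improved by extending or shortening either end and which are
not contained in a higher-scoring such segment. These are enumerated exactly
with the linear-time Ruzzo–Tompa all-maximal-scoring-subsequences algorithm
(consecutive same-sign scores are collapsed into runs first; a maximal
segment always contains whole positive runs). The implementation is verified
against a quadratic brute-force oracle that applies the definition directly
(prefix-sum strict minimum/maximum conditions plus a containment filter).

## 3. Karlin–Altschul calibration by simulation

Null model: an ancestral sequence drawn i.i.d. with P(G)=P(C)=GC/2, then
exactly `round(divergence·L)` positions (uniform, without replacement)
replaced by a different base. Defaults: GC 40 %, divergence 30 %, searched
as 100 sequences × 100 kb.

**Replacement kernel (own design).** The natural recipe — redraw the new
base from the background composition restricted to the three alternatives —
does *not* preserve GC content: at GC = 0.40 the mutated sites end at
GC ≈ 0.443, shifting whole-row GC to ≈ 0.413, more than 3 standard errors
over 100 kb. We instead use the zero-diagonal kernel whose replacement
distribution, averaged over the stationary composition, equals the stationary
composition itself, so expected GC is preserved exactly. Among such kernels
the maximum-entropy one is chosen (a one-dimensional root-find); at GC = 0.5
it reduces to the uniform choice over the three alternatives.

**Fitting.** Null alignments are scanned with the very same six-framing
search used on queries, so the six-fold search multiplicity is absorbed into
`k`. All locally maximal segment scores are pooled and binned (width 1 nat);
the natural log of the bin proportions is regressed against the bin centers
by ordinary least squares. Bins holding fewer than 10 segments are excluded:
a near-empty tail bin carries a log proportion with ~unit sampling error and
would get full leverage on the slope (including them biased a known decay of
1.219 to a fitted 1.41 at 10⁴ draws). Count-weighted regression was tried
and rejected — it hands the fit to the lowest-score bins, where short
segments have not yet reached the exponential asymptotic regime, and made the
resulting P-values anti-conservative on fresh null data. Then

    a = −slope,
    k = exp(intercept) · M / (n_seq · N · 2·sinh(a·w/2)),

where `M` is the number of pooled segments, `N` the per-sequence search
length in nucleotides and `w` the bin width (the `sinh` factor converts a bin
mass to the density of the exceedance law `P = k·N·exp(−a·S)`).

**Self-consistency (measured).** With a matrix trained on 2,000 × 260-codon
synthetic alignments and a 100 × 10 kb null: `k = 0.357`, `a = 1.063`,
`r² = 0.994`; on 200 fresh null sequences the best-segment P-value fell below
0.05 in 12 cases and below 0.01 in 4 — inside the binomial 95 % intervals.
P-values are computed as `min(1, k·N·exp(−a·S))` with `N` the nucleotide
length of the region actually searched.

## 4. Exon filtering and evaluation

A predicted exon (0-based half-open interval on the ungapped target row) is
mapped to its alignment window (optional flank), the window is scanned in all
six framings, and the best locally maximal segment score is converted to a
P-value with `N` = window length. The exon passes iff a positive segment
exists and `P ≤ α` (default 0.01). Truth labels use same-strand overlap of
at least 1 bp with an annotated exon (boundary mismatches accepted).

The evaluation table reports PPV = TP/(TP+FP), sensitivity = TP/(TP+FN) and
a false-positive rate with denominator **TP+FN**, reproducing the printed
formula of the source method; the conventional FP/(FP+TN) is reported
alongside wherever TN is countable (nucleotide level). The filtering effect
is tested with a Pearson chi-square (1 df, no continuity correction) on the
2×2 TP/FP table before vs after. On the published-scale counts
(1818/1243 before, 1345/262 after) this statistic is 284.92; an independent
hand computation is asserted in the tests.

## 5. Synthetic generators and their limits

The coding generator draws ancestral codons from a usage distribution
(uniform over the 61 sense codons by default) and, per codon, applies one
synonymous codon exchange with probability 0.4 and one amino-acid-changing
single-nucleotide substitution with probability 0.05, rejecting stops. This
reproduces the qualitative signature the matrix needs — synonymous far
outnumbering nonsynonymous changes, differences concentrated at the third
position — but it is not a time-reversible codon model: there is no rate
matrix, no transition/transversion bias, and no site-rate variation. Mosaics
are coding blocks spliced into null background at exact boundaries — no
splice sites, introns or UTR structure. Conclusions drawn from mosaics are
therefore about the statistical machinery, not about biological realism.

Problem sizes used in tests and the acceptance script (training corpus of
2,000 × 260 codons ≈ 520 k codon pairs, calibration on 100 × 100 kb,
200 fresh null sequences, 20 mosaic seeds) are this package's choices,
selected so every stage has stable statistics yet the full suite runs on one
CPU in minutes.

## 6. Numerical choices

* All randomness flows through `numpy.random.Generator`; every pipeline
  stage is byte-reproducible per seed (checksum manifest in the fixture
  bundle).
* Scores are float64 nats end to end; segment scores are sums of matrix
  cells, so implementation and oracle agree to 1e-9 absolute.
* OLS via `scipy.stats.linregress`; kernel root-find via
  `scipy.optimize.brentq`; chi-square via
  `scipy.stats.chi2_contingency(correction=False)`.
* With pseudocount 0 an unobserved codon pair scores −inf, which is
  propagated deliberately (such a segment can never be locally maximal).
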