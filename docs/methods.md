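# Methods

## Model and procedure

`thintail` treats a DNA sequence as a bag of overlapping *m*-letter windows
on a single strand. Every distinct window word is a **seed-word**; its
**similar-word set** is the full Hamming ball of words within *j*
substitutions over {A, C, G, T}, a crude but assumption-light model of a
binding-site motif family. The family's occurrence count *n* is the number
of window positions whose word belongs to the set, overlaps allowed.

The null model is a Bernoulli sequence: i.i.d. letters drawn with the input
sequence's own mononucleotide frequencies. Under this null the occurrence
count of a word set over the N = L − m + 1 windows has exact moments

    E = N·P,   P = Σ_{w ∈ set} p(w)
    V = N·P(1 − P) + 2 Σ_{d=1}^{min(m−1, N−1)} (N − d)·Cov_d
    Cov_d = Σ_{w, w′: w[d:] = w′[:m−d]} p(w)·p(w′[m−d:]) − P²

where the covariance at window offset d runs over every ordered pair of
members whose overlap is compatible, the merged (m+d)-letter word's
probability factorizing under independent letters. This
indicator-covariance expansion is exact at finite L (no asymptotics, edge
windows handled by the (N − d) pair counts) and is verified against an
exhaustive enumeration oracle (every sequence of length L, weighted by its
probability) to ~1e-14 across randomized binary- and four-letter instances.
Self-overlap covariance is why periodic words (AAAAA, CACAC) get inflated V
and hence damped Z — the feature that de-emphasizes simple repeats.

Per sequence, the Z = (n − E)/√V values of all M seed-words form the
**Z profile**; its excess kurtosis

    k = Σᵢ (Zᵢ − μ)⁴ / ((M − 1)·σ⁴) − 3

uses the sample mean and the sample standard deviation (denominator M − 1)
of the Z values. The histogram f(Z) (bin width 0.5, bins centered at 0) is
exported for inspection only; the coefficients never depend on binning.

Two coefficients rescale k₀, the kurtosis of the original sequence:

* **E = (k₀ + 2ε)/(4ε)** with ε = √(c/M). It linearly maps the ±2ε
  normality band of the kurtosis onto [0, 1], so E ≈ 0.5 is
  normal-shaped, E < 0 decisively thin-tailed, E > 1 decisively
  fat-tailed. The constant defaults to c = 26; the classical normal-theory
  standard error of excess kurtosis would use c = 24 and is available via
  `epsilon_constant=24` (results state which constant was used).
* **T_r = (k₀ − mean(k₁..k_r)) / sd(k₁..k_r)** over r = 50 independent
  letter-permutation shuffles (Fisher–Yates, seeded), which preserve the
  mononucleotide composition exactly, hence also the null moments.
  Sample standard deviation (denominator r − 1) throughout; the analogous
  fluffy-tail statistic F_r uses the same construction on the tail
  statistic L (by default the occurrence count of the most abundant
  family; the `count_at_max` reading is available and recorded in output).

Decision rules use strict inequalities: CRM iff (E < 0.6 and T_r < 0), NCNR
iff (E > 0.6 and T_r > 0), otherwise indeterminate; F_r > 2 calls CRM for
the baseline. The evaluation harness scores indeterminate predictions
against the predictor (false negative on a true CRM, false positive on a
true background) and reports their count; `which="crm_call"` instead applies
the binary operational rule (predicted CRM iff E < 0.6 and T < 0, everything
else not-CRM), which is how a two-class screening deployment would use the
test.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| m | 5 | word length (bases); core binding sites are short |
| j | 1 | allowed substitutions defining a family |
| r | 50 | shuffles for T_r and F_r; sd of T stabilizes ∝ 1/√r |
| c | 26 | radicand constant in ε = √(c/M) (24 = classical) |
| tE, tT, tF | 0.6, 0, 2 | decision thresholds |
| counting mode | occurrences | window positions in the family; `distinct_words` counts distinct member words (ceiling 16 at m=5, j=1) |
| include_cross | true | full member-pair covariance in V; false keeps only self-overlap terms |

Seeds with numerically zero variance (degenerate compositions) are dropped
from the profile and counted; kurtosis requires at least 4 defined-Z seeds.
Degenerate shuffles are redrawn a bounded number of times and logged.

## What the synthetic generator emulates — and what it cannot

`synthetic_data` builds **CRM-like** records as i.i.d. background with
mutated copies of several 5-letter consensus motifs planted at
non-overlapping positions (one family per emulated transcription factor),
and **background** records as pure i.i.d. draws. Benchmark defaults: length
1000–1650, 4–8 motif families per record, 8–15 copies per family, 10–20%
per-letter mutation, uniform composition. These were frozen after a design
study, before the acceptance measurements, as a plausible density for
site-rich enhancers (roughly 15–45% site coverage).

The generator deliberately emulates only the clustering of degenerate
sites. It does **not** simulate repeat content, dinucleotide structure, or
any real enhancer grammar. That has a measurable consequence worth being
explicit about: planted families form a smeared, one-sided *right* tail in
the Z profile — the family group's internal spread is comparable to its
separation, at every density the placement constraint allows — so planted
sequences are *leptokurtic* relative to i.i.d. background. On this synthetic
benchmark the fluffy-tail F direction (larger for planted sequences)
reproduces cleanly, while the thin-tail direction reported for real corpora
(CRMs *platykurtic* relative to non-regulatory regions) does not: in real
data the fat-tailed class is the negative one, driven largely by repetitive
elements (a planted poly-A or CA tract sends k₀ to +15 or more in this
implementation), and real regulatory regions are merely close to null.
Passing the synthetic suite therefore validates the machinery — counts,
moments, coefficients, calibration and the harness — not the real-data
separation direction, which requires sequence features the generator
excludes. A side observation from the same study: under the cardinality
counting mode (`distinct_words`, where a family's count saturates at 16),
planted sequences do become mildly platykurtic, because saturation
compresses the right tail; the occurrence mode remains the default because
it is the one consistent with the occurrence moments above.

## Numerical choices

* All randomness flows through `numpy.random.Generator`; every public
  entry point takes a seed or generator, and batch runs derive one child
  seed per record so results do not depend on batch composition.
* Equal shuffle statistics raise an "undefined" error rather than dividing
  by a numerically tiny sd; boundary ties on thresholds classify as
  indeterminate (strict inequalities).
* The enumeration oracle is guarded at 10⁷ states; the vectorized batch
  moment path chunks the member-pair tensor at 512 seeds to bound memory,
  and is pinned against the readable per-pair reference implementation in
  the tests.
* Problem sizes in the test suite and acceptance script (null calibration
  at L = 500 with 200/100 replicates; Monte-Carlo at L = 2000 with 5000
  simulations; a 60+60 benchmark at r = 50) were chosen to give stable
  statistics at desk scale; all are parameters, not constants.

## Known limitations

* Single-strand counting only; no reverse-complement folding, no IUPAC
  degenerate consensi, no sliding-window localization of modules within
  long sequences — the unit of classification is the whole input record.
* The null is Bernoulli with mononucleotide composition; no Markov
  (dinucleotide) null, and only the first two moments (no exact p-values
  for word counts).
* The fluffy-tail baseline implements the statistic as described above for
  head-to-head comparison; it is not a line-by-line port of the original
  fluffy-tail software, and both plausible readings of its tail statistic
  are implemented and recorded in the output.
* The kurtosis standard error ε = √(26/M) treats the Z values as
  independent; in truth neighboring families share windows, so ε is
  approximate and E is a screening index, not a calibrated p-value.
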