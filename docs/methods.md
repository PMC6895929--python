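# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Read preprocessing

Reads are processed adapter → quality → length. Adapter contamination
in small-RNA protocols is 3'-terminal read-through into the ligation
adapter, so adapter removal must precede quality trimming (a read whose
adapter-proximal bases are low quality is trimmed identically either
way; this is asserted in the tests). Matching is exact: the longest
read suffix equal to an adapter prefix (≥ 4 nt overlap), or any full
internal adapter occurrence, is removed. Quality trimming is
3'-suffix-only: bases are removed until the terminal base reaches
Q ≥ 20 (Sanger Phred+33). No sliding-window rule is applied. The
length filter keeps 17–35 nt inclusive. Reads containing N are dropped.
Each input read increments exactly one counter (kept, short, long,
empty-after-trim, N), and the accounting identity is checked on every
library.

## Alignment and counting

Alignment is ungapped end-to-end with at most one substitution
(configurable): 17–35 nt reads essentially never require gaps, and
ungapped scoring keeps the aligner exactly equivalent to a brute-force
Hamming scan, which the tests exploit as an oracle. Candidate loci come
from a k-mer index (k = 8 by default); seeding uses max_mismatch + 1
non-overlapping k-mers, which by the pigeonhole principle is complete
whenever k ≤ ⌊L/(max_mismatch+1)⌋.

Pass 1 searches the mature-miRNA reference (forward strand only — small
RNA reads are sense), then tRNA, rRNA and adapter references; a read is
assigned to the best class, ties broken miRNA > tRNA > rRNA > adapter.
A read hitting several mature miRNAs equally well contributes 1/n to
each; fractions are rounded only at reporting. Pass 2 maps the
leftovers to the genome (both strands). A genome hit with ≥ 90% of the
read inside an annotated miRNA locus on the same strand increments that
miRNA's count — this reproduces the two-aligner count adjustment of
reference-first pipelines, and it is how reads that extend a mature
sequence beyond the reference entry (length isoforms) are recovered.
Remaining genome hits are retained for novel-miRNA discovery; reads
hitting nothing are counted unmapped.

Library summaries report each class as a raw count and as a percentage
of preprocessed reads, rounded half-up to 2 decimals (4 for the adapter
class, whose fractions are tiny). The additive identity
mapped_total = miRNA + tRNA + rRNA + adapter is asserted on every
summary.

## Differential expression

The model is the classic negative-binomial exact test for two-condition
count data:

* **Size factors** — median over genes with all-positive counts of
  count/geometric-mean. Factors are defined relative to this
  pseudo-reference, so only factor *ratios* are identifiable; the tests
  assert scale equivariance in ratio form.
* **Dispersion** — per-gene method of moments on common-scale counts,
  α̂ = max(0, (v − μ̄ξ)/μ̄²) with v the pooled within-group variance and
  ξ the mean reciprocal size factor; a lowess trend of α̂ against
  log₁₀ mean is fitted and the working dispersion is
  max(per-gene, trend) — the conservative sharing rule. With fewer than
  10 positive genes the trend degenerates to the median.
* **Exact test** — conditional on the total K = K_A + K_B of a gene,
  the two condition sums are modelled NB with means q₀·Σs_j and
  variances q₀Σs_j + αq₀²Σs_j²; the two-sided p-value sums the
  probabilities of all splits no more likely than the observed one
  (a 1 + 10⁻¹⁰ relative tolerance guards ties in the pmf comparison).
  As α → 0 this reduces to the conditional binomial test, verified by
  enumeration. Sums are computed over the full 0..K support with
  vectorised pmfs, so no truncation tolerance is needed.
* **Calls** — p < 0.05 raw, fold change ≥ 2 (or ≤ ½) on common-scale
  means, and a max-raw-count ≥ 3 input filter. When a condition mean is
  zero, 0.5 is added to both means before forming the ratio.
  Benjamini–Hochberg q-values are reported but never gate calls.

## RNA folding

`fold.py` implements a Zuker-style minimum-free-energy dynamic program
(O(n³), no pseudoknots) over a nearest-neighbor model: Watson-Crick
stack energies from the published Turner parameter set, approximate
G:U wobble stacks clamped at ≤ 0, tabulated hairpin/bulge/internal
loop initiations with Jacobson–Stockmayer extrapolation
(1.75·RT·ln(n/n₀)), loop asymmetry 0.5/nt capped at 3.0, a linear
multiloop model (a = 3.4, b = 0.4 per branch, c = 0 per unpaired), a
minimum hairpin loop of 3 nt, and interior loops capped at 30 unpaired
bases. There are no dangling ends, coaxial stacks, or special hairpin
tables, and no terminal-AU penalty: reproducing any particular
folding program's energies is explicitly not the goal — the pipeline's
decisions depend only on a −20 kcal/mol threshold, which a 30 bp
planted stem clears by a wide margin.

The same energy functions score an explicit dot-bracket structure, so
the DP is verified by re-scoring its own traceback (equality within
10⁻⁶ across 1000 random sequences), and its pair count is bounded by an
independent Nussinov maximum-pairing DP.

Duplex (intermolecular) energies for target sites reuse the stack and
loop tables with no intramolecular pairing and no initiation term; two
strands with no complementarity score exactly 0.

## Novel miRNA discovery

Genome hits outside annotated miRNA loci are merged into same-strand
clusters (gap ≤ 10 nt). Clusters need ≥ 4 reads summed across samples
("across the samples" is read as summed, not per-sample). The putative
mature is the **modal read** (most frequent sequence/position), not the
merged-read envelope — a single stray fragment within merge distance
must not stretch the mature span. Overlap with a known miRNA locus
discards a cluster; overlap with any other annotation (tRNA/rRNA) only
flags it, mirroring how tRNA-overlapping candidates are reported but
set aside.

Two excision windows per cluster pin the mature near the 5' or the 3'
end (10 nt pad on the mature side, 70 nt flank on the other), matching
the ~60–110 nt span of animal precursors. Because the window carries
arbitrary flanking genome sequence, the folded window is trimmed to the
outermost stem-loop branch containing the mature and re-folded before
the criteria are applied; otherwise a detached 5-bp hairpin in random
flank would veto genuine precursors. The three criteria, all inclusive
at their boundaries: ΔG ≤ −20 kcal/mol; exactly one hairpin loop;
≥ 75% of mature bases paired with every partner on the opposite arm.
The best-scoring window per cluster is kept.

## Target prediction

The seed is miRNA bases 2–8 (1-based from the 5' end, 7 nt); a site
requires its exact reverse complement on the UTR — no G:U, no
mismatches. Around each seed match a window extending to cover the
miRNA 3' end (plus 8 nt gap allowance) is scored by affine-gap local
alignment of the reversed miRNA against the window: complementary
match +5 (×4 at seed positions), G:U +1 outside the seed (a seed G:U
scores as a mismatch), mismatch −3, gap open −9, gap extend −4. A fully
complementary 22-mer scores 5·15 + 20·7 = 215; a seed-only match scores
140 and so fails the ≥ 150 gate — the 3' region must contribute. The
duplex MFE of miRNA vs window must be ≤ −20 kcal/mol. Both thresholds
are inclusive. Expression pairing emits (miRNA, target) pairs whose
calls move in opposite directions; genes targeted by more than one
miRNA are flagged.

## Clinical statistics

Group tests run on log2(expression + 1) — the moderated t assumes
roughly Gaussian log expression and the cohort simulator produces
log-normal values. Patients with truncating p53 are excluded from
mutant-vs-wild-type comparisons (only missense mutants carry
gain-of-function activity); miRNAs need read coverage ≥ 2.

* **Outlier screen** — complete-linkage Euclidean clustering; samples
  in singleton branches above a cut at mean + 3·SD of the merge heights
  are flagged. The cut rule is this package's own choice: 2 SD flags a
  spurious sample in ~15–20% of homogeneous cohorts, 3 SD keeps that
  below ~5% while still catching gross outliers.
* **Moderated t** — limma-style empirical Bayes: the prior (d₀, s₀²)
  comes from a method-of-moments fit on log sample variances (trigamma
  inversion by Newton iteration); the posterior variance is
  (d₀s₀² + d·s²)/(d₀ + d) with d₀ + d degrees of freedom. d₀ = 0
  recovers the ordinary t exactly; d₀ = ∞ uses the prior exactly.
* **Mann–Whitney** — exact enumeration when there are no ties and
  n_A·n_B ≤ 400, else the tie-corrected normal approximation with
  continuity correction (delegated to scipy; the exact 3-vs-3
  enumeration p = 0.1 is asserted in tests).
* **ROC** — AUC = (concordant + ½ ties)/(n₊n₋), identical to
  U/(n₊n₋); p-value vs AUC = 0.5 from the Mann–Whitney approximation.
* **Survival** — product-limit Kaplan–Meier (median = smallest t with
  Ŝ(t) ≤ 0.5, undefined if never reached); Mantel–Cox log-rank with
  hypergeometric variance; hazard ratio as (O_A/E_A)/(O_B/E_B) — the
  estimate survival-plotting software reports — rather than Cox
  regression. Expression splits use linear-interpolation quantiles
  with inclusive ≥ 75th / ≤ 25th boundaries; the middle half is
  excluded.
* **EMT** — epithelial iff log2(E-cadherin/Vimentin) > 0; equality is
  mesenchymal (strict inequality, documented tie rule).

Two-sided tests throughout; no multiplicity correction on the small
clinical panels (raw p is the reported quantity).

## Synthetic data

The generator is the package's specification of its study conditions:

* **Toy genome** (default 1 × 50 kb): planted hairpins have a random
  30 bp 5' arm, an 8 nt loop and an exact reverse-complement 3' arm;
  up to three G:C pairs of the non-mature arm are then converted to
  G:U wobbles (C→T). The wobbles keep the stem (G:U pairs in folding)
  but break the exact arm palindrome, so mature reads map uniquely —
  real precursor stems are imperfect for the same reason. The mature
  (22 nt) occupies the outer end of one arm. tRNA (75 nt) and rRNA
  (120 nt) decoy loci are planted and emitted as references. Loci are
  non-overlapping with a 150 nt guard.
* **Reads** (default 5000/library, 2 conditions × 2 replicates):
  per-miRNA counts are NB with variance μ + αμ² (α = 0.05) around
  Dirichlet-weighted means; planted fold changes multiply the means in
  the mutant condition. Reads carry ±2 nt 3' length jitter taken from
  genomic context, 3' adapter read-through up to the 35 nt instrument
  length, and Phred qualities decaying 0.3 units/base from Q38 with
  Gaussian noise. Class fractions: miRNA 0.77, tRNA 0.04, rRNA 0.005,
  adapter dimers 0.002, genomic intergenic noise 0.01 — the remaining
  ~17% are unmappable junk reads. This split is deliberate: the real
  unmapped fraction of a library does not map to the genome, whereas
  on a 50 kb toy genome a comparable mass of genomic noise would chain
  into spurious ≥ 4-read clusters that a 3 Gb genome never produces.
  A planted novel hairpin receives Poisson(3) reads per library.
* **Cohort** (default n = 200): p53 status Bernoulli (35% mutant, 15%
  of those truncating), log-normal expression (log2 SD 1.0) with
  planted log2 shifts in missense mutants, node status Bernoulli (38%
  positive, 3% unknown) with planted shifts in node-positive patients,
  exponential survival (baseline median 36 months) with each
  planted-HR miRNA multiplying the hazard of its above-median
  expressors, and uniform-backdating censoring at rate 0.3.

What the generator does **not** emulate: sequencing errors beyond
quality decay, flow-space (Ion Torrent) artifacts, isomiR biogenesis,
multi-isoform UTRs, correlated expression between miRNAs, competing
risks, or cohort-level confounding. Passing tests therefore demonstrate
algorithmic correctness and calibration under the stated generative
model, not robustness to every artifact of real libraries.

## Problem sizes and determinism

Default validation runs use a 50 kb genome, ~5000 reads/library and a
200-patient cohort; the calibration suites use 2000 null genes for the
exact test and 20 seeds for the uniformity checks, and the hazard-ratio
recovery uses 200 replicates of 100 patients/arm. These sizes give
stable statistics while keeping a full run in seconds. Every stochastic
step draws from `numpy.random.default_rng` seeded explicitly; the
pipeline derives per-stage seeds from one master seed via
`SeedSequence`, so identical configurations reproduce byte-identical
outputs.

## Known limitations

* The folding energies are Turner-like, not any specific program's;
  absolute ΔG values should be compared only against this package's
  own model.
* The exact test enumerates the full 0..K support; for very deep
  libraries (K ≫ 10⁵) this is slower than a normal approximation.
* The O/E hazard ratio is biased toward the null relative to Cox
  regression for strong effects; it is reported because it matches the
  convention of the survival-plotting software whose output it mirrors.
* Multi-mapping resolution is fractional rather than EM-based.
* The duplex model has no initiation or terminal-AU terms, so duplex
  ΔG values are slightly more negative than Turner-complete values.
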