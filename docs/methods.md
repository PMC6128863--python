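# Methods

## The setting

The pipeline analyses digital gene expression (DGE) count libraries from
four ordered flower-development stages (BD, BB, EB, FB) of a de novo
assembled transcriptome, with a small number of replicate libraries per
stage.  Three sequential comparisons — early (BD→BB), middle (BB→EB) and
mature (EB→FB) — structure all downstream reporting.  Gene-level units
("unigenes") are opaque identifiers with a known transcript length; no
genome annotation is assumed.

## Expression quantification

RPKM_gs = 10⁹ · C_gs / (N_s · L_g), where N_s is the column sum of the
count table.  The true "million mapped reads" denominator is an alignment
statistic that is not recoverable from a count table, so the column sum is
used as the standard surrogate; RPKM is invariant to doubling every count
in a sample, which the tests verify.  Expression calls use the stage mean
of replicate RPKM with a strict threshold (expressed iff RPKM > 0.1).  The
sharing (Venn) partition assigns every gene expressed anywhere to exactly
one stage combination.

## Differential expression

The test is the 2010-generation negative-binomial exact test, implemented
here in full rather than delegated, because its internals are the point of
the module:

- **Normalization.** Median-of-ratios size factors over genes with nonzero
  counts in every library; a `pseudo_reference` fallback (geometric mean
  over positive entries only) is available for sparse data.
- **Dispersion.** Per gene and condition, the method-of-moments estimate
  α̂ = max(0, (v − μ)/μ²) from normalized counts across replicates,
  averaged over conditions; a mean–dispersion trend is fitted as the
  median α̂ within ~10 equal-occupancy bins of log₁₀ mean expression, and
  the final per-gene α is max(α̂, trend).  Take-maximum sharing is
  deliberately conservative with two replicates.
- **Exact test.** Conditional on the total T = K_A + K_B of the
  per-condition count sums, the two-sided p-value sums the probabilities
  of all splits (a, T−a) no more probable than the observed one,
  normalized by the total over all splits.  Each condition sum is modelled
  as NB with mean q·S (q = T/(S_A+S_B), S the summed size factors) and
  variance assembled per library, q·S + α·q²·Σ_s sf_s², matched to an NB
  by moments.  α = 0 degenerates to Poisson, where the test is exactly
  the two-sided conditional Binomial(T, ½) test — the oracle the
  acceptance suite enumerates to 1e−9 for all T ≤ 50.
- **Calling.** Fold change is the later/earlier ratio of normalized stage
  means with 0/0 → 1 and x/0 → +∞ (no pseudocount, so the gate stays
  interpretable); BH step-up q-values; a DEU is q < 0.01 and FC > 2 or
  FC < ½, both strict.  "Up-regulated" always means higher in the later
  stage of the pair.

Under null simulation (no planted effects, α = 0.1, two replicates, 2000
genes, five seeds) the raw p < 0.05 fraction sits near 0.056 — the mild
excess over 0.05 reflects moment-estimated dispersions with two replicates
— and essentially nothing (≲10⁻⁴) passes the joint DEU gates.

The family-level comparison (are flavonoid structural genes expressed
above the transcriptome background?) is a one-sided Wilcoxon rank-sum
test: exact enumeration for combined n ≤ 12 without ties, otherwise the
normal approximation with midranks and tie correction (scipy's
`mannwhitneyu` supplies both regimes).

## Pattern scores

Per gene, the ordered triple over the three phases with +1 for an up
call, −1 for down, 0 for none, e.g. {1,0,0} for a gene induced only
between the first two stages.  The triple representation (rather than a
cumulative running score) is used because only values in {−1, 0, +1} are
meaningful per phase.  Tabulation per family reports the count of genes
per (family, pattern) and the number of distinct patterns per family;
genes without a family label fall under "unassigned".

## GO enrichment

Hypergeometric with GO-term *occurrences* as the sampling unit: N = all
annotations in the universe, m = occurrences of one term, n = annotations
among DEUs, k = occurrences of the term among DEUs.  Two p-value modes are
exposed side by side:

- `upper_tail` (default): p = Σ_{i≥k} f(i; n, m, N) — the standard
  over-representation tail.
- `as_printed`: p = 1 − f(k; n, m, N) — the single-point complement some
  pipelines report.  It is **not** a tail probability (it is close to 1
  precisely when the observed k is individually unlikely, in either
  direction) and is retained only for comparability.

A `count_unit="genes"` option counts distinct genes instead of
occurrences.  BH correction is applied across the terms present in the
DEU set; terms absent from the DEU set would all receive p = 1 under the
upper tail and are omitted from the table.

## Co-expression motifs

Profiles are log₂(normalized count + 1) across all replicate libraries
(eight points with four stages × two replicates).  Replicate-level
profiles are the default because with only four stage means, R = 0.8 can
never reach p ≤ 0.01 under the t test — the two published thresholds are
only jointly satisfiable with replicates.  For each
(structural, regulator) pair, Pearson's R and the two-sided p from
t = R·√((n−2)/(1−R²)) on n−2 df are computed; among pairs with R ≥ 0.8
and p ≤ 0.01 the regulator with maximal R is retained per structural gene
("positive maximum"), and symmetrically the minimal-R regulator among
those with R ≤ −0.8 ("negative maximum").  Ties break lexicographically
by regulator id.  Retention is scoped per structural gene across all
candidate regulators; per-family scoping is a plausible alternative
reading of "maximum retained" and can be emulated by calling
`build_motifs` per family.  Replicate concordance QC reports Pearson R
between replicate libraries of a stage on the log₂(x+1) scale.

## qPCR

2^−ΔΔCt with replicates averaged on the Ct scale before ΔCt (the standard
convention; geometric averaging of relative quantities is the main
alternative), amplification efficiency fixed at 2, calibrator defaulting
to the earliest stage.  The calibrator stage maps to exactly 1.0 for every
gene and a global Ct shift cancels in the double difference — both exact
identities in the test suite.  Concordance with RNA-seq uses Pearson R on
log₂(x + 0.01) profiles plus a coarse pattern-agreement flag (sign of the
stage-to-stage change matches in all but at most one transition).

## Synthetic data

The generator emulates the structure the analysis assumes, not sequence
content: no reads, assembly or mapping are simulated.

- **Counts.** Independent NB draws per gene and library with
  var = μ + αμ² (α = 0 → Poisson), baseline means log₁₀-uniform on
  (0.5, 3.0) — i.e. ~3 to 1000 — matching the dynamic range of a typical
  DGE library; default α = 0.1, four stages × 2 replicates, 2000 genes.
- **Families.** The first genes of the catalog carry family labels with
  the structural-family sizes of the studied transcriptome (CHS 14, CHI 4,
  FNS 2, F3H 10, F3′H 7, F3′5′H 18, FLS 17, DFR 8, ANS 4, 3GT 13) and
  regulator families MYB 25, bHLH 20, WD40 37.
- **Planted DEUs.** 30 disjoint genes per phase, alternating sign, with a
  2^±3 multiplicative step applied from the later stage of the phase
  onward (a persistent step, so the change is confined to one sequential
  comparison and early-phase plantings score {±1,0,0}).  Planted genes are
  guaranteed baseline mean ≥ 50 so that recovery measures test power at
  informative counts rather than shot-noise limits.
- **GO.** Each gene draws Poisson(3) distinct terms from a 200-term
  vocabulary; five planted terms are over-assigned to planted DEUs with
  probability 0.6 each.
- **Motifs.** Six triples (structural, positive regulator, negative
  regulator) over six structural families.  Planted structural genes get
  a random stage profile (×2^N(0,1) per stage) so correlation carries
  stage signal; positive regulators copy the structural gene's realized
  counts exactly (Pearson R = +1 exactly at zero noise), negative
  regulators mirror them on the log₂ scale via y+1 = (max+1)(min+1)/(x+1)
  with integer rounding (R ≈ −0.98 … −1; exact −1 is unattainable with
  integer counts).  Multiplicative noise of sd 0.1·μ is then applied by
  default.
- **Streams.** All draws derive from one master seed through named child
  streams (lengths, GO, planting, baselines, counts, profiles, motif
  noise), so identical configurations are byte-identical and enlarging
  one component does not perturb the others.

What passing the recovery suites does **not** show: the generator has no
GC/length biases, no correlated genes outside the planted motifs, no
batch or library-preparation effects, and treats replicates generically
(the variance model does not distinguish technical from biological
replication).  Calibration and power on real libraries can differ.

## Problem sizes and numerical choices

The simulation suites use 2000 genes × 8 libraries × 5 fixed seeds per
condition, which keeps the full test suite under half a minute while
leaving Monte-Carlo margins far from the asserted bounds.  Probability
comparisons inside the exact test use a 1e−12 relative tie tolerance;
hypergeometric probabilities come from scipy's log-space implementation
and are verified against exact rationals for N ≤ 30; report rounding is
half-up to 2 decimals.  Degenerate inputs are defined explicitly: empty
count totals give p = 1, μ = 0 genes give α̂ = 0, constant profiles are
skipped with a warning in correlation steps, and genes expressed nowhere
join no Venn region.

## Known limitations

- The exact test's conditional construction assumes a shared dispersion
  per gene across conditions; strong per-condition dispersion differences
  are not modelled.
- GO enrichment does not propagate terms up the ontology DAG; a term and
  its ancestors are independent labels here.
- Motif inference is marginal correlation: it cannot distinguish direct
  regulation from co-regulation, and the retained-extreme rule keeps at
  most one regulator per sign per structural gene.
- The FASTQ filter supports the legacy Phred+64 encoding as its default
  on purpose; modern data need `offset=33`.
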