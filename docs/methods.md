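# Methods

## The calling model

Per amplicon, variant-supporting read counts in the plasma sample and in a
negative control are modelled as Poisson with exposures equal to their
informative read depths. The null hypothesis is a rate ratio of 1 against
the one-sided alternative that the sample rate is higher. Conditioning on
the total count m = k₁ + k₂ reduces the problem to a binomial: under the
null, k₁ ~ Binomial(m, p₀) with p₀ = n₁/(n₁+n₂), and the p-value is the
inclusive upper tail P(X ≥ k₁). We use the inclusive convention, standard
for exact conditional tests; at k₁ = 0 the p-value is 1 by construction.
The tail is evaluated through the regularised incomplete beta function
(`scipy.stats.binom.sf`), which is numerically stable for totals well
beyond 10⁶; the test suite cross-checks it against an independent
log-space tail summation to 10⁻¹⁰ relative error.

The Poisson (rather than a two-proportion) model is chosen because it is
discrete, behaves well when the control has zero variant reads, and
tolerates unequal depths. Overdispersion is handled structurally rather
than parametrically: with at most three controls per run there is no
information to fit a negative-binomial noise model, so the test is run
against the control with the **maximum** variant-read proportion. Ties on
proportion are broken toward the smallest control depth, which yields the
larger p₀ and therefore the more conservative p-value. This choice makes
the caller markedly conservative under the null — the empirical false-call
rate at α = 0.01 in the acceptance simulation is far below 0.01 — which is
the intended operating regime for an MRD assay, where a false positive is
costlier than a marginal loss of sensitivity.

Calling is strict (`p < α`, default α = 0.01) and gated by a 1000X depth
filter: amplicons below it are `not_called` and excluded from sample
positivity and from every metric denominator. No multiple-testing
correction is applied across amplicons or timepoints; sample positivity is
"any amplicon called", and the calibrated per-amplicon cutoff is the unit
of error control.

### Cutoff calibration

`calibrate_cutoff` sweeps the distinct observed p-values of a labelled set
(expected-positive and expected-negative amplicons) as candidate
thresholds, computes accuracy at each, and reports the first
maximum-accuracy threshold, the next larger candidate, and their geometric
midpoint as a recommended cutoff. The operating default stays 0.01 and is
user-controlled; the sweep is a diagnostic, not an auto-tuner.

## Error correction

**Consensus masking.** Mates are merged over the overlap that maximises
concordant (non-N) positions, subject to a minimum overlap (default 10 nt)
and a maximum mismatch fraction (default 0.25 — permissive, because
masking rather than rejection is the error-control mechanism). Discordant
positions become `N`; a position where exactly one mate calls `N` takes
the other mate's call; single-covered overhangs are kept unmasked. Ties
are broken by longest overlap, then leftmost offset. There is no
quality-aware consensus: masking is binary, and base qualities are ignored
throughout (the simulator writes constant Q30 strings). With independent
per-mate error rate e, a double-covered position carries a wrong call only
when both mates err identically, probability e²/3, and is masked with
probability ≈ 2e(1−e); both predictions are verified by test.

**Per-base noise filtering.** Beyond the target positions, every
non-reference base call set at every insert position can be tested against
the same base in the position's worst control (`base_noise_filter`),
zeroing call sets with p ≥ α. Positions uncovered in all controls are
tested against zero events at the smallest observed control depth (or the
sample's own depth if the controls are empty), and logged.

**Read screening.** Merged reads shorter than 40 nt are discarded;
discarded reads matching a primer-pair concatenation p + revcomp(q) within
2 mismatches are attributed to a primer dimer, crediting both primers.
Reads shorter than the concatenation are compared against its prefix but
must extend at least 4 nt into the partner primer to credit it, and when
several pairs match, the fewest-mismatch pair wins (ties: first in panel
order). Primers with dimer fractions above 20% of total reads are flagged
for removal from the multiplex.

## Counting conventions

Internal coordinates are 0-based half-open; TSV/VCF interchange is
1-based. Reads are anchored to amplicons by their forward primer (unique
match within 2 mismatches; ambiguous or unmatched reads are dropped), so
no aligner is needed for well-formed amplicon data; a SAM ingestion path
(`sam_variant_counts`, via pysam aligned pairs) accepts pre-aligned reads
instead.

At the target position, a read is variant-supporting (SNV: aligned base
equals alt; indel: the read suffix from the variant position reproduces
the alt haplotype exactly, N positions ignored), reference, "other"
(a third allele), or `N`-masked. The depth denominator n counts
variant + reference + other; `N`-masked reads support neither allele and
are removed from n so the Poisson exposures equal informative depth. For
indel targets at nonzero error rates this is slightly conservative: a
mutant read with a downstream sequencing error matches neither haplotype
exactly and falls into "other" (in n, not in k). At error rate 0 counting
is exact against simulator ground truth, by test.

## The synthetic-data generator

The generator emulates the statistical structure the caller assumes, and
its defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| substitution_rate | 2.8 × 10⁻³ /base | raw-read non-reference call regime |
| genome_equivalents | 3000 | template molecules in ~10 ng plasma DNA |
| panel size | ≤ 15 amplicons | patient panels average ~10 |
| insert length | 60-150 bp | short amplicons for fragmented cfDNA |
| dilution ratios | 1:10 … 1:2560 | nine 2-fold tumour:normal steps |
| mate_error_mode | independent | `correlated` shares error events |

Sampling is two-stage: mutant template count ~ Binomial(G, f) per
amplicon, then read pairs drawn uniformly from templates with per-base
substitution errors applied to each sequenced base. Read names encode the
amplicon, template and mutant status, giving exact ground truth. A fixed
seed yields byte-identical FASTQ (gzip members are written without
filename/mtime).

A dilution ratio "1:r" is read as tumour:normal **parts**, tumour mass
fraction d = 1/(1+r); the alternative reading d = 1/r is available via
`ratio_convention="fraction"`. Expected frequency per (amplicon, ratio) is
the mixture d·tumour_VAF + (1−d)·normal_VAF. Dilution simulations default
to genome_equivalents = 50 000: serial dilutions are prepared from tissue
DNA, which is not limited to the 10 ng plasma input, so read-sampling
noise rather than the template bottleneck should dominate there. Plasma
simulations keep G = 3000.

What the generator does **not** model: PCR-cycle error propagation and
polymerase error phylogenies, quality-score profiles, strand bias,
structural variants, amplification efficiency differences between
amplicons, and (by default) correlated mate errors. Consequently a passing
suite shows the pipeline's statistics behave as designed under the assumed
noise model; it does not certify performance on real libraries, where the
post-merge error floor is set by shared-mate errors (see the correlated
mode and `examples/error_correction_cascade.py`) and background rates vary
by sequence context.

## Reported quantities and problem sizes

`scripts/acceptance.py` recomputes, from the seed given on the command
line: (1) the template-bottleneck detection percentage at f = 0.1%,
G = 3000 over 20 000 replicate amplicons, against the closed form
1 − (1−f)^G = 95.03%; (2) the null false-call rate over 10 000 replicate
amplicons at error rate 10⁻³ and depth 5000 with three controls at the
0.01 cutoff. The dilution-linearity check in the test suite uses ten
amplicons with tumour VAFs log-spaced over 0.005-0.11, nine ratios at
5000X — enough points for stable per-amplicon correlations while keeping
the whole suite fast on one core. These sizes are the package's chosen
validation scale; all are parameters, not constants.

## Known limitations and open choices

- The per-sample "ctDNA fraction" has no canonical definition; this
  package reports the **maximum** VAF among called amplicons (robust to
  per-variant dropout and monotone in new calls), with a mean-over-called
  alternative behind `fraction_rule="mean"`. Negative samples report "ND".
- Undefined per-amplicon dilution correlations (constant observed series)
  are reported as NA but still count against the r > 0.95 fraction, so
  flat undetectable amplicons cannot inflate the linearity summary.
- Calls at exactly p = α are negative (strict inequality).
- The cancer-gene list used by priority class b of `rank_variants` is user
  configuration, not a built-in.
- The primer-anchored assignment assumes intact forward primers at the
  read 5' end; heavily trimmed or chimeric reads should go through the SAM
  path instead.
- No primer design is performed; panels are accepted as given (or
  generated synthetically).
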