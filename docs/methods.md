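# Methods

`pqtlmr` re-implements, as a tested and reusable pipeline, a proteome-wide
Mendelian-randomization (MR) workflow for drug-target discovery: circulating
proteins are screened as exposures against a disease outcome using cis-pQTL
genetic instruments, and every surviving signal is stress-tested with
direction checks, pleiotropy scans, Bayesian colocalization, replication in
an independent pQTL cohort, and a phenome-wide side-effect screen. This note
records the statistical model at each stage, the tunable parameters and
their defaults, what the synthetic-data generator does and does not emulate,
and the design choices made where the design was genuinely open.

## Data model and harmonization

Summary statistics are per-variant marginal association records
(`variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
pvalue, n[, n_case, n_control]`), read from tab-separated text with a
configurable column dialect. Effects are log odds ratios for case-control
traits and per-SD effects for quantitative (protein) traits. Only biallelic
SNPs are modelled; indels and multi-allelic rows are rejected at parse time
and counted. Positions are 1-based and cis windows are closed intervals.

Harmonization expresses the outcome record on the exposure's effect allele:
identical codings pass through; swapped codings negate the outcome beta and
complement its frequency. Palindromic variants (A/T, C/G) are
strand-ambiguous: they are kept, un-flipped, only when both studies report
frequencies on the same side of 0.5 and outside the ambiguous band
`[limit, 1-limit]` (default `palindromic_eaf_limit = 0.42`); otherwise they
are dropped. Any other allele combination is dropped as incompatible — no
strand flipping is attempted. All drop reasons are statuses carried in the
output, never exceptions. These palindromic rules are standard two-sample MR
practice and configurable; they are a convention of this package, not a
published algorithm.

## Instrument selection

For each protein, candidate instruments are filtered in order:

1. **cis restriction** — variants within `cis_radius` (default 1 Mb) of the
   gene anchor. The anchor position and radius are configuration inputs
   because cis-window conventions vary across studies.
2. **significance** — `p < 5e-8` (strict: a p exactly at the threshold is
   excluded).
3. **LD clumping** — greedy: take the smallest-p unclaimed candidate as an
   index (ties broken lexicographically by variant id, for reproducibility),
   discard every unclaimed candidate with `r² > 0.001` within 10 000 kb on
   the same chromosome, repeat. r² comes from an external reference panel
   (a haplotype matrix or a precomputed matrix).
4. **instrument strength** — F-statistic `(beta/se)² >= 10` (strict: F
   exactly 10 is retained, mirroring the "F < 10 excluded" convention).
   F is computed from the squared z-score rather than from r² and n because
   per-variant sample sizes are often unreliable in summary files; the two
   are equivalent to first order.

Tightening any threshold can only shrink the instrument set, and the
retained set is LD-independent by construction; both properties are tested
directly.

## Causal estimation

With one instrument the causal effect per SD of protein is the Wald ratio
`beta_out / beta_exp` with first-order delta-method standard error
`se_out / |beta_exp|`. With two or more, per-instrument ratios are combined
by fixed-effect inverse-variance weighting (weights `1/se_j²`,
`se = 1/sqrt(Σ w_j)`). Two-sided p-values use the standard normal. Effects
on disease are reported as odds ratios per SD with 95% CIs using the
multiplier 1.959964. Fixed-effect IVW was chosen because cis-instrumented
proteins here carry one or two instruments, where random-effects models are
moot. Bonferroni correction divides alpha by the number of proteins
*attempted*, not the number with usable instruments, so that a protein
failing harmonization still consumes its share of the error budget.

## Direction tests

**Steiger filtering.** Per instrument, the variance explained in a trait is
`r² = z²/(z² + n − 2)`; for case-control traits n is the effective size
`4/(1/n_case + 1/n_control)`. r² is summed over instruments per trait, and
the two correlations `r = sqrt(r²)` are compared with the
independent-samples Fisher-z test (the two cohorts do not overlap in a
two-sample design). The forward direction passes when the exposure r²
exceeds the outcome r² with `p < 0.05`.

**Bidirectional MR.** The reverse effect (disease → protein) is estimated
with instruments selected from the disease GWAS genome-wide under the same
significance/clumping/strength criteria. Each candidate reverse instrument
is additionally Steiger-screened: a variant explaining more variance in the
protein than in the disease is a forward (mediated) signal and is removed.
Without this screen, any mediated cis signal that reaches genome-wide
significance in the disease GWAS enters the reverse regression with an
enormous ratio and mechanically labels every truly causal protein as
reverse-causal. A reverse p > 0.05 is read as no evidence of reverse
causation. Note the built-in 5% false-positive rate of this rule: about one
in twenty truly forward-causal proteins will fail it by chance; the
pipeline reports the raw p so users can judge borderline cases.

## Colocalization

Per-variant evidence is Wakefield's approximate Bayes factor: with
`V = se²`, `W = prior_sd²`, `z = beta/se`, `r = W/(V+W)`,
`lABF = 0.5·ln(1−r) + z²·r/2`. Prior effect scales default to 0.15 (SD
units) for quantitative traits and 0.2 (log-OR) for case-control traits.
Assuming at most one causal variant per trait, the posterior is enumerated
over five hypotheses (H0 none, H1/H2 one trait only, H3 two distinct
variants, H4 one shared variant) with per-variant priors
`p1 = p2 = 1e-4`, `p12 = 1e-5` — the published defaults of the standard
method, all configuration-exposed. Every hypothesis sum runs in log space
via log-sum-exp (the H3 cross-product sum uses a log-difference of the full
product and the diagonal), so z-scores of 60+ cannot overflow; equality
with exhaustive enumeration is tested to 1e-12. A region is called
colocalized when `PPH4 > 0.7`, strictly. The source study annotates one row
(PPH4 = 0.789) as not colocalized while its own tally requires counting it
as a pass at 0.7; this package applies the numeric rule and leaves the
threshold configurable.

## Screens, replication and the verdict

**Pleiotropy scan.** Instruments are checked against a local variant–trait
annotation catalog (a stand-in for a web phenotype-scanner): instruments
associated (`p < 5e-8`) with the target disease or a configured list of
risk factors are dropped, and a protein whose instruments associate with
two or more distinct other proteins at that level is flagged a pleiotropy
hub and excluded from the target list (the hub threshold of 2 is inferred
from the narrative of the emulated study and configurable).

**Phenome-wide MR.** Each surviving protein is screened against a manifest
of outcome GWAS; significance is Bonferroni at `0.05/N` over the N outcomes
attempted. A significant effect whose direction matches the protein's
effect on the index disease is classed *benefit* (a drug normalizing the
protein would help both), an opposite direction *adverse*.

**Replication.** Two strategies against an independent pQTL cohort:
*same-variant* reuses the discovery instrument ids in the replication
exposure; *significant-variant* re-selects instruments from the replication
exposure under the discovery criteria. Passing requires p below the
per-outcome threshold — 0.05 divided by the outcome's discovery hit count —
**and** direction concordance with discovery (the source study implies but
never states the direction requirement; it is imposed here and documented).
Missing variants and harmonization-incompatible alleles become
`lack_of_data` / `incompatible_alleles` statuses.

**Evidence integration.** One row per protein × outcome with seven
tri-state flags (discovery significance, Steiger, bidirectional, pleiotropy
scan, colocalization, both replications); the verdict is YES only when
every flag is affirmatively true — unknown (lack of data) vetoes, matching
the emulated study's treatment of its data-poor rows.

## Synthetic data

The generator emulates the statistical structure of the study's inputs
without any real data. A reference panel of binary haplotypes is built by a
copy-with-mutation chain: variant j+1 copies variant j with probability
`ld_decay` (default 0.9) and otherwise draws fresh at its own frequency
(uniform in [0.1, 0.9], realized frequencies clamped to [0.05, 0.95]), so
adjacent r² ≈ ld_decay² and LD decays geometrically. Study cohorts are
*generated fresh from the same process*, not resampled from the panel: with
cohorts much larger than the panel, resampling would promote the panel's
sampling noise (r ≈ 1/sqrt(n_hap) between unlinked loci) into genuine
cohort LD and measurably inflate null association z-scores; generating
cohorts independently keeps null GWAS statistics calibrated while the panel
plays its realistic role as an external LD reference.

Phenotypes are generated at the individual level. The protein is a
unit-variance quantitative trait with one cis causal variant explaining
`h2_exposure` (default 0.05, giving a discovery-cohort association around
z ≈ 20 at the default n = 7,213). Disease status is drawn from a logistic
model on a balanced case-control cohort; scenarios place a direct variant
effect (H2/H3/H4; default per-allele log-OR 0.15), no effect (H0/H1/null),
or a mediated effect `mr_effect` (default 0.25) acting on the genetically
proxied exposure score `mr_effect·b_exp·g`. Mediating through the full
exposure (genetic + residual) instead would attenuate every marginal
log-OR by noncollapsibility (~3% at these settings, verified at n = 2·10⁶)
and make the generative causal effect unequal to the estimand; anchoring
the disease model on the genetic score keeps the true log-OR per SD exactly
`mr_effect`, which is what an MR estimator evaluation needs. In the
reverse-causal scenario the exposure inherits the disease's logistic-latent
liability with slope `reverse_effect` (default 0.3), so the disease →
protein effect per unit log-odds equals `reverse_effect`.

Summary statistics are exact per-variant marginal fits on the simulated
cohorts — vectorized OLS for quantitative traits and a vectorized
Newton-Raphson logistic regression for case-control traits (float32 matrix
work, float64 accumulation; coefficients match `statsmodels.Logit` to six
decimals) — so LD-induced shadow associations arise naturally and clumping
and colocalization are tested honestly.

What the generator does **not** emulate: realistic human demography and
recombination maps, allele-frequency spectra, imputation error, sample
overlap between cohorts, population stratification, assay batch effects,
and polygenic backgrounds beyond the explicitly placed loci. Passing tests
therefore demonstrate the correctness and calibration of the statistical
machinery under the stated generative model, not robustness to those
real-data complications.

## Validation batches and problem sizes

Operating characteristics are measured by seeded replicate batches
(`pqtlmr.validation`), at desk-scale sizes chosen to keep a full run in
minutes on one CPU:

- **Colocalization recovery** — 200-variant regions, pQTL cohort 7,213,
  disease cohort 10,000/10,000 with per-allele log-OR 0.2; 200 replicates
  per hypothesis. Shared-variant (H4) scenarios must give PPH4 > 0.9 in at
  least 90% of replicates; distinct-variant (H3) scenarios must make PPH3
  the dominant hypothesis.
- **Forward recovery** — 60-variant regions, disease cohort 20,000/20,000,
  `h2 = 0.05`, `mr_effect = 0.25`; 500 replicates running the full
  selection + estimation path. The mean estimate must sit within 3
  Monte-Carlo standard errors of 0.25 and the Steiger direction call must
  be correct in at least 95% of replicates.
- **Null calibration** — 40-variant regions, exposure 5,000, disease
  2,500/2,500, zero causal effect; 1,000 replicates. The MR rejection rate
  at alpha = 0.05 must lie within the binomial 95% band around 0.05.
- **Clumping** — greedy clumping must agree exactly with an independent
  brute-force implementation of the same rule on 100 random 50-variant
  instances.
- **End to end** — a five-protein synthetic study (one forward-causal,
  colocalizing protein with designed `mr_effect = 0.45`, plus two disease
  background loci that give the bidirectional check genuine reverse
  instruments) must return exactly the causal protein as the final YES.

## Numerical choices and degenerate inputs

Ties in clumping break on variant id; p-values are floored at 1e-300 to
stay inside (0, 1]; monomorphic simulated variants get zero effect with an
effectively infinite standard error; r² values summed over instruments are
capped just below 1 before the Fisher transform; a single shared variant
forces PPH3 = 0 exactly (the log-difference returns −inf); empty instrument
sets, missing chromosomes, failed harmonization and absent replication
variants all become explicit row statuses rather than errors. Re-running
any stage with the same configuration and seed is byte-identical, which the
test suite asserts on the full pipeline output.

## Known limitations

Single-causal-variant colocalization (no SuSiE-style multi-signal
decomposition or conditional analysis); no MR-Egger/weighted-median
sensitivity estimators (the emulated workflow has at most two instruments
per protein); no sample-overlap correction in Steiger filtering; no VCF
input, liftover or frequency imputation; the pleiotropy catalog is a local
table, not a live phenotype-scanner query; and the bidirectional pass rule
inherits the nominal 5% false-positive rate of any p > 0.05 criterion.
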