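# Methods

`radml` implements a two-group epigenome analysis for Illumina
450K-style methylation data paired with RNA-seq: it calls differentially
methylated loci (DMLs) between two strata of ER-negative tumors, keeps
the loci in noncoding genomic space, asks which nearby genes their
methylation tracks, and checks whether the findings survive in a second
cohort. The package also ships a synthetic-cohort generator with planted
ground truth, because the analysis it mirrors was developed on cohort
data that cannot be redistributed.

## DML calling

For each probe the methylation level is a beta value β ∈ [0,1]. Group
differences are tested per probe with the Wilcoxon rank-sum test; effect
size is Δβ = mean β(group A) − mean β(group B), so Δβ > 0 means
hypermethylated in A. A probe is a race-associated DML (raDML) when

* |Δβ| ≥ 0.10 (boundary inclusive), and
* the Benjamini–Hochberg adjusted p-value is < 0.05, with BH applied
  once over all probes surviving QC (a single family).

Methylation is tested unadjusted — no covariates enter this stage.

**Wilcoxon details.** Midranks are used for ties. For pooled sizes
n₁+n₂ ≤ 12 the exact permutation distribution of the rank sum is
enumerated (valid under ties). Otherwise a normal approximation is used
with the *exact* permutation variance (the standard tie correction) and
a continuity correction equal to half the spacing of the rank-sum
support: 0.5 without ties, 0.25 when midranks are present. A fixed 0.5
correction systematically overshoots on tied data; with the adaptive
correction the approximation stays within 0.03 of the exact p on
tie-light 6-vs-6 data. With *heavy* ties at that size no normal
approximation is adequate (deviations up to ≈0.1 arise from the coarse
discrete support, not from the variance), which is why the exact path is
auto-selected there.

**Detection-p QC.** A probe is dropped when its detection p exceeds 0.05
in strictly more than half of samples. A sample is *retained* when
strictly more than 75% of its loci are well detected (detection
p < 1e-5). The second rule is often printed in an inverted form that
would discard the best-detected samples; the implementation follows the
evidently intended reading and logs a note.

## Noncoding classification cascade

raDMLs pass through an exclusion-first cascade:

1. removed if the array manifest assigns the probe at least one
   protein-coding gene;
2. removed if the probe position falls inside a protein-coding gene
   *body* in the updated annotation (any-transcript vs gene-body overlap
   is a genuine choice; gene-body is the default and configurable);
3. survivors overlapping a noncoding-RNA gene body are classed `ncRNA`;
4. everything else is `intergenic`.

Coordinates are 0-based half-open everywhere internally; manifest
positions (1-based) are shifted on read, BED is used verbatim, GTF
starts are shifted by −1. A CpG is a 1-bp interval; probe strand is
carried but ignored (CpG methylation is strand-symmetric). Interval
queries go through pyranges; a brute-force scan serves as the
independent oracle in the tests.

## Cis correlation and replication

For every noncoding raDML, all genes whose strand-aware TSS lies within
1 Mb on either side (boundary inclusive) are candidate partners. The
signed distance is (TSS − CpG)/1000 kb on the genome axis — negative
when the TSS is left of the CpG. Each pair gets a midrank Spearman ρ
between β and log₂CPM expression, with the p-value from the t
approximation on n−2 degrees of freedom; BH is applied over the *full*
enumerated pair family, and pairs with q < 0.05 are significant.
Constant expression vectors are dropped (not assigned ρ = 0), and pairs
with fewer than 4 complete observations are untestable.

Replication recomputes ρ in a validation cohort for the
discovery-significant pairs measured there, applies BH within that
tested subset only (a second, separate family), and flags a pair
replicated when the validation sign matches discovery and the
replication q is < 0.05. Direction consistency of the raDMLs themselves
is the sign agreement of Δβ across cohorts for probes present in both.

## Differential expression

logCPM = log₂((count + 0.5) / (libsize + 1) × 10⁶). Genes appearing in
significant pairs are tested with an ordinary linear model
`logCPM ~ group + age` (two-sided test on the group coefficient, BH over
the tested gene set). This deliberately replaces a negative-binomial GLM
with dispersion shrinkage: only the direction and significance of a
handful of pre-selected genes are consumed downstream, where the two
approaches agree; exact NB machinery is out of scope.

## Regulatory annotation

CpGs are intersected with named interval tracks — the six ChromHMM
states singled out for interpretation (TssA, TssAFlnk, TssBiv, EnhG,
Enh, EnhBiv), DNase hypersensitive sites, enhancers and super-enhancers.
The probe is a 1-bp interval with an optional symmetric flank (default
0; the 50-mer probe footprint is ignored). Increasing the flank can only
add overlaps. Summaries report per-track counts and how many CpGs fall
in ≥1 and ≥2 distinct feature classes.

## Synthetic cohorts

`generate_cohort` draws a toy genome (genes evenly spread over 1–3
chromosomes with a 65/35 coding/noncoding biotype mix, plus random
regulatory tracks) and a two-group cohort:

* **Beta values** are simulated on the logit scale:
  β = σ(N(μ, s)) with μ chosen so that E[β] matches the requested group
  mean (using E[σ(N(μ,s))] ≈ σ(μ/√(1+πs²/8))). This keeps planted Δβ
  effects of ~0.10–0.13 attainable near the [0,1] boundary without
  clipping. Planted DML probes have group means m ± Δ/2 with a random
  sign per probe.
* **Counts** are negative binomial via a gamma–Poisson mixture
  (var = m + α·m²). For a planted coupled pair the log-mean is linear in
  the standardized logit-β of the partner CpG:
  log m = μ₀ + b·z. The link is strictly monotone in the latent
  methylation, so it induces exactly the rank dependence Spearman
  measures. The slope b needed for a target |ρ| was calibrated once by
  Monte-Carlo (4×10⁵ samples, α = 0.2, μ₀ = log 100) and frozen as an
  interpolation grid; e.g. b = 0.5 ↦ ρ ≈ 0.707.
* **Coupling placement.** Partners are only planted at DML probes with
  no protein-coding overlap, mirroring the study design in which pairs
  are formed for noncoding raDMLs.

Defaults (chosen once, not revisited): 25 samples per group (a
desk-scale stand-in for the cohorts), 2,000 probes, 300 genes over
2×30 Mb (≈10 genes per 2 Mb window), 5% planted DMLs with Δβ = 0.12,
half of them coupled at |ρ| = 0.7, NB dispersion 0.2, gene log-mean
N(log 100, 1), ages uniform on [35, 75], and within-group logit-β
standard deviation 0.4 (≈0.09 on the beta scale at mid-methylation —
typical for tumor 450K cohorts; the source analysis states no
within-group variance, so this is an exposed parameter).

**What the generator does not emulate:** array chemistry and dye bias,
batch effects, genome-scale probe density, cell-type composition,
linkage between neighboring CpGs, or realistic gene length/expression
couplings. A green recovery test therefore establishes that the
*statistics* behave as designed under the planted model, not that the
pipeline would reproduce any particular cohort's biology.

Two measurement consequences are worth stating explicitly:

* **raDML recall ceiling.** With a true Δβ of 0.12, n = 25 per group and
  beta-scale noise ≈0.09, the standard error of the estimated Δβ is
  ≈0.026, so the *hard effect threshold* |Δβ| ≥ 0.10 caps recall near
  Φ(0.02/0.026) ≈ 0.78 regardless of test power. Recovery tests
  therefore check that every called planted probe has the planted
  direction (and that a clear majority are called), and assess pair
  sensitivity at the correlation stage, where it is a property of the
  statistics rather than of the threshold geometry.
* **Empirical FDR definition.** Both planted methylation and its coupled
  expression are group-shifted, so a DML CpG genuinely correlates with a
  gene coupled to a *different* DML CpG (the shared two-group factor is
  a real confounder, as it is in the motivating biology). Flagging such
  a cross-pair is not a test error; empirical FDR is therefore computed
  over flagged pairs whose gene is independent of all methylation
  (measured ≈0.05 at defaults over 5 seeds).

`generate_validation` redraws samples on the same genome/manifest
(as a shared array design implies) with configurable fractions of
sign-discordant probes and pairs.

## The demonstration fixture

`generate_demo_fixture` builds a discovery + validation pair whose
per-stage bookkeeping is *structural*: planted raDMLs have complete
group separation (within-group ramps of spread 0.04 around means split
by Δ ∈ {0.105, 0.11, 0.12, 0.13}), planted significant pairs are exactly
monotone (integer counts linear in the partner CpG's beta ranks, with a
filler gene equalizing library sizes so logCPM preserves the ranks), and
null pairs use a fixed stride permutation whose rank correlation with
every planted beta profile is ≤ 0.04. The randomness seed only adds
rank-preserving jitter of ±1e-7, so the cascade counts
(396 → 276/24 removed → 96 survivors: 59 intergenic + 37 ncRNA,
58 hypo + 38 hyper), the pair counts (39 significant over 23 CpGs and 36
genes, 25 positive) and the replication counts (28 testable, 20
replicated; 59 probes shared, 1 discordant) hold for any seed.

## Numerical choices

* BH FDR delegates to `statsmodels.stats.multitest.multipletests`
  (step-up with cumulative-minimum monotonicity); a naive O(m²)
  implementation is the test oracle.
* Spearman delegates to `scipy.stats.spearmanr`; a hand-computed
  midrank + Pearson oracle checks tie handling.
* Matrix TSV round-trips are exact: floats are written with `%.17g` and
  read with the correctly-rounded parser.
* The 1 Mb window boundary and the 0.10 effect threshold are inclusive;
  both are configurable and logged.
* Chromosome names are normalised to a configured style ("chr" or
  plain); the genome build is a configuration string, never hard-coded.

## Known limitations

Region-level (DMR) methods, cell-type deconvolution, covariate-adjusted
methylation models, trans (>1 Mb or inter-chromosomal) correlation,
causal mediation, NB dispersion shrinkage and enhancer–gene target
inference beyond interval overlap are all out of scope. Real-data users
must supply their own annotation and regulatory-track BEDs for the
genome build of their arrays.
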