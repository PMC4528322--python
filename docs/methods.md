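# Methods

## Design and notation

A reciprocal cross between Africanized (A) and European (E) lineages yields
two families: AE (A queen × E drone) and EA (E queen × A drone). Because
drones are haploid, any SNP with a homozygous queen and a discordant drone
allele (`aa × b` or `bb × a`) is *informative*: every F1 read at that site
has a known parent of origin, and — through the family — a known lineage of
origin. Informative-SNP selection therefore retains exactly those two
genotype configurations; heterozygous queens and queen-matching drones are
dropped, a heterozygous drone call is treated as a genotyping error
(haploidy violation) rather than a salvageable site, and multi-allelic sites
are excluded because the whole design rests on a two-allele 1:1 expectation.
Reference/alternate status plays no role in informativeness.

## The per-transcript mixed model

For one transcript and sample group, each (SNP *s*, library *r*, parental
allele) read count is one response cell:

y = b0 + bP·P + bL·L + bPL·(P·L) + u_s + v_r + e,
u_s ~ N(0, σ²_snp), v_r ~ N(0, σ²_rep), e ~ N(0, σ²_resid)

* **Response scale.** Raw read counts are strongly heteroskedastic, so the
  model uses `y = log2(count + 1)`; on this scale `bP` is the
  maternal−paternal mean log2 difference. A `response="raw"` switch exists
  for sensitivity analysis.
* **Effect coding.** P = +1/2 maternal, −1/2 paternal; L = +1/2 Africanized,
  −1/2 European, so ±1 coefficient differences correspond to the factor
  contrasts directly.
* **Aliasing.** Within AE every row has L = P, within EA L = −P. Hence
  P·L = +1/4 in AE and −1/4 in EA on every row: the interaction column *is*
  the (scaled) family indicator, asserted at design-build time. Consequences:
  `bL` is identified by the flip of the parent contrast across families,
  while `bPL` is identified purely by the between-family mean difference.
  This is an unavoidable property of a two-family reciprocal design, not an
  implementation choice. Libraries are coded uniquely across families, so
  with a non-zero replicate variance the interaction is tested against
  between-library variation.
* **Estimation.** REML via the profiled restricted likelihood: with
  γ = σ²_component/σ²_resid, the criterion
  log|W| + log|XᵀW⁻¹X| + (n−p)·log(rᵀW⁻¹r), W = I + Σ γ·ZZᵀ, is minimized
  over γ ≥ 0 (L-BFGS-B, relative tolerance 1e−8, at most 200 iterations; a
  non-converged fit is flagged but still reported). A component estimated at
  the zero boundary (γ < 1e−6) is fixed to zero and the model refit without
  it, mirroring common REML practice. Random intercepts with a single level
  (e.g. one SNP) are inestimable — confounded with the intercept — and are
  omitted.
* **Term tests.** Wald χ²(1) on (β/SE)². The study this design emulates used
  a proprietary mixed-model fit whose term-test and denominator-df choices
  are not recoverable, so the package prefers the deterministic Wald form
  over F approximations; its small-sample liberality is quantified below.
* **Degenerate fits.** If OLS interpolates the data exactly (noiseless
  designs), all variance components are zero and SEs vanish; by convention
  p = 1 for zero coefficients and p = 0 for non-zero ones, with the fit
  flagged `degenerate`. A transcript observed in a single family falls back
  to the intercept+parent model (lineage/interaction reported as NaN).
  Transcripts with all-zero counts are excluded with a logged reason.
* **Multiple testing.** Benjamini–Hochberg step-up within each sample group ×
  term family; significance is q < 0.05.

## Ratios and classification

Family ratios pool raw counts over SNPs and replicates (R = maternal/total,
Q = Africanized/total per family and sample group). Pooling weights SNPs by
coverage and stays defined with sparse SNPs; a mean-of-per-SNP-ratios variant
is available behind `ratio_method="mean_snp"`. A zero family total leaves the
ratio undefined and the transcript untestable for any rule requiring that
family.

Calls (defaults: ratio threshold 0.6, q\* = 0.05, both configurable):
maternal/paternal PSGE require the parent term significant and the ratio
beyond threshold *in the same direction in both crosses*; lineage calls
mirror this with Q. The asymmetric-maternal call requires the interaction
term significant and R > 0.6 in exactly one cross; a transcript already
maternal in both crosses is not asym-flagged, keeping the lists distinct. A
transcript may carry a parent and a lineage flag simultaneously; the
parent-flag pair and the asym-flag pair are each mutually exclusive, and
these invariants are asserted on every output row.

## Follow-up statistics

* **Storer–Kim exact unconditional test** for two binomial proportions:
  outcome probabilities at the pooled estimate p̂ = (x1+x2)/(n1+n2), summed
  over all outcome pairs whose pooled-variance z statistic is at least as
  extreme as observed (z := 0 when the pooled estimate is 0 or 1). Used as
  maternal-vs-paternal (and European-vs-Africanized) call-count comparisons
  with n1 = n2 = transcripts tested in the group.
* **Hypergeometric overlap**: inclusive upper tail P[X ≥ o]; for each group
  pair the universe is the transcripts tested in *both* groups and each
  biased list is intersected with it first.
* **2×2 chi-square** (no continuity correction by default, flag exposed)
  for membership enrichment, e.g. {parent-biased vs. not} × {in a
  user-supplied mitochondria-localized gene list vs. not}; expected counts
  below 5 raise a warning and set a flag.

## Synthetic data generator

The generator emulates the study design: two reciprocal families; pooled
larvae (2 libraries per family), pooled adults (2), individual brains (3);
biallelic informative SNPs in contiguous transcript blocks on two synthetic
chromosomes; parental VCFs (diploid queen, haploid drone) that re-select to
exactly the emitted informative-SNP table.

Per (transcript, SNP, family, library) cell: total depth ~ negative binomial
(mean 50, variance μ(1+αμ) with α = 0.02, i.e. CV ≈ 0.2 — modest
overdispersion typical of per-SNP coverage across libraries); maternal count
~ beta-binomial around the class- and family-specific maternal fraction with
intraclass correlation ρ = 0.02, so replicate-level allelic overdispersion
exists for the random effects to absorb. Truth classes map to per-family
maternal fractions through the family–lineage design: e.g. an
Africanized-lineage bias θ appears as maternal fraction θ in AE and 1−θ in
EA, and `asym_maternal_EA` as (0.5, θ_m). Defaults θ_m = θ_l = 0.8; SNPs per
transcript ~ 1 + Poisson(2) (fixable); everything is deterministic given the
config and seed, byte-for-byte.

Reference-mapping bias is modeled as one-sided read loss: each read carrying
the Africanized allele is dropped with probability b, mimicking alignment
against a European-derived reference. On an all-null dataset this
masquerades as a European lineage bias while the reciprocal design protects
parent-of-origin calls — the `simulate_ascertainment_null` report quantifies
both call rates. This is an explicit analog of, not a replication of, the
original study's ascertainment simulation, whose design is not public.

What the generator does **not** emulate: family- or class-dependent total
expression levels, read-level artifacts (mapping is summarized by the single
thinning parameter), genomic clustering of biased transcripts, and
correlation of effects across sample groups beyond sharing the transcript's
class. Passing recovery tests therefore demonstrate correctness of the
machinery under the stated generative model, not performance on real
libraries.

## Numerical choices and edge cases

Exact-fit detection at residual SS ≤ 1e−10 × signal; boundary tolerance
γ < 1e−6; Wald p with SE = 0 follows the degenerate convention above; BH on
NaN p-values (inestimable terms) leaves them NaN and out of the adjustment;
filter thresholds default to min 10 reads per SNP×library cell, ≥ 1
surviving SNP and ≥ 2 libraries per family per transcript (the original
study's exact coverage/quality cutoffs are not public; these are exposed in
the run config). Parental VCF records below QUAL 20 are dropped by default
when QUAL is present, likewise configurable.

## Known limitations

* **Interaction power.** Because `bPL` is aliased with the family mean
  difference, an asymmetric transcript with equal total expression in both
  families registers on the interaction term only through the log-scale
  concavity gap (≈ 0.58 log2 units at θ_m = 0.8, depth 50), so one-cross
  maternal bias is recovered with low sensitivity at realistic depth unless
  it is accompanied by a family-level expression difference. On real hybrid
  data such expression differences are plausible (hybrid incompatibility),
  which is likely why this contrast was productive in the motivating study.
* **One-SNP transcripts.** With a single SNP the replicate intercept leaves
  roughly two residual degrees of freedom and the Wald χ²(1) test can be
  catastrophically liberal (arbitrarily small null p-values). Interpret
  parent-term significance for 1-SNP transcripts with caution, or raise
  `min_snps_per_transcript`.
* **Wald liberality.** Even at 3 SNPs the null rejection rate at nominal
  0.05 is ≈ 0.07–0.08 under the study's replicate design; no
  Satterthwaite/Kenward–Roger correction is attempted.
* The generic 2×2 chi-square leaves the choice of margins to the analyst;
  the pipeline's built-in table is {parent-biased vs. not} × membership.
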