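# psge — parent-specific gene expression in reciprocal crosses

`psge` analyzes allele-specific RNA-seq read counts from a reciprocal cross
between two lineages — the motivating design is honey bee crosses between
Africanized (A) and European (E) strains — to find transcripts whose
expression depends on the **parent of origin** of an allele (matrigene vs.
patrigene), on its **lineage of origin** (A vs. E allele, regardless of
parent), or on their interaction (a maternal bias present in only one of the
two crosses). It is aimed at researchers studying genomic imprinting and
parent-of-origin effects in species where reciprocal crosses are feasible,
and at anyone who needs a tested, self-contained reference implementation of
this analysis with a matching synthetic-data generator.

## The design and the model

Honey bees are haplodiploid: queens are diploid, drone fathers haploid. At a
SNP where the queen is homozygous `aa` and the drone carries `b` (or `bb` ×
`a`), every F1 worker is heterozygous and the parental origin of every read
is unambiguous, with a 1:1 maternal:paternal expectation under the null.
Two mirror-image families uncouple parent from lineage: in the AE family the
mother is Africanized, in the EA family she is European.

For each transcript and sample group (pooled larvae, pooled adults,
individual brains), every (SNP, library, parental allele) read count is a
response cell and the package fits the linear mixed model

```
log2(count + 1) = b0 + bP·P + bL·L + bPL·(P·L) + u_snp + v_library + e
```

with effect codes `P` (+1/2 maternal, −1/2 paternal) and `L` (+1/2
Africanized, −1/2 European), random intercepts for SNP and library, REML
estimation over the non-negative variance orthant, and Wald χ²(1) tests per
fixed term. Benjamini–Hochberg q-values are computed within each sample
group × term. A transcript is called:

- **maternal / paternal PSGE** — parent term q < 0.05 and the pooled
  maternal read ratio R > 0.6 (resp. < 0.4) *in both crosses*;
- **lineage A / E biased** — lineage term q < 0.05 and the Africanized read
  ratio Q > 0.6 (resp. < 0.4) in both crosses;
- **asymmetrically maternal (one cross)** — interaction term q < 0.05 and
  R > 0.6 in exactly one cross.

Note that with exactly two reciprocal families the interaction column `P·L`
is constant within a family: the interaction is aliased with the family
indicator and is estimated against between-family variation (see
`docs/methods.md`).

Follow-up statistics mirror the downstream questions: a Storer–Kim exact
unconditional two-proportion test compares maternal vs. paternal (or
European vs. Africanized) call counts, a hypergeometric test measures
overlap of biased-transcript lists between sample groups on their shared
tested universe, and a 2×2 chi-square tests membership enrichment (e.g.
mitochondria-localized genes) among biased transcripts.

## Worked example

Simulate a small reciprocal-cross study with known truth (70% unbiased
transcripts, 10% maternal PSGE, 5% paternal, 10% European-lineage biased,
5% maternally biased only in the EA cross), then run the full pipeline:

```bash
cat > sim.json <<'JSON'
{"n_transcripts": 80, "seed": 7,
 "class_proportions": {"null": 0.7, "maternal": 0.1, "paternal": 0.05,
                        "lineage_E": 0.1, "asym_maternal_EA": 0.05}}
JSON
psge simulate --config sim.json --out sim
cat > run.json <<'JSON'
{"counts_path": "sim/counts.tsv",
 "informative_snps_path": "sim/informative_snps.tsv",
 "out_dir": "results"}
JSON
psge run-all --config run.json
```

which prints

```
sample_group  n_tested_transcripts  n_snps  n_maternal_psge  n_paternal_psge  n_lineage_A  n_lineage_E  n_asym_maternal_AE  n_asym_maternal_EA
      adults                    80     229               11                4            0            5                   0                   0
      brains                    80     229               12                4            0            5                   0                   0
      larvae                    80     229               11                4            0            5                   0                   0
results written to results
```

Each row tallies, per sample group, the transcripts tested (with the number
of informative SNPs used) and the bias calls of each kind. `results/`
contains the per-transcript model fits (`fits.tsv`: coefficients, variance
components, p/q per term), the calls with their supporting family ratios
(`bias_calls.tsv`), a JSON summary with the enrichment statistics, and a
readable report; `psge report --results-dir results` ends with

```
adults: maternal 11 vs paternal 4 of 80 tested (Storer-Kim p = 0.06358)
brains: maternal 12 vs paternal 4 of 80 tested (Storer-Kim p = 0.03613)
larvae: maternal 11 vs paternal 4 of 80 tested (Storer-Kim p = 0.06358)
```

i.e. in brains significantly more transcripts over-express the maternal than
the paternal allele. Real data enter the same way: parental genotypes as
VCF (`psge select-snps`, or `vcf_ae`/`vcf_ea` entries in the run config) and
a long-format TSV of per-SNP, per-library allele counts.

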