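"""Synthetic reciprocal-cross datasets with known truth.

Emulates the study design: two reciprocal families (AE: Africanized queen x
European drone; EA: the reverse), pooled larvae (2 libraries per family),
pooled adults (2 per family) and individual brains (3 per family), with
biallelic informative SNPs carrying a 1:1 maternal:paternal read expectation
under the null.

Per (transcript, SNP, family, library) cell the total read depth is negative
binomial around the configured mean; the maternal read count is
beta-binomial around the class- and family-specific maternal fraction, so
replicate-level allelic overdispersion exists for the model's random effects
to absorb.  Reference-mapping bias is modelled as one-sided read loss on the
Africanized allele (probability ``mapping_bias`` per read), mimicking
alignment against a European-derived reference genome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

CLASSES = (
    "null",
    "maternal",
    "paternal",
    "lineage_A",
    "lineage_E",
    "asym_maternal_AE",
    "asym_maternal_EA",
)

#: replicates per family (AE, EA) per sample group, matching the study design
DEFAULT_REPLICATES: Dict[str, Tuple[int, int]] = {
    "larvae": (2, 2),
    "adults": (2, 2),
    "brains": (3, 3),
}


class SimConfig(BaseModel):
    """Generator settings; defaults reproduce the study's design conditions."""

    model_config = ConfigDict(extra="forbid")

    n_transcripts: int = Field(default=500, ge=1)
    class_proportions: Dict[str, float] = Field(default_factory=lambda: {"null": 1.0})
    maternal_fraction: float = Field(default=0.8, gt=0.0, lt=1.0)
    lineage_fraction: float = Field(default=0.8, gt=0.0, lt=1.0)
    snp_lambda: float = Field(default=2.0, ge=0.0)  # SNPs per transcript ~ 1 + Poisson(lambda)
    fixed_snps_per_transcript: Optional[int] = Field(default=None, ge=1)
    replicates: Dict[str, Tuple[int, int]] = Field(
        default_factory=lambda: dict(DEFAULT_REPLICATES)
    )
    mean_depth: float = Field(default=50.0, gt=0.0)
    depth_dispersion: float = Field(default=0.02, ge=0.0)  # var = mu * (1 + a*mu)
    rho: float = Field(default=0.02, ge=0.0, lt=1.0)  # beta-binomial overdispersion
    mapping_bias: float = Field(default=0.0, ge=0.0, lt=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown transcript classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if not np.isclose(total, 1.0, atol=1e-9) or min(self.class_proportions.values()) < 0:
            raise ValueError("class proportions must be non-negative and sum to 1")
        for g, (a, e) in self.replicates.items():
            if a < 1 or e < 1:
                raise ValueError(f"replicates for {g} must be >= 1 per family")
        return self


def expected_maternal_fractions(cls: str, theta_m: float, theta_l: float) -> Dict[str, float]:
    """Per-family expected maternal read fraction implied by a truth class.

    Lineage classes map through the family design: the maternal allele is
    Africanized only in AE, so an Africanized-lineage bias theta_l appears as
    maternal fraction theta_l in AE but 1 - theta_l in EA.
    """
    if cls == "null":
        return {"AE": 0.5, "EA": 0.5}
    if cls == "maternal":
        return {"AE": theta_m, "EA": theta_m}
    if cls == "paternal":
        return {"AE": 1 - theta_m, "EA": 1 - theta_m}
    if cls == "lineage_A":
        return {"AE": theta_l, "EA": 1 - theta_l}
    if cls == "lineage_E":
        return {"AE": 1 - theta_l, "EA": theta_l}
    if cls == "asym_maternal_AE":
        return {"AE": theta_m, "EA": 0.5}
    if cls == "asym_maternal_EA":
        return {"AE": 0.5, "EA": theta_m}
    raise ValueError(f"unknown class {cls!r}")


def _negbin_depth(rng: np.random.Generator, mu: float, alpha: float, size: int) -> np.ndarray:
    if alpha == 0.0:
        return rng.poisson(mu, size=size)
    size_param = 1.0 / alpha  # var = mu + alpha * mu^2
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p, size=size)


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, mean: float, rho: float) -> np.ndarray:
    """Beta-binomial draw; rho is the intraclass correlation 1/(a+b+1)."""
    n = np.asarray(n)
    if rho == 0.0 or mean in (0.0, 1.0):
        return rng.binomial(n, mean)
    ab = 1.0 / rho - 1.0
    p = rng.beta(mean * ab, (1.0 - mean) * ab, size=n.shape)
    return rng.binomial(n, p)


@dataclass
class SimResult:
    """In-memory simulated dataset plus optional written file paths."""

    informative_snps: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame
    vcf_paths: Dict[str, str]
    config: SimConfig


def simulate_dataset(config: SimConfig, out_dir: Optional[str] = None) -> SimResult:
    """Draw a full reciprocal-cross dataset; deterministic given config+seed.

    When ``out_dir`` is given, writes per-family parental VCFs (queen diploid
    GT, drone haploid GT), the informative-SNP TSV, the counts TSV, the truth
    TSV and a JSON echo of the config.
    """
    rng = np.random.default_rng(config.seed)
    classes = sorted(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    true_class = rng.choice(classes, size=config.n_transcripts, p=probs)
    if config.fixed_snps_per_transcript is not None:
        n_snps = np.full(config.n_transcripts, config.fixed_snps_per_transcript)
    else:
        n_snps = 1 + rng.poisson(config.snp_lambda, size=config.n_transcripts)

    # SNP layout: two synthetic chromosomes, uniformly spaced sites,
    # transcripts assigned to contiguous blocks.
    half = (config.n_transcripts + 1) // 2
    snp_rows, truth_rows, count_rows = [], [], []
    pos_counter = {"chr1": 0, "chr2": 0}
    for t in range(config.n_transcripts):
        tid = f"TX{t:05d}"
        chrom = "chr1" if t < half else "chr2"
        cls = str(true_class[t])
        frac = expected_maternal_fractions(cls, config.maternal_fraction, config.lineage_fraction)
        truth_rows.append(
            {
                "transcript_id": tid,
                "true_class": cls,
                "expected_R_AE": frac["AE"],
                "expected_R_EA": frac["EA"],
                "theta_m": config.maternal_fraction,
                "theta_l": config.lineage_fraction,
                "n_snps": int(n_snps[t]),
            }
        )
        positions = []
        for _ in range(int(n_snps[t])):
            pos_counter[chrom] += 1000
            positions.append(pos_counter[chrom])
        # reference allele = European ('A'), alternate = Africanized ('G')
        for pos in positions:
            for fam, mat, pat in [("AE", "G", "A"), ("EA", "A", "G")]:
                snp_rows.append(
                    {
                        "family": fam,
                        "chrom": chrom,
                        "pos": pos,
                        "transcript_id": tid,
                        "maternal_allele": mat,
                        "paternal_allele": pat,
                        "maternal_lineage": "Africanized" if fam == "AE" else "European",
                    }
                )
        for group, (n_ae, n_ea) in config.replicates.items():
            for fam, n_rep in [("AE", n_ae), ("EA", n_ea)]:
                p_mat = frac[fam]
                mat_lineage = "Africanized" if fam == "AE" else "European"
                pat_lineage = "European" if fam == "AE" else "Africanized"
                for rep in range(1, n_rep + 1):
                    rep_id = f"{fam}_{group}_{rep}"
                    depth = _negbin_depth(
                        rng, config.mean_depth, config.depth_dispersion, len(positions)
                    )
                    maternal = _beta_binomial(rng, depth, p_mat, config.rho)
                    paternal = depth - maternal
                    if config.mapping_bias > 0.0:
                        # thin reads on the Africanized allele (reference is European)
                        if fam == "AE":
                            maternal = rng.binomial(maternal, 1.0 - config.mapping_bias)
                        else:
                            paternal = rng.binomial(paternal, 1.0 - config.mapping_bias)
                    for pos, m, pcount in zip(positions, maternal, paternal):
                        count_rows.append(
                            (tid, chrom, pos, fam, rep_id, group, "maternal", mat_lineage, int(m))
                        )
                        count_rows.append(
                            (tid, chrom, pos, fam, rep_id, group, "paternal", pat_lineage, int(pcount))
                        )

    counts = pd.DataFrame(
        count_rows,
        columns=[
            "transcript_id",
            "chrom",
            "pos",
            "family",
            "replicate_id",
            "sample_group",
            "parent",
            "lineage",
            "count",
        ],
    )
    informative = pd.DataFrame(snp_rows)
    truth = pd.DataFrame(truth_rows)

    vcf_paths: Dict[str, str] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for fam in ("AE", "EA"):
            path = out / f"parents_{fam}.vcf"
            _write_parental_vcf(informative[informative["family"] == fam], fam, path)
            vcf_paths[fam] = str(path)
        informative.to_csv(out / "informative_snps.tsv", sep="\t", index=False)
        counts.to_csv(out / "counts.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        (out / "sim_config.json").write_text(json.dumps(config.model_dump(), indent=2, sort_keys=True))
    return SimResult(
        informative_snps=informative, counts=counts, truth=truth, vcf_paths=vcf_paths, config=config
    )


def _write_parental_vcf(snps: pd.DataFrame, family: str, path: Path) -> None:
    """VCF 4.2 with a diploid homozygous queen and a haploid drone.

    REF is the European allele, ALT the Africanized allele; in family AE the
    queen (Africanized) is 1/1 and the drone (European) is 0, and vice versa.
    """
    queen_gt, drone_gt = ("1/1", "0") if family == "AE" else ("0/0", "1")
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=psge-simulate family={family}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in sorted(snps["chrom"].unique()):
        max_pos = int(snps.loc[snps["chrom"] == chrom, "pos"].max()) + 1000
        lines.append(f"##contig=<ID={chrom},length={max_pos}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tQUEEN\tDRONE")
    ordered = snps.sort_values(["chrom", "pos"])
    ref_alt = ordered.apply(
        lambda r: (r["paternal_allele"], r["maternal_allele"])
        if family == "AE"
        else (r["maternal_allele"], r["paternal_allele"]),
        axis=1,
    )
    for (_, row), (ref, alt) in zip(ordered.iterrows(), ref_alt):
        lines.append(
            f"{row['chrom']}\t{row['pos']}\t.\t{ref}\t{alt}\t100\tPASS\t.\tGT\t{queen_gt}\t{drone_gt}"
        )
    path.write_text("\n".join(lines) + "\n")


@dataclass
class AscertainmentReport:
    """Full-pipeline call rates on an all-null, mapping-biased simulation."""

    per_transcript: pd.DataFrame  # one row per transcript, union of groups
    lineage_call_rate: float
    parent_call_rate: float
    mapping_bias: float


def simulate_ascertainment_null(config: SimConfig) -> AscertainmentReport:
    """Run the full pipeline on an all-null simulation with mapping bias.

    All class mass must be on ``null``.  Reference-mapping read loss on the
    Africanized allele masquerades as a European lineage bias, so the
    lineage-biased call rate inflates with the bias while the parent-of-origin
    call rate stays near its nominal null level — parent-of-origin calls are
    protected by the reciprocal design.
    """
    if set(config.class_proportions) - {"null"} or config.class_proportions.get("null") != 1.0:
        raise ValueError("ascertainment simulation requires all class mass on 'null'")
    from .classify import make_bias_calls
    from .counts import filter_counts, ratios_table
    from .model import fdr_adjust, fit_all

    sim = simulate_dataset(config)
    filtered, _ = filter_counts(sim.counts)
    fits = fdr_adjust(fit_all(filtered))
    ratios = ratios_table(filtered)
    calls = make_bias_calls(fits, ratios)
    agg = calls.groupby("transcript_id")[
        ["maternal_psge", "paternal_psge", "lineage_A", "lineage_E"]
    ].any()
    agg = agg.reindex(sim.truth["transcript_id"]).fillna(False)
    per_transcript = agg.reset_index()
    lineage_rate = float((agg["lineage_A"] | agg["lineage_E"]).mean())
    parent_rate = float((agg["maternal_psge"] | agg["paternal_psge"]).mean())
    return AscertainmentReport(
        per_transcript=per_transcript,
        lineage_call_rate=lineage_rate,
        parent_call_rate=parent_rate,
        mapping_bias=config.mapping_bias,
    )
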