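"""Parental genotypes and informative-SNP selection.

In a reciprocal cross between Africanized (A) and European (E) honey bee
lineages, every F1 worker is heterozygous at sites where the diploid queen
is homozygous for one allele and the haploid drone father carries the other
(queen aa x drone b, or queen bb x drone a).  At such *informative* sites
the parental origin — and, via the family, the lineage of origin — of every
RNA-seq read is unambiguous, and maternal and paternal read counts have a
1:1 expectation under the null of no expression bias.

Family codes follow the maternal lineage: ``AE`` is an Africanized queen
crossed to a European drone, ``EA`` the reverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_FAMILIES = ("AE", "EA")
BASES = frozenset("ACGT")

#: maternal/paternal lineage implied by the family code
FAMILY_LINEAGES = {
    "AE": ("Africanized", "European"),
    "EA": ("European", "Africanized"),
}


class HaploidViolationError(ValueError):
    """A drone (haploid father) genotype was reported heterozygous."""


@dataclass(frozen=True)
class ParentalSite:
    """Genotypes of the two parents of one cross family at one site."""

    family: str
    chrom: str
    pos: int
    queen_alleles: Optional[tuple[str, str]]
    drone_alleles: Optional[tuple[str, ...]]
    transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family not in VALID_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class InformativeSnp:
    """A site where parental origin of each F1 allele is unambiguous."""

    family: str
    chrom: str
    pos: int
    transcript_id: Optional[str]
    maternal_allele: str
    paternal_allele: str
    maternal_lineage: str
    paternal_lineage: str

    def __post_init__(self) -> None:
        if self.maternal_allele == self.paternal_allele:
            raise ValueError("maternal and paternal alleles must differ")
        expected = FAMILY_LINEAGES[self.family]
        if (self.maternal_lineage, self.paternal_lineage) != expected:
            raise ValueError(
                f"family {self.family} implies lineages {expected}, got "
                f"({self.maternal_lineage}, {self.paternal_lineage})"
            )


def select_informative_snps(sites: Iterable[ParentalSite]) -> list[InformativeSnp]:
    """Retain sites with a homozygous queen and a discordant haploid drone.

    A site is informative iff the queen is homozygous X/X and the drone
    carries a single allele Y != X; then every maternal F1 allele is X and
    every paternal allele is Y.  Heterozygous queens and drones matching the
    queen are dropped; a diploid-heterozygous drone call violates haplodiploidy
    and raises :class:`HaploidViolationError`.
    """
    retained: list[InformativeSnp] = []
    for site in sites:
        if site.queen_alleles is None or site.drone_alleles is None or not site.drone_alleles:
            logger.info("skipping %s:%d (%s): missing genotype", site.chrom, site.pos, site.family)
            continue
        drone_set = set(site.drone_alleles)
        if len(drone_set) > 1:
            raise HaploidViolationError(
                f"drone genotype at {site.chrom}:{site.pos} ({site.family}) is "
                f"heterozygous {site.drone_alleles}; drones are haploid"
            )
        (drone_allele,) = drone_set
        qa, qb = site.queen_alleles
        if qa != qb:
            continue  # heterozygous queen: maternal origin ambiguous
        if drone_allele == qa:
            continue  # F1 homozygous, alleles indistinguishable
        if qa not in BASES or drone_allele not in BASES:
            logger.info("skipping %s:%d: non-ACGT allele", site.chrom, site.pos)
            continue
        mat_lin, pat_lin = FAMILY_LINEAGES[site.family]
        retained.append(
            InformativeSnp(
                family=site.family,
                chrom=site.chrom,
                pos=site.pos,
                transcript_id=site.transcript_id,
                maternal_allele=qa,
                paternal_allele=drone_allele,
                maternal_lineage=mat_lin,
                paternal_lineage=pat_lin,
            )
        )
    return retained


@dataclass
class FamilyIntersection:
    """Pairing of informative SNPs across the two reciprocal families."""

    paired: list[tuple[InformativeSnp, InformativeSnp]]
    single_family: list[InformativeSnp]
    conflicting: list[tuple[InformativeSnp, InformativeSnp]]


def intersect_families(
    snps_ae: Sequence[InformativeSnp], snps_ea: Sequence[InformativeSnp]
) -> FamilyIntersection:
    """Pair sites informative in both families with the same two alleles.

    Sites informative in only one family are returned separately (usable for
    within-family ratios only).  The same position with a different allele
    pair in the two families is excluded and logged.
    """
    by_pos_ae = {(s.chrom, s.pos): s for s in snps_ae}
    by_pos_ea = {(s.chrom, s.pos): s for s in snps_ea}
    paired, singles, conflicting = [], [], []
    for key, ae in by_pos_ae.items():
        ea = by_pos_ea.get(key)
        if ea is None:
            singles.append(ae)
        elif {ae.maternal_allele, ae.paternal_allele} == {ea.maternal_allele, ea.paternal_allele}:
            paired.append((ae, ea))
        else:
            logger.warning(
                "site %s:%d has different allele pairs in AE and EA; excluded", key[0], key[1]
            )
            conflicting.append((ae, ea))
    for key, ea in by_pos_ea.items():
        if key not in by_pos_ae:
            singles.append(ea)
    return FamilyIntersection(paired=paired, single_family=singles, conflicting=conflicting)


def read_parental_vcf(
    path: str,
    family: str,
    queen_sample: str,
    drone_sample: str,
    min_qual: Optional[float] = 20.0,
    transcript_map: Optional[Mapping[tuple[str, int], str]] = None,
) -> list[ParentalSite]:
    """Read queen and drone genotypes for one family from a multi-sample VCF.

    Only biallelic SNPs are considered; multi-allelic records are dropped.
    Missing/half calls yield ``None`` genotypes (the site is later skipped).
    Records with QUAL below ``min_qual`` are dropped when QUAL is present
    (the study's exact upstream quality thresholds are not public, so this
    is a documented, configurable default).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    for name in (queen_sample, drone_sample):
        if name not in samples:
            raise ValueError(f"sample {name!r} not in VCF {path} (has {samples})")
    qi, di = samples.index(queen_sample), samples.index(drone_sample)

    sites: list[ParentalSite] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue  # multi-allelic or indel
        if min_qual is not None and rec.QUAL is not None and rec.QUAL < min_qual:
            continue
        alleles = [rec.REF] + list(rec.ALT)
        gts = rec.genotypes

        def _calls(idx: int) -> Optional[tuple[str, ...]]:
            codes = [c for c in gts[idx][:-1] if c is not None and c >= 0]
            if not codes or len(gts[idx][:-1]) != len(codes):
                return None
            return tuple(alleles[c] for c in codes)

        queen = _calls(qi)
        drone = _calls(di)
        if queen is not None and len(queen) == 1:
            queen = None  # half-call on a diploid queen: treat as missing
        sites.append(
            ParentalSite(
                family=family,
                chrom=rec.CHROM,
                pos=rec.POS,
                queen_alleles=queen,  # type: ignore[arg-type]
                drone_alleles=drone,
                transcript_id=(transcript_map or {}).get((rec.CHROM, rec.POS)),
            )
        )
    return sites


def informative_snps_to_frame(snps: Sequence[InformativeSnp]) -> pd.DataFrame:
    """Tabulate informative SNPs (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "family": s.family,
                "chrom": s.chrom,
                "pos": s.pos,
                "transcript_id": s.transcript_id,
                "maternal_allele": s.maternal_allele,
                "paternal_allele": s.paternal_allele,
                "maternal_lineage": s.maternal_lineage,
            }
            for s in snps
        ],
        columns=[
            "family",
            "chrom",
            "pos",
            "transcript_id",
            "maternal_allele",
            "paternal_allele",
            "maternal_lineage",
        ],
    )


def write_informative_snps(snps: Sequence[InformativeSnp], path: str) -> None:
    informative_snps_to_frame(snps).to_csv(path, sep="\t", index=False)


def read_informative_snps(path: str) -> list[InformativeSnp]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out = []
    for row in df.itertuples(index=False):
        mat_lin, pat_lin = FAMILY_LINEAGES[row.family]
        out.append(
            InformativeSnp(
                family=row.family,
                chrom=row.chrom,
                pos=int(row.pos),
                transcript_id=None if pd.isna(row.transcript_id) else str(row.transcript_id),
                maternal_allele=row.maternal_allele,
                paternal_allele=row.paternal_allele,
                maternal_lineage=mat_lin,
                paternal_lineage=pat_lin,
            )
        )
    return out
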