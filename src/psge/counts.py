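"""Allele-specific read counts: loading, validation, filtering, ratios.

The central table is long-format: one row per (transcript, SNP, family,
library, parental allele) with the number of uniquely mapped reads carrying
that allele.  Because every informative SNP has exactly one maternal and one
paternal allele, and the family fixes which lineage each parent contributes,
the ``lineage`` column is fully determined by (family, parent) — this design
identity is validated on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import FAMILY_LINEAGES, VALID_FAMILIES

logger = logging.getLogger(__name__)

VALID_SAMPLE_GROUPS = ("larvae", "adults", "brains")
VALID_PARENTS = ("maternal", "paternal")

COUNT_COLUMNS = [
    "transcript_id",
    "chrom",
    "pos",
    "family",
    "replicate_id",
    "sample_group",
    "parent",
    "lineage",
    "count",
]

_KEY = ["transcript_id", "chrom", "pos", "family", "replicate_id", "sample_group", "parent"]


@dataclass(frozen=True)
class AlleleCountRecord:
    """One allele's read count in one library at one SNP."""

    transcript_id: str
    chrom: str
    pos: int
    family: str
    replicate_id: str
    sample_group: str
    parent: str
    lineage: str
    count: int


@dataclass
class FilterReport:
    """Bookkeeping for coverage/representation filtering.

    Record counts conserve: ``n_input_records = n_retained +
    n_dropped_low_coverage + n_dropped_few_snps``.
    """

    n_input_records: int = 0
    n_dropped_low_coverage: int = 0
    n_dropped_few_snps: int = 0
    n_retained: int = 0
    n_transcripts_tested: dict = field(default_factory=dict)

    def check(self) -> None:
        assert (
            self.n_input_records
            == self.n_retained + self.n_dropped_low_coverage + self.n_dropped_few_snps
        ), "filter report does not reconcile"


class CountsValidationError(ValueError):
    pass


def expected_lineage(family: str, parent: str) -> str:
    mat, pat = FAMILY_LINEAGES[family]
    return mat if parent == "maternal" else pat


def load_counts(
    path_or_df,
    informative_snps: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, list[int]]:
    """Load and validate the long-format counts TSV.

    Returns the validated frame and the 0-based row numbers of rejected rows
    (rows whose lineage contradicts the family/parent mapping, or whose SNP
    is absent from the informative-SNP table when one is supplied).  Unknown
    family/sample-group/parent tokens and negative counts are hard errors.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t", dtype={"chrom": str, "replicate_id": str})
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise CountsValidationError(f"counts table missing columns: {missing}")
    df = df[COUNT_COLUMNS].reset_index(drop=True)

    for col, valid in [
        ("family", VALID_FAMILIES),
        ("sample_group", VALID_SAMPLE_GROUPS),
        ("parent", VALID_PARENTS),
    ]:
        bad = set(df[col].unique()) - set(valid)
        if bad:
            raise CountsValidationError(f"unknown {col} token(s): {sorted(bad)}")
    if len(df) and (not np.issubdtype(df["count"].dtype, np.number) or (df["count"] < 0).any()):
        raise CountsValidationError("counts must be non-negative integers")
    df["count"] = df["count"].astype(np.int64)
    df["pos"] = df["pos"].astype(np.int64)

    dup = df.duplicated(subset=_KEY, keep=False)
    if dup.any():
        raise CountsValidationError(
            f"duplicate (transcript, snp, family, replicate, parent) rows at "
            f"{df.index[dup].tolist()[:10]}"
        )

    mat_lin = df["family"].map({f: FAMILY_LINEAGES[f][0] for f in VALID_FAMILIES})
    pat_lin = df["family"].map({f: FAMILY_LINEAGES[f][1] for f in VALID_FAMILIES})
    expected = np.where(df["parent"] == "maternal", mat_lin, pat_lin)
    rejected = df.index[df["lineage"] != expected].tolist()
    if informative_snps is not None:
        known = pd.MultiIndex.from_frame(informative_snps[["family", "chrom", "pos"]])
        keys = pd.MultiIndex.from_frame(df[["family", "chrom", "pos"]])
        rejected = sorted(set(rejected) | set(df.index[~keys.isin(known)]))
    if rejected:
        logger.warning("rejected %d inconsistent count rows: %s", len(rejected), rejected[:20])
        df = df.drop(index=rejected).reset_index(drop=True)
    return df, rejected


def records_to_frame(records: list[AlleleCountRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=COUNT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[AlleleCountRecord]:
    return [AlleleCountRecord(**row) for row in df[COUNT_COLUMNS].to_dict("records")]


def filter_counts(
    df: pd.DataFrame,
    min_total_per_snp_library: int = 10,
    min_snps_per_transcript: int = 1,
    min_libraries_per_family: int = 2,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop low-coverage SNP x library cells, then under-supported transcripts.

    A cell is one (transcript, SNP, family, library, sample group); it is
    dropped when its maternal+paternal total is below
    ``min_total_per_snp_library``.  Within each sample group a transcript is
    then dropped when fewer than ``min_snps_per_transcript`` distinct SNPs
    survive, or when it is represented in fewer than
    ``min_libraries_per_family`` libraries in either family.
    """
    if min(min_total_per_snp_library, min_snps_per_transcript, min_libraries_per_family) < 0:
        raise ValueError("filter thresholds must be non-negative")
    report = FilterReport(n_input_records=len(df))

    cell_cols = ["transcript_id", "chrom", "pos", "family", "replicate_id", "sample_group"]
    if len(df) == 0:
        report.n_transcripts_tested = {g: 0 for g in VALID_SAMPLE_GROUPS}
        report.check()
        return df.copy(), report

    totals = df.groupby(cell_cols, sort=False)["count"].transform("sum")
    keep_cell = totals >= min_total_per_snp_library
    report.n_dropped_low_coverage = int((~keep_cell).sum())
    kept = df[keep_cell]
    if len(kept) == 0:
        report.n_transcripts_tested = {g: 0 for g in VALID_SAMPLE_GROUPS}
        report.check()
        return kept.reset_index(drop=True), report

    grp = kept.groupby(["transcript_id", "sample_group"], sort=False)
    n_snps = grp.apply(
        lambda g: g[["chrom", "pos"]].drop_duplicates().shape[0], include_groups=False
    )
    n_libs_min = grp.apply(
        lambda g: g.groupby("family")["replicate_id"].nunique().reindex(VALID_FAMILIES).fillna(0).min(),
        include_groups=False,
    )
    ok = (n_snps >= min_snps_per_transcript) & (n_libs_min >= min_libraries_per_family)
    ok_keys = set(ok.index[ok])
    in_ok = kept.set_index(["transcript_id", "sample_group"]).index.isin(ok_keys)
    report.n_dropped_few_snps = int((~in_ok).sum())
    retained = kept[in_ok].reset_index(drop=True)
    report.n_retained = len(retained)
    report.n_transcripts_tested = {
        g: int(retained.loc[retained["sample_group"] == g, "transcript_id"].nunique())
        for g in VALID_SAMPLE_GROUPS
    }
    report.check()
    return retained, report


@dataclass
class FamilyRatios:
    """Pooled maternal (R) and Africanized-lineage (Q) read ratios per family.

    Ratios pool raw counts over SNPs and replicates within a family and
    sample group; an undefined ratio (zero total or family absent) is NaN
    and the transcript is untestable for rules requiring that family.
    """

    R_AE: float
    R_EA: float
    Q_AE: float
    Q_EA: float


def family_ratios(df: pd.DataFrame, transcript_id: str, sample_group: str) -> FamilyRatios:
    """Ratios for one transcript in one sample group (see :func:`ratios_table`)."""
    sub = df[(df["transcript_id"] == transcript_id) & (df["sample_group"] == sample_group)]
    vals = {}
    for fam in VALID_FAMILIES:
        fsub = sub[sub["family"] == fam]
        total = fsub["count"].sum()
        if total == 0:
            vals[f"R_{fam}"] = np.nan
            vals[f"Q_{fam}"] = np.nan
        else:
            vals[f"R_{fam}"] = fsub.loc[fsub["parent"] == "maternal", "count"].sum() / total
            vals[f"Q_{fam}"] = fsub.loc[fsub["lineage"] == "Africanized", "count"].sum() / total
    return FamilyRatios(**vals)


def ratios_table(df: pd.DataFrame, method: str = "pooled") -> pd.DataFrame:
    """Per (transcript, sample group): R_AE, R_EA, Q_AE, Q_EA.

    ``method="pooled"`` (default) sums raw counts over SNPs and replicates,
    weighting by coverage; ``method="mean_snp"`` averages per-SNP pooled
    ratios instead (sensitivity analysis).
    """
    if method not in ("pooled", "mean_snp"):
        raise ValueError(f"unknown ratio method {method!r}")
    if len(df) == 0:
        return pd.DataFrame(
            columns=["transcript_id", "sample_group", "R_AE", "R_EA", "Q_AE", "Q_EA"]
        )
    work = df.assign(
        maternal=np.where(df["parent"] == "maternal", df["count"], 0),
        africanized=np.where(df["lineage"] == "Africanized", df["count"], 0),
    )
    if method == "pooled":
        agg = work.groupby(["transcript_id", "sample_group", "family"], sort=False).agg(
            total=("count", "sum"), maternal=("maternal", "sum"), africanized=("africanized", "sum")
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            agg["R"] = np.where(agg["total"] > 0, agg["maternal"] / agg["total"], np.nan)
            agg["Q"] = np.where(agg["total"] > 0, agg["africanized"] / agg["total"], np.nan)
    else:
        per_snp = work.groupby(
            ["transcript_id", "sample_group", "family", "chrom", "pos"], sort=False
        ).agg(
            total=("count", "sum"), maternal=("maternal", "sum"), africanized=("africanized", "sum")
        )
        per_snp = per_snp[per_snp["total"] > 0]
        per_snp["R"] = per_snp["maternal"] / per_snp["total"]
        per_snp["Q"] = per_snp["africanized"] / per_snp["total"]
        agg = per_snp.groupby(["transcript_id", "sample_group", "family"], sort=False)[
            ["R", "Q"]
        ].mean()
    wide = agg[["R", "Q"]].unstack("family")
    out = pd.DataFrame(
        {
            "R_AE": wide.get(("R", "AE"), pd.Series(np.nan, index=wide.index)),
            "R_EA": wide.get(("R", "EA"), pd.Series(np.nan, index=wide.index)),
            "Q_AE": wide.get(("Q", "AE"), pd.Series(np.nan, index=wide.index)),
            "Q_EA": wide.get(("Q", "EA"), pd.Series(np.nan, index=wide.index)),
        }
    ).reset_index()
    return out
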