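"""End-to-end orchestration: SNP selection -> filter -> fit -> classify -> enrich.

Every run writes deterministic result tables (no timestamps) plus a
``summary.json`` carrying per-group tallies, the enrichment statistics, the
filter report, package versions, the seed and a hash of the full
configuration, so identical configs reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import classify, counts as counts_mod, genotypes, model, stats

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Failure in a named pipeline stage (machine-readable)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage={stage}] {message}")
        self.stage = stage


class VcfInput(BaseModel):
    model_config = ConfigDict(extra="forbid")
    path: str
    queen_sample: str = "QUEEN"
    drone_sample: str = "DRONE"


class RunConfig(BaseModel):
    """All pipeline inputs and thresholds; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    counts_path: str
    informative_snps_path: Optional[str] = None
    vcf_ae: Optional[VcfInput] = None
    vcf_ea: Optional[VcfInput] = None
    out_dir: str = "psge_results"
    membership_lists: Dict[str, str] = Field(default_factory=dict)

    min_total_per_snp_library: int = Field(default=10, ge=0)
    min_snps_per_transcript: int = Field(default=1, ge=0)
    min_libraries_per_family: int = Field(default=2, ge=0)
    min_vcf_qual: Optional[float] = 20.0
    ratio_threshold: float = Field(default=0.6, gt=0.5, lt=1.0)
    q_threshold: float = Field(default=0.05, gt=0.0, lt=1.0)
    response: str = "log2"
    ratio_method: str = "pooled"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    informative_snps: pd.DataFrame
    filtered_counts: pd.DataFrame
    fits: pd.DataFrame
    calls: pd.DataFrame
    summary: dict
    out_dir: Optional[str]


def _versions() -> dict:
    import numpy, pandas as pd_, scipy, statsmodels

    from . import __version__

    return {
        "psge": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd_.__version__,
        "statsmodels": statsmodels.__version__,
    }


def load_informative_snps(config: RunConfig) -> pd.DataFrame:
    if config.informative_snps_path:
        snps = genotypes.read_informative_snps(config.informative_snps_path)
        return genotypes.informative_snps_to_frame(snps)
    if config.vcf_ae is None or config.vcf_ea is None:
        raise StageError("select-snps", "need informative_snps_path or both parental VCFs")
    selected = []
    for fam, vcf in [("AE", config.vcf_ae), ("EA", config.vcf_ea)]:
        sites = genotypes.read_parental_vcf(
            vcf.path, fam, vcf.queen_sample, vcf.drone_sample, min_qual=config.min_vcf_qual
        )
        selected.extend(genotypes.select_informative_snps(sites))
    return genotypes.informative_snps_to_frame(selected)


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write result tables under ``out_dir``.

    An empty or fully filtered counts table exits cleanly with zeroed
    summaries rather than raising.
    """
    try:
        informative = load_informative_snps(config)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("select-snps", str(exc)) from exc

    try:
        counted, rejected = counts_mod.load_counts(config.counts_path, informative_snps=informative)
    except Exception as exc:
        raise StageError("load-counts", str(exc)) from exc

    try:
        filtered, report = counts_mod.filter_counts(
            counted,
            min_total_per_snp_library=config.min_total_per_snp_library,
            min_snps_per_transcript=config.min_snps_per_transcript,
            min_libraries_per_family=config.min_libraries_per_family,
        )
    except Exception as exc:
        raise StageError("filter", str(exc)) from exc

    try:
        fits = model.fdr_adjust(model.fit_all(filtered, response=config.response), config.q_threshold)
        ratios = counts_mod.ratios_table(filtered, method=config.ratio_method)
    except Exception as exc:
        raise StageError("fit", str(exc)) from exc

    try:
        calls = classify.make_bias_calls(
            fits, ratios, ratio_threshold=config.ratio_threshold, q_threshold=config.q_threshold
        )
        tallies = classify.summarize_calls(calls, fits)
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc

    try:
        enrich = _enrichment(calls, config)
    except Exception as exc:
        raise StageError("enrich", str(exc)) from exc

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "n_rejected_count_rows": len(rejected),
        "filter_report": {
            "n_input_records": report.n_input_records,
            "n_dropped_low_coverage": report.n_dropped_low_coverage,
            "n_dropped_few_snps": report.n_dropped_few_snps,
            "n_retained": report.n_retained,
            "n_transcripts_tested": report.n_transcripts_tested,
        },
        "calls_per_group": tallies.to_dict("records"),
        "enrichment": enrich,
        "no_testable_transcripts": bool(len(fits) == 0),
    }
    result = RunResult(
        informative_snps=informative,
        filtered_counts=filtered,
        fits=fits,
        calls=calls,
        summary=summary,
        out_dir=config.out_dir,
    )
    if config.out_dir:
        _write_outputs(result, config)
    return result


def _enrichment(calls: pd.DataFrame, config: RunConfig) -> dict:
    """Per-group Storer-Kim maternal-vs-paternal tests plus list overlaps."""
    out: dict = {"storer_kim": [], "overlap_matrix": [], "membership_chisq": []}
    if len(calls) == 0:
        return out
    tested: Dict[str, set] = {}
    parent_biased: Dict[str, set] = {}
    for group, sub in calls.groupby("sample_group"):
        n = int(sub["transcript_id"].nunique())
        n_mat = int(sub["maternal_psge"].sum())
        n_pat = int(sub["paternal_psge"].sum())
        n_eur = int(sub["lineage_E"].sum())
        n_afr = int(sub["lineage_A"].sum())
        row = {"sample_group": group, "n_tested": n, "n_maternal": n_mat, "n_paternal": n_pat,
               "n_lineage_E": n_eur, "n_lineage_A": n_afr}
        if n >= 1:
            row["p_maternal_vs_paternal"] = stats.storer_kim_test(
                stats.TwoProportionData(n_mat, n, n_pat, n)
            )
            row["p_european_vs_africanized"] = stats.storer_kim_test(
                stats.TwoProportionData(n_eur, n, n_afr, n)
            )
        out["storer_kim"].append(row)
        tested[group] = set(sub["transcript_id"])
        flagged = sub["maternal_psge"] | sub["paternal_psge"]
        parent_biased[group] = set(sub.loc[flagged, "transcript_id"])
    if len(tested) >= 2:
        out["overlap_matrix"] = stats.overlap_matrix(parent_biased, tested).to_dict("records")
    for name, path in sorted(config.membership_lists.items()):
        members = stats.read_membership_list(path)
        biased_all = set().union(*parent_biased.values()) if parent_biased else set()
        tested_all = set().union(*tested.values())
        if biased_all and (tested_all - biased_all):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                res = stats.membership_chisq(biased_all, tested_all - biased_all, members)
            out["membership_chisq"].append(
                {
                    "list": name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "low_expected_count": res.low_expected_count,
                }
            )
    return out


def _write_outputs(result: RunResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash()}
    result.informative_snps.to_csv(out / "informative_snps.tsv", sep="\t", index=False)
    fits = result.fits.copy()
    fits["config_hash"] = stamp["config_hash"]
    fits.to_csv(out / "fits.tsv", sep="\t", index=False, float_format="%.10g")
    calls = result.calls.copy()
    calls["config_hash"] = stamp["config_hash"]
    calls.to_csv(out / "bias_calls.tsv", sep="\t", index=False, float_format="%.10g")
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2, sort_keys=True))
    (out / "report.txt").write_text(make_report(result))


def make_report(result: RunResult) -> str:
    """Human-readable per-group tallies and a family-ratio matrix of calls."""
    lines = [f"# PSGE run report (config {result.summary['config_hash']})", ""]
    tallies = pd.DataFrame(result.summary["calls_per_group"])
    if len(tallies) == 0:
        lines.append("No testable transcripts.")
        return "\n".join(lines) + "\n"
    lines.append(tallies.to_string(index=False))
    lines.append("")
    flagged = result.calls[result.calls[list(classify.FLAGS)].any(axis=1)]
    if len(flagged):
        lines.append("Flagged transcripts (maternal read ratio per family):")
        matrix = flagged[
            ["transcript_id", "sample_group", "R_AE", "R_EA"] + list(classify.FLAGS)
        ].copy()
        flag_col = matrix[list(classify.FLAGS)].apply(
            lambda r: ",".join(f for f in classify.FLAGS if r[f]), axis=1
        )
        matrix = matrix[["transcript_id", "sample_group", "R_AE", "R_EA"]]
        matrix["flags"] = flag_col
        lines.append(matrix.round(3).to_string(index=False))
    else:
        lines.append("No biased transcripts called.")
    for row in result.summary["enrichment"]["storer_kim"]:
        if "p_maternal_vs_paternal" in row:
            lines.append(
                f"{row['sample_group']}: maternal {row['n_maternal']} vs paternal "
                f"{row['n_paternal']} of {row['n_tested']} tested "
                f"(Storer-Kim p = {row['p_maternal_vs_paternal']:.4g})"
            )
    return "\n".join(lines) + "\n"
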