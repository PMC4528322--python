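"""Bias classification: parent-of-origin, lineage-of-origin, one-cross maternal.

A transcript is called parent-biased when the parent term survives FDR and
the pooled maternal read ratio exceeds the threshold *in the same direction
in both crosses* (maternal: R > 0.6 in AE and EA; paternal: R < 0.4 in
both).  Lineage calls mirror this with the Africanized-read ratio.  A
transcript significant for the parent x lineage interaction whose maternal
ratio exceeds the threshold in exactly one cross is called asymmetrically
maternal in that cross; transcripts already maternal in both crosses are
not asym-flagged (the lists are presented as distinct).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FLAGS = (
    "maternal_psge",
    "paternal_psge",
    "lineage_A",
    "lineage_E",
    "asym_maternal_AE",
    "asym_maternal_EA",
)


@dataclass
class Thresholds:
    ratio: float = 0.6
    q: float = 0.05


def _defined(x: float) -> bool:
    return x is not None and not np.isnan(x)


def call_parent_bias(
    q_P: float, R_AE: float, R_EA: float, ratio_threshold: float = 0.6, q_threshold: float = 0.05
) -> dict:
    """Both-cross parent-of-origin call; requires both family ratios defined."""
    flags = {"maternal_psge": False, "paternal_psge": False}
    if not (_defined(q_P) and _defined(R_AE) and _defined(R_EA)):
        return flags
    if q_P < q_threshold:
        if min(R_AE, R_EA) > ratio_threshold:
            flags["maternal_psge"] = True
        elif max(R_AE, R_EA) < 1.0 - ratio_threshold:
            flags["paternal_psge"] = True
    return flags


def call_lineage_bias(
    q_L: float, Q_AE: float, Q_EA: float, ratio_threshold: float = 0.6, q_threshold: float = 0.05
) -> dict:
    """Both-cross lineage-of-origin call on Africanized-read ratios."""
    flags = {"lineage_A": False, "lineage_E": False}
    if not (_defined(q_L) and _defined(Q_AE) and _defined(Q_EA)):
        return flags
    if q_L < q_threshold:
        if min(Q_AE, Q_EA) > ratio_threshold:
            flags["lineage_A"] = True
        elif max(Q_AE, Q_EA) < 1.0 - ratio_threshold:
            flags["lineage_E"] = True
    return flags


def call_asymmetric_maternal(
    q_PL: float, R_AE: float, R_EA: float, ratio_threshold: float = 0.6, q_threshold: float = 0.05
) -> dict:
    """Interaction-significant maternal bias in exactly one cross.

    The flagged family's ratio must be defined and exceed the threshold; the
    other family must not exceed it (an undefined other-family ratio cannot
    demonstrate asymmetry, so no call is made).  A transcript maternal in
    both crosses is left to the both-cross parent rule.
    """
    flags = {"asym_maternal_AE": False, "asym_maternal_EA": False}
    if not (_defined(q_PL) and _defined(R_AE) and _defined(R_EA)):
        return flags
    if q_PL < q_threshold:
        ae_hi, ea_hi = R_AE > ratio_threshold, R_EA > ratio_threshold
        if ae_hi and not ea_hi:
            flags["asym_maternal_AE"] = True
        elif ea_hi and not ae_hi:
            flags["asym_maternal_EA"] = True
    return flags


def _check_invariants(row: dict, ratio_threshold: float, q_threshold: float) -> None:
    if row["maternal_psge"]:
        assert row["R_AE"] > ratio_threshold and row["R_EA"] > ratio_threshold
        assert row["q_parent"] < q_threshold
        assert not row["paternal_psge"]
    if row["paternal_psge"]:
        assert row["R_AE"] < 1 - ratio_threshold and row["R_EA"] < 1 - ratio_threshold
        assert row["q_parent"] < q_threshold
    assert not (row["asym_maternal_AE"] and row["asym_maternal_EA"])


def make_bias_calls(
    fits: pd.DataFrame,
    ratios: pd.DataFrame,
    ratio_threshold: float = 0.6,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Join FDR-adjusted fits with family ratios and apply all three rules.

    Returns one row per (transcript, sample group) with boolean flag columns,
    the supporting ratios and the per-term q-values.
    """
    merged = fits.merge(ratios, on=["transcript_id", "sample_group"], how="left")
    rows = []
    for rec in merged.to_dict("records"):
        row = {
            "transcript_id": rec["transcript_id"],
            "sample_group": rec["sample_group"],
            "R_AE": rec.get("R_AE", np.nan),
            "R_EA": rec.get("R_EA", np.nan),
            "Q_AE": rec.get("Q_AE", np.nan),
            "Q_EA": rec.get("Q_EA", np.nan),
            "q_parent": rec.get("q_parent", np.nan),
            "q_lineage": rec.get("q_lineage", np.nan),
            "q_interaction": rec.get("q_interaction", np.nan),
        }
        row.update(
            call_parent_bias(row["q_parent"], row["R_AE"], row["R_EA"], ratio_threshold, q_threshold)
        )
        row.update(
            call_lineage_bias(row["q_lineage"], row["Q_AE"], row["Q_EA"], ratio_threshold, q_threshold)
        )
        row.update(
            call_asymmetric_maternal(
                row["q_interaction"], row["R_AE"], row["R_EA"], ratio_threshold, q_threshold
            )
        )
        _check_invariants(row, ratio_threshold, q_threshold)
        rows.append(row)
    cols = (
        ["transcript_id", "sample_group"]
        + list(FLAGS)
        + ["R_AE", "R_EA", "Q_AE", "Q_EA", "q_parent", "q_lineage", "q_interaction"]
    )
    return pd.DataFrame(rows, columns=cols)


def summarize_calls(calls: pd.DataFrame, fits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-group tallies of each flag plus tested transcript and SNP counts."""
    groups = sorted(calls["sample_group"].unique()) if len(calls) else []
    rows = []
    for g in groups:
        sub = calls[calls["sample_group"] == g]
        row = {"sample_group": g, "n_tested_transcripts": int(sub["transcript_id"].nunique())}
        for f in FLAGS:
            row[f"n_{f}"] = int(sub[f].sum())
        if fits is not None and len(fits):
            fsub = fits[fits["sample_group"] == g]
            row["n_snps"] = int(fsub["n_snps"].sum())
        else:
            row["n_snps"] = 0
        rows.append(row)
    cols = ["sample_group", "n_tested_transcripts", "n_snps"] + [f"n_{f}" for f in FLAGS]
    return pd.DataFrame(rows, columns=cols)
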