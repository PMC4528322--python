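"""Counts loading, filtering and family-ratio computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psge.counts import (
    COUNT_COLUMNS,
    CountsValidationError,
    family_ratios,
    filter_counts,
    frame_to_records,
    load_counts,
    ratios_table,
    records_to_frame,
)
from tests.conftest import make_counts


class TestLoadCounts:
    def test_well_formed_rows_load(self, balanced_counts, tmp_path):
        path = tmp_path / "counts.tsv"
        balanced_counts.head(2).to_csv(path, sep="\t", index=False)
        df, rejected = load_counts(str(path))
        assert len(df) == 2 and rejected == []

    def test_lineage_contradicting_family_rejected(self, balanced_counts):
        bad = balanced_counts.copy()
        bad.loc[0, "lineage"] = "European"  # AE maternal must be Africanized
        df, rejected = load_counts(bad)
        assert rejected == [0] and len(df) == len(bad) - 1

    def test_unknown_tokens_and_negative_counts_hard_error(self, balanced_counts):
        for col, val in [("family", "XX"), ("sample_group", "pupae"), ("parent", "stepparent")]:
            bad = balanced_counts.copy()
            bad.loc[0, col] = val
            with pytest.raises(CountsValidationError):
                load_counts(bad)
        bad = balanced_counts.copy()
        bad.loc[0, "count"] = -1
        with pytest.raises(CountsValidationError):
            load_counts(bad)

    def test_duplicate_cell_rows_rejected(self, balanced_counts):
        with pytest.raises(CountsValidationError, match="duplicate"):
            load_counts(pd.concat([balanced_counts, balanced_counts.head(1)]))

    def test_snp_absent_from_informative_table_rejected(self, balanced_counts):
        informative = pd.DataFrame(
            {"family": ["AE", "EA"], "chrom": ["chr1", "chr1"], "pos": [100, 100]}
        )
        df, rejected = load_counts(balanced_counts, informative_snps=informative)
        assert set(df["pos"]) == {100}
        assert len(rejected) == (balanced_counts["pos"] == 200).sum()

    def test_write_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        cells = [
            (f"tx{t}", "chr2", 100 * s, fam, f"{fam}_adults_{r}", rng.integers(0, 99), rng.integers(0, 99))
            for t in range(3)
            for s in range(1, 4)
            for fam in ("AE", "EA")
            for r in (1, 2)
        ]
        df = make_counts(cells, sample_group="adults")
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t", index=False)
        back, rejected = load_counts(str(path))
        assert rejected == []
        pd.testing.assert_frame_equal(back, df.astype(back.dtypes))
        assert records_to_frame(frame_to_records(back)).equals(back)


def _brute_force_filter(df, min_total, min_snps, min_libs):
    """Record-wise oracle: independent re-derivation of the filter rules."""
    keep = []
    for _, row in df.iterrows():
        cell = df[
            (df.transcript_id == row.transcript_id)
            & (df.chrom == row.chrom)
            & (df.pos == row.pos)
            & (df.family == row.family)
            & (df.replicate_id == row.replicate_id)
            & (df.sample_group == row.sample_group)
        ]
        keep.append(cell["count"].sum() >= min_total)
    kept = df[np.array(keep)]
    final = []
    for _, row in kept.iterrows():
        sub = kept[(kept.transcript_id == row.transcript_id) & (kept.sample_group == row.sample_group)]
        n_snps = sub[["chrom", "pos"]].drop_duplicates().shape[0]
        libs_ok = all(
            sub[sub.family == fam]["replicate_id"].nunique() >= min_libs for fam in ("AE", "EA")
        )
        final.append(n_snps >= min_snps and libs_ok)
    return kept[np.array(final)] if len(kept) else kept


class TestFilterCounts:
    def test_low_coverage_cell_dropped(self):
        df = make_counts([("tx1", "chr1", 100, "AE", "AE_larvae_1", 4, 5)])
        out, report = filter_counts(df, min_total_per_snp_library=10, min_libraries_per_family=0)
        assert len(out) == 0 and report.n_dropped_low_coverage == 2
        report.check()

    def test_zero_thresholds_are_identity(self, balanced_counts):
        out, report = filter_counts(balanced_counts, 0, 0, 0)
        assert len(out) == len(balanced_counts)
        assert report.n_dropped_low_coverage == 0 and report.n_dropped_few_snps == 0

    def test_min_libraries_drops_underrepresented_family(self):
        cells = [
            ("tx1", "chr1", 100, "AE", "AE_larvae_1", 30, 30),
            ("tx1", "chr1", 100, "AE", "AE_larvae_2", 30, 30),
            ("tx1", "chr1", 100, "EA", "EA_larvae_1", 30, 30),
        ]
        out, _ = filter_counts(make_counts(cells), min_libraries_per_family=2)
        assert len(out) == 0

    def test_negative_threshold_rejected(self, balanced_counts):
        with pytest.raises(ValueError):
            filter_counts(balanced_counts, -1, 0, 0)

    def test_randomized_fixture_matches_bruteforce_oracle(self, rng):
        cells = []
        for t in range(4):
            for s in range(rng.integers(1, 4)):
                for fam in ("AE", "EA"):
                    for r in range(1, int(rng.integers(1, 4))):
                        cells.append(
                            (f"tx{t}", "chr1", 100 * (s + 1), fam, f"{fam}_brains_{r}",
                             int(rng.integers(0, 30)), int(rng.integers(0, 30)))
                        )
        df = make_counts(cells, sample_group="brains")
        for args in [(10, 1, 2), (15, 2, 1), (0, 1, 1)]:
            got, report = filter_counts(df, *args)
            oracle = _brute_force_filter(df, *args)
            assert sorted(map(tuple, got.values.tolist())) == sorted(
                map(tuple, oracle.values.tolist())
            )
            report.check()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        t1=st.integers(0, 25),
        t2=st.integers(0, 25),
        s1=st.integers(1, 3),
        l1=st.integers(0, 3),
    )
    def test_filtering_is_monotone_in_thresholds(self, t1, t2, s1, l1):
        """Raising any threshold never grows the retained set."""
        rng = np.random.default_rng(99)
        cells = [
            (f"tx{t}", "chr1", 100 * s, fam, f"{fam}_larvae_{r}",
             int(rng.integers(0, 25)), int(rng.integers(0, 25)))
            for t in range(3)
            for s in range(1, 3)
            for fam in ("AE", "EA")
            for r in (1, 2)
        ]
        df = make_counts(cells)
        lo, hi = sorted((t1, t2))
        small, _ = filter_counts(df, hi, s1, l1)
        big, _ = filter_counts(df, lo, s1, l1)
        keys = lambda d: set(map(tuple, d.values.tolist()))
        assert keys(small) <= keys(big)


class TestFamilyRatios:
    def test_symmetric_totals_give_half(self):
        cells = [
            ("tx1", "chr1", 100, "AE", "AE_larvae_1", 30, 25),
            ("tx1", "chr1", 200, "AE", "AE_larvae_1", 20, 25),
        ]
        r = family_ratios(make_counts(cells), "tx1", "larvae")
        assert r.R_AE == pytest.approx(0.5)
        assert r.Q_AE == pytest.approx(0.5)  # AE: maternal reads are Africanized

    def test_single_snp_direct_fraction(self):
        df = make_counts([("tx1", "chr1", 100, "EA", "EA_larvae_1", 80, 20)])
        r = family_ratios(df, "tx1", "larvae")
        assert r.R_EA == pytest.approx(0.8)
        assert r.Q_EA == pytest.approx(0.2)  # EA: Africanized reads are paternal
        assert np.isnan(r.R_AE)

    def test_pooled_ratio_matches_row_summation_oracle(self, rng):
        cells = [
            ("tx1", "chr1", 100 * s, fam, f"{fam}_larvae_{r}",
             int(rng.integers(1, 60)), int(rng.integers(1, 60)))
            for s in (1, 2, 3)
            for fam in ("AE", "EA")
            for r in (1, 2)
        ]
        df = make_counts(cells)
        r = family_ratios(df, "tx1", "larvae")
        for fam, attr in [("AE", "R_AE"), ("EA", "R_EA")]:
            sub = df[df.family == fam]
            oracle = sub.loc[sub.parent == "maternal", "count"].sum() / sub["count"].sum()
            assert getattr(r, attr) == pytest.approx(oracle)
        # complementarity: maternal + paternal ratio == 1 exactly
        for fam in ("AE", "EA"):
            sub = df[df.family == fam]
            pat = sub.loc[sub.parent == "paternal", "count"].sum() / sub["count"].sum()
            assert getattr(r, f"R_{fam}") + pat == pytest.approx(1.0, abs=1e-12)
        # design identity: R_AE == Q_AE, R_EA == 1 - Q_EA
        assert r.R_AE == pytest.approx(r.Q_AE)
        assert r.R_EA == pytest.approx(1.0 - r.Q_EA)

    def test_zero_family_total_is_nan(self):
        df = make_counts([("tx1", "chr1", 100, "AE", "AE_larvae_1", 0, 0)])
        r = family_ratios(df, "tx1", "larvae")
        assert np.isnan(r.R_AE) and np.isnan(r.Q_AE)

    def test_ratios_table_agrees_with_scalar_path(self, rng):
        cells = [
            (f"tx{t}", "chr1", 100 * s, fam, f"{fam}_larvae_{r}",
             int(rng.integers(0, 60)), int(rng.integers(0, 60)))
            for t in range(3)
            for s in (1, 2)
            for fam in ("AE", "EA")
            for r in (1, 2)
        ]
        df = make_counts(cells)
        table = ratios_table(df).set_index("transcript_id")
        for tid in table.index:
            scalar = family_ratios(df, tid, "larvae")
            for col in ("R_AE", "R_EA", "Q_AE", "Q_EA"):
                assert table.loc[tid, col] == pytest.approx(getattr(scalar, col), nan_ok=True)

    def test_mean_snp_method_differs_from_pooled_when_coverage_skewed(self):
        cells = [
            ("tx1", "chr1", 100, "AE", "AE_larvae_1", 90, 10),  # deep SNP, R=0.9
            ("tx1", "chr1", 200, "AE", "AE_larvae_1", 1, 9),  # shallow SNP, R=0.1
            ("tx1", "chr1", 100, "EA", "EA_larvae_1", 50, 50),
        ]
        df = make_counts(cells)
        pooled = ratios_table(df, method="pooled").iloc[0]["R_AE"]
        mean_snp = ratios_table(df, method="mean_snp").iloc[0]["R_AE"]
        assert pooled == pytest.approx(91 / 110)
        assert mean_snp == pytest.approx(0.5)
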