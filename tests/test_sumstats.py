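"""Parsing, allele harmonization and QC filtering of summary statistics."""

import numpy as np
import pandas as pd
import pytest

from gsemkit.sumstats import (
    ConfigurationError, InputError, MungedTrait, RawSumstats, ReferencePanel,
    effective_n, munge, parse_sumstats, sum_effective_n,
)

CMAP = {"snp": "SNP", "effect_allele": "A1", "other_allele": "A2",
        "beta": "BETA", "se": "SE", "p": "P", "n": "N"}


def write_sumstats(path, rows, header="SNP A1 A2 BETA SE P N"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestParse:
    def test_identity_parse(self, tmp_path):
        f = write_sumstats(tmp_path / "s.txt", [
            "rs1 A G 0.1 0.05 0.045 1000",
            "rs2 C T -0.2 0.10 0.045 1000",
            "rs3 A G 0.0 0.05 0.999 1000",
        ])
        raw = parse_sumstats(f, CMAP)
        assert len(raw.table) == 3
        assert raw.n_dropped_parse == 0
        assert list(raw.table["SNP"]) == ["rs1", "rs2", "rs3"]

    def test_na_row_dropped_and_counted(self, tmp_path):
        f = write_sumstats(tmp_path / "s.txt", [
            "rs1 A G 0.1 0.05 0.045 1000",
            "rs2 C T -0.2 NA NA 1000",
            "rs3 A G 0.0 0.05 0.999 1000",
        ])
        raw = parse_sumstats(f, CMAP)
        assert len(raw.table) == 2
        assert raw.n_dropped_parse == 1

    def test_z_column_passthrough_exact(self, tmp_path):
        f = write_sumstats(tmp_path / "s.txt", [
            "rs1 A G 1.234 1000",
            "rs2 C T -2.5 1000",
        ], header="SNP A1 A2 Z N")
        cmap = {"snp": "SNP", "effect_allele": "A1", "other_allele": "A2",
                "z": "Z", "n": "N"}
        raw = parse_sumstats(f, cmap)
        assert raw.table["Z"].tolist() == [1.234, -2.5]

    def test_missing_mandatory_column_names_it(self, tmp_path):
        f = write_sumstats(tmp_path / "s.txt", ["rs1 A 0.1 0.05 0.5 100"],
                           header="SNP A1 BETA SE P N")
        with pytest.raises(ConfigurationError, match="other_allele"):
            parse_sumstats(f, CMAP)

    def test_no_signed_statistic_rejected(self, tmp_path):
        f = write_sumstats(tmp_path / "s.txt", ["rs1 A G 0.5 100"],
                           header="SNP A1 A2 P N")
        with pytest.raises(ConfigurationError, match="signed statistic"):
            parse_sumstats(f, {"snp": "SNP", "effect_allele": "A1",
                               "other_allele": "A2", "p": "P", "n": "N"})


def make_raw(records) -> RawSumstats:
    return RawSumstats("t", pd.DataFrame(records))


class TestMunge:
    def test_sign_flip_when_effect_allele_is_panel_a2(self, small_panel):
        # panel rs1 is A/G; effect allele G (= panel A2) must flip the sign
        raw = make_raw([{"SNP": "rs1", "A1": "G", "A2": "A",
                         "BETA": 0.1, "SE": 0.05, "N": 1000.0}])
        out = munge(raw, small_panel)
        assert out.table["Z"].iloc[0] == pytest.approx(-2.0)

    def test_low_info_dropped(self, small_panel):
        raw = make_raw([
            {"SNP": "rs1", "A1": "A", "A2": "G", "BETA": 0.1, "SE": 0.05,
             "N": 1000.0, "INFO": 0.85},
            {"SNP": "rs3", "A1": "A", "A2": "G", "BETA": 0.1, "SE": 0.05,
             "N": 1000.0, "INFO": 0.95},
        ])
        out = munge(raw, small_panel)
        assert list(out.table["SNP"]) == ["rs3"]
        assert out.qc_report["low_info"] == 1

    def test_low_maf_dropped(self, small_panel):
        raw = make_raw([
            {"SNP": "rs1", "A1": "A", "A2": "G", "BETA": 0.1, "SE": 0.05,
             "N": 1000.0, "EAF": 0.995},
            {"SNP": "rs3", "A1": "A", "A2": "G", "BETA": 0.1, "SE": 0.05,
             "N": 1000.0, "EAF": 0.30},
        ])
        out = munge(raw, small_panel)
        assert list(out.table["SNP"]) == ["rs3"]
        assert out.qc_report["low_maf"] == 1

    @pytest.mark.parametrize("a1,a2,kept,flipped", [
        ("A", "G", True, False),   # same orientation
        ("G", "A", True, True),    # swapped -> sign flip
        ("T", "C", True, False),   # strand complement of A/G
        ("C", "T", True, True),    # complement swapped
        ("A", "T", False, False),  # strand-ambiguous
        ("T", "A", False, False),
        ("C", "G", False, False),
        ("G", "C", False, False),
        ("A", "C", False, False),  # mismatch with panel pair
        ("C", "A", False, False),
        ("G", "T", False, False),
        ("T", "G", False, False),
    ])
    def test_allele_pair_enumeration(self, small_panel, a1, a2, kept, flipped):
        """All 12 ordered allele pairs against the panel's A/G record."""
        raw = make_raw([{"SNP": "rs1", "A1": a1, "A2": a2,
                         "BETA": 0.1, "SE": 0.05, "N": 1000.0}])
        if not kept:
            with pytest.raises(InputError):
                munge(raw, small_panel)
            return
        out = munge(raw, small_panel)
        assert len(out) == 1
        assert out.table["Z"].iloc[0] == pytest.approx(-2.0 if flipped else 2.0)

    def test_z_from_signed_beta_and_p(self, small_panel):
        from scipy import stats
        raw = make_raw([{"SNP": "rs1", "A1": "A", "A2": "G",
                         "BETA": -0.1, "P": 0.05, "N": 1000.0}])
        out = munge(raw, small_panel)
        assert out.table["Z"].iloc[0] == pytest.approx(-stats.norm.isf(0.025))

    def test_munging_is_idempotent(self, small_panel):
        raw = make_raw([
            {"SNP": "rs1", "A1": "A", "A2": "G", "BETA": 0.1, "SE": 0.05, "N": 1000.0},
            {"SNP": "rs4", "A1": "T", "A2": "C", "BETA": -0.3, "SE": 0.1, "N": 1000.0},
        ])
        once = munge(raw, small_panel)
        panel_t = small_panel.table.set_index("SNP")
        again_raw = RawSumstats("t", pd.DataFrame({
            "SNP": once.table["SNP"],
            "A1": panel_t.loc[once.table["SNP"], "A1"].to_numpy(),
            "A2": panel_t.loc[once.table["SNP"], "A2"].to_numpy(),
            "Z": once.table["Z"], "N": once.table["N"],
        }))
        twice = munge(again_raw, small_panel)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_allele_swap_antisymmetry(self, small_panel):
        base = {"SNP": "rs1", "SE": 0.05, "N": 1000.0}
        fwd = make_raw([{**base, "A1": "A", "A2": "G", "BETA": 0.1}])
        rev = make_raw([{**base, "A1": "G", "A2": "A", "BETA": -0.1}])
        out_f = munge(fwd, small_panel)
        out_r = munge(rev, small_panel)
        pd.testing.assert_frame_equal(out_f.table, out_r.table)

    @pytest.mark.parametrize("kind", ["info", "maf"])
    def test_filter_monotonicity(self, small_panel, kind):
        rng = np.random.default_rng(0)
        recs = []
        for i, snp in enumerate(["rs1", "rs2", "rs3", "rs4", "rs5"]):
            panel_row = small_panel.table.iloc[i]
            recs.append({"SNP": snp, "A1": panel_row["A1"], "A2": panel_row["A2"],
                         "BETA": rng.normal(), "SE": 0.1, "N": 1000.0,
                         "INFO": rng.uniform(0.7, 1.0),
                         "EAF": rng.uniform(0.0, 0.5)})
        raw = make_raw(recs)
        counts = []
        for thr in (0.0, 0.25, 0.5, 0.75, 0.95):
            kw = {"min_info": thr} if kind == "info" else {"min_maf": thr / 2}
            try:
                counts.append(len(munge(raw, small_panel, **kw)))
            except InputError:
                counts.append(0)
        assert counts == sorted(counts, reverse=True)

    def test_duplicates_keep_first(self, small_panel):
        raw = make_raw([
            {"SNP": "rs1", "A1": "A", "A2": "G", "BETA": 0.1, "SE": 0.05, "N": 1000.0},
            {"SNP": "rs1", "A1": "A", "A2": "G", "BETA": 0.9, "SE": 0.05, "N": 1000.0},
        ])
        out = munge(raw, small_panel)
        assert len(out) == 1
        assert out.table["Z"].iloc[0] == pytest.approx(2.0)
        assert out.qc_report["duplicate"] == 1

    def test_roundtrip_write_read(self, small_panel, tmp_path):
        raw = make_raw([{"SNP": "rs1", "A1": "A", "A2": "G",
                         "BETA": 0.1, "SE": 0.05, "N": 1000.0}])
        out = munge(raw, small_panel)
        p = tmp_path / "t.sumstats.tsv"
        out.write(p)
        back = MungedTrait.read(p)
        pd.testing.assert_frame_equal(out.table, back.table)


class TestEffectiveN:
    def test_balanced_design(self):
        assert effective_n(500, 500) == pytest.approx(1000.0)

    def test_alzheimers_cohort_value(self):
        # 17 008 cases / 37 154 controls
        assert effective_n(17_008, 37_154) == pytest.approx(46_669.0, abs=1.0)

    def test_meta_analysis_sums_cohorts(self):
        assert sum_effective_n([(100, 100), (200, 200)]) == pytest.approx(600.0)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(InputError):
            effective_n(0, 10)
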