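"""Summary-statistics I/O, validation, and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from targetmr.sumstats import (GeneAnnotation, cis_window, harmonize,
                               harmonize_frames, read_gene_annotations,
                               read_sumstats, write_sumstats)

from conftest import make_table


class TestReadWrite:
    def test_round_trip_identity(self, tmp_path):
        table = make_table([{"beta": 0.123456789}, {"pos": 2000, "beta": -0.2},
                            {"pos": 3000, "se": 0.01}])
        path = tmp_path / "t.tsv"
        write_sumstats(table, path)
        back = read_sumstats(path, trait_id="trait")
        pd.testing.assert_frame_equal(back.df, table.df, check_exact=False,
                                      rtol=1e-9)
        assert back.n_dropped == 0

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        df = make_table([{}, {"pos": 2000}, {"pos": 3000}]).df.copy()
        df.loc[1, "se"] = 0.0
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_sumstats(path)
        assert len(table) == 2
        assert table.drop_reasons == {"nonpositive_se": 1}

    def test_indels_dropped_with_reason(self, tmp_path):
        df = make_table([{}, {"pos": 2000}]).df.copy()
        df.loc[0, "effect_allele"] = "AT"
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_sumstats(path)
        assert table.drop_reasons == {"indel_or_multiallelic": 1}

    def test_missing_pval_filled_from_normal_tail(self, tmp_path):
        df = make_table([{"beta": 1.96, "se": 1.0}]).df.drop(columns=["pval"])
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_sumstats(path)
        assert table.df["pval"].iloc[0] == pytest.approx(0.0500, abs=5e-4)

    def test_missing_mandatory_column_names_it(self, tmp_path):
        df = make_table([{}]).df.drop(columns=["se"])
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="'se'"):
            read_sumstats(path)

    def test_column_map_renames_foreign_headers(self, tmp_path):
        df = make_table([{}]).df.rename(columns={"beta": "Effect", "se": "StdErr"})
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_sumstats(path, column_map={"beta": "Effect", "se": "StdErr"})
        assert table.df["beta"].iloc[0] == pytest.approx(0.1)


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.2}])
        out = make_table([{"effect_allele": "G", "other_allele": "A",
                           "beta": -0.10, "eaf": 0.30}])
        (pair,) = harmonize(exp, out)
        assert pair.action_taken == "sign_flipped"
        assert pair.beta_out == pytest.approx(0.10)
        assert pair.eaf_out == pytest.approx(0.70)
        assert pair.effect_allele == "A"

    def test_ambiguous_palindromic_dropped(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}])
        out = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}])
        (pair,) = harmonize(exp, out)
        assert pair.action_taken == "dropped_palindromic"

    def test_palindromic_resolved_by_frequency(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "T",
                           "eaf": 0.10, "beta": 0.2}])
        # outcome reports the T allele: eaf on the other side of 0.5
        out = make_table([{"effect_allele": "A", "other_allele": "T",
                           "eaf": 0.90, "beta": 0.3}])
        (pair,) = harmonize(exp, out)
        assert pair.action_taken == "freq_inferred"
        assert pair.beta_out == pytest.approx(-0.3)
        assert pair.eaf_out == pytest.approx(0.10)

    def test_allele_set_mismatch_dropped(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G"}])
        out = make_table([{"effect_allele": "A", "other_allele": "C"}])
        (pair,) = harmonize(exp, out)
        assert pair.action_taken == "dropped_mismatch"

    def test_self_harmonization_is_identity(self):
        table = make_table([{"beta": 0.2}, {"pos": 2000, "beta": -0.4},
                            {"pos": 3000, "effect_allele": "T",
                             "other_allele": "G", "beta": 0.05}])
        pairs = harmonize(table, table)
        assert all(p.action_taken == "kept" for p in pairs)
        assert [p.beta_out for p in pairs] == [p.beta_exp for p in pairs]

    def test_idempotent_on_kept_output(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.2},
                          {"pos": 2000, "beta": 0.1}])
        out = make_table([{"effect_allele": "G", "other_allele": "A",
                           "beta": -0.1, "eaf": 0.7},
                          {"pos": 2000, "beta": 0.3}])
        first = harmonize_frames(exp.df, out.df)
        kept = first[first["action_taken"].isin(("kept", "sign_flipped"))]
        realigned = out.df.copy()
        idx = realigned.set_index("variant_id").index
        for r in kept.itertuples(index=False):
            sel = realigned["variant_id"] == r.variant_id
            realigned.loc[sel, ["effect_allele", "other_allele", "beta", "eaf"]] = [
                r.effect_allele, r.other_allele, r.beta_out, r.eaf_out]
        second = harmonize_frames(exp.df, realigned)
        assert (second["action_taken"] == "kept").all()
        np.testing.assert_allclose(second["beta_out"].to_numpy(),
                                   kept["beta_out"].to_numpy())

    @given(flip_exp=st.booleans(), flip_out=st.booleans(),
           beta_exp=st.floats(-1, 1, allow_nan=False),
           beta_out=st.floats(-1, 1, allow_nan=False))
    def test_flip_invariance_of_effect_product(self, flip_exp, flip_out,
                                               beta_exp, beta_out):
        """Recoding alleles on either side leaves beta_exp * beta_out invariant."""
        def table(beta, flipped):
            rec = {"effect_allele": "G" if flipped else "A",
                   "other_allele": "A" if flipped else "G",
                   "beta": -beta if flipped else beta,
                   "eaf": 0.7 if flipped else 0.3}
            return make_table([rec])
        baseline = harmonize(table(beta_exp, False), table(beta_out, False))
        variant = harmonize(table(beta_exp, flip_exp), table(beta_out, flip_out))
        prod0 = baseline[0].beta_exp * baseline[0].beta_out
        prod1 = variant[0].beta_exp * variant[0].beta_out
        assert prod1 == pytest.approx(prod0, abs=1e-12)


class TestCisWindow:
    GENE = GeneAnnotation("G1", "G1", "1", 2_000_000, 2_010_000)

    @pytest.mark.parametrize("pos,included", [
        (1_500_000, True),        # 0.5 Mb upstream
        (3_600_000, False),       # > 1 Mb downstream
        (1_000_000, True),        # exactly 1 Mb before start: boundary inclusive
        (3_010_000, True),        # exactly 1 Mb after end
        (999_999, False),
    ])
    def test_window_boundaries(self, pos, included):
        table = make_table([{"pos": pos}])
        sub = cis_window(self.GENE, table)
        assert (len(sub) == 1) == included

    def test_unknown_chromosome_empty_with_warning(self, caplog):
        table = make_table([{"chrom": "2", "pos": 2_000_000}])
        with caplog.at_level("WARNING"):
            sub = cis_window(self.GENE, table)
        assert len(sub) == 0
        assert "chromosome" in caplog.text


def test_gene_annotations_zero_based_conversion(tmp_path):
    path = tmp_path / "genes.bed"
    path.write_text("1\t999\t2000\tG1\tSYM1\n")
    (g0,) = read_gene_annotations(path, zero_based_half_open=True)
    (g1,) = read_gene_annotations(path, zero_based_half_open=False)
    assert (g0.start, g0.end) == (1000, 2000)
    assert (g1.start, g1.end) == (999, 2000)
    assert g0.symbol == "SYM1"
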