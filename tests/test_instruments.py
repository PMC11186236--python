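"""Instrument selection, LD clumping, F-statistics, and the Steiger filter."""

import numpy as np
import pytest

from targetmr.ld import (LDMatrix, clump, f_statistic, is_weak_instrument,
                         read_ld, select_instruments, steiger_filter, write_ld)

from conftest import make_pair, make_table


class TestSelectInstruments:
    @pytest.mark.parametrize("threshold,retained", [
        (1.8e-9, True),       # deCODE-style genome-wide threshold
        (1.004e-11, False),   # Fenland-style, stricter
        (1.7e-11, False),     # UKB-PPP-style
    ])
    def test_source_thresholds(self, threshold, retained):
        table = make_table([{"pval": 1e-10}])
        assert (len(select_instruments(table, threshold)) == 1) == retained

    def test_empty_input_empty_output(self):
        table = make_table([{"pval": 0.5}])
        empty = table.subset(table.df["pval"] < 0)
        assert len(select_instruments(empty, 1e-8)) == 0


def _ld_from_r(ids, r):
    return LDMatrix(ids, np.asarray(r))


def _brute_force_clump(df, ld, r2_max, window_kb):
    """Reference greedy clumping re-derived from the definition."""
    remaining = list(df.sort_values(["pval", "chrom", "pos"]).itertuples())
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best.variant_id)
        survivors = []
        for row in remaining:
            close = (row.chrom == best.chrom
                     and abs(row.pos - best.pos) <= window_kb * 1000)
            r2 = ld.r_between(best.variant_id, row.variant_id) ** 2
            if not (close and r2 > r2_max):
                survivors.append(row)
        remaining = survivors
    return sorted(kept)


class TestClump:
    def test_greedy_keeps_independent_signals(self):
        table = make_table([{"pval": 1e-20}, {"pos": 2000, "pval": 1e-15},
                            {"pos": 3000, "pval": 1e-12}])
        r = [[1.0, 0.71, 0.03], [0.71, 1.0, 0.10], [0.03, 0.10, 1.0]]
        kept = clump(table, _ld_from_r(["rs1", "rs2", "rs3"], r),
                     r2_max=0.01, window_kb=10_000)
        assert list(kept.df["variant_id"]) == ["rs1", "rs3"]

    def test_no_ld_keeps_all(self):
        table = make_table([{"pval": 1e-20}, {"pos": 2000, "pval": 1e-15}])
        kept = clump(table, _ld_from_r(["rs1", "rs2"], np.eye(2)), 0.01, 10_000)
        assert len(kept) == 2

    def test_loose_r2_and_zero_window_return_input(self):
        table = make_table([{"pval": 1e-20}, {"pos": 2000, "pval": 1e-15}])
        ld = _ld_from_r(["rs1", "rs2"], [[1.0, 0.99], [0.99, 1.0]])
        kept = clump(table, ld, r2_max=1.0, window_kb=0)
        assert list(kept.df["variant_id"]) == ["rs1", "rs2"]

    def test_missing_variant_is_hard_error(self):
        table = make_table([{"pval": 1e-20}])
        with pytest.raises(KeyError, match="rs1"):
            clump(table, _ld_from_r(["other"], np.eye(1)), 0.01, 10_000)

    def test_matches_reference_on_random_instances(self, rng):
        for _ in range(20):
            m = 10
            A = rng.standard_normal((m, 2 * m))
            r = np.corrcoef(A)
            table = make_table([{"pos": 1000 + 5000 * i,
                                 "pval": float(rng.uniform(1e-12, 1e-4))}
                                for i in range(m)])
            ld = LDMatrix(list(table.df["variant_id"]), r)
            kept = clump(table, ld, r2_max=0.1, window_kb=20)
            assert sorted(kept.df["variant_id"]) == _brute_force_clump(
                table.df, ld, 0.1, 20)
            # invariants: subset of input containing the global minimum-p variant
            assert set(kept.df["variant_id"]) <= set(table.df["variant_id"])
            best = table.df.loc[table.df["pval"].idxmin(), "variant_id"]
            assert best in set(kept.df["variant_id"])


class TestFStatistic:
    @pytest.mark.parametrize("beta,se,f,weak", [
        (0.1, 0.02, 25.0, False),
        (0.0, 0.02, 0.0, True),
        (0.03, 0.01, 9.0, True),   # below the F > 10 rule of thumb
    ])
    def test_values_and_weak_flag(self, beta, se, f, weak):
        val = f_statistic(beta, se)
        assert val == pytest.approx(f)
        assert is_weak_instrument(val) is weak

    def test_sign_flip_invariance(self):
        assert f_statistic(0.1, 0.02) == f_statistic(-0.1, 0.02)


class TestSteiger:
    def test_exposure_dominant_retained(self):
        # exposure t = 20 at n = 10,000; outcome t = 2 at n = 400,000
        pair = make_pair(bx=0.2, sx=0.01, by=0.002, sy=0.001,
                         n_exp=10_000, n_out=400_000)
        kept, (rec,) = steiger_filter([pair])
        assert rec.r2_exposure == pytest.approx(0.0385, abs=1e-4)
        assert rec.r2_outcome == pytest.approx(1.0e-5, abs=2e-6)
        assert len(kept) == 1

    def test_outcome_dominant_dropped(self):
        pair = make_pair(bx=0.01, sx=0.01, by=0.5, sy=0.01,
                         n_exp=10_000, n_out=10_000)
        kept, (rec,) = steiger_filter([pair])
        assert kept == [] and not rec.retained

    def test_exact_tie_dropped(self):
        pair = make_pair(bx=0.1, sx=0.01, by=0.1, sy=0.01,
                         n_exp=10_000, n_out=10_000)
        kept, (rec,) = steiger_filter([pair])
        assert kept == [] and rec.reason == "outcome_variance_not_smaller"

    def test_insufficient_n_dropped_with_reason(self):
        pair = make_pair(bx=0.1, sx=0.01, by=0.0, sy=0.01, n_exp=2)
        kept, (rec,) = steiger_filter([pair])
        assert kept == [] and rec.reason == "insufficient_n"


class TestLDMatrixIO:
    def test_round_trip(self, tmp_path, rng):
        A = rng.standard_normal((4, 8))
        ld = LDMatrix([f"v{i}" for i in range(4)], np.corrcoef(A))
        path = tmp_path / "ld.txt"
        write_ld(ld, path)
        back = read_ld(path)
        assert back.variant_ids == ld.variant_ids
        np.testing.assert_allclose(back.r, ld.r, atol=1e-9)

    def test_rejects_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            LDMatrix(["a", "b"], [[1.0, 0.5], [0.4, 1.0]])

    def test_rejects_non_psd(self):
        with pytest.raises(ValueError, match="semi-definite"):
            LDMatrix(["a", "b", "c"],
                     [[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
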