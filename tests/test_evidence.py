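"""FDR, meta-analysis, replication counting, direction, and tier assignment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from targetmr.evidence import (EvidenceRow, OutcomeSpec, assign_tier, bh_fdr,
                               build_evidence_table, count_replications,
                               direction_consistency, fixed_effect_meta)
from targetmr.mr import MRResult


class TestBHFDR:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.001, 0.02, 0.9]),
                                   [0.003, 0.03, 0.9], atol=1e-12)

    def test_monotone_enforcement_on_ties(self):
        np.testing.assert_allclose(bh_fdr([0.05, 0.05]), [0.05, 0.05])

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(0.001, 1, 20)
        q = bh_fdr(p)
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm], atol=1e-14)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_null_fdr_control(self, rng):
        """Realized false-discovery proportion under the uniform null."""
        fdps = []
        for _ in range(200):
            p = rng.uniform(0, 1, 500).clip(1e-12)
            fdps.append(np.mean(bh_fdr(p) < 0.05) if p.size else 0.0)
        assert np.mean(fdps) <= 0.05


class TestFixedEffectMeta:
    def test_equal_precision_average(self):
        beta, se, *_ = fixed_effect_meta([(0.2, 0.1), (0.4, 0.1)])
        assert beta == pytest.approx(0.3)
        assert se == pytest.approx(0.1 / np.sqrt(2))

    def test_single_estimate_passes_through(self):
        beta, se, p, or_, ci = fixed_effect_meta([(0.2, 0.1)])
        assert beta == pytest.approx(0.2, abs=1e-15)
        assert se == pytest.approx(0.1, abs=1e-15)
        assert or_ == pytest.approx(np.exp(0.2))

    def test_matches_closed_form_oracle(self, rng):
        for _ in range(10):
            b = rng.normal(0, 0.3, 5)
            s = rng.uniform(0.05, 0.3, 5)
            beta, se, *_ = fixed_effect_meta(list(zip(b, s)))
            w = 1 / s**2
            assert beta == pytest.approx(np.sum(w * b) / np.sum(w), abs=1e-12)
            assert se == pytest.approx(np.sqrt(1 / np.sum(w)), abs=1e-12)

    def test_se_never_exceeds_smallest_input_se(self, rng):
        for _ in range(10):
            ests = [(float(b), float(s)) for b, s in
                    zip(rng.normal(0, 1, 4), rng.uniform(0.01, 0.5, 4))]
            _, se, *_ = fixed_effect_meta(ests)
            assert se <= min(s for _, s in ests) + 1e-15


def _mr(beta, pval, oid="o"):
    return MRResult("P", oid, "ivw", beta, 0.1, pval, 3)


class TestCountReplications:
    SPECS = {
        "eGFRcrea": OutcomeSpec("eGFRcrea", "egfr_continuous", -1),
        "CKD2": OutcomeSpec("CKD2", "ckd_binary", +1),
    }

    def test_polarity_maps_egfr_decrease_to_risk(self):
        # harmful protein: lower eGFR (negative beta, polarity -1) replicates
        n = count_replications(0.3, {"eGFRcrea": _mr(-0.05, 0.001)}, self.SPECS)
        assert n == 1

    def test_nonsignificant_not_counted(self):
        n = count_replications(0.3, {"eGFRcrea": _mr(-0.05, 0.2)}, self.SPECS)
        assert n == 0

    def test_wrong_direction_not_counted(self):
        n = count_replications(0.3, {"eGFRcrea": _mr(0.05, 0.001)}, self.SPECS)
        assert n == 0

    def test_missing_results_skipped(self):
        n = count_replications(0.3, {"eGFRcrea": None}, self.SPECS)
        assert n == 0

    def test_protective_protein_replication_count(self):
        """A protective protein with 11 concordant significant panel outcomes."""
        specs, results = {}, {}
        for i in range(3):  # concordant significant CKD replications
            oid = f"CKD{i + 2}"
            specs[oid] = OutcomeSpec(oid, "ckd_binary", +1)
            results[oid] = _mr(-0.2, 0.001, oid)
        for i in range(8):  # concordant significant eGFR-style outcomes
            oid = f"egfr{i}"
            specs[oid] = OutcomeSpec(oid, "egfr_continuous", -1)
            results[oid] = _mr(+0.05, 0.001, oid)
        for i in range(6):  # discordant or non-significant: never counted
            oid = f"clin{i}"
            specs[oid] = OutcomeSpec(oid, "clinical_binary", +1)
            results[oid] = _mr(-0.2, 0.5, oid) if i % 2 else _mr(+0.2, 0.001, oid)
        assert count_replications(-0.3, results, specs) == 11

    def test_never_exceeds_panel_size_and_zero_when_all_null(self, rng):
        specs = {f"o{i}": OutcomeSpec(f"o{i}", "ckd_binary", +1) for i in range(5)}
        results = {f"o{i}": _mr(float(rng.normal()), float(rng.uniform(0.05, 1)))
                   for i in range(5)}
        assert 0 <= count_replications(0.3, results, specs) <= 5
        assert count_replications(0.3, results, specs) == 0


class TestAssignTier:
    @pytest.mark.parametrize("mr_sig,smr,coloc", list(itertools.product([True, False],
                                                                        repeat=3)))
    def test_exhaustive_truth_table(self, mr_sig, smr, coloc):
        tier = assign_tier(mr_sig, smr, coloc)
        if not mr_sig:
            assert tier is None
        elif smr and coloc:
            assert tier == 1
        elif smr or coloc:
            assert tier == 2
        else:
            assert tier == 3


class TestDirectionConsistency:
    def test_all_tissues_agree(self):
        flags, summary = direction_consistency(-0.3, {"blood": -0.1})
        assert summary == "consistent" and flags == {"blood": True}

    def test_all_tissues_opposite(self):
        _, summary = direction_consistency(-0.3, {"blood": 0.1, "kidney": 0.2})
        assert summary == "opposite"

    def test_mixed_across_tissues(self):
        _, summary = direction_consistency(-0.3, {"blood": -0.1, "kidney": 0.2})
        assert summary == "mixed"

    def test_no_estimates(self):
        flags, summary = direction_consistency(0.3, {})
        assert summary == "no_gene_estimate" and flags == {}


class TestEvidenceTable:
    def test_empty_input(self):
        assert len(build_evidence_table([])) == 0

    def test_duplicate_protein_ids_hard_error(self):
        rows = [EvidenceRow("P1"), EvidenceRow("P1")]
        with pytest.raises(ValueError, match="P1"):
            build_evidence_table(rows)

    def test_ordering_tier_then_q(self):
        rows = [EvidenceRow("A", q_value=0.01, tier=2),
                EvidenceRow("B", q_value=0.04, tier=1),
                EvidenceRow("C", q_value=0.02, tier=1),
                EvidenceRow("D", tier=None)]
        table = build_evidence_table(rows)
        assert list(table["protein_id"]) == ["C", "B", "A", "D"]

    def test_tsv_round_trip(self, tmp_path):
        rows = [EvidenceRow("P1", combined_beta=0.25, q_value=0.01, tier=3,
                            replication_count=4)]
        table = build_evidence_table(rows)
        path = tmp_path / "evidence.tsv"
        table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        back = pd.read_csv(path, sep="\t")
        assert back["protein_id"].iloc[0] == "P1"
        assert back["combined_beta"].iloc[0] == pytest.approx(0.25)
        assert back["replication_count"].iloc[0] == 4
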