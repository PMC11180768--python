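"""Pleiotropy scan, Phe-MR, replication and evidence integration."""

import pandas as pd
import pytest

from pqtlmr import (AnnotationCatalog, EvidenceRow, Instrument, MREstimate,
                    evidence_summary, f_statistic, phemr_screen,
                    phenoscan_filter, replicate, replay_coloc_calls,
                    replay_discovery_flags, replay_evidence, wald_ratio,
                    harmonize_record)

from conftest import make_stats, va


def ins(record):
    return Instrument(variant=record, f_stat=f_statistic(record.beta, record.se))


def catalog(rows):
    return AnnotationCatalog(pd.DataFrame(
        rows, columns=["variant_id", "trait_id", "pvalue", "trait_class"]))


class TestPhenoscanFilter:
    def test_risk_factor_hit_drops_instrument(self):
        cat = catalog([("rs1", "bmi", 1e-9, "risk_factor")])
        rep = phenoscan_filter([ins(va("rs1"))], cat)
        assert rep.retained == [] and rep.dropped_variant_ids == ["rs1"]
        assert not rep.passed

    def test_subthreshold_hit_is_ignored(self):
        cat = catalog([("rs1", "bmi", 1e-5, "risk_factor")])
        rep = phenoscan_filter([ins(va("rs1"))], cat)
        assert len(rep.retained) == 1 and rep.passed

    def test_multi_protein_association_flags_hub(self):
        cat = catalog([("rs1", f"protein_{k}", 1e-10, "protein") for k in range(3)])
        rep = phenoscan_filter([ins(va("rs1"))], cat)
        assert rep.is_hub and rep.hub_protein_count == 3
        assert len(rep.retained) == 1  # instrument kept, protein fails
        assert not rep.passed


def index_estimate(beta=0.3):
    return MREstimate("P1", "index_disease", "wald_ratio", beta, 0.05, 1e-9, 1)


class TestPheMR:
    def outcome(self, beta, pvalue, trait_id):
        return (trait_id, make_stats(
            [va(beta=beta, se=0.02, pvalue=pvalue, n_case=1e4, n_control=1e4)],
            trait_id=trait_id, trait_type="case_control",
            default_n_case=1e4, default_n_control=1e4))

    def test_consistent_direction_is_benefit(self):
        recs = phemr_screen([ins(va(beta=0.5, se=0.02, pvalue=1e-20))],
                            index_estimate(0.3),
                            [self.outcome(0.2, 1e-12, "d1")])
        assert recs[0].significant and recs[0].classification == "benefit"

    def test_opposite_direction_is_adverse(self):
        recs = phemr_screen([ins(va(beta=0.5, se=0.02, pvalue=1e-20))],
                            index_estimate(0.3),
                            [self.outcome(-0.2, 1e-12, "d1")])
        assert recs[0].classification == "adverse"

    def test_nonsignificant_is_none_and_bonferroni_uses_attempted(self):
        # d1's Wald p ~ 0.046: nominal but not at 0.05/3
        outcomes = [self.outcome(0.04, 0.046, "d1"),
                    self.outcome(0.0, 0.9, "d2"),
                    self.outcome(0.0, 0.8, "d3")]
        recs = phemr_screen([ins(va(beta=0.5, se=0.02, pvalue=1e-20))],
                            index_estimate(0.3), outcomes)
        assert [r.classification for r in recs] == ["none"] * 3

    def test_missing_outcome_data_gets_status(self):
        missing = ("d1", make_stats(
            [va("rsX", pos=9, n_case=1e4, n_control=1e4)], trait_id="d1",
            trait_type="case_control", default_n_case=1e4, default_n_control=1e4))
        recs = phemr_screen([ins(va("rs1", beta=0.5, se=0.02))],
                            index_estimate(), [missing])
        assert recs[0].status == "lack_of_data"


class TestReplicate:
    def discovery(self):
        exp = va(beta=0.5, se=0.02, pvalue=1e-20)
        out = va(beta=0.1, se=0.02, pvalue=2e-6)
        est = wald_ratio(harmonize_record(exp, out), "P1", "d")
        return [ins(exp)], est, make_stats(
            [out], trait_id="d", trait_type="case_control",
            default_n_case=1e4, default_n_control=1e4)

    def test_missing_discovery_snp_is_lack_of_data(self):
        instruments, est, outcome = self.discovery()
        repl_exp = make_stats([va("rsZ", pos=7, beta=0.4, se=0.02)], trait_id="r")
        res = replicate(instruments, est, repl_exp, outcome, "same_variant", 0.0045)
        assert res.status == "lack_of_data"

    def test_replication_below_threshold_passes(self):
        instruments, est, outcome = self.discovery()
        repl_exp = make_stats([va(beta=0.45, se=0.02, pvalue=1e-15)], trait_id="r")
        res = replicate(instruments, est, repl_exp, outcome, "same_variant", 0.0045)
        assert res.status == "passed"
        assert res.estimate.pvalue < 0.0045

    def test_replication_above_threshold_fails(self):
        instruments, est, outcome = self.discovery()
        # weaken the outcome so replication p ~ 0.0168 > 0.0045
        weak_out = make_stats(
            [va(beta=0.048, se=0.02, pvalue=0.0168, n_case=1e4, n_control=1e4)],
            trait_id="d", trait_type="case_control",
            default_n_case=1e4, default_n_control=1e4)
        repl_exp = make_stats([va(beta=0.45, se=0.02, pvalue=1e-15)], trait_id="r")
        res = replicate(instruments, est, repl_exp, weak_out, "same_variant", 0.0045)
        assert res.status == "failed"

    def test_opposite_direction_fails_despite_small_p(self):
        instruments, est, outcome = self.discovery()
        repl_exp = make_stats([va(beta=-0.45, se=0.02, pvalue=1e-15)], trait_id="r")
        res = replicate(instruments, est, repl_exp, outcome, "same_variant", 0.0045)
        assert res.status == "failed"

    def test_incompatible_alleles_status(self):
        instruments, est, outcome = self.discovery()
        repl_exp = make_stats([va(ea="C", oa="T", beta=0.45, se=0.02)], trait_id="r")
        res = replicate(instruments, est, repl_exp, outcome, "same_variant", 0.0045)
        assert res.status == "incompatible_alleles"

    def test_same_variant_on_discovery_reproduces_discovery_exactly(self):
        instruments, est, outcome = self.discovery()
        disc_exp = make_stats([instruments[0].variant], trait_id="P1")
        res = replicate(instruments, est, disc_exp, outcome, "same_variant", 0.05)
        assert res.estimate.beta == est.beta
        assert res.estimate.se == est.se
        assert res.status == "passed"


class TestEvidence:
    def test_all_passes_is_yes(self):
        row = EvidenceRow("P", "d", True, True, True, True, True, True, True)
        assert row.verdict == "YES"

    def test_single_failure_is_no(self):
        row = EvidenceRow("P", "d", True, True, True, True, False, True, True)
        assert row.verdict == "NO"

    def test_unknown_counts_as_not_passed(self):
        row = EvidenceRow("P", "d", True, True, None, True, True, True, True)
        assert row.verdict == "NO"


class TestPublishedReplay:
    def test_discovery_flags_eleven_overall_rows(self):
        df = replay_discovery_flags()
        assert int(df[df.outcome == "BC_overall"].discovery_significant.sum()) == 11
        assert int(df.discovery_significant.sum()) == 16

    def test_seven_of_sixteen_colocalize_at_0_7(self):
        df = replay_coloc_calls()
        assert int(df.coloc_pass.sum()) == 7

    def test_conjunction_yields_exactly_five_targets(self):
        ev = replay_evidence()
        yes = ev[ev.verdict == "YES"]
        assert len(yes) == 5
        assert set(zip(yes.protein_id, yes.outcome_id)) == {
            ("TLR1", "BC_overall"), ("A4GALT", "BC_overall"),
            ("SNUPN", "BC_overall"), ("CTSF", "BC_overall"),
            ("TLR1", "BC_ER+"),
        }

    def test_replayed_verdicts_match_published_column(self):
        ev = replay_evidence()
        assert (ev.verdict == ev.published_verdict).all()
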