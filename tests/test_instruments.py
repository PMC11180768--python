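"""Instrument selection: F-statistic, greedy LD clumping, cis filtering."""

import numpy as np
import pytest

from pqtlmr import (CisRegion, InstrumentParams, f_statistic, greedy_clump,
                    select_instruments, simulate_panel, simulate_two_trait_gwas,
                    SimScenario)

from conftest import make_stats, va


class TestFStatistic:
    @pytest.mark.parametrize("beta,se,expected", [
        (0.5, 0.05, 100.0),
        (0.1, 0.1, 1.0),
        (0.0316228, 0.01, 10.0),
    ])
    def test_values(self, beta, se, expected):
        assert f_statistic(beta, se) == pytest.approx(expected, rel=1e-4)

    def test_nonpositive_se_raises(self):
        with pytest.raises(ValueError):
            f_statistic(0.1, 0.0)


def brute_force_clump(candidates, panel, r2_max, window_kb):
    """Independent reference implementation of the greedy rule: repeatedly
    scan the full remaining set for the minimum-(p, id) candidate and
    remove its LD neighbourhood."""
    remaining = {c.variant_id: c for c in candidates if c.variant_id in panel}
    retained = []
    while remaining:
        index = min(remaining.values(), key=lambda v: (v.pvalue, v.variant_id))
        retained.append(index)
        del remaining[index.variant_id]
        for vid in list(remaining):
            v = remaining[vid]
            if (v.chrom == index.chrom
                    and abs(v.pos - index.pos) <= window_kb * 1000
                    and panel.r2(index.variant_id, vid) > r2_max):
                del remaining[vid]
    return retained


class TestGreedyClump:
    def test_stronger_snp_dominates_ld_partner(self, tiny_panel):
        # rs1/rs2 are in high LD 1 kb apart
        cands = [va("rs1", pos=1000, pvalue=1e-10), va("rs2", pos=2000, pvalue=1e-8)]
        kept = greedy_clump(cands, tiny_panel, r2_max=0.001, window_kb=10_000)
        assert [v.variant_id for v in kept] == ["rs1"]

    def test_window_never_spans_chromosomes(self, tiny_panel):
        cands = [va("rs1", chrom="1", pos=1000, pvalue=1e-10),
                 va("rs4", chrom="2", pos=1000, pvalue=1e-8)]
        kept = greedy_clump(cands, tiny_panel, r2_max=0.0, window_kb=10_000)
        assert [v.variant_id for v in kept] == ["rs1", "rs4"]

    def test_matches_bruteforce_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for seed in range(20):
            panel = simulate_panel(200, 50, 0.8, seed=seed)
            cands = [va(vid, pos=int(panel.pos[j]), pvalue=float(rng.random()))
                     for j, vid in enumerate(panel.variant_ids)]
            got = greedy_clump(cands, panel, r2_max=0.1, window_kb=20)
            want = brute_force_clump(cands, panel, r2_max=0.1, window_kb=20)
            assert [v.variant_id for v in got] == [v.variant_id for v in want]

    def test_retained_set_is_ld_independent(self):
        panel = simulate_panel(500, 40, 0.9, seed=3)
        rng = np.random.default_rng(3)
        cands = [va(vid, pos=int(panel.pos[j]), pvalue=float(rng.random()))
                 for j, vid in enumerate(panel.variant_ids)]
        kept = greedy_clump(cands, panel, r2_max=0.05, window_kb=10_000)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if a.chrom == b.chrom and abs(a.pos - b.pos) <= 10_000 * 1000:
                    assert panel.r2(a.variant_id, b.variant_id) <= 0.05

    def test_input_order_is_irrelevant(self, tiny_panel):
        cands = [va("rs1", pos=1000, pvalue=1e-8), va("rs2", pos=2000, pvalue=1e-8),
                 va("rs3", pos=500_000, pvalue=1e-9)]
        fwd = greedy_clump(cands, tiny_panel, 0.001, 10_000)
        rev = greedy_clump(cands[::-1], tiny_panel, 0.001, 10_000)
        assert [v.variant_id for v in fwd] == [v.variant_id for v in rev]


class TestSelectInstruments:
    def region(self):
        return CisRegion("GENE", "1", 1, 600_000)

    def test_single_strong_cis_snp(self, tiny_panel):
        stats = make_stats([va("rs1", pos=1000, beta=0.22, se=0.02, pvalue=1e-12)])
        ins = select_instruments(stats, self.region(), tiny_panel)
        assert len(ins) == 1 and ins[0].variant_id == "rs1"
        assert ins[0].f_stat == pytest.approx(121.0)

    def test_subthreshold_snp_gives_empty_list(self, tiny_panel):
        stats = make_stats([va("rs1", pos=1000, beta=0.22, se=0.02, pvalue=1e-6)])
        assert select_instruments(stats, self.region(), tiny_panel) == []

    def test_weak_instrument_excluded(self, tiny_panel):
        stats = make_stats([va("rs1", pos=1000, beta=0.05, se=0.02, pvalue=1e-9)])
        assert select_instruments(stats, self.region(), tiny_panel) == []

    def test_absent_chromosome_gives_empty_list(self, tiny_panel):
        stats = make_stats([va("rs1", chrom="9", pos=1000, pvalue=1e-12)])
        region = CisRegion("GENE", "7", 1, 10_000)
        assert select_instruments(stats, region, tiny_panel) == []

    def test_recovers_causal_variant_or_close_proxy(self):
        panel = simulate_panel(1_000, 80, 0.9, seed=21)
        scen = SimScenario(hypothesis="null_mr", n_variants=80, n_exposure=6_000,
                           n_case=1_000, n_control=1_000, seed=21)
        exp, _, truth = simulate_two_trait_gwas(panel, scen)
        region = CisRegion("GENE", "1", 1, 10**9)
        ins = select_instruments(exp, region, panel)
        assert len(ins) == 1
        r2 = panel.r2(ins[0].variant_id, truth.causal_exposure_id)
        assert r2 > 0.8  # causal variant itself or a tight proxy

    def test_tightening_thresholds_never_adds_instruments(self):
        panel = simulate_panel(1_000, 80, 0.9, seed=22)
        scen = SimScenario(hypothesis="null_mr", n_variants=80, n_exposure=6_000,
                           n_case=1_000, n_control=1_000, seed=22)
        exp, _, _ = simulate_two_trait_gwas(panel, scen)
        region = CisRegion("GENE", "1", 1, 10**9)
        loose = select_instruments(exp, region, panel,
                                   InstrumentParams(p_threshold=1e-4, r2_max=0.2, f_min=10))
        tight = select_instruments(exp, region, panel,
                                   InstrumentParams(p_threshold=5e-8, r2_max=0.001, f_min=30))
        assert len(tight) <= len(loose)
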