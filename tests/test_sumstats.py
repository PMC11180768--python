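"""Summary-statistics parsing, writing and allele harmonization."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from pqtlmr import (ConfigError, InputError, harmonize, harmonize_record,
                    read_sumstats, wald_ratio, write_sumstats)

from conftest import make_stats, va

CANONICAL_TSV = """\
variant_id	chrom	pos	effect_allele	other_allele	eaf	beta	se	pvalue	n	n_case	n_control
rs1	1	1000	A	G	0.30	0.25	0.02	1e-20	5000
rs2	1	2000	C	T	0.10	-0.10	0.05	0.045	5000
rs3	2	500	G	C	0.25	0.00	0.10	1.0	5000
"""


class TestReadWrite:
    def test_identity_parse(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(CANONICAL_TSV)
        stats = read_sumstats(p, trait_id="t")
        assert len(stats) == 3
        rec = stats.get("rs1")
        assert rec.beta == 0.25 and rec.se == 0.02 and rec.eaf == 0.30

    def test_invariant_violating_row_counted_not_kept(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(CANONICAL_TSV.replace("rs2	1	2000	C	T	0.10	-0.10	0.05",
                                           "rs2	1	2000	C	T	0.10	-0.10	0.0"))
        stats = read_sumstats(p, trait_id="t")
        assert len(stats) == 2
        assert stats.n_rejected == 1

    def test_indel_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(CANONICAL_TSV.replace("rs2	1	2000	C	T",
                                           "rs2	1	2000	CAT	T"))
        stats = read_sumstats(p, trait_id="t")
        assert "rs2" not in stats and stats.n_rejected == 1

    def test_dialect_mapping_matches_canonical(self, tmp_path):
        canon = tmp_path / "canon.tsv"
        canon.write_text(CANONICAL_TSV)
        renamed = tmp_path / "renamed.tsv"
        renamed.write_text(
            CANONICAL_TSV.replace(
                "variant_id	chrom	pos	effect_allele	other_allele	eaf	beta	se	pvalue	n",
                "SNP	CHR	BP	A1	A2	FRQ	b	SE	P	N"))
        dialect = {"SNP": "variant_id", "CHR": "chrom", "BP": "pos",
                   "A1": "effect_allele", "A2": "other_allele", "FRQ": "eaf",
                   "b": "beta", "SE": "se", "P": "pvalue", "N": "n"}
        s1 = read_sumstats(canon, trait_id="t")
        s2 = read_sumstats(renamed, trait_id="t", dialect=dialect)
        assert {k: dataclasses.astuple(v) for k, v in s1.records.items()} \
            == {k: dataclasses.astuple(v) for k, v in s2.records.items()}

    def test_round_trip_is_identity(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text(CANONICAL_TSV)
        s1 = read_sumstats(p, trait_id="t")
        q = tmp_path / "w.tsv"
        write_sumstats(s1, q)
        s2 = read_sumstats(q, trait_id="t")
        assert {k: dataclasses.astuple(v) for k, v in s1.records.items()} \
            == {k: dataclasses.astuple(v) for k, v in s2.records.items()}

    def test_missing_column_is_config_error(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("variant_id\tchrom\npos1\t1\n")
        with pytest.raises(ConfigError, match="pos"):
            read_sumstats(p, trait_id="t")

    def test_zero_valid_rows_is_input_error(self, tmp_path):
        p = tmp_path / "s.tsv"
        header = CANONICAL_TSV.splitlines()[0]
        p.write_text(header + "\nrs1	1	1000	A	G	0.3	0.1	0.0	0.5	100		\n")
        with pytest.raises(InputError):
            read_sumstats(p, trait_id="t")


class TestHarmonize:
    def test_identical_coding(self):
        pair = harmonize_record(va(beta=0.2), va(beta=0.1))
        assert pair.ok and not pair.flipped and pair.outcome.beta == 0.1

    def test_swapped_coding_flips_sign_and_frequency(self):
        pair = harmonize_record(va(beta=0.2, eaf=0.7),
                                va(ea="G", oa="A", beta=0.1, eaf=0.3))
        assert pair.ok and pair.flipped
        assert pair.outcome.beta == -0.1
        assert pair.outcome.eaf == pytest.approx(0.7)
        assert pair.outcome.effect_allele == "A"

    def test_palindromic_at_half_frequency_dropped(self):
        pair = harmonize_record(va(ea="A", oa="T", eaf=0.50),
                                va(ea="A", oa="T", eaf=0.50),
                                palindromic_eaf_limit=0.42)
        assert pair.status == "dropped_palindromic"

    def test_palindromic_outside_band_same_side_kept(self):
        pair = harmonize_record(va(ea="C", oa="G", eaf=0.10),
                                va(ea="C", oa="G", eaf=0.15))
        assert pair.ok and not pair.flipped

    def test_palindromic_opposite_sides_dropped(self):
        pair = harmonize_record(va(ea="C", oa="G", eaf=0.10),
                                va(ea="C", oa="G", eaf=0.90))
        assert pair.status == "dropped_palindromic"

    def test_incompatible_alleles_dropped(self):
        pair = harmonize_record(va(ea="A", oa="G"), va(ea="A", oa="C"))
        assert pair.status == "dropped_incompatible"

    def test_missing_outcome_status(self):
        exp = make_stats([va("rs1"), va("rs2", pos=200)])
        out = make_stats([va("rs1", beta=0.05)], trait_id="o")
        pairs = harmonize(exp, out, ["rs1", "rs2"])
        assert [p.status for p in pairs] == ["ok", "missing_outcome"]

    def test_unknown_exposure_variant_raises(self):
        exp = make_stats([va("rs1")])
        with pytest.raises(InputError):
            harmonize(exp, exp, ["rs99"])

    @given(beta_out=st.floats(-1, 1, allow_nan=False),
           eaf=st.floats(0.01, 0.99))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_harmonize_idempotent(self, beta_out, eaf):
        """Re-harmonizing an already-harmonized outcome changes nothing."""
        exposure = va(beta=0.2)
        outcome = va(ea="G", oa="A", beta=beta_out, eaf=eaf)
        once = harmonize_record(exposure, outcome)
        twice = harmonize_record(exposure, once.outcome)
        assert twice.ok and not twice.flipped
        assert twice.outcome.beta == once.outcome.beta
        assert twice.outcome.eaf == once.outcome.eaf

    @given(beta_exp=st.floats(0.05, 1.0), beta_out=st.floats(-0.5, 0.5),
           se_out=st.floats(0.01, 0.2))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_recoded_outcome_gives_identical_estimate(self, beta_exp, beta_out, se_out):
        """Flipping the outcome file's allele coding leaves MR unchanged."""
        exposure = va(beta=beta_exp)
        as_is = va(beta=beta_out, se=se_out)
        recoded = va(ea="G", oa="A", beta=-beta_out, se=se_out, eaf=0.7)
        e1 = wald_ratio(harmonize_record(exposure, as_is))
        e2 = wald_ratio(harmonize_record(exposure, recoded))
        assert e1.beta == pytest.approx(e2.beta, abs=1e-15)
        assert e1.se == pytest.approx(e2.se, abs=1e-15)
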