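import numpy as np
import pytest

from pqtlmr import LDPanel, SummaryStats, VariantAssociation


def va(variant_id="rs1", chrom="1", pos=100, ea="A", oa="G", beta=0.1, se=0.02,
       pvalue=1e-4, eaf=0.3, n=10_000.0, n_case=None, n_control=None):
    """Shorthand VariantAssociation builder for tests."""
    return VariantAssociation(
        variant_id=variant_id, chrom=chrom, pos=pos, effect_allele=ea,
        other_allele=oa, beta=beta, se=se, pvalue=pvalue, eaf=eaf, n=n,
        n_case=n_case, n_control=n_control,
    )


def make_stats(records, trait_id="trait", trait_type="quantitative", **kw):
    stats = SummaryStats(trait_id=trait_id, trait_type=trait_type, **kw)
    for r in records:
        stats.add(r)
    return stats


@pytest.fixture
def tiny_panel():
    """Deterministic 4-variant panel with known pairwise r²."""
    rng = np.random.default_rng(42)
    n_hap = 2_000
    a = (rng.random(n_hap) < 0.4).astype(np.int8)
    b = a.copy()
    flip = rng.random(n_hap) < 0.1  # high LD with a
    b[flip] = rng.random(flip.sum()) < 0.4
    c = (rng.random(n_hap) < 0.5).astype(np.int8)  # independent
    d = (rng.random(n_hap) < 0.2).astype(np.int8)  # independent, other chrom
    hap = np.column_stack([a, b, c, d])
    return LDPanel(["rs1", "rs2", "rs3", "rs4"],
                   np.array(["1", "1", "1", "2"], dtype=object),
                   np.array([1000, 2000, 500_000, 1000]), haplotypes=hap)
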