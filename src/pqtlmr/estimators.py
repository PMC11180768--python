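"""Causal-effect estimation: Wald ratio, fixed-effect IVW, odds-ratio
reporting and Bonferroni multiplicity control.

With a single instrument the causal effect of a one-SD increase in the
protein on the outcome is the Wald ratio beta_out / beta_exp, with
first-order delta-method standard error se_out / |beta_exp|.  With two or
more instruments the per-instrument ratios are combined by inverse-variance
weighting.  Effects on case-control outcomes are reported as odds ratios
per SD with 95% confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats as sps

from .errors import InputError
from .instruments import Instrument
from .sumstats import HarmonizedPair, SummaryStats, harmonize, PALINDROMIC_EAF_LIMIT

logger = logging.getLogger("pqtlmr")

#: z multiplier for a 95% CI, fixed to match 2-decimal printed ORs.
Z_95 = 1.959964


@dataclass(slots=True)
class MREstimate:
    """Causal effect of an exposure on an outcome (per SD of exposure)."""

    exposure_id: str
    outcome_id: str
    method: str  # "wald_ratio" | "ivw"
    beta: float
    se: float
    pvalue: float
    n_snp: int

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z_95 * self.se)

    def __str__(self) -> str:
        return (f"{self.exposure_id}->{self.outcome_id} OR={self.or_:.2f} "
                f"({self.ci_low:.2f},{self.ci_high:.2f}) p={self.pvalue:.3g} "
                f"[{self.method}, {self.n_snp} SNP]")


def _normal_p(beta: float, se: float) -> float:
    """Two-sided p from the standard normal."""
    return float(2.0 * sps.norm.sf(abs(beta / se)))


def wald_ratio(pair: HarmonizedPair, exposure_id: str = "", outcome_id: str = "") -> MREstimate:
    """Single-instrument causal estimate beta_out/beta_exp."""
    if not pair.ok:
        raise InputError(f"wald_ratio requires an ok pair, got status {pair.status}")
    b_exp = pair.exposure.beta
    if b_exp == 0:
        raise ValueError("wald_ratio undefined for exposure beta = 0")
    beta = pair.outcome.beta / b_exp
    se = pair.outcome.se / abs(b_exp)
    return MREstimate(exposure_id, outcome_id, "wald_ratio",
                      beta, se, _normal_p(beta, se), n_snp=1)


def ivw(pairs: Sequence[HarmonizedPair], exposure_id: str = "", outcome_id: str = "",
        allow_single: bool = False) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate over per-instrument
    Wald ratios (weights 1/se_j²)."""
    ok = [p for p in pairs if p.ok]
    if len(ok) < 2 and not allow_single:
        raise InputError(f"ivw requires >= 2 ok pairs (got {len(ok)}); use wald_ratio")
    if not ok:
        raise InputError("ivw requires at least one ok pair")
    sw = swb = 0.0
    for p in ok:
        r = wald_ratio(p)
        w = 1.0 / (r.se * r.se)
        sw += w
        swb += w * r.beta
    beta = swb / sw
    se = 1.0 / math.sqrt(sw)
    return MREstimate(exposure_id, outcome_id, "ivw",
                      beta, se, _normal_p(beta, se), n_snp=len(ok))


def estimate_effect(pairs: Sequence[HarmonizedPair], exposure_id: str = "",
                    outcome_id: str = "") -> MREstimate:
    """Wald ratio for one usable instrument, IVW for two or more."""
    ok = [p for p in pairs if p.ok]
    if not ok:
        raise InputError("no harmonized instruments usable for estimation")
    if len(ok) == 1:
        return wald_ratio(ok[0], exposure_id, outcome_id)
    return ivw(ok, exposure_id, outcome_id)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m controlling the family-wise error rate."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if not isinstance(m, int) or m < 1:
        raise ValueError(f"m must be a positive integer, got {m}")
    return alpha / m


@dataclass(slots=True)
class ScanRecord:
    """Per-protein result of a batch MR scan."""

    protein_id: str
    estimate: MREstimate | None
    status: str  # "ok" | "lack_of_data"
    significant: bool = False


def mr_scan(
    proteins: Mapping[str, Sequence[Instrument]],
    outcome: SummaryStats,
    alpha: float = 0.05,
    palindromic_eaf_limit: float = PALINDROMIC_EAF_LIMIT,
) -> list[ScanRecord]:
    """Estimate every protein's effect on one outcome and flag significance
    at the Bonferroni level alpha/m, with m = proteins attempted (not
    proteins with usable instruments).  Proteins whose instruments are all
    missing or dropped in harmonization are reported with a lack-of-data
    status, never silently skipped.
    """
    m = len(proteins)
    if m == 0:
        return []
    threshold = bonferroni_threshold(alpha, m)
    out: list[ScanRecord] = []
    for protein_id in sorted(proteins):
        instruments = proteins[protein_id]
        exp_stats = SummaryStats(trait_id=protein_id, trait_type="quantitative")
        for ins in instruments:
            exp_stats.add(ins.variant)
        ids = sorted(exp_stats.records)
        if not ids:
            out.append(ScanRecord(protein_id, None, "lack_of_data"))
            continue
        pairs = harmonize(exp_stats, outcome, ids, palindromic_eaf_limit)
        ok = [p for p in pairs if p.ok]
        if not ok:
            out.append(ScanRecord(protein_id, None, "lack_of_data"))
            continue
        est = estimate_effect(ok, protein_id, outcome.trait_id)
        out.append(ScanRecord(protein_id, est, "ok", significant=est.pvalue < threshold))
    n_sig = sum(r.significant for r in out)
    logger.info("mr_scan outcome=%s n_proteins=%d threshold=%.4g n_significant=%d",
                outcome.trait_id, m, threshold, n_sig)
    return out
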