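"""Reverse-causation defenses: Steiger filtering and bidirectional MR.

Steiger filtering asks whether the instruments explain more variance in
the exposure than in the outcome — the pattern expected when causation
runs exposure -> outcome.  Bidirectional MR estimates the reverse effect
(disease -> protein) from the disease GWAS's own instruments; a reverse
p > 0.05 is read as no evidence of reverse causality.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats as sps

from .errors import InputError
from .estimators import MREstimate, estimate_effect
from .instruments import InstrumentParams, LDPanel, f_statistic, greedy_clump
from .sumstats import HarmonizedPair, SummaryStats, harmonize

logger = logging.getLogger("pqtlmr")


def variance_explained(z: float, n: float) -> float:
    """Variance in a trait explained by one variant, from its association
    z-score and sample size: r² = z²/(z² + n − 2).

    For case-control traits pass the effective size 4/(1/n_case+1/n_control).
    """
    if n <= 2:
        raise ValueError(f"sample size must exceed 2, got {n}")
    z2 = z * z
    return z2 / (z2 + n - 2.0)


@dataclass(slots=True)
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    pvalue: float

    @property
    def correct_direction(self) -> bool:
        return self.r2_exposure > self.r2_outcome


def steiger_filter(
    pairs: Sequence[HarmonizedPair],
    n_exp: float,
    n_out: float,
) -> SteigerResult:
    """Compare instrument variance explained in exposure vs outcome.

    r² is summed over the ok instruments per trait; the two correlations
    r = sqrt(r²) are compared by the independent-samples Fisher-z test
    (exposure and outcome cohorts do not overlap in a two-sample design):
    z = (atanh(r_exp) − atanh(r_out)) / sqrt(1/(n_exp−3) + 1/(n_out−3)),
    two-sided.
    """
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("sample sizes must exceed 3 for the Fisher-z comparison")
    ok = [p for p in pairs if p.ok]
    if not ok:
        raise InputError("steiger_filter requires at least one ok pair")
    r2_exp = sum(variance_explained(p.exposure.zscore, n_exp) for p in ok)
    r2_out = sum(variance_explained(p.outcome.zscore, n_out) for p in ok)
    r2_exp = min(r2_exp, 1.0 - 1e-12)
    r2_out = min(r2_out, 1.0 - 1e-12)
    z = (math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))) \
        / math.sqrt(1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0))
    p = float(2.0 * sps.norm.sf(abs(z)))
    return SteigerResult(r2_exposure=r2_exp, r2_outcome=r2_out, pvalue=p)


@dataclass(slots=True)
class DirectionVerdict:
    """Combined direction check for one protein × outcome.

    Passes when Steiger affirms the forward direction (correct_direction
    with p < 0.05) and the reverse MR shows no effect (p > 0.05).  A
    reverse analysis with no usable instruments is recorded as
    lack-of-data and does not pass.
    """

    steiger: SteigerResult
    reverse_mr: MREstimate | None
    reverse_status: str  # "ok" | "lack_of_data"

    @property
    def passed(self) -> bool:
        if not (self.steiger.correct_direction and self.steiger.pvalue < 0.05):
            return False
        if self.reverse_status != "ok" or self.reverse_mr is None:
            return False
        return self.reverse_mr.pvalue > 0.05


def bidirectional_mr(
    outcome_stats: SummaryStats,
    exposure_stats: SummaryStats,
    panel: LDPanel,
    params: InstrumentParams | None = None,
    steiger_filter_instruments: bool = True,
) -> tuple[MREstimate | None, str]:
    """Reverse-direction MR: the disease as exposure, the protein as outcome.

    Instruments are selected from the disease GWAS genome-wide (not
    cis-restricted) under the same significance / clumping / F criteria
    used for pQTLs.  Each candidate reverse instrument is additionally
    Steiger-screened: a variant explaining more variance in the protein
    than in the disease is a forward-acting (mediated) signal, not a valid
    disease instrument, and is dropped.  Returns (estimate, "ok") or
    (None, "lack_of_data") when no instrument survives.
    """
    params = params or InstrumentParams()
    records = list(outcome_stats.records.values())
    significant = [r for r in records if r.pvalue < params.p_threshold]
    clumped = greedy_clump(significant, panel, params.r2_max, params.window_kb)
    strong = [r for r in clumped if f_statistic(r.beta, r.se) >= params.f_min]
    if not strong:
        logger.info("bidirectional_mr disease=%s no genome-wide instruments", outcome_stats.trait_id)
        return None, "lack_of_data"

    ids = sorted(r.variant_id for r in strong)
    pairs = [p for p in harmonize(outcome_stats, exposure_stats, ids) if p.ok]
    if steiger_filter_instruments:
        n_dis = outcome_stats.effective_n()
        n_prot = exposure_stats.effective_n()
        kept = []
        for p in pairs:
            r2_dis = variance_explained(p.exposure.zscore, n_dis)
            r2_prot = variance_explained(p.outcome.zscore, n_prot)
            if r2_dis > r2_prot:
                kept.append(p)
        dropped = len(pairs) - len(kept)
        if dropped:
            logger.info("bidirectional_mr disease=%s protein=%s steiger_dropped=%d",
                        outcome_stats.trait_id, exposure_stats.trait_id, dropped)
        pairs = kept
    if not pairs:
        return None, "lack_of_data"
    est = estimate_effect(pairs, outcome_stats.trait_id, exposure_stats.trait_id)
    return est, "ok"
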