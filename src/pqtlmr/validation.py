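"""Scenario-recovery batches: repeated simulation runs that score the
pipeline's operating characteristics against the generator's known truth.

Each function runs one family of seeded replicates — colocalization
hypothesis recovery, forward-causal effect recovery with Steiger
direction scoring, and the null type-I error of the MR scan — and
returns the raw per-replicate outcomes so callers can summarize them.
Problem sizes default to desk-scale versions of the emulated study (a
pQTL cohort of 7,213; balanced case-control outcome cohorts of 20-40k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coloc import coloc_abf
from .direction import steiger_filter
from .estimators import estimate_effect
from .instruments import CisRegion, select_instruments
from .simulate import SimScenario, simulate_panel, simulate_two_trait_gwas
from .sumstats import harmonize

_WHOLE_CHROM = CisRegion("sim", "1", 1, 10**12)


def _rep_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def coloc_recovery(
    hypothesis: str,
    n_reps: int,
    seed: int,
    n_variants: int = 200,
    n_hap: int = 1_000,
    ld_decay: float = 0.9,
    n_exposure: int = 7_213,
    n_case: int = 10_000,
    n_control: int = 10_000,
    outcome_variant_logor: float = 0.2,
    h2_exposure: float = 0.05,
) -> np.ndarray:
    """Posterior probabilities (rows: replicates, columns: PPH0..PPH4)
    for repeated simulations of one colocalization hypothesis."""
    out = np.empty((n_reps, 5))
    for k, s in enumerate(_rep_seeds(seed, n_reps)):
        panel = simulate_panel(n_hap, n_variants, ld_decay, seed=int(s))
        scen = SimScenario(hypothesis=hypothesis, n_variants=n_variants,
                           n_exposure=n_exposure, n_case=n_case,
                           n_control=n_control, h2_exposure=h2_exposure,
                           outcome_variant_logor=outcome_variant_logor,
                           seed=int(s) + 1)
        e, o, _ = simulate_two_trait_gwas(panel, scen)
        res = coloc_abf(list(e.records.values()), list(o.records.values()))
        out[k] = res.as_tuple()
    return out


@dataclass(slots=True)
class ForwardRecovery:
    estimates: np.ndarray        # per-replicate causal estimates (NaN = no instrument)
    steiger_correct: np.ndarray  # per-replicate bool
    true_effect: float

    @property
    def mean_estimate(self) -> float:
        return float(np.nanmean(self.estimates))

    @property
    def mc_se(self) -> float:
        e = self.estimates[~np.isnan(self.estimates)]
        return float(e.std(ddof=1) / np.sqrt(len(e)))

    @property
    def steiger_rate(self) -> float:
        return float(np.mean(self.steiger_correct))


def forward_recovery(
    n_reps: int,
    seed: int,
    mr_effect: float = 0.25,
    h2_exposure: float = 0.05,
    n_variants: int = 60,
    n_hap: int = 1_000,
    n_exposure: int = 7_213,
    n_case: int = 20_000,
    n_control: int = 20_000,
) -> ForwardRecovery:
    """Repeatedly simulate forward causation, run the full instrument
    selection + estimation path, and score effect recovery and Steiger
    direction calls."""
    estimates = np.full(n_reps, np.nan)
    steiger_ok = np.zeros(n_reps, dtype=bool)
    for k, s in enumerate(_rep_seeds(seed, n_reps)):
        panel = simulate_panel(n_hap, n_variants, 0.9, seed=int(s))
        scen = SimScenario(hypothesis="forward_causal", n_variants=n_variants,
                           n_exposure=n_exposure, n_case=n_case,
                           n_control=n_control, h2_exposure=h2_exposure,
                           mr_effect=mr_effect, seed=int(s) + 1)
        e, o, _ = simulate_two_trait_gwas(panel, scen)
        ins = select_instruments(e, _WHOLE_CHROM, panel)
        if not ins:
            continue
        pairs = [p for p in harmonize(e, o, sorted(i.variant_id for i in ins)) if p.ok]
        if not pairs:
            continue
        estimates[k] = estimate_effect(pairs).beta
        st = steiger_filter(pairs, e.effective_n(), o.effective_n())
        steiger_ok[k] = st.correct_direction and st.pvalue < 0.05
    return ForwardRecovery(estimates, steiger_ok, mr_effect)


def null_type_i(
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    n_variants: int = 40,
    n_hap: int = 1_000,
    n_exposure: int = 5_000,
    n_case: int = 2_500,
    n_control: int = 2_500,
) -> tuple[int, int]:
    """Null MR replicates (valid pQTL instrument, zero causal effect):
    returns (rejections at level alpha, replicates with a usable test)."""
    n_rej = n_tested = 0
    for s in _rep_seeds(seed, n_reps):
        panel = simulate_panel(n_hap, n_variants, 0.9, seed=int(s))
        scen = SimScenario(hypothesis="null_mr", n_variants=n_variants,
                           n_exposure=n_exposure, n_case=n_case,
                           n_control=n_control, seed=int(s) + 1)
        e, o, _ = simulate_two_trait_gwas(panel, scen)
        ins = select_instruments(e, _WHOLE_CHROM, panel)
        if not ins:
            continue
        pairs = [p for p in harmonize(e, o, sorted(i.variant_id for i in ins)) if p.ok]
        if not pairs:
            continue
        n_tested += 1
        if estimate_effect(pairs).pvalue < alpha:
            n_rej += 1
    return n_rej, n_tested
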