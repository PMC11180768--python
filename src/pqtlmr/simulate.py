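"""Synthetic LD panels and paired exposure/outcome GWAS with known truth.

The generator emulates the statistical structure of the study's inputs —
a pQTL discovery cohort (protein levels measured in thousands of
individuals), a large case-control disease GWAS, and an external LD
reference panel — without any real data.  Haplotypes carry spatially
decaying LD; phenotypes are generated at the individual level (a linear
model for the protein, a logistic model for disease status) and then
reduced to per-variant marginal summary statistics by exact per-variant
regression, so LD-induced shadow associations arise naturally.  Every
dataset ships with a :class:`SimTruth` sidecar sufficient to score
instrument recovery, MR sign and magnitude, Steiger direction and the
colocalization hypothesis.

Scenario vocabulary (``SimScenario.hypothesis``):

=================  ======================================================
H0                 no causal variant for either trait
H1 / null_mr       exposure has its cis pQTL, outcome entirely null
H2                 outcome has a direct causal variant, exposure null
H3                 distinct causal variants for the two traits
H4                 one shared variant affects both traits directly
forward_causal     exposure pQTL + outcome effect mediated by the
                   exposure (scaled by ``mr_effect``)
reverse_causal     disease variant; the exposure inherits a share of the
                   disease liability (``reverse_effect``)
=================  ======================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .instruments import LDPanel
from .sumstats import SummaryStats, VariantAssociation

logger = logging.getLogger("pqtlmr")

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4", "forward_causal", "reverse_causal", "null_mr")

_P_FLOOR = 1e-300  # keep p-values inside (0, 1]


# ---------------------------------------------------------------------------
# LD panel


def chain_haplotypes(n_hap: int, freqs: np.ndarray,
                     blocks: list[tuple[int, int, float]],
                     rng: np.random.Generator) -> np.ndarray:
    """Haplotypes from a copy-with-mutation chain: within each block
    (start, length, decay), variant j+1 copies variant j's allele with
    probability ``decay`` and otherwise draws fresh at its own frequency;
    the chain restarts at block boundaries (blocks are unlinked)."""
    hap = np.empty((n_hap, len(freqs)), dtype=np.int8)
    for start, length, decay in blocks:
        hap[:, start] = rng.random(n_hap) < freqs[start]
        for j in range(start + 1, start + length):
            copy = rng.random(n_hap) < decay
            fresh = rng.random(n_hap) < freqs[j]
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    return hap


def simulate_panel(
    n_hap: int,
    n_variants: int,
    ld_decay: float,
    seed: int | np.random.Generator,
    chrom: str = "1",
    start: int = 1_000_000,
    spacing: int = 1_000,
    id_offset: int = 1,
) -> LDPanel:
    """Simulate a haplotype reference panel with exponentially decaying LD.

    Haplotypes come from a copy-with-mutation chain (see
    :func:`chain_haplotypes`), so adjacent-variant correlation is about
    ``ld_decay`` (r² about ld_decay²) and decays geometrically with
    distance.  Allele frequencies are kept inside [0.05, 0.95].  The
    panel remembers its generative parameters so study cohorts can be
    drawn fresh from the same process rather than by resampling the
    panel's finite haplotype pool (resampling would leak the panel's
    sampling noise into every cohort as spurious long-range LD).
    """
    if n_hap < 100:
        raise ValueError(f"n_hap must be >= 100, got {n_hap}")
    if not 0.0 <= ld_decay < 1.0:
        raise ValueError(f"ld_decay must be in [0, 1), got {ld_decay}")
    if n_variants < 1:
        raise ValueError("n_variants must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    target_freq = rng.uniform(0.1, 0.9, size=n_variants)
    hap = chain_haplotypes(n_hap, target_freq, [(0, n_variants, ld_decay)], rng)

    # enforce the frequency bounds by flipping a minimal number of alleles
    for j in range(n_variants):
        freq = hap[:, j].mean()
        lo, hi = 0.05, 0.95
        if freq < lo:
            need = int(np.ceil(lo * n_hap)) - int(hap[:, j].sum())
            zeros = np.flatnonzero(hap[:, j] == 0)
            hap[rng.choice(zeros, size=need, replace=False), j] = 1
        elif freq > hi:
            need = int(hap[:, j].sum()) - int(np.floor(hi * n_hap))
            ones = np.flatnonzero(hap[:, j] == 1)
            hap[rng.choice(ones, size=need, replace=False), j] = 0

    ids = [f"rs{id_offset + j}" for j in range(n_variants)]
    pos = start + spacing * np.arange(n_variants, dtype=np.int64)
    panel = LDPanel(ids, np.full(n_variants, chrom, dtype=object), pos, haplotypes=hap)
    panel.sim_freqs = target_freq
    panel.sim_blocks = [(0, n_variants, ld_decay)]
    return panel


def draw_genotypes(panel: LDPanel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Diploid genotypes for ``n`` independent individuals.

    When the panel carries its generative parameters (it was simulated),
    2n fresh haplotypes are generated from the same process, so cohorts
    share the panel's LD structure in expectation but none of its
    finite-sample noise.  A file-loaded panel without parameters falls
    back to resampling haplotype pairs with replacement.
    """
    freqs = getattr(panel, "sim_freqs", None)
    if freqs is not None:
        hap = chain_haplotypes(2 * n, freqs, panel.sim_blocks, rng)
        return (hap[0::2] + hap[1::2]).astype(np.float64)
    n_hap = panel.haplotypes.shape[0]
    i1 = rng.integers(0, n_hap, size=n)
    i2 = rng.integers(0, n_hap, size=n)
    return (panel.haplotypes[i1] + panel.haplotypes[i2]).astype(np.float64)


# ---------------------------------------------------------------------------
# Marginal per-variant GWAS


def linear_gwas(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant simple linear regression (slope + intercept), vectorized.

    Returns (beta, se, pvalue) arrays; p from the t reference with n-2 df.
    Monomorphic variants get beta 0 with an effectively infinite se.
    """
    n, m = G.shape
    yc = y - y.mean()
    Gc = G - G.mean(axis=0)
    sgg = (Gc * Gc).sum(axis=0)
    sgy = Gc.T @ yc
    syy = float(yc @ yc)
    safe = sgg > 0
    beta = np.zeros(m)
    beta[safe] = sgy[safe] / sgg[safe]
    rss = syy - beta * sgy
    rss = np.maximum(rss, 0.0)
    se = np.full(m, np.inf)
    se[safe] = np.sqrt(rss[safe] / (n - 2) / sgg[safe])
    se[se == 0] = np.finfo(float).tiny
    t = np.zeros(m)
    ok = np.isfinite(se) & (se > 0)
    t[ok] = beta[ok] / se[ok]
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, _P_FLOOR, 1.0)
    se[~np.isfinite(se)] = 1e6
    return beta, se, p


def logistic_gwas(G: np.ndarray, y: np.ndarray, max_iter: int = 30,
                  tol: float = 1e-6) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant logistic regression (intercept + genotype), vectorized
    Newton-Raphson across variants.  Returns per-allele log-ORs with Wald
    standard errors and normal two-sided p-values.

    Matrix work runs in float32 (the parameter updates accumulate in
    float64); with a convergence tolerance of 1e-6 on the updates the
    resulting log-ORs match a float64 fit far beyond the statistical
    noise floor.
    """
    n, m = G.shape
    ybar = y.mean()
    a = np.full(m, np.log(ybar / (1.0 - ybar)))
    b = np.zeros(m)
    G32 = np.ascontiguousarray(G, dtype=np.float32)
    G2 = G32 * G32
    y32 = np.asarray(y, dtype=np.float32)[:, None]
    for _ in range(max_iter):
        eta = G32 * b.astype(np.float32) + a.astype(np.float32)
        mu = 1.0 / (1.0 + np.exp(-eta))
        resid = y32 - mu
        ga = resid.sum(axis=0, dtype=np.float64)
        gb = (resid * G32).sum(axis=0, dtype=np.float64)
        w = mu * (1.0 - mu)
        saa = w.sum(axis=0, dtype=np.float64)
        sab = (w * G32).sum(axis=0, dtype=np.float64)
        sbb = (w * G2).sum(axis=0, dtype=np.float64)
        det = saa * sbb - sab * sab
        det = np.where(det <= 0, np.finfo(float).tiny, det)
        da = (sbb * ga - sab * gb) / det
        db = (saa * gb - sab * ga) / det
        a += da
        b += db
        if max(np.abs(da).max(), np.abs(db).max()) < tol:
            break
    se = np.sqrt(np.maximum(saa / det, np.finfo(float).tiny))
    p = 2.0 * sps.norm.sf(np.abs(b) / se)
    p = np.clip(p, _P_FLOOR, 1.0)
    return b, se, p


# ---------------------------------------------------------------------------
# Scenarios


@dataclass(slots=True)
class SimScenario:
    """Study conditions for one simulated protein × disease dataset.

    Defaults mirror the emulated study: a pQTL cohort of 7,213
    individuals, a large balanced case-control disease GWAS, a cis causal
    variant explaining 5% of protein variance, and a protein → disease
    log-OR of 0.25 per SD when causation is present.
    """

    hypothesis: str = "forward_causal"
    n_variants: int = 200
    cis_span: int = 200_000
    ld_decay: float = 0.9
    n_exposure: int = 7_213
    n_case: int = 20_000
    n_control: int = 20_000
    h2_exposure: float = 0.05
    mr_effect: float = 0.25
    outcome_variant_logor: float = 0.15  # per-allele direct disease effect (H2/H3/H4)
    reverse_effect: float = 0.3  # share of disease liability inherited by the exposure
    causal_exposure_idx: int | None = None
    causal_outcome_idx: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if not 0.0 < self.h2_exposure < 1.0:
            raise ValueError("h2_exposure must be in (0,1)")
        for name in ("n_variants", "n_exposure", "n_case", "n_control"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(slots=True)
class SimTruth:
    """Ground truth emitted with every simulated dataset."""

    hypothesis: str
    causal_exposure_id: str | None
    causal_outcome_id: str | None
    mr_effect: float
    exposure_allele_beta: float  # per-allele effect of the cis variant on the protein
    outcome_allele_logor: float  # per-allele direct disease effect (0 if mediated/none)
    expected_direction: str | None  # "forward" | "reverse" | None


def _exposure_needs_pqtl(hyp: str) -> bool:
    return hyp in ("H1", "H3", "H4", "forward_causal", "null_mr")


def _outcome_direct_variant(hyp: str) -> bool:
    return hyp in ("H2", "H3", "H4", "reverse_causal")


def simulate_two_trait_gwas(
    panel: LDPanel,
    scenario: SimScenario,
) -> tuple[SummaryStats, SummaryStats, SimTruth]:
    """Generate exposure (protein) and outcome (disease) summary statistics
    for independent cohorts drawn from one LD panel.

    The exposure is a unit-variance quantitative trait; the outcome is a
    balanced case-control trait whose status is drawn from a logistic
    model.  Summary statistics are exact per-variant marginal fits on the
    simulated cohorts.
    """
    rng = np.random.default_rng(scenario.seed)
    m = len(panel)
    if scenario.n_variants != m:
        raise ValueError(f"scenario.n_variants={scenario.n_variants} != panel size {m}")
    hyp = scenario.hypothesis

    # causal variant placement: distinct, well-separated variants under H3
    if scenario.causal_exposure_idx is not None:
        i_exp = scenario.causal_exposure_idx
    else:
        i_exp = int(rng.integers(0, max(1, m // 3))) if m > 3 else 0
    if scenario.causal_outcome_idx is not None:
        i_out = scenario.causal_outcome_idx
    elif hyp == "H3":
        i_out = int(rng.integers(2 * m // 3, m)) if m > 3 else m - 1
    else:
        i_out = i_exp

    freqs = panel.frequencies()
    var_g_exp = 2.0 * freqs[i_exp] * (1.0 - freqs[i_exp])
    b_exp = float(np.sqrt(scenario.h2_exposure / var_g_exp)) if _exposure_needs_pqtl(hyp) else 0.0
    direct_logor = scenario.outcome_variant_logor if _outcome_direct_variant(hyp) else 0.0
    mr_effect = scenario.mr_effect if hyp == "forward_causal" else 0.0

    # --- exposure cohort ---------------------------------------------------
    G_e = draw_genotypes(panel, scenario.n_exposure, rng)
    noise_sd = float(np.sqrt(max(1e-12, 1.0 - scenario.h2_exposure)))
    if hyp == "reverse_causal":
        # the exposure inherits the disease liability (logistic latent scale)
        # with slope reverse_effect, so the disease -> protein causal effect
        # per unit log-odds of disease equals reverse_effect
        liab = direct_logor * G_e[:, i_out] + rng.logistic(size=scenario.n_exposure)
        lam = scenario.reverse_effect
        var_liab = direct_logor ** 2 * 2.0 * freqs[i_out] * (1.0 - freqs[i_out]) \
            + np.pi ** 2 / 3.0
        resid_var = max(0.05, 1.0 - lam * lam * var_liab)
        x = lam * (liab - liab.mean()) + rng.normal(0.0, np.sqrt(resid_var),
                                                    size=scenario.n_exposure)
    else:
        x = b_exp * G_e[:, i_exp] + rng.normal(0.0, noise_sd, size=scenario.n_exposure)
    beta_e, se_e, p_e = linear_gwas(G_e, x)
    eaf_e = G_e.mean(axis=0) / 2.0

    # --- outcome cohort ----------------------------------------------------
    n_out = scenario.n_case + scenario.n_control
    G_o = draw_genotypes(panel, n_out, rng)
    frac_case = scenario.n_case / n_out
    alpha0 = float(np.log(frac_case / (1.0 - frac_case)))
    eta = np.full(n_out, alpha0)
    if direct_logor != 0.0:
        g = G_o[:, i_out]
        eta = eta + direct_logor * (g - g.mean())
    if mr_effect != 0.0:
        # the disease acts on the genetically proxied exposure score, so the
        # causal log-OR per SD of exposure is exactly mr_effect; folding the
        # exposure's non-genetic residual into the liability would attenuate
        # every marginal log-OR (noncollapsibility) and shift the estimand
        g = G_o[:, i_exp]
        eta = eta + mr_effect * b_exp * (g - g.mean())
    y = (rng.random(n_out) < 1.0 / (1.0 + np.exp(-eta))).astype(np.float64)
    beta_o, se_o, p_o = logistic_gwas(G_o, y)
    eaf_o = G_o.mean(axis=0) / 2.0
    n_case_real = float(y.sum())
    n_control_real = float(n_out - y.sum())

    # --- assemble ----------------------------------------------------------
    exp_stats = SummaryStats(trait_id="exposure", trait_type="quantitative",
                             default_n=float(scenario.n_exposure))
    out_stats = SummaryStats(trait_id="outcome", trait_type="case_control",
                             default_n=float(n_out),
                             default_n_case=n_case_real, default_n_control=n_control_real)
    for j, vid in enumerate(panel.variant_ids):
        common = dict(variant_id=vid, chrom=str(panel.chrom[j]), pos=int(panel.pos[j]),
                      effect_allele="A", other_allele="G")
        exp_stats.add(VariantAssociation(
            **common, beta=float(beta_e[j]), se=float(se_e[j]), pvalue=float(p_e[j]),
            eaf=float(eaf_e[j]), n=float(scenario.n_exposure)))
        out_stats.add(VariantAssociation(
            **common, beta=float(beta_o[j]), se=float(se_o[j]), pvalue=float(p_o[j]),
            eaf=float(eaf_o[j]), n=float(n_out),
            n_case=n_case_real, n_control=n_control_real))

    if hyp == "forward_causal":
        direction = "forward"
    elif hyp == "reverse_causal":
        direction = "reverse"
    else:
        direction = None
    truth = SimTruth(
        hypothesis=hyp,
        causal_exposure_id=panel.variant_ids[i_exp] if _exposure_needs_pqtl(hyp) else None,
        causal_outcome_id=(panel.variant_ids[i_out]
                           if (_outcome_direct_variant(hyp) or hyp == "forward_causal") else None),
        mr_effect=mr_effect,
        exposure_allele_beta=b_exp,
        outcome_allele_logor=direct_logor,
        expected_direction=direction,
    )
    return exp_stats, out_stats, truth
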