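"""Bayesian colocalization of two association signals in one region.

Given per-variant summary statistics for two traits over a shared region,
each variant's evidence of association with each trait is summarized by
Wakefield's approximate Bayes factor (ABF).  Assuming at most one causal
variant per trait, the posterior mass is enumerated over five hypotheses:

  H0  no association with either trait
  H1  association with trait 1 only
  H2  association with trait 2 only
  H3  both traits, two distinct causal variants
  H4  both traits, one shared causal variant

A posterior probability of H4 above a cutoff (0.7 by default) is read as
evidence that the protein's cis signal and the disease signal share a
causal variant.  All hypothesis sums are computed in log space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import InputError
from .sumstats import VariantAssociation

logger = logging.getLogger("pqtlmr")

#: Prior effect-size scales: SD units for quantitative traits, log-OR for
#: case-control traits (the published defaults of the standard method).
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_CASE_CONTROL = 0.2


@dataclass(frozen=True, slots=True)
class ColocPriors:
    """Per-variant prior probabilities of association.

    p1: trait 1 only; p2: trait 2 only; p12: both traits.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.p12 > min(self.p1, self.p2):
            logger.warning("coloc priors: p12=%g exceeds min(p1,p2)=%g",
                           self.p12, min(self.p1, self.p2))


@dataclass(slots=True)
class ColocResult:
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps: int
    priors: ColocPriors

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.pph0, self.pph1, self.pph2, self.pph3, self.pph4)


def log_abf(beta: float, se: float, prior_sd: float) -> float:
    """Wakefield log approximate Bayes factor for one variant.

    With V = se², W = prior_sd², z = beta/se and r = W/(V+W):
    lABF = 0.5·ln(1−r) + z²·r/2.  Positive values favour association.
    """
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    if prior_sd <= 0:
        raise ValueError(f"prior_sd must be positive, got {prior_sd}")
    V = se * se
    W = prior_sd * prior_sd
    r = W / (V + W)
    z = beta / se
    return 0.5 * math.log1p(-r) + 0.5 * z * z * r


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) − exp(b)) for a >= b, −inf when the difference vanishes."""
    if b >= a:
        return -math.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_abf(
    region1: Sequence[VariantAssociation],
    region2: Sequence[VariantAssociation],
    priors: ColocPriors | None = None,
    sd1: float = PRIOR_SD_QUANTITATIVE,
    sd2: float = PRIOR_SD_CASE_CONTROL,
) -> ColocResult:
    """Enumerate the five colocalization hypotheses over the shared variants.

    The regions are intersected on variant id (variants missing from either
    trait are dropped and logged).  With per-variant log-ABFs l1, l2 and
    priors (p1, p2, p12), the unnormalized hypothesis masses are

      H0 = 1
      H1 = p1 Σ_i BF1_i          H2 = p2 Σ_j BF2_j
      H3 = p1 p2 Σ_{i≠j} BF1_i BF2_j
      H4 = p12 Σ_i BF1_i BF2_i

    computed with log-sum-exp throughout and normalized to posteriors.
    """
    priors = priors or ColocPriors()
    idx2 = {v.variant_id: v for v in region2}
    shared = [(v, idx2[v.variant_id]) for v in region1 if v.variant_id in idx2]
    n_dropped = len(region1) + len(region2) - 2 * len(shared)
    if n_dropped:
        logger.info("coloc_abf n_shared=%d n_dropped=%d", len(shared), n_dropped)
    if not shared:
        raise InputError("coloc_abf: no shared variants between the two regions")

    l1 = np.array([log_abf(a.beta, a.se, sd1) for a, _ in shared])
    l2 = np.array([log_abf(b.beta, b.se, sd2) for _, b in shared])

    lsum1 = float(logsumexp(l1))
    lsum2 = float(logsumexp(l2))
    lsum12 = float(logsumexp(l1 + l2))

    lh0 = 0.0
    lh1 = math.log(priors.p1) + lsum1
    lh2 = math.log(priors.p2) + lsum2
    # sum over i != j equals the full cross product minus the diagonal
    lh3 = math.log(priors.p1) + math.log(priors.p2) + _logdiffexp(lsum1 + lsum2, lsum12)
    lh4 = math.log(priors.p12) + lsum12

    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    post = np.exp(lh - logsumexp(lh))
    post /= post.sum()
    return ColocResult(*(float(x) for x in post), n_snps=len(shared), priors=priors)


def coloc_call(result: ColocResult, threshold: float = 0.7) -> bool:
    """True (colocalized) iff PPH4 strictly exceeds the cutoff."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    return result.pph4 > threshold
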