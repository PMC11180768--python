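"""Pleiotropy scanning, phenome-wide MR, replication, and the final
evidence-integration verdict.

A protein survives as a candidate drug target only if every line of
evidence passes: a Bonferroni-significant discovery estimate, Steiger and
bidirectional direction checks, a clean pleiotropy scan of its
instruments, colocalization of its cis signal with the disease signal,
and replication (both same-variant and significant-variant strategies) in
an independent pQTL cohort.  Missing data never passes a filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ConfigError
from .estimators import MREstimate, bonferroni_threshold, estimate_effect
from .instruments import CisRegion, Instrument, InstrumentParams, LDPanel, select_instruments
from .sumstats import SummaryStats, harmonize

logger = logging.getLogger("pqtlmr")

TRAIT_CLASSES = ("target_disease", "risk_factor", "protein", "other")


class AnnotationCatalog:
    """Local variant–trait association catalog (a PhenoScanner stand-in).

    Records are (variant_id, trait_id, pvalue, trait_class) with
    trait_class one of target_disease / risk_factor / protein / other.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"variant_id", "trait_id", "pvalue", "trait_class"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigError(f"annotation catalog missing columns {sorted(missing)}")
        bad = set(df.trait_class) - set(TRAIT_CLASSES)
        if bad:
            raise ConfigError(f"annotation catalog has unknown trait_class values {sorted(bad)}")
        self.df = df

    @classmethod
    def read(cls, path) -> "AnnotationCatalog":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def empty(cls) -> "AnnotationCatalog":
        return cls(pd.DataFrame(columns=["variant_id", "trait_id", "pvalue", "trait_class"]))

    def hits(self, variant_ids: Sequence[str], p_max: float) -> pd.DataFrame:
        d = self.df
        return d[(d.variant_id.isin(list(variant_ids))) & (d.pvalue < p_max)]


@dataclass(slots=True)
class PhenoscanReport:
    retained: list[Instrument]
    dropped_variant_ids: list[str]
    hub_protein_count: int  # distinct other proteins the instruments associate with
    is_hub: bool

    @property
    def passed(self) -> bool:
        # a hub protein fails; so does a protein left with no instruments
        return (not self.is_hub) and len(self.retained) > 0


def phenoscan_filter(
    instruments: Sequence[Instrument],
    catalog: AnnotationCatalog,
    p_assoc: float = 5e-8,
    hub_min_proteins: int = 2,
) -> PhenoscanReport:
    """Drop instruments with a catalog association (p < p_assoc) to the
    target disease or a known risk factor, and flag the protein as a
    pleiotropy hub when its instruments associate with
    >= ``hub_min_proteins`` distinct other proteins at the same level
    (hub proteins likely regulate multiple pathways and are excluded from
    the target list).
    """
    ids = [i.variant_id for i in instruments]
    hits = catalog.hits(ids, p_assoc)
    confounded = set(hits[hits.trait_class.isin(["target_disease", "risk_factor"])].variant_id)
    retained = [i for i in instruments if i.variant_id not in confounded]
    protein_hits = hits[hits.trait_class == "protein"]
    n_proteins = protein_hits.trait_id.nunique()
    is_hub = n_proteins >= hub_min_proteins
    logger.info("phenoscan_filter n_instruments=%d n_dropped=%d n_protein_links=%d hub=%s",
                len(instruments), len(instruments) - len(retained), n_proteins, is_hub)
    return PhenoscanReport(
        retained=retained,
        dropped_variant_ids=sorted(confounded),
        hub_protein_count=int(n_proteins),
        is_hub=is_hub,
    )


# ---------------------------------------------------------------------------
# Phenome-wide MR


@dataclass(slots=True)
class PheMRRecord:
    protein_id: str
    outcome_id: str
    estimate: MREstimate | None
    status: str  # "ok" | "lack_of_data"
    significant: bool = False
    classification: str = "none"  # benefit | adverse | none


def phemr_screen(
    instruments: Sequence[Instrument],
    index_estimate: MREstimate,
    outcomes: Sequence[tuple[str, SummaryStats]],
    alpha: float = 0.05,
) -> list[PheMRRecord]:
    """Screen one protein against a catalog of disease outcomes.

    Significance is Bonferroni-controlled at alpha/N over the N outcomes
    attempted.  A significant effect whose direction matches the protein's
    effect on the index disease is classed *benefit* (a drug lowering the
    protein to treat the index disease would also lower that outcome's
    risk); an opposite direction is an *adverse* on-target effect.
    """
    n_out = len(outcomes)
    if n_out < 1:
        raise ConfigError("phemr_screen needs at least one outcome")
    threshold = bonferroni_threshold(alpha, n_out)
    exp_stats = SummaryStats(trait_id=index_estimate.exposure_id or "protein",
                             trait_type="quantitative")
    for ins in instruments:
        exp_stats.add(ins.variant)
    ids = sorted(exp_stats.records)
    index_sign = math.copysign(1.0, index_estimate.beta)

    records: list[PheMRRecord] = []
    for outcome_id, stats in outcomes:
        pairs = [p for p in harmonize(exp_stats, stats, ids) if p.ok]
        if not ids or not pairs:
            records.append(PheMRRecord(exp_stats.trait_id, outcome_id, None, "lack_of_data"))
            continue
        est = estimate_effect(pairs, exp_stats.trait_id, outcome_id)
        significant = est.pvalue < threshold
        if not significant:
            cls = "none"
        elif math.copysign(1.0, est.beta) == index_sign:
            cls = "benefit"
        else:
            cls = "adverse"
        records.append(PheMRRecord(exp_stats.trait_id, outcome_id, est, "ok",
                                   significant=significant, classification=cls))
    n_sig = sum(r.significant for r in records)
    logger.info("phemr_screen protein=%s n_outcomes=%d threshold=%.4g n_significant=%d",
                exp_stats.trait_id, n_out, threshold, n_sig)
    return records


# ---------------------------------------------------------------------------
# Replication


@dataclass(slots=True)
class ReplicationResult:
    protein_id: str
    outcome_id: str
    strategy: str  # same_variant | significant_variant
    estimate: MREstimate | None
    status: str  # passed | failed | lack_of_data | incompatible_alleles


def replicate(
    discovery_instruments: Sequence[Instrument],
    discovery_estimate: MREstimate,
    replication_exposure: SummaryStats,
    outcome: SummaryStats,
    strategy: str,
    threshold: float,
    region: CisRegion | None = None,
    panel: LDPanel | None = None,
    params: InstrumentParams | None = None,
) -> ReplicationResult:
    """Re-estimate a discovery signal in an independent pQTL cohort.

    same_variant: reuse the discovery instrument ids in the replication
    exposure.  significant_variant: re-select instruments from the
    replication exposure under the discovery selection criteria (needs the
    cis region and LD panel).  Passing requires p below the per-outcome
    threshold AND the same effect direction as the discovery estimate; all
    failure modes are statuses, never exceptions.
    """
    pid = discovery_estimate.exposure_id
    oid = outcome.trait_id
    if strategy == "same_variant":
        ids = [i.variant_id for i in discovery_instruments
               if i.variant_id in replication_exposure]
        if not ids:
            return ReplicationResult(pid, oid, strategy, None, "lack_of_data")
    elif strategy == "significant_variant":
        if region is None or panel is None:
            raise ConfigError("significant_variant replication needs a cis region and LD panel")
        repl_instruments = select_instruments(replication_exposure, region, panel, params)
        ids = [i.variant_id for i in repl_instruments]
        if not ids:
            return ReplicationResult(pid, oid, strategy, None, "lack_of_data")
    else:
        raise ConfigError(f"unknown replication strategy {strategy!r}")

    pairs = harmonize(replication_exposure, outcome, sorted(ids))
    ok = [p for p in pairs if p.ok]
    if not ok:
        if any(p.status == "dropped_incompatible" for p in pairs):
            return ReplicationResult(pid, oid, strategy, None, "incompatible_alleles")
        return ReplicationResult(pid, oid, strategy, None, "lack_of_data")
    est = estimate_effect(ok, pid, oid)
    same_direction = math.copysign(1.0, est.beta) == math.copysign(1.0, discovery_estimate.beta)
    status = "passed" if (est.pvalue < threshold and same_direction) else "failed"
    return ReplicationResult(pid, oid, strategy, est, status)


# ---------------------------------------------------------------------------
# Evidence integration


FLAG_FIELDS = (
    "discovery_significant", "steiger_pass", "bidirectional_pass",
    "phenoscan_pass", "coloc_pass", "replication_significant_pass",
    "replication_same_pass",
)


@dataclass(slots=True)
class EvidenceRow:
    """Per protein × outcome pass/fail ledger.  Flags are True / False /
    None (unknown, e.g. lack of data); only an affirmative pass on every
    filter yields verdict YES."""

    protein_id: str
    outcome_id: str
    discovery_significant: bool | None = None
    steiger_pass: bool | None = None
    bidirectional_pass: bool | None = None
    phenoscan_pass: bool | None = None
    coloc_pass: bool | None = None
    replication_significant_pass: bool | None = None
    replication_same_pass: bool | None = None

    @property
    def verdict(self) -> str:
        return "YES" if all(getattr(self, f) is True for f in FLAG_FIELDS) else "NO"


def evidence_summary(rows: Sequence[EvidenceRow]) -> pd.DataFrame:
    """Tabulate the flag ledger with the final verdict column."""
    out = pd.DataFrame([
        {"protein_id": r.protein_id, "outcome_id": r.outcome_id,
         **{f: r.__getattribute__(f) for f in FLAG_FIELDS},
         "verdict": r.verdict}
        for r in rows
    ])
    if not out.empty:
        logger.info("evidence_summary n_rows=%d n_yes=%d",
                    len(out), int((out.verdict == "YES").sum()))
    return out
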