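"""GWAS summary-statistics data model, I/O and allele harmonization.

Two-sample Mendelian randomization combines per-variant association
statistics from two independent GWAS: an exposure (here, a plasma protein
level) and an outcome (a disease).  Everything downstream operates on the
containers defined here: :class:`VariantAssociation` (one variant's record
for one trait), :class:`SummaryStats` (one trait's table) and
:class:`HarmonizedPair` (an exposure/outcome record pair expressed on a
common effect allele).

Only biallelic SNPs are modelled.  Indels and multi-allelic records are
rejected at parse time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, InputError

logger = logging.getLogger("pqtlmr")

#: Canonical column order for summary-statistics TSV files.
CANONICAL_COLUMNS = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n", "n_case", "n_control",
)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default bound of the ambiguous allele-frequency band for palindromic SNPs:
#: variants with eaf inside [limit, 1-limit] cannot be strand-resolved.
PALINDROMIC_EAF_LIMIT = 0.42


@dataclass(slots=True)
class VariantAssociation:
    """One variant's marginal association with one trait.

    ``beta`` is a log odds ratio for case-control traits and a per-SD
    effect for quantitative (protein) traits.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None
    n_case: float | None = None
    n_control: float | None = None

    def validate(self) -> None:
        if self.effect_allele not in _VALID_ALLELES or self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.variant_id}: non-SNP alleles "
                             f"{self.effect_allele}/{self.other_allele}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: identical alleles")
        if not self.se > 0 or not math.isfinite(self.se):
            raise ValueError(f"{self.variant_id}: se must be positive, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: non-finite beta")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant_id}: pvalue {self.pvalue} outside (0, 1]")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf {self.eaf} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position {self.pos} < 1 (1-based)")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G variants are strand-ambiguous."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass
class SummaryStats:
    """All summary statistics for one trait, keyed by variant id."""

    trait_id: str
    trait_type: str  # "quantitative" | "case_control"
    records: dict[str, VariantAssociation] = field(default_factory=dict)
    default_n: float | None = None
    default_n_case: float | None = None
    default_n_control: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "case_control"):
            raise ConfigError(f"unknown trait_type {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def get(self, variant_id: str) -> VariantAssociation | None:
        return self.records.get(variant_id)

    def add(self, rec: VariantAssociation) -> None:
        if rec.variant_id in self.records:
            raise InputError(f"duplicate variant_id {rec.variant_id} in trait {self.trait_id}")
        self.records[rec.variant_id] = rec

    def sample_size(self, variant_id: str | None = None) -> float:
        """Total sample size for a variant, falling back to the trait default."""
        rec = self.records.get(variant_id) if variant_id else None
        if rec is not None and rec.n is not None:
            return rec.n
        if self.default_n is not None:
            return self.default_n
        if self.trait_type == "case_control":
            nca, nco = self.case_control_sizes(variant_id)
            return nca + nco
        raise InputError(f"no sample size resolvable for trait {self.trait_id}")

    def case_control_sizes(self, variant_id: str | None = None) -> tuple[float, float]:
        rec = self.records.get(variant_id) if variant_id else None
        n_case = rec.n_case if (rec and rec.n_case is not None) else self.default_n_case
        n_control = rec.n_control if (rec and rec.n_control is not None) else self.default_n_control
        if n_case is None or n_control is None:
            raise InputError(f"case/control sizes not resolvable for trait {self.trait_id}")
        return n_case, n_control

    def effective_n(self, variant_id: str | None = None) -> float:
        """Effective sample size: total n for quantitative traits,
        4/(1/n_case + 1/n_control) for case-control traits."""
        if self.trait_type == "case_control":
            n_case, n_control = self.case_control_sizes(variant_id)
            return 4.0 / (1.0 / n_case + 1.0 / n_control)
        return self.sample_size(variant_id)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {c: getattr(r, c) for c in CANONICAL_COLUMNS}
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


@dataclass(slots=True)
class HarmonizedPair:
    """Exposure and outcome records for one variant on a common effect allele.

    When ``status == "ok"`` the outcome record has been re-expressed (sign
    of beta, complement of eaf, alleles swapped) so that its effect allele
    equals the exposure's.  Dropped pairs carry the original records and a
    reason; they feed no estimate downstream.
    """

    variant_id: str
    exposure: VariantAssociation
    outcome: VariantAssociation | None
    flipped: bool = False
    status: str = "ok"  # ok | dropped_palindromic | dropped_incompatible | missing_outcome

    @property
    def ok(self) -> bool:
        return self.status == "ok"


# ---------------------------------------------------------------------------
# Readers / writers


def _coerce_optional(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    return float(value)


def read_sumstats(
    path,
    trait_id: str,
    trait_type: str = "quantitative",
    dialect: Mapping[str, str] | None = None,
    sep: str = "\t",
    default_n: float | None = None,
    default_n_case: float | None = None,
    default_n_control: float | None = None,
) -> SummaryStats:
    """Read a delimited summary-statistics file into a :class:`SummaryStats`.

    ``dialect`` maps source column names onto the canonical fields, e.g.
    ``{"SNP": "variant_id", "A1": "effect_allele", ...}``.  Rows violating
    the record invariants (se<=0, p outside (0,1], indels, ...) are counted
    and logged, never silently dropped.

    Raises
    ------
    ConfigError
        if a mandatory canonical column cannot be resolved.
    InputError
        if no valid row remains.
    """
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if dialect:
        df = df.rename(columns=dict(dialect))
    mandatory = ("variant_id", "chrom", "pos", "effect_allele", "other_allele",
                 "beta", "se", "pvalue")
    for col in mandatory:
        if col not in df.columns:
            raise ConfigError(f"{path}: missing mandatory column {col!r} "
                              "(declare a dialect mapping for it)")
    stats = SummaryStats(
        trait_id=trait_id, trait_type=trait_type,
        default_n=default_n, default_n_case=default_n_case,
        default_n_control=default_n_control,
    )
    rejected = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            rec = VariantAssociation(
                variant_id=str(d["variant_id"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                effect_allele=str(d["effect_allele"]).upper(),
                other_allele=str(d["other_allele"]).upper(),
                beta=float(d["beta"]),
                se=float(d["se"]),
                pvalue=float(d["pvalue"]),
                eaf=_coerce_optional(d.get("eaf")),
                n=_coerce_optional(d.get("n")),
                n_case=_coerce_optional(d.get("n_case")),
                n_control=_coerce_optional(d.get("n_control")),
            )
            rec.validate()
            stats.add(rec)
        except (ValueError, KeyError) as exc:
            rejected += 1
            logger.debug("read_sumstats reject trait=%s reason=%s", trait_id, exc)
    logger.info("read_sumstats trait=%s path=%s n_valid=%d n_rejected=%d",
                trait_id, path, len(stats), rejected)
    if len(stats) == 0:
        raise InputError(f"{path}: zero valid summary-statistic rows")
    stats.n_rejected = rejected  # type: ignore[attr-defined]
    return stats


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write a trait's records as a canonical tab-separated file."""
    stats.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Harmonization


def harmonize_record(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindromic_eaf_limit: float = PALINDROMIC_EAF_LIMIT,
) -> HarmonizedPair:
    """Express ``outcome`` on the exposure's effect allele.

    Same coding: kept unchanged.  Swapped coding (exposure effect allele is
    the outcome's other allele and vice versa): the outcome beta is negated,
    its eaf complemented and the alleles swapped (``flipped=True``).
    Palindromic variants (A/T, C/G) are strand-ambiguous: they are kept,
    un-flipped, only when both studies report an allele frequency on the
    same side of 0.5 and both lie outside the ambiguous band
    ``[limit, 1-limit]``; otherwise dropped.  Any other allele combination
    is dropped as incompatible (no strand flipping is attempted).
    """
    vid = exposure.variant_id
    ea, oa = exposure.effect_allele, exposure.other_allele
    same = outcome.effect_allele == ea and outcome.other_allele == oa
    swapped = outcome.effect_allele == oa and outcome.other_allele == ea

    if not (same or swapped):
        return HarmonizedPair(vid, exposure, outcome, status="dropped_incompatible")

    if exposure.is_palindromic:
        f1, f2 = exposure.eaf, outcome.eaf
        lo, hi = palindromic_eaf_limit, 1.0 - palindromic_eaf_limit
        if f1 is None or f2 is None:
            return HarmonizedPair(vid, exposure, outcome, status="dropped_palindromic")
        ambiguous = (lo <= f1 <= hi) or (lo <= f2 <= hi)
        same_side = (f1 - 0.5) * (f2 - 0.5) > 0
        if ambiguous or not same_side:
            return HarmonizedPair(vid, exposure, outcome, status="dropped_palindromic")
        # frequencies concordant: the coding is taken at face value
        return HarmonizedPair(vid, exposure, outcome, flipped=False, status="ok")

    if same:
        return HarmonizedPair(vid, exposure, outcome, flipped=False, status="ok")

    flipped = replace(
        outcome,
        effect_allele=outcome.other_allele,
        other_allele=outcome.effect_allele,
        beta=-outcome.beta,
        eaf=None if outcome.eaf is None else 1.0 - outcome.eaf,
    )
    return HarmonizedPair(vid, exposure, flipped, flipped=True, status="ok")


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    variant_ids: Sequence[str] | Iterable[str],
    palindromic_eaf_limit: float = PALINDROMIC_EAF_LIMIT,
) -> list[HarmonizedPair]:
    """Harmonize the requested variants between two traits.

    Every requested id must be present in ``exposure``; ids absent from
    ``outcome`` come back with ``status="missing_outcome"``.  Statuses are
    data, not exceptions.
    """
    pairs: list[HarmonizedPair] = []
    for vid in variant_ids:
        exp_rec = exposure.get(vid)
        if exp_rec is None:
            raise InputError(f"variant {vid} absent from exposure trait {exposure.trait_id}")
        out_rec = outcome.get(vid)
        if out_rec is None:
            pairs.append(HarmonizedPair(vid, exp_rec, None, status="missing_outcome"))
            continue
        pairs.append(harmonize_record(exp_rec, out_rec, palindromic_eaf_limit))
    n_ok = sum(p.ok for p in pairs)
    logger.info("harmonize exposure=%s outcome=%s n_requested=%d n_ok=%d",
                exposure.trait_id, outcome.trait_id, len(pairs), n_ok)
    return pairs
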