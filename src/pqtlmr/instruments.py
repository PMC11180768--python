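"""Cis instrument selection: significance filter, LD clumping, weak-instrument
filter and cis restriction.

A valid instrument for a protein is a cis variant (within ``cis_radius`` of
the gene anchor) reaching genome-wide significance (p < 5e-8), surviving
greedy LD clumping (r² threshold 0.001 within a 10 000 kb window) against a
reference panel, and strong enough to avoid weak-instrument bias
(F-statistic >= 10, where F = (beta/se)²).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .sumstats import SummaryStats, VariantAssociation

logger = logging.getLogger("pqtlmr")

DEFAULT_CIS_RADIUS = 1_000_000  # 1 Mb either side of the gene anchor


@dataclass(frozen=True, slots=True)
class CisRegion:
    """Closed 1-based interval around a protein-coding gene's anchor."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: cis region start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @classmethod
    def around(cls, gene: str, chrom: str, anchor_pos: int,
               cis_radius: int = DEFAULT_CIS_RADIUS) -> "CisRegion":
        return cls(gene, chrom, max(1, anchor_pos - cis_radius), anchor_pos + cis_radius)


def read_gene_annotation(path, cis_radius: int = DEFAULT_CIS_RADIUS) -> dict[str, CisRegion]:
    """Read a TSV of (gene, chrom, anchor_pos) into cis regions."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "chrom", "anchor_pos"):
        if col not in df.columns:
            raise ConfigError(f"{path}: annotation table missing column {col!r}")
    return {
        str(r.gene): CisRegion.around(str(r.gene), str(r.chrom), int(r.anchor_pos), cis_radius)
        for r in df.itertuples(index=False)
    }


@dataclass(slots=True)
class Instrument:
    """A retained instrument: the exposure-GWAS record plus its selection flags."""

    variant: VariantAssociation
    f_stat: float
    is_cis: bool = True
    clump_index: bool = True

    @property
    def variant_id(self) -> str:
        return self.variant.variant_id


class LDPanel:
    """Reference panel exposing pairwise r² between variants.

    Backed either by a 0/1 haplotype matrix (rows = haplotypes, columns =
    variants) or by a precomputed square r² matrix.  Variant coordinates
    come with the panel so clumping can apply its distance window.
    """

    def __init__(self, variant_ids: list[str], chrom: np.ndarray, pos: np.ndarray,
                 haplotypes: np.ndarray | None = None, r2: np.ndarray | None = None):
        if (haplotypes is None) == (r2 is None):
            raise ConfigError("LDPanel needs exactly one of haplotypes or r2")
        self.variant_ids = list(variant_ids)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        self.chrom = np.asarray(chrom)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.haplotypes = None if haplotypes is None else np.asarray(haplotypes, dtype=np.float64)
        self._r2 = None if r2 is None else np.asarray(r2, dtype=np.float64)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def __len__(self) -> int:
        return len(self.variant_ids)

    def frequencies(self) -> np.ndarray:
        if self.haplotypes is None:
            raise InputError("panel has no haplotypes; frequencies unavailable")
        return self.haplotypes.mean(axis=0)

    def r2(self, id1: str, id2: str) -> float:
        i, j = self._index[id1], self._index[id2]
        if self._r2 is not None:
            return float(self._r2[i, j])
        if i == j:
            return 1.0
        a, b = self.haplotypes[:, i], self.haplotypes[:, j]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            return 0.0
        r = float(np.corrcoef(a, b)[0, 1])
        return r * r

    def r2_matrix(self, ids: list[str]) -> np.ndarray:
        idx = [self._index[v] for v in ids]
        if self._r2 is not None:
            return self._r2[np.ix_(idx, idx)]
        sub = self.haplotypes[:, idx]
        sd = sub.std(axis=0)
        sd[sd == 0] = np.nan
        c = np.corrcoef(sub, rowvar=False)
        c = np.nan_to_num(c, nan=0.0)
        np.fill_diagonal(c, 1.0)
        return c * c

    # -- I/O -----------------------------------------------------------------

    def write(self, hap_path, sites_path) -> None:
        """Write haplotypes (0/1 matrix, no header) plus a variant sidecar TSV."""
        if self.haplotypes is None:
            raise InputError("cannot write a haplotype file from an r²-backed panel")
        np.savetxt(hap_path, self.haplotypes.astype(np.int8), fmt="%d", delimiter="\t")
        pd.DataFrame({
            "variant_id": self.variant_ids,
            "chrom": self.chrom,
            "pos": self.pos,
        }).to_csv(sites_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, hap_path, sites_path) -> "LDPanel":
        sites = pd.read_csv(sites_path, sep="\t")
        hap = np.loadtxt(hap_path, delimiter="\t", dtype=np.int8)
        if hap.ndim == 1:
            hap = hap[:, None]
        if hap.shape[1] != len(sites):
            raise InputError(f"haplotype matrix has {hap.shape[1]} columns but "
                             f"sidecar lists {len(sites)} variants")
        return cls(list(sites.variant_id.astype(str)), sites.chrom.astype(str).to_numpy(),
                   sites.pos.to_numpy(), haplotypes=hap)

    @classmethod
    def from_r2_file(cls, path, sites_path) -> "LDPanel":
        sites = pd.read_csv(sites_path, sep="\t")
        mat = pd.read_csv(path, sep="\t", index_col=0)
        ids = list(sites.variant_id.astype(str))
        mat = mat.loc[ids, ids].to_numpy(dtype=np.float64)
        return cls(ids, sites.chrom.astype(str).to_numpy(), sites.pos.to_numpy(), r2=mat)


# ---------------------------------------------------------------------------
# Selection steps


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F-statistic, (beta/se)².

    Equivalent to the squared association z-score; values below 10
    conventionally flag weak instruments.
    """
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    z = beta / se
    return z * z


def greedy_clump(
    candidates: list[VariantAssociation],
    panel: LDPanel,
    r2_max: float = 0.001,
    window_kb: float = 10_000,
) -> list[VariantAssociation]:
    """Greedy LD clumping: keep the smallest-p variant, discard everything
    correlated with it (r² > r2_max) within ``window_kb`` on the same
    chromosome, repeat.  Ties on p are broken lexicographically by
    variant_id.  Candidates absent from the panel are dropped (counted in
    the log).  Output sorted by p ascending.
    """
    usable = [c for c in candidates if c.variant_id in panel]
    n_missing = len(candidates) - len(usable)
    if n_missing:
        logger.info("greedy_clump n_missing_from_panel=%d", n_missing)
    remaining = sorted(usable, key=lambda v: (v.pvalue, v.variant_id))
    window_bp = window_kb * 1000.0
    retained: list[VariantAssociation] = []
    while remaining:
        index = remaining.pop(0)
        retained.append(index)
        keep: list[VariantAssociation] = []
        for v in remaining:
            if v.chrom == index.chrom and abs(v.pos - index.pos) <= window_bp \
                    and panel.r2(index.variant_id, v.variant_id) > r2_max:
                continue
            keep.append(v)
        remaining = keep
    return retained


@dataclass(slots=True)
class InstrumentParams:
    """Selection thresholds. Defaults follow standard drug-target MR practice:
    genome-wide significance, near-independent instruments, F >= 10."""

    p_threshold: float = 5e-8
    r2_max: float = 0.001
    window_kb: float = 10_000
    f_min: float = 10.0
    cis_radius: int = DEFAULT_CIS_RADIUS
    counts: dict = field(default_factory=dict, compare=False)


def select_instruments(
    protein_stats: SummaryStats,
    region: CisRegion,
    panel: LDPanel,
    params: InstrumentParams | None = None,
) -> list[Instrument]:
    """Apply, in order: cis restriction -> p filter -> LD clumping -> F filter.

    Boundary conventions: p equal to the threshold is excluded (strict <);
    F equal to the minimum is retained (the exclusion rule is strict <).
    An empty list is a legal result.  A region chromosome absent from the
    stats yields an empty list with a logged warning.
    """
    params = params or InstrumentParams()
    records = list(protein_stats.records.values())
    if not any(r.chrom == region.chrom for r in records):
        logger.warning("select_instruments trait=%s gene=%s chrom=%s absent from stats",
                       protein_stats.trait_id, region.gene, region.chrom)
        params.counts = {"cis": 0, "significant": 0, "clumped": 0, "strong": 0}
        return []

    cis = [r for r in records if region.contains(r.chrom, r.pos)]
    significant = [r for r in cis if r.pvalue < params.p_threshold]
    clumped = greedy_clump(significant, panel, params.r2_max, params.window_kb)
    out = []
    for rec in clumped:
        f = f_statistic(rec.beta, rec.se)
        if f < params.f_min:  # "F < 10 excluded": F == 10 is retained
            continue
        out.append(Instrument(variant=rec, f_stat=f, is_cis=True, clump_index=True))
    params.counts = {"cis": len(cis), "significant": len(significant),
                     "clumped": len(clumped), "strong": len(out)}
    logger.info("select_instruments trait=%s gene=%s n_cis=%d n_significant=%d "
                "n_clumped=%d n_instruments=%d", protein_stats.trait_id, region.gene,
                len(cis), len(significant), len(clumped), len(out))
    return out
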