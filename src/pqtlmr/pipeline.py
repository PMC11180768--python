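"""End-to-end orchestration: one YAML config in, an evidence table out.

The pipeline wires the stages together in the order the analysis runs:
instrument selection → discovery MR scan → direction tests (Steiger +
bidirectional) → pleiotropy scan → colocalization → replication (both
strategies) → phenome-wide screen → evidence integration.  Every stage
writes a TSV under ``outdir`` and logs structured ``key=value`` count
lines; a protein that drops out at any stage is carried to the final
table with explicit statuses rather than disappearing.

:func:`simulate_study` writes a complete self-contained synthetic study
(per-protein pQTL files, one disease GWAS, a replication cohort, an LD
panel, an annotation catalog, a phenome-wide manifest and the config)
so the whole pipeline can be exercised without any external data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coloc import ColocPriors, coloc_abf, coloc_call
from .direction import DirectionVerdict, bidirectional_mr, steiger_filter
from .errors import ConfigError, InputError
from .estimators import MREstimate, ScanRecord, bonferroni_threshold, mr_scan
from .instruments import (CisRegion, Instrument, InstrumentParams, LDPanel,
                          select_instruments)
from .screens import (AnnotationCatalog, EvidenceRow, evidence_summary,
                      phemr_screen, phenoscan_filter, replicate)
from .simulate import draw_genotypes, linear_gwas, logistic_gwas, simulate_panel
from .sumstats import SummaryStats, VariantAssociation, harmonize, read_sumstats, write_sumstats

logger = logging.getLogger("pqtlmr")

_THRESHOLD_DEFAULTS = {
    "p_instrument": 5e-8,
    "r2_max": 0.001,
    "window_kb": 10_000,
    "f_min": 10.0,
    "cis_radius": 1_000_000,
    "alpha": 0.05,
    "palindromic_eaf_limit": 0.42,
    "pph4_threshold": 0.7,
    "p_phenoscan": 5e-8,
    "hub_min_proteins": 2,
    "coloc_p1": 1e-4,
    "coloc_p2": 1e-4,
    "coloc_p12": 1e-5,
    "coloc_sd_quantitative": 0.15,
    "coloc_sd_case_control": 0.2,
}

_TOP_KEYS = {"outdir", "seed", "proteins", "outcome", "panel", "catalog",
             "phemr_manifest", "thresholds"}
_PROTEIN_KEYS = {"id", "sumstats", "n", "replication_sumstats", "replication_n",
                 "gene", "chrom", "anchor_pos"}
_OUTCOME_KEYS = {"id", "sumstats", "n_case", "n_control"}
_PANEL_KEYS = {"haplotypes", "sites", "r2"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} in {where}")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration. Paths are resolved relative to the
    config file's directory."""

    outdir: Path
    seed: int
    proteins: list[dict]
    outcome: dict
    panel: dict
    thresholds: dict
    catalog: Path | None = None
    phemr_manifest: Path | None = None
    base_dir: Path = field(default_factory=Path)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        _check_keys(raw, _TOP_KEYS, str(path))
        base = path.parent
        thresholds = dict(_THRESHOLD_DEFAULTS)
        user_thr = raw.get("thresholds") or {}
        _check_keys(user_thr, set(_THRESHOLD_DEFAULTS), "thresholds")
        thresholds.update(user_thr)
        _validate_thresholds(thresholds)
        proteins = raw.get("proteins") or []
        for p in proteins:
            _check_keys(p, _PROTEIN_KEYS, f"protein entry {p.get('id', '?')}")
        outcome = raw.get("outcome")
        if proteins and not outcome:
            raise ConfigError("config needs an outcome section")
        if outcome:
            _check_keys(outcome, _OUTCOME_KEYS, "outcome")
        panel = raw.get("panel") or {}
        _check_keys(panel, _PANEL_KEYS, "panel")
        return cls(
            outdir=base / raw.get("outdir", "results"),
            seed=int(raw.get("seed", 0)),
            proteins=proteins,
            outcome=outcome or {},
            panel=panel,
            thresholds=thresholds,
            catalog=(base / raw["catalog"]) if raw.get("catalog") else None,
            phemr_manifest=(base / raw["phemr_manifest"]) if raw.get("phemr_manifest") else None,
            base_dir=base,
        )

    def instrument_params(self) -> InstrumentParams:
        t = self.thresholds
        return InstrumentParams(
            p_threshold=t["p_instrument"], r2_max=t["r2_max"],
            window_kb=t["window_kb"], f_min=t["f_min"],
            cis_radius=int(t["cis_radius"]),
        )

    def coloc_priors(self) -> ColocPriors:
        t = self.thresholds
        return ColocPriors(p1=t["coloc_p1"], p2=t["coloc_p2"], p12=t["coloc_p12"])


def _validate_thresholds(t: dict) -> None:
    for key in ("p_instrument", "alpha", "pph4_threshold", "p_phenoscan",
                "coloc_p1", "coloc_p2", "coloc_p12"):
        if not 0 < t[key] < 1:
            raise ConfigError(f"threshold {key}={t[key]} outside (0,1)")
    if not 0 <= t["r2_max"] <= 1:
        raise ConfigError(f"r2_max={t['r2_max']} outside [0,1]")
    if not 0 <= t["palindromic_eaf_limit"] <= 0.5:
        raise ConfigError("palindromic_eaf_limit must lie in [0, 0.5]")
    for key in ("window_kb", "f_min", "cis_radius", "hub_min_proteins"):
        if t[key] < 0:
            raise ConfigError(f"threshold {key} must be non-negative")


# ---------------------------------------------------------------------------
# Study loading


@dataclass
class ProteinData:
    protein_id: str
    stats: SummaryStats
    region: CisRegion
    replication: SummaryStats | None = None


@dataclass
class StudyData:
    config: PipelineConfig
    proteins: dict[str, ProteinData]
    outcome: SummaryStats
    panel: LDPanel
    catalog: AnnotationCatalog
    phemr_outcomes: list[tuple[str, SummaryStats]]


def load_study(config: PipelineConfig) -> StudyData:
    """Read every input the config points to."""
    base = config.base_dir
    if config.panel.get("haplotypes"):
        panel = LDPanel.from_files(base / config.panel["haplotypes"], base / config.panel["sites"])
    elif config.panel.get("r2"):
        panel = LDPanel.from_r2_file(base / config.panel["r2"], base / config.panel["sites"])
    else:
        raise ConfigError("panel section needs haplotypes+sites or r2+sites")

    outcome = read_sumstats(
        base / config.outcome["sumstats"], trait_id=config.outcome.get("id", "outcome"),
        trait_type="case_control",
        default_n_case=config.outcome.get("n_case"),
        default_n_control=config.outcome.get("n_control"),
    )

    cis_radius = int(config.thresholds["cis_radius"])
    proteins: dict[str, ProteinData] = {}
    for entry in config.proteins:
        pid = str(entry["id"])
        stats = read_sumstats(base / entry["sumstats"], trait_id=pid,
                              trait_type="quantitative", default_n=entry.get("n"))
        region = CisRegion.around(entry.get("gene", pid), str(entry["chrom"]),
                                  int(entry["anchor_pos"]), cis_radius)
        repl = None
        if entry.get("replication_sumstats"):
            repl = read_sumstats(base / entry["replication_sumstats"], trait_id=f"{pid}_repl",
                                 trait_type="quantitative", default_n=entry.get("replication_n"))
        proteins[pid] = ProteinData(pid, stats, region, repl)

    catalog = AnnotationCatalog.read(config.catalog) if config.catalog \
        else AnnotationCatalog.empty()

    phemr: list[tuple[str, SummaryStats]] = []
    if config.phemr_manifest:
        with open(config.phemr_manifest) as fh:
            manifest = yaml.safe_load(fh) or []
        for item in manifest:
            _check_keys(item, {"id", "sumstats", "n_case", "n_control"}, "phemr manifest entry")
            phemr.append((str(item["id"]), read_sumstats(
                base / item["sumstats"], trait_id=str(item["id"]), trait_type="case_control",
                default_n_case=item.get("n_case"), default_n_control=item.get("n_control"))))
    return StudyData(config, proteins, outcome, panel, catalog, phemr)


# ---------------------------------------------------------------------------
# Pipeline


#: Stage order; ``run_pipeline(stop_after=...)`` truncates the run here.
STAGES = ("instruments", "mr", "direction", "phenoscan", "coloc",
          "replicate", "phemr", "evidence")


def run_pipeline(config: PipelineConfig, stop_after: str | None = None) -> pd.DataFrame:
    """Execute the stages in order and return the last table produced.

    Per-stage TSVs are written under ``config.outdir``.  Stages beyond the
    discovery scan run only for discovery-significant proteins; everything
    else is carried with explicit statuses.  The per-outcome replication
    threshold is 0.05 divided by the number of discovery hits for the
    outcome, mirroring the discovery-count-based correction.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ConfigError(f"unknown stage {stop_after!r}; choose from {STAGES}")
    last = STAGES.index(stop_after) if stop_after else len(STAGES) - 1
    enabled = set(STAGES[:last + 1])
    study = load_study(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = config.thresholds
    params = config.instrument_params()
    pal = t["palindromic_eaf_limit"]

    # --- stage 1: instrument selection -------------------------------------
    instruments: dict[str, list[Instrument]] = {}
    inst_rows = []
    for pid, pdata in study.proteins.items():
        ins = select_instruments(pdata.stats, pdata.region, study.panel, params)
        instruments[pid] = ins
        for i in ins:
            inst_rows.append({"protein_id": pid, "variant_id": i.variant_id,
                              "chrom": i.variant.chrom, "pos": i.variant.pos,
                              "beta": i.variant.beta, "se": i.variant.se,
                              "pvalue": i.variant.pvalue, "f_stat": i.f_stat})
    inst_df = pd.DataFrame(inst_rows, columns=["protein_id", "variant_id", "chrom", "pos",
                                               "beta", "se", "pvalue", "f_stat"])
    inst_df.to_csv(outdir / "instruments.tsv", sep="\t", index=False)
    if "mr" not in enabled:
        return inst_df

    # --- stage 2: discovery MR scan -----------------------------------------
    scan = mr_scan(instruments, study.outcome, alpha=t["alpha"], palindromic_eaf_limit=pal)
    scan_df = _write_scan(scan, outdir / "mr.tsv", study.outcome.trait_id)
    if "direction" not in enabled:
        return scan_df
    hits = [r for r in scan if r.significant]
    n_hits = len(hits)
    repl_threshold = bonferroni_threshold(t["alpha"], n_hits) if n_hits else t["alpha"]
    logger.info("pipeline stage=mr n_proteins=%d n_hits=%d repl_threshold=%.4g",
                len(scan), n_hits, repl_threshold)

    # --- stages 3-7 for significant proteins --------------------------------
    direction_rows, coloc_rows, phenoscan_rows, repl_rows, phemr_rows = [], [], [], [], []
    evidence_rows: list[EvidenceRow] = []
    for rec in scan:
        pid = rec.protein_id
        pdata = study.proteins[pid]
        row = EvidenceRow(protein_id=pid, outcome_id=study.outcome.trait_id,
                          discovery_significant=bool(rec.significant))
        if not rec.significant:
            evidence_rows.append(row)
            continue
        est = rec.estimate
        ins = instruments[pid]
        ids = sorted(i.variant_id for i in ins)
        exp_stats = pdata.stats
        pairs = [p for p in harmonize(exp_stats, study.outcome, ids, pal) if p.ok]

        # Steiger + bidirectional: the reverse direction (disease -> protein)
        # is measured in the replication cohort when available (the
        # discovery pQTL study has no full protein summary statistics in
        # the emulated design)
        steiger = steiger_filter(pairs, exp_stats.effective_n(), study.outcome.effective_n())
        protein_outcome_stats = pdata.replication or exp_stats
        rev_est, rev_status = bidirectional_mr(study.outcome, protein_outcome_stats,
                                               study.panel, params)
        verdict = DirectionVerdict(steiger, rev_est, rev_status)
        row.steiger_pass = bool(steiger.correct_direction and steiger.pvalue < 0.05)
        row.bidirectional_pass = (bool(rev_est.pvalue > 0.05) if rev_status == "ok" else None)
        direction_rows.append({
            "protein_id": pid, "outcome_id": study.outcome.trait_id,
            "steiger_r2_exposure": steiger.r2_exposure,
            "steiger_r2_outcome": steiger.r2_outcome,
            "steiger_p": steiger.pvalue,
            "reverse_beta": rev_est.beta if rev_est else math.nan,
            "reverse_p": rev_est.pvalue if rev_est else math.nan,
            "reverse_status": rev_status,
            "passed": verdict.passed,
        })

        # pleiotropy scan
        if "phenoscan" in enabled:
            report = phenoscan_filter(ins, study.catalog, t["p_phenoscan"],
                                      int(t["hub_min_proteins"]))
            row.phenoscan_pass = report.passed
            phenoscan_rows.append({
                "protein_id": pid, "n_instruments": len(ins),
                "n_dropped": len(report.dropped_variant_ids),
                "hub_protein_count": report.hub_protein_count,
                "is_hub": report.is_hub, "passed": report.passed,
            })

        # colocalization over the cis window
        if "coloc" in enabled:
            region1 = [v for v in exp_stats.records.values()
                       if pdata.region.contains(v.chrom, v.pos)]
            region2 = [v for v in study.outcome.records.values()
                       if pdata.region.contains(v.chrom, v.pos)]
            try:
                cres = coloc_abf(region1, region2, config.coloc_priors(),
                                 sd1=t["coloc_sd_quantitative"],
                                 sd2=t["coloc_sd_case_control"])
                row.coloc_pass = coloc_call(cres, t["pph4_threshold"])
                coloc_rows.append({"protein_id": pid, "outcome_id": study.outcome.trait_id,
                                   "n_snps": cres.n_snps, "pph0": cres.pph0,
                                   "pph1": cres.pph1, "pph2": cres.pph2,
                                   "pph3": cres.pph3, "pph4": cres.pph4,
                                   "colocalized": row.coloc_pass})
            except InputError:
                row.coloc_pass = None

        # replication, both strategies
        if "replicate" in enabled and pdata.replication is not None:
            for strategy in ("same_variant", "significant_variant"):
                res = replicate(ins, est, pdata.replication, study.outcome,
                                strategy, repl_threshold,
                                region=pdata.region, panel=study.panel, params=params)
                passed = (True if res.status == "passed"
                          else False if res.status == "failed" else None)
                if strategy == "same_variant":
                    row.replication_same_pass = passed
                else:
                    row.replication_significant_pass = passed
                repl_rows.append({
                    "protein_id": pid, "outcome_id": study.outcome.trait_id,
                    "strategy": strategy, "status": res.status,
                    "beta": res.estimate.beta if res.estimate else math.nan,
                    "pvalue": res.estimate.pvalue if res.estimate else math.nan,
                    "threshold": repl_threshold,
                })

        # phenome-wide screen
        if "phemr" in enabled and study.phemr_outcomes:
            for r in phemr_screen(ins, est, study.phemr_outcomes, t["alpha"]):
                phemr_rows.append({
                    "protein_id": r.protein_id, "outcome_id": r.outcome_id,
                    "status": r.status,
                    "beta": r.estimate.beta if r.estimate else math.nan,
                    "pvalue": r.estimate.pvalue if r.estimate else math.nan,
                    "significant": r.significant, "classification": r.classification,
                })
        evidence_rows.append(row)

    tables = {
        "direction": (direction_rows, "direction.tsv"),
        "phenoscan": (phenoscan_rows, "phenoscan.tsv"),
        "coloc": (coloc_rows, "coloc.tsv"),
        "replicate": (repl_rows, "replication.tsv"),
        "phemr": (phemr_rows, "phemr.tsv"),
    }
    last_df = scan_df
    for stage, (rows, fname) in tables.items():
        if stage in enabled:
            last_df = pd.DataFrame(rows)
            last_df.to_csv(outdir / fname, sep="\t", index=False)
    if "evidence" not in enabled:
        return last_df
    evidence = evidence_summary(evidence_rows)
    evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    logger.info("pipeline stage=evidence n_rows=%d n_yes=%d", len(evidence),
                int((evidence.verdict == "YES").sum()) if len(evidence) else 0)
    return evidence


def _write_scan(scan: list[ScanRecord], path, outcome_id: str) -> pd.DataFrame:
    rows = []
    for r in scan:
        e = r.estimate
        rows.append({
            "protein_id": r.protein_id, "outcome_id": outcome_id, "status": r.status,
            "method": e.method if e else "", "n_snp": e.n_snp if e else 0,
            "beta": e.beta if e else math.nan, "se": e.se if e else math.nan,
            "or": e.or_ if e else math.nan,
            "ci_low": e.ci_low if e else math.nan, "ci_high": e.ci_high if e else math.nan,
            "pvalue": e.pvalue if e else math.nan, "significant": r.significant,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# Synthetic study writer


def simulate_study(
    outdir,
    seed: int,
    n_proteins: int = 5,
    n_variants_per_region: int = 120,
    n_hap: int = 1_000,
    ld_decay: float = 0.9,
    n_exposure: int = 7_213,
    n_replication: int = 10_000,
    n_case: int = 15_000,
    n_control: int = 15_000,
    h2_exposure: float = 0.05,
    mr_effect: float = 0.45,
    background_logor: float = 0.15,
    n_background_loci: int = 2,
    n_background_variants: int = 40,
) -> Path:
    """Write a complete synthetic study: the first protein is truly causal
    for the disease (its cis pQTL signal is mediated into the disease GWAS),
    the rest have cis pQTLs but no disease effect.  Additional background
    loci give the disease GWAS genuine instruments of its own so the
    bidirectional check has something to work with.  Returns the config path.
    """
    outdir = Path(outdir)
    data_dir = outdir / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    spacing = 1_500

    regions: list[LDPanel] = []
    id_offset = 1
    for k in range(n_proteins):
        regions.append(simulate_panel(n_hap, n_variants_per_region, ld_decay,
                                      rng, chrom=str(k + 1), start=1_000_000,
                                      spacing=spacing, id_offset=id_offset))
        id_offset += n_variants_per_region
    bg_regions: list[LDPanel] = []
    for k in range(n_background_loci):
        bg_regions.append(simulate_panel(n_hap, n_background_variants, ld_decay,
                                         rng, chrom=str(20 + k + 1), start=1_000_000,
                                         spacing=spacing, id_offset=id_offset))
        id_offset += n_background_variants

    all_panels = regions + bg_regions
    panel = _concat_panels(all_panels)
    panel.write(data_dir / "panel_haplotypes.tsv", data_dir / "panel_sites.tsv")

    # per-protein causal architecture
    causal_idx = [int(rng.integers(0, n_variants_per_region)) for _ in range(n_proteins)]
    freqs = [reg.frequencies() for reg in regions]
    b_exp = [float(np.sqrt(h2_exposure / (2 * f[i] * (1 - f[i]))))
             for f, i in zip(freqs, causal_idx)]

    # discovery pQTL files cover only the cis region (the emulated discovery
    # study published cis summary statistics only); replication files also
    # cover the disease background loci, like a genome-wide protein GWAS —
    # the bidirectional check needs protein data at the disease's own hits.
    bg_panel = _concat_panels(bg_regions) if bg_regions else None
    protein_entries = []
    for k, reg in enumerate(regions):
        pid = f"P{k + 1}"
        for label, n_cohort in (("discovery", n_exposure), ("replication", n_replication)):
            genome = reg if (label == "discovery" or bg_panel is None) \
                else _concat_panels([reg, bg_panel])
            G = draw_genotypes(genome, n_cohort, rng)
            x = b_exp[k] * G[:, causal_idx[k]] + rng.normal(
                0.0, math.sqrt(1 - h2_exposure), size=n_cohort)
            beta, se, p = linear_gwas(G, x)
            stats = _stats_from_arrays(pid if label == "discovery" else f"{pid}_repl",
                                       "quantitative", genome, beta, se, p,
                                       G.mean(axis=0) / 2.0, n=n_cohort)
            write_sumstats(stats, data_dir / f"{pid}_{label}.tsv")
        anchor = int(reg.pos[causal_idx[k]])
        protein_entries.append({
            "id": pid, "sumstats": f"data/{pid}_discovery.tsv", "n": n_exposure,
            "replication_sumstats": f"data/{pid}_replication.tsv",
            "replication_n": n_replication,
            "gene": pid, "chrom": str(k + 1), "anchor_pos": anchor,
        })

    # disease GWAS across all regions: protein P1 mediated + background loci
    n_out = n_case + n_control
    G_blocks = [draw_genotypes(reg, n_out, rng) for reg in all_panels]
    g_c = G_blocks[0][:, causal_idx[0]]
    eta = mr_effect * b_exp[0] * (g_c - g_c.mean())
    for kb in range(n_background_loci):
        g = G_blocks[n_proteins + kb][:, n_background_variants // 2]
        eta = eta + background_logor * (g - g.mean())
    y = (rng.random(n_out) < 1.0 / (1.0 + np.exp(-eta))).astype(np.float64)
    G_all = np.hstack(G_blocks)
    beta_o, se_o, p_o = logistic_gwas(G_all, y)
    out_stats = _stats_from_arrays("disease", "case_control", panel, beta_o, se_o, p_o,
                                   G_all.mean(axis=0) / 2.0, n=n_out,
                                   n_case=float(y.sum()), n_control=float(n_out - y.sum()))
    write_sumstats(out_stats, data_dir / "disease.tsv")

    # phenome-wide outcomes on P1's region: benefit, adverse, null
    phemr_entries = []
    for name, effect in (("side_benefit", 0.5), ("side_adverse", -0.5), ("side_null", 0.0)):
        G = draw_genotypes(regions[0], n_out, rng)
        g_s = G[:, causal_idx[0]]
        eta_s = effect * b_exp[0] * (g_s - g_s.mean())
        y_s = (rng.random(n_out) < 1.0 / (1.0 + np.exp(-eta_s))).astype(np.float64)
        beta_s, se_s, p_s = logistic_gwas(G, y_s)
        stats = _stats_from_arrays(name, "case_control", regions[0], beta_s, se_s, p_s,
                                   G.mean(axis=0) / 2.0, n=n_out,
                                   n_case=float(y_s.sum()), n_control=float(n_out - y_s.sum()))
        write_sumstats(stats, data_dir / f"{name}.tsv")
        phemr_entries.append({"id": name, "sumstats": f"data/{name}.tsv",
                              "n_case": float(y_s.sum()), "n_control": float(n_out - y_s.sum())})
    with open(data_dir / "phemr_manifest.yaml", "w") as fh:
        yaml.safe_dump(phemr_entries, fh)

    # annotation catalog: benign entries only (no disqualifying pleiotropy)
    catalog = pd.DataFrame({
        "variant_id": [regions[0].variant_ids[causal_idx[0]]],
        "trait_id": ["unrelated_trait"],
        "pvalue": [1e-3],
        "trait_class": ["other"],
    })
    catalog.to_csv(data_dir / "catalog.tsv", sep="\t", index=False)

    config = {
        "outdir": "results",
        "seed": int(seed),
        "proteins": protein_entries,
        "outcome": {"id": "disease", "sumstats": "data/disease.tsv",
                    "n_case": float(y.sum()), "n_control": float(n_out - y.sum())},
        "panel": {"haplotypes": "data/panel_haplotypes.tsv",
                  "sites": "data/panel_sites.tsv"},
        "catalog": "data/catalog.tsv",
        "phemr_manifest": "data/phemr_manifest.yaml",
        "thresholds": {},
    }
    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    logger.info("simulate_study outdir=%s seed=%d n_proteins=%d causal=P1", outdir, seed,
                n_proteins)
    return config_path


def _concat_panels(panels: list[LDPanel]) -> LDPanel:
    """Join unlinked regions into one panel, preserving the generative
    parameters (each input region stays its own chain block)."""
    ids = [v for p in panels for v in p.variant_ids]
    chrom = np.concatenate([p.chrom for p in panels])
    pos = np.concatenate([p.pos for p in panels])
    hap = np.hstack([p.haplotypes for p in panels])
    joined = LDPanel(ids, chrom, pos, haplotypes=hap.astype(np.int8))
    if all(getattr(p, "sim_freqs", None) is not None for p in panels):
        joined.sim_freqs = np.concatenate([p.sim_freqs for p in panels])
        blocks, offset = [], 0
        for p in panels:
            for start, length, decay in p.sim_blocks:
                blocks.append((start + offset, length, decay))
            offset += len(p)
        joined.sim_blocks = blocks
    return joined


def _stats_from_arrays(trait_id: str, trait_type: str, panel: LDPanel,
                       beta, se, p, eaf, n: float,
                       n_case: float | None = None,
                       n_control: float | None = None) -> SummaryStats:
    stats = SummaryStats(trait_id=trait_id, trait_type=trait_type, default_n=float(n),
                         default_n_case=n_case, default_n_control=n_control)
    for j, vid in enumerate(panel.variant_ids):
        stats.add(VariantAssociation(
            variant_id=vid, chrom=str(panel.chrom[j]), pos=int(panel.pos[j]),
            effect_allele="A", other_allele="G",
            beta=float(beta[j]), se=float(se[j]), pvalue=float(p[j]),
            eaf=float(eaf[j]), n=float(n), n_case=n_case, n_control=n_control))
    return stats
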