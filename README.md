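# pqtlmr

Proteome-wide Mendelian randomization (MR) for drug-target discovery.

Circulating proteins are attractive drug targets because they can be
assayed and modulated directly — but observational protein–disease
associations are riddled with confounding and reverse causation. `pqtlmr`
implements the genetic-epidemiology workflow that addresses this: each
protein's cis-pQTLs (variants near its encoding gene that shift its plasma
level) serve as instrumental variables, and the protein's causal effect on
a disease is estimated from two independent GWAS — then stress-tested until
only signals with target-grade evidence survive. The package is aimed at
statistical geneticists and biostatisticians who want the whole chain —
instrument selection, estimation, and every published sensitivity filter —
as one tested, scriptable pipeline that also ships its own synthetic-data
generator with known ground truth.

## The method

For a protein with a single valid instrument, the causal log odds ratio per
SD of protein is the **Wald ratio**

```
β̂ = β_out / β_exp,    se(β̂) = se_out / |β_exp|
```

and with several instruments the **inverse-variance-weighted** combination
`β̂ = Σ wⱼβ̂ⱼ / Σ wⱼ`, `wⱼ = 1/se(β̂ⱼ)²`. Instruments are cis variants at
`p < 5×10⁻⁸`, LD-clumped (r² ≤ 0.001 within 10 000 kb against a reference
panel) and strong (`F = (β/se)² ≥ 10`). A discovery hit must then pass, in
order:

- **Steiger filtering** — instruments explain more variance in the protein
  than in the disease (`r² = z²/(z²+n−2)`, Fisher-z comparison);
- **bidirectional MR** — the reverse (disease → protein) estimate, from the
  disease GWAS's own genome-wide instruments, is null (p > 0.05);
- **pleiotropy scanning** — no instrument is independently associated with
  the disease or its risk factors, and the protein is not a multi-protein
  "hub";
- **Bayesian colocalization** — Wakefield approximate Bayes factors and
  enumeration of the five hypotheses H0–H4; the protein's cis signal and
  the disease signal share a causal variant when `PPH4 > 0.7`;
- **replication** — same-variant and significant-variant strategies in an
  independent pQTL cohort, at `0.05 / (discovery hits per outcome)` with
  direction concordance;
- **phenome-wide MR** — the protein screened against a catalog of disease
  outcomes at `0.05/N`, classifying significant effects as on-target
  *benefit* or *adverse* by direction consistency with the index disease.

The final verdict is a conjunction: a protein is called a potential drug
target only if every filter affirmatively passes. See `docs/methods.md`
for the full model, parameter defaults and design choices.

## Worked example

Generate a fully synthetic five-protein study — one protein (P1) truly
causal for the disease with a colocalizing cis signal, four with pQTLs but
no disease effect — and run the whole pipeline:

```python
from pqtlmr import PipelineConfig, run_pipeline, simulate_study

config_path = simulate_study("demo_study", seed=7)
evidence = run_pipeline(PipelineConfig.from_yaml(config_path))
print(evidence.to_string(index=False))
```

```
protein_id outcome_id  discovery_significant steiger_pass bidirectional_pass phenoscan_pass coloc_pass replication_significant_pass replication_same_pass verdict
        P1    disease                   True         True               True           True       True                         True                  True     YES
        P2    disease                  False         None               None           None       None                         None                  None      NO
        P3    disease                  False         None               None           None       None                         None                  None      NO
        P4    disease                  False         None               None           None       None                         None                  None      NO
        P5    disease                  False         None               None           None       None                         None                  None      NO
```

Exactly the causal protein survives; the nulls stop at the discovery scan
(flags beyond that stage stay unknown and a non-pass vetoes the verdict).
The per-stage tables land next to the config; the discovery scan
(`results/mr.tsv`) shows P1's odds ratio per SD of protein and the nulls'
flat estimates:

```
protein_id     method  n_snp    or  ci_low  ci_high  pvalue  significant
        P1 wald_ratio      1 1.623   1.461    1.804   0.000         True
        P2 wald_ratio      1 0.927   0.834    1.031   0.162        False
        P3 wald_ratio      1 0.986   0.890    1.092   0.782        False
        P4 wald_ratio      1 0.963   0.866    1.072   0.496        False
        P5 wald_ratio      1 0.965   0.878    1.060   0.459        False
```

(P1's generative truth is a log-OR of 0.45 per SD, i.e. OR ≈ 1.57; the
direction table shows its Steiger asymmetry — r² 0.046 in the protein vs
0.003 in the disease — and a null reverse estimate, p = 0.489.) The same
run is available from the shell:

```bash
pqtlmr simulate --outdir demo_study --seed 7
pqtlmr run --config demo_study/config.yaml
```

with stage-wise subcommands `instruments`, `mr`, `direction`, `coloc`,
`replicate` and `screen`, and `pqtlmr replay` to push the published
16-row breast-cancer evidence table through the same decision rules
(it prints the five published targets and `n_yes=5`).

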