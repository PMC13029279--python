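# Table schemas

All tables are comma-separated UTF-8 text with a header row.  Multi-valued
cells use `;` as the intra-cell separator (configurable on read/write).

## Case table (`cases.csv`)

One row per deduplicated ICSR.

| column | type | meaning |
|---|---|---|
| `case_id` | string | unique case identifier |
| `suspect_actives` | `;`-list | reporter-designated causal candidate drugs (nonempty) |
| `concomitant_actives` | `;`-list | co-administered actives (disjoint from suspects) |
| `reactions` | `;`-list | reaction terms |
| `serious` | 0/1 | regulatory seriousness flag |
| `sex` | string | `female` / `male` / `unknown` |
| `follow_up` | 0/1 | follow-up (parent-child) report flag |
| `literature` | 0/1 | literature report flag |
| `raw_cluster` | string | raw ADR phenotype cluster label (input, not re-estimated) |

Validation on load: unique nonempty ids, nonempty suspect sets; violations
are reported per row.

## Expanded table (`expanded.csv`)

One row per (case, suspect drug, reaction): `case_id, drug, reaction,
cluster, serious`.  Expansion never introduces case ids absent from the case
table.

## Drug catalog (`drug_catalog.csv`)

`drug, drug_class (INSTI|PI|NNRTI|NRTI|RdRp|other), phenotype (affiliated
harmonised phenotype; synthetic data only), mw (g/mol), is_hub`.

## ADMET table (`admet.csv`)

`drug, drug_class, mw` plus continuous predictors `ADMET_Risk, TOX_Risk,
CYP_HLM_CLint, BSEP_IC50, hERG_pIC50, LogBB, hmufup` (missing values allowed;
median-imputed where a model requires completeness) and 0/1 liability flags
`BSEP_inhibition, Pgp_inhibition, Pgp_substrate, BCRP_substrate,
CYP3A4_inhibition`.

## PK bounds table (`pk_bounds.csv`)

`drug, stage (trimester-2|trimester-3|postpartum), metric (Cmax|AUC0-24),
min, max, central, mw`.  Units: Cmax in ug/mL, AUC0-24 in ug*h/mL, mw in
g/mol.  Either (`min`,`max`) or `central` must be present; `min <= max`.

## Potency table (`potency.csv`)

`drug, mechanism (BSEP_IC50|CYP1A2_Ki|CYP2D6_Ki|CYP3A4_Ki), potency_um`
(micromolar, positive).

## Ground truth (`ground_truth.json`)

Planted generator parameters: per-active odds ratio, seriousness intercept,
phenotype x feature shift matrix (sd units), hub drug list, raw phenotype
probabilities, booster probability, drug phenotype affiliations.

## Result tables

- `enrichment_*.csv`: `drug, phenotype, a, b, c, d, ror, ci_lo, ci_hi, p, q,
  oe_ratio, enriched`.
- `mvi.csv`: `drug, total_reports, n_clusters, adr_composite, high_burden,
  rf_prob, z_poly, z_net, z_sev, composite_raw, mvi_pct, serious_frac,
  mean_degree, mean_polypharmacy, dominant_phenotype`.
- `dps.csv`: `regimen (;-joined), n_drugs, mos, nas, svs, dps, tier`.
- `exposure_ratios.csv`: `drug, stage, ratio, median, lo95, hi95, p_gt_1,
  p_gt_10, n_samples, seed`.
- `robustness.csv`: `strategy, depth, frac_edges_removed, frac_lo95,
  frac_hi95, modularity, mod_lo95, mod_hi95, replicates`.
- `run_manifest.json`: config (with hash), per-stage seeds, per-stage
  artifact names.  No timestamps, so identical configs give identical runs.
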