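"""End-to-end pipeline orchestration with config, provenance and manifest.

Stages run in dependency order, each reading its inputs from delimited-text
artifacts in the run directory and writing its outputs there, so any stage
can be re-run from cached upstream artifacts.  A machine-readable manifest
records the config hash, the per-stage seeds and every artifact written; the
manifest carries no timestamps, so identical configs produce byte-identical
runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import embedding, enrichment, network, phenotypes, scoring, seriousness
from .exposure import exposure_liability_table
from .icsr import (
    DrugProfile,
    assign_primary_active,
    compute_polypharmacy,
    expand_cases,
    read_cases_csv,
)
from .synthetic import (
    HEPATOBILIARY_TERMS,
    SynthConfig,
    write_synthetic_inputs,
)

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "ingest",
    "phenotypes",
    "enrich",
    "network",
    "regress",
    "score",
    "exposure",
    "embed",
]


@dataclass
class RunConfig:
    """Pipeline configuration; every stochastic stage has an explicit seed."""

    outdir: str = "runs/default"
    seed: int = 0
    n_cases: int = 1938
    harmonise_threshold: float = 0.02
    fdr_alpha: float = 0.05
    top_k: int = 10
    mvi_weights: tuple = (0.60, 0.15, 0.15, 0.10)
    rf_trees: int = 500
    dps_thresholds: tuple = (0.75, 0.50)
    dps_tier_mode: str = "absolute"
    mc_n: int = 10_000
    robustness_depths: tuple = (0, 2, 5, 10)
    robustness_replicates: int = 200
    diagnostics: bool = False
    diagnostics_B: int = 200
    stages: tuple = tuple(STAGES)
    synth: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.harmonise_threshold < 1:
            raise ValueError("harmonise_threshold outside (0, 1)")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha outside (0, 1)")
        if abs(sum(self.mvi_weights) - 1) > 1e-9:
            raise ValueError("mvi_weights must sum to 1")
        if self.mc_n < 1 or self.robustness_replicates < 1:
            raise ValueError("simulation sizes must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1_000 + STAGES.index(stage)) % (2**31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("mvi_weights", "dps_thresholds", "robustness_depths", "stages"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write the run manifest.

    Returns the manifest dict.  Stages not listed in ``config.stages`` are
    skipped; their artifacts must already exist if a later stage needs them.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("vigimech").addHandler(handler)
    try:
        return _run_stages(config, out)
    finally:
        logging.getLogger("vigimech").removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, out: Path) -> dict:
    artifacts: dict[str, dict[str, str]] = {}

    def save(stage: str, name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)
        artifacts.setdefault(stage, {})[name] = path.name

    def save_json(stage: str, name: str, payload: dict) -> None:
        path = out / f"{name}.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
        artifacts.setdefault(stage, {})[name] = path.name

    if "simulate" in config.stages:
        synth = SynthConfig(
            n_cases=config.n_cases, seed=config.stage_seed("simulate"), **config.synth
        )
        paths = write_synthetic_inputs(synth, out)
        artifacts["simulate"] = {k: Path(v).name for k, v in paths.items()}

    # shared inputs -------------------------------------------------------
    def load_cases():
        if not (out / "cases.csv").exists():
            raise FileNotFoundError(
                f"{out / 'cases.csv'} not found: run the simulate stage or place a "
                "case table at that path"
            )
        return read_cases_csv(out / "cases.csv")

    def load_catalog() -> dict[str, DrugProfile]:
        path = out / "drug_catalog.csv"
        if not path.exists():
            raise FileNotFoundError(f"{path} not found: run the simulate stage first")
        df = pd.read_csv(path)
        return {
            r.drug: DrugProfile(drug=r.drug, drug_class=r.drug_class, mw=r.mw)
            for r in df.itertuples(index=False)
        }

    def load_admet() -> pd.DataFrame:
        path = out / "admet.csv"
        if not path.exists():
            raise FileNotFoundError(
                f"{path} not found: the scoring/phenotype stages need the ADMET "
                "feature table; run the simulate stage or provide one"
            )
        return pd.read_csv(path)

    if "ingest" in config.stages:
        cases = load_cases()
        save("ingest", "expanded", expand_cases(cases))
        poly = pd.DataFrame(
            [{"case_id": c.case_id, **compute_polypharmacy(c)} for c in cases]
        )
        save("ingest", "polypharmacy", poly)

    if "phenotypes" in config.stages:
        cases = load_cases()
        admet = load_admet()
        catalog = load_catalog()
        expanded = pd.read_csv(out / "expanded.csv")
        pmap = phenotypes.harmonise_phenotypes(cases, config.harmonise_threshold)
        save_json("phenotypes", "phenotype_map",
                  {"threshold": pmap.threshold_frac, "mapping": pmap.mapping})
        save("phenotypes", "phenotype_summary",
             phenotypes.seriousness_by_phenotype(cases, pmap))
        sig = phenotypes.admet_signature(expanded, admet, pmap)
        save("phenotypes", "signature_z", sig.z.reset_index())
        save("phenotypes", "signature_long", phenotypes.signature_long(sig))
        save("phenotypes", "kw_panel", phenotypes.kw_panel(expanded, admet, pmap))
        # ICC: expanded records carrying the primary drug's composite ADMET risk
        primary = {c.case_id: assign_primary_active(c, catalog) for c in cases}
        risk = dict(zip(admet["drug"], admet["ADMET_Risk"]))
        icc_df = expanded.assign(
            value=[risk.get(primary[cid]) for cid in expanded["case_id"]],
            phenotype=expanded["cluster"].map(pmap.mapping),
        ).dropna(subset=["value"])
        icc = phenotypes.icc_one_way(icc_df["value"], icc_df["phenotype"])
        save_json("phenotypes", "icc", dataclasses.asdict(icc))
        hep = {
            ph: phenotypes.reaction_class_or(cases, HEPATOBILIARY_TERMS, ph, pmap)
            for ph in pmap.phenotypes
        }
        save_json("phenotypes", "hepatobiliary_or",
                  {ph: {k: v for k, v in d.items()} for ph, d in hep.items()})

    if "enrich" in config.stages:
        cases = load_cases()
        catalog = load_catalog()
        pmap = phenotypes.harmonise_phenotypes(cases, config.harmonise_threshold)
        res_p = enrichment.enrich(cases, pmap, "primary", catalog, config.fdr_alpha)
        res_a = enrichment.enrich(cases, pmap, "all_suspect", catalog, config.fdr_alpha)
        save("enrich", "enrichment_primary", res_p)
        save("enrich", "enrichment_all_suspect", res_a)
        save("enrich", "attribution_jaccard",
             enrichment.attribution_sensitivity(res_p, res_a, config.top_k))
        topk = pd.DataFrame(
            [
                {"phenotype": ph, "rank": i + 1, "drug": d}
                for ph in sorted(set(res_p["phenotype"]))
                for i, d in enumerate(enrichment.top_k(res_p, ph, config.top_k))
            ]
        )
        save("enrich", "top_k", topk)

    if "network" in config.stages:
        cases = load_cases()
        g = network.build_graph(cases)
        save("network", "edges", network.export_edge_list(g))
        save("network", "centrality", network.node_centrality(g))
        depths = [d for d in config.robustness_depths if d <= g.number_of_nodes() - 1]
        curves = pd.concat(
            [
                network.robustness_sim(
                    g, strat, depths, config.robustness_replicates,
                    seed=config.stage_seed("network"),
                )
                for strat in ("targeted", "random")
            ],
            ignore_index=True,
        )
        save("network", "robustness", curves)

    if "regress" in config.stages:
        cases = load_cases()
        fit = seriousness.fit_seriousness(cases)
        robust = seriousness.fit_seriousness(cases, robust_se=True)
        _, restricted, retained = seriousness.sensitivity_restrict(cases)
        save_json("regress", "seriousness_fit", {
            "primary": fit.to_dict(),
            "robust": robust.to_dict(),
            "restricted": {**restricted.to_dict(), "retained_frac": retained},
            "compounded": {
                "k5": seriousness.compound_or(fit.or_per_active, 5).rounded,
                "k10": seriousness.compound_or(fit.or_per_active, 10).rounded,
            },
        })
        save("regress", "model_matrix", seriousness.model_matrix(cases))

    if "score" in config.stages:
        cases = load_cases()
        admet = load_admet()
        catalog = load_catalog()
        pmap = phenotypes.harmonise_phenotypes(cases, config.harmonise_threshold)
        centrality = pd.read_csv(out / "centrality.csv")
        table = scoring.build_drug_table(cases, pmap, centrality, admet, drugs=sorted(catalog))
        mvi, rf = scoring.mvi_table(
            table, seed=config.stage_seed("score"), weights=config.mvi_weights,
            n_trees=config.rf_trees,
        )
        save("score", "mvi", mvi.reset_index())
        flags = admet.set_index("drug")[
            [c for c in admet.columns if c.endswith(("_inhibition", "_substrate"))]
        ]
        degree = dict(zip(centrality["drug"], centrality["degree"]))
        mvi_map = dict(zip(mvi.index, mvi["mvi_pct"]))
        regimens = scoring.regimens_from_cases(cases, restrict_to=catalog)
        dps = scoring.dps_table(
            regimens, flags, degree, mvi_map,
            thresholds=config.dps_thresholds, tier_mode=config.dps_tier_mode,
        )
        save("score", "dps", dps)
        save_json("score", "score_provenance", {
            "weights": list(config.mvi_weights),
            "seed": config.stage_seed("score"),
            "rf_trees": config.rf_trees,
            "excluded_features": list(scoring.DEFAULT_EXCLUDE),
            "dps_thresholds": list(config.dps_thresholds),
            "dps_tier_mode": config.dps_tier_mode,
        })
        if config.diagnostics:
            feature_cols = [c for c in rf.features]
            diag = scoring.mvi_diagnostics(
                table[feature_cols], mvi.loc[table.index, "high_burden"], table,
                seed=config.stage_seed("score"), n_trees=config.rf_trees,
                B=config.diagnostics_B,
            )
            save_json("score", "mvi_diagnostics", diag)

    if "exposure" in config.stages:
        bounds = pd.read_csv(out / "pk_bounds.csv")
        potency = pd.read_csv(out / "potency.csv")
        save("exposure", "exposure_ratios",
             exposure_liability_table(bounds, potency, n=config.mc_n,
                                      seed=config.stage_seed("exposure")))

    if "embed" in config.stages:
        cases = load_cases()
        admet = load_admet()
        catalog = load_catalog()
        pmap = phenotypes.harmonise_phenotypes(cases, config.harmonise_threshold)
        centrality = pd.read_csv(out / "centrality.csv")
        table = scoring.build_drug_table(cases, pmap, centrality, admet, drugs=sorted(catalog))
        X = embedding.select_features(table, mode="mixed")
        fit = embedding.pca_embed(embedding.zscore_features(X), k=2)
        save("embed", "pca_loadings", fit.loadings.reset_index(names="feature"))
        save("embed", "pca_variance", pd.DataFrame({
            "component": fit.loadings.columns,
            "variance_frac": fit.variance_frac,
        }))
        scores = fit.scores.reset_index(names="drug")
        scores["dominant_phenotype"] = scores["drug"].map(table["dominant_phenotype"])
        save("embed", "pca_scores", scores)
        save("embed", "pca_lodo_stability", embedding.lodo_loading_stability(X, k=2))

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": {s: config.stage_seed(s) for s in config.stages},
        "stages": {s: artifacts.get(s, {}) for s in config.stages},
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest
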