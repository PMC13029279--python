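"""Synthetic ICSR cohort generator with known ground truth.

Emulates the statistical structure of a pregnancy pharmacovigilance line
listing: a deduplicated case table with hub-dominated co-medication sets,
heavy-tailed polypharmacy counts (median 11 actives per report, IQR 6-27),
seriousness driven by a logistic model in the polypharmacy burden, raw ADR
phenotype cluster labels with one dominant cluster and at least one cluster
below the 2% harmonisation threshold, plus a drug-level ADMET feature table
with phenotype-linked mean shifts and a pregnancy PK bounds / potency table
pair.  Every draw flows from a single seed through spawned child generators,
and the returned GroundTruth records the planted parameters so that recovery
tests can close the loop.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .icsr import CaseReport

CONTINUOUS_FEATURES = [
    "ADMET_Risk",
    "TOX_Risk",
    "CYP_HLM_CLint",
    "BSEP_IC50",
    "hERG_pIC50",
    "LogBB",
    "hmufup",
]

#: Baseline (mean, sd) per continuous ADMET feature, on plausible native scales.
FEATURE_BASELINES = {
    "ADMET_Risk": (5.0, 1.5),
    "TOX_Risk": (3.0, 1.0),
    "CYP_HLM_CLint": (30.0, 10.0),
    "BSEP_IC50": (60.0, 20.0),
    "hERG_pIC50": (5.0, 0.7),
    "LogBB": (-0.5, 0.5),
    "hmufup": (0.2, 0.08),
}

LIABILITY_FLAGS = [
    "BSEP_inhibition",
    "Pgp_inhibition",
    "Pgp_substrate",
    "BCRP_substrate",
    "CYP3A4_inhibition",
]

#: Reaction vocabulary; the four hepatobiliary terms form the default term set
#: for reaction-class concordance analyses.
HEPATOBILIARY_TERMS = frozenset(
    {
        "cholestasis",
        "blood bilirubin increased",
        "hepatic enzyme increased",
        "jaundice cholestatic",
    }
)

GENERIC_TERMS = [
    "drug exposure during pregnancy",
    "premature baby",
    "abortion spontaneous",
    "foetal growth restriction",
    "nausea",
    "vomiting",
    "pyrexia",
    "rash",
    "anaemia",
    "headache",
    "dizziness",
    "diarrhoea",
    "renal impairment",
    "thrombocytopenia",
    "hypertension",
    "gestational diabetes",
    "preeclampsia",
    "insomnia",
    "depressed mood",
    "weight decreased",
]

REACTION_VOCAB = GENERIC_TERMS + sorted(HEPATOBILIARY_TERMS)

BOOSTERS = ("cobicistat", "ritonavir")

_DEFAULT_PHENOTYPE_PROBS = {
    "C1": 0.46,
    "C3": 0.25,
    "C2": 0.18,
    "C5": 0.08,
    "C4": 0.012,
    "C6": 0.010,
    "C7": 0.008,
}

_DEFAULT_CLASS_MIX = {
    "INSTI": 0.20,
    "PI": 0.20,
    "NNRTI": 0.15,
    "NRTI": 0.25,
    "RdRp": 0.10,
    "other": 0.10,
}

# Phenotype-linked mean shifts (in units of feature sd) for the harmonised
# phenotypes; signs follow the qualitative signature pattern the analysis is
# meant to recover (e.g. the transporter phenotype C3 has depressed BSEP IC50,
# i.e. stronger predicted BSEP inhibition).
_DEFAULT_SHIFTS = {
    "C1": {"ADMET_Risk": 0.8, "TOX_Risk": 0.8, "CYP_HLM_CLint": -0.8, "hERG_pIC50": -0.8},
    "C2": {"ADMET_Risk": -1.0, "TOX_Risk": -1.0, "CYP_HLM_CLint": 1.0, "hERG_pIC50": 1.0},
    "C3": {"BSEP_IC50": -1.0, "ADMET_Risk": 0.5, "TOX_Risk": 0.5},
    "C5": {"LogBB": -0.5},
    "Other": {"LogBB": 1.5, "BSEP_IC50": 1.5},
}

# Per-phenotype weight multiplier on hepatobiliary reaction terms; below 1
# means the phenotype under-reports that reaction class.
_DEFAULT_HEPATOBILIARY_WEIGHT = {"C1": 1.0, "C2": 1.0, "C3": 0.4, "C5": 1.0, "Other": 1.2}


@dataclass
class PolypharmacyDist:
    """Shifted negative binomial for per-report active counts.

    Defaults reproduce a median of 11 unique actives per report with IQR 6-27:
    count = shift + NB(r, r/(r+mu)).
    """

    shift: int = 5
    r: float = 0.35
    mu: float = 18.4

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.r / (self.r + self.mu)
        return self.shift + rng.negative_binomial(self.r, p, size=n)


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    The defaults are the study conditions the analysis assumes; tests and the
    acceptance script use them unchanged except for cohort size.
    """

    n_cases: int = 1938
    n_drugs: int = 25
    n_other_actives: int = 150
    n_comed_communities: int = 12
    comed_affinity: float = 1e12
    comed_zipf: float = 0.8
    suspect_zipf: float = 1.1
    class_mix: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_MIX))
    phenotype_probs: dict = field(default_factory=lambda: dict(_DEFAULT_PHENOTYPE_PROBS))
    harmonise_threshold: float = 0.02
    seriousness_intercept: float = 0.9
    per_active_log_or: float = math.log(1.05)
    polypharmacy_dist: PolypharmacyDist = field(default_factory=PolypharmacyDist)
    polypharmacy_cap: int = 40
    hub_strength: float = 8.0
    n_hubs: int = 5
    affinity_boost: float = 8.0
    booster_prob: float = 0.236
    female_prob: float = 0.95
    follow_up_prob: float = 0.35
    literature_prob: float = 0.35
    mean_extra_reactions: float = 3.4
    admet_shift_matrix: dict = field(default_factory=lambda: {p: dict(v) for p, v in _DEFAULT_SHIFTS.items()})
    admet_noise_sd: float = 1.0
    admet_missing_frac: float = 0.1
    hepatobiliary_weight: dict = field(default_factory=lambda: dict(_DEFAULT_HEPATOBILIARY_WEIGHT))
    n_pk_drugs: int = 15
    pk_stages: tuple = ("trimester-2", "trimester-3", "postpartum")
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        for name, probs in (("class_mix", self.class_mix), ("phenotype_probs", self.phenotype_probs)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} contains negative probabilities")
        if not 0 < self.harmonise_threshold < 1:
            raise ValueError("harmonise_threshold must lie in (0, 1)")
        if self.polypharmacy_dist.shift < 1:
            raise ValueError("polypharmacy counts must be >= 1")

    def harmonised_label(self, raw: str) -> str:
        """Harmonised phenotype implied by the configured raw probabilities."""
        return raw if self.phenotype_probs.get(raw, 0.0) >= self.harmonise_threshold else "Other"

    @property
    def harmonised_phenotypes(self) -> list[str]:
        labels = {self.harmonised_label(raw) for raw in self.phenotype_probs}
        return sorted(labels)


@dataclass
class GroundTruth:
    """Planted parameters recorded for parameter-recovery tests."""

    true_per_active_or: float
    seriousness_intercept: float
    true_admet_shifts: pd.DataFrame
    hub_drugs: list[str]
    phenotype_probs: dict
    booster_prob: float
    drug_phenotype: dict

    def __post_init__(self) -> None:
        if self.true_per_active_or <= 0:
            raise ValueError("true_per_active_or must be positive")

    def to_json(self) -> str:
        payload = {
            "true_per_active_or": self.true_per_active_or,
            "seriousness_intercept": self.seriousness_intercept,
            "true_admet_shifts": self.true_admet_shifts.to_dict(),
            "hub_drugs": self.hub_drugs,
            "phenotype_probs": self.phenotype_probs,
            "booster_prob": self.booster_prob,
            "drug_phenotype": self.drug_phenotype,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def make_catalog(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Drug catalog: antiviral actives with class, affiliated phenotype, MW.

    The first ``n_hubs`` drugs are the co-prescription hubs.  Each drug is
    affiliated with one harmonised phenotype; cases of that phenotype
    preferentially report the drug as suspect, which is what lets signature
    recovery work downstream.
    """
    classes = list(config.class_mix)
    class_p = np.array([config.class_mix[c] for c in classes])
    phen = config.harmonised_phenotypes
    raw_probs = np.array(
        [sum(v for r, v in config.phenotype_probs.items() if config.harmonised_label(r) == p) for p in phen]
    )
    raw_probs = raw_probs / raw_probs.sum()
    # deterministic largest-remainder allocation of drugs to phenotypes (every
    # phenotype keeps a stable affiliated-drug count across seeds), assignment
    # to individual drugs shuffled
    quota = raw_probs * config.n_drugs
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: config.n_drugs - counts.sum()]:
        counts[i] += 1
    assignment = np.repeat(phen, counts)
    rng.shuffle(assignment)
    drugs = [f"antiviral-{i + 1:02d}" for i in range(config.n_drugs)]
    return pd.DataFrame(
        {
            "drug": drugs,
            "drug_class": rng.choice(classes, size=config.n_drugs, p=class_p),
            "phenotype": assignment,
            "mw": np.round(rng.uniform(250.0, 800.0, size=config.n_drugs), 1),
            "is_hub": [i < config.n_hubs for i in range(config.n_drugs)],
        }
    )


def _gumbel_topk(logw: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Weighted sampling without replacement via Gumbel perturbation."""
    keys = logw + rng.gumbel(size=logw.shape[0])
    return np.argpartition(-keys, k - 1)[:k]


def generate_cohort(config: SynthConfig) -> tuple[list[CaseReport], GroundTruth]:
    """Draw a synthetic deduplicated cohort plus its ground-truth record."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss = root.spawn(6)
    rng_cat, rng_struct, rng_drugs, rng_react, rng_flags, rng_serious = [
        np.random.default_rng(s) for s in ss
    ]

    catalog = make_catalog(config, rng_cat)
    truth = GroundTruth(
        true_per_active_or=math.exp(config.per_active_log_or),
        seriousness_intercept=config.seriousness_intercept,
        true_admet_shifts=shift_matrix_frame(config),
        hub_drugs=list(catalog.loc[catalog.is_hub, "drug"]),
        phenotype_probs=dict(config.phenotype_probs),
        booster_prob=config.booster_prob,
        drug_phenotype=dict(zip(catalog.drug, catalog.phenotype)),
    )
    if config.n_cases == 0:
        return [], truth

    n = config.n_cases
    raw_labels = list(config.phenotype_probs)
    raw_p = np.array([config.phenotype_probs[x] for x in raw_labels])
    raw = rng_struct.choice(raw_labels, size=n, p=raw_p)
    harmonised = np.array([config.harmonised_label(x) for x in raw])

    n_total = config.polypharmacy_dist.sample(n, rng_struct)
    universe = list(catalog.drug) + [f"comed-{i + 1:02d}" for i in range(config.n_other_actives)]
    n_universe = len(universe)
    # +1 below leaves room for a booster, which is added outside the natural
    # draw; the cap bounds the heavy negative-binomial tail at a clinically
    # plausible regimen size
    n_total = np.clip(
        n_total,
        config.polypharmacy_dist.shift,
        min(config.polypharmacy_cap, n_universe + 1),
    )
    n_suspect = np.minimum(rng_struct.integers(1, 4, size=n), config.n_drugs)

    # suspect draws follow phenotype affinity only: a case reports drugs
    # affiliated with its phenotype affinity_boost times more often.  Hub
    # dominance of the network comes from the concomitant pool, where report
    # volume is long-tailed like real line listings.
    av_popularity = (1.0 + np.arange(config.n_drugs)) ** (-config.suspect_zipf)
    phen_logw = {
        p: np.log(np.where(catalog.phenotype == p, config.affinity_boost, 1.0))
        for p in config.harmonised_phenotypes
    }
    # Concomitant actives come in regimen-like communities: a case draws mostly
    # from one community, spilling into the two ring-adjacent ones for very
    # large regimens, plus the globally shared hub drugs.  This keeps the
    # binary co-occurrence graph sparse and modular with concentrated hubs,
    # the topology the robustness analysis assumes.
    n_comm = max(1, config.n_comed_communities)
    comed_community = np.arange(config.n_other_actives) % n_comm
    # communities are allocated to phenotypes so that regimen context tracks
    # the clinical phenotype; a case draws its community among its phenotype's
    phen_list = config.harmonised_phenotypes
    comm_of_phen = {
        p: [k for k in range(n_comm) if k * len(phen_list) // n_comm == i] or [i % n_comm]
        for i, p in enumerate(phen_list)
    }
    case_community = np.array(
        [
            comm_of_phen[p][rng_struct.integers(len(comm_of_phen[p]))]
            for p in harmonised
        ]
    )
    # non-hub antivirals enter cases as suspects only (the hub backbone drugs
    # also appear as concomitants); within a community, concomitant popularity
    # decays like a Zipf law so that rare actives exist and node degrees are
    # heterogeneous
    conc_av_w = np.where(catalog.is_hub, config.hub_strength, 1e-12) * av_popularity
    popularity = (1.0 + np.arange(config.n_other_actives) // n_comm) ** (
        -config.comed_zipf
    )
    comm_logw = {}
    for k in range(n_comm):
        comed_w = np.full(config.n_other_actives, 1.0 / config.comed_affinity)
        comed_w[comed_community == k] = 1.0
        comed_w[comed_community == (k + 1) % n_comm] = 0.3
        comed_w[comed_community == (k + 2) % n_comm] = 0.1
        comm_logw[k] = np.log(np.concatenate([conc_av_w, comed_w * popularity]))

    booster = rng_struct.random(n) < config.booster_prob
    booster_pick = rng_struct.integers(0, len(BOOSTERS), size=n)
    serious = rng_serious.random(n) < _expit(
        config.seriousness_intercept + config.per_active_log_or * n_total
    )
    sex = np.where(rng_flags.random(n) < config.female_prob, "female", "male")
    follow_up = rng_flags.random(n) < config.follow_up_prob
    literature = rng_flags.random(n) < config.literature_prob
    n_react = 1 + rng_react.poisson(config.mean_extra_reactions, size=n)
    n_react = np.minimum(n_react, len(REACTION_VOCAB))

    vocab = np.array(REACTION_VOCAB)
    hep_mask = np.isin(vocab, list(HEPATOBILIARY_TERMS))
    react_logw = {}
    for p in config.harmonised_phenotypes:
        w = np.ones(len(vocab))
        w[hep_mask] = config.hepatobiliary_weight.get(p, 1.0)
        react_logw[p] = np.log(w)

    drug_arr = np.array(universe)
    cases: list[CaseReport] = []
    for i in range(n):
        p = harmonised[i]
        k_s = int(n_suspect[i])
        sus_idx = _gumbel_topk(phen_logw[p], k_s, rng_drugs)
        suspects = frozenset(drug_arr[sus_idx])
        k_c = int(n_total[i]) - k_s - int(booster[i])
        logw = comm_logw[int(case_community[i])].copy()
        logw[sus_idx] = -np.inf
        k_c = max(0, min(k_c, n_universe - k_s))
        conc = set(drug_arr[_gumbel_topk(logw, k_c, rng_drugs)]) if k_c else set()
        if booster[i]:
            conc.add(BOOSTERS[booster_pick[i]])
        reactions = tuple(vocab[_gumbel_topk(react_logw[p], int(n_react[i]), rng_react)])
        cases.append(
            CaseReport(
                case_id=f"EU-{i + 1:06d}",
                suspect_actives=suspects,
                concomitant_actives=frozenset(conc),
                reactions=reactions,
                serious=bool(serious[i]),
                sex=str(sex[i]),
                follow_up=bool(follow_up[i]),
                literature=bool(literature[i]),
                raw_cluster=str(raw[i]),
            )
        )
    return cases, truth


def shift_matrix_frame(config: SynthConfig) -> pd.DataFrame:
    """Planted shift matrix as phenotype x feature (sd units), zero-filled."""
    unknown = {
        f for row in config.admet_shift_matrix.values() for f in row if f not in CONTINUOUS_FEATURES
    }
    if unknown:
        raise KeyError(f"unknown feature(s) in shift matrix: {sorted(unknown)}")
    frame = pd.DataFrame(
        0.0, index=sorted(config.admet_shift_matrix), columns=CONTINUOUS_FEATURES
    )
    for p, row in config.admet_shift_matrix.items():
        for f, v in row.items():
            frame.loc[p, f] = v
    return frame


def generate_admet_table(
    catalog: pd.DataFrame,
    shifts: dict | pd.DataFrame | None = None,
    seed: int = 0,
    noise_sd: float = 1.0,
    missing_frac: float = 0.1,
) -> pd.DataFrame:
    """Per-drug ADMET feature table with phenotype-linked shifts.

    Continuous feature = baseline mean + (planted shift + noise) * baseline sd,
    where the shift row is selected by the drug's affiliated phenotype.  A
    ``missing_frac`` fraction of continuous cells is blanked to exercise the
    downstream median imputation; at least one value per feature survives.
    """
    rng = np.random.default_rng(seed)
    if shifts is None:
        shifts = _DEFAULT_SHIFTS
    if isinstance(shifts, pd.DataFrame):
        shifts = {p: row.dropna().to_dict() for p, row in shifts.iterrows()}
    unknown = {f for row in shifts.values() for f in row if f not in CONTINUOUS_FEATURES}
    if unknown:
        raise KeyError(f"unknown feature(s) in shift matrix: {sorted(unknown)}")

    out = catalog[["drug", "drug_class", "mw"]].copy()
    n = len(catalog)
    for feature in CONTINUOUS_FEATURES:
        mean, sd = FEATURE_BASELINES[feature]
        shift = np.array([shifts.get(p, {}).get(feature, 0.0) for p in catalog.phenotype])
        values = mean + (shift + noise_sd * rng.standard_normal(n)) * sd
        out[feature] = np.round(values, 4)
    if missing_frac > 0 and n > 1:
        for feature in CONTINUOUS_FEATURES:
            mask = rng.random(n) < missing_frac
            if mask.all():
                mask[rng.integers(n)] = False
            out.loc[mask, feature] = np.nan
    for flag in LIABILITY_FLAGS:
        out[flag] = (rng.random(n) < 0.3).astype(int)
    return out


@dataclass(frozen=True)
class PkSpecRow:
    """Explicit exposure-bound specification for one drug x stage x metric."""

    drug: str
    stage: str
    metric: str  # "Cmax" (ug/mL) or "AUC0-24" (ug*h/mL)
    min: float | None = None
    max: float | None = None
    central: float | None = None

    def validate(self) -> None:
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError(f"{self.drug}/{self.stage}/{self.metric}: min > max")
        if self.min is None and self.central is None:
            raise ValueError(f"{self.drug}/{self.stage}/{self.metric}: no exposure information")


def generate_pk_tables(
    catalog: pd.DataFrame,
    spec: list[PkSpecRow] | None = None,
    seed: int = 0,
    n_pk_drugs: int = 15,
    stages: tuple = ("trimester-2", "trimester-3", "postpartum"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pregnancy PK bounds and potency tables.

    Without an explicit spec, bounds are drawn for the first ``n_pk_drugs``
    drugs: per stage a lognormal central Cmax (ug/mL) and AUC0-24 (ug*h/mL)
    with min/max at 0.6x/1.6x the central value.  Potency values (uM) cover
    BSEP IC50 and three CYP Ki axes.  Molecular weight is attached per drug.
    """
    rng = np.random.default_rng(seed)
    mw = dict(zip(catalog.drug, catalog.mw))
    if (catalog.mw <= 0).any():
        raise ValueError("molecular weights must be positive")
    rows = []
    if spec is not None:
        for s in spec:
            s.validate()
            if s.drug not in mw:
                raise KeyError(f"unknown drug in PK spec: {s.drug}")
            rows.append((s.drug, s.stage, s.metric, s.min, s.max, s.central, mw[s.drug]))
        drugs = sorted({s.drug for s in spec})
    else:
        drugs = list(catalog.drug[: min(n_pk_drugs, len(catalog))])
        for drug in drugs:
            for stage in stages:
                cmax = float(np.exp(rng.normal(1.0, 0.5)))
                auc = cmax * float(rng.uniform(8.0, 16.0))
                rows.append((drug, stage, "Cmax", round(0.6 * cmax, 4), round(1.6 * cmax, 4), round(cmax, 4), mw[drug]))
                rows.append((drug, stage, "AUC0-24", round(0.6 * auc, 4), round(1.6 * auc, 4), round(auc, 4), mw[drug]))
    bounds = pd.DataFrame(rows, columns=["drug", "stage", "metric", "min", "max", "central", "mw"])

    pot_rows = []
    for drug in drugs:
        pot_rows.append((drug, "BSEP_IC50", round(float(np.exp(rng.normal(np.log(50.0), 0.8))), 4)))
        for cyp in ("CYP1A2_Ki", "CYP2D6_Ki", "CYP3A4_Ki"):
            pot_rows.append((drug, cyp, round(float(np.exp(rng.normal(np.log(20.0), 1.0))), 4)))
    potency = pd.DataFrame(pot_rows, columns=["drug", "mechanism", "potency_um"])
    return bounds, potency


def write_synthetic_inputs(config: SynthConfig, outdir: str | Path) -> dict[str, str]:
    """Generate and write all three input tables plus the ground-truth JSON."""
    from .icsr import write_cases_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cases, truth = generate_cohort(config)
    root = np.random.SeedSequence(config.seed)
    cat_rng = np.random.default_rng(root.spawn(6)[0])
    catalog = make_catalog(config, cat_rng)
    admet = generate_admet_table(
        catalog,
        config.admet_shift_matrix,
        seed=config.seed + 1,
        noise_sd=config.admet_noise_sd,
        missing_frac=config.admet_missing_frac,
    )
    bounds, potency = generate_pk_tables(
        catalog, seed=config.seed + 2, n_pk_drugs=config.n_pk_drugs, stages=config.pk_stages
    )
    paths = {
        "cases": str(outdir / "cases.csv"),
        "catalog": str(outdir / "drug_catalog.csv"),
        "admet": str(outdir / "admet.csv"),
        "pk_bounds": str(outdir / "pk_bounds.csv"),
        "potency": str(outdir / "potency.csv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    write_cases_csv(cases, paths["cases"])
    catalog.to_csv(paths["catalog"], index=False)
    admet.to_csv(paths["admet"], index=False)
    bounds.to_csv(paths["pk_bounds"], index=False)
    potency.to_csv(paths["potency"], index=False)
    Path(paths["ground_truth"]).write_text(truth.to_json())
    return paths


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))
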