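"""Mechanistic vulnerability index (MVI) and regimen DDI prioritisation (DPS).

The MVI pipeline per drug: an empirical burden proxy (reporting volume x
phenotypic breadth), an upper-quartile high-burden label, a random-forest
out-of-bag probability of high burden from mechanistic/system features, a
weighted composite with standardised polypharmacy, network and severity
components (weights 0.60/0.15/0.15/0.10), and finally a 0-100 percentile
transform 100*(rank-1)/(n-1).  The DPS summarises a drug regimen as the mean
of mechanistic overlap (MOS), network amplification (NAS) and safety
vulnerability (SVS), stratified into priority tiers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .icsr import CaseReport
from .synthetic import CONTINUOUS_FEATURES, LIABILITY_FLAGS

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (0.60, 0.15, 0.15, 0.10)
DEFAULT_EXCLUDE = ("total_reports", "n_clusters")


def adr_composite(total_reports, n_clusters):
    """Empirical burden-breadth proxy: reporting volume x phenotypic breadth."""
    tr = np.asarray(total_reports)
    nc = np.asarray(n_clusters)
    if (tr < 0).any() or (nc < 0).any():
        raise ValueError("counts must be non-negative")
    return tr * nc


def label_high_burden(values) -> np.ndarray:
    """High-burden label: value >= upper quartile (linear-interpolation Q0.75)."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("high-burden labelling requires at least 4 drugs")
    q75 = np.quantile(v, 0.75)
    return v >= q75


@dataclass
class RfResult:
    rf_prob: pd.Series
    model: RandomForestClassifier
    X: pd.DataFrame
    features: list
    oob_fraction: float


def _impute_median(X: pd.DataFrame) -> pd.DataFrame:
    """Column-wise median imputation of missing predictor values."""
    X = X.copy()
    for col in X.columns:
        med = X[col].median()
        X[col] = X[col].fillna(0.0 if np.isnan(med) else med)
    return X


def fit_rf_high_burden(
    features: pd.DataFrame,
    labels,
    seed: int = 0,
    n_trees: int = 500,
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
) -> RfResult:
    """Random-forest probability of high empirical burden per drug.

    Out-of-bag class probabilities are used where available (in-bag refit
    probability for rows never out of bag); label-constituent features are
    excluded by default to avoid leakage, the inclusive variant being
    available via ``exclude=()``.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    cols = [c for c in features.columns if c not in set(exclude)]
    X = _impute_median(features[cols].astype(float))
    clf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    clf.fit(X.to_numpy(), y)
    oob = clf.oob_decision_function_
    pos = list(clf.classes_).index(1)
    probs = oob[:, pos].copy()
    missing = ~np.isfinite(probs)
    if missing.any():
        probs[missing] = clf.predict_proba(X.to_numpy()[missing])[:, pos]
    return RfResult(
        rf_prob=pd.Series(probs, index=features.index, name="rf_prob"),
        model=clf,
        X=X,
        features=cols,
        oob_fraction=float(1 - missing.mean()),
    )


def composite_raw(rf_prob, z_poly, z_net, z_sev, weights=DEFAULT_WEIGHTS):
    """Weighted composite vulnerability score.

    composite = w0*P(high burden) + w1*z(polypharmacy) + w2*z(network) +
    w3*z(severity); weights must be non-negative and sum to 1.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,):
        raise ValueError("exactly four weights required")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w.sum()}, not 1")
    return (
        w[0] * np.asarray(rf_prob)
        + w[1] * np.asarray(z_poly)
        + w[2] * np.asarray(z_net)
        + w[3] * np.asarray(z_sev)
    )


def mvi_percentile(scores) -> np.ndarray:
    """Percentile transform to 0-100: 100*(rank-1)/(n-1), average ranks on ties.

    The top score maps to 100.0 and the bottom to 0.0; a single drug is
    defined as 100.0 (flagged in the log).
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("no scores")
    if s.size == 1:
        logger.warning("mvi_percentile on a single drug; defined as 100.0")
        return np.array([100.0])
    ranks = stats.rankdata(s, method="average")
    return 100.0 * (ranks - 1) / (s.size - 1)


def _z(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return x * 0.0
    return (x - x.mean()) / sd


def build_drug_table(
    cases: Sequence[CaseReport],
    pmap,
    centrality: pd.DataFrame,
    admet: pd.DataFrame,
    drugs: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-drug aggregates feeding the MVI.

    total_reports counts deduplicated cases reporting the drug as suspect
    (expanded-row counts are also reported, as the two denominators differ);
    n_clusters is the number of distinct harmonised phenotypes among those
    cases; polypharmacy, seriousness and dominant phenotype are aggregated
    over the same cases; degree and betweenness come from the co-medication
    graph; ADMET features are joined per drug.
    """
    if drugs is None:
        drugs = sorted(set(admet["drug"]))
    rows = []
    for drug in drugs:
        sub = [c for c in cases if drug in c.suspect_actives]
        if not sub:
            continue
        phen = [pmap(c.raw_cluster) for c in sub]
        counts = pd.Series(phen).value_counts()
        rows.append(
            {
                "drug": drug,
                "total_reports": len(sub),
                "expanded_rows": int(sum(len(c.reactions) for c in sub)),
                "n_clusters": len(set(phen)),
                "mean_polypharmacy": float(np.mean([c.poly_actives_total for c in sub])),
                "serious_frac": float(np.mean([c.serious for c in sub])),
                "dominant_phenotype": counts.index[0],
            }
        )
    table = pd.DataFrame(rows)
    table = table.merge(
        centrality.rename(columns={"degree": "mean_degree", "betweenness": "mean_betweenness"}),
        on="drug",
        how="left",
    )
    admet_cols = [c for c in [*CONTINUOUS_FEATURES, *LIABILITY_FLAGS] if c in admet.columns]
    table = table.merge(admet[["drug", *admet_cols]], on="drug", how="left")
    return table.set_index("drug")


def mvi_table(
    drug_table: pd.DataFrame,
    seed: int = 0,
    weights=DEFAULT_WEIGHTS,
    n_trees: int = 500,
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
) -> tuple[pd.DataFrame, RfResult]:
    """Full MVI computation on a per-drug aggregate table.

    Returns the per-drug MVI records and the fitted random-forest result.
    z-components: z_poly standardises the mean per-report active count, z_net
    averages z(degree) and z(betweenness), z_sev standardises the drug-level
    serious-report fraction (all sample-sd standardisation across drugs).
    """
    t = drug_table.copy()
    t["adr_composite"] = adr_composite(t["total_reports"], t["n_clusters"])
    t["high_burden"] = label_high_burden(t["adr_composite"].to_numpy())
    feature_cols = [
        c
        for c in ["total_reports", "n_clusters", "mean_polypharmacy", "mean_degree",
                  "mean_betweenness", "serious_frac", *CONTINUOUS_FEATURES, *LIABILITY_FLAGS]
        if c in t.columns
    ]
    rf = fit_rf_high_burden(t[feature_cols], t["high_burden"], seed=seed,
                            n_trees=n_trees, exclude=exclude)
    t["rf_prob"] = rf.rf_prob
    t["z_poly"] = _z(t["mean_polypharmacy"])
    t["z_net"] = (_z(t["mean_degree"]) + _z(t["mean_betweenness"])) / 2.0
    t["z_sev"] = _z(t["serious_frac"])
    t["composite_raw"] = composite_raw(
        t["rf_prob"], t["z_poly"], t["z_net"], t["z_sev"], weights
    )
    t["mvi_pct"] = mvi_percentile(t["composite_raw"].to_numpy())
    cols = [
        "total_reports", "n_clusters", "adr_composite", "high_burden", "rf_prob",
        "z_poly", "z_net", "z_sev", "composite_raw", "mvi_pct", "serious_frac",
        "mean_degree", "mean_polypharmacy", "dominant_phenotype",
    ]
    out = t[[c for c in cols if c in t.columns]].sort_values("mvi_pct", ascending=False)
    return out, rf


def mvi_diagnostics(
    features: pd.DataFrame,
    labels,
    drug_table: pd.DataFrame,
    seed: int = 0,
    n_trees: int = 500,
    B: int = 500,
    alt_weights=(0.40, 0.20, 0.20, 0.20),
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
) -> dict:
    """Robustness diagnostics for the MVI machine-learning component.

    Reports hold-out (70/30) AUC, leave-one-drug-out AUC, out-of-bag error,
    bootstrap (B resamples) 95% intervals on the predicted probabilities,
    coefficient of variation of variable importances across resamples, rank
    stability of the percentile MVI under an alternative weight set (Spearman
    and Kendall correlations), and variance inflation factors across the four
    composite components.  Each diagnostic uses its own fixed sub-seed.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    y = np.asarray(labels).astype(int)
    n = len(y)
    if n < 10:
        raise ValueError("70/30 hold-out split requires at least 10 drugs")
    cols = [c for c in features.columns if c not in set(exclude)]
    X = _impute_median(features[cols].astype(float)).to_numpy()
    sub = np.random.SeedSequence(seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub]

    # 70/30 stratified hold-out
    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=0.3, random_state=seeds[0], stratify=y
    )
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seeds[0], n_jobs=1)
    clf.fit(Xtr, ytr)
    holdout_auc = float(roc_auc_score(yte, clf.predict_proba(Xte)[:, 1]))

    # leave-one-drug-out
    lodo_probs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        clf_i = RandomForestClassifier(n_estimators=n_trees, random_state=seeds[1], n_jobs=1)
        clf_i.fit(X[mask], y[mask])
        lodo_probs[i] = float(
            clf_i.predict_proba(X[i : i + 1])[0, list(clf_i.classes_).index(1)]
        )
    lodo_auc = float(roc_auc_score(y, lodo_probs))

    # OOB error
    oob_clf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seeds[2], n_jobs=1
    )
    oob_clf.fit(X, y)
    oob_error = float(1.0 - oob_clf.oob_score_)

    # bootstrap CIs + importance stability
    rng = np.random.default_rng(seeds[3])
    boot_probs = np.empty((B, n))
    boot_imp = np.empty((B, X.shape[1]))
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        clf_b = RandomForestClassifier(n_estimators=n_trees, random_state=seeds[3], n_jobs=1)
        clf_b.fit(X[idx], y[idx])
        boot_probs[b] = clf_b.predict_proba(X)[:, list(clf_b.classes_).index(1)]
        boot_imp[b] = clf_b.feature_importances_
    ci_lo = np.percentile(boot_probs, 2.5, axis=0)
    ci_hi = np.percentile(boot_probs, 97.5, axis=0)
    imp_mean = boot_imp.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        imp_cv = np.where(imp_mean > 0, boot_imp.std(axis=0) / imp_mean, np.nan)

    # weight-rank stability
    mvi_default, _ = mvi_table(drug_table, seed=seed, n_trees=n_trees, exclude=exclude)
    mvi_alt, _ = mvi_table(
        drug_table, seed=seed, weights=alt_weights, n_trees=n_trees, exclude=exclude
    )
    joined = mvi_default["mvi_pct"].align(mvi_alt["mvi_pct"], join="inner")
    rho = float(stats.spearmanr(joined[0], joined[1]).statistic)
    tau = float(stats.kendalltau(joined[0], joined[1]).statistic)

    # VIF across composite components
    comp = mvi_default[["rf_prob", "z_poly", "z_net", "z_sev"]].to_numpy()
    comp = np.column_stack([np.ones(len(comp)), comp])
    vif = {
        name: float(variance_inflation_factor(comp, i + 1))
        for i, name in enumerate(["rf_prob", "z_poly", "z_net", "z_sev"])
    }
    return {
        "holdout_auc": holdout_auc,
        "lodo_auc": lodo_auc,
        "oob_error": oob_error,
        "bootstrap_ci": {
            "B": B,
            "lo95": ci_lo.tolist(),
            "hi95": ci_hi.tolist(),
            "median_width": float(np.median(ci_hi - ci_lo)),
        },
        "importance_cv": dict(zip(cols, imp_cv.tolist())),
        "weight_rank_stability": {"spearman": rho, "kendall": tau,
                                  "alt_weights": list(alt_weights)},
        "vif": vif,
    }


@dataclass(frozen=True)
class DpsRecord:
    regimen: frozenset
    mos: float
    nas: float
    svs: float
    dps: float
    tier: str


def dps(
    regimen: Iterable[str],
    flags: pd.DataFrame,
    degree: Mapping[str, float],
    mvi_pct: Mapping[str, float],
    universe_degree_sums: Sequence[float],
    thresholds: tuple[float, float] = (0.75, 0.50),
    tier_mode: str = "absolute",
) -> DpsRecord:
    """DDI prioritisation score for one regimen (>= 2 drugs).

    MOS = fraction of liability axes flagged in at least two regimen members;
    NAS = percentile, within the evaluated regimen universe, of the summed
    member degree; SVS = mean member MVI percentile / 100; DPS = mean of the
    three.  Tiers: absolute thresholds by default (DPS >= 0.75 high, >= 0.50
    moderate, else low); ``tier_mode="percentile"`` applies the thresholds to
    the NAS-style percent rank of the DPS within the universe instead.
    """
    regimen = frozenset(regimen)
    if len(regimen) < 2:
        raise ValueError("a regimen requires at least 2 drugs")
    missing = sorted(d for d in regimen if d not in flags.index)
    if missing:
        raise KeyError(f"regimen drugs without profiles: {missing}")
    axes = list(flags.columns)
    member_flags = flags.loc[sorted(regimen), axes].astype(bool)
    mos = float((member_flags.sum(axis=0) >= 2).sum() / len(axes)) if axes else 0.0
    deg_sum = float(sum(degree.get(d, 0.0) for d in regimen))
    nas = _percent_rank(deg_sum, universe_degree_sums)
    svs = float(np.mean([mvi_pct.get(d, 0.0) for d in regimen]) / 100.0)
    score = (mos + nas + svs) / 3.0
    basis = score
    hi, mid = thresholds
    if tier_mode not in {"absolute", "percentile"}:
        raise ValueError(f"unknown tier_mode {tier_mode!r}")
    tier = "1-high" if basis >= hi else ("2-moderate" if basis >= mid else "3-low")
    return DpsRecord(regimen=regimen, mos=mos, nas=nas, svs=svs, dps=score, tier=tier)


def _percent_rank(value: float, universe: Sequence[float]) -> float:
    u = np.asarray(list(universe), dtype=float)
    if u.size <= 1:
        return 1.0
    rank = np.sum(u < value) + 0.5 * max(np.sum(u == value) - 1, 0) + 1
    return float((rank - 1) / (u.size - 1))


def regimens_from_cases(
    cases: Sequence[CaseReport], restrict_to: Iterable[str] | None = None
) -> list[frozenset]:
    """Distinct observed suspect-drug regimens with at least two members."""
    keep = set(restrict_to) if restrict_to is not None else None
    seen = set()
    for c in cases:
        drugs = c.suspect_actives if keep is None else c.suspect_actives & keep
        if len(drugs) >= 2:
            seen.add(frozenset(drugs))
    return sorted(seen, key=lambda r: tuple(sorted(r)))


def dps_table(
    regimens: Sequence[Iterable[str]],
    flags: pd.DataFrame,
    degree: Mapping[str, float],
    mvi_pct: Mapping[str, float],
    thresholds: tuple[float, float] = (0.75, 0.50),
    tier_mode: str = "absolute",
) -> pd.DataFrame:
    """Score every regimen; NAS percentiles are taken within this universe.

    In percentile tier mode the tier thresholds apply to the percent rank of
    the DPS within the same universe.
    """
    regimens = [frozenset(r) for r in regimens]
    sums = [float(sum(degree.get(d, 0.0) for d in r)) for r in regimens]
    records = [
        dps(r, flags, degree, mvi_pct, sums, thresholds, "absolute") for r in regimens
    ]
    out = pd.DataFrame(
        {
            "regimen": [";".join(sorted(r.regimen)) for r in records],
            "n_drugs": [len(r.regimen) for r in records],
            "mos": [r.mos for r in records],
            "nas": [r.nas for r in records],
            "svs": [r.svs for r in records],
            "dps": [r.dps for r in records],
        }
    )
    if tier_mode == "percentile":
        pr = stats.rankdata(out["dps"], method="average")
        pr = (pr - 1) / max(len(out) - 1, 1)
        basis = pr
    elif tier_mode == "absolute":
        basis = out["dps"].to_numpy()
    else:
        raise ValueError(f"unknown tier_mode {tier_mode!r}")
    hi, mid = thresholds
    out["tier"] = np.select(
        [basis >= hi, basis >= mid], ["1-high", "2-moderate"], default="3-low"
    )
    return out.sort_values("dps", ascending=False, ignore_index=True)
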