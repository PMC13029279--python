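"""Linear embedding of standardised drug-level features.

PCA on z-scored features with a deterministic sign convention (the
largest-magnitude loading of each component is positive), variance
decomposition, and leave-one-drug-out loading-stability diagnostics.  Two
feature sets are supported: the mixed system+mechanistic set and a
continuous-ADMET-only set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CONTINUOUS_FEATURES

logger = logging.getLogger(__name__)

#: Mixed system-level + mechanistic feature set.
FEATURES_MIXED = [
    "mean_polypharmacy",
    "mean_degree",
    "mean_betweenness",
    "total_reports",
    "n_clusters",
    "ADMET_Risk",
    "BSEP_IC50",
    "hERG_pIC50",
    "CYP_HLM_CLint",
]

#: Continuous ADMET predictors only.
FEATURES_ADMET_ONLY = list(CONTINUOUS_FEATURES)


def select_features(drug_table: pd.DataFrame, mode: str = "mixed") -> pd.DataFrame:
    """Feature matrix for embedding; missing values median-imputed."""
    cols = {"mixed": FEATURES_MIXED, "admet_only": FEATURES_ADMET_ONLY}.get(mode)
    if cols is None:
        raise ValueError(f"unknown feature mode {mode!r}")
    present = [c for c in cols if c in drug_table.columns]
    X = drug_table[present].astype(float)
    return X.fillna(X.median())


def zscore_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-feature standardisation: mean 0, sample (n-1) sd 1.

    Constant features are dropped with a log entry; an all-constant matrix is
    an error.
    """
    X = matrix.astype(float)
    sd = X.std(ddof=1)
    constant = list(sd.index[(sd == 0) | ~np.isfinite(sd)])
    if constant:
        logger.warning("dropping constant feature(s): %s", constant)
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise ValueError("all features constant; nothing to embed")
    return (X - X.mean()) / X.std(ddof=1)


@dataclass
class EmbeddingResult:
    loadings: pd.DataFrame  # feature x component
    variance_frac: np.ndarray  # per retained component
    scores: pd.DataFrame  # drug x component
    feature_list: list
    rank_truncated: bool = False


def pca_embed(standardized: pd.DataFrame, k: int = 2) -> EmbeddingResult:
    """PCA via singular value decomposition of the standardised matrix.

    Components are ordered by explained variance; the sign of each component
    is fixed so its largest-magnitude loading is positive, making repeated
    runs bit-comparable.  Rank-deficient input is truncated and flagged.
    """
    X = standardized.to_numpy(float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(n, p) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    truncated = rank < min(k, s.size)
    k_eff = min(k, rank) if rank else min(k, s.size)
    if truncated:
        logger.warning("rank-deficient input: retaining %d component(s)", k_eff)
    total_var = float(np.sum(s**2))
    var_frac = (s[:k_eff] ** 2) / total_var if total_var else np.zeros(k_eff)
    load = vt[:k_eff].T.copy()
    scores = u[:, :k_eff] * s[:k_eff]
    for j in range(k_eff):
        i_max = int(np.argmax(np.abs(load[:, j])))
        if load[i_max, j] < 0:
            load[:, j] *= -1
            scores[:, j] *= -1
    comp_names = [f"PC{j + 1}" for j in range(k_eff)]
    return EmbeddingResult(
        loadings=pd.DataFrame(load, index=standardized.columns, columns=comp_names),
        variance_frac=var_frac,
        scores=pd.DataFrame(scores, index=standardized.index, columns=comp_names),
        feature_list=list(standardized.columns),
        rank_truncated=truncated,
    )


def lodo_loading_stability(matrix: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Leave-one-drug-out loading stability.

    For each left-out drug the embedding is refit on the remaining drugs, its
    loadings sign-aligned to the full fit, and a Pearson correlation per
    component reported.  Refits whose rank collapses below k are flagged and
    excluded from correlations.
    """
    if len(matrix) < 4:
        raise ValueError("leave-one-out stability requires at least 4 drugs")
    full = pca_embed(zscore_features(matrix), k=k)
    rows = []
    for drug in matrix.index:
        sub = matrix.drop(index=drug)
        try:
            fit = pca_embed(zscore_features(sub), k=k)
        except ValueError:
            rows.append({"left_out": drug, "ok": False})
            continue
        common = [f for f in full.loadings.index if f in fit.loadings.index]
        rec = {"left_out": drug, "ok": fit.loadings.shape[1] >= full.loadings.shape[1]}
        for comp in full.loadings.columns:
            if comp not in fit.loadings.columns:
                rec[f"r_{comp}"] = np.nan
                rec["ok"] = False
                continue
            a = full.loadings.loc[common, comp].to_numpy()
            b = fit.loadings.loc[common, comp].to_numpy()
            if np.dot(a, b) < 0:  # sign-align to the full fit
                b = -b
            denom = np.linalg.norm(a - a.mean()) * np.linalg.norm(b - b.mean())
            rec[f"r_{comp}"] = (
                float(np.dot(a - a.mean(), b - b.mean()) / denom) if denom else np.nan
            )
        rows.append(rec)
    return pd.DataFrame(rows)
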