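"""ADR phenotype harmonisation and phenotype-level mechanistic summaries.

Raw reaction co-occurrence cluster labels arrive with the cases (they are not
re-estimated here).  Low-frequency clusters are collapsed into an "Other"
phenotype; the harmonised phenotypes are then profiled for seriousness, ADMET
signatures (z-scored medians), Kruskal-Wallis significance panels, one-way
intraclass correlation, and reaction-class concordance odds ratios.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr
from .icsr import CaseReport
from .synthetic import CONTINUOUS_FEATURES

logger = logging.getLogger(__name__)

OTHER_LABEL = "Other"


@dataclass(frozen=True)
class PhenotypeMap:
    """Raw cluster label -> harmonised phenotype label."""

    mapping: dict
    threshold_frac: float = 0.02

    def __call__(self, raw: str) -> str:
        return self.mapping[raw]

    @property
    def phenotypes(self) -> list[str]:
        return sorted(set(self.mapping.values()))


def harmonise_phenotypes(
    cases: Sequence[CaseReport], threshold_frac: float = 0.02
) -> PhenotypeMap:
    """Collapse raw cluster labels below a case-frequency threshold to Other.

    The default 2% threshold reproduces the harmonisation rule used for
    pregnancy ADR phenotypes; labels at or above the threshold map to
    themselves.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must lie in (0, 1)")
    counts = Counter(c.raw_cluster for c in cases)
    total = sum(counts.values())
    mapping = {
        raw: raw if n / total >= threshold_frac else OTHER_LABEL
        for raw, n in counts.items()
    }
    return PhenotypeMap(mapping=mapping, threshold_frac=threshold_frac)


def apply_map(cases: Sequence[CaseReport], pmap: PhenotypeMap) -> pd.Series:
    """Harmonised phenotype per case, indexed by case id."""
    return pd.Series(
        {c.case_id: pmap(c.raw_cluster) for c in cases}, name="phenotype"
    )


def seriousness_by_phenotype(
    cases: Sequence[CaseReport], pmap: PhenotypeMap, min_cases: int = 5
) -> pd.DataFrame:
    """Serious-outcome fraction per harmonised phenotype.

    Phenotypes with fewer than ``min_cases`` cases are flagged unstable (their
    fraction is still reported).
    """
    df = pd.DataFrame(
        {
            "phenotype": [pmap(c.raw_cluster) for c in cases],
            "serious": [c.serious for c in cases],
        }
    )
    out = (
        df.groupby("phenotype")["serious"]
        .agg(n_cases="size", serious_frac="mean")
        .reset_index()
    )
    out["stability_flag"] = out["n_cases"] >= min_cases
    return out


@dataclass
class SignatureMatrix:
    """Phenotype x feature matrix of z-scored medians.

    z-scores standardise the (at most five) phenotype medians within each
    feature with the sample (n-1) standard deviation; features whose medians
    are constant across phenotypes get z = 0 and are listed in
    ``constant_features``.
    """

    z: pd.DataFrame
    medians: pd.DataFrame
    constant_features: list = field(default_factory=list)


def admet_signature(
    expanded: pd.DataFrame,
    admet: pd.DataFrame,
    pmap: PhenotypeMap,
    features: Sequence[str] = tuple(CONTINUOUS_FEATURES),
) -> SignatureMatrix:
    """Phenotype-level ADMET signature: per-feature medians, z-scored.

    Expanded records are joined to their drug's ADMET values; for each
    phenotype x feature the median over records is taken, then standardised
    across phenotypes within the feature.
    """
    usable = [f for f in features if f in admet.columns and admet[f].notna().any()]
    dropped = sorted(set(features) - set(usable))
    if dropped:
        logger.warning("features with no ADMET values excluded from signature: %s", dropped)
    df = expanded.merge(admet[["drug", *usable]], on="drug", how="left")
    df["phenotype"] = df["cluster"].map(pmap.mapping)
    medians = df.groupby("phenotype")[usable].median()
    z = medians.copy()
    constant = []
    for f in usable:
        col = medians[f]
        sd = col.std(ddof=1) if len(col) > 1 else 0.0
        if not np.isfinite(sd) or sd == 0 or col.nunique() < 2:
            z[f] = 0.0
            constant.append(f)
        else:
            z[f] = (col - col.mean()) / sd
    return SignatureMatrix(z=z, medians=medians, constant_features=constant)


def signature_long(sig: SignatureMatrix) -> pd.DataFrame:
    """Tidy long-format view of a signature matrix, for plotting."""
    return (
        sig.z.reset_index()
        .melt(id_vars="phenotype", var_name="feature", value_name="z")
        .sort_values(["feature", "phenotype"], ignore_index=True)
    )


def kw_panel(
    expanded: pd.DataFrame,
    admet: pd.DataFrame,
    pmap: PhenotypeMap,
    features: Sequence[str] = tuple(CONTINUOUS_FEATURES),
) -> pd.DataFrame:
    """Kruskal-Wallis panel across phenotypes with BH-FDR correction.

    One tie-corrected H test per feature at the expanded-record level; q-values
    are Benjamini-Hochberg across the feature panel.  Features represented in
    fewer than two phenotypes are skipped with a log entry.
    """
    df = expanded.merge(admet[["drug", *[f for f in features if f in admet.columns]]], on="drug", how="left")
    df["phenotype"] = df["cluster"].map(pmap.mapping)
    rows = []
    for f in features:
        if f not in df.columns:
            logger.warning("feature %s absent from ADMET table; skipped", f)
            continue
        groups = [
            g.dropna().to_numpy()
            for _, g in df.groupby("phenotype")[f]
            if g.notna().any()
        ]
        if len(groups) < 2:
            logger.warning("feature %s represented in <2 phenotypes; skipped", f)
            continue
        try:
            h, p = stats.kruskal(*groups)
        except ValueError:  # all values identical
            h, p = 0.0, 1.0
        rows.append({"feature": f, "H": h, "p": p})
    panel = pd.DataFrame(rows)
    if not panel.empty:
        panel["q"] = bh_fdr(panel["p"].to_numpy())
    return panel


@dataclass(frozen=True)
class ICCResult:
    icc: float
    msb: float
    msw: float
    k0: float
    n_groups: int
    n_obs: int
    degenerate: bool = False


def icc_one_way(values: Iterable[float], groups: Iterable) -> ICCResult:
    """One-way random-effects intraclass correlation, ICC(1).

    ICC(1) = (MSB - MSW) / (MSB + (k0 - 1) MSW) with the unbalanced-design
    group-size constant k0 = (N - sum(n_i^2)/N) / (k - 1); truncated at 0 from
    below.  If every observation is identical the ICC is defined as 0 and
    flagged degenerate.
    """
    df = pd.DataFrame({"y": list(values), "g": list(groups)}).dropna()
    sizes = df.groupby("g")["y"].size()
    k = len(sizes)
    n_tot = int(sizes.sum())
    if k < 2:
        raise ValueError("ICC requires at least 2 groups")
    if n_tot - k < 1:
        raise ValueError("ICC requires more observations than groups")
    y = df["y"].to_numpy(float)
    if np.ptp(y) == 0:
        return ICCResult(0.0, 0.0, 0.0, float(n_tot) / k, k, n_tot, degenerate=True)
    grand = y.mean()
    means = df.groupby("g")["y"].mean()
    ssb = float((sizes * (means - grand) ** 2).sum())
    ssw = float(((df["y"] - df["g"].map(means)) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n_tot - k)
    k0 = (n_tot - float((sizes**2).sum()) / n_tot) / (k - 1)
    if msw == 0:
        return ICCResult(1.0, msb, msw, k0, k, n_tot)
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    return ICCResult(max(icc, 0.0), msb, msw, k0, k, n_tot)


def reaction_class_or(
    cases: Sequence[CaseReport],
    term_set: Iterable[str],
    phenotype: str,
    pmap: PhenotypeMap,
) -> dict:
    """Case-level odds ratio of a reaction-term class in one phenotype.

    2x2 of term-set membership (any reaction in ``term_set``) in ``phenotype``
    versus all other phenotypes, with Haldane-Anscombe 0.5 correction on zero
    cells and a Woolf log-normal 95% CI.
    """
    term_set = set(term_set)
    if not term_set:
        raise ValueError("term_set must be nonempty")
    labels = [pmap(c.raw_cluster) for c in cases]
    if phenotype not in labels:
        raise ValueError(f"phenotype {phenotype!r} has no cases")
    in_ph = np.array([lab == phenotype for lab in labels])
    has_term = np.array([bool(set(c.reactions) & term_set) for c in cases])
    a = int(np.sum(in_ph & has_term))
    b = int(np.sum(in_ph & ~has_term))
    c = int(np.sum(~in_ph & has_term))
    d = int(np.sum(~in_ph & ~has_term))
    corrected = 0 in (a, b, c, d)
    aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d)) if corrected else (a, b, c, d)
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return {
        "OR": or_,
        "ci_lo": or_ * np.exp(-1.959963984540054 * se),
        "ci_hi": or_ * np.exp(1.959963984540054 * se),
        "table": (a, b, c, d),
        "corrected": corrected,
    }
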