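"""Drug-phenotype contextual disproportionality.

Reporting odds ratios (ROR) with Fisher exact tests and Benjamini-Hochberg
FDR control over the drug x phenotype panel, observed/expected enrichment
ratios, and the all-suspect attribution sensitivity analysis.  Counting is at
the deduplicated case level throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .icsr import CaseReport, DrugProfile, assign_primary_active

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054


@dataclass(frozen=True)
class Contingency2x2:
    """Case counts: a = drug & phenotype, b = drug & other phenotype,
    c = other drug & phenotype, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def drug_phenotype_tables(
    cases: Sequence[CaseReport],
    pmap,
    attribution: str = "primary",
    catalog: Mapping[str, DrugProfile] | None = None,
) -> dict[tuple[str, str], Contingency2x2]:
    """2x2 tables for every drug x harmonised phenotype pair.

    attribution="primary" credits each case to its single primary active drug
    (class-hierarchy assignment; requires a catalog); "all_suspect" credits a
    case to every suspect drug it reports.
    """
    if attribution not in {"primary", "all_suspect"}:
        raise ValueError(f"unknown attribution mode {attribution!r}")
    n = len(cases)
    phen = [pmap(c.raw_cluster) for c in cases]
    if attribution == "primary":
        if catalog is None:
            raise ValueError("primary attribution requires a drug catalog")
        case_drugs = [{assign_primary_active(c, catalog)} for c in cases]
    else:
        case_drugs = [set(c.suspect_actives) for c in cases]
    drugs = sorted(set().union(*case_drugs)) if case_drugs else []
    phenotypes = sorted(set(phen))
    tables: dict[tuple[str, str], Contingency2x2] = {}
    for drug in drugs:
        has_drug = np.array([drug in ds for ds in case_drugs])
        for ph in phenotypes:
            in_ph = np.array([p == ph for p in phen])
            a = int(np.sum(has_drug & in_ph))
            b = int(np.sum(has_drug & ~in_ph))
            c = int(np.sum(~has_drug & in_ph))
            tables[(drug, ph)] = Contingency2x2(a, b, c, n - a - b - c)
    return tables


def ror_fisher(t: Contingency2x2) -> dict:
    """Reporting odds ratio with Woolf 95% CI and two-sided Fisher exact p.

    If any cell is zero, the Haldane-Anscombe continuity correction adds 0.5
    to all four cells for the ROR and CI (the Fisher p uses the raw counts).
    """
    if t.total == 0:
        raise ValueError("all-zero contingency table")
    corrected = 0 in (t.a, t.b, t.c, t.d)
    a, b, c, d = (
        (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5) if corrected else (t.a, t.b, t.c, t.d)
    )
    ror = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return {
        "ror": ror,
        "ci_lo": ror * np.exp(-Z975 * se),
        "ci_hi": ror * np.exp(Z975 * se),
        "p": float(p),
        "corrected": corrected,
    }


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p elementwise).

    NaN p-values are excluded from the correction (logged) and returned as
    NaN.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if (~ok).any():
        logger.warning("bh_fdr: %d NaN p-value(s) excluded", int((~ok).sum()))
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        _, qv, _, _ = multipletests(p[ok], method="fdr_bh")
        q[ok] = qv
    return q


def oe_enrichment(t: Contingency2x2) -> float:
    """Observed/expected ratio: a over (a+b)(a+c)/N under independence.

    Returns NaN (with a log entry) when a margin is zero.
    """
    n = t.total
    expected = (t.a + t.b) * (t.a + t.c) / n if n else 0.0
    if expected == 0:
        logger.warning("oe_enrichment undefined for zero margin: %s", t)
        return float("nan")
    return t.a / expected


def enrich(
    cases: Sequence[CaseReport],
    pmap,
    attribution: str = "primary",
    catalog: Mapping[str, DrugProfile] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Long-format enrichment panel over all drug x phenotype pairs.

    ``enriched`` is true iff q < alpha and ROR > 1, the rule used to call a
    drug-phenotype association enriched for mechanistic interpretation.
    """
    tables = drug_phenotype_tables(cases, pmap, attribution, catalog)
    rows = []
    for (drug, ph), t in tables.items():
        r = ror_fisher(t)
        rows.append(
            {
                "drug": drug,
                "phenotype": ph,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "ror": r["ror"],
                "ci_lo": r["ci_lo"],
                "ci_hi": r["ci_hi"],
                "p": r["p"],
                "oe_ratio": oe_enrichment(t),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["enriched"] = (out["q"] < alpha) & (out["ror"] > 1)
    return out.sort_values(["phenotype", "drug"], ignore_index=True)


def top_k(results: pd.DataFrame, phenotype: str, k: int = 10) -> list[str]:
    """Top-k drugs in one phenotype ranked by O/E ratio (ties: q, then name)."""
    sub = results[results["phenotype"] == phenotype]
    if len(sub) < k:
        logger.warning(
            "phenotype %s has %d drugs (< k=%d); using all", phenotype, len(sub), k
        )
    ranked = sub.sort_values(
        ["oe_ratio", "q", "drug"], ascending=[False, True, True]
    )
    return list(ranked["drug"].head(k))


def attribution_sensitivity(
    results_primary: pd.DataFrame,
    results_all_suspect: pd.DataFrame,
    k: int = 10,
) -> pd.DataFrame:
    """Per-phenotype Jaccard overlap of top-k drugs under the two attribution
    modes (primary-active vs all-suspect)."""
    phenotypes = sorted(
        set(results_primary["phenotype"]) & set(results_all_suspect["phenotype"])
    )
    rows = []
    for ph in phenotypes:
        top_p = set(top_k(results_primary, ph, k))
        top_a = set(top_k(results_all_suspect, ph, k))
        union = top_p | top_a
        rows.append(
            {
                "phenotype": ph,
                "jaccard": len(top_p & top_a) / len(union) if union else float("nan"),
                "n_shared": len(top_p & top_a),
                "n_union": len(union),
            }
        )
    return pd.DataFrame(rows)
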