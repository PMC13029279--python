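"""Case-level logistic regression of seriousness on polypharmacy burden.

One row per deduplicated ICSR; the primary predictor is the total number of
unique co-reported actives.  The per-active odds ratio, exp(slope), is the
headline effect; compounding it over k additional drugs gives the cumulative
odds multiplier (e.g. an OR of 1.03 per drug compounds to ~1.16 over five
drugs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .icsr import CaseReport


class SeparationError(ValueError):
    """Raised when the logistic fit is degenerate (e.g. one outcome class)."""


@dataclass(frozen=True)
class LogisticFit:
    or_per_active: float
    ci_lo: float
    ci_hi: float
    p: float
    n: int
    intercept: float
    robust: bool
    specification: str = "seriousness ~ poly_actives_total"

    def __post_init__(self) -> None:
        if not self.ci_lo <= self.or_per_active <= self.ci_hi:
            raise ValueError("confidence interval must bracket the point estimate")

    def to_dict(self) -> dict:
        return {
            "or_per_active": self.or_per_active,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "p": self.p,
            "n": self.n,
            "intercept": self.intercept,
            "robust": self.robust,
            "specification": self.specification,
        }


def model_matrix(cases: Sequence[CaseReport]) -> pd.DataFrame:
    """Case-level model matrix (exportable for audit)."""
    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "serious": [int(c.serious) for c in cases],
            "poly_actives_total": [c.poly_actives_total for c in cases],
        }
    )


def fit_seriousness(
    cases: Sequence[CaseReport],
    robust_se: bool = False,
    covariates: pd.DataFrame | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of seriousness on polypharmacy burden.

    Wald 95% CI on the per-active odds ratio; ``robust_se`` switches to an
    HC1 heteroskedasticity-robust covariance (point estimates unchanged).
    Optional extra ``covariates`` (indexed like the cases) give the adjusted
    specification; the reported OR is always the polypharmacy slope.
    """
    df = model_matrix(cases)
    y = df["serious"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome has a single class; logistic fit is degenerate")
    X = df[["poly_actives_total"]].copy()
    spec = "seriousness ~ poly_actives_total"
    if covariates is not None:
        X = pd.concat([X.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1)
        spec += " + " + " + ".join(covariates.columns)
    X = sm.add_constant(X.astype(float))
    try:
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(cov_type="HC1" if robust_se else "nonrobust")
    except Exception as exc:  # statsmodels raises PerfectSeparation* variously
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.bse)):
        raise SeparationError("non-finite standard errors: perfect separation suspected")
    slope = res.params["poly_actives_total"]
    lo, hi = res.conf_int().loc["poly_actives_total"]
    return LogisticFit(
        or_per_active=float(np.exp(slope)),
        ci_lo=float(np.exp(lo)),
        ci_hi=float(np.exp(hi)),
        p=float(res.pvalues["poly_actives_total"]),
        n=len(df),
        intercept=float(res.params["const"]),
        robust=robust_se,
        specification=spec,
    )


@dataclass(frozen=True)
class CompoundedOr:
    """Odds multiplier for k additional actives, with its 2-dp report form."""

    value: float
    rounded: float
    or_per_unit: float
    k: int


def compound_or(or_per_unit: float, k: int) -> CompoundedOr:
    """Compound a per-unit odds ratio over k units: or_per_unit ** k."""
    if or_per_unit <= 0:
        raise ValueError("or_per_unit must be positive")
    if k < 0:
        raise ValueError("k must be >= 0")
    value = float(or_per_unit**k)
    return CompoundedOr(value=value, rounded=round(value, 2), or_per_unit=or_per_unit, k=k)


def sensitivity_restrict(
    cases: Sequence[CaseReport], robust_se: bool = False
) -> tuple[list[CaseReport], LogisticFit, float]:
    """Refit on female, non-follow-up, non-literature reports.

    Returns the retained subset, the refit, and the retained fraction.
    """
    subset = [
        c for c in cases if c.sex == "female" and not c.follow_up and not c.literature
    ]
    if not subset:
        raise ValueError("sensitivity restriction retained no cases")
    fit = fit_seriousness(subset, robust_se=robust_se)
    return subset, fit, len(subset) / len(cases)
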