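"""Range-based Monte Carlo exposure-potency ratio engine.

Pregnancy exposure bounds (Cmax in ug/mL, AUC0-24 in ug*h/mL) are sampled
uniformly within literature-reported minimum-maximum bounds (degenerate at
the central estimate when bounds are absent), converted to uM via molecular
weight, and divided by a potency threshold (IC50 or Ki, uM).  Summaries give
the empirical median, 95% interval and the exceedance probabilities
P(ratio > 1) and P(ratio > 10); stages are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PKBound:
    """Exposure bound for one drug x pregnancy stage x metric."""

    drug: str
    stage: str
    metric: str  # "Cmax" or "AUC0-24"
    min: float | None = None
    max: float | None = None
    central: float | None = None
    mw: float = 0.0

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError(f"{self.drug}: molecular weight must be positive")
        if self.min is not None and self.max is not None and self.min > self.max:
            raise ValueError(f"{self.drug}/{self.stage}/{self.metric}: min > max")
        if self.min is None and self.central is None:
            raise ValueError(f"{self.drug}/{self.stage}/{self.metric}: no exposure information")


@dataclass(frozen=True)
class RatioSummary:
    drug: str
    stage: str
    ratio_name: str
    median: float
    lo95: float
    hi95: float
    p_gt_1: float
    p_gt_10: float
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if not self.lo95 <= self.median <= self.hi95:
            raise ValueError("interval must bracket the median")
        if self.p_gt_10 > self.p_gt_1:
            raise ValueError("P(>10) cannot exceed P(>1)")


def to_micromolar(c: float | np.ndarray, mw: float):
    """ug/mL -> uM conversion: c * 1000 / mw (mw in g/mol)."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return np.asarray(c, dtype=float) * 1000.0 / mw


def cavg24(auc: float | np.ndarray):
    """24-hour average concentration from AUC0-24: auc / 24."""
    return np.asarray(auc, dtype=float) / 24.0


def analytic_exceedance(a: float, b: float, threshold: float) -> float:
    """P(U(a,b) > threshold), the closed-form oracle for the uniform sampler."""
    if a > b:
        raise ValueError("a must be <= b")
    if a == b:
        return float(a > threshold)
    return float(np.clip((b - threshold) / (b - a), 0.0, 1.0))


def simulate_ratios(
    bound: PKBound,
    potency: float,
    n: int = 10_000,
    seed: int = 0,
    mechanism: str | None = None,
) -> RatioSummary:
    """Monte Carlo exposure/potency ratio summary for one drug x stage.

    Exposure is drawn uniformly in [min, max] (or fixed at the central value
    when bounds are absent); AUC0-24 bounds are first reduced to Cavg24.  The
    exceedance probabilities use a strict '>' comparison.
    """
    if potency <= 0:
        raise ValueError("potency must be positive")
    rng = np.random.default_rng(seed)
    if bound.min is not None and bound.max is not None and bound.min != bound.max:
        exposure = rng.uniform(bound.min, bound.max, size=n)
    else:
        value = bound.central if bound.central is not None else bound.min
        exposure = np.full(n, float(value))
    if bound.metric == "AUC0-24":
        exposure = cavg24(exposure)
        exposure_label = "Cavg24"
    elif bound.metric == "Cmax":
        exposure_label = "Cmax"
    else:
        raise ValueError(f"unknown exposure metric {bound.metric!r}")
    ratios = to_micromolar(exposure, bound.mw) / potency
    name = f"{exposure_label}/{mechanism}" if mechanism else exposure_label
    return RatioSummary(
        drug=bound.drug,
        stage=bound.stage,
        ratio_name=name,
        median=float(np.median(ratios)),
        lo95=float(np.percentile(ratios, 2.5)),
        hi95=float(np.percentile(ratios, 97.5)),
        p_gt_1=float(np.mean(ratios > 1.0)),
        p_gt_10=float(np.mean(ratios > 10.0)),
        n_samples=n,
        seed=seed,
    )


def exposure_liability_table(
    pk_bounds: pd.DataFrame,
    potency: pd.DataFrame,
    n: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Ratio summaries for every drug x stage x metric x potency mechanism.

    ``pk_bounds`` columns: drug, stage, metric, min, max, central, mw;
    ``potency`` columns: drug, mechanism, potency_um.  Each row gets its own
    sub-seed derived deterministically from ``seed``.
    """
    _validate_bounds(pk_bounds)
    _validate_potency(potency)
    pot = {
        drug: dict(zip(g["mechanism"], g["potency_um"]))
        for drug, g in potency.groupby("drug")
    }
    rows = []
    counter = 0
    for rec in pk_bounds.itertuples(index=False):
        bound = PKBound(
            drug=rec.drug,
            stage=rec.stage,
            metric=rec.metric,
            min=_opt(rec.min),
            max=_opt(rec.max),
            central=_opt(rec.central),
            mw=float(rec.mw),
        )
        for mechanism, pot_um in sorted(pot.get(rec.drug, {}).items()):
            sub_seed = (seed + 7919 * counter) % (2**31)
            counter += 1
            s = simulate_ratios(bound, pot_um, n=n, seed=sub_seed, mechanism=mechanism)
            rows.append(
                {
                    "drug": s.drug,
                    "stage": s.stage,
                    "ratio": s.ratio_name,
                    "median": s.median,
                    "lo95": s.lo95,
                    "hi95": s.hi95,
                    "p_gt_1": s.p_gt_1,
                    "p_gt_10": s.p_gt_10,
                    "n_samples": s.n_samples,
                    "seed": s.seed,
                }
            )
    return pd.DataFrame(rows)


def _opt(x):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)


def _validate_bounds(df: pd.DataFrame) -> None:
    required = {"drug", "stage", "metric", "min", "max", "central", "mw"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"PK bounds table missing columns: {sorted(missing)}")
    bad = df[df["mw"] <= 0]
    if len(bad):
        raise ValueError(f"non-positive molecular weight for: {sorted(set(bad['drug']))}")


def _validate_potency(df: pd.DataFrame) -> None:
    required = {"drug", "mechanism", "potency_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"potency table missing columns: {sorted(missing)}")
    if (df["potency_um"] <= 0).any():
        raise ValueError("potency values must be positive")
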