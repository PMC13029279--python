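"""Case-level data model for individual case safety reports (ICSRs).

An ICSR is one spontaneous adverse-event case.  Public line listings expand a
case across its drugs and reactions, so the same case id can appear on many
rows; every inference-sensitive analysis in this package runs on the
deduplicated one-row-per-case representation, while mechanistic linkage runs
on the structurally expanded (case x suspect drug x reaction) table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Priority of antiviral drug classes used to pick the primary active drug of a
#: multi-drug regimen.  Lower rank = higher priority.  Classes outside the five
#: antiviral classes rank below RdRp.
CLASS_PRIORITY: dict[str, int] = {
    "INSTI": 0,
    "PI": 1,
    "NNRTI": 2,
    "NRTI": 3,
    "RdRp": 4,
    "other": 5,
}

#: Default pharmacokinetic boosters flagged in polypharmacy accounting.
DEFAULT_BOOSTERS: frozenset[str] = frozenset({"ritonavir", "cobicistat"})

#: Intra-cell separator for multi-valued fields in delimited-text exports.
DEFAULT_CELL_SEP = ";"

CASE_COLUMNS = [
    "case_id",
    "suspect_actives",
    "concomitant_actives",
    "reactions",
    "serious",
    "sex",
    "follow_up",
    "literature",
    "raw_cluster",
]

EXPANDED_COLUMNS = ["case_id", "drug", "reaction", "cluster", "serious"]


@dataclass(frozen=True)
class CaseReport:
    """One deduplicated ICSR."""

    case_id: str
    suspect_actives: frozenset[str]
    concomitant_actives: frozenset[str]
    reactions: tuple[str, ...]
    serious: bool
    sex: str = "female"
    follow_up: bool = False
    literature: bool = False
    raw_cluster: str = "C1"

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be nonempty")
        if not self.suspect_actives:
            raise ValueError(f"case {self.case_id!r}: suspect_actives must be nonempty")

    @property
    def all_actives(self) -> frozenset[str]:
        return self.suspect_actives | self.concomitant_actives

    @property
    def poly_actives_total(self) -> int:
        """Polypharmacy burden: unique actives (suspect plus concomitant)."""
        return len(self.all_actives)


@dataclass(frozen=True)
class DrugProfile:
    """Per-drug mechanistic profile: class, ADMET features, liability flags."""

    drug: str
    drug_class: str = "other"
    admet: Mapping[str, float] = field(default_factory=dict)
    flags: Mapping[str, bool] = field(default_factory=dict)
    mw: float | None = None

    def __post_init__(self) -> None:
        if self.drug_class not in CLASS_PRIORITY:
            raise ValueError(
                f"unknown drug class {self.drug_class!r} for {self.drug!r}; "
                f"expected one of {sorted(CLASS_PRIORITY)}"
            )


def deduplicate_cases(rows: Iterable[Mapping] | pd.DataFrame) -> list[CaseReport]:
    """Collapse a (possibly expanded) record stream to one CaseReport per id.

    Drug and reaction fields are set-unions across the id's rows and
    seriousness is the logical OR.  Conflicting sex values within an id trigger
    a warning; the first-seen value wins.
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")
    acc: dict[str, dict] = {}
    order: list[str] = []
    for row in rows:
        cid = str(row["case_id"])
        if not cid:
            raise ValueError("row without a case id")
        if cid not in acc:
            order.append(cid)
            acc[cid] = {
                "suspect": set(),
                "concomitant": set(),
                "reactions": [],
                "serious": False,
                "sex": None,
                "follow_up": False,
                "literature": False,
                "raw_cluster": None,
            }
        slot = acc[cid]
        slot["suspect"].update(_as_set(row.get("suspect_actives")))
        slot["concomitant"].update(_as_set(row.get("concomitant_actives")))
        for r in _as_list(row.get("reactions")):
            if r not in slot["reactions"]:
                slot["reactions"].append(r)
        slot["serious"] = slot["serious"] or _as_bool(row.get("serious", False))
        slot["follow_up"] = slot["follow_up"] or _as_bool(row.get("follow_up", False))
        slot["literature"] = slot["literature"] or _as_bool(row.get("literature", False))
        sex = row.get("sex")
        if sex is not None and not pd.isna(sex):
            if slot["sex"] is None:
                slot["sex"] = str(sex)
            elif slot["sex"] != str(sex):
                logger.warning(
                    "case %s: conflicting sex values (%r vs %r); keeping first-seen",
                    cid, slot["sex"], sex,
                )
        cluster = row.get("raw_cluster")
        if cluster is not None and not pd.isna(cluster) and slot["raw_cluster"] is None:
            slot["raw_cluster"] = str(cluster)
    return [
        CaseReport(
            case_id=cid,
            suspect_actives=frozenset(acc[cid]["suspect"]),
            concomitant_actives=frozenset(acc[cid]["concomitant"]) - frozenset(acc[cid]["suspect"]),
            reactions=tuple(acc[cid]["reactions"]),
            serious=acc[cid]["serious"],
            sex=acc[cid]["sex"] or "unknown",
            follow_up=acc[cid]["follow_up"],
            literature=acc[cid]["literature"],
            raw_cluster=acc[cid]["raw_cluster"] or "C1",
        )
        for cid in order
    ]


def expand_cases(cases: Sequence[CaseReport]) -> pd.DataFrame:
    """Structurally expand cases to one row per (case, suspect drug, reaction).

    Concomitant drugs are excluded: mechanistic linkage is anchored to suspect
    drugs only.  A case without reactions contributes zero rows (logged).
    """
    records = []
    for case in cases:
        if not case.reactions:
            logger.info("case %s has no reactions; contributes no expanded rows", case.case_id)
            continue
        for drug in sorted(case.suspect_actives):
            for reaction in case.reactions:
                records.append(
                    (case.case_id, drug, reaction, case.raw_cluster, case.serious)
                )
    return pd.DataFrame(records, columns=EXPANDED_COLUMNS)


def assign_primary_active(
    case: CaseReport, catalog: Mapping[str, DrugProfile]
) -> str:
    """Pick the suspect drug whose class has highest priority.

    The class hierarchy is INSTI > PI > NNRTI > NRTI > RdRp, with any other
    class below RdRp.  Ties within the top class break lexicographically so the
    assignment is deterministic and order-invariant.
    """
    unknown = sorted(d for d in case.suspect_actives if d not in catalog)
    if unknown:
        raise KeyError(
            f"case {case.case_id}: suspect drug(s) not in catalog: {', '.join(unknown)}"
        )
    return min(
        case.suspect_actives,
        key=lambda d: (CLASS_PRIORITY[catalog[d].drug_class], d),
    )


def compute_polypharmacy(
    case: CaseReport, boosters: frozenset[str] = DEFAULT_BOOSTERS
) -> dict:
    """Polypharmacy burden summary for one case."""
    return {
        "poly_actives_total": case.poly_actives_total,
        "n_concomitant": len(case.concomitant_actives),
        "booster_present": bool(case.all_actives & boosters),
    }


def cases_to_frame(cases: Sequence[CaseReport], sep: str = DEFAULT_CELL_SEP) -> pd.DataFrame:
    """Serialise cases to a flat table; multi-valued cells joined with `sep`."""
    return pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "suspect_actives": [sep.join(sorted(c.suspect_actives)) for c in cases],
            "concomitant_actives": [sep.join(sorted(c.concomitant_actives)) for c in cases],
            "reactions": [sep.join(c.reactions) for c in cases],
            "serious": [int(c.serious) for c in cases],
            "sex": [c.sex for c in cases],
            "follow_up": [int(c.follow_up) for c in cases],
            "literature": [int(c.literature) for c in cases],
            "raw_cluster": [c.raw_cluster for c in cases],
        }
    )


def frame_to_cases(df: pd.DataFrame, sep: str = DEFAULT_CELL_SEP) -> list[CaseReport]:
    """Parse a flat case table back into CaseReport objects, with validation.

    Raises ValueError listing every offending row if the schema is violated.
    """
    missing = [c for c in CASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"case table missing columns: {missing}")
    errors: list[str] = []
    cases: list[CaseReport] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            cid = str(row.case_id)
            if cid in seen:
                raise ValueError(f"duplicate case id {cid!r}")
            seen.add(cid)
            cases.append(
                CaseReport(
                    case_id=cid,
                    suspect_actives=frozenset(_split(row.suspect_actives, sep)),
                    concomitant_actives=frozenset(_split(row.concomitant_actives, sep)),
                    reactions=tuple(_split(row.reactions, sep)),
                    serious=_as_bool(row.serious),
                    sex=str(row.sex),
                    follow_up=_as_bool(row.follow_up),
                    literature=_as_bool(row.literature),
                    raw_cluster=str(row.raw_cluster),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("case table validation failed:\n" + "\n".join(errors))
    return cases


def read_cases_csv(path, sep: str = DEFAULT_CELL_SEP) -> list[CaseReport]:
    return frame_to_cases(pd.read_csv(path, keep_default_na=False), sep=sep)


def write_cases_csv(cases: Sequence[CaseReport], path, sep: str = DEFAULT_CELL_SEP) -> None:
    cases_to_frame(cases, sep=sep).to_csv(path, index=False)


def _split(cell, sep: str) -> list[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return []
    text = str(cell).strip()
    if not text:
        return []
    return [part.strip() for part in text.split(sep) if part.strip()]


def _as_set(value) -> set[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return set()
    if isinstance(value, str):
        return set(_split(value, DEFAULT_CELL_SEP))
    return {str(v) for v in value}


def _as_list(value) -> list[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return []
    if isinstance(value, str):
        return _split(value, DEFAULT_CELL_SEP)
    return [str(v) for v in value]


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    return bool(value)
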