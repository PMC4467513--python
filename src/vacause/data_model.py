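"""VA records, symptom codebook, inclusion filtering and age stratification.

A verbal autopsy (VA) study is a table of deaths: one row per deceased
child, columns holding sign/symptom responses keyed by a codebook, plus
reserved columns for identifiers, age, survey-design fields and an
optional comparator cause (e.g. a physician-review assignment).  This
module reads/writes that table, applies the five record-inclusion
criteria (live birth; age 0-59 months; complete interview; sufficient age
information; age-appropriate questionnaire) and splits included records
into the two analysis strata: neonates (0-27 days) and children
(1-59 months).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

#: days per month used to convert reported ages; 59 months -> 1826 days
DAYS_PER_MONTH = 30.4375
MAX_AGE_DAYS = 1826
NEONATAL_MAX_AGE_DAYS = 27

#: columns with fixed meaning that are not symptom items
RESERVED_COLUMNS = {
    "record_id",
    "live_birth",
    "age_at_death_days",
    "age_at_death_months",
    "questionnaire_type",
    "survey_weight",
    "stratum_id",
    "psu_id",
    "comparator_cause",
    "interview_complete",
}

ITEM_KINDS = {"binary", "count", "duration_days", "categorical"}

_TRUE_TOKENS = {"1", "y", "yes", "true"}
_FALSE_TOKENS = {"0", "n", "no", "false"}


class AgeStratum(enum.Enum):
    """The two parallel analysis strata of the assignment algorithm."""

    NEONATE = "neonate_0_27d"
    CHILD = "child_1_59m"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SymptomItem:
    """One sign/symptom question of the VA instrument.

    ``kind`` is one of ``binary`` (yes/no), ``count`` (non-negative
    integer, e.g. stools per day), ``duration_days`` (non-negative integer
    number of days) or ``categorical`` (one of ``allowed_values``).
    Raw values listed in ``missing_codes`` parse to missing.
    """

    id: str
    kind: str
    allowed_values: tuple = ()
    missing_codes: tuple = ("", "9", "dk", "DK", "NA")

    def __post_init__(self) -> None:
        if self.kind not in ITEM_KINDS:
            raise ValueError(f"item {self.id!r}: unknown kind {self.kind!r}")

    def parse(self, raw: object):
        """Parse a raw CSV token; return None for missing codes."""
        token = "" if raw is None else str(raw).strip()
        if token in self.missing_codes:
            return None
        if self.kind == "binary":
            low = token.lower()
            if low in _TRUE_TOKENS:
                return True
            if low in _FALSE_TOKENS:
                return False
            raise ValueError(f"item {self.id!r}: unparseable binary value {raw!r}")
        if self.kind in ("count", "duration_days"):
            try:
                value = int(float(token))
            except ValueError as exc:
                raise ValueError(
                    f"item {self.id!r}: unparseable {self.kind} value {raw!r}"
                ) from exc
            if value < 0:
                raise ValueError(f"item {self.id!r}: negative value {raw!r}")
            return value
        # categorical
        if self.allowed_values and token not in self.allowed_values:
            raise ValueError(
                f"item {self.id!r}: value {raw!r} not in allowed_values"
            )
        return token


@dataclass(frozen=True)
class Codebook:
    """Ordered collection of :class:`SymptomItem` with unique ids."""

    items: tuple

    def __post_init__(self) -> None:
        ids = [it.id for it in self.items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate codebook item ids: {sorted(dupes)}")

    @property
    def ids(self) -> tuple:
        return tuple(it.id for it in self.items)

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.ids

    def __getitem__(self, item_id: str) -> SymptomItem:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "Codebook":
        raw_items = payload.get("items")
        if not isinstance(raw_items, list) or not raw_items:
            raise ValueError("codebook must contain a non-empty 'items' list")
        items = []
        for entry in raw_items:
            items.append(
                SymptomItem(
                    id=str(entry["id"]),
                    kind=str(entry["kind"]),
                    allowed_values=tuple(entry.get("allowed_values", ()) or ()),
                    missing_codes=tuple(
                        str(c) for c in entry.get("missing_codes", ("", "9", "dk", "DK", "NA"))
                    ),
                )
            )
        return cls(items=tuple(items))

    def to_dict(self) -> dict:
        out = []
        for it in self.items:
            entry = {"id": it.id, "kind": it.kind, "missing_codes": list(it.missing_codes)}
            if it.allowed_values:
                entry["allowed_values"] = list(it.allowed_values)
            out.append(entry)
        return {"items": out}


@dataclass
class VARecord:
    """One deceased child: identifiers, age, symptom responses, design fields.

    ``responses`` maps codebook item id to a parsed value; missing
    responses are simply absent from the map (the case-definition engine
    treats absent and missing identically, as symptom-absent).
    """

    record_id: str
    live_birth: str = "yes"  # yes / no / unknown
    age_at_death_days: Optional[int] = None
    questionnaire_type: Optional[str] = None  # neonatal / child
    responses: dict = field(default_factory=dict)
    survey_weight: float = 1.0
    stratum_id: str = "S1"
    psu_id: str = "P1"
    comparator_cause: Optional[str] = None
    interview_complete: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.survey_weight > 0:
            raise ValueError(f"record {self.record_id!r}: survey_weight must be > 0")


def load_codebook(path) -> Codebook:
    """Load a codebook from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    return Codebook.from_dict(yaml.safe_load(text))


def default_codebook() -> Codebook:
    """The codebook bundled with the package (WHO-style VA item vocabulary)."""
    text = resources.files("vacause.data").joinpath("codebook.yaml").read_text("utf-8")
    return Codebook.from_dict(yaml.safe_load(text))


def _parse_tristate(raw: object) -> str:
    token = ("" if raw is None else str(raw).strip()).lower()
    if token in _TRUE_TOKENS:
        return "yes"
    if token in _FALSE_TOKENS:
        return "no"
    return "unknown"


def _parse_age_days(row: Mapping) -> Optional[int]:
    raw_days = str(row.get("age_at_death_days", "") or "").strip()
    if raw_days:
        try:
            return int(float(raw_days))
        except ValueError:
            pass  # fall through to months, else missing
    raw_months = str(row.get("age_at_death_months", "") or "").strip()
    if raw_months:
        try:
            return int(math.floor(float(raw_months) * DAYS_PER_MONTH))
        except ValueError:
            return None
    return None


def load_records(path, codebook: Codebook) -> list:
    """Read a VA records CSV into :class:`VARecord` objects.

    Every column must be either a reserved column or a codebook item;
    unknown columns raise a :class:`ValueError` naming all offenders.
    Unparseable ages load with age marked missing (the inclusion filter
    will exclude such records); unparseable item values raise.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in frame.columns if c not in RESERVED_COLUMNS and c not in codebook]
    if unknown:
        raise ValueError(f"columns not in codebook or reserved set: {unknown}")
    if "record_id" not in frame.columns:
        raise ValueError("records CSV must contain a 'record_id' column")

    item_cols = [c for c in frame.columns if c in codebook]
    records = []
    for _, row in frame.iterrows():
        responses = {}
        for col in item_cols:
            value = codebook[col].parse(row[col])
            if value is not None:
                responses[col] = value
        weight_raw = str(row.get("survey_weight", "") or "").strip()
        complete_raw = str(row.get("interview_complete", "") or "").strip()
        records.append(
            VARecord(
                record_id=str(row["record_id"]),
                live_birth=_parse_tristate(row.get("live_birth", "yes")),
                age_at_death_days=_parse_age_days(row),
                questionnaire_type=(str(row["questionnaire_type"]).strip() or None)
                if "questionnaire_type" in frame.columns
                else None,
                responses=responses,
                survey_weight=float(weight_raw) if weight_raw else 1.0,
                stratum_id=str(row.get("stratum_id", "S1") or "S1"),
                psu_id=str(row.get("psu_id", "P1") or "P1"),
                comparator_cause=(str(row["comparator_cause"]).strip() or None)
                if "comparator_cause" in frame.columns
                else None,
                interview_complete=(complete_raw.lower() in _TRUE_TOKENS)
                if complete_raw
                else None,
            )
        )
    return records


def write_records(records: Iterable[VARecord], path, codebook: Codebook) -> None:
    """Write records to CSV in the same layout :func:`load_records` reads."""
    rows = []
    for rec in records:
        row = {
            "record_id": rec.record_id,
            "live_birth": rec.live_birth,
            "age_at_death_days": "" if rec.age_at_death_days is None else rec.age_at_death_days,
            "questionnaire_type": rec.questionnaire_type or "",
            "survey_weight": rec.survey_weight,
            "stratum_id": rec.stratum_id,
            "psu_id": rec.psu_id,
            "comparator_cause": rec.comparator_cause or "",
            "interview_complete": ""
            if rec.interview_complete is None
            else ("1" if rec.interview_complete else "0"),
        }
        for item in codebook.items:
            value = rec.responses.get(item.id)
            if value is None:
                row[item.id] = ""
            elif item.kind == "binary":
                row[item.id] = "1" if value else "0"
            else:
                row[item.id] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Inclusion criteria
# ---------------------------------------------------------------------------

REASON_NOT_LIVE_BIRTH = "not live birth"
REASON_AGE_OUT_OF_RANGE = "age out of range"
REASON_INCOMPLETE_INTERVIEW = "incomplete interview"
REASON_INSUFFICIENT_AGE = "insufficient age information"
REASON_WRONG_QUESTIONNAIRE = "age-inappropriate questionnaire"

#: fraction of codebook items that may be missing before an interview with
#: no explicit completeness flag is deemed incomplete
INCOMPLETE_MISSING_FRACTION = 0.5

_QUESTIONNAIRE_FOR_STRATUM = {
    AgeStratum.NEONATE: "neonatal",
    AgeStratum.CHILD: "child",
}


def _first_failed_criterion(rec: VARecord, codebook: Optional[Codebook]) -> Optional[str]:
    # 1. live birth
    if rec.live_birth != "yes":
        return REASON_NOT_LIVE_BIRTH
    # 2. died between 0 and 59 months (evaluable only when age is known;
    #    an unknown age fails criterion 4 instead)
    age = rec.age_at_death_days
    if age is not None and (age < 0 or age > MAX_AGE_DAYS):
        return REASON_AGE_OUT_OF_RANGE
    # 3. complete VA interview: explicit flag when present, else a
    #    missingness threshold over codebook items
    if rec.interview_complete is False:
        return REASON_INCOMPLETE_INTERVIEW
    if rec.interview_complete is None and codebook is not None and codebook.items:
        n_items = len(codebook.items)
        n_answered = sum(1 for i in codebook.ids if rec.responses.get(i) is not None)
        if (n_items - n_answered) / n_items >= INCOMPLETE_MISSING_FRACTION:
            return REASON_INCOMPLETE_INTERVIEW
    # 4. sufficient information on age at death
    if age is None:
        return REASON_INSUFFICIENT_AGE
    # 5. age-appropriate questionnaire (explicit mismatch only)
    if rec.questionnaire_type is not None:
        expected = _QUESTIONNAIRE_FOR_STRATUM[stratify(rec)]
        if rec.questionnaire_type != expected:
            return REASON_WRONG_QUESTIONNAIRE
    return None


def apply_inclusion_criteria(records, codebook: Optional[Codebook] = None):
    """Split records into (included, exclusion_log).

    The exclusion log maps record_id to the FIRST failed criterion in the
    order: live birth; age range; interview completeness; age information;
    questionnaire appropriateness.  When ``codebook`` is omitted the
    missingness-based completeness check is skipped (only an explicit
    ``interview_complete`` flag can then fail criterion 3).
    """
    included = []
    log = {}
    for rec in records:
        reason = _first_failed_criterion(rec, codebook)
        if reason is None:
            included.append(rec)
        else:
            log[rec.record_id] = reason
    return included, log


def stratify(record: VARecord) -> AgeStratum:
    """Age stratum of an included record; boundary 27 d -> neonate, 28 d -> child."""
    age = record.age_at_death_days
    if age is None:
        raise ValueError(f"record {record.record_id!r}: age missing, cannot stratify")
    if age < 0 or age > MAX_AGE_DAYS:
        raise ValueError(f"record {record.record_id!r}: age {age} d out of 0-59 m range")
    return AgeStratum.NEONATE if age <= NEONATAL_MAX_AGE_DAYS else AgeStratum.CHILD


def write_exclusion_log(log: Mapping, path) -> None:
    pd.DataFrame(
        [{"record_id": rid, "reason": reason} for rid, reason in log.items()]
    ).to_csv(path, index=False)
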