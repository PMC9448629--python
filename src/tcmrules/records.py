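"""Domain types for clinical-record transactions plus JSONL/CSV readers and writers.

A corpus is an ordered list of :class:`MedicalRecord`; each record carries
typed categorical items (symptoms, a primary constitution from the fixed
nine-label set, optional secondary constitutions, regimen/disease/drug
tokens).  Records project onto transactions (item sets) for mining.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Role",
    "CONSTITUTIONS",
    "Item",
    "MedicalRecord",
    "Transaction",
    "symptom",
    "constitution",
    "regimen",
    "read_records",
    "write_records",
    "to_transactions",
    "PROJECTIONS",
]


class Role(str, Enum):
    """The five roles an item token can play in a record."""

    SYMPTOM = "symptom"
    CONSTITUTION = "constitution"
    REGIMEN = "regimen"
    DISEASE = "disease"
    DRUG = "drug"


#: The fixed nine-label constitution vocabulary, in canonical order.
CONSTITUTIONS: tuple[str, ...] = (
    "BC", "YADC", "YIDC", "QDC", "QSC", "PDC", "DHC", "BSC", "ISC",
)

_WS = re.compile(r"\s+")


def _normalize_token(token: str, role: Role) -> str:
    token = _WS.sub(" ", token.strip())
    if role is Role.CONSTITUTION:
        return token.upper()
    return token.casefold()


@dataclass(frozen=True, order=True)
class Item:
    """A typed categorical token: the atom of every transaction.

    Tokens are whitespace-normalized and case-folded on construction
    (constitution labels are upper-cased instead, to match the fixed
    vocabulary).  Constitution tokens must be one of ``CONSTITUTIONS``.
    """

    token: str
    role: Role

    def __post_init__(self) -> None:
        norm = _normalize_token(self.token, self.role)
        if not norm:
            raise ValueError("item token must be non-empty after normalization")
        object.__setattr__(self, "token", norm)
        if self.role is Role.CONSTITUTION and norm not in CONSTITUTIONS:
            raise ValueError(
                f"unknown constitution label {norm!r}; expected one of {CONSTITUTIONS}"
            )

    def __str__(self) -> str:  # pragma: no cover - debugging nicety
        return f"{self.role.value}:{self.token}"


def symptom(token: str) -> Item:
    return Item(token, Role.SYMPTOM)


def constitution(token: str) -> Item:
    return Item(token, Role.CONSTITUTION)


def regimen(token: str) -> Item:
    return Item(token, Role.REGIMEN)


#: A transaction is simply a set of items; set semantics within a record,
#: multiset semantics across a corpus (duplicate records count twice).
Transaction = frozenset  # frozenset[Item]


@dataclass(frozen=True)
class MedicalRecord:
    """One patient record: labeled symptom set plus regimen/disease/drug items."""

    record_id: str
    symptoms: frozenset = field(default_factory=frozenset)
    primary_constitution: Item = None  # type: ignore[assignment]
    secondary_constitutions: frozenset = field(default_factory=frozenset)
    regimen: frozenset = field(default_factory=frozenset)
    diseases: frozenset = field(default_factory=frozenset)
    drugs: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if self.primary_constitution is None or self.primary_constitution.role is not Role.CONSTITUTION:
            raise ValueError("primary_constitution must be a constitution-role Item")
        object.__setattr__(self, "symptoms", frozenset(self.symptoms))
        object.__setattr__(self, "secondary_constitutions", frozenset(self.secondary_constitutions))
        object.__setattr__(self, "regimen", frozenset(self.regimen))
        object.__setattr__(self, "diseases", frozenset(self.diseases))
        object.__setattr__(self, "drugs", frozenset(self.drugs))
        if self.primary_constitution in self.secondary_constitutions:
            raise ValueError("primary constitution may not appear among secondary constitutions")
        for it in self.symptoms:
            if it.role is not Role.SYMPTOM:
                raise ValueError(f"non-symptom item {it} in symptoms")
        for it in self.secondary_constitutions:
            if it.role is not Role.CONSTITUTION:
                raise ValueError(f"non-constitution item {it} in secondary_constitutions")
        for it in self.regimen:
            if it.role is not Role.REGIMEN:
                raise ValueError(f"non-regimen item {it} in regimen")
        for it in self.diseases:
            if it.role is not Role.DISEASE:
                raise ValueError(f"non-disease item {it} in diseases")
        for it in self.drugs:
            if it.role is not Role.DRUG:
                raise ValueError(f"non-drug item {it} in drugs")


_FIELDS = (
    "record_id",
    "symptoms",
    "primary_constitution",
    "secondary_constitutions",
    "regimen",
    "diseases",
    "drugs",
)

_MULTI_ROLES = {
    "symptoms": Role.SYMPTOM,
    "secondary_constitutions": Role.CONSTITUTION,
    "regimen": Role.REGIMEN,
    "diseases": Role.DISEASE,
    "drugs": Role.DRUG,
}


def _record_from_mapping(obj: dict, where: str) -> MedicalRecord:
    try:
        kwargs: dict = {"record_id": str(obj["record_id"])}
        kwargs["primary_constitution"] = Item(str(obj["primary_constitution"]), Role.CONSTITUTION)
        for name, role in _MULTI_ROLES.items():
            tokens = obj.get(name) or []
            kwargs[name] = frozenset(Item(str(t), role) for t in tokens)
        return MedicalRecord(**kwargs)
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"{where}: {exc}") from exc


def _record_to_mapping(rec: MedicalRecord) -> dict:
    return {
        "record_id": rec.record_id,
        "symptoms": sorted(i.token for i in rec.symptoms),
        "primary_constitution": rec.primary_constitution.token,
        "secondary_constitutions": sorted(i.token for i in rec.secondary_constitutions),
        "regimen": sorted(i.token for i in rec.regimen),
        "diseases": sorted(i.token for i in rec.diseases),
        "drugs": sorted(i.token for i in rec.drugs),
    }


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"unknown format {fmt!r}; expected 'jsonl' or 'csv'")
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def read_records(path: str | Path, format: str | None = None) -> list[MedicalRecord]:
    """Read a corpus from JSONL (canonical) or CSV (pipe-delimited multi cells).

    Order is preserved; every line/row yields exactly one validated record.
    Malformed input raises ``ValueError`` naming the offending line.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    records: list[MedicalRecord] = []
    if fmt == "jsonl":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed JSON ({exc})") from exc
                records.append(_record_from_mapping(obj, f"{path}:{lineno}"))
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                obj = {
                    "record_id": row.get("record_id", ""),
                    "primary_constitution": row.get("primary_constitution", ""),
                }
                for name in _MULTI_ROLES:
                    cell = (row.get(name) or "").strip()
                    obj[name] = [t for t in cell.split("|") if t.strip()] if cell else []
                records.append(_record_from_mapping(obj, f"{path}:{lineno}"))
    seen: set[str] = set()
    for rec in records:
        if rec.record_id in seen:
            raise ValueError(f"duplicate record_id {rec.record_id!r} in {path}")
        seen.add(rec.record_id)
    return records


def write_records(records: Iterable[MedicalRecord], path: str | Path,
                  format: str | None = None) -> None:
    """Write records as JSONL or CSV; the round-trip with :func:`read_records`
    is the identity on validated records."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w") as fh:
            for rec in records:
                fh.write(json.dumps(_record_to_mapping(rec), sort_keys=True) + "\n")
    else:
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS)
            writer.writeheader()
            for rec in records:
                row = _record_to_mapping(rec)
                for name in _MULTI_ROLES:
                    row[name] = "|".join(row[name])
                writer.writerow(row)


PROJECTIONS = ("symptom_constitution", "constitution_regimen", "full")


def to_transactions(records: Sequence[MedicalRecord], projection: str,
                    include_secondary: bool = False) -> list[frozenset]:
    """Project records onto transactions.

    ``symptom_constitution``: symptoms plus the primary constitution (the
    stage-1 symptom-rule substrate).  ``constitution_regimen``: the primary
    constitution plus regimen items.  ``full``: union of all item sets.
    One transaction per record — duplicates across records are preserved.
    """
    if projection not in PROJECTIONS:
        raise ValueError(f"unknown projection {projection!r}; expected one of {PROJECTIONS}")
    out: list[frozenset] = []
    for rec in records:
        labels: frozenset = frozenset({rec.primary_constitution})
        if include_secondary:
            labels |= rec.secondary_constitutions
        if projection == "symptom_constitution":
            out.append(rec.symptoms | labels)
        elif projection == "constitution_regimen":
            out.append(labels | rec.regimen)
        else:
            out.append(rec.symptoms | labels | rec.regimen | rec.diseases | rec.drugs)
    return out
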