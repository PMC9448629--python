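"""Pre-training cleanup: stop-word removal and cross-constitution
shared-symptom ("noise") filtering.

Shared-symptom removal uses a discriminability threshold: a symptom seen at
least ``min_occurrences`` times whose most-frequent constitution accounts
for less than ``min_discriminability`` of its occurrences is deleted from
every record.  Records themselves are never deleted.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .records import CONSTITUTIONS, Item, MedicalRecord, Role

__all__ = [
    "StopList",
    "SymptomProfile",
    "default_stoplist",
    "load_stoplist",
    "remove_stopwords",
    "remove_stopword_symptoms",
    "profile_symptoms",
    "remove_shared_symptoms",
]


@dataclass(frozen=True)
class StopList:
    words: frozenset

    def __contains__(self, token: str) -> bool:
        return token.casefold() in self.words

    @classmethod
    def from_words(cls, words: Iterable[str]) -> "StopList":
        return cls(frozenset(w.strip().casefold() for w in words if w.strip()))


def load_stoplist(path: str | Path) -> StopList:
    """Load a stop list from a plain-text file, one word per line."""
    return StopList.from_words(Path(path).read_text().splitlines())


def default_stoplist() -> StopList:
    """The packaged default list: articles, pronouns, conjunctions, auxiliaries."""
    text = resources.files("tcmrules").joinpath("data/stopwords.txt").read_text()
    return StopList.from_words(text.splitlines())


def remove_stopwords(tokens: Sequence[str], stoplist: StopList | None = None) -> list[str]:
    """Drop stop-list members (case-insensitive), preserving token order."""
    if stoplist is None:
        stoplist = default_stoplist()
    return [t for t in tokens if t not in stoplist]


def remove_stopword_symptoms(records: Sequence[MedicalRecord],
                             stoplist: StopList | None = None) -> list[MedicalRecord]:
    """Apply the stop list to symptom items only; label items are untouched."""
    if stoplist is None:
        stoplist = default_stoplist()
    out = []
    for rec in records:
        kept = frozenset(s for s in rec.symptoms if s.token not in stoplist)
        if kept == rec.symptoms:
            out.append(rec)
        else:
            out.append(_replace_symptoms(rec, kept))
    return out


def _replace_symptoms(rec: MedicalRecord, symptoms: frozenset) -> MedicalRecord:
    return MedicalRecord(
        record_id=rec.record_id,
        symptoms=symptoms,
        primary_constitution=rec.primary_constitution,
        secondary_constitutions=rec.secondary_constitutions,
        regimen=rec.regimen,
        diseases=rec.diseases,
        drugs=rec.drugs,
    )


@dataclass(frozen=True)
class SymptomProfile:
    """Per-constitution occurrence counts for one symptom."""

    symptom: Item
    per_constitution_counts: tuple  # aligned with CONSTITUTIONS

    @property
    def total(self) -> int:
        return sum(self.per_constitution_counts)

    @property
    def discriminability(self) -> float:
        """max(count) / total — 1.0 when the symptom is class-unique."""
        total = self.total
        return max(self.per_constitution_counts) / total if total else 0.0

    def as_dict(self) -> dict:
        return {
            "symptom": self.symptom.token,
            "counts": dict(zip(CONSTITUTIONS, self.per_constitution_counts)),
            "total": self.total,
            "discriminability": self.discriminability,
        }


def profile_symptoms(records: Sequence[MedicalRecord]) -> dict:
    """Tally, for every symptom, how many records of each constitution contain it.

    Returns ``{symptom Item: SymptomProfile}``.
    """
    idx = {label: i for i, label in enumerate(CONSTITUTIONS)}
    counts: dict[Item, list[int]] = {}
    for rec in records:
        ci = idx[rec.primary_constitution.token]
        for s in rec.symptoms:
            counts.setdefault(s, [0] * len(CONSTITUTIONS))[ci] += 1
    return {s: SymptomProfile(s, tuple(v)) for s, v in counts.items()}


def remove_shared_symptoms(records: Sequence[MedicalRecord],
                           min_discriminability: float = 0.8,
                           min_occurrences: int = 2,
                           ) -> tuple[list[MedicalRecord], dict]:
    """Delete cross-constitution shared symptoms from every record.

    A symptom is removed when it occurs at least ``min_occurrences`` times in
    the corpus and its discriminability (share of its occurrences in its most
    frequent constitution) falls below ``min_discriminability``.  Idempotent.

    Returns ``(filtered records, report)`` where the report lists the removed
    symptoms with their profiles.
    """
    if not (0.0 < min_discriminability <= 1.0):
        raise ValueError("min_discriminability must lie in (0, 1]")
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    profiles = profile_symptoms(records)
    removed = {
        s: p for s, p in profiles.items()
        if p.total >= min_occurrences and p.discriminability < min_discriminability
    }
    out = []
    for rec in records:
        kept = frozenset(s for s in rec.symptoms if s not in removed)
        out.append(rec if kept == rec.symptoms else _replace_symptoms(rec, kept))
    report = {
        "min_discriminability": min_discriminability,
        "min_occurrences": min_occurrences,
        "removed": sorted((p.as_dict() for p in removed.values()),
                          key=lambda d: d["symptom"]),
    }
    return out, report
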