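"""Extensional value sets and their registry.

A value set is an explicitly enumerated list of terminology codes (system +
code) standing for a drug class, a condition group, or any other concept
collection an artifact needs to reference.  Codes are opaque, case-sensitive
strings: no terminology-server normalization, no hierarchy expansion — a
concept is a member iff its (system, code) pair is listed.

File formats: CSV with a ``system,code,display`` header, or a JSON array of
objects with the same keys.  Both round-trip losslessly.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Union

from .errors import FormatError, MissingValueSetError, ValueSetConflictError
from .model import CodedConcept, ValueSetRef

__all__ = [
    "ValueSet",
    "ValueSetRegistry",
    "read_value_set",
    "write_value_set",
]


@dataclass(frozen=True)
class ValueSet:
    """An extensional value set: all member codes are simply listed."""

    id: str
    name: str = ""
    purpose: str = ""
    members: tuple[CodedConcept, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ValueSet requires a non-empty id")
        seen: set[tuple[str, str]] = set()
        for m in self.members:
            if m.key in seen:
                raise ValueError(
                    f"duplicate member {m.key} in value set {self.id!r}"
                )
            seen.add(m.key)

    def contains(self, concept: CodedConcept) -> bool:
        """Exact, case-sensitive (system, code) membership; display is
        never consulted."""
        return any(m == concept for m in self.members)

    def __contains__(self, concept: CodedConcept) -> bool:
        return self.contains(concept)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[CodedConcept]:
        return iter(self.members)


class ValueSetRegistry:
    """Mapping from value-set id to :class:`ValueSet`; unknown ids fail
    loudly with :class:`~pddikit.errors.MissingValueSetError`."""

    def __init__(self, value_sets: Iterable[ValueSet] = ()) -> None:
        self._sets: dict[str, ValueSet] = {}
        for vs in value_sets:
            self.register(vs)

    def register(self, vs: ValueSet, *, overwrite: bool = False) -> "ValueSetRegistry":
        """Add a value set; re-registering an id requires ``overwrite=True``.

        Raises
        ------
        ValueSetConflictError
            If the id is taken and ``overwrite`` is not set.
        """
        if vs.id in self._sets and not overwrite:
            raise ValueSetConflictError(
                f"value set id {vs.id!r} already registered; pass overwrite=True "
                "to replace it"
            )
        self._sets[vs.id] = vs
        return self

    def get(self, ref: Union[str, ValueSetRef]) -> ValueSet:
        vs_id = ref.id if isinstance(ref, ValueSetRef) else ref
        try:
            return self._sets[vs_id]
        except KeyError:
            raise MissingValueSetError(
                f"no value set registered under id {vs_id!r}"
            ) from None

    def expand(self, ref: Union[str, ValueSetRef]) -> list[CodedConcept]:
        """All members of the referenced set, in registration order."""
        return list(self.get(ref).members)

    def __contains__(self, vs_id: str) -> bool:
        return vs_id in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def ids(self) -> list[str]:
        return list(self._sets)

    def __iter__(self) -> Iterator[ValueSet]:
        return iter(self._sets.values())


_COLUMNS = ("system", "code", "display")


def _members_from_rows(
    rows: Iterable[dict[str, str]], source: str
) -> tuple[CodedConcept, ...]:
    members: list[CodedConcept] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(rows):
        missing = [c for c in ("system", "code") if not (row.get(c) or "").strip()]
        if missing:
            raise FormatError(f"{source}: row {i + 1} missing column(s) {missing}")
        concept = CodedConcept(
            system=row["system"].strip(),
            code=row["code"].strip(),
            display=(row.get("display") or "").strip(),
        )
        if concept.key in seen:
            warnings.warn(
                f"{source}: duplicate row for {concept.key}; collapsed",
                stacklevel=3,
            )
            continue
        seen.add(concept.key)
        members.append(concept)
    return tuple(members)


def read_value_set(path: Union[str, Path], *, id: str | None = None) -> ValueSet:
    """Read a value set from a CSV or JSON file.

    CSV files need a ``system,code,display`` header (comma-separated,
    UTF-8, quoted fields allowed).  JSON files are either an array of
    member objects or an object with ``id``/``name``/``purpose``/
    ``members``.  Duplicate member rows collapse with a warning.  The set
    id defaults to the file stem.

    Raises
    ------
    FormatError
        On a missing column, an empty file, or malformed JSON.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise FormatError(f"{path}: empty value-set file")
    vs_id = id or path.stem

    if path.suffix.lower() == ".json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON ({exc})") from None
        if isinstance(data, dict):
            rows = data.get("members", [])
            vs_id = id or data.get("id", vs_id)
            name = data.get("name", "")
            purpose = data.get("purpose", "")
        else:
            rows, name, purpose = data, "", ""
        if not isinstance(rows, list):
            raise FormatError(f"{path}: JSON members must be an array")
        return ValueSet(
            id=vs_id,
            name=name,
            purpose=purpose,
            members=_members_from_rows(rows, str(path)),
        )

    reader = csv.DictReader(io.StringIO(text))
    header = reader.fieldnames or []
    missing = [c for c in ("system", "code") if c not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return ValueSet(id=vs_id, members=_members_from_rows(reader, str(path)))


def write_value_set(vs: ValueSet, path: Union[str, Path]) -> None:
    """Write a value set to CSV (default) or JSON, chosen by suffix.

    ``read_value_set(write_value_set(vs, p))`` is structurally lossless
    for (system, code, display); name/purpose survive only in JSON.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "id": vs.id,
            "name": vs.name,
            "purpose": vs.purpose,
            "members": [
                {"system": m.system, "code": m.code, "display": m.display}
                for m in vs.members
            ],
        }
        path.write_text(json.dumps(doc, indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
        return
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(_COLUMNS)
    for m in vs.members:
        writer.writerow([m.system, m.code, m.display])
    path.write_text(buf.getvalue(), encoding="utf-8")
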