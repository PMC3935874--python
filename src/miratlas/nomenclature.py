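"""Harmonize microRNA names across miRBase releases onto stable MIMAT accessions.

MicroRNA nomenclature has been revised repeatedly (e.g. ``let-7b*`` became
``let-7b-3p``); mature-form MIMAT accessions are the only stable handle.
This module builds a lookup key from a miRBase ``aliases.txt``-style table
(accession TAB semicolon-separated historical names) and resolves free-text
names, as printed in heterogeneous source studies, to :class:`MirnaId`
records carrying the current name, arm and carrier-strand status.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "MirnaId",
    "NomenclatureKey",
    "NomenclatureConflictError",
    "UnknownMirnaError",
    "build_key",
    "read_aliases",
    "harmonize",
]


class NomenclatureConflictError(ValueError):
    """The same alias is claimed by two different accessions."""


class UnknownMirnaError(KeyError):
    """A queried name resolves to no accession in the key."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"unresolvable microRNA name: {self.name!r}"


@dataclass(frozen=True)
class MirnaId:
    """A mature microRNA: stable accession plus current naming metadata.

    ``carrier_strand`` marks the historically ``*``-suffixed minor arm of the
    duplex, which is typically lowly expressed; ``None`` means the alias
    history carries no evidence either way (treated as guide downstream).
    """

    accession: str
    canonical_name: str
    arm: str = "unknown"  # one of {"5p", "3p", "unknown"}
    carrier_strand: bool | None = None


@dataclass
class NomenclatureKey:
    """Bidirectional mapping between name variants and MIMAT accessions."""

    alias_to_accession: dict[str, str]
    accession_to_id: dict[str, MirnaId]
    _misses: list[str] = field(default_factory=list, repr=False)

    def __len__(self) -> int:
        return len(self.accession_to_id)

    def __contains__(self, name: str) -> bool:
        try:
            self.lookup(name)
        except UnknownMirnaError:
            return False
        return True

    def lookup(self, name: str) -> MirnaId:
        return harmonize(name, self)


_ARM_RE = re.compile(r"-(5p|3p)$", re.IGNORECASE)


def _norm(name: str) -> str:
    return name.strip().casefold()


def _candidates(name: str) -> list[str]:
    """Normalized lookup candidates: as-is, then with an ``hsa-`` prefix."""
    n = _norm(name)
    cands = [n]
    if not n.startswith("hsa-"):
        cands.append("hsa-" + n)
    return cands


def _arm_of(name: str) -> str:
    m = _ARM_RE.search(name)
    return m.group(1).lower() if m else "unknown"


def build_key(
    alias_table: Iterable[tuple[str, str]],
    carrier_annotations: Mapping[str, bool] | None = None,
) -> NomenclatureKey:
    """Build a :class:`NomenclatureKey` from (accession, "name;name;...") rows.

    The last listed name is taken as current (the miRBase aliases convention
    orders names oldest to newest).  Carrier-strand status is inferred from
    any ``*``-suffixed alias; an optional per-accession annotation mapping
    overrides the inference.  A name listed under two accessions raises
    :class:`NomenclatureConflictError` naming both.
    """
    alias_to_accession: dict[str, str] = {}
    accession_to_id: dict[str, MirnaId] = {}
    rows = list(alias_table)
    if not rows:
        raise ValueError("alias table is empty")
    for accession, names_field in rows:
        accession = accession.strip()
        names = [n.strip() for n in str(names_field).split(";") if n.strip()]
        if not accession or not names:
            raise ValueError(f"blank accession or name list in row {accession!r}")
        canonical = names[-1]
        starred = any(n.endswith("*") for n in names)
        carrier: bool | None = True if starred else None
        if carrier_annotations and accession in carrier_annotations:
            carrier = bool(carrier_annotations[accession])
        mid = MirnaId(
            accession=accession,
            canonical_name=canonical,
            arm=_arm_of(canonical),
            carrier_strand=carrier,
        )
        if accession in accession_to_id:
            raise ValueError(f"accession {accession} listed twice")
        accession_to_id[accession] = mid
        for name in names:
            norm = _norm(name)
            prior = alias_to_accession.get(norm)
            if prior is not None and prior != accession:
                raise NomenclatureConflictError(
                    f"alias {name!r} claimed by both {prior} and {accession}"
                )
            alias_to_accession[norm] = accession
    return NomenclatureKey(alias_to_accession, accession_to_id)


def read_aliases(path: str | Path) -> list[tuple[str, str]]:
    """Read a miRBase ``aliases.txt``-dialect file.

    Two tab-separated columns: accession, semicolon-separated (and
    conventionally semicolon-terminated) name list.  Tolerates CRLF line
    endings, blank lines and trailing semicolons.  Hairpin (``MI``-prefixed)
    rows are passed through; filtering is the caller's business.
    """
    rows: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            rows.append((parts[0], parts[1]))
    return rows


def harmonize(name: str, key: NomenclatureKey) -> MirnaId:
    """Resolve a free-text microRNA name to its :class:`MirnaId`.

    Case-insensitive; an ``hsa-`` prefix is inserted if the bare name does
    not resolve.  Raises :class:`UnknownMirnaError` for unresolvable names
    (callers in the plausibility layer map that to the "unknown" category).
    """
    if not isinstance(name, str) or not name.strip():
        raise UnknownMirnaError(str(name))
    for cand in _candidates(name):
        acc = key.alias_to_accession.get(cand)
        if acc is not None:
            return key.accession_to_id[acc]
    key._misses.append(name)
    raise UnknownMirnaError(name)
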