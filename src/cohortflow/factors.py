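"""Factor vocabularies: mapping raw diagnosis/procedure codes to named factors.

A *factor* is a single binary criterion (a disease or a procedure) used to
characterise patients.  Factors are defined by code-pattern rules over ICD-9-CM
diagnosis codes and (Taiwan NHI style) procedure codes:

* ``prefix`` — an ICD-9 category such as ``250`` matches itself and every
  child code (``250``, ``2500`` … ``25093``).  Dots and case are ignored.
* ``numeric-range`` — ``430-438`` matches any code whose leading category
  (same digit width as the endpoints) falls in the closed range.
* ``decimal-range`` — ``425.4-425.9`` matches codes interpreted as
  ``category.decimal`` lying in the closed interval; both endpoints must
  share the 3-digit category.
* ``exact`` — procedure codes such as ``58001C`` are terminal identifiers
  and match by string equality only.

The package ships a default chronic-kidney-disease vocabulary
(:func:`default_ckd_map`) with CKD as the index factor.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CodePattern",
    "FactorEntry",
    "FactorMap",
    "normalize_code",
    "parse_code_spec",
    "parse_factor_map",
    "match_code",
    "default_ckd_map",
]

_DASHES = re.compile(r"[-‐‑‒–—]")


def normalize_code(code: str) -> str:
    """Canonical form of a raw code: whitespace and dots stripped, uppercased."""
    return code.replace(".", "").replace(" ", "").strip().upper()


@dataclass(frozen=True)
class CodePattern:
    """One matching rule.  ``kind`` is prefix | numeric-range | decimal-range | exact."""

    kind: str
    payload: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in {"prefix", "numeric-range", "decimal-range", "exact"}:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if not self.payload or any(not p for p in self.payload):
            raise ValueError("empty pattern payload")
        if self.kind == "numeric-range":
            lo, hi = self.payload
            if int(lo) > int(hi):
                raise ValueError(f"malformed range {lo}-{hi} (low > high)")
        if self.kind == "decimal-range":
            lo, hi = self.payload
            if lo[:3] != hi[:3]:
                raise ValueError(f"decimal range {lo}-{hi} spans categories")
            if _decimal_value(lo) > _decimal_value(hi):
                raise ValueError(f"malformed range {lo}-{hi} (low > high)")

    def matches(self, norm: str) -> bool:
        if self.kind == "exact":
            return norm == self.payload[0]
        if self.kind == "prefix":
            return norm.startswith(self.payload[0])
        if self.kind == "numeric-range":
            lo, hi = self.payload
            width = len(lo)
            head = norm[:width]
            if len(head) < width or not head.isdigit():
                return False
            return int(lo) <= int(head) <= int(hi)
        # decimal-range: category must agree, decimal part compared numerically
        lo, hi = self.payload
        if not norm.isdigit() or norm[:3] != lo[:3] or len(norm) < 4:
            return False
        return _decimal_value(lo) <= _decimal_value(norm) <= _decimal_value(hi)

    def spec_token(self) -> str:
        """Round-trippable textual form of the pattern."""
        if self.kind in {"numeric-range", "decimal-range"}:
            lo, hi = self.payload
            if self.kind == "decimal-range":
                lo, hi = _dotted(lo), _dotted(hi)
            return f"{lo}-{hi}"
        return self.payload[0]


def _decimal_value(norm: str) -> float:
    """``4254`` -> 425.4 — a normalized diagnosis code as category.decimal."""
    return float(norm[:3] + "." + (norm[3:] or "0"))


def _dotted(norm: str) -> str:
    return norm[:3] + "." + norm[3:] if len(norm) > 3 else norm


@dataclass(frozen=True)
class FactorEntry:
    name: str
    abbreviation: str
    patterns: tuple[CodePattern, ...]
    kind: str = "diagnosis"  # diagnosis | procedure


@dataclass
class FactorMap:
    """Ordered collection of factor rules plus the index factor defining day 0."""

    entries: list[FactorEntry]
    index_factor: str

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        abbrs = [e.abbreviation for e in self.entries]
        if len(set(names)) != len(names) or len(set(abbrs)) != len(abbrs):
            dup = sorted({n for n in abbrs + names if (abbrs + names).count(n) > 1})
            raise ValueError(f"duplicate factor name(s): {', '.join(dup)}")
        if not self.entries:
            raise ValueError("factor map must define at least one factor")
        if self.index_factor not in set(abbrs) | set(names):
            raise ValueError(f"index factor {self.index_factor!r} not among factors")

    @property
    def factor_names(self) -> list[str]:
        """Canonical factor identifiers (the abbreviations) in table order."""
        return [e.abbreviation for e in self.entries]

    @property
    def procedure_factors(self) -> set[str]:
        return {e.abbreviation for e in self.entries if e.kind == "procedure"}

    def entry(self, factor: str) -> FactorEntry:
        for e in self.entries:
            if factor in (e.abbreviation, e.name):
                return e
        raise KeyError(factor)

    def to_dict(self) -> dict:
        return {
            "index_factor": self.index_factor,
            "factors": [
                {
                    "name": e.name,
                    "abbreviation": e.abbreviation,
                    "codes": ",".join(p.spec_token() for p in e.patterns),
                    "kind": e.kind,
                }
                for e in self.entries
            ],
        }


def parse_code_spec(spec: str, *, row: str = "?") -> tuple[CodePattern, ...]:
    """Split a comma-separated code spec string into patterns.

    Hyphenated tokens become range patterns (numeric or decimal); tokens ending
    in a letter are treated as exact procedure codes; everything else is a
    prefix pattern.
    """
    tokens = [t.strip() for t in spec.split(",")]
    tokens = [t for t in tokens if t]
    if not tokens:
        raise ValueError(f"row {row!r}: empty code spec")
    patterns: list[CodePattern] = []
    for tok in tokens:
        tok = _DASHES.sub("-", tok)
        try:
            if "-" in tok:
                lo, hi = (normalize_code(p) for p in tok.split("-", 1))
                if "." in tok:
                    patterns.append(CodePattern("decimal-range", (lo, hi)))
                else:
                    if not (lo.isdigit() and hi.isdigit()):
                        raise ValueError(f"non-numeric range {tok!r}")
                    patterns.append(CodePattern("numeric-range", (lo, hi)))
            elif tok[-1].isalpha() and any(ch.isdigit() for ch in tok):
                patterns.append(CodePattern("exact", (normalize_code(tok),)))
            else:
                patterns.append(CodePattern("prefix", (normalize_code(tok),)))
        except ValueError as err:
            raise ValueError(f"row {row!r}: {err}") from None
    return tuple(patterns)


def parse_factor_map(config: Mapping | str | Path) -> FactorMap:
    """Build a :class:`FactorMap` from a config document.

    Accepts a mapping (parsed JSON: ``{"index_factor": ..., "factors": [...]}``),
    a path to a ``.json`` file of that shape, or a path to a ``.csv`` file with
    columns ``name, abbreviation, codes`` (optional ``kind``) whose first data
    row's factor is taken as the index factor unless a row has
    ``index`` in an ``index_factor`` column.
    """
    if isinstance(config, (str, Path)):
        path = Path(config)
        if path.suffix.lower() == ".csv":
            config = _read_csv_config(path)
        else:
            config = json.loads(path.read_text())
    rows = config.get("factors")
    if not rows:
        raise ValueError("factor config has no 'factors' entries")
    entries = []
    for row in rows:
        name = (row.get("name") or "").strip()
        if not name:
            raise ValueError(f"factor row without a name: {row!r}")
        abbr = (row.get("abbreviation") or "").strip() or name
        codes = row.get("codes", "")
        if isinstance(codes, (list, tuple)):
            codes = ",".join(str(c) for c in codes)
        patterns = parse_code_spec(str(codes), row=name)
        entries.append(FactorEntry(name, abbr, patterns, row.get("kind", "diagnosis")))
    index = config.get("index_factor") or entries[0].abbreviation
    return FactorMap(entries, index)


def _read_csv_config(path: Path) -> dict:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise ValueError(f"{path}: CSV factor config needs a 'name' column")
        rows = list(reader)
    index = next(
        (r["name"] for r in rows if (r.get("index_factor") or "").strip().lower() in {"1", "true", "index", "yes"}),
        None,
    )
    return {"index_factor": index, "factors": rows}


def match_code(code: str, fm: FactorMap) -> set[str]:
    """Factors whose rules match ``code``; empty set when nothing matches."""
    norm = normalize_code(code)
    if not norm:
        return set()
    return {
        e.abbreviation
        for e in fm.entries
        if any(p.matches(norm) for p in e.patterns)
    }


def default_ckd_map() -> FactorMap:
    """The shipped chronic-kidney-disease factor vocabulary (index factor CKD)."""
    text = resources.files("cohortflow.data").joinpath("ckd_factors.json").read_text()
    return parse_factor_map(json.loads(text))
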