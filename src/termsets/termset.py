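"""Term sets: intensional code set definitions, and their verification.

A term set is the intensional counterpart of a code set: inclusion
terms, exclusion terms, and the name+version of the terminology they are
meant to be executed against.  Evaluating a term set re-derives the
extensional code set:

    M(T, I, E) = f⁻¹( MDE(T, I, E) )

i.e. a code is selected when at least one of its definitions survives
inclusion/exclusion matching.  Because the terminology is pinned by name
and version, the same term set re-executed later either reproduces the
same code set or fails loudly, which is the point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

from .matching import (
    TermPattern,
    matching_definition_set_with_exclusions,
    parse_term,
    term_matches_definition,
)
from .terminology import CodeSet, Terminology

__all__ = [
    "TermSet",
    "VerificationReport",
    "TermSetError",
    "evaluate",
    "unmatched_descendants",
    "verify",
    "load_termset",
    "save_termset",
]


class TermSetError(ValueError):
    pass


@dataclass(frozen=True)
class TermSet:
    """Inclusion terms I, exclusion terms E, pinned terminology."""

    inclusions: tuple[TermPattern, ...]
    exclusions: tuple[TermPattern, ...]
    terminology_name: str
    terminology_version: str
    metadata: dict[str, str] = field(default_factory=dict)
    extra: dict[str, Any] = field(default_factory=dict)  # unknown JSON keys, preserved

    def __post_init__(self) -> None:
        if not self.terminology_name or not self.terminology_version:
            raise TermSetError("a term set must pin a terminology name and version")
        overlap = {p.raw for p in self.inclusions} & {p.raw for p in self.exclusions}
        if overlap:
            raise TermSetError(
                f"terms appear in both inclusions and exclusions: {sorted(overlap)}"
            )

    @classmethod
    def from_strings(
        cls,
        inclusions: Iterable[str],
        exclusions: Iterable[str] = (),
        terminology_name: str = "",
        terminology_version: str = "",
        metadata: dict[str, str] | None = None,
    ) -> "TermSet":
        return cls(
            inclusions=tuple(parse_term(s) for s in inclusions),
            exclusions=tuple(parse_term(s) for s in exclusions),
            terminology_name=terminology_name,
            terminology_version=terminology_version,
            metadata=dict(metadata or {}),
        )

    @property
    def n_terms(self) -> int:
        return len(self.inclusions) + len(self.exclusions)


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of checking a term set against a target code set."""

    matched: frozenset[str]
    missing: frozenset[str]
    extra: frozenset[str]
    unmatched_descendants: frozenset[str]
    excluded_descendants: frozenset[str]  # descendants matching an exclusion term
    closure_violations: tuple[tuple[str, frozenset[str], frozenset[str]], ...]

    @property
    def passed(self) -> bool:
        return not self.missing and not self.extra

    def to_dict(self) -> dict[str, Any]:
        return {
            "pass": self.passed,
            "matched": sorted(self.matched),
            "missing": sorted(self.missing),
            "extra": sorted(self.extra),
            "unmatched_descendants": sorted(self.unmatched_descendants),
            "excluded_descendants": sorted(self.excluded_descendants),
            "closure_violations": [
                {
                    "definition": d,
                    "included": sorted(inc),
                    "omitted": sorted(om),
                }
                for d, inc, om in self.closure_violations
            ],
        }

    def summary(self) -> str:
        lines = [
            f"verification: {'PASS' if self.passed else 'FAIL'}",
            f"  matched codes:         {len(self.matched)}",
            f"  missing (in target):   {len(self.missing)}",
            f"  extra (not in target): {len(self.extra)}",
            f"  unmatched descendants: {len(self.unmatched_descendants)}",
            f"  closure violations:    {len(self.closure_violations)}",
        ]
        for name, codes in (("missing", self.missing), ("extra", self.extra)):
            for c in sorted(codes)[:20]:
                lines.append(f"    {name}: {c}")
        for d, inc, om in self.closure_violations[:20]:
            lines.append(
                f"    shared definition {d!r}: included {sorted(inc)}, omitted {sorted(om)}"
            )
        return "\n".join(lines)


def _check_binding(ts: TermSet, t: Terminology, allow_version_drift: bool) -> None:
    if ts.terminology_name != t.name or ts.terminology_version != t.version:
        msg = (
            f"term set targets {ts.terminology_name!r} {ts.terminology_version!r} "
            f"but terminology is {t.name!r} {t.version!r}"
        )
        if not allow_version_drift:
            raise TermSetError(msg + " (pass allow_version_drift=True to override)")
        warnings.warn(msg + "; evaluating anyway", stacklevel=3)


def evaluate(
    ts: TermSet, t: Terminology, *, allow_version_drift: bool = False
) -> CodeSet:
    """Evaluate a term set into its extensional code set, ``M(T, I, E)``.

    A code is selected when any of its definitions is in
    ``MDE(T, I, E)`` (its other definitions may match nothing, or even
    match an exclusion term).
    """
    _check_binding(ts, t, allow_version_drift)
    mde = matching_definition_set_with_exclusions(t, ts.inclusions, ts.exclusions)
    codes = {c for c in t.codes if any(d in mde for d in t.defs_of(c))}
    return CodeSet(frozenset(codes), t.name, t.version, ts.metadata.get("title", ""))


def unmatched_descendants(
    t: Terminology, matched: CodeSet, inclusions: Sequence[TermPattern]
) -> set[str]:
    """Descendants of matched codes with no definition matching any
    inclusion term.

    These are flagged for explicit review, never auto-included: a child
    code often narrows its parent in a way the author did not intend to
    cover ("family history of X" under "X"), and silent inclusion would
    hide that decision.
    """
    matched.bind_check(t)
    desc: set[str] = set()
    for code in matched.codes:
        desc |= t.descendants(code)
    desc -= matched.codes
    out: set[str] = set()
    for code in desc:
        if not any(
            term_matches_definition(p, d) for d in t.defs_of(code) for p in inclusions
        ):
            out.add(code)
    return out


def _closure_violations(
    t: Terminology, target: CodeSet
) -> tuple[tuple[str, frozenset[str], frozenset[str]], ...]:
    """Definitions shared between an included and an omitted code."""
    seen: set[str] = set()
    out: list[tuple[str, frozenset[str], frozenset[str]]] = []
    for code in sorted(target.codes):
        for d in t.defs_of(code):
            key = d.casefold()
            if key in seen:
                continue
            seen.add(key)
            carriers = t.codes_for_folded(key)
            omitted = carriers - target.codes
            if omitted:
                out.append(
                    (d, frozenset(carriers & target.codes), frozenset(omitted))
                )
    return tuple(out)


def verify(
    ts: TermSet,
    t: Terminology,
    target: CodeSet,
    *,
    allow_version_drift: bool = False,
) -> VerificationReport:
    """Compare the evaluation of ``ts`` with an intended target code set."""
    target.bind_check(t)
    result = evaluate(ts, t, allow_version_drift=allow_version_drift)
    matched = result.codes
    desc_unmatched = unmatched_descendants(t, result, ts.inclusions)
    desc_excluded = {
        c
        for c in desc_unmatched
        if any(
            term_matches_definition(p, d)
            for d in t.defs_of(c)
            for p in ts.exclusions
        )
    }
    return VerificationReport(
        matched=frozenset(matched),
        missing=frozenset(target.codes - matched),
        extra=frozenset(matched - target.codes),
        unmatched_descendants=frozenset(desc_unmatched - desc_excluded),
        excluded_descendants=frozenset(desc_excluded),
        closure_violations=_closure_violations(t, target),
    )


# ----------------------------------------------------------------------
# JSON I/O
#
# {"name": ..., "title": ..., "description": ..., "author": ...,
#  "terminology": {"name": ..., "version": ...},
#  "include": [...], "exclude": [...]}

_META_KEYS = ("name", "title", "description", "author")


def load_termset(path: str) -> TermSet:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if "include" not in doc:
        raise TermSetError(f"{path!r}: term set file lacks an 'include' list")
    term = doc.get("terminology") or {}
    if not term.get("name") or not term.get("version"):
        raise TermSetError(f"{path!r}: terminology name and version are required")
    metadata = {k: doc[k] for k in _META_KEYS if k in doc}
    if not metadata:
        warnings.warn(f"{path!r}: no descriptive metadata (name/title/description)")
    known = set(_META_KEYS) | {"terminology", "include", "exclude"}
    extra = {k: v for k, v in doc.items() if k not in known}
    return TermSet(
        inclusions=tuple(parse_term(s) for s in doc["include"]),
        exclusions=tuple(parse_term(s) for s in doc.get("exclude", [])),
        terminology_name=term["name"],
        terminology_version=term["version"],
        metadata=metadata,
        extra=extra,
    )


def save_termset(ts: TermSet, path: str) -> None:
    doc: dict[str, Any] = {}
    for k in _META_KEYS:
        if k in ts.metadata:
            doc[k] = ts.metadata[k]
    doc["terminology"] = {
        "name": ts.terminology_name,
        "version": ts.terminology_version,
    }
    doc["include"] = [p.raw for p in ts.inclusions]
    doc["exclude"] = [p.raw for p in ts.exclusions]
    doc.update(ts.extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, ensure_ascii=False)
        fh.write("\n")
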