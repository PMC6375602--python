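"""Clinical code terminologies: codes, definitions, hierarchy.

A terminology is modelled as a triple ``T = (C, D, f)``: a set of codes
``C``, a set of textual definitions ``D``, and a surjective mapping ``f``
assigning each code one or more definitions.  Because ``f`` is surjective
the inverse ``f⁻¹`` exists for every definition and maps it back to the
(possibly several) codes that carry it.  A hierarchy is represented by a
partial parent relation; for Read-v2-style terminologies the parent is
implicit in the code string itself (``G30``'s parent is ``G3``).
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

__all__ = [
    "Terminology",
    "CodeSet",
    "TerminologyError",
    "load_terminology",
    "save_terminology",
    "load_codeset",
    "save_codeset",
    "generate_synthetic_terminology",
]

Dialect = Literal["generic-parent", "read-prefix"]

_WS_RUN = re.compile(r"\s+")


class TerminologyError(ValueError):
    """Malformed terminology input (empty file, bad rows, parent cycles)."""


def normalize_definition(text: str) -> str:
    """Collapse internal whitespace runs and trim; case is preserved."""
    return _WS_RUN.sub(" ", text).strip()


@dataclass(frozen=True)
class Terminology:
    """A clinical code terminology ``T = (C, D, f)`` plus hierarchy.

    ``code_to_defs`` is ``f``: each code maps to an ordered tuple of one or
    more whitespace-normalized definition strings.  ``parent`` holds the
    hierarchy where known; root codes are absent from it.
    """

    name: str
    version: str
    code_to_defs: Mapping[str, tuple[str, ...]]
    parent: Mapping[str, str] = field(default_factory=dict)
    dialect: Dialect = "generic-parent"

    def __post_init__(self) -> None:
        if not self.name or not self.version:
            raise TerminologyError("terminology name and version must be non-empty")
        for code, defs in self.code_to_defs.items():
            if not defs:
                raise TerminologyError(f"code {code!r} has no definitions")
        # Materialize f⁻¹ and children once; the dataclass is frozen so
        # these stay consistent with f for the object's lifetime.
        inv: dict[str, set[str]] = {}
        for code, defs in self.code_to_defs.items():
            for d in defs:
                inv.setdefault(d, set()).add(code)
        object.__setattr__(self, "_inverse", inv)
        children: dict[str, set[str]] = {}
        for child, par in self.parent.items():
            if par not in self.code_to_defs:
                raise TerminologyError(f"parent {par!r} of {child!r} is not a known code")
            children.setdefault(par, set()).add(child)
        object.__setattr__(self, "_children", children)
        _check_acyclic(self.parent)
        # Case-folded definition index used by matching and closure.
        folded: dict[str, set[str]] = {}
        for d in inv:
            folded.setdefault(d.casefold(), set()).add(d)
        object.__setattr__(self, "_folded_defs", folded)

    # -- basic views -------------------------------------------------

    @property
    def codes(self) -> frozenset[str]:
        return frozenset(self.code_to_defs)

    @property
    def definitions(self) -> frozenset[str]:
        return frozenset(self._inverse)  # type: ignore[attr-defined]

    def defs_of(self, code: str) -> tuple[str, ...]:
        """``f(code)``."""
        try:
            return self.code_to_defs[code]
        except KeyError:
            raise TerminologyError(f"unknown code {code!r}") from None

    def inverse_lookup(self, definition: str) -> set[str]:
        """``f⁻¹(definition)``: all codes carrying it; empty if unknown."""
        return set(self._inverse.get(normalize_definition(definition), ()))  # type: ignore[attr-defined]

    def codes_for_folded(self, folded_definition: str) -> set[str]:
        """All codes carrying any definition whose case-folded text matches."""
        out: set[str] = set()
        for d in self._folded_defs.get(folded_definition, ()):  # type: ignore[attr-defined]
            out |= self._inverse[d]  # type: ignore[attr-defined]
        return out

    # -- hierarchy ---------------------------------------------------

    def children(self, code: str) -> set[str]:
        if code not in self.code_to_defs:
            raise TerminologyError(f"unknown code {code!r}")
        return set(self._children.get(code, ()))  # type: ignore[attr-defined]

    def descendants(self, code: str) -> set[str]:
        """Transitive closure of the child relation, excluding ``code``."""
        out: set[str] = set()
        stack = list(self.children(code))
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(self._children.get(c, ()))  # type: ignore[attr-defined]
        return out


def _check_acyclic(parent: Mapping[str, str]) -> None:
    seen_done: set[str] = set()
    for start in parent:
        trail: set[str] = set()
        c: str | None = start
        while c is not None and c not in seen_done:
            if c in trail:
                raise TerminologyError(f"cycle in parent relation involving {c!r}")
            trail.add(c)
            c = parent.get(c)
        seen_done |= trail


@dataclass(frozen=True)
class CodeSet:
    """An extensional code set: an explicit subset ``X ⊆ C``."""

    codes: frozenset[str]
    terminology_name: str = ""
    terminology_version: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", frozenset(self.codes))

    def __len__(self) -> int:
        return len(self.codes)

    def bind_check(self, t: Terminology) -> None:
        unknown = self.codes - t.codes
        if unknown:
            raise TerminologyError(
                f"code set contains {len(unknown)} codes not in terminology "
                f"{t.name} {t.version}: {sorted(unknown)[:5]}"
            )


# ----------------------------------------------------------------------
# Module-level operations (thin wrappers so the functional surface matches
# the class-based one)


def inverse_lookup(t: Terminology, definition: str) -> set[str]:
    return t.inverse_lookup(definition)


def descendants(t: Terminology, code: str) -> set[str]:
    return t.descendants(code)


def definition_closure(t: Terminology, x: CodeSet) -> tuple[CodeSet, set[str]]:
    """Close ``x`` under shared definitions.

    If any code in ``x`` carries a definition ``d``, every code in
    ``f⁻¹(d)`` joins the result, iterated to a fixpoint.  Definitions are
    compared case-folded, consistent with the case-insensitive matching
    semantics.  Returns the closed code set and the codes that were added.
    """
    x.bind_check(t)
    closed = set(x.codes)
    frontier = set(closed)
    while frontier:
        nxt: set[str] = set()
        for code in frontier:
            for d in t.defs_of(code):
                nxt |= t.codes_for_folded(d.casefold())
        frontier = nxt - closed
        closed |= nxt
    return (
        CodeSet(frozenset(closed), t.name, t.version, x.label),
        closed - set(x.codes),
    )


# ----------------------------------------------------------------------
# File I/O

def _read_prefix_parents(codes: Iterable[str], pad: str = ".") -> dict[str, str]:
    """Derive parents for Read-style prefix codes padded with ``pad``.

    The parent of a code is its longest proper prefix (padding stripped)
    that is itself a code, re-padded form.
    """
    stripped_to_code = {c.rstrip(pad): c for c in codes}
    parent: dict[str, str] = {}
    for s, code in stripped_to_code.items():
        for k in range(len(s) - 1, 0, -1):
            p = s[:k]
            if p in stripped_to_code:
                parent[code] = stripped_to_code[p]
                break
    return parent


def load_terminology(
    path: str,
    dialect: Dialect = "generic-parent",
    *,
    name: str | None = None,
    version: str | None = None,
) -> Terminology:
    """Load a terminology from a UTF-8 TSV file.

    Columns: ``code``, ``definition``, optional ``parent``.  One row per
    (code, definition) pair, so a code with several synonymous definitions
    occupies several rows.  A header row is recognised if its first cell is
    literally ``code``.  Two comment pragmas, ``#name:`` and ``#version:``,
    may set the terminology identity; the *name*/*version* arguments
    override them.
    """
    code_to_defs: dict[str, list[str]] = {}
    parent: dict[str, str] = {}
    meta = {"name": "unnamed", "version": "0"}
    seen_pairs: set[tuple[str, str]] = set()
    n_rows = 0
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for i, row in enumerate(reader):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            first = row[0].strip()
            if first.startswith("#"):
                m = re.match(r"#\s*(name|version)\s*:\s*(.+)", first, re.I)
                if m:
                    meta[m.group(1).lower()] = m.group(2).strip()
                continue
            if i == 0 and first.lower() == "code":
                continue  # header
            if len(row) < 2:
                raise TerminologyError(f"row {i + 1}: expected code<TAB>definition")
            code = first
            definition = normalize_definition(row[1])
            if not code:
                raise TerminologyError(f"row {i + 1}: empty code")
            if not definition:
                raise TerminologyError(f"row {i + 1}: empty definition for code {code!r}")
            n_rows += 1
            if (code, definition) in seen_pairs:
                warnings.warn(
                    f"duplicate row for ({code!r}, {definition!r}); deduplicated",
                    stacklevel=2,
                )
                continue
            seen_pairs.add((code, definition))
            code_to_defs.setdefault(code, []).append(definition)
            if len(row) > 2 and row[2].strip():
                parent[code] = row[2].strip()
    if n_rows == 0:
        raise TerminologyError(f"no rows in terminology file {path!r}")
    if dialect == "read-prefix":
        parent = _read_prefix_parents(code_to_defs)
    return Terminology(
        name=name or meta["name"],
        version=version or meta["version"],
        code_to_defs={c: tuple(ds) for c, ds in code_to_defs.items()},
        parent=parent,
        dialect=dialect,
    )


def save_terminology(t: Terminology, path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"#name: {t.name}\n#version: {t.version}\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for code in sorted(t.code_to_defs):
            for d in t.code_to_defs[code]:
                if t.dialect == "read-prefix":
                    w.writerow([code, d])
                else:
                    w.writerow([code, d, t.parent.get(code, "")])


def load_codeset(path: str) -> CodeSet:
    """Read a plain-text code set: one code per line, ``#`` comments.

    ``# label:``, ``# terminology:`` and ``# version:`` comment pragmas
    populate the metadata fields.
    """
    codes: set[str] = set()
    meta = {"label": "", "terminology": "", "version": ""}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(label|terminology|version)\s*:\s*(.+)", line, re.I)
                if m:
                    meta[m.group(1).lower()] = m.group(2).strip()
                continue
            codes.add(line)
    return CodeSet(frozenset(codes), meta["terminology"], meta["version"], meta["label"])


def save_codeset(x: CodeSet, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if x.label:
            fh.write(f"# label: {x.label}\n")
        if x.terminology_name:
            fh.write(f"# terminology: {x.terminology_name}\n")
        if x.terminology_version:
            fh.write(f"# version: {x.terminology_version}\n")
        for code in sorted(x.codes):
            fh.write(code + "\n")


# ----------------------------------------------------------------------
# Synthetic terminology generator
#
# Emulates the structure that makes real terminologies hard to search:
# a prefix hierarchy, synonymous definitions for one code, distinct codes
# sharing one definition, and modifier phrases ("family history of X")
# that create genuine inclusion/exclusion ambiguity.  Uses a fixed word
# list rather than random strings so bag-of-words terms collide the way
# they do in practice.

_BASE_CONDITIONS = [
    "fracture", "stroke", "diabetes", "asthma", "dementia", "infection",
    "arthritis", "hypertension", "anaemia", "eczema", "migraine", "angina",
    "epilepsy", "psoriasis", "glaucoma", "hepatitis", "pneumonia",
    "bronchitis", "nephritis", "dermatitis", "cataract", "thrombosis",
    "embolism", "sepsis", "ulcer", "hernia", "cirrhosis", "fibrosis",
    "neuropathy", "retinopathy",
]

_SITES = [
    "shoulder", "hip", "knee", "ankle", "wrist", "cardiac", "renal",
    "hepatic", "pulmonary", "cerebral", "femoral", "lumbar", "cervical",
    "gastric", "ocular",
]

_QUALIFIERS = ["acute", "chronic", "recurrent", "severe", "mild", "unspecified"]

DEFAULT_MODIFIER_TEMPLATES = [
    "family history of {x}",
    "history of {x}",
    "{x} screening",
    "{x} monitoring",
    "{x} NOS",
    "suspected {x}",
    "{x} resolved",
    "{x} annual review",
]

_SYNONYM_SUFFIXES = ["(disorder)", "(finding)", "syndrome", "disease"]

_CODE_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"


def generate_synthetic_terminology(
    n_roots: int = 8,
    depth: int = 3,
    branching: int = 3,
    synonym_prob: float = 0.15,
    duplicate_def_prob: float = 0.05,
    modifier_templates: list[str] | None = None,
    seed: int = 0,
    name: str = "synthread",
    version: str = "1.0",
) -> Terminology:
    """Build a deterministic Read-prefix-style synthetic terminology.

    Roots receive a core phrase drawn from a clinical word list (e.g.
    "shoulder fracture"); each child applies a modifier template to its
    parent's core phrase ("family history of shoulder fracture") or
    specialises it with a qualifier.  With probability *synonym_prob* a
    code gains a second, synonymous definition; with probability
    *duplicate_def_prob* a non-root code re-uses another code's definition
    verbatim, producing the shared-definition situation that the closure
    audit exists for.
    """
    if n_roots < 1 or depth < 1 or branching < 1:
        raise ValueError("n_roots, depth and branching must be positive")
    for p in (synonym_prob, duplicate_def_prob):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    templates = list(modifier_templates or DEFAULT_MODIFIER_TEMPLATES)
    rng = __import__("random").Random(seed)

    width = depth  # code length: 1 char per level, '.'-padded
    code_to_defs: dict[str, tuple[str, ...]] = {}
    core_phrase: dict[str, str] = {}  # stripped code -> phrase modifiers build on
    used_defs_folded: set[str] = set()
    all_defs: list[str] = []

    def register(code: str, defs: list[str]) -> None:
        code_to_defs[code] = tuple(defs)
        for d in defs:
            if d.casefold() not in used_defs_folded:
                used_defs_folded.add(d.casefold())
                all_defs.append(d)

    def fresh(candidates: list[str]) -> str | None:
        for c in candidates:
            if normalize_definition(c).casefold() not in used_defs_folded:
                return normalize_definition(c)
        return None

    def make_unique(base: str) -> str:
        cand = fresh([base])
        if cand:
            return cand
        for q in _QUALIFIERS + _SYNONYM_SUFFIXES:
            cand = fresh([f"{q} {base}", f"{base} {q}"])
            if cand:
                return cand
        i = 2
        while True:
            cand = fresh([f"{base} type {i}"])
            if cand:
                return cand
            i += 1

    def maybe_synonym(definition: str) -> list[str]:
        defs = [definition]
        if rng.random() < synonym_prob:
            suffix = rng.choice(_SYNONYM_SUFFIXES)
            defs.append(make_unique(f"{definition} {suffix}"))
        return defs

    # roots
    roots: list[str] = []
    for r in range(n_roots):
        stripped = _CODE_ALPHABET[r % len(_CODE_ALPHABET)]
        if r >= len(_CODE_ALPHABET):  # beyond 36 roots: two-char roots
            stripped = _CODE_ALPHABET[r % len(_CODE_ALPHABET)] + str(r)
        code = stripped.ljust(width, ".")
        cond = _BASE_CONDITIONS[r % len(_BASE_CONDITIONS)]
        if rng.random() < 0.5:
            phrase = f"{rng.choice(_SITES)} {cond}"
        else:
            phrase = cond
        definition = make_unique(phrase.capitalize())
        core_phrase[stripped] = phrase
        register(code, maybe_synonym(definition))
        roots.append(stripped)

    # children, breadth-first by level
    level = list(roots)
    for _ in range(depth - 1):
        next_level: list[str] = []
        for parent_stripped in level:
            for b in range(branching):
                stripped = parent_stripped + _CODE_ALPHABET[b]
                code = stripped.ljust(width, ".")
                if rng.random() < duplicate_def_prob and all_defs:
                    # verbatim duplicate of an existing definition
                    dup = rng.choice(all_defs)
                    register(code, [dup])
                    core_phrase[stripped] = core_phrase[parent_stripped]
                    next_level.append(stripped)
                    continue
                base = core_phrase[parent_stripped]
                if rng.random() < 0.5:
                    phrase = rng.choice(templates).format(x=base)
                else:
                    phrase = f"{rng.choice(_QUALIFIERS)} {base}"
                definition = make_unique(phrase[0].upper() + phrase[1:])
                core_phrase[stripped] = base
                register(code, maybe_synonym(definition))
                next_level.append(stripped)
        level = next_level

    return Terminology(
        name=name,
        version=version,
        code_to_defs=code_to_defs,
        parent=_read_prefix_parents(code_to_defs),
        dialect="read-prefix",
    )
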