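"""Term parsing and the search rules.

A term is a short natural-language word sequence used to select code
definitions.  Matching is governed by six rules:

1. case insensitive;
2. bag-of-words terms match their words in any order;
3. all words of a term must be present in the definition;
4. a term wrapped in double quotes matches only as a contiguous phrase;
5. a trailing ``*`` turns a word into a prefix wildcard;
6. a definition exactly equal to an inclusion term can never be excluded.

Rules 1-5 live in :func:`term_matches_definition`; rule 6 is the
protected stratum ``W ∩ D`` of
:func:`matching_definition_set_with_exclusions`:

    MD(T, W)      = ⋃ᵢ { d ∈ D : wᵢ matches d }
    MDE(T, W, E)  = [W ∩ D] ∪ [MD(T, W) ∩ MD(T, E)ᶜ]

Terminology-wide queries go through a small inverted index (word →
definitions) built lazily per terminology; the per-definition predicate
:func:`term_matches_definition` is the semantic ground truth the index
path must, and does, agree with.
"""

from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Literal

from .terminology import Terminology, normalize_definition

__all__ = [
    "TermPattern",
    "TermParseError",
    "tokenize",
    "parse_term",
    "term_matches_definition",
    "matching_definition_set",
    "matching_definition_set_with_exclusions",
    "definition_match_keys",
    "exact_definition_matches",
]

_TOKEN = re.compile(r"[0-9a-z]+")
_PATTERN_TOKEN = re.compile(r"[0-9a-z]+\*?")


class TermParseError(ValueError):
    """A term string uses syntax the search rules do not define."""


def tokenize(text: str) -> list[str]:
    """Case-folded word tokens; any run of non-alphanumerics is a boundary.

    >>> tokenize("Diabetes, type 2")
    ['diabetes', 'type', '2']
    >>> tokenize("Fracture of shoulder")
    ['fracture', 'of', 'shoulder']
    >>> tokenize("")
    []
    """
    return _TOKEN.findall(text.casefold())


@dataclass(frozen=True)
class TermPattern:
    """One parsed inclusion or exclusion term.

    ``tokens`` holds ``(word, is_wildcard)`` pairs; a wildcard word
    matches any definition token it is a prefix of.  ``raw`` is the term
    exactly as authored, so serialisation is a bit-exact round trip.
    """

    raw: str
    kind: Literal["bag-of-words", "quoted-phrase"]
    tokens: tuple[tuple[str, bool], ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise TermParseError(f"term {self.raw!r} contains no words")

    @property
    def exact_key(self) -> str:
        """Case-folded, whitespace-normalized text used for the
        exact-match-protection comparison (quotes stripped)."""
        body = self.raw.strip()
        if self.kind == "quoted-phrase":
            body = body[1:-1]
        return normalize_definition(body).casefold()


def parse_term(raw: str) -> TermPattern:
    """Parse a term string as authored in a term set.

    >>> parse_term("type 2 diabetes").kind
    'bag-of-words'
    >>> parse_term('"type 2 diabetes"').kind
    'quoted-phrase'
    >>> parse_term("diabet*").tokens
    (('diabet', True),)
    """
    stripped = raw.strip()
    if not stripped:
        raise TermParseError("blank term")
    quoted = len(stripped) >= 2 and stripped[0] == '"' and stripped[-1] == '"'
    body = stripped[1:-1] if quoted else stripped
    if quoted and "*" in body:
        raise TermParseError(
            f"term {raw!r}: wildcard inside a quoted phrase is not defined"
        )
    folded = body.casefold()
    # a '*' is legal only at the tail of a word
    for m in re.finditer(r"\*", folded):
        i = m.start()
        before = folded[i - 1] if i else ""
        after = folded[i + 1] if i + 1 < len(folded) else ""
        if not before.isalnum() or after.isalnum() or after == "*":
            raise TermParseError(f"term {raw!r}: unsupported wildcard position")
    toks = tuple(
        (t[:-1], True) if t.endswith("*") else (t, False)
        for t in _PATTERN_TOKEN.findall(folded)
    )
    if not toks:
        raise TermParseError(f"term {raw!r} contains no words")
    return TermPattern(raw=raw, kind="quoted-phrase" if quoted else "bag-of-words", tokens=toks)


# ----------------------------------------------------------------------
# Single-definition predicate (rules 1-5)


def _token_matches(pattern_word: str, wildcard: bool, def_token: str) -> bool:
    return def_token.startswith(pattern_word) if wildcard else def_token == pattern_word


def _bag_matches(tokens: tuple[tuple[str, bool], ...], def_tokens: list[str]) -> bool:
    """Every pattern token consumes a distinct definition-token position.

    Multiset semantics: [pain pain] needs "pain" at two positions.  The
    assignment is found by backtracking, scarcest pattern tokens first;
    terms and definitions are a handful of words so this is never costly.
    """
    if len(tokens) > len(def_tokens):
        return False
    cands: list[list[int]] = []
    for word, wild in tokens:
        c = [i for i, dt in enumerate(def_tokens) if _token_matches(word, wild, dt)]
        if not c:
            return False
        cands.append(c)
    order = sorted(range(len(cands)), key=lambda k: len(cands[k]))
    used: set[int] = set()

    def assign(k: int) -> bool:
        if k == len(order):
            return True
        for i in cands[order[k]]:
            if i not in used:
                used.add(i)
                if assign(k + 1):
                    return True
                used.discard(i)
        return False

    return assign(0)


def _phrase_matches(tokens: tuple[tuple[str, bool], ...], def_tokens: list[str]) -> bool:
    words = [w for w, _ in tokens]
    n = len(words)
    return any(def_tokens[i : i + n] == words for i in range(len(def_tokens) - n + 1))


def term_matches_definition(p: TermPattern, definition: str) -> bool:
    """Apply the search rules to one definition.

    >>> term_matches_definition(parse_term("fracture"), "Shoulder fracture")
    True
    >>> term_matches_definition(parse_term("type 2 diabetes"), "Type 1 diabetes")
    False
    >>> term_matches_definition(parse_term('"type 2 diabetes"'), "Diabetes, type 2")
    False
    >>> term_matches_definition(parse_term("diabet*"), "Diabetic patient")
    True
    """
    def_tokens = tokenize(definition)
    if p.kind == "quoted-phrase":
        return _phrase_matches(p.tokens, def_tokens)
    return _bag_matches(p.tokens, def_tokens)


# ----------------------------------------------------------------------
# Terminology-wide queries via an inverted index
#
# Definitions are keyed by their case-folded text; two definitions that
# differ only in case tokenize identically, so they always match the
# same terms and can share one index entry.


@dataclass(frozen=True)
class _MatchIndex:
    key_tokens: dict[str, list[str]]          # folded def -> token list
    postings: dict[str, set[str]]             # word -> folded defs containing it
    words: list[str]                          # sorted vocabulary, for wildcards
    key_to_displays: dict[str, list[str]]     # folded def -> stored spellings


def _index(t: Terminology) -> _MatchIndex:
    idx = getattr(t, "_match_index", None)
    if idx is None:
        key_tokens: dict[str, list[str]] = {}
        postings: dict[str, set[str]] = {}
        key_to_displays: dict[str, list[str]] = {}
        for d in sorted(t.definitions):
            k = d.casefold()
            key_to_displays.setdefault(k, []).append(d)
            if k not in key_tokens:
                toks = tokenize(k)
                key_tokens[k] = toks
                for w in set(toks):
                    postings.setdefault(w, set()).add(k)
        idx = _MatchIndex(key_tokens, postings, sorted(postings), key_to_displays)
        object.__setattr__(t, "_match_index", idx)
    return idx


def definition_match_keys(t: Terminology, p: TermPattern) -> frozenset[str]:
    """Case-folded definitions of ``t`` matched by one pattern."""
    idx = _index(t)
    sets: list[set[str]] = []
    for word, wild in p.tokens:
        if wild:
            s: set[str] = set()
            i = bisect_left(idx.words, word)
            while i < len(idx.words) and idx.words[i].startswith(word):
                s |= idx.postings[idx.words[i]]
                i += 1
        else:
            s = idx.postings.get(word, set())
        if not s:
            return frozenset()
        sets.append(s)
    sets.sort(key=len)
    cands = set(sets[0]).intersection(*sets[1:]) if len(sets) > 1 else set(sets[0])
    if p.kind == "quoted-phrase":
        return frozenset(k for k in cands if _phrase_matches(p.tokens, idx.key_tokens[k]))
    words = [w for w, _ in p.tokens]
    if len(set(words)) == len(words) and all(not wild for _, wild in p.tokens):
        return frozenset(cands)  # distinct plain words: presence ⇒ distinct positions
    return frozenset(k for k in cands if _bag_matches(p.tokens, idx.key_tokens[k]))


def _displays(t: Terminology, keys: Iterable[str]) -> set[str]:
    idx = _index(t)
    out: set[str] = set()
    for k in keys:
        out.update(idx.key_to_displays[k])
    return out


def matching_definition_set(
    t: Terminology, patterns: Iterable[TermPattern]
) -> set[str]:
    """``MD(T, W)``: definitions matched by at least one pattern."""
    keys: set[str] = set()
    for p in patterns:
        keys |= definition_match_keys(t, p)
    return _displays(t, keys)


def exact_definition_matches(
    t: Terminology, patterns: Iterable[TermPattern]
) -> set[str]:
    """``W ∩ D``: definitions whose normalized case-folded text equals the
    text of some pattern as authored (quotes stripped)."""
    idx = _index(t)
    out: set[str] = set()
    for p in patterns:
        out.update(idx.key_to_displays.get(p.exact_key, ()))
    return out


def matching_definition_set_with_exclusions(
    t: Terminology,
    inclusions: Iterable[TermPattern],
    exclusions: Iterable[TermPattern],
) -> set[str]:
    """``MDE(T, W, E)``: included definitions minus excluded ones, except
    that a definition exactly equal to an inclusion term survives any
    exclusion."""
    incl = list(inclusions)
    excl = list(exclusions)
    md_w = matching_definition_set(t, incl)
    if not excl:
        return md_w
    md_e = matching_definition_set(t, excl)
    return exact_definition_matches(t, incl) | (md_w - md_e)
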