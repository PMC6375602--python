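"""Convert a code set into an exactly-equivalent term set.

Two constructions are provided.  The *trivial* construction mirrors the
completeness argument: include an exact term for every definition of
every in-set code, then exclude, again by exact term, every other
definition those inclusion terms happen to match.  Exact inclusion
terms sit in the protected stratum of MDE, so no exclusion can touch
them, and the result is equal to the input code set by construction.

The *greedy* construction searches for a much shorter term set: it
enumerates candidate terms (word n-grams, quoted phrases and wildcard
prefixes drawn from the in-set definitions), repeatedly picks the
candidate covering the most not-yet-covered in-set definitions net of
the out-of-set definitions it drags in, then picks exclusion terms to
eliminate that spill.  Both phases fall back to exact-definition terms,
so termination and exactness are guaranteed; minimality is not (set
cover is NP-hard, and a human reviewer still reads the result), but the
greedy result never has more terms than the trivial one.

Both require the input to be *definition-closed*: when several codes
share one definition, a term set cannot separate them, so they must be
all in or all out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal

from .matching import (
    TermParseError,
    TermPattern,
    definition_match_keys,
    parse_term,
)
from .terminology import CodeSet, Terminology, definition_closure, normalize_definition
from .termset import TermSet, VerificationReport, verify

__all__ = [
    "BuildConfig",
    "BuildResult",
    "BuildError",
    "trivial_termset",
    "candidate_patterns",
    "greedy_minimize",
    "build_termset",
]


class BuildError(ValueError):
    pass


@dataclass(frozen=True)
class BuildConfig:
    """Knobs for term-set construction.

    max_ngram
        Longest candidate term, in words.  3 keeps the candidate pool
        small while still capturing phrases like "type 2 diabetes".
    allow_wildcards
        Offer trailing-wildcard candidates (``diabet*``) built from word
        prefixes of at least min_prefix characters.
    closure_mode
        "extend": silently close the input under shared definitions and
        record the added codes; "error": refuse non-closed input.
    spill_penalty
        λ in the greedy score (in-set definitions newly covered minus
        λ × out-of-set definitions newly spilled).  1.0 weighs a needed
        exclusion term the same as a saved inclusion term.
    """

    max_ngram: int = 3
    allow_wildcards: bool = True
    closure_mode: Literal["extend", "error"] = "extend"
    spill_penalty: float = 1.0
    min_prefix: int = 4
    tie_break: str = "words-length-lex"

    def __post_init__(self) -> None:
        if self.max_ngram < 1:
            raise BuildError("max_ngram must be >= 1")
        if self.min_prefix < 1:
            raise BuildError("min_prefix must be >= 1")


@dataclass(frozen=True)
class BuildResult:
    termset: TermSet
    added_by_closure: frozenset[str]
    compression: float  # 100·(|I|+|E|)/|X|, 1 decimal
    report: VerificationReport | None = None
    review: tuple[tuple[str, str, tuple[str, ...]], ...] = field(default_factory=tuple)
    # review rows: (term as authored, role, definitions it gained/eliminated)


def round1_half_up(value: float | Decimal) -> float:
    return float(Decimal(str(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def compression_pct(n_terms: int, n_codes: int) -> float:
    if n_codes < 1:
        raise BuildError("code set is empty")
    return round1_half_up(Decimal(100 * n_terms) / Decimal(n_codes))


# ----------------------------------------------------------------------
# helpers


def _exact_term(display_def: str) -> TermPattern:
    """An inclusion/exclusion term whose text is the definition itself.

    Such a term always matches its own definition and, when used for
    inclusion, is protected from every exclusion term.
    """
    try:
        p = parse_term(display_def)
    except TermParseError as e:
        raise BuildError(
            f"definition {display_def!r} cannot be written as an exact term: {e}"
        ) from e
    if p.exact_key != normalize_definition(display_def).casefold():
        raise BuildError(
            f"definition {display_def!r} cannot be written as an exact term "
            "(its text parses as term syntax)"
        )
    return p


def _in_set_definitions(t: Terminology, x: CodeSet) -> dict[str, str]:
    """folded key -> one stored spelling, for every definition of ``x``."""
    out: dict[str, str] = {}
    for code in sorted(x.codes):
        for d in t.defs_of(code):
            out.setdefault(d.casefold(), d)
    return out


def _require_closed(t: Terminology, x: CodeSet) -> None:
    _, added = definition_closure(t, x)
    if added:
        raise BuildError(
            f"code set is not definition-closed: codes {sorted(added)[:5]} share "
            "definitions with members; apply definition_closure first or use "
            "closure_mode='extend'"
        )


# ----------------------------------------------------------------------
# trivial construction


def trivial_termset(x: CodeSet, t: Terminology) -> TermSet:
    """The constructive proof that every (closed) code set has a term set.

    I = one exact term per definition of every code in X; E = one exact
    term per out-of-set definition any inclusion term also matches.
    ``evaluate`` of the result equals X exactly.
    """
    x.bind_check(t)
    _require_closed(t, x)
    in_defs = _in_set_definitions(t, x)
    inclusions = tuple(_exact_term(in_defs[k]) for k in sorted(in_defs))
    spilled: set[str] = set()
    for p in inclusions:
        spilled |= definition_match_keys(t, p)
    spilled -= set(in_defs)
    from .matching import _index  # one spelling per folded key

    idx = _index(t)
    exclusions = tuple(_exact_term(idx.key_to_displays[k][0]) for k in sorted(spilled))
    return TermSet(
        inclusions=inclusions,
        exclusions=exclusions,
        terminology_name=t.name,
        terminology_version=t.version,
        metadata={"title": x.label} if x.label else {},
    )


# ----------------------------------------------------------------------
# candidate generation


def candidate_patterns(defs: set[str] | list[str], cfg: BuildConfig) -> list[TermPattern]:
    """Candidate terms drawn from a set of definitions.

    All contiguous word n-grams (n ≤ max_ngram) as bag-of-words terms;
    the same n-grams (n ≥ 2) as quoted phrases; and, if enabled, proper
    word prefixes of length ≥ min_prefix as single wildcard terms.
    Deduplicated and deterministically ordered.
    """
    from .matching import tokenize

    raws: set[str] = set()
    for d in sorted(set(defs)):
        toks = tokenize(d)
        for n in range(1, cfg.max_ngram + 1):
            for i in range(len(toks) - n + 1):
                gram = " ".join(toks[i : i + n])
                raws.add(gram)
                if n >= 2:
                    raws.add(f'"{gram}"')
        if cfg.allow_wildcards:
            for w in set(toks):
                for k in range(cfg.min_prefix, len(w)):
                    raws.add(w[:k] + "*")
    pats = [parse_term(r) for r in sorted(raws)]
    pats.sort(key=_tie_key)
    return pats


def _tie_key(p: TermPattern) -> tuple[int, int, int, str]:
    # fewer words, then no wildcards (they creep as dictionaries grow),
    # then shorter, then lexicographic: fully deterministic
    n_wild = sum(1 for _, wild in p.tokens if wild)
    return (len(p.tokens), n_wild, len(p.raw), p.raw)


# ----------------------------------------------------------------------
# greedy minimization


def greedy_minimize(x: CodeSet, t: Terminology, cfg: BuildConfig = BuildConfig()) -> BuildResult:
    """Build a compact term set exactly equivalent to ``x``.

    The loop invariantly maintains exactness: any in-set definition a
    chosen exclusion term might touch is first promoted to an exact
    (hence protected) inclusion term, and any spill the promotion causes
    is queued for exclusion in turn.  The fall-back to exact-definition
    terms guarantees termination; if the greedy outcome ever ends up
    larger than the trivial construction, the trivial one is returned
    instead, so the result never has more terms than the proof's bound.
    """
    x.bind_check(t)
    if cfg.closure_mode == "extend":
        x_closed, added = definition_closure(t, x)
    else:
        _require_closed(t, x)
        x_closed, added = x, set()
    if not x_closed.codes:
        raise BuildError("cannot build a term set for an empty code set")

    in_defs = _in_set_definitions(t, x_closed)  # folded -> display
    in_keys = set(in_defs)

    # --- inclusion phase ------------------------------------------------
    pool = candidate_patterns(list(in_defs.values()), cfg)
    # A candidate whose text equals an out-of-set definition would place
    # that definition in the protected stratum forever; it can never be
    # used, so drop it up front.
    universe = _folded_universe(t)
    match_keys: dict[str, frozenset[str]] = {}
    usable: list[TermPattern] = []
    for p in pool:
        if p.exact_key not in in_keys and p.exact_key in universe:
            continue
        match_keys[p.raw] = definition_match_keys(t, p)
        usable.append(p)

    covered: set[str] = set()
    spilled: set[str] = set()
    inclusions: list[TermPattern] = []
    incl_raws: set[str] = set()
    review: list[tuple[str, str, tuple[str, ...]]] = []

    def add_inclusion(p: TermPattern, role: str) -> None:
        mk = match_keys.get(p.raw)
        if mk is None:
            mk = definition_match_keys(t, p)
            match_keys[p.raw] = mk
        gained = sorted((mk & in_keys) - covered)
        covered.update(mk & in_keys)
        spilled.update(mk - in_keys)
        inclusions.append(p)
        incl_raws.add(p.raw)
        review.append((p.raw, role, tuple(in_defs[k] for k in gained)))

    while covered != in_keys:
        best: TermPattern | None = None
        best_score = None
        for p in usable:
            if p.raw in incl_raws:
                continue
            mk = match_keys[p.raw]
            new_in = len((mk & in_keys) - covered)
            if new_in == 0:
                continue
            score = new_in - cfg.spill_penalty * len((mk - in_keys) - spilled)
            # equal net score: prefer broader coverage, then readability
            key = (-score, -new_in, *_tie_key(p))
            if best_score is None or key < best_score:
                best_score, best = key, p
        if best is not None and -best_score[0] > 0:
            add_inclusion(best, "inclusion")
        else:
            # no candidate is net-positive: take the cheapest uncovered
            # definition verbatim (always net ≥ 0 for that definition)
            k = min(in_keys - covered)
            add_inclusion(_exact_term(in_defs[k]), "inclusion (exact fallback)")

    protected_in = {p.exact_key for p in inclusions} & in_keys

    # --- exclusion phase ------------------------------------------------
    exclusions: list[TermPattern] = []
    excl_raws: set[str] = set()
    idx_displays = _display_lookup(t)

    def promote(keys: set[str]) -> None:
        """Give in-set definitions exact-term protection so an exclusion
        touching them becomes safe; their own spill joins the queue."""
        for k in sorted(keys):
            p = _exact_term(in_defs[k])
            if p.raw in incl_raws:
                protected_in.add(k)
                continue
            add_inclusion(p, "inclusion (protects against exclusion)")
            review[-1] = (p.raw, review[-1][1], (in_defs[k],))
            protected_in.add(k)

    while spilled - _excluded(t, exclusions):
        remaining = spilled - _excluded(t, exclusions)
        excl_pool = candidate_patterns([idx_displays[k] for k in sorted(remaining)], cfg)
        best = None
        best_score = None
        for p in excl_pool:
            if p.raw in excl_raws or p.raw in incl_raws:
                continue
            mk = match_keys.get(p.raw)
            if mk is None:
                mk = definition_match_keys(t, p)
                match_keys[p.raw] = mk
            if (mk & in_keys) - protected_in:
                continue  # would take out an unprotected in-set definition
            hit = len(mk & remaining)
            if hit == 0:
                continue
            # specificity: at equal usefulness prefer a term matching
            # fewer definitions overall — stop words make bad exclusions
            key = (-hit, len(mk), *_tie_key(p))
            if best_score is None or key < best_score:
                best_score, best = key, p
        if best is None:
            # fall back: exclude one spilled definition verbatim,
            # promoting any unprotected in-set definitions it touches
            k = min(remaining)
            best = _exact_term(idx_displays[k])
            mk = definition_match_keys(t, best)
            match_keys[best.raw] = mk
            promote((mk & in_keys) - protected_in)
        mk = match_keys[best.raw]
        eliminated = sorted(mk & remaining)
        exclusions.append(best)
        excl_raws.add(best.raw)
        review.append(
            (best.raw, "exclusion", tuple(idx_displays[k] for k in eliminated))
        )

    ts = TermSet(
        inclusions=tuple(inclusions),
        exclusions=tuple(exclusions),
        terminology_name=t.name,
        terminology_version=t.version,
        metadata={"title": x.label} if x.label else {},
    )

    # hard guarantee: never worse than the constructive bound
    triv = trivial_termset(x_closed, t)
    if ts.n_terms > triv.n_terms:
        ts = triv
        review = [(p.raw, "inclusion (exact)", ()) for p in triv.inclusions] + [
            (p.raw, "exclusion (exact)", ()) for p in triv.exclusions
        ]

    report = verify(ts, t, x_closed)
    if not report.passed:  # pragma: no cover - exactness is an invariant
        raise BuildError(
            "internal error: built term set is not equivalent to its code set\n"
            + report.summary()
        )
    return BuildResult(
        termset=ts,
        added_by_closure=frozenset(added),
        compression=compression_pct(ts.n_terms, len(x_closed.codes)),
        report=report,
        review=tuple(review),
    )


def _excluded(t: Terminology, exclusions: list[TermPattern]) -> set[str]:
    out: set[str] = set()
    for p in exclusions:
        out |= definition_match_keys(t, p)
    return out


def _folded_universe(t: Terminology) -> set[str]:
    from .matching import _index

    return set(_index(t).key_to_displays)


def _display_lookup(t: Terminology) -> dict[str, str]:
    from .matching import _index

    return {k: v[0] for k, v in _index(t).key_to_displays.items()}


# ----------------------------------------------------------------------
# full pipeline


def build_termset(
    x: CodeSet, t: Terminology, cfg: BuildConfig = BuildConfig()
) -> BuildResult:
    """definition_closure → greedy_minimize → verify, with the
    unmatched-descendant advisory attached to the report."""
    if not x.codes:
        raise BuildError("cannot build a term set for an empty code set")
    return greedy_minimize(x, t, cfg)


def write_review_file(result: BuildResult, path: str) -> None:
    """Tab-delimited ledger: every term, its role, and the definitions it
    gained (inclusions) or eliminated (exclusions).  Makes each automatic
    decision explicit for a human reviewer."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term\trole\tdefinitions\n")
        for raw, role, defs in result.review:
            fh.write(f"{raw}\t{role}\t{'; '.join(defs)}\n")
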