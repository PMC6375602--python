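"""Shared fixtures: tiny hand-built terminologies and an independent
matching oracle re-derived from the search rules."""

from __future__ import annotations

import itertools
import re

import pytest

from termsets import CodeSet, Terminology


@pytest.fixture
def stroke_terminology() -> Terminology:
    """Flat toy terminology around 'stroke' with classic exclusion bait."""
    return Terminology(
        name="toy",
        version="1",
        code_to_defs={
            "c1": ("Stroke",),
            "c2": ("Family history of stroke",),
            "c3": ("Stroke screening",),
            "c4": ("Acute stroke",),
            "c5": ("Heart failure", "Cardiac failure"),
            "c6": ("Rosacea",),
        },
    )


@pytest.fixture
def nodule_terminology() -> Terminology:
    """Two codes share the definition 'Rheumatoid nodule'."""
    return Terminology(
        name="readv2",
        version="20180401",
        code_to_defs={
            "N040.00": ("Rheumatoid arthritis",),
            "N040R00": ("Rheumatoid nodule",),
            "N042200": ("Rheumatoid nodule",),
            "N065.00": ("Unspecified polyarthropathy",),
        },
    )


@pytest.fixture
def prefix_terminology() -> Terminology:
    """Read-style prefix hierarchy G -> G3 -> G30 plus a sibling branch."""
    from termsets.terminology import _read_prefix_parents

    code_to_defs = {
        "G....": ("Circulatory system disease",),
        "G3...": ("Ischaemic heart disease",),
        "G30..": ("Acute myocardial infarction",),
        "G58..": ("Heart failure", "Cardiac failure"),
        "G581.": ("History of heart failure",),
    }
    return Terminology(
        name="readv2",
        version="1",
        code_to_defs=code_to_defs,
        parent=_read_prefix_parents(code_to_defs),
        dialect="read-prefix",
    )


def make_codeset(t: Terminology, codes) -> CodeSet:
    return CodeSet(frozenset(codes), t.name, t.version)


# ----------------------------------------------------------------------
# Independent matching oracle: a from-scratch reading of the search
# rules, deliberately different mechanics from the implementation
# (position permutations instead of backtracking, no index).


def oracle_matches(raw_term: str, definition: str) -> bool:
    raw = raw_term.strip()
    quoted = len(raw) >= 2 and raw[0] == '"' and raw[-1] == '"'
    body = (raw[1:-1] if quoted else raw).casefold()
    ptoks = re.findall(r"[0-9a-z]+\*?", body)
    dtoks = re.findall(r"[0-9a-z]+", definition.casefold())
    if quoted:
        plain = [p.rstrip("*") for p in ptoks]
        return any(
            dtoks[i : i + len(plain)] == plain
            for i in range(len(dtoks) - len(plain) + 1)
        )
    if len(ptoks) > len(dtoks):
        return False

    def tok_ok(p: str, d: str) -> bool:
        return d.startswith(p[:-1]) if p.endswith("*") else d == p

    for positions in itertools.permutations(range(len(dtoks)), len(ptoks)):
        if all(tok_ok(p, dtoks[i]) for p, i in zip(ptoks, positions)):
            return True
    return False


def oracle_md(definitions, raw_terms) -> set[str]:
    return {d for d in definitions if any(oracle_matches(w, d) for w in raw_terms)}


def _norm_fold(s: str) -> str:
    return re.sub(r"\s+", " ", s).strip().casefold()


def oracle_mde(definitions, raw_incl, raw_excl) -> set[str]:
    exact_keys = {_norm_fold(w.strip()[1:-1] if w.strip().startswith('"') and w.strip().endswith('"') else w) for w in raw_incl}
    exact = {d for d in definitions if _norm_fold(d) in exact_keys}
    return exact | (oracle_md(definitions, raw_incl) - oracle_md(definitions, raw_excl))
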