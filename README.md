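# termsets

Clinical code sets — the lists of terminology codes (Read v2, SNOMED CT,
ICD) that define cohorts in electronic-health-record research — are
usually shared as bare code lists. That makes them hard to check, hard
to reuse, and silently wrong when the underlying code dictionary
changes. A **term set** is the intensional counterpart: a short list of
natural-language *inclusion terms* and *exclusion terms* together with a
pinned terminology name and version. Executed against that terminology,
a term set deterministically re-derives the code set; read by a human,
it states *why* each code is in.

This package is a library and command-line tool for working with term
sets: evaluating them into code sets, verifying them against intended
code sets (with hierarchy and shared-definition audits), and converting
any existing code set into an exactly equivalent — and usually much
shorter — term set.

## The model

A terminology is a triple *T* = (*C*, *D*, *f*): codes *C*, textual
definitions *D*, and a surjective mapping *f* : *C* → *D* giving each
code one or more definitions (so the inverse *f*⁻¹ exists for every
definition). For inclusion terms *W* and exclusion terms *E*:

```
MD(T, W)     = ⋃ᵢ { d ∈ D : wᵢ matches d }              matching definitions
MDE(T, W, E) = [W ∩ D] ∪ [MD(T, W) ∩ MD(T, E)ᶜ]          with exclusions
M(T, W, E)   = f⁻¹( MDE(T, W, E) )                       the code set
```

The `W ∩ D` stratum encodes the rule that *an exact match is never
excluded*: a definition whose full text equals an inclusion term stays
in, whatever the exclusion terms say. Matching itself is case
insensitive; a plain term matches when all of its words occur (any
order, distinct positions); `"quoted terms"` match as a contiguous
phrase; a trailing `*` matches by word prefix.

Every code set has an exactly equivalent term set (take one exact term
per definition of every in-set code, then exclude whatever else those
terms match), provided it is *definition-closed*: codes sharing an
identical definition must be all in or all out. The converter uses that
construction as a fall-back bound and greedily searches for a much
smaller term set; the result is always exactly equivalent, never
approximate.

## Worked example

```python
from termsets import Terminology, CodeSet, build_termset, evaluate

t = Terminology(
    name="demo", version="1",
    code_to_defs={
        "C1": ("Stroke",),
        "C2": ("Acute stroke",),
        "C3": ("Stroke monitoring",),
        "C4": ("Family history of stroke",),
        "C5": ("Stroke screening",),
        "C6": ("Heart failure", "Cardiac failure"),
    },
)
x = CodeSet(frozenset({"C1", "C2", "C3"}), "demo", "1", "stroke events")
res = build_termset(x, t)
print("inclusions:", [p.raw for p in res.termset.inclusions])
print("exclusions:", [p.raw for p in res.termset.exclusions])
print("compression:", res.compression, "%")
print("round trip:", sorted(evaluate(res.termset, t).codes))
```

prints

```
inclusions: ['stroke']
exclusions: ['of', 'screening']
compression: 100.0 %
round trip: ['C1', 'C2', 'C3']
```

One inclusion term covers all three target definitions; the two
exclusion terms remove the family-history and screening codes that
`stroke` would otherwise drag in (`of` is chosen here because, in this
tiny dictionary, it is the most specific single word separating
"Family history of stroke"; the tab-separated review ledger written by
`--review` records exactly which definitions every term gained or
eliminated, so such choices are open to inspection). *Compression* is
(|inclusions| + |exclusions|) / |code set| in percent — 3 terms for 3
codes here, hence 100.0.

The same workflow from the shell:

```
termsets synth --out term.tsv --seed 7            # synthetic terminology
termsets convert --terminology term.tsv --codeset x.txt \
    --dialect read-prefix --out ts.json --review review.tsv
termsets evaluate --terminology term.tsv --termset ts.json --dialect read-prefix
termsets verify --terminology term.tsv --termset ts.json --codeset x.txt \
    --dialect read-prefix
termsets audit  --terminology term.tsv --codeset x.txt --dialect read-prefix
termsets report --stats src/termsets/data/published_codeset_survey.tsv
```

`verify` exits non-zero when the term set and the target code set
disagree, reporting missing/extra codes, descendants of matched codes
that no inclusion term covers (flagged for review, never auto-included),
and *closure violations* — definitions shared between an included and an
omitted code. `audit` runs the closure check alone. `report` summarises
a TSV of code-set and term-set sizes; the bundled survey of 31 published
cohort-definition code sets gives a median code-set size of 48
(IQR [18, 120]) and term sets averaging 74% of the size of their code
sets.

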