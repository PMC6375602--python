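# Methods

## Model

A clinical code terminology is modelled as *T* = (*C*, *D*, *f*) with a
surjective mapping *f* from codes to non-empty sets of definitions, plus
an optional acyclic parent relation. Two dialects are supported for the
hierarchy: an explicit parent column, and Read-v2-style prefix codes
(fixed width, `.`-padded), where a code's parent is its longest proper
prefix present in the terminology (`G30`'s parent is `G3`, `G3`'s is
`G`). Definitions are stored whitespace-normalized but case-preserved;
all matching operates on case-folded copies.

A term set is (*I*, *E*, terminology name, terminology version). Its
evaluation is *M*(*T*, *I*, *E*) = *f*⁻¹(*MDE*(*T*, *I*, *E*)), where
*MDE* = [*I* ∩ *D*] ∪ [*MD*(*T*, *I*) ∖ *MD*(*T*, *E*)]. A code is
selected when *any* of its definitions survives: *f*⁻¹ is defined
definition-wise and union is the only reading consistent with a
surjective *f* mapping one code to several synonymous definitions.

## Matching semantics and their edge cases

Word boundaries are maximal runs of non-alphanumeric characters, so
`Diabetes, type 2` tokenizes as `diabetes / type / 2` and hyphenated
spellings split. Plain (bag-of-words) terms require every pattern word
to match a *distinct* token position — `[pain pain]` needs "pain" twice
— which is the only order-free reading that is not lossy; the assignment
is found by backtracking (terms are a handful of words, so cost is
negligible). Quoted terms match as a *token-contiguous phrase*, not a
raw substring: `["type 2 diabetes"]` does not match "Subtype 2
diabetes". Raw-substring semantics would also satisfy the documented
examples, but contradicts the whole-word spirit of the other rules; the
divergence, if any, from other tools is deliberate and recorded here.
Wildcards are trailing-only word-prefix matches (`diabet*`); any other
placement is rejected loudly rather than silently reinterpreted, and a
wildcard inside a quoted phrase is undefined and rejected. The
exact-match-never-excluded rule compares the whitespace-normalized,
case-folded term text (quotes stripped — the protection applies to both
term kinds) with full definitions.

Terminology-wide queries run through an inverted index (word → defining
definitions, with a sorted vocabulary for prefix queries). The index is
an optimisation only: property tests assert it equals a plain scan with
the single-definition predicate, and both are checked against an
independently written brute-force oracle.

## Definition closure

A term set cannot distinguish two codes with the same definition text,
so exact representability requires the code set to be closed under
shared definitions. Closure iterates to a fixpoint and compares
definitions case-folded — consistent with case-insensitive matching,
which is what makes the exactness guarantee hold. The verifier reports
any definition shared between an included and an omitted code as a
closure violation regardless of whether the evaluation happens to pass.

## Conversion

`trivial_termset` is the constructive existence argument: one exact
inclusion term per definition of every in-set code, then one exact
exclusion term per out-of-set definition those inclusion terms also
match. Exact inclusion terms are protected from every exclusion, so the
result evaluates to exactly the input.

`greedy_minimize` searches for a small equivalent term set:

1. **Candidates** are word n-grams of the in-set definitions (n ≤
   `max_ngram`, default 3) as bag-of-words terms, the same n-grams (n ≥
   2) as quoted phrases, and word prefixes of ≥ `min_prefix` (default 4)
   characters as wildcard terms. A candidate whose text equals an
   out-of-set definition is dropped up front — as an inclusion term it
   would protect that definition forever.
2. **Inclusion phase**: repeatedly take the candidate maximising
   (newly covered in-set definitions − λ · newly spilled out-of-set
   definitions), λ = `spill_penalty` = 1 by default, until all in-set
   definitions are covered; when no candidate is net-positive the
   cheapest uncovered definition is taken verbatim (exact term).
3. **Exclusion phase**: greedily pick terms eliminating the spilled
   out-of-set definitions. An exclusion may only touch in-set
   definitions that are protected (exact inclusion terms); if a needed
   exclusion would touch an unprotected one, that definition is first
   *promoted* to an exact inclusion term, and any spill the promotion
   causes joins the queue. The per-definition exact exclusion always
   exists, so the loop terminates.
4. Ties are broken deterministically everywhere: higher coverage, fewer
   words, fewer wildcards (wildcard terms silently grow as dictionaries
   evolve, so plain words win ties), global specificity for exclusions
   (a term matching fewer definitions overall beats a stop word), then
   shorter and lexicographically smaller text. Identical inputs always
   produce identical term sets.
5. If the greedy outcome is larger than the trivial construction (which
   can happen on adversarial inputs), the trivial one is returned, so
   the result never exceeds the constructive bound. Every build ends
   with a full verification; a failure would be an internal error, not a
   degraded result.

Minimality is *not* claimed — minimal term-set selection is a set-cover
problem — and the procedure is deliberately automatic-but-inspectable:
the review ledger lists every term with the definitions it gained or
eliminated, so a clinician can audit each decision. Descendants of
matched codes that no inclusion term covers are reported as an advisory
and never auto-included; descendants matching an exclusion term are
annotated separately rather than suppressed.

## Synthetic terminologies

The generator emulates the structural features that make real
terminologies hard to search: a prefix hierarchy (one character per
level, `.`-padded codes); core concept phrases drawn from a fixed
clinical word list (so bag-of-words collisions are realistic, unlike
random strings); child definitions formed by modifier templates
("family history of {x}", "{x} screening", "{x} NOS", …) or qualifiers;
synonymous second definitions for a code (probability `synonym_prob`,
default 0.15); and verbatim duplicate definitions across distinct codes
(probability `duplicate_def_prob`, default 0.05), which exercise the
closure machinery. Generation is deterministic for a fixed seed.

It does **not** emulate: misspelled definitions, cross-terminology code
translation, multi-parent hierarchies, or the semantic drift of real
dictionary releases. Passing tests on synthetic terminologies therefore
demonstrate the engine's logical guarantees (exactness, determinism,
closure handling), not retrieval quality on any licensed terminology.

## Statistics

Per-set *compression* is 100 · (|I| + |E|) / |X|, rounded half-up to one
decimal with exact decimal arithmetic. Collection summaries use Tukey
hinges for the interquartile range (medians of the lower/upper halves,
excluding the overall median when the count is odd); this convention is
recorded in the summary output. The bundled survey of 31 published
cohort-definition code sets is transcribed with its published proportion
column preserved verbatim; recomputing each proportion from the integer
counts agrees with the published figure for 30 of the 31 rows — the
"Residence" row computes to 120.8% against a published 120.1% — and the
summary statistics (median 48, IQR [18, 120], mean proportion 74%,
subgroup mean 118.5% for the four sets above 100%) are reproduced from
the published column.

## Problem sizes

The randomized exactness and oracle studies run on terminologies of up
to ~200 codes (8 roots, depth 3, branching 4) with hundreds of random
definition-closed code sets, and on definition pools of up to 100 for
the brute-force oracle comparison; these sizes give dense coverage of
the combinatorial space (shared definitions, synonym codes, modifier
collisions) while keeping any single study in the tens of seconds. The
concept-coherence compression study uses each root's subtree as one
"clinical concept" with 20% of its codes randomly omitted before
closure, emulating the incompleteness documented in published code
sets.

## Known limitations

- A definition whose raw text itself parses as term syntax (contains
  `*`, or is wrapped in double quotes) cannot be expressed as an exact
  term; conversion fails loudly. Real terminology definitions do not
  use these characters.
- Exclusion-term choice optimises compactness and specificity, not
  clinical readability; on tiny dictionaries a stop word can be the
  most specific separator (see the worked example in the README).
- Cross-terminology translation, regular expressions, Boolean operators
  within a term, and fuzzy matching are out of scope by design.
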