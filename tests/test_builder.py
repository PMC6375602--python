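"""Code-set → term-set conversion: exactness, compactness, determinism."""

from __future__ import annotations

import random

import pytest

from termsets import (
    BuildConfig,
    BuildError,
    CodeSet,
    Terminology,
    build_termset,
    candidate_patterns,
    definition_closure,
    evaluate,
    generate_synthetic_terminology,
    greedy_minimize,
    trivial_termset,
)

from conftest import make_codeset


# --------------------------------------------------------- trivial form


def test_trivial_whole_terminology_has_no_exclusions(stroke_terminology):
    t = stroke_terminology
    ts = trivial_termset(make_codeset(t, t.codes), t)
    assert ts.exclusions == ()
    assert evaluate(ts, t).codes == t.codes


def test_trivial_empty_set(stroke_terminology):
    t = stroke_terminology
    ts = trivial_termset(make_codeset(t, set()), t)
    assert ts.inclusions == () and evaluate(ts, t).codes == frozenset()


def test_trivial_requires_closed_input(nodule_terminology):
    t = nodule_terminology
    with pytest.raises(BuildError, match="definition-closed"):
        trivial_termset(make_codeset(t, {"N040R00"}), t)


def test_trivial_exact_on_random_closed_sets():
    t = generate_synthetic_terminology(n_roots=6, depth=3, branching=2, seed=4)
    rng = random.Random(4)
    for _ in range(25):
        k = rng.randint(1, len(t.codes))
        x = make_codeset(t, rng.sample(sorted(t.codes), k))
        xc, _ = definition_closure(t, x)
        ts = trivial_termset(xc, t)
        assert evaluate(ts, t).codes == xc.codes


def test_trivial_excludes_spill_of_exact_inclusions():
    # the exact inclusion term for "Stroke" bag-matches the longer
    # out-of-set definition, which must therefore be excluded
    t = Terminology(
        name="t", version="1",
        code_to_defs={"a": ("Stroke",), "b": ("Acute stroke",)},
    )
    ts = trivial_termset(make_codeset(t, {"a"}), t)
    assert [p.raw for p in ts.inclusions] == ["Stroke"]
    assert [p.raw for p in ts.exclusions] == ["Acute stroke"]
    assert evaluate(ts, t).codes == {"a"}


# ---------------------------------------------------------- candidates


def test_candidate_enumeration_contains_expected_forms():
    cfg = BuildConfig(max_ngram=2)
    raws = {p.raw for p in candidate_patterns({"Heart failure"}, cfg)}
    assert {"heart", "failure", "heart failure", '"heart failure"'} <= raws
    wilds = {p.raw for p in candidate_patterns({"Diabetes"}, cfg)}
    assert {"diab*", "diabe*", "diabet*", "diabete*", "diabetes"} <= wilds
    no_wild = candidate_patterns({"Diabetes"}, BuildConfig(allow_wildcards=False))
    assert all("*" not in p.raw for p in no_wild)


def test_candidate_list_deterministic():
    cfg = BuildConfig()
    defs = {"Heart failure", "Acute stroke", "Diabetes NOS"}
    a = [p.raw for p in candidate_patterns(defs, cfg)]
    b = [p.raw for p in candidate_patterns(set(defs), cfg)]
    assert a == b


# -------------------------------------------------------------- greedy


def test_greedy_single_perfect_term():
    t = Terminology(
        name="t", version="1",
        code_to_defs={
            "a": ("Shoulder fracture",),
            "b": ("Hip fracture",),
            "c": ("Fracture of wrist",),
            "d": ("Asthma",),
            "e": ("Stroke",),
        },
    )
    res = greedy_minimize(make_codeset(t, {"a", "b", "c"}), t)
    assert [p.raw for p in res.termset.inclusions] == ["fracture"]
    assert res.termset.exclusions == ()
    assert res.compression == 33.3


def test_greedy_stroke_family_history():
    t = Terminology(
        name="t", version="1",
        code_to_defs={
            "a": ("Stroke",),
            "b": ("Acute stroke",),
            "c": ("Family history of stroke",),
        },
    )
    res = greedy_minimize(make_codeset(t, {"a", "b"}), t)
    assert [p.raw for p in res.termset.inclusions] == ["stroke"]
    # one exclusion term suffices, built from the family-history definition
    assert len(res.termset.exclusions) == 1
    assert res.termset.exclusions[0].raw in {"of", "family", "history"}
    assert evaluate(res.termset, t).codes == {"a", "b"}


def test_greedy_protects_exact_inclusions_from_exclusion():
    # "Stroke" itself is in-set; the exclusion needed for the out-of-set
    # spill must not take it out (it is an exact match of an inclusion)
    t = Terminology(
        name="t", version="1",
        code_to_defs={
            "a": ("Stroke",),
            "b": ("Stroke screening",),
        },
    )
    res = greedy_minimize(make_codeset(t, {"a"}), t)
    assert evaluate(res.termset, t).codes == {"a"}


def test_greedy_never_uses_a_term_equal_to_an_out_of_set_definition():
    # in-set {"Acute stroke"}, out-of-set {"Stroke"}: the tempting term
    # [stroke] would protect the out-of-set definition forever
    t = Terminology(
        name="t", version="1",
        code_to_defs={"a": ("Acute stroke",), "b": ("Stroke",)},
    )
    res = greedy_minimize(make_codeset(t, {"a"}), t)
    assert evaluate(res.termset, t).codes == {"a"}
    assert all(p.exact_key != "stroke" for p in res.termset.inclusions)


def test_greedy_deterministic():
    t = generate_synthetic_terminology(n_roots=6, depth=3, branching=2, seed=9)
    rng = random.Random(9)
    x, _ = definition_closure(t, make_codeset(t, rng.sample(sorted(t.codes), 15)))
    a = greedy_minimize(x, t)
    b = greedy_minimize(x, t)
    assert [p.raw for p in a.termset.inclusions] == [p.raw for p in b.termset.inclusions]
    assert [p.raw for p in a.termset.exclusions] == [p.raw for p in b.termset.exclusions]


def test_greedy_no_exclusions_when_vocabularies_disjoint():
    # in-set and out-of-set definitions share no words and no 4+ letter
    # prefixes, so no candidate can spill
    t = Terminology(
        name="t", version="1",
        code_to_defs={
            "a": ("Asthma",),
            "b": ("Asthma monitoring",),
            "c": ("Stroke",),
            "d": ("Diabetic review",),
        },
    )
    res = greedy_minimize(make_codeset(t, {"a", "b"}), t)
    assert res.termset.exclusions == ()
    assert evaluate(res.termset, t).codes == {"a", "b"}


def test_greedy_exact_and_never_larger_than_trivial_on_synthetic():
    t = generate_synthetic_terminology(
        n_roots=6, depth=3, branching=3, duplicate_def_prob=0.1, seed=2
    )
    rng = random.Random(2)
    for _ in range(20):
        k = rng.randint(1, 30)
        x, _ = definition_closure(
            t, make_codeset(t, rng.sample(sorted(t.codes), k))
        )
        res = greedy_minimize(x, t)
        triv = trivial_termset(x, t)
        assert evaluate(res.termset, t).codes == x.codes
        assert res.termset.n_terms <= triv.n_terms
        assert res.report is not None and res.report.passed


# ------------------------------------------------------------- pipeline


def test_build_termset_closes_input_and_records_added(nodule_terminology):
    t = nodule_terminology
    res = build_termset(make_codeset(t, {"N040R00"}), t)
    assert res.added_by_closure == {"N042200"}
    assert evaluate(res.termset, t).codes == {"N040R00", "N042200"}


def test_build_termset_closure_error_mode(nodule_terminology):
    t = nodule_terminology
    with pytest.raises(BuildError, match="definition-closed"):
        build_termset(
            make_codeset(t, {"N040R00"}), t, BuildConfig(closure_mode="error")
        )


def test_build_termset_rejects_empty_input(stroke_terminology):
    with pytest.raises(BuildError, match="empty"):
        build_termset(make_codeset(stroke_terminology, set()), stroke_terminology)


def test_singleton_unique_definition_compresses_to_100(stroke_terminology):
    res = build_termset(make_codeset(stroke_terminology, {"c6"}), stroke_terminology)
    assert len(res.termset.inclusions) == 1
    assert res.termset.exclusions == ()
    assert res.compression == 100.0


def test_compression_can_exceed_100():
    # two codes whose definitions are single common words: every short
    # term spills, so the builder needs more terms than codes — it must
    # still succeed and report compression > 100
    t = Terminology(
        name="t", version="1",
        code_to_defs={
            "a": ("Single",),
            "b": ("Single parent",),
            "c": ("Single dose",),
            "d": ("Single room",),
            "e": ("Single use",),
        },
    )
    res = build_termset(make_codeset(t, {"a", "b"}), t)
    assert evaluate(res.termset, t).codes == {"a", "b"}
    assert res.compression > 100.0


def test_compression_arithmetic():
    from termsets.builder import compression_pct

    assert compression_pct(5 + 9, 116) == 12.1
    assert compression_pct(20 + 48, 55) == 123.6
    assert compression_pct(1, 1) == 100.0
    with pytest.raises(BuildError):
        compression_pct(1, 0)


def test_review_ledger_lists_every_term(tmp_path, stroke_terminology):
    from termsets.builder import write_review_file

    t = stroke_terminology
    res = build_termset(make_codeset(t, {"c1", "c4"}), t)
    path = tmp_path / "review.tsv"
    write_review_file(res, str(path))
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "term\trole\tdefinitions"
    terms_in_file = {l.split("\t")[0] for l in lines[1:]}
    assert terms_in_file == {
        p.raw for p in res.termset.inclusions + res.termset.exclusions
    }
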