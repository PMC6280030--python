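import pytest

from sdrwatch import annotate, synthetic
from sdrwatch.annotate import (
    DrugLexicon,
    RuleBasedAEClassifier,
    Terminology,
    annotate_corpus,
    classify_ae,
    deidentify,
    detect_drugs,
    detect_intake,
    match_concepts,
    normalize,
)


# -- deidentify -------------------------------------------------------------


@pytest.mark.parametrize(
    "raw,clean",
    [
        ("call me 0612345678", "call me <PHONE>"),
        ("write to jo.doe@example.org please", "write to <EMAIL> please"),
        ("i live at 75013 near the park", "i live at <POSTCODE> near the park"),
        ("saw Dr Martin yesterday", "saw <NAME> yesterday"),
        ("nothing personal here", "nothing personal here"),
    ],
)
def test_deidentify_patterns(raw, clean):
    assert deidentify(raw) == clean


def test_deidentify_idempotent():
    texts = [
        "call 0612345678 or mail a@b.fr, zip 75013, ask Mr Smith",
        "no personal data",
    ]
    for t in texts:
        once = deidentify(t)
        assert deidentify(once) == once


# -- normalize --------------------------------------------------------------


def test_normalize_lowercases_tokenizes_and_stems():
    assert normalize("Headaches  HURT") == ["headach", "hurt"]
    assert normalize("") == []
    assert normalize("Weight-gain, again!") == ["weight", "gain", "again"]


# -- drug detection ---------------------------------------------------------


def build_small_lexicon():
    lex = DrugLexicon()
    lex.add("D1", "zolpidem")
    lex.add("D1", "stilnox")
    lex.add("D1", "zolpidme")  # planted misspelling
    lex.add("D2", "insulin glargine")
    lex.add("D2", "lantus")
    return lex


def test_misspelling_in_lexicon_is_detected():
    lex = build_small_lexicon()
    assert detect_drugs(normalize("i took zolpidme last night"), lex) == {"D1"}


def test_no_lexicon_form_gives_empty_set():
    lex = build_small_lexicon()
    assert detect_drugs(normalize("i slept well"), lex) == set()


def test_two_drugs_detected_and_multiword_forms():
    lex = build_small_lexicon()
    toks = normalize("switched from insulin glargine to stilnox")
    found = detect_drugs(toks, lex)
    # oracle: exhaustive scan over every surface form of every drug
    expected = set()
    for drug_id, forms in lex.forms.items():
        for form in forms:
            ftoks = tuple(form.split())
            for i in range(len(toks) - len(ftoks) + 1):
                if tuple(toks[i : i + len(ftoks)]) == ftoks:
                    expected.add(drug_id)
    assert found == expected == {"D1", "D2"}


def test_conflicting_surface_form_rejected():
    lex = DrugLexicon()
    lex.add("D1", "stilnox")
    with pytest.raises(ValueError):
        lex.add("D2", "stilnox")


# -- intake -----------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("I took X yesterday", True),
        ("i have been taking lantus for a year", True),
        ("my doctor put me on stilnox", True),
        ("does X cause nausea?", False),
        ("", False),
        ("X is a sleeping pill", False),
    ],
)
def test_intake_detection(text, expected):
    assert detect_intake(text.lower()) is expected


# -- concept matching -------------------------------------------------------


def build_small_terminology():
    term = Terminology()
    term.add("weight", "PT_W", "weight")
    term.add("weight gain", "PT_WG", "weight increased")
    term.add("abnormal weight gain", "PT_WG", "weight increased")
    term.add("headache", "PT_H", "headache")
    term.add("mal de tete", "PT_H", "headache")
    return term


def brute_force_concepts(tokens, term):
    """Enumerate all variant spans, then greedy longest-match."""
    spans = []
    for variant_toks, code in term.stemmed_index.items():
        L = len(variant_toks)
        for i in range(len(tokens) - L + 1):
            if tuple(tokens[i : i + L]) == variant_toks:
                spans.append((i, i + L, code))
    spans.sort(key=lambda s: (-(s[1] - s[0]), s[0]))
    taken, out = [], set()
    for s, e, code in spans:
        if not any(s >= ts and e <= te for ts, te in taken):
            taken.append((s, e))
            out.add(code)
    return out


def test_variant_maps_to_parent_preferred_term():
    term = build_small_terminology()
    toks = normalize("terrible mal de tete since monday")
    assert match_concepts(toks, term) == {"PT_H"}


def test_no_variant_gives_empty_set():
    term = build_small_terminology()
    assert match_concepts(normalize("all is fine"), term) == set()


@pytest.mark.parametrize(
    "text",
    [
        "noticed weight gain this month",
        "abnormal weight gain and headache",
        "my weight stayed stable",
        "weight gain weight",
    ],
)
def test_longest_match_suppresses_nested_variant(text):
    term = build_small_terminology()
    toks = normalize(text)
    assert match_concepts(toks, term) == brute_force_concepts(toks, term)


def test_nested_variant_only_parent_of_longest():
    term = build_small_terminology()
    assert match_concepts(normalize("sudden weight gain"), term) == {"PT_WG"}


def test_nos_stripping_and_stop_terms(tmp_path):
    src = tmp_path / "term.csv"
    src.write_text(
        "variant_term,pt_code,pt_label\n"
        "Allergy NOS,PT_A,allergy\n"
        "poverty,PT_P,poverty\n",
        encoding="utf-8",
    )
    term = Terminology.from_csv(src, stop_terms=["poverty"])
    assert "Allergy" in term.variants
    assert "PT_P" not in term.pt_codes


# -- AE classification ------------------------------------------------------


def test_indication_phrase_excluded():
    text = "i was prescribed stilnox for headache ."
    assert classify_ae(text, {"PT_H"}) == set()


def test_plain_intake_report_included():
    text = "i took stilnox and since then i have headache ."
    assert classify_ae(text, {"PT_H"}) == {"PT_H"}


@pytest.mark.parametrize(
    "text",
    [
        "does stilnox cause headache ?",
        "i never had headache with it",
        "i took stilnox but i already had headache before that .",
    ],
)
def test_question_negation_and_preintake_excluded(text):
    assert classify_ae(text, {"PT_H"}) == set()


def test_classifier_accuracy_on_designed_templates(small_study):
    """The rule-based classifier separates positives from its decoy classes."""
    msgs, truth = synthetic.render_forum_corpus(
        small_study["stream"],
        small_study["lexicon"],
        small_study["terminology"],
        synthetic.RenderConfig(decoy_fraction=0.3, misspelling_prob=0.2, seed=9),
    )
    clf = RuleBasedAEClassifier()
    # evaluate only on messages that would reach the classifier stage
    correct = total = 0
    for msg, (_, _, _, label, cls) in zip(msgs, truth.itertuples(index=False)):
        if cls in ("question", "no_intake"):
            continue  # filtered upstream of the classifier
        verdict = clf(msg["text"].lower(), "", None)
        correct += int(verdict == bool(label))
        total += 1
    assert total > 100
    assert correct / total >= 0.95


# -- corpus driver ----------------------------------------------------------


def test_message_failing_intake_contributes_nothing():
    lex = build_small_lexicon()
    term = build_small_terminology()
    corpus = [
        {"id": "m1", "date": "2010-01-03", "text": "stilnox gives headache maybe"},
        {"id": "m2", "date": "2010-01-04", "text": "i took stilnox and got headache"},
    ]
    occ, funnel = annotate_corpus(corpus, lex, term)
    assert funnel.with_drug == 2 and funnel.with_intake == 1
    assert set(occ["unit_id"]) == {"m2"}


def test_one_drug_two_ae_concepts_gives_two_occurrences():
    lex = build_small_lexicon()
    term = build_small_terminology()
    corpus = [
        {
            "id": "m1",
            "date": "2010-05-01",
            "text": "i took stilnox and now i have headache and weight gain",
        }
    ]
    occ, _ = annotate_corpus(corpus, lex, term)
    assert len(occ) == 2
    assert set(occ["pt_code"]) == {"PT_H", "PT_WG"}


def test_funnel_counts_non_increasing_and_truth_recovered(small_study):
    msgs, truth = synthetic.render_forum_corpus(
        small_study["stream"],
        small_study["lexicon"],
        small_study["terminology"],
        synthetic.RenderConfig(decoy_fraction=0.2, misspelling_prob=0.3, seed=1),
    )
    occ, funnel = annotate_corpus(msgs, small_study["lexicon"], small_study["terminology"])
    stages = funnel.stages()
    assert stages == sorted(stages, reverse=True)
    positives = truth[truth["is_true_AE"] == 1]
    assert set(zip(occ.unit_id, occ.drug_id, occ.pt_code)) == set(
        zip(positives.message_id, positives.drug_id, positives.pt_code)
    )
    # every emitted code/drug exists in the resources
    assert set(occ["pt_code"]) <= small_study["terminology"].pt_codes
    assert set(occ["drug_id"]) <= set(small_study["lexicon"].forms)


def test_unreadable_records_counted_and_skipped():
    lex = build_small_lexicon()
    term = build_small_terminology()
    corpus = [
        {"id": "m1", "date": "not-a-date", "text": "x"},
        {"id": "m2", "date": "2010-01-01", "text": "i took stilnox and got headache"},
    ]
    occ, funnel = annotate_corpus(corpus, lex, term)
    assert funnel.unreadable == 1
    assert len(occ) == 1
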