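"""Message annotation: from raw forum posts to drug-event occurrences.

The chain mirrors how Web pharmacovigilance systems prepare social-media
text for disproportionality analysis:

1. deidentify      -- scrub phone numbers, e-mails, postal codes, names;
2. normalize       -- lowercase, tokenize, Porter-stem;
3. detect_drugs    -- dictionary match against a drug lexicon that includes
                      brand names and common misspellings;
4. detect_intake   -- keep only messages whose author (or a relative)
                      actually took the drug, via first-person cue patterns;
5. match_concepts  -- exact stemmed match against a two-level terminology
                      (variant terms mapped to preferred terms);
6. classify_ae     -- keep only concepts that plausibly describe an adverse
                      event (not an indication, negation, question, or a
                      symptom predating the intake).

Each stage only narrows the candidate set, so per-stage message counts form
a non-increasing funnel, which :func:`annotate_corpus` reports.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .months import month_index
from .porter import stem

logger = logging.getLogger(__name__)

OCCURRENCE_COLUMNS = ["unit_id", "month", "source", "drug_id", "pt_code"]


# ---------------------------------------------------------------------------
# resources


def _load_packaged_lines(name: str) -> list[str]:
    text = _ilres.files("sdrwatch.data").joinpath(name).read_text(encoding="utf-8")
    return [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def load_deident_patterns(path: str | Path | None = None) -> list[tuple[str, re.Pattern]]:
    """(placeholder, compiled regex) pairs, applied in file order."""
    lines = (
        _load_packaged_lines("deident_patterns.txt")
        if path is None
        else [
            ln
            for ln in Path(path).read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    )
    out = []
    for ln in lines:
        placeholder, pattern = ln.split("\t", 1)
        out.append((placeholder, re.compile(pattern)))
    return out


def load_intake_patterns(path: str | Path | None = None) -> list[re.Pattern]:
    lines = (
        _load_packaged_lines("intake_patterns.txt")
        if path is None
        else [
            ln
            for ln in Path(path).read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    )
    return [re.compile(p, re.IGNORECASE) for p in lines]


def load_exclusion_patterns(
    path: str | Path | None = None,
) -> list[tuple[str, re.Pattern]]:
    """(class tag, compiled regex) pairs for the rule-based AE classifier."""
    lines = (
        _load_packaged_lines("ae_exclusion_patterns.txt")
        if path is None
        else [
            ln
            for ln in Path(path).read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    )
    out = []
    for ln in lines:
        tag, pattern = ln.split("\t", 1)
        out.append((tag, re.compile(pattern, re.IGNORECASE)))
    return out


# ---------------------------------------------------------------------------
# text primitives

_WORD_RE = re.compile(r"\w+", re.UNICODE)


def deidentify(text: str, patterns: Sequence[tuple[str, re.Pattern]] | None = None) -> str:
    """Replace personal-data substrings with placeholder tokens.

    Idempotent: placeholders contain nothing the patterns match.
    """
    if patterns is None:
        patterns = _DEFAULT_DEIDENT
    for placeholder, rx in patterns:
        text = rx.sub(placeholder, text)
    return text


def normalize(text: str) -> list[str]:
    """Lowercase, tokenize on non-word boundaries and Porter-stem each token."""
    return [stem(tok) for tok in _WORD_RE.findall(text.lower())]


_DEFAULT_DEIDENT = load_deident_patterns()
_DEFAULT_INTAKE = load_intake_patterns()
_DEFAULT_EXCLUSION = load_exclusion_patterns()


# ---------------------------------------------------------------------------
# lexicon / terminology


@dataclass
class DrugLexicon:
    """Drug id -> surface forms (substance, brands, known misspellings).

    Surface forms are stored stemmed+tokenized through :func:`normalize`, the
    same pipeline applied to messages, so matching is exact on stems.
    """

    forms: dict[str, set[str]] = field(default_factory=dict)
    _index: dict[tuple[str, ...], str] = field(default_factory=dict, repr=False)

    def add(self, drug_id: str, surface_form: str) -> None:
        toks = tuple(normalize(surface_form))
        if not toks:
            raise ValueError(f"empty surface form for {drug_id!r}")
        owner = self._index.get(toks)
        if owner is not None and owner != drug_id:
            raise ValueError(
                f"surface form {surface_form!r} maps to both {owner!r} and {drug_id!r}"
            )
        self.forms.setdefault(drug_id, set()).add(" ".join(toks))
        self._index[toks] = drug_id

    @property
    def index(self) -> Mapping[tuple[str, ...], str]:
        return self._index

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugLexicon":
        """CSV columns: drug_id, surface_form, form_type."""
        lex = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                lex.add(row["drug_id"], row["surface_form"])
        return lex

    def to_csv(self, path: str | Path, form_types: Mapping[str, str] | None = None) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["drug_id", "surface_form", "form_type"])
            for drug_id in sorted(self.forms):
                for form in sorted(self.forms[drug_id]):
                    ftype = (form_types or {}).get(form, "substance")
                    w.writerow([drug_id, form, ftype])


@dataclass
class Terminology:
    """Two-level event terminology: variant terms -> preferred terms.

    Mirrors the MedDRA LLT/PT structure: every variant (lower-level term)
    belongs to exactly one preferred term.  The stemmed index maps the
    stemmed token tuple of each variant to its preferred-term code; variants
    that collide after stemming are deduplicated (first entry wins).
    """

    variants: dict[str, tuple[str, str]] = field(default_factory=dict)
    pt_labels: dict[str, str] = field(default_factory=dict)
    stemmed_index: dict[tuple[str, ...], str] = field(default_factory=dict, repr=False)

    def add(self, variant: str, pt_code: str, pt_label: str) -> None:
        variant = variant.strip()
        if variant in self.variants and self.variants[variant][0] != pt_code:
            raise ValueError(f"variant {variant!r} maps to two preferred terms")
        self.variants[variant] = (pt_code, pt_label)
        self.pt_labels[pt_code] = pt_label
        toks = tuple(normalize(variant))
        if toks and toks not in self.stemmed_index:
            self.stemmed_index[toks] = pt_code

    @property
    def pt_codes(self) -> set[str]:
        return set(self.pt_labels)

    def resolve(self, term: str) -> str:
        """Map a term (variant or preferred-term code) to its PT code."""
        if term in self.pt_labels:
            return term
        if term in self.variants:
            return self.variants[term][0]
        toks = tuple(normalize(term))
        try:
            return self.stemmed_index[toks]
        except KeyError:
            raise KeyError(f"term {term!r} not in terminology") from None

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        stop_terms: Iterable[str] = (),
        strip_nos: bool = True,
    ) -> "Terminology":
        """CSV columns: variant_term, pt_code, pt_label.

        Preprocessing mirrors common terminology adjustments: variants whose
        preferred-term label is in *stop_terms* (out-of-scope concepts such
        as "poverty") are dropped, and a trailing ``NOS`` ("not otherwise
        specified") qualifier is stripped from variant terms.
        """
        stop = {s.lower() for s in stop_terms}
        term = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                label = row["pt_label"]
                if label.lower() in stop:
                    continue
                variant = row["variant_term"]
                if strip_nos:
                    variant = re.sub(r"\s+NOS$", "", variant, flags=re.IGNORECASE)
                term.add(variant, row["pt_code"], label)
        return term

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["variant_term", "pt_code", "pt_label"])
            for variant in sorted(self.variants):
                code, label = self.variants[variant]
                w.writerow([variant, code, label])


# ---------------------------------------------------------------------------
# detection stages


def _find_token_runs(
    tokens: Sequence[str], index: Mapping[tuple[str, ...], str], max_len: int
) -> list[tuple[int, int, str]]:
    """All (start, end, value) matches of index keys as contiguous runs."""
    hits = []
    n = len(tokens)
    for i in range(n):
        for L in range(min(max_len, n - i), 0, -1):
            key = tuple(tokens[i : i + L])
            if key in index:
                hits.append((i, i + L, index[key]))
    return hits


def detect_drugs(tokens: Sequence[str], lexicon: DrugLexicon) -> set[str]:
    """Drug ids whose surface forms occur as contiguous token runs."""
    if not lexicon.index:
        return set()
    max_len = max(len(k) for k in lexicon.index)
    return {d for _, _, d in _find_token_runs(tokens, lexicon.index, max_len)}


def detect_intake(text: str, patterns: Sequence[re.Pattern] | None = None) -> bool:
    """True when the message reports a drug intake in the first person."""
    if patterns is None:
        patterns = _DEFAULT_INTAKE
    return any(rx.search(text) for rx in patterns)


def match_concepts(tokens: Sequence[str], terminology: Terminology) -> set[str]:
    """Preferred-term codes whose variants occur in the stemmed tokens.

    Longest match first; a span consumed by a longer variant suppresses any
    shorter variant nested inside it (so "weight gain" does not also fire
    the bare "weight" entry).
    """
    index = terminology.stemmed_index
    if not index:
        return set()
    max_len = max(len(k) for k in index)
    hits = _find_token_runs(tokens, index, max_len)
    hits.sort(key=lambda h: (-(h[1] - h[0]), h[0]))
    consumed: list[tuple[int, int]] = []
    out: set[str] = set()
    for start, end, code in hits:
        if any(start >= s and end <= e for s, e in consumed):
            continue
        consumed.append((start, end))
        out.add(code)
    return out


class RuleBasedAEClassifier:
    """Default potential-adverse-event filter.

    A statistical classifier (the interface expects ``(text, pt_code,
    context) -> bool``) can be plugged in instead; this default applies the
    packaged exclusion-cue patterns to the message: a concept is rejected
    when the message is a question, negates the concept, mentions it as the
    drug's indication, or dates it before the intake.  Cues are evaluated on
    the whole message, which is adequate for short single-clause posts.
    """

    def __init__(self, patterns: Sequence[tuple[str, re.Pattern]] | None = None):
        self.patterns = list(patterns) if patterns is not None else _DEFAULT_EXCLUSION

    def __call__(self, text: str, pt_code: str, context: str | None = None) -> bool:
        scope = context if context is not None else text
        return not any(rx.search(scope) for _, rx in self.patterns)


AEClassifier = Callable[[str, str, str | None], bool]


def classify_ae(
    text: str, concepts: set[str], classifier: AEClassifier | None = None
) -> set[str]:
    """Subset of *concepts* judged potential adverse events."""
    clf = classifier if classifier is not None else RuleBasedAEClassifier()
    return {c for c in sorted(concepts) if clf(text, c, None)}


# ---------------------------------------------------------------------------
# corpus-level driver


@dataclass
class AnnotatedMessage:
    message_id: str
    month: int
    drugs: set[str]
    intake: bool
    concepts: set[str]
    ae_concepts: set[str]


@dataclass
class FunnelReport:
    """Per-stage surviving-message counts of the annotation chain."""

    total: int = 0
    unreadable: int = 0
    with_drug: int = 0
    with_intake: int = 0
    with_concept: int = 0
    with_ae: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "unreadable": self.unreadable,
            "with_drug": self.with_drug,
            "with_intake": self.with_intake,
            "with_concept": self.with_concept,
            "with_ae": self.with_ae,
        }

    def stages(self) -> list[int]:
        return [self.with_drug, self.with_intake, self.with_concept, self.with_ae]


def annotate_message(
    message_id: str,
    month: int,
    text: str,
    lexicon: DrugLexicon,
    terminology: Terminology,
    classifier: AEClassifier | None = None,
    deident: Sequence[tuple[str, re.Pattern]] | None = None,
    intake_patterns: Sequence[re.Pattern] | None = None,
) -> AnnotatedMessage:
    clean = deidentify(text, deident)
    tokens = normalize(clean)
    drugs = detect_drugs(tokens, lexicon)
    intake = detect_intake(clean.lower(), intake_patterns) if drugs else False
    concepts = match_concepts(tokens, terminology) if drugs and intake else set()
    ae = classify_ae(clean.lower(), concepts, classifier) if concepts else set()
    if not drugs:
        ae = set()
    return AnnotatedMessage(message_id, month, drugs, intake, concepts, ae)


def annotate_corpus(
    corpus: Iterable[Mapping],
    lexicon: DrugLexicon,
    terminology: Terminology,
    classifier: AEClassifier | None = None,
    source: str = "forum",
) -> tuple[pd.DataFrame, FunnelReport]:
    """Annotate a message corpus into drug-event occurrences.

    *corpus* yields mappings with keys ``id``, ``date``, ``text`` (and
    optionally ``source``).  Returns one occurrence row per (message, drug,
    adverse-event preferred term) triple, plus the stage funnel.
    """
    funnel = FunnelReport()
    rows = []
    for rec in corpus:
        funnel.total += 1
        try:
            mid = str(rec["id"])
            month = month_index(str(rec["date"]))
            text = str(rec["text"])
        except (KeyError, ValueError) as exc:
            funnel.unreadable += 1
            logger.warning("skipping unreadable record: %s", exc)
            continue
        try:
            ann = annotate_message(mid, month, text, lexicon, terminology, classifier)
        except Exception as exc:  # classifier failure must never be silent
            funnel.unreadable += 1
            logger.warning("annotation failed on message %s: %s", mid, exc)
            continue
        if not ann.drugs:
            continue
        funnel.with_drug += 1
        if not ann.intake:
            continue
        funnel.with_intake += 1
        if not ann.concepts:
            continue
        funnel.with_concept += 1
        if not ann.ae_concepts:
            continue
        funnel.with_ae += 1
        src = str(rec.get("source", source))
        for drug in sorted(ann.drugs):
            for code in sorted(ann.ae_concepts):
                rows.append((mid, ann.month, src, drug, code))
    logger.info("annotation funnel: %s", funnel.as_dict())
    occ = pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)
    return occ, funnel


def read_corpus_jsonl(path: str | Path) -> list[dict]:
    """Read a message corpus (JSON-lines: id, date, source, text)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(json.loads(line))
    return out


def read_occurrences_csv(path: str | Path) -> pd.DataFrame:
    """Read an occurrences table written by the pipeline (month as YYYY-MM)."""
    df = pd.read_csv(path, dtype=str)
    df["month"] = df["month"].map(month_index)
    return df[OCCURRENCE_COLUMNS]


def read_reports_csv(path: str | Path, terminology: Terminology) -> pd.DataFrame:
    """Read a spontaneous-report table (CSV: report_id, date, drug_id, term).

    Each input row is one reporting unit.  Event terms may be given at
    either terminology level; they are resolved to preferred-term codes.
    """
    df = pd.read_csv(path, dtype=str)
    rows = [
        (r.report_id, month_index(r.date), "reference", r.drug_id, terminology.resolve(r.term))
        for r in df.itertuples()
    ]
    return pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)
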