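"""Synthetic paired forum / spontaneous-report data with known signals.

The generator emulates the comparative study design that motivates this
package: a handful of study drugs plus a background comparator group of 327
drugs, a few hundred adverse-event preferred terms, and monthly reporting
over an 11-year window in two sources (a Web-forum corpus and a reference
spontaneous-report database).  Occurrence counts per (drug, event, month,
source) are independent Poisson draws whose mean is a per-pair baseline,
optionally multiplied by a planted relative reporting rate from a
source-specific onset month onward, and scaled by a messages-per-report
ratio in the forum source.  Planted pairs, effect sizes and the forum
lead/lag are recorded in a ground-truth object so every downstream stage
can be validated without any external data.

Forum occurrences can additionally be rendered into template-based text
messages (drug surface form + first-person intake phrase + event variant
term), with configurable decoy messages, to exercise the annotation chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotate import OCCURRENCE_COLUMNS, DrugLexicon, Terminology
from .months import month_index, month_range, month_str

FORUM = "forum"
REFERENCE = "reference"


@dataclass(frozen=True)
class PlantedSignal:
    """One disproportionate pair planted into the generator.

    ``onset_month`` is the reference-source onset (``YYYY-MM``); the forum
    onset is shifted by ``forum_lead_months`` (negative = forum leads, i.e.
    the excess reporting starts earlier on the forum).
    """

    drug_id: str
    pt_code: str
    relative_rate: float
    onset_month: str
    forum_lead_months: int = 0


@dataclass(frozen=True)
class SimConfig:
    n_study_drugs: int = 3
    n_background_drugs: int = 327
    n_events: int = 150
    start_month: str = "2005-01"
    end_month: str = "2015-12"
    baseline_rate: float = 3.0 / 132.0  # mean pair total ~3 over the window
    planted_signals: tuple[PlantedSignal, ...] = ()
    messages_per_report_ratio: float = 1.0
    seed: int = 0
    #: Optional per-drug reporting-propensity multipliers (drug id -> rate
    #: factor).  Real reporting volume is strongly skewed toward a few
    #: heavily-discussed drugs; the default (None) is a homogeneous rate.
    #: Multipliers act on rows only, so drug-event independence is kept and
    #: the true relative rate of unplanted pairs stays 1.
    drug_rate_multipliers: tuple[tuple[str, float], ...] | None = None

    def __post_init__(self):
        if self.n_background_drugs < 1:
            raise ValueError("need at least one background drug")
        if self.n_study_drugs < 0 or self.n_events < 1:
            raise ValueError("invalid universe size")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        if self.messages_per_report_ratio <= 0:
            raise ValueError("messages_per_report_ratio must be positive")
        if month_index(self.end_month) < month_index(self.start_month):
            raise ValueError("end_month before start_month")
        drugs = set(self.drug_ids)
        events = set(self.pt_codes)
        for sig in self.planted_signals:
            if sig.relative_rate < 1:
                raise ValueError(f"relative_rate < 1 for {sig}")
            if sig.drug_id not in drugs or sig.pt_code not in events:
                raise ValueError(f"planted pair outside universe: {sig}")
            month_index(sig.onset_month)

    @property
    def study_drug_ids(self) -> list[str]:
        return [f"DS{i + 1:02d}" for i in range(self.n_study_drugs)]

    @property
    def background_drug_ids(self) -> list[str]:
        return [f"DB{i + 1:03d}" for i in range(self.n_background_drugs)]

    @property
    def drug_ids(self) -> list[str]:
        return self.study_drug_ids + self.background_drug_ids

    @property
    def pt_codes(self) -> list[str]:
        return [f"PT{j + 1:04d}" for j in range(self.n_events)]

    @property
    def months(self) -> range:
        return month_range(self.start_month, self.end_month)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_study_drugs": self.n_study_drugs,
            "n_background_drugs": self.n_background_drugs,
            "n_events": self.n_events,
            "start_month": self.start_month,
            "end_month": self.end_month,
            "baseline_rate": self.baseline_rate,
            "messages_per_report_ratio": self.messages_per_report_ratio,
            "seed": self.seed,
            "planted_signals": [
                {
                    "drug_id": s.drug_id,
                    "pt_code": s.pt_code,
                    "relative_rate": s.relative_rate,
                    "onset_month": s.onset_month,
                    "forum_lead_months": s.forum_lead_months,
                }
                for s in self.planted_signals
            ],
            "drug_rate_multipliers": (
                None
                if self.drug_rate_multipliers is None
                else {d: m for d, m in self.drug_rate_multipliers}
            ),
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        planted = tuple(
            PlantedSignal(**s) for s in doc.pop("planted_signals", [])
        )
        mults = doc.pop("drug_rate_multipliers", None)
        if mults is not None:
            mults = tuple(sorted(mults.items()))
        return cls(planted_signals=planted, drug_rate_multipliers=mults, **doc)


@dataclass
class GroundTruth:
    """What was planted: pairs, per-source onsets, and effect sizes."""

    signal_pairs: set[tuple[str, str]]
    onset: dict[tuple[tuple[str, str], str], int]  # (pair, source) -> month index
    relative_rate: dict[tuple[str, str], float]

    def labels(self, universe) -> pd.Series:
        """Boolean ground-truth label for each pair of *universe*."""
        idx = sorted(universe)
        return pd.Series(
            [p in self.signal_pairs for p in idx],
            index=pd.MultiIndex.from_tuples(idx, names=["drug_id", "pt_code"]),
        )


@dataclass
class OccurrenceStream:
    """Raw occurrence records for both sources, at variant-term level."""

    records: pd.DataFrame  # columns: occ_id, source, drug_id, term, month
    config: SimConfig

    def for_source(self, source: str) -> pd.DataFrame:
        return self.records[self.records["source"] == source]


# ---------------------------------------------------------------------------
# vocabulary synthesis


def _letters(i: int, width: int = 3) -> str:
    out = []
    for _ in range(width):
        i, r = divmod(i, 26)
        out.append(chr(ord("a") + r))
    return "".join(reversed(out))


def drug_surface_forms(drug_ids) -> dict[str, dict[str, str]]:
    """Raw surface forms per drug: substance, brand name, misspelling.

    Names are coined letter-only words so they cannot collide with template
    prose or event terms.  The misspelling drops the substance's final
    letter ("doraaain" for "doraaaine"), a common typing error that is
    always distinct from the canonical spelling.
    """
    out = {}
    for k, drug_id in enumerate(drug_ids):
        code = _letters(k)
        substance = f"dor{code}ine"
        out[drug_id] = {
            "substance": substance,
            "brand": f"vex{code}ol",
            "misspelling": substance[:-1],
        }
    return out


def build_lexicon(drug_ids) -> tuple[DrugLexicon, dict[str, str]]:
    """Deterministic synthetic drug lexicon over ``drug_surface_forms``."""
    lex = DrugLexicon()
    form_types: dict[str, str] = {}
    for drug_id, forms in drug_surface_forms(drug_ids).items():
        for ftype, form in forms.items():
            lex.add(drug_id, form)
            form_types[form] = ftype
    return lex, form_types


def build_terminology(pt_codes, variants_per_pt: int = 3) -> Terminology:
    """Deterministic synthetic two-level terminology.

    Each preferred term gets a coined base word plus nested multiword
    variants ("<base>", "severe <base>", "<base> attack") so that
    longest-match resolution is exercised.
    """
    term = Terminology()
    patterns = ("{b}", "severe {b}", "{b} attack")
    for j, code in enumerate(pt_codes):
        base = f"mal{_letters(j)}ia"
        label = f"{base} disorder"
        for pat in patterns[:variants_per_pt]:
            term.add(pat.format(b=base), code, label)
    return term


def plant_signals(
    config: SimConfig,
    n_signals: int,
    relative_rate: float,
    onset_month: str | None = None,
    forum_lead_months: int = 0,
    rng: np.random.Generator | None = None,
) -> SimConfig:
    """Return a copy of *config* with *n_signals* random pairs planted."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    drugs, events = config.drug_ids, config.pt_codes
    total = len(drugs) * len(events)
    if n_signals > total:
        raise ValueError("more signals than pairs in the universe")
    onset = onset_month if onset_month is not None else config.start_month
    picks = rng.choice(total, size=n_signals, replace=False)
    planted = tuple(
        PlantedSignal(
            drugs[p // len(events)],
            events[p % len(events)],
            relative_rate,
            onset,
            forum_lead_months,
        )
        for p in sorted(picks)
    )
    return replace(config, planted_signals=config.planted_signals + planted)


# ---------------------------------------------------------------------------
# stream generation


def generate_streams(config: SimConfig) -> tuple[OccurrenceStream, GroundTruth]:
    """Draw the paired forum/reference occurrence streams.

    Counts per (source, drug, event, month) are independent Poisson with
    mean ``baseline_rate * drug_multiplier * relative_rate(source, month)``,
    times ``messages_per_report_ratio`` in the forum source.  Identical
    config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    drugs = config.drug_ids
    events = config.pt_codes
    months = np.array(list(config.months))
    n_d, n_e, n_m = len(drugs), len(events), len(months)
    drug_pos = {d: i for i, d in enumerate(drugs)}
    event_pos = {e: j for j, e in enumerate(events)}

    mult = np.ones(n_d)
    if config.drug_rate_multipliers is not None:
        for d, m in config.drug_rate_multipliers:
            if m <= 0:
                raise ValueError("drug rate multipliers must be positive")
            mult[drug_pos[d]] = m

    base = config.baseline_rate * mult[:, None, None] * np.ones((n_d, n_e, n_m))
    rate = {FORUM: base.copy(), REFERENCE: base.copy()}

    truth = GroundTruth(set(), {}, {})
    for sig in config.planted_signals:
        i, j = drug_pos[sig.drug_id], event_pos[sig.pt_code]
        ref_onset = month_index(sig.onset_month)
        forum_onset = ref_onset + sig.forum_lead_months
        pair = (sig.drug_id, sig.pt_code)
        truth.signal_pairs.add(pair)
        truth.relative_rate[pair] = sig.relative_rate
        truth.onset[(pair, REFERENCE)] = ref_onset
        truth.onset[(pair, FORUM)] = forum_onset
        rate[REFERENCE][i, j, months >= ref_onset] *= sig.relative_rate
        rate[FORUM][i, j, months >= forum_onset] *= sig.relative_rate
    rate[FORUM] *= config.messages_per_report_ratio

    frames = []
    next_id = 0
    for source in (REFERENCE, FORUM):
        counts = rng.poisson(rate[source])
        di, ej, mk = np.nonzero(counts)
        reps = counts[di, ej, mk]
        di, ej, mk = (np.repeat(x, reps) for x in (di, ej, mk))
        n = di.size
        variant_pick = rng.integers(0, 3, size=n) if n else np.array([], dtype=int)
        prefix = "r" if source == REFERENCE else "f"
        base_words = np.array([f"mal{_letters(j)}ia" for j in range(n_e)])
        terms = np.array(["{b}", "severe {b}", "{b} attack"], dtype=object)
        term_strs = [
            str(terms[v]).format(b=base_words[j]) for v, j in zip(variant_pick, ej)
        ]
        frames.append(
            pd.DataFrame(
                {
                    "occ_id": [f"{prefix}{next_id + k:08d}" for k in range(n)],
                    "source": source,
                    "drug_id": np.array(drugs, dtype=object)[di],
                    "term": term_strs,
                    "month": months[mk],
                }
            )
        )
        next_id += n
    records = pd.concat(frames, ignore_index=True)
    return OccurrenceStream(records, config), truth


def stream_to_occurrences(
    stream: OccurrenceStream, terminology: Terminology
) -> pd.DataFrame:
    """Resolve a stream's variant terms to preferred terms.

    Yields the standard occurrence frame consumed by the counting module,
    bypassing text rendering/annotation (each stream record is one unit).
    """
    df = stream.records
    pt = df["term"].map(lambda t: terminology.resolve(t))
    out = pd.DataFrame(
        {
            "unit_id": df["occ_id"],
            "month": df["month"],
            "source": df["source"],
            "drug_id": df["drug_id"],
            "pt_code": pt,
        }
    )
    return out[OCCURRENCE_COLUMNS]


# ---------------------------------------------------------------------------
# text rendering

POSITIVE_TEMPLATES = (
    "i took {drug} and since then i have {event} .",
    "i have been taking {drug} and now i get {event} .",
    "i started {drug} last month and developed {event} .",
    "after a while on {drug} i used to feel fine but i experienced {event} .",
)

DECOY_TEMPLATES = {
    "indication": "i was prescribed {drug} for {event} .",
    "question": "does {drug} cause {event} ?",
    "no_intake": "my friend read that {drug} may give {event} .",
    "pre_intake": "i took {drug} but i already had {event} before that .",
}


@dataclass(frozen=True)
class RenderConfig:
    decoy_fraction: float = 0.1  # fraction of the corpus that is decoys
    misspelling_prob: float = 0.15  # P(drug written with the planted typo)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")
        if not 0 <= self.misspelling_prob <= 1:
            raise ValueError("misspelling_prob must be a probability")


def render_forum_corpus(
    stream: OccurrenceStream,
    lexicon: DrugLexicon,
    terminology: Terminology,
    render: RenderConfig = RenderConfig(),
) -> tuple[list[dict], pd.DataFrame]:
    """Render forum occurrences into text messages plus a truth table.

    One positive message per forum occurrence (drug surface form +
    first-person intake phrase + event variant), plus decoy messages in the
    configured proportion, cycling through the decoy classes.  The truth
    table labels every message: ``is_true_AE`` is 1 only for positives.
    """
    config = stream.config
    rng = np.random.default_rng(render.seed + config.seed * 100003)
    forum = stream.for_source(FORUM).reset_index(drop=True)
    # raw (unnormalized) spellings; the lexicon stores the same vocabulary,
    # so a complete lexicon resolves every rendered form after stemming
    drug_forms = drug_surface_forms(config.drug_ids)

    def pick_form(drug_id: str) -> str:
        forms = drug_forms[drug_id]
        if rng.random() < render.misspelling_prob:
            return forms["misspelling"]
        return forms["substance"] if rng.random() < 0.5 else forms["brand"]

    messages: list[dict] = []
    truth_rows: list[tuple] = []

    def emit(month: int, text: str, drug_id: str, pt_code: str, label: int, cls: str):
        mid = f"m{len(messages):07d}"
        day = int(rng.integers(1, 29))
        messages.append(
            {
                "id": mid,
                "date": f"{month_str(month)}-{day:02d}",
                "source": FORUM,
                "text": text,
            }
        )
        truth_rows.append((mid, drug_id, pt_code, label, cls))

    templates = POSITIVE_TEMPLATES
    for row in forum.itertuples():
        text = templates[rng.integers(0, len(templates))].format(
            drug=pick_form(row.drug_id), event=row.term
        )
        emit(int(row.month), text, row.drug_id, terminology.resolve(row.term), 1, "")

    n_pos = len(forum)
    frac = render.decoy_fraction
    n_decoys = int(round(n_pos * frac / (1 - frac))) if frac > 0 else 0
    classes = sorted(DECOY_TEMPLATES)
    all_drugs = config.drug_ids
    all_variants = sorted(terminology.variants)
    months = list(config.months)
    for k in range(n_decoys):
        cls = classes[k % len(classes)]
        drug_id = all_drugs[rng.integers(0, len(all_drugs))]
        variant = all_variants[rng.integers(0, len(all_variants))]
        month = months[rng.integers(0, len(months))]
        text = DECOY_TEMPLATES[cls].format(drug=pick_form(drug_id), event=variant)
        emit(month, text, drug_id, terminology.resolve(variant), 0, cls)

    truth = pd.DataFrame(
        truth_rows,
        columns=["message_id", "drug_id", "pt_code", "is_true_AE", "decoy_class"],
    )
    return messages, truth


# ---------------------------------------------------------------------------
# file output


def write_corpus_jsonl(messages: list[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for msg in messages:
            fh.write(json.dumps(msg, sort_keys=True) + "\n")


def write_reports_csv(
    stream: OccurrenceStream, terminology: Terminology, path: str | Path
) -> None:
    """Reference-source reports: CSV report_id, date, drug_id, term."""
    ref = stream.for_source(REFERENCE)
    df = pd.DataFrame(
        {
            "report_id": ref["occ_id"],
            "date": ref["month"].map(month_str),
            "drug_id": ref["drug_id"],
            "term": ref["term"].map(lambda t: terminology.resolve(t)),
        }
    )
    df.to_csv(path, index=False)


def write_truth_csv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)
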