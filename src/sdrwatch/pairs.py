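"""Drug-event pair counting and 2x2 contingency tables.

The counting unit is the message (forum) or report (reference source): a
unit attests a pair at most once, and a unit mentioning k drugs and m event
terms contributes k*m distinct pairs.  Margins are sums over the pair-count
table, so the classical decomposition holds exactly for every pair:

    a = n(drug, event)            b = drug margin - a
    c = event margin - a          d = grand total - a - b - c

where the "other drugs" stratum is the study drugs plus the background
comparator group pooled together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .months import month_index

Pair = tuple[str, str]


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


class PairCountTable:
    """Counts of units attesting each (drug, preferred-term) pair.

    Built from an occurrence frame (columns ``unit_id, month, source,
    drug_id, pt_code``), optionally restricted to dates up to an as-of
    month (cumulative counting).
    """

    def __init__(self, counts: pd.Series, as_of: int | None = None):
        counts = counts[counts > 0].astype(int)
        counts.index = counts.index.set_names(["drug_id", "pt_code"])
        self.counts = counts.sort_index()
        self.as_of = as_of
        self.drug_margin = self.counts.groupby(level="drug_id").sum()
        self.event_margin = self.counts.groupby(level="pt_code").sum()
        self.grand_total = int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)

    def get(self, pair: Pair) -> int:
        return int(self.counts.get(pair, 0))

    @property
    def pairs(self) -> set[Pair]:
        return set(self.counts.index)

    def to_frame(self) -> pd.DataFrame:
        """Pair counts with margins (and a,b,c,d) as a flat frame."""
        df = self.counts.rename("n").reset_index()
        df["drug_margin"] = df["drug_id"].map(self.drug_margin)
        df["event_margin"] = df["pt_code"].map(self.event_margin)
        df["grand_total"] = self.grand_total
        df["a"] = df["n"]
        df["b"] = df["drug_margin"] - df["a"]
        df["c"] = df["event_margin"] - df["a"]
        df["d"] = df["grand_total"] - df["a"] - df["b"] - df["c"]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def count_pairs(
    occurrences: pd.DataFrame,
    as_of_month: int | str | None = None,
    source: str | None = None,
) -> PairCountTable:
    """Count units attesting each pair, cumulatively up to *as_of_month*.

    ``as_of_month=None`` counts the whole window; occurrences are
    deduplicated so a unit counts once per distinct (drug, term) pair.
    """
    df = occurrences
    if source is not None:
        df = df[df["source"] == source]
    if as_of_month is not None:
        if isinstance(as_of_month, str):
            as_of_month = month_index(as_of_month)
        df = df[df["month"] <= as_of_month]
    dedup = df.drop_duplicates(subset=["unit_id", "drug_id", "pt_code"])
    counts = dedup.groupby(["drug_id", "pt_code"]).size()
    if counts.empty:
        counts = pd.Series(
            dtype=int,
            index=pd.MultiIndex.from_arrays([[], []], names=["drug_id", "pt_code"]),
        )
    return PairCountTable(counts, as_of=as_of_month)


def build_contingency(pair: Pair, table: PairCountTable) -> ContingencyTable:
    """2x2 table of *pair* against the rest of the counting universe."""
    if table.grand_total <= 0:
        raise ValueError("empty pair-count table: grand total is zero")
    a = table.get(pair)
    drug_total = int(table.drug_margin.get(pair[0], 0))
    event_total = int(table.event_margin.get(pair[1], 0))
    b = drug_total - a
    c = event_total - a
    d = table.grand_total - a - b - c
    return ContingencyTable(a, b, c, d)


def overlap_pairs(
    forum_table: PairCountTable,
    reference_table: PairCountTable,
    min_count: int = 1,
) -> set[Pair]:
    """Pairs attested in both sources with at least *min_count* units each.

    Matching is exact on (drug id, preferred-term code): no fuzzy event
    matching, so near-synonymous preferred terms stay distinct.
    """
    forum = {p for p, n in forum_table.counts.items() if n >= min_count}
    ref = {p for p, n in reference_table.counts.items() if n >= min_count}
    return forum & ref
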