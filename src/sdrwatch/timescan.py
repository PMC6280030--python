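"""Time-to-detection analysis: first month each signal criterion holds.

For every pair, definition and source, the monthly scan recomputes the
cumulative pair counts and contingency cells as of each month in turn and
returns the first month at which the signal definition fires (none if it
never does).  The signed difference

    delta_time = forum detection month - reference detection month

is negative when the Web source detects first.  ``tabulate_delta`` produces
the per-definition breakdown of pairs with delta < 0, = 0, > 0 among pairs
detected in both sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dispro
from .dispro import DEFINITIONS, GPSPrior

logger = logging.getLogger(__name__)


def _cumulative_cells(occurrences: pd.DataFrame, source: str):
    """Cumulative a,b,c,d per observed pair per month, vectorized.

    Returns (pairs, months, A, B, C, D) where the cell arrays have shape
    (n_pairs, n_months) and months spans the source's observed range.
    """
    df = occurrences[occurrences["source"] == source]
    df = df.drop_duplicates(subset=["unit_id", "drug_id", "pt_code"])
    if df.empty:
        raise ValueError(f"no occurrences for source {source!r}")
    months = np.arange(df["month"].min(), df["month"].max() + 1)
    counts = df.groupby(["drug_id", "pt_code", "month"]).size()
    pairs = sorted({(d, p) for d, p, _ in counts.index})
    pair_pos = {pr: i for i, pr in enumerate(pairs)}
    mat = np.zeros((len(pairs), len(months)), dtype=np.int64)
    m0 = months[0]
    for (d, p, m), v in counts.items():
        mat[pair_pos[(d, p)], m - m0] = v
    cum = np.cumsum(mat, axis=1)

    drugs = np.array([d for d, _ in pairs])
    events = np.array([p for _, p in pairs])
    drug_ids, drug_inv = np.unique(drugs, return_inverse=True)
    event_ids, event_inv = np.unique(events, return_inverse=True)
    drug_cum = np.zeros((len(drug_ids), len(months)))
    event_cum = np.zeros((len(event_ids), len(months)))
    np.add.at(drug_cum, drug_inv, cum)
    np.add.at(event_cum, event_inv, cum)
    total = cum.sum(axis=0)

    a = cum.astype(float)
    b = drug_cum[drug_inv] - a
    c = event_cum[event_inv] - a
    d = total[None, :] - a - b - c
    grid = _GridMargins(drug_inv, event_inv, drug_cum, event_cum, total)
    return pairs, months, a, b, c, d, grid


@dataclass
class _GridMargins:
    """Cumulative margins for the full drug x event grid of one source."""

    drug_inv: np.ndarray
    event_inv: np.ndarray
    drug_cum: np.ndarray
    event_cum: np.ndarray
    total: np.ndarray

    def fit_points(self, a_month: np.ndarray, k: int):
        """(n, E) over the whole grid at month *k*, zero cells included.

        Fitting the empirical-Bayes prior on observed pairs only is badly
        biased when the database is young (nearly every observed count is
        1, so the likelihood concentrates the prior far from 1); the zero
        cells anchor it, as in standard MGPS practice.
        """
        n_grid = np.zeros((self.drug_cum.shape[0], self.event_cum.shape[0]))
        n_grid[self.drug_inv, self.event_inv] = a_month
        e_grid = np.outer(self.drug_cum[:, k], self.event_cum[:, k]) / self.total[k]
        mask = e_grid > 0
        return n_grid[mask], e_grid[mask]


def _flags_at_month(a, b, c, d, prior: GPSPrior | None, ic025_threshold: float):
    """Boolean flag matrix (n_pairs, n_definitions) for one month's cells."""
    e = dispro.expected_count((a, b, c, d))
    panel = pd.DataFrame({"n": a, "E": e})
    panel["PRR"], panel["PRR025"], panel["chi2"] = dispro.prr((a, b, c, d))
    panel["ROR"], panel["ROR025"] = dispro.ror((a, b, c, d))
    panel["RFET_P"] = dispro.rfet((a, b, c, d))
    ebgm_v = np.full(a.shape, np.nan)
    eb05_v = np.full(a.shape, np.nan)
    valid = e > 0
    if prior is not None and valid.any():
        ebgm_v[valid], eb05_v[valid] = dispro.ebgm(a[valid], e[valid], prior)
    panel["EBGM"], panel["EB05"] = ebgm_v, eb05_v
    panel["IC"], panel["IC025"] = dispro.ic(a, e)
    return dispro.apply_definitions(panel, ic025_threshold=ic025_threshold)


def detection_dates(
    occurrences: pd.DataFrame,
    source: str,
    definitions=DEFINITIONS,
    prior_mode: str = "refit",
    ic025_threshold: float = 0.0,
) -> pd.DataFrame:
    """First detection month per pair x definition for one source.

    ``prior_mode="refit"`` re-fits the empirical-Bayes prior on the data
    available as of each month (the surveillance-faithful choice);
    ``"final"`` fits once on the full window and reuses it (faster, and a
    reasonable approximation once the database is large).  Values are
    month indices; NaN when the criterion never holds.
    """
    if prior_mode not in ("refit", "final"):
        raise ValueError("prior_mode must be 'refit' or 'final'")
    pairs, months, a, b, c, d, grid = _cumulative_cells(occurrences, source)
    needs_ebgm = any(dfn in ("ebgm2", "ebgm4", "eb05") for dfn in definitions)

    final_prior: GPSPrior | None = None
    if needs_ebgm and prior_mode == "final":
        n_fit, e_fit = grid.fit_points(a[:, -1], a.shape[1] - 1)
        final_prior = dispro.fit_gps_prior(n_fit, e_fit)

    idx = pd.MultiIndex.from_tuples(pairs, names=["drug_id", "pt_code"])
    det = pd.DataFrame(np.nan, index=idx, columns=list(definitions))
    undetected = {dfn: np.ones(len(pairs), dtype=bool) for dfn in definitions}

    for k, month in enumerate(months):
        ak, bk, ck, dk = a[:, k], b[:, k], c[:, k], d[:, k]
        if ak.sum() + bk.sum() == 0:
            continue
        prior = final_prior
        if needs_ebgm and prior_mode == "refit":
            n_fit, e_fit = grid.fit_points(ak, k)
            if n_fit.size >= 2:
                try:
                    prior = dispro.fit_gps_prior(n_fit, e_fit)
                except dispro.GPSFitError as exc:
                    prior = exc.incumbent
                    logger.warning("GPS fit at %s: using incumbent", month)
            else:
                prior = None
        flags = _flags_at_month(ak, bk, ck, dk, prior, ic025_threshold)
        for dfn in definitions:
            newly = undetected[dfn] & flags[dfn].values
            if newly.any():
                det.loc[newly, dfn] = month
                undetected[dfn] &= ~newly
    return det


def detection_date(
    pair,
    definition: str,
    occurrences: pd.DataFrame,
    source: str,
    prior_mode: str = "refit",
) -> int | None:
    """First month *definition* holds for *pair* in *source*, or None."""
    det = detection_dates(occurrences, source, [definition], prior_mode=prior_mode)
    try:
        value = det.loc[pair, definition]
    except KeyError:
        return None
    return None if pd.isna(value) else int(value)


def delta_time(forum_month: int, reference_month: int) -> int:
    """Signed month difference; negative when the forum detects first."""
    return int(forum_month) - int(reference_month)


def delta_records(
    det_forum: pd.DataFrame, det_reference: pd.DataFrame, definitions=DEFINITIONS
) -> pd.DataFrame:
    """Long frame of delta_time per pair x definition, both-detected only."""
    rows = []
    common = det_forum.index.intersection(det_reference.index)
    for dfn in definitions:
        f = det_forum.loc[common, dfn]
        r = det_reference.loc[common, dfn]
        both = f.notna() & r.notna()
        for pair in common[both]:
            rows.append(
                (*pair, dfn, delta_time(f.loc[pair], r.loc[pair]))
            )
    return pd.DataFrame(rows, columns=["drug_id", "pt_code", "definition", "delta"])


def tabulate_delta(records: pd.DataFrame, definitions=DEFINITIONS) -> pd.DataFrame:
    """Per-definition counts/percentages of delta < 0, = 0, > 0."""
    rows = {}
    for dfn in definitions:
        deltas = records.loc[records["definition"] == dfn, "delta"]
        total = len(deltas)
        neg = int((deltas < 0).sum())
        zero = int((deltas == 0).sum())
        pos = int((deltas > 0).sum())
        rows[dfn] = {
            "n_neg": neg,
            "pct_neg": 100.0 * neg / total if total else float("nan"),
            "n_zero": zero,
            "pct_zero": 100.0 * zero / total if total else float("nan"),
            "n_pos": pos,
            "pct_pos": 100.0 * pos / total if total else float("nan"),
            "total": total,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "definition"
    return out
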