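"""Disproportionality statistics and signal definitions.

For each drug-event pair with 2x2 cells (a, b, c, d) the module computes:

* PRR, its 95% lower confidence bound PRR025, and the Pearson chi-square;
* ROR and its 95% lower confidence bound ROR025;
* RFET: the one-sided upper-tail Fisher exact P value;
* EBGM and EB05: the empirical-Bayes geometric mean of the relative
  reporting ratio under a two-component gamma-Poisson (MGPS) prior, and the
  5th percentile of the posterior;
* IC and IC025: the shrunk information component log2((n+.5)/(E+.5)) with
  its closed-form credibility lower bound.

The eight signal definitions applied to the panel:

    EBGM >= 2;  EBGM >= 4;  EB05 >= 2;  PRR >= 2 & n >= 3 & chi2 >= 4;
    PRR025 >= 1;  ROR025 >= 1;  IC025 > 0;  RFET P <= .05.

Metrics undefined because of zero cells are NaN and never flag a signal;
an optional Haldane-Anscombe +0.5 correction is available but off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .pairs import ContingencyTable, PairCountTable

Z95 = 1.959963984540054  # two-sided 95% normal quantile

DEFINITIONS = ["ebgm2", "ebgm4", "eb05", "prr", "prr025", "ror025", "ic025", "rfet"]

DEFINITION_LABELS = {
    "ebgm2": "EBGM>=2",
    "ebgm4": "EBGM>=4",
    "eb05": "EB05>=2",
    "prr": "PRR>=2, N>=3, chi2>=4",
    "prr025": "PRR025>=1",
    "ror025": "ROR025>=1",
    "ic025": "IC025>0",
    "rfet": "RFET P<=.05",
}


def _cells(table, haldane: bool):
    if isinstance(table, ContingencyTable):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        a, b, c, d = table
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d


def expected_count(table) -> float | np.ndarray:
    """Expected pair count under independence: E = (a+b)(a+c)/N."""
    a, b, c, d = _cells(table, haldane=False)
    n = a + b + c + d
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(n > 0, (a + b) * (a + c) / np.where(n > 0, n, 1.0), np.nan)
    if np.any(n == 0):
        # scalar zero-total tables are a caller error; vector callers get NaN
        if np.ndim(e) == 0:
            raise ValueError("expected_count undefined: grand total is zero")
    return e[()] if np.ndim(e) == 0 else e


def prr(table, haldane: bool = False):
    """(PRR, PRR025, chi2).

    PRR = [a/(a+b)] / [c/(c+d)]; the lower bound uses the standard
    log-normal approximation; chi2 is Pearson's without continuity
    correction.  Zero cells make PRR or its bound NaN unless *haldane*.
    """
    a, b, c, d = _cells(table, haldane)
    n = a + b + c + d
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(
            (a > 0) & (c > 0), (a / (a + b)) / np.where(c > 0, c / (c + d), np.nan), np.nan
        )
        se = np.sqrt(1.0 / a - 1.0 / (a + b) + 1.0 / c - 1.0 / (c + d))
        lower = np.exp(np.log(value) - Z95 * se)
        chi2 = np.where(
            ((a + b) > 0) & ((c + d) > 0) & ((a + c) > 0) & ((b + d) > 0),
            n * (a * d - b * c) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d)).clip(min=1e-300),
            np.nan,
        )
    if np.ndim(value) == 0:
        return float(value), float(lower), float(chi2)
    return value, lower, chi2


def ror(table, haldane: bool = False):
    """(ROR, ROR025): reporting odds ratio ad/(bc) with its 95% lower bound."""
    a, b, c, d = _cells(table, haldane)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where((a > 0) & (b > 0) & (c > 0) & (d > 0), a * d / (b * c), np.nan)
        se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
        lower = np.exp(np.log(value) - Z95 * se)
    if np.ndim(value) == 0:
        return float(value), float(lower)
    return value, lower


def rfet(table):
    """One-sided upper-tail Fisher exact P: P(X >= a | margins fixed)."""
    a, b, c, d = _cells(table, haldane=False)
    n = a + b + c + d
    p = stats.hypergeom.sf(a - 1, n, a + b, a + c)
    p = np.clip(p, 0.0, 1.0)
    return float(p) if np.ndim(p) == 0 else p


def ic(n, e):
    """(IC, IC025): shrunk information component and credibility lower bound.

    IC = log2((n + 0.5)/(E + 0.5));
    IC025 = IC - 3.3 (n+.5)^(-1/2) - 2 (n+.5)^(-3/2).
    """
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    value = np.log2((n + 0.5) / (e + 0.5))
    lower = value - 3.3 * (n + 0.5) ** -0.5 - 2.0 * (n + 0.5) ** -1.5
    if np.ndim(value) == 0:
        return float(value), float(lower)
    return value, lower


# ---------------------------------------------------------------------------
# MGPS empirical-Bayes shrinker


@dataclass(frozen=True)
class GPSPrior:
    """Two-component gamma mixture prior on the relative reporting ratio.

    Component k has shape ``alpha_k`` and rate ``beta_k`` (mean alpha/beta);
    ``p`` is the weight of component 1.  Fitted by maximum marginal
    likelihood across all pairs of a source ("empirical" Bayes).
    """

    p: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")

    def geometric_mean(self) -> float:
        """Prior geometric mean of the relative reporting ratio."""
        g1 = special.psi(self.alpha1) - np.log(self.beta1)
        g2 = special.psi(self.alpha2) - np.log(self.beta2)
        return float(np.exp(self.p * g1 + (1 - self.p) * g2))


def _nb_logpmf(n, e, alpha, beta):
    """log marginal P(n | E) for lambda ~ Gamma(alpha, beta), n ~ Poisson(lambda E)."""
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = n * np.log(e / (beta + e))
    tail = np.where(n == 0, 0.0, tail)  # n=0, E=0 limit: mass 1
    return (
        special.gammaln(alpha + n)
        - special.gammaln(alpha)
        - special.gammaln(n + 1.0)
        + alpha * np.log(beta / (beta + e))
        + tail
    )


def marginal_logpmf(n, e, prior: GPSPrior):
    """log of the mixture marginal mass of observing n with expectation E."""
    l1 = _nb_logpmf(n, e, prior.alpha1, prior.beta1) + np.log(max(prior.p, 1e-300))
    l2 = _nb_logpmf(n, e, prior.alpha2, prior.beta2) + np.log(max(1 - prior.p, 1e-300))
    return np.logaddexp(l1, l2)


#: Fixed multi-start points (p, alpha1, beta1, alpha2, beta2).  The first is
#: the classical MGPS default prior; the others cover well-separated and
#: near-degenerate configurations.
GPS_STARTS: tuple[tuple[float, float, float, float, float], ...] = (
    (1 / 3, 0.2, 0.1, 2.0, 4.0),
    (0.2, 2.0, 0.5, 2.0, 2.0),
    (0.5, 1.0, 1.0, 1.0, 1.0),
    (0.1, 0.5, 0.1, 5.0, 5.0),
    (0.8, 1.0, 0.5, 3.0, 10.0),
)


class GPSFitError(RuntimeError):
    """Raised when no optimizer start converges; carries the best incumbent."""

    def __init__(self, message: str, incumbent: GPSPrior | None, diagnostics: list):
        super().__init__(message)
        self.incumbent = incumbent
        self.diagnostics = diagnostics


def fit_gps_prior(
    n,
    e,
    starts=GPS_STARTS,
) -> GPSPrior:
    """Maximum-marginal-likelihood fit of the two-gamma MGPS prior.

    Parameters are optimized on an unconstrained scale (logit weight, log
    shapes/rates) with L-BFGS-B from each documented start; the best
    optimum wins.  Components are returned ordered by decreasing prior
    mean so fits are comparable across runs.
    """
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    if n.size < 2:
        raise ValueError("need at least 2 (n, E) points to fit a prior")
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")

    def nll(theta):
        p = special.expit(theta[0])
        a1, b1, a2, b2 = np.exp(np.clip(theta[1:], -20, 20))
        l1 = _nb_logpmf(n, e, a1, b1) + np.log(max(p, 1e-300))
        l2 = _nb_logpmf(n, e, a2, b2) + np.log(max(1 - p, 1e-300))
        return -np.sum(np.logaddexp(l1, l2))

    best = None
    diagnostics = []
    for start in starts:
        theta0 = np.array(
            [special.logit(start[0])] + [np.log(v) for v in start[1:]]
        )
        res = optimize.minimize(nll, theta0, method="L-BFGS-B")
        diagnostics.append((start, res.success, float(res.fun)))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise GPSFitError("GPS prior fit failed from all starts", None, diagnostics)
    p = float(special.expit(best.x[0]))
    a1, b1, a2, b2 = (float(v) for v in np.exp(np.clip(best.x[1:], -20, 20)))
    if a1 / b1 < a2 / b2:  # canonical order: high-mean component first
        p, a1, b1, a2, b2 = 1 - p, a2, b2, a1, b1
    prior = GPSPrior(p, a1, b1, a2, b2)
    if not any(ok for _, ok, _ in diagnostics):
        raise GPSFitError(
            "no optimizer start reported convergence", prior, diagnostics
        )
    return prior


def _posterior_weights(n, e, prior: GPSPrior):
    l1 = _nb_logpmf(n, e, prior.alpha1, prior.beta1) + np.log(max(prior.p, 1e-300))
    l2 = _nb_logpmf(n, e, prior.alpha2, prior.beta2) + np.log(max(1 - prior.p, 1e-300))
    m = np.maximum(l1, l2)
    w1 = np.exp(l1 - m)
    w2 = np.exp(l2 - m)
    tot = w1 + w2
    return w1 / tot, w2 / tot


def _mixture_gamma_ppf(q, w1, shape1, rate1, w2, shape2, rate2, iters=200):
    """Quantile of w1*Gamma(shape1, rate1) + w2*Gamma(shape2, rate2).

    Vectorized bisection on the mixture CDF, which is strictly increasing;
    200 halvings of the initial bracket give far better than 1e-10 relative
    precision.
    """
    lo1 = stats.gamma.ppf(q, shape1, scale=1.0 / rate1)
    lo2 = stats.gamma.ppf(q, shape2, scale=1.0 / rate2)
    lo = np.minimum(lo1, lo2)
    hi = np.maximum(lo1, lo2)
    same = np.isclose(lo, hi, rtol=1e-14, atol=0.0)
    lo = np.where(same, lo * 0.999999, lo)
    hi = np.where(same, hi * 1.000001 + 1e-300, hi)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        cdf = w1 * stats.gamma.cdf(mid, shape1, scale=1.0 / rate1) + w2 * stats.gamma.cdf(
            mid, shape2, scale=1.0 / rate2
        )
        below = cdf < q
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def ebgm(n, e, prior: GPSPrior):
    """(EBGM, EB05) for observed count(s) *n* and expected count(s) *e*.

    The posterior over the relative reporting ratio is a two-component
    gamma mixture with shapes alpha_k + n, rates beta_k + E and weights
    proportional to prior weight times component marginal mass.  EBGM is
    the posterior geometric mean 2**E[log2 lambda]; EB05 its 5th
    percentile.
    """
    n = np.asarray(n, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(e < 0) or np.any((e == 0) & (n > 0)):
        raise ValueError("EBGM undefined for negative E (or E=0 with n>0)")
    w1, w2 = _posterior_weights(n, e, prior)
    s1, r1 = prior.alpha1 + n, prior.beta1 + e
    s2, r2 = prior.alpha2 + n, prior.beta2 + e
    log_gm = w1 * (special.psi(s1) - np.log(r1)) + w2 * (special.psi(s2) - np.log(r2))
    value = np.exp(log_gm)
    lower = _mixture_gamma_ppf(0.05, w1, s1, r1, w2, s2, r2)
    if np.ndim(value) == 0:
        return float(value), float(lower)
    return value, lower


# ---------------------------------------------------------------------------
# panel + definitions

PANEL_COLUMNS = [
    "n", "E", "PRR", "PRR025", "chi2", "ROR", "ROR025", "RFET_P",
    "EBGM", "EB05", "IC", "IC025",
]


def metric_panel(
    contingency: pd.DataFrame,
    prior: GPSPrior | None = None,
    haldane: bool = False,
) -> pd.DataFrame:
    """All eight statistics for every pair of a contingency frame.

    *contingency* needs columns ``a, b, c, d`` (as produced by
    ``PairCountTable.to_frame``); the GPS *prior* is fitted on the frame's
    own (n, E) points when not supplied.
    """
    out = contingency.copy()
    cells = (out["a"].values, out["b"].values, out["c"].values, out["d"].values)
    e = expected_count(cells)
    out["n"] = out["a"]
    out["E"] = e
    out["PRR"], out["PRR025"], out["chi2"] = prr(cells, haldane=haldane)
    out["ROR"], out["ROR025"] = ror(cells, haldane=haldane)
    out["RFET_P"] = rfet(cells)
    valid = e > 0
    if prior is None:
        prior = fit_gps_prior(out.loc[valid, "n"].values, e[valid])
    ebgm_v = np.full(len(out), np.nan)
    eb05_v = np.full(len(out), np.nan)
    if valid.any():
        ebgm_v[valid], eb05_v[valid] = ebgm(out.loc[valid, "n"].values, e[valid], prior)
    out["EBGM"], out["EB05"] = ebgm_v, eb05_v
    out["IC"], out["IC025"] = ic(out["n"].values, e)
    out.attrs["gps_prior"] = prior
    return out


def apply_definitions(
    panel: pd.DataFrame,
    ic025_threshold: float = 0.0,
) -> pd.DataFrame:
    """Boolean flag per pair for each of the eight signal definitions.

    NaN metrics (zero-cell tables) never flag.  The information-component
    rule is strict (IC025 > threshold); all other thresholds are inclusive.
    A pair with no observed report (n = 0) is never a signal of
    disproportionate *reporting*, whatever a fitted prior might say.
    """
    with np.errstate(invalid="ignore"):
        flags = pd.DataFrame(
            {
                "ebgm2": panel["EBGM"] >= 2.0,
                "ebgm4": panel["EBGM"] >= 4.0,
                "eb05": panel["EB05"] >= 2.0,
                "prr": (panel["PRR"] >= 2.0) & (panel["n"] >= 3) & (panel["chi2"] >= 4.0),
                "prr025": panel["PRR025"] >= 1.0,
                "ror025": panel["ROR025"] >= 1.0,
                "ic025": panel["IC025"] > ic025_threshold,
                "rfet": panel["RFET_P"] <= 0.05,
            },
            index=panel.index,
        )
    flags = flags.fillna(False)
    return flags & (panel["n"].values >= 1)[:, None]


def score_source(
    table: PairCountTable,
    prior: GPSPrior | None = None,
    haldane: bool = False,
    ic025_threshold: float = 0.0,
) -> pd.DataFrame:
    """Panel + flags for every pair of one source's count table."""
    frame = table.to_frame()
    panel = metric_panel(frame, prior=prior, haldane=haldane)
    flags = apply_definitions(panel, ic025_threshold=ic025_threshold)
    result = pd.concat([panel, flags], axis=1)
    result.attrs["gps_prior"] = panel.attrs["gps_prior"]
    return result.set_index(["drug_id", "pt_code"])
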