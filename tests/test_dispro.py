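import math

import numpy as np
import pytest
from scipy import special, stats

from sdrwatch import dispro
from sdrwatch.dispro import (
    GPSPrior,
    apply_definitions,
    ebgm,
    expected_count,
    fit_gps_prior,
    ic,
    prr,
    rfet,
    ror,
)

DEFAULT_PRIOR = GPSPrior(1 / 3, 0.2, 0.1, 2.0, 4.0)


# -- expected count ---------------------------------------------------------


def test_expected_count_hand_arithmetic():
    assert expected_count((10, 90, 10, 890)) == pytest.approx(2.0)


def test_expected_count_degenerate_and_independent():
    assert expected_count((7, 0, 0, 0)) == pytest.approx(7.0)  # a = N
    # cells proportional to margins: E = a
    assert expected_count((20, 80, 180, 720)) == pytest.approx(20.0)


def test_expected_count_empty_table_signalled():
    with pytest.raises(ValueError):
        expected_count((0, 0, 0, 0))


# -- PRR / ROR / chi2 -------------------------------------------------------


def test_prr_hand_arithmetic():
    value, lower, chi2 = prr((10, 90, 10, 890))
    assert value == pytest.approx(9.0)
    assert lower < value
    assert chi2 > 4


def test_independence_table_is_null():
    value, _, chi2 = prr((20, 80, 180, 720))
    assert value == pytest.approx(1.0)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    r, _ = ror((20, 80, 180, 720))
    assert r == pytest.approx(1.0)


def test_chi2_matches_brute_force_cell_sum(rng):
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(1, 60, size=4))
        n = a + b + c + d
        exp = np.outer([a + b, c + d], [a + c, b + d]) / n
        brute = (((np.array([[a, b], [c, d]]) - exp) ** 2) / exp).sum()
        assert prr((a, b, c, d))[2] == pytest.approx(brute, rel=1e-10)


def test_ror_hand_arithmetic():
    value, lower = ror((10, 90, 10, 890))
    assert value == pytest.approx(8900 / 900)
    assert lower < value


def test_prr_ror_agree_in_rare_event_limit():
    # event proportions below 1e-3 in both strata -> relative gap under 1%
    for a, scale in [(3, 10_000), (10, 50_000), (50, 100_000)]:
        table = (a, scale - a, 2 * a, 3 * scale - 2 * a)
        p = prr(table)[0]
        r = ror(table)[0]
        assert abs(r - p) / p < 0.01


def test_zero_cells_give_nan_unless_haldane():
    value, lower, _ = prr((0, 10, 5, 100))
    assert math.isnan(value) or value == 0.0
    assert math.isnan(lower)
    r, rl = ror((5, 0, 3, 100))
    assert math.isnan(r) and math.isnan(rl)
    r2, _ = ror((5, 0, 3, 100), haldane=True)
    assert np.isfinite(r2)


# -- RFET -------------------------------------------------------------------


def test_fisher_one_sided_small_enumeration():
    # support of X given margins (2,2): {0,1,2}; P(X>=2) = C(2,2)C(2,0)/C(4,2)
    assert rfet((2, 0, 0, 2)) == pytest.approx(1 / 6)


def test_fisher_p_is_one_when_margins_force_a():
    assert rfet((3, 0, 5, 0)) == pytest.approx(1.0)  # all units have the event
    assert rfet((0, 4, 0, 6)) == pytest.approx(1.0)


def test_fisher_matches_scipy_one_sided(rng):
    for _ in range(30):
        a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
        if a + b + c + d == 0:
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        assert rfet((a, b, c, d)) == pytest.approx(p, abs=1e-12)


# -- IC ---------------------------------------------------------------------


def test_ic_zero_when_observed_equals_expected():
    value, lower = ic(5, 5)
    assert value == pytest.approx(0.0)
    assert lower < value


def test_ic_hand_arithmetic():
    value, _ = ic(25, 5)
    assert value == pytest.approx(math.log2(25.5 / 5.5), abs=1e-12)
    assert value == pytest.approx(2.213, abs=5e-4)


def test_ic025_below_ic_for_all_n():
    n = np.arange(0, 200)
    value, lower = ic(n, np.full_like(n, 3.0, dtype=float))
    assert np.all(lower < value)


# -- EBGM -------------------------------------------------------------------


def test_single_component_closed_forms():
    alpha, beta = 1.7, 0.9
    prior = GPSPrior(1.0, alpha, beta, 1.0, 1.0)
    for n in (0, 1, 4, 30):
        for e in (0.2, 2.0, 25.0):
            value, lower = ebgm(n, e, prior)
            assert value == pytest.approx(
                math.exp(special.psi(alpha + n) - math.log(beta + e)), abs=1e-8
            )
            assert lower == pytest.approx(
                stats.gamma.ppf(0.05, alpha + n, scale=1 / (beta + e)), abs=1e-8
            )


def test_posterior_at_no_data_is_prior():
    prior = GPSPrior(1.0, 1.0, 1.0, 2.0, 2.0)
    value, _ = ebgm(0, 0.0, prior)
    assert value == pytest.approx(math.exp(special.psi(1.0)), rel=1e-10)


def test_shrinkage_vanishes_for_large_counts():
    value, _ = ebgm(1000, 100, DEFAULT_PRIOR)
    assert abs(value / 10.0 - 1) < 0.05


def test_ebgm_between_prior_gm_and_mle_on_log_scale():
    prior = DEFAULT_PRIOR
    log_prior_gm = math.log(prior.geometric_mean())
    for n in range(0, 25):
        for e in (0.5, 2.0, 8.0):
            value, lower = ebgm(n, e, prior)
            assert lower <= value
            log_mle = math.log(n / e) if n > 0 else -math.inf
            bound = max(abs(log_prior_gm), abs(log_mle))
            assert abs(math.log(value)) <= bound + 1e-9


def test_ebgm_rejects_bad_expected_counts():
    with pytest.raises(ValueError):
        ebgm(3, 0.0, DEFAULT_PRIOR)
    with pytest.raises(ValueError):
        ebgm(3, -1.0, DEFAULT_PRIOR)


# -- prior fitting ----------------------------------------------------------


def test_fit_requires_two_points_and_positive_e():
    with pytest.raises(ValueError):
        fit_gps_prior([3], [1.0])
    with pytest.raises(ValueError):
        fit_gps_prior([3, 4], [1.0, 0.0])


def test_fit_likelihood_at_optimum_beats_generating_point(rng):
    truth = GPSPrior(0.3, 1.0, 0.5, 2.0, 4.0)
    n_pts = 4000
    comp = rng.random(n_pts) < truth.p
    lam = np.where(
        comp,
        rng.gamma(truth.alpha1, 1 / truth.beta1, n_pts),
        rng.gamma(truth.alpha2, 1 / truth.beta2, n_pts),
    )
    e = np.clip(np.exp(rng.normal(0, 1, n_pts)), 0.05, 50)
    n = rng.poisson(lam * e)
    fit = fit_gps_prior(n, e)
    ll_fit = float(np.sum(dispro.marginal_logpmf(n, e, fit)))
    ll_truth = float(np.sum(dispro.marginal_logpmf(n, e, truth)))
    assert ll_fit >= ll_truth - 1e-6


def test_prior_validation():
    with pytest.raises(ValueError):
        GPSPrior(1.5, 1, 1, 1, 1)
    with pytest.raises(ValueError):
        GPSPrior(0.5, -1, 1, 1, 1)


# -- monotonicity in a at fixed margins ------------------------------------


def test_metrics_monotone_in_a_with_margins_fixed():
    """Transfer one unit into the (drug, event) cell, margins unchanged:
    every disproportionality metric moves toward 'more signal'."""
    tables = [
        (1, 9, 9, 81), (2, 8, 8, 82), (3, 17, 7, 73), (5, 15, 25, 155),
        (1, 19, 4, 76), (4, 6, 16, 74),
    ]
    for a, b, c, d in tables:
        t0, t1 = (a, b, c, d), (a + 1, b - 1, c - 1, d + 1)
        assert prr(t1)[0] > prr(t0)[0]
        assert ror(t1)[0] > ror(t0)[0]
        assert rfet(t1) < rfet(t0)
        e0, e1 = expected_count(t0), expected_count(t1)
        assert e0 == pytest.approx(e1)  # margins preserved
        assert ic(a + 1, e1)[0] > ic(a, e0)[0]
        assert ebgm(a + 1, e1, DEFAULT_PRIOR)[0] > ebgm(a, e0, DEFAULT_PRIOR)[0]


# -- signal definitions -----------------------------------------------------


def _panel_row(**kw):
    import pandas as pd

    base = dict(
        n=5, E=1.0, PRR=np.nan, PRR025=np.nan, chi2=np.nan, ROR=np.nan,
        ROR025=np.nan, RFET_P=np.nan, EBGM=np.nan, EB05=np.nan, IC=np.nan,
        IC025=np.nan,
    )
    base.update(kw)
    return pd.DataFrame([base])


def test_prr_rule_requires_three_cases():
    flags = apply_definitions(_panel_row(n=2, PRR=2.5, chi2=10.0))
    assert not flags.loc[0, "prr"]
    flags = apply_definitions(_panel_row(n=3, PRR=2.5, chi2=10.0))
    assert flags.loc[0, "prr"]


def test_ebgm_thresholds_are_inclusive():
    flags = apply_definitions(_panel_row(EBGM=4.0))
    assert flags.loc[0, "ebgm2"] and flags.loc[0, "ebgm4"]
    flags = apply_definitions(_panel_row(EBGM=3.999))
    assert flags.loc[0, "ebgm2"] and not flags.loc[0, "ebgm4"]


def test_ic_rule_is_strict():
    assert not apply_definitions(_panel_row(IC025=0.0)).loc[0, "ic025"]
    assert apply_definitions(_panel_row(IC025=1e-9)).loc[0, "ic025"]


def test_undefined_metrics_never_flag():
    flags = apply_definitions(_panel_row())
    assert set(flags.columns) == set(dispro.DEFINITIONS)
    assert not flags.loc[0].any()


def test_no_observed_report_never_flags():
    flags = apply_definitions(_panel_row(n=0, EBGM=5.0, EB05=3.0))
    assert not flags.loc[0].any()


def test_ebgm4_implies_ebgm2_on_scored_panel(small_study):
    from sdrwatch.pairs import count_pairs

    scored = dispro.score_source(count_pairs(small_study["occurrences"], source="forum"))
    assert (~scored["ebgm4"] | scored["ebgm2"]).all()
    # invariant ordering of point estimates and lower bounds
    defined = scored.dropna(subset=["PRR", "PRR025", "ROR", "ROR025"])
    assert (defined["PRR025"] <= defined["PRR"] + 1e-12).all()
    assert (defined["ROR025"] <= defined["ROR"] + 1e-12).all()
    assert (scored["EB05"] <= scored["EBGM"] + 1e-12).all()
    assert (scored["IC025"] <= scored["IC"]).all()
    assert scored["RFET_P"].between(0, 1).all()
    e = (scored["n"] + scored["b"]) * (scored["n"] + scored["c"]) / scored["grand_total"]
    assert np.allclose(scored["E"], e)
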