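"""The Audic-Claverie statistic and DET calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from locustexpr.diffexpr import (
    audic_pmf,
    audic_pvalue,
    audic_test,
    bh_fdr,
    call_dets,
)
from locustexpr.simdata import simulate_pair
from locustexpr.readcount import CountTable

GRID_XY = [0, 1, 5, 20, 100]
GRID_R = [0.25, 1.0, 4.0]


def pmf_direct(x, y, r):
    """Direct evaluation of the posterior mass, independent of the tested path."""
    log_mass = (
        y * np.log(r) + gammaln(x + y + 1) - gammaln(x + 1) - gammaln(y + 1)
        - (x + y + 1) * np.log(1 + r)
    )
    return np.exp(log_mass)


def upper_tail_by_summation(x, y, r, tol=1e-16):
    """Term-by-term summation of P(Y >= y | x) to convergence (integer y)."""
    total, k = 0.0, int(np.ceil(y))
    while True:
        term = pmf_direct(x, k, r)
        total += term
        k += 1
        if term < tol * max(total, 1e-300) and k > y + 10:
            return total


def test_pmf_hand_values():
    assert audic_pmf(0, 0, 1, 1) == pytest.approx(0.5)
    assert audic_pmf(1, 1, 1, 1) == pytest.approx(0.25)        # C(2,1)/2^3
    assert audic_pmf(0, 1, 1, 2) == pytest.approx(2 / 9)       # 2/(3^2)


def test_pmf_sums_to_one():
    for x in (0, 3, 10):
        for r in GRID_R:
            total = audic_pmf(x, np.arange(0, 4000), 1, r).sum()
            assert total == pytest.approx(1.0, abs=1e-9)


def test_tail_closed_form_vs_summation():
    from locustexpr.diffexpr import _tails

    for x in GRID_XY:
        for y in GRID_XY:
            for r in GRID_R:
                if y == 0:
                    continue
                _, upper = _tails(np.array(float(x)), np.array(float(y)), r)
                direct = upper_tail_by_summation(x, y, r)
                assert upper == pytest.approx(direct, abs=1e-9), (x, y, r)


@pytest.mark.parametrize("x,r", [(0, 1.0), (5, 1.0), (20, 0.25), (5, 4.0)])
def test_tail_vs_monte_carlo(x, r):
    """For integer x the posterior is NB(x+1, 1/(1+r)); simulate it."""
    from locustexpr.diffexpr import _tails

    rng = np.random.default_rng(42)
    n = 1_000_000
    draws = rng.negative_binomial(x + 1, 1 / (1 + r), size=n)
    for y in (1, 5, 20):
        _, upper = _tails(np.array(float(x)), np.array(float(y)), r)
        est = (draws >= y).mean()
        se = np.sqrt(max(est * (1 - est), float(upper)) / n)
        assert abs(upper - est) < 3 * se + 1e-9


def test_two_sided_hand_values():
    # equal counts, equal sizes: both tails reach 1/2, capped at 1
    assert audic_test(7, 7, 1.0, 1000, 1000) == pytest.approx(1.0)
    # P(Y>=3|x=0, r=1) = sum_{k>=3} (1/2)^{k+1} = 1/8; doubled
    assert audic_test(0, 3, 1.0, 1000, 1000) == pytest.approx(0.25)


def test_length_normalization_defines_x():
    counts = CountTable(
        pd.DataFrame({"A": [10], "B": [4]}, index=["t"]), pd.Series({"A": 100, "B": 100})
    )
    dets = call_dets(counts, "A", "B", pd.Series({"t": 2000}))
    assert dets.loc["t", "x"] == pytest.approx(5.0)  # 10 reads / 2 kb
    assert dets.loc["t", "y"] == pytest.approx(2.0)


def test_symmetry_on_random_tuples():
    rng = np.random.default_rng(0)
    c1 = rng.integers(0, 500, 1000)
    c2 = rng.integers(0, 500, 1000)
    ell = rng.uniform(0.1, 5.0, 1000)
    n1 = rng.integers(10_000, 1_000_000, 1000).astype(float)
    n2 = rng.integers(10_000, 1_000_000, 1000).astype(float)
    p_ab = np.array([audic_test(a, b, l, x, y) for a, b, l, x, y in zip(c1, c2, ell, n1, n2)])
    p_ba = np.array([audic_test(b, a, l, y, x) for a, b, l, x, y in zip(c1, c2, ell, n1, n2)])
    np.testing.assert_allclose(p_ab, p_ba, rtol=1e-9)


def test_upper_tail_monotone_in_y():
    from locustexpr.diffexpr import _tails

    y = np.linspace(0.5, 60, 200)
    for x in (0, 5, 20):
        _, upper = _tails(np.full_like(y, float(x)), y, 1.0)
        assert (np.diff(upper) <= 1e-12).all()


def test_negative_inputs_raise():
    with pytest.raises(ValueError):
        audic_pmf(-1, 0, 1, 1)
    with pytest.raises(ValueError):
        audic_test(1, 1, 0.0, 10, 10)


def test_bh_fdr_hand_values():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert bh_fdr([0.3]) == pytest.approx([0.3])
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3)
    assert bh_fdr([]).size == 0


def test_call_dets_excludes_double_zero(pair_counts):
    dets = call_dets(pair_counts, "lib1", "lib2", pd.Series(
        {"u1": 1000, "u2": 1000, "u3": 1000, "u4": 1000}))
    assert set(dets.index) == {"u1", "u2", "u3", "u4"} - set()
    # all four have at least one nonzero count here; drop u3 to force a zero pair
    counts = pair_counts.counts.copy()
    counts.loc["u3"] = 0
    table = CountTable(counts, counts.sum(axis=0))
    dets = call_dets(table, "lib1", "lib2", pd.Series(
        {"u1": 1000, "u2": 1000, "u3": 1000, "u4": 1000}))
    assert "u3" not in dets.index


def test_null_poisson_type_one_error():
    rates = []
    for seed in range(5):
        counts, _, cat = simulate_pair(5000, de_fraction=0.0, dispersion=0.0, seed=seed)
        dets = call_dets(counts, "A", "B", cat.lengths)
        rates.append((dets["call"] != "ns").mean())
    assert max(rates) <= 0.02


def test_planted_fold_power_and_precision():
    for seed in range(3):
        counts, truth, cat = simulate_pair(
            5000, de_fraction=0.10, fold=4.0, depth=20.0, dispersion=0.0, seed=seed
        )
        dets = call_dets(counts, "A", "B", cat.lengths)
        called = set(dets.index[dets["call"] != "ns"])
        tp = len(called & truth.de_units)
        assert tp / len(called) >= 0.9
        assert tp / len(truth.de_units) >= 0.9


def test_deeper_libraries_yield_more_calls():
    counts_d, _, cat = simulate_pair(3000, 0.10, 2.5, depth=20.0, dispersion=0.0, seed=3)
    counts_s, _, cat_s = simulate_pair(3000, 0.10, 2.5, depth=1.0, dispersion=0.0, seed=3)
    n_deep = (call_dets(counts_d, "A", "B", cat.lengths)["call"] != "ns").sum()
    n_shallow = (call_dets(counts_s, "A", "B", cat_s.lengths)["call"] != "ns").sum()
    assert n_deep > n_shallow
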