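"""Group statistics: median split, Bayes factors, ANOVA, classical tests.

The Bayes-factor integrators are checked three ways: against frozen
hand-verifiable limits, against an independent dense-grid quadrature
oracle written here, and against pingouin's independent implementations.
"""

import numpy as np
import pandas as pd
import pytest

from dotbias import stats as st
from dotbias.stats import _rm_anova_from_array


# ---------------------------------------------------------------------------
# median split
# ---------------------------------------------------------------------------

def test_median_split_two_subjects():
    s = st.median_split([10, 20])
    assert s.threshold == 15 and len(s.low_ids) == 1 and len(s.high_ids) == 1


def test_median_split_reproduces_11_10_groups():
    # 21 scores, median 15, eleven at or below -> 11 low / 10 high
    scores = [5, 7, 9, 10, 11, 12, 13, 14, 14, 15, 15,
              17, 19, 21, 23, 25, 26, 28, 30, 32, 33]
    s = st.median_split(scores)
    assert s.threshold == 15
    assert len(s.low_ids) == 11 and len(s.high_ids) == 10


def test_median_split_degenerate_all_equal():
    with pytest.warns(RuntimeWarning):
        s = st.median_split([15, 15, 15])
    assert len(s.low_ids) == 3 and len(s.high_ids) == 0


# ---------------------------------------------------------------------------
# dense-grid quadrature oracles (independent of scipy.integrate.quad)
# ---------------------------------------------------------------------------

def _jzs_oracle(t, n_eff, df, scale=st.DEFAULT_CAUCHY_SCALE, m=200_001):
    # substitute g = e^x so the integrand decays at both ends; trapezoid
    x = np.linspace(-30.0, 30.0, m)
    g = np.exp(x)
    f = ((1 + n_eff * g) ** -0.5
         * (1 + t * t / ((1 + n_eff * g) * df)) ** (-(df + 1) / 2)
         * scale / np.sqrt(2 * np.pi) * g ** -1.5 * np.exp(-scale ** 2 / (2 * g)))
    num = np.trapezoid(f * g, x)
    return num / (1 + t * t / df) ** (-(df + 1) / 2)


def _pearson_sb_oracle(r, n, m=400_001):
    from scipy import special
    rho = np.linspace(-1 + 1e-12, 1 - 1e-12, m)
    lg = special.gammaln
    c = np.log(n - 2) + lg(n - 1) - 0.5 * np.log(2 * np.pi) - lg(n - 0.5)
    logf = (c + (n - 1) / 2 * np.log1p(-rho ** 2) + (n - 4) / 2 * np.log1p(-r ** 2)
            - (n - 1.5) * np.log1p(-rho * r)
            + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)))
    num = np.trapezoid(np.exp(logf) * 0.5, rho)      # uniform prior on (-1, 1)
    den = np.exp(c + (n - 4) / 2 * np.log1p(-r ** 2)
                 + np.log(special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)))
    return num / den


def _wetzels_oracle(r, n, m=200_001):
    from scipy import special
    x = np.linspace(-30.0, 30.0, m)
    g = np.exp(x)
    logf = ((n - 2) / 2 * np.log1p(g) - (n - 1) / 2 * np.log1p((1 - r * r) * g)
            - 1.5 * np.log(g) - n / (2 * g))
    return np.sqrt(n / 2) / special.gamma(0.5) * np.trapezoid(np.exp(logf) * g, x)


@pytest.mark.parametrize("t,n1,n2", [(0.0, 11, 10), (0.62, 11, 10),
                                     (2.5, 8, 8), (3.32, 11, 10), (5.0, 20, 20)])
def test_jzs_ttest_matches_dense_grid_oracle(t, n1, n2):
    got = st.bf_ttest_jzs(t, n1, n2).bf10
    want = _jzs_oracle(t, n1 * n2 / (n1 + n2), n1 + n2 - 2)
    assert abs(got - want) / want < 1e-6
    assert got == pytest.approx(want, rel=1e-6)


@pytest.mark.parametrize("r,n", [(0.0, 21), (0.24, 21), (0.5, 10),
                                 (0.72, 21), (0.9, 40)])
def test_pearson_bfs_match_dense_grid_oracles(r, n):
    got_sb = st.bf_pearson(r, n).bf10
    assert abs(got_sb - _pearson_sb_oracle(r, n)) / got_sb < 1e-6
    got_jzs = st.bf_pearson_jzs(r, n).bf10
    assert abs(got_jzs - _wetzels_oracle(r, n)) / got_jzs < 1e-6


def test_bfs_match_pingouin():
    pg = pytest.importorskip("pingouin")
    got = st.bf_ttest_jzs(3.32, 11, 10).bf10
    assert got == pytest.approx(float(pg.bayesfactor_ttest(3.32, 11, 10,
                                                           paired=False)),
                                rel=1e-4)
    got = st.bf_pearson(0.72, 21).bf10
    assert got == pytest.approx(float(pg.bayesfactor_pearson(0.72, 21)),
                                rel=1e-4)
    got = st.bf_pearson_jzs(0.72, 21).bf10
    assert got == pytest.approx(float(pg.bayesfactor_pearson(
        0.72, 21, method="wetzels")), rel=1e-4)


def test_bf_null_cases_favour_null():
    assert st.bf_ttest_jzs(0.0, 11, 10).bf10 < 1
    assert st.bf_pearson(0.0, 21).bf10 < 1


def test_bf_symmetry_and_monotonicity():
    for t in (0.5, 1.5, 3.0):
        assert (st.bf_ttest_jzs(t, 11, 10).bf10
                == pytest.approx(st.bf_ttest_jzs(-t, 11, 10).bf10, rel=1e-9))
    bfs = [st.bf_ttest_jzs(t, 11, 10).bf10 for t in (0, 0.5, 1, 2, 3, 4)]
    assert all(a < b for a, b in zip(bfs, bfs[1:]))
    for r in (0.3, 0.6):
        assert (st.bf_pearson(r, 21).bf10
                == pytest.approx(st.bf_pearson(-r, 21).bf10, rel=1e-9))
    bfs = [st.bf_pearson(r, 21).bf10 for r in (0, 0.2, 0.4, 0.6, 0.8)]
    assert all(a < b for a, b in zip(bfs, bfs[1:]))


def test_bfresult_log_consistency():
    res = st.bf_ttest_jzs(2.0, 11, 10)
    assert res.log10_bf10 == pytest.approx(np.log10(res.bf10), abs=1e-12)
    with pytest.raises(ValueError):
        st.BFResult(bf10=-1.0)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

#: 3 subjects x 4 numerosities x 2 conditions, hand-checkable fixture
Y_FIXTURE = np.array([[[3., 5], [4, 7], [6, 8], [5, 9]],
                      [[2., 4], [3, 6], [5, 9], [4, 8]],
                      [[4., 6], [5, 8], [7, 9], [6, 11]]])


def test_rm_anova_hand_computed_fixture():
    tab = _rm_anova_from_array(Y_FIXTURE)
    # frozen from the manual sums-of-squares decomposition
    assert tab.F.to_numpy() == pytest.approx([62.588235, 432.0, 6.117647],
                                             abs=1e-5)
    assert list(tab.df1) == [3, 1, 3] and list(tab.df2) == [6, 2, 6]
    assert tab.ss.to_numpy() == pytest.approx([44.333333, 54.0, 4.333333],
                                              abs=1e-5)


def test_rm_anova_matches_statsmodels():
    sm_anova = pytest.importorskip("statsmodels.stats.anova")
    rows = [dict(subject=s, A=a, B=b, y=Y_FIXTURE[s, a, b])
            for s in range(3) for a in range(4) for b in range(2)]
    df = pd.DataFrame(rows)
    ref = sm_anova.AnovaRM(df, "y", "subject", within=["A", "B"]).fit()
    tab = st.rm_anova_2way(df, dv="y", subject="subject", within=("A", "B"))
    assert tab.F.to_numpy() == pytest.approx(
        ref.anova_table["F Value"].to_numpy(), rel=1e-9)
    assert tab.p.to_numpy() == pytest.approx(
        ref.anova_table["Pr > F"].to_numpy(), rel=1e-9)


def test_rm_anova_zero_variance_gives_zero_F():
    Y = np.tile(np.array([1.0, 2.0, 3.0])[:, None, None], (1, 4, 2))
    tab = _rm_anova_from_array(Y)
    assert (tab.F == 0).all()


def test_rm_anova_rejects_incomplete_design():
    rows = [dict(subject=s, A=a, B=b, y=1.0)
            for s in range(3) for a in range(2) for b in range(2)]
    df = pd.DataFrame(rows[:-1])
    with pytest.raises(ValueError):
        st.rm_anova_2way(df, dv="y", subject="subject", within=("A", "B"))


def test_rm_anova_type_I_error_calibrated():
    rng = np.random.default_rng(99)
    rej = 0
    runs = 2000
    for _ in range(runs):
        tab = _rm_anova_from_array(rng.normal(size=(6, 4, 2)))
        rej += tab.p.iloc[2] < 0.05
    assert abs(rej / runs - 0.05) < 0.015


# ---------------------------------------------------------------------------
# Jarque-Bera and classical tests
# ---------------------------------------------------------------------------

def test_jarque_bera_matches_moment_formula():
    rng = np.random.default_rng(5)
    x = rng.normal(size=20)
    jb, p = st.jarque_bera(x)
    n = len(x)
    m = x - x.mean()
    m2 = np.mean(m ** 2)
    skew = np.mean(m ** 3) / m2 ** 1.5
    kurt = np.mean(m ** 4) / m2 ** 2 - 3
    assert jb == pytest.approx(n / 6 * (skew ** 2 + kurt ** 2 / 4), abs=1e-10)
    from scipy.stats import chi2
    assert p == pytest.approx(chi2.sf(jb, 2), abs=1e-10)


def test_jarque_bera_type_I_error_calibrated():
    rng = np.random.default_rng(17)
    rej = np.mean([st.jarque_bera(rng.normal(size=300))[1] < 0.05
                   for _ in range(2000)])
    assert abs(rej - 0.05) < 0.015


def test_jarque_bera_needs_eight():
    with pytest.raises(ValueError):
        st.jarque_bera([1, 2, 3])


def test_pearson_and_t_hand_values():
    x = [1.0, 2, 3, 4, 5]
    r, _ = st.pearson_r(x, [2.0, 1, 4, 3, 6])
    assert r == pytest.approx(0.8219949365267865, abs=1e-12)
    r, _ = st.pearson_r(x, x)
    assert r == pytest.approx(1.0)
    t, df, p = st.two_sample_t([1.0, 2, 3], [2.0, 4, 9])
    assert t == pytest.approx(-1.3887301496588271, abs=1e-10)
    assert df == 4
    t, _, _ = st.two_sample_t([1.0, 2, 3], [1.0, 2, 3])
    assert t == 0
    with pytest.raises(ValueError):
        st.pearson_r([1, 1, 1], [1, 2, 3])
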