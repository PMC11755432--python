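"""Statistics panel: each statistic against an independent naive oracle."""

import numpy as np
import pytest

from mcqsar.errors import UndefinedStatisticError
from mcqsar.metrics import (
    concordance,
    correlation_intensity,
    cross_validated_q2,
    determination,
    error_stats,
    fisher_ratio,
    ideality_index,
    panel,
)


# -- independent oracles (deliberately naive, loop-based) -----------------

def oracle_r2(obs, pred):
    o, p = np.asarray(obs, float), np.asarray(pred, float)
    cov = np.mean((o - o.mean()) * (p - p.mean()))
    return cov * cov / (o.var() * p.var())


def oracle_ccc(obs, pred):
    o, p = np.asarray(obs, float), np.asarray(pred, float)
    cov = np.mean((o - o.mean()) * (p - p.mean()))
    return 2 * cov / (o.var() + p.var() + (o.mean() - p.mean()) ** 2)


def oracle_iic(obs, pred):
    o, p = np.asarray(obs, float), np.asarray(pred, float)
    r = np.corrcoef(o, p)[0, 1]
    neg = [abs(x - y) for x, y in zip(o, p) if x - y < 0]
    pos = [abs(x - y) for x, y in zip(o, p) if x - y >= 0]
    if not neg or not pos:
        return r
    lo, hi = sorted([np.mean(neg), np.mean(pos)])
    return r if hi == 0 else r * lo / hi


def oracle_cii(obs, pred):
    o, p = np.asarray(obs, float), np.asarray(pred, float)
    r2 = oracle_r2(o, p)
    total = 0.0
    for k in range(o.size):
        ok = np.delete(o, k)
        pk = np.delete(p, k)
        if ok.var() == 0 or pk.var() == 0:
            continue
        total += max(0.0, oracle_r2(ok, pk) - r2)
    return 1.0 - total


def oracle_q2(x, y):
    """Leave-one-out by n explicit univariate refits."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    press = 0.0
    for k in range(x.size):
        xk, yk = np.delete(x, k), np.delete(y, k)
        c1 = np.cov(xk, yk, bias=True)[0, 1] / xk.var()
        c0 = yk.mean() - c1 * xk.mean()
        press += (y[k] - (c0 + c1 * x[k])) ** 2
    return 1.0 - press / ((y - y.mean()) ** 2).sum()


def random_pair(rng, n):
    x = rng.normal(size=n)
    y = 0.7 * x + rng.normal(scale=0.5, size=n) + rng.uniform(-1, 1)
    return x, y


# -- exact examples -------------------------------------------------------

def test_determination_exact_cases():
    y = [1.0, 2.0, 4.0, 8.0]
    assert determination(y, y) == pytest.approx(1.0)
    assert determination(y, [-v for v in y]) == pytest.approx(1.0)


def test_concordance_shift_closed_form():
    obs = np.array([1.0, 2.0, 3.0, 6.0])
    c = 1.5
    v = obs.var()
    assert concordance(obs, obs + c) == pytest.approx(2 * v / (2 * v + c * c))
    assert concordance(obs, obs) == pytest.approx(1.0)


def test_ideality_index_symmetric_residuals():
    obs = np.array([0.0, 1.0, 2.0, 3.0])
    pred = obs + np.array([0.5, -0.5, 0.5, -0.5])
    r = np.corrcoef(obs, pred)[0, 1]
    assert ideality_index(obs, pred) == pytest.approx(r)
    assert ideality_index(obs, obs) == pytest.approx(1.0)


def test_correlation_intensity_collinear():
    x = np.arange(6.0)
    assert correlation_intensity(x, 2 * x + 1) == pytest.approx(1.0)


def test_q2_collinear():
    x = np.array([0.0, 1.0, 2.0, 4.0])
    assert cross_validated_q2(x, 3 * x - 2) == pytest.approx(1.0)


def test_error_stats_hand_cases():
    assert error_stats([1.0, 1.0], [0.0, 2.0]) == (1.0, 1.0)
    rmse, mae = error_stats([0.0, 2.0], [0.0, 0.0])
    assert rmse == pytest.approx(np.sqrt(2))
    assert mae == pytest.approx(1.0)
    assert error_stats([3.0], [3.0]) == (0.0, 0.0)


def test_fisher_ratio_printed_rows():
    """F values recomputed from the published (R2, n) pairs."""
    assert fisher_ratio(0.5, 35) == pytest.approx(33.0)
    assert round(fisher_ratio(0.6235, 35)) == 55
    assert round(fisher_ratio(0.4800, 35)) == 30


# -- oracle equivalence on random data ------------------------------------

@pytest.mark.parametrize(
    "fn, oracle, needs_x",
    [
        (determination, oracle_r2, False),
        (concordance, oracle_ccc, False),
        (ideality_index, oracle_iic, False),
        (correlation_intensity, oracle_cii, False),
        (cross_validated_q2, oracle_q2, True),
    ],
    ids=["r2", "ccc", "iic", "cii", "q2"],
)
def test_statistic_matches_oracle(fn, oracle, needs_x, rng):
    for _ in range(100):
        n = int(rng.integers(5, 51))
        x, y = random_pair(rng, n)
        if needs_x:
            assert fn(x, y) == pytest.approx(oracle(x, y), abs=1e-10)
        else:
            assert fn(y, x) == pytest.approx(oracle(y, x), abs=1e-10)


def test_permutation_invariance(rng):
    x, y = random_pair(rng, 20)
    perm = rng.permutation(20)
    before = panel(y, x, dcw=x)
    after = panel(y[perm], x[perm], dcw=x[perm])
    for name in ("r2", "ccc", "iic", "cii", "q2", "rmse", "mae", "f"):
        assert getattr(before, name) == pytest.approx(getattr(after, name), abs=1e-12)


def test_r2_shift_invariant_ccc_not(rng):
    x, y = random_pair(rng, 15)
    assert determination(y + 3.0, x + 3.0) == pytest.approx(determination(y, x))
    assert concordance(y, y + 3.0) != pytest.approx(1.0)


def test_panel_internal_consistency(rng):
    x, y = random_pair(rng, 30)
    s = panel(y, x, dcw=x)
    assert s.mae <= s.rmse + 1e-12
    assert abs(s.iic) <= np.sqrt(s.r2) + 1e-12
    assert s.q2 <= 1.0


def test_q2_never_exceeds_r2(rng):
    for _ in range(30):
        x, y = random_pair(rng, int(rng.integers(6, 30)))
        pred = np.polyval(np.polyfit(x, y, 1), x)
        assert cross_validated_q2(x, y) <= determination(y, pred) + 1e-12


def test_cii_bounded_and_penalizes_prop_points(rng):
    """CII never exceeds 1 and drops when one point props up the fit."""
    for _ in range(20):
        x, y = random_pair(rng, 12)
        c1, c0 = np.polyfit(x, y, 1)
        assert correlation_intensity(y, c0 + c1 * x) <= 1.0 + 1e-12
    # uncorrelated cloud plus one far outlier that creates the correlation
    x = rng.normal(size=10)
    y = rng.normal(size=10)
    x_prop, y_prop = np.append(x, 12.0), np.append(y, 12.0)
    assert correlation_intensity(y_prop, x_prop) < 0.9


def test_undefined_statistics_raise():
    const = [2.0, 2.0, 2.0, 2.0]
    var = [1.0, 2.0, 3.0, 4.0]
    with pytest.raises(UndefinedStatisticError):
        determination(const, var)
    with pytest.raises(UndefinedStatisticError):
        concordance(const, const)
    with pytest.raises(UndefinedStatisticError):
        cross_validated_q2(const, var)
    with pytest.raises(UndefinedStatisticError):
        fisher_ratio(1.0, 35)
    with pytest.raises(UndefinedStatisticError):
        fisher_ratio(0.5, 2)
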