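"""DACT composite test, empirical null, HIMA screen/MCP, joint-sig, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from epimediate import hdma
from epimediate.assoc import MediationScan
from epimediate.dataio import ValidationError
from epimediate.hdma import (
    NullModel,
    bh_adjust,
    dact,
    estimate_null_proportions,
    hima_screen,
    joint_significance,
    mcp_select,
    prefilter,
)


def _scan_frame(rows):
    df = pd.DataFrame(
        rows, columns=["estimate", "p"],
        index=pd.Index([f"cg{i}" for i in range(len(rows))], name="probe_id"),
    )
    df["se"] = 1.0
    df["statistic"] = df["estimate"]
    df["n"] = 100
    df["converged"] = True
    return df


def test_prefilter_matches_hand_enumeration():
    # six probes with known p/sign patterns; expected survivors enumerated
    em = _scan_frame([(2.0, 0.04), (2.0, 0.04), (-1.0, 0.04),
                      (2.0, 0.06), (2.0, 0.01), (-2.0, 0.03)])
    mo = _scan_frame([(-3.0, 0.04), (3.0, 0.04), (-2.0, 0.04),
                      (-3.0, 0.01), (-1.0, 0.06), (3.0, 0.02)])
    scan = MediationScan(em=em, mo=mo)
    kept = prefilter(scan, alpha=0.05, direction="negative")
    assert list(kept) == ["cg0", "cg5"]  # both p<0.05 and product < 0
    kept_any = prefilter(scan, alpha=0.05, direction="any")
    assert list(kept_any) == ["cg0", "cg1", "cg2", "cg5"]
    kept_pos = prefilter(scan, alpha=0.05, direction="positive")
    assert list(kept_pos) == ["cg1", "cg2"]


def test_empirical_null_on_pure_null_scores():
    for seed in range(10):
        z = np.random.default_rng(500 + seed).normal(0, 1, 10_000)
        nm = estimate_null_proportions(z)
        assert 0.95 <= nm.pi0 <= 1.0
        assert abs(nm.delta) < 0.05
        assert 0.95 <= nm.sigma <= 1.05


def test_empirical_null_detects_signal_fraction():
    # 10% of scores from N(4,1): pi0 should land near 0.9
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        z = np.concatenate([rng.normal(0, 1, 9000), rng.normal(4, 1, 1000)])
        nm = estimate_null_proportions(z)
        assert 0.85 <= nm.pi0 <= 0.95


def test_empirical_null_degenerate_and_fallback():
    with pytest.raises(ValidationError, match="identical"):
        estimate_null_proportions(np.ones(5000))
    # < 200 tests: theoretical null with Storey pi0
    z = np.random.default_rng(1).normal(0, 1, 50)
    nm = estimate_null_proportions(z)
    assert nm.delta == 0.0 and nm.sigma == 1.0 and 0 <= nm.pi0 <= 1


def _aligned(p1, p2):
    idx = pd.Index([f"cg{i}" for i in range(len(p1))], name="probe_id")
    return pd.Series(p1, index=idx), pd.Series(p2, index=idx)


def test_dact_weighted_sum_closed_cases():
    both_null = NullModel(pi0=1.0, delta=0.0, sigma=1.0)
    p_em, p_mo = _aligned([0.2, 0.0], [0.2, 0.0])
    out = dact(p_em, p_mo, both_null, both_null)
    assert out.weights == (0.0, 0.0, 1.0)
    assert out.p_dact.iloc[0] == pytest.approx(0.04)  # max(0.2, 0.2)^2
    assert out.p_dact.iloc[1] == 0.0
    # weights always normalized and nonnegative
    n1 = NullModel(pi0=0.7, delta=0.0, sigma=1.0)
    n2 = NullModel(pi0=0.4, delta=0.0, sigma=1.0)
    out2 = dact(p_em, p_mo, n1, n2)
    assert sum(out2.weights) == pytest.approx(1.0, abs=1e-12)
    assert all(w >= 0 for w in out2.weights)
    expected = (
        out2.weights[0] * 0.2 + out2.weights[1] * 0.2 + out2.weights[2] * 0.04
    )
    assert out2.p_dact.iloc[0] == pytest.approx(expected)


def test_dact_rejects_doubly_zero_pi0():
    none = NullModel(pi0=0.0, delta=0.0, sigma=1.0)
    p_em, p_mo = _aligned([0.5], [0.5])
    with pytest.raises(ValidationError, match="composite null"):
        dact(p_em, p_mo, none, none)


def test_dact_p_bounded_by_max_component():
    rng = np.random.default_rng(3)
    p_em, p_mo = _aligned(rng.uniform(size=500), rng.uniform(size=500))
    nm = NullModel(pi0=0.9, delta=0.0, sigma=1.0)
    out = dact(p_em, p_mo, nm, nm)
    mx = np.maximum(p_em.to_numpy(), p_mo.to_numpy())
    assert (out.p_dact.to_numpy() <= mx + 1e-12).all()
    assert out.p_dact.between(0, 1).all()


def test_hima_screen_dimension_and_ties():
    n = 110  # ceil(110 / ln 110) = 24
    rows = [(float(i % 7), 0.5) for i in range(40)]
    scan_mo = _scan_frame(rows)
    top = hima_screen(scan_mo, n)
    assert len(top) == 24
    # all-|effect|-6 probes come first; ties broken by p then input order
    small = _scan_frame([(3.0, 0.5), (2.0, 0.5), (1.0, 0.5)])
    assert hima_screen(small, 110) == ["cg0", "cg1", "cg2"]
    tie = _scan_frame([(2.0, 0.5), (2.0, 0.1), (1.0, 0.5)])
    d2 = [p for p in hima_screen(tie, 8)]  # d = ceil(8/ln 8) = 4 -> all
    assert d2 == ["cg0", "cg1", "cg2"]
    with pytest.raises(ValidationError):
        hima_screen(small, 2)


def test_mcp_univariate_matches_brute_force():
    # oracle: numeric minimization of 0.5(b-z)^2 + MCP_penalty(b)
    gamma = 3.0

    def mcp_pen(b, lam):
        ab = abs(b)
        if ab <= gamma * lam:
            return lam * ab - b * b / (2 * gamma)
        return 0.5 * gamma * lam * lam

    for z in (-2.0, -0.8, -0.3, 0.0, 0.3, 0.9, 2.5):
        for lam in (0.1, 0.5, 1.0):
            got = hdma._mcp_threshold(z, lam, gamma)
            res = optimize.minimize_scalar(
                lambda b: 0.5 * (b - z) ** 2 + mcp_pen(b, lam),
                bounds=(-10, 10), method="bounded",
                options={"xatol": 1e-10},
            )
            assert got == pytest.approx(res.x, abs=1e-6)


def test_mcp_select_returns_ols_for_strong_single_signal(rng):
    # in the firm-threshold identity region |z| > gamma*lambda the MCP
    # solution is the unpenalized slope; oracle = OLS on residualized data
    n = 300
    e = rng.normal(size=n)
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    y = 2.0 * x + 0.5 * e + rng.normal(size=n) * 0.3
    sel = mcp_select(
        pd.DataFrame({"m": x}), pd.Series(y), pd.Series(e), None
    )
    # once lambda drops below |z|/gamma the MCP solution is unpenalized, so
    # the selected coefficient equals the joint OLS slope of the mediator
    X = np.column_stack([np.ones(n), e, x])
    ols = np.linalg.lstsq(X, y, rcond=None)[0][2]
    assert sel["m"] == pytest.approx(ols, abs=1e-6)


def test_mcp_selects_active_mediators(rng):
    # 8 screened probes, 2 truly active, n=500, low noise
    hits = 0
    for rep in range(100):
        r = np.random.default_rng(rep)
        n = 500
        M = r.normal(size=(n, 8)) * 0.05 + 0.5
        e = r.integers(0, 2, n).astype(float)
        y = 100 - 30 * M[:, 0] - 30 * M[:, 1] - 2 * e + r.normal(size=n) * 1.0
        sel = mcp_select(
            pd.DataFrame(M, columns=[f"m{j}" for j in range(8)]),
            pd.Series(y), pd.Series(e), None,
        )
        hits += {"m0", "m1"} <= set(sel.index)
    assert hits >= 90


def test_joint_significance_and_null_conservativeness(rng):
    p_em, p_mo = _aligned([0.01, 0.0], [0.20, 0.0])
    pj = joint_significance(p_em, p_mo)
    assert pj.iloc[0] == 0.20 and pj.iloc[1] == 0.0
    u1, u2 = _aligned(rng.uniform(size=10_000), rng.uniform(size=10_000))
    rate = (joint_significance(u1, u2) <= 0.05).mean()
    assert rate <= 0.05**2 * 1.4  # conservative: ~alpha^2 under H00


def _bh_oracle(p):
    """Hand step-up BH: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_bh_matches_hand_computation():
    q = bh_adjust(pd.Series([0.01, 0.02, 0.03, 0.04]))
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert bh_adjust(pd.Series([0.3])).iloc[0] == pytest.approx(0.3)
    assert (bh_adjust(pd.Series([1.0, 1.0, 1.0])) == 1.0).all()
    rng = np.random.default_rng(9)
    for _ in range(20):
        p = rng.uniform(size=25)
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)
    with pytest.raises(ValidationError):
        bh_adjust(pd.Series([0.5, 1.5]))


def test_bh_q_monotone_in_p_rank(rng):
    p = rng.uniform(size=100)
    q = bh_adjust(p).to_numpy()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_property_matches_oracle_and_bounds(p):
    q = bh_adjust(pd.Series(p)).to_numpy()
    np.testing.assert_allclose(q, _bh_oracle(p), atol=1e-12)
    assert (q >= np.asarray(p) - 1e-12).all() and (q <= 1.0 + 1e-12).all()


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st.floats(min_value=0.01, max_value=0.99),
    st.floats(min_value=0.01, max_value=0.99),
    st.floats(min_value=1e-8, max_value=1.0),
    st.floats(min_value=1e-8, max_value=1.0),
)
def test_dact_weights_normalized_and_p_in_unit_interval(pi_a, pi_b, p1, p2):
    na = NullModel(pi0=pi_a, delta=0.0, sigma=1.0)
    nb = NullModel(pi0=pi_b, delta=0.0, sigma=1.0)
    p_em, p_mo = _aligned([p1], [p2])
    out = dact(p_em, p_mo, na, nb)
    assert sum(out.weights) == pytest.approx(1.0, abs=1e-12)
    assert all(w >= 0 for w in out.weights)
    assert 0.0 <= out.p_dact.iloc[0] <= 1.0
    assert out.p_dact.iloc[0] <= max(p1, p2) + 1e-12
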