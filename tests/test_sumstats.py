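"""Summary-statistic correctness against hand computations and brute force."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from recombpast import sumstats
from recombpast.sumstats import (HUDSON_C_MAX, haplotype_diversity, hudsons_c,
                                 n_haplotypes, rmin, rmmg, scale_by_s,
                                 seg_sites, summarize, walls_b, walls_q, zns)


def M(*rows):
    return np.array([[int(c) for c in r] for r in rows], dtype=np.uint8)


FOUR_GAMETES = M("00", "01", "10", "11")
PERFECT_LD = M("00", "00", "11", "11")


# ---------------------------------------------------------------------------
# independent oracles


def rmin_oracle(m):
    """Maximum number of mutually disjoint incompatible open intervals,
    by exhaustive search over interval subsets."""
    n, S = m.shape
    pairs = []
    for i, j in itertools.combinations(range(S), 2):
        gametes = {(a, b) for a, b in zip(m[:, i], m[:, j])}
        if len(gametes) == 4:
            pairs.append((i, j))
    best = 0
    for r in range(1, len(pairs) + 1):
        for subset in itertools.combinations(pairs, r):
            ok = all(a2 >= b1 or a1 >= b2
                     for (a1, b1), (a2, b2) in itertools.combinations(subset, 2))
            if ok:
                best = max(best, r)
    return best


def zns_oracle(m):
    n, S = m.shape
    vals = []
    for i, j in itertools.combinations(range(S), 2):
        p1 = m[:, i].mean()
        p2 = m[:, j].mean()
        p11 = np.mean((m[:, i] == 1) & (m[:, j] == 1))
        d = p11 - p1 * p2
        vals.append(d * d / (p1 * (1 - p1) * p2 * (1 - p2)))
    return float(np.mean(vals))


def hudsons_c_oracle(m, c_max=HUDSON_C_MAX):
    """Independent route: variance-of-pairwise-differences moment equation
    with the theta^2 damping factor obtained by numerical quadrature and the
    root found on a fine grid + local bisection."""
    n = m.shape[0]
    d = [int(np.sum(m[i] != m[j]))
         for i, j in itertools.combinations(range(n), 2)]
    d = np.asarray(d, float)
    kbar = d.mean()
    sksq = np.mean((d - kbar) ** 2)
    if kbar == 0:
        return 0.0

    def F(c):
        if c == 0:
            return 1.0
        val, _ = quad(lambda x: (c - x) * (x + 18) / (x * x + 13 * x + 18),
                      0.0, c, limit=200)
        return 2.0 * val / (c * c)

    def E(c):
        lin = 2.0 * (n - 2) / (3.0 * (n - 1))
        qd = (n - 2) * (7.0 * n + 3.0) / (9.0 * n * (n - 1))
        return kbar * lin + kbar * kbar * qd * F(c)

    if sksq >= E(0.0):
        return 0.0
    if sksq <= E(c_max):
        return c_max
    lo, hi = 0.0, c_max
    while hi - lo > 1e-8:
        mid = 0.5 * (lo + hi)
        if E(mid) > sksq:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# hand-computed fixtures


def test_seg_sites():
    assert seg_sites(M("000", "000")) == 0
    assert seg_sites(FOUR_GAMETES) == 2
    # restricted to a row subset, only sites segregating there count
    assert seg_sites(FOUR_GAMETES[:2]) == 1


def test_rmin_fixtures():
    assert rmin(FOUR_GAMETES) == 1
    assert rmin(PERFECT_LD) == 0
    # two disjoint incompatible intervals among 5 sites: (0,1) and (3,4)
    m = M("00000", "01000", "10001", "11010", "00011")
    assert rmin_oracle(m) >= 2
    assert rmin(m) == rmin_oracle(m)


def test_rmmg_fixtures():
    assert rmmg(FOUR_GAMETES) == max(0, 4 - 2 - 1)
    assert rmmg(M("0101", "0101", "0101")) == 0
    assert rmmg(PERFECT_LD) == 0  # nHaps=2 <= S+1


def test_haplotype_counts_and_diversity():
    assert n_haplotypes(FOUR_GAMETES) == 4
    assert haplotype_diversity(FOUR_GAMETES) == pytest.approx(1.0)
    assert n_haplotypes(M("00", "00", "00")) == 1
    assert haplotype_diversity(M("000", "000")) == 0.0
    assert haplotype_diversity(PERFECT_LD) == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        haplotype_diversity(M("01"))


def test_walls_b_and_q():
    assert walls_b(PERFECT_LD) == pytest.approx(1.0)
    assert walls_q(PERFECT_LD) == pytest.approx(1.0)
    assert walls_b(FOUR_GAMETES) == 0.0
    assert walls_q(FOUR_GAMETES) == 0.0
    # 3 sites: pair (0,1) congruent, pair (1,2) incompatible -> B = 1/2
    m = M("000", "001", "110", "111")
    assert walls_b(m) == pytest.approx(0.5)
    assert walls_q(m) == pytest.approx((1 + 1) / 3)
    assert math.isnan(walls_b(M("01", "10")[:, :1]))  # S=1


def test_zns_fixtures():
    assert zns(PERFECT_LD) == pytest.approx(1.0)
    assert zns(FOUR_GAMETES) == pytest.approx(0.0)
    m = M("001", "010", "101", "110")
    assert zns(m) == pytest.approx(zns_oracle(m))
    assert math.isnan(zns(M("0", "1")))


def test_hudsons_c_conventions():
    assert hudsons_c(M("000", "000")) == 0.0
    # variance far above the C=0 expectation clamps to zero
    # (three identical rows and one divergent: kbar=3, S_k^2=9 > E[S_k^2|C=0])
    big = M("000000", "000000", "000000", "111111")
    assert hudsons_c(big) == 0.0


def test_hudsons_c_matches_independent_route():
    # coalescent-shaped matrices give interior roots; iid-random ones
    # exercise the clamps — both routes must agree everywhere
    from recombpast import SimulationConfig, simulate

    rng = np.random.default_rng(7)
    cfg = SimulationConfig(sample_n=10, seed=99)
    mats = [simulate(cfg, replicate_index=i).matrix for i in range(15)]
    mats += [rng.integers(0, 2, size=(10, 20)).astype(np.uint8)
             for _ in range(10)]
    hit_interior = 0
    for m in mats:
        ours = hudsons_c(m)
        ref = hudsons_c_oracle(sumstats._segregating(m))
        assert ours == pytest.approx(ref, abs=1e-4)
        if 0 < ours < HUDSON_C_MAX:
            hit_interior += 1
    assert hit_interior > 0  # the comparison exercised the solver, not just clamps


def test_summarize_and_scaling():
    sv = summarize(FOUR_GAMETES)
    assert (sv.S, sv.Rmin, sv.rmmg, sv.nHaps) == (2, 1, 1, 4)
    sc = scale_by_s(sv)
    assert sc.nHaps == pytest.approx(2.0)
    assert sc.Rmin == pytest.approx(0.5)
    # multiplying back by S recovers the originals
    for name in ("Rmin", "rmmg", "nHaps"):
        assert getattr(sc, name) * sv.S == pytest.approx(getattr(sv, name))
    empty = summarize(M("000", "000"))
    assert empty.S == 0 and empty.HudsonC == 0.0
    assert all(math.isnan(v) for v in scale_by_s(empty).as_array())


# ---------------------------------------------------------------------------
# properties

matrices = st.integers(2, 6).flatmap(
    lambda n: st.integers(1, 6).flatmap(
        lambda s: st.lists(
            st.lists(st.integers(0, 1), min_size=s, max_size=s),
            min_size=n, max_size=n)))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(matrices)
def test_rmin_equals_exhaustive_oracle(rows):
    m = np.array(rows, dtype=np.uint8)
    assert rmin(m) == rmin_oracle(sumstats._segregating(m))


def test_haplotype_bound_can_exceed_four_gamete_bound_on_adversarial_data():
    """Both rmmg and Rmin bound the *true* number of recombination events;
    the haplotype bound is not dominated by the four-gamete bound in
    general (that is why composite bounds improve on either).  Six distinct
    haplotypes over three sites need >= 2 events, which the four-gamete
    test cannot see."""
    m = M("001", "110", "101", "111", "011", "010")
    assert rmmg(m) == 2
    assert rmin(m) == 1  # two incompatible pairs, but their intervals overlap


@settings(max_examples=100, deadline=None, derandomize=True)
@given(matrices)
def test_bounded_statistics_stay_in_unit_interval(rows):
    m = np.array(rows, dtype=np.uint8)
    sv = summarize(m)
    for v in (sv.HapDiv, sv.WallB, sv.WallQ, sv.ZnS):
        assert math.isnan(v) or 0.0 <= v <= 1.0 + 1e-12
    assert sv.HudsonC >= 0.0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(matrices, st.randoms(use_true_random=False))
def test_row_order_invariance(rows, rnd):
    m = np.array(rows, dtype=np.uint8)
    perm = list(range(m.shape[0]))
    rnd.shuffle(perm)
    a = summarize(m).as_array()
    b = summarize(m[perm]).as_array()
    np.testing.assert_allclose(a, b, equal_nan=True)
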