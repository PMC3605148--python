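"""The recombination summary-statistic suite.

Nine statistics of a binary haplotype matrix: the number of segregating
sites ``S`` (a negative control whose mean is invariant to recombination),
and eight recombination-sensitive summaries — the Hudson–Kaplan minimum
number of recombination events ``Rmin``; the Myers–Griffiths haplotype
bound ``rmmg``; the number of distinct haplotypes ``nHaps``; haplotype
diversity ``HapDiv``; Wall's ``B`` and ``Q`` (congruent adjacent
segregating-site pairs); Hudson's ``C`` (a moment estimator of
``rho = 4 Ne r L`` from the variance of pairwise differences); and ``ZnS``
(mean pairwise r² linkage disequilibrium).

A *scaled* variant divides the eight recombination summaries by ``S``,
which acts as a robust proxy for the age of a subsample: old subsamples
accumulate both more mutations and more detectable recombination events,
so the ratio carries joint information about amount and age.

Statistics whose denominators vanish (Wall's B and ZnS at S < 2, Wall's Q
at S = 0, every scaled value at S = 0) are *undefined* and returned as NaN;
downstream feature aggregation skips NaNs rather than zero-filling, which
would bias the feature distributions for young subsamples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from functools import lru_cache
from typing import Tuple, Union

import numpy as np
from scipy.optimize import brentq

from .coalsim import HaplotypeDataset

__all__ = [
    "SummaryVector",
    "ScaledSummaryVector",
    "STAT_NAMES",
    "SCALED_STAT_NAMES",
    "seg_sites",
    "rmin",
    "rmmg",
    "n_haplotypes",
    "haplotype_diversity",
    "walls_b",
    "walls_q",
    "hudsons_c",
    "zns",
    "summarize",
    "scale_by_s",
    "HUDSON_C_MAX",
]

STAT_NAMES = ("S", "Rmin", "rmmg", "nHaps", "HapDiv", "WallB", "WallQ",
              "HudsonC", "ZnS")
SCALED_STAT_NAMES = tuple(s for s in STAT_NAMES if s != "S")

#: Upper clamp for Hudson's C (10x the default simulated rho of 15).
HUDSON_C_MAX = 150.0


@dataclass(frozen=True)
class SummaryVector:
    S: float
    Rmin: float
    rmmg: float
    nHaps: float
    HapDiv: float
    WallB: float
    WallQ: float
    HudsonC: float
    ZnS: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


@dataclass(frozen=True)
class ScaledSummaryVector:
    """The eight recombination summaries divided by S (NaN when S = 0)."""

    Rmin: float
    rmmg: float
    nHaps: float
    HapDiv: float
    WallB: float
    WallQ: float
    HudsonC: float
    ZnS: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


MatrixLike = Union[HaplotypeDataset, np.ndarray]


def _as_matrix(data: MatrixLike) -> np.ndarray:
    m = data.matrix if isinstance(data, HaplotypeDataset) else np.asarray(data)
    return np.asarray(m, dtype=np.uint8)


def _segregating(m: np.ndarray) -> np.ndarray:
    """Columns with both alleles present among the rows given."""
    if m.size == 0:
        return m.reshape(m.shape[0], 0)
    c = m.sum(axis=0)
    keep = (c > 0) & (c < m.shape[0])
    return m[:, keep]


# ---------------------------------------------------------------------------
# individual statistics (public entry points re-filter to segregating columns)


def seg_sites(data: MatrixLike) -> int:
    """Number of segregating sites among the rows considered."""
    return _segregating(_as_matrix(data)).shape[1]


@lru_cache(maxsize=512)
def _triu(s: int) -> Tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(s, 1)


def _gamete_counts(m: np.ndarray) -> Tuple[np.ndarray, ...]:
    """Per site-pair counts of the 11/10/01/00 gametes (S x S arrays).

    The matmul runs in float64 (BLAS) and is exact for any realistic S.
    """
    mf = m.astype(np.float64)
    c = mf.sum(axis=0)
    c11 = mf.T @ mf
    c10 = c[:, None] - c11
    c01 = c[None, :] - c11
    c00 = m.shape[0] - c11 - c10 - c01
    return c11, c10, c01, c00


def _incompatible_pairs(m: np.ndarray) -> np.ndarray:
    """Boolean S x S matrix: pair exhibits all four gametes."""
    c11, c10, c01, c00 = _gamete_counts(m)
    return (c11 > 0) & (c10 > 0) & (c01 > 0) & (c00 > 0)


def _rmin_from_incompatible(inc: np.ndarray) -> int:
    """Greedy scan over incompatible open intervals sorted by right end."""
    ii, jj = np.nonzero(np.triu(inc, 1))
    if len(ii) == 0:
        return 0
    order = np.lexsort((ii, jj))
    count = 0
    last_right = -1
    for a, b in zip(ii[order], jj[order]):
        if a >= last_right:
            count += 1
            last_right = b
    return count


def rmin(data: MatrixLike) -> int:
    """Hudson–Kaplan minimum number of recombination events.

    Every four-gamete-incompatible site pair forces one event in the open
    interval between the sites; the bound is the maximum number of such
    intervals that can be chosen pairwise disjoint, found by the classic
    greedy scan over intervals sorted by right endpoint.
    """
    m = _segregating(_as_matrix(data))
    if m.shape[1] < 2:
        return 0
    return _rmin_from_incompatible(_incompatible_pairs(m))


def n_haplotypes(data: MatrixLike) -> int:
    m = _as_matrix(data)
    return len(_hap_counts(m))


def _hap_counts(m: np.ndarray) -> np.ndarray:
    if m.shape[1] == 0:
        return np.array([m.shape[0]]) if m.shape[0] else np.array([], int)
    v = np.ascontiguousarray(m).view(
        np.dtype((np.void, m.dtype.itemsize * m.shape[1])))
    _, counts = np.unique(v.ravel(), return_counts=True)
    return counts


def rmmg(data: MatrixLike) -> int:
    """Myers–Griffiths haplotype bound over the whole locus:
    max(0, nHaps - S - 1).  A conservative lower bound on Rmin."""
    m = _segregating(_as_matrix(data))
    counts = _hap_counts(m)
    return max(0, len(counts) - m.shape[1] - 1)


def haplotype_diversity(data: MatrixLike) -> float:
    """Sample-corrected probability that two random sequences differ:
    (n/(n-1)) (1 - sum p_h^2)."""
    m = _as_matrix(data)
    n = m.shape[0]
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    counts = _hap_counts(m)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p * p)))


def _wall_bprime_a(m: np.ndarray) -> Tuple[int, int]:
    """(B', A): congruent adjacent pairs and their distinct bipartitions."""
    S = m.shape[1]
    if S < 2:
        return 0, 0
    left = m[:, :-1]
    right = m[:, 1:]
    same = np.all(left == right, axis=0)
    compl = np.all(left != right, axis=0)
    cong = same | compl
    bprime = int(cong.sum())
    if bprime == 0:
        return 0, 0
    # canonical bipartition: flip each congruent column so its first row is 0
    cols = m[:, :-1][:, cong]
    cols = cols ^ cols[0:1, :]
    a = len({cols[:, j].tobytes() for j in range(cols.shape[1])})
    return bprime, a


def walls_b(data: MatrixLike) -> float:
    """Wall's B: fraction of adjacent segregating-site pairs that are
    congruent (induce the same sample bipartition).  NaN when S < 2."""
    m = _segregating(_as_matrix(data))
    S = m.shape[1]
    if S < 2:
        return math.nan
    bprime, _ = _wall_bprime_a(m)
    return bprime / (S - 1)


def walls_q(data: MatrixLike) -> float:
    """Wall's Q: (B' + A)/S with A the number of distinct bipartitions among
    congruent adjacent pairs.  NaN when S = 0."""
    m = _segregating(_as_matrix(data))
    S = m.shape[1]
    if S == 0:
        return math.nan
    bprime, a = _wall_bprime_a(m)
    return (bprime + a) / S


def _zns_from_counts(c11: np.ndarray, n: int) -> float:
    S = c11.shape[0]
    p = np.diag(c11) / n
    d = c11 / n - np.outer(p, p)
    het = p * (1.0 - p)
    r2 = (d * d) / np.outer(het, het)
    return float(r2[_triu(S)].mean())


def zns(data: MatrixLike) -> float:
    """Mean r² linkage disequilibrium over all pairs of segregating sites,
    r² = D²/(p₁(1-p₁)p₂(1-p₂)) with D the gametic disequilibrium.
    NaN when S < 2."""
    m = _segregating(_as_matrix(data))
    if m.shape[1] < 2:
        return math.nan
    mf = m.astype(np.float64)
    return _zns_from_counts(mf.T @ mf, m.shape[0])


# ---------------------------------------------------------------------------
# Hudson's C

_SQRT97 = math.sqrt(97.0)
_ALPHA = (-13.0 + _SQRT97) / 2.0
_BETA = (-13.0 - _SQRT97) / 2.0
_PF_A = (_ALPHA + 18.0) / _SQRT97
_PF_B = -(_BETA + 18.0) / _SQRT97


def _f_locus(c: float) -> float:
    """F(C) = (2/C²) ∫₀^C (C-x)(x+18)/(x²+13x+18) dx — the factor by which
    intragenic recombination at total rate C deflates the θ² component of
    the variance of pairwise differences.  F(0)=1, decreasing to 0."""
    if c < 1e-2:
        # series about 0 avoids catastrophic cancellation in the closed form
        return 1.0 - (2.0 / 9.0) * c + (23.0 / 324.0) * c * c

    def term(a: float) -> float:
        return (c - a) * math.log((c - a) / (-a)) - c

    return 2.0 * (_PF_A * term(_ALPHA) + _PF_B * term(_BETA)) / (c * c)


def _expected_sksq(c: float, n: int, theta: float) -> float:
    """Expected variance (divisor n(n-1)/2) of the pairwise difference
    counts, given sample size n, theta and total recombination C.

    Exact at C = 0 (Tajima's moments of pairwise differences); for C > 0
    the θ² component is damped by the two-locus coalescence-time
    covariance integral F(C).  Monotone decreasing in C.
    """
    lin = 2.0 * (n - 2) / (3.0 * (n - 1))
    quad = (n - 2) * (7.0 * n + 3.0) / (9.0 * n * (n - 1))
    return theta * lin + theta * theta * quad * _f_locus(c)


def hudsons_c(data: MatrixLike, c_max: float = HUDSON_C_MAX) -> float:
    """Hudson's moment estimator of the population recombination rate.

    Equates the observed variance of the ``n(n-1)/2`` pairwise difference
    counts with its expectation given ``theta-hat = mean pairwise
    difference`` and solves for C by bisection (tolerance 1e-6).  Clamped to
    0 when the observed variance exceeds the no-recombination expectation
    and to ``c_max`` when it falls below the expectation at ``c_max``.
    Monomorphic data return 0 by convention.
    """
    m = _segregating(_as_matrix(data))
    if m.shape[0] < 2:
        raise ValueError("hudsons_c requires n >= 2")
    return _hudsons_c_filtered(m, c_max)


def _hudsons_c_filtered(m: np.ndarray, c_max: float) -> float:
    n, S = m.shape
    if S == 0:
        return 0.0
    mf = m.astype(np.float64)
    g = mf @ mf.T
    rs = np.einsum("ii->i", g)
    d = rs[:, None] + rs[None, :] - 2.0 * g
    dv = d[_triu(n)]
    kbar = dv.mean()
    sksq = dv.var()  # divisor n(n-1)/2, matching _expected_sksq
    if kbar == 0.0:
        return 0.0
    if sksq >= _expected_sksq(0.0, n, kbar):
        return 0.0
    if sksq <= _expected_sksq(c_max, n, kbar):
        return float(c_max)
    return float(brentq(lambda c: _expected_sksq(c, n, kbar) - sksq,
                        0.0, c_max, xtol=1e-6))


# ---------------------------------------------------------------------------
# assembly


def summarize(data: MatrixLike, c_max: float = HUDSON_C_MAX) -> SummaryVector:
    """All nine statistics of one dataset (or row-subsample matrix)."""
    m = _segregating(_as_matrix(data))
    n, S = m.shape
    counts = _hap_counts(m)
    nhaps = len(counts)
    p = counts / n
    hapdiv = float(n / (n - 1) * (1.0 - np.sum(p * p))) if n >= 2 else math.nan

    if S >= 2:
        c11, c10, c01, c00 = _gamete_counts(m)
        inc = (c11 > 0) & (c10 > 0) & (c01 > 0) & (c00 > 0)
        r_min = _rmin_from_incompatible(inc)
        bprime, a_parts = _wall_bprime_a(m)
        wall_b = bprime / (S - 1)
        wall_q = (bprime + a_parts) / S
        z = _zns_from_counts(c11, n)
    else:
        r_min = 0
        wall_b = math.nan
        wall_q = math.nan if S == 0 else 0.0
        z = math.nan

    return SummaryVector(
        S=float(S),
        Rmin=float(r_min),
        rmmg=float(max(0, nhaps - S - 1)),
        nHaps=float(nhaps),
        HapDiv=hapdiv,
        WallB=wall_b,
        WallQ=wall_q,
        HudsonC=_hudsons_c_filtered(m, c_max),
        ZnS=z,
    )


def scale_by_s(sv: SummaryVector) -> ScaledSummaryVector:
    """Divide the eight recombination summaries by S (NaN when S = 0)."""
    if sv.S == 0:
        vals = {name: math.nan for name in SCALED_STAT_NAMES}
    else:
        vals = {name: getattr(sv, name) / sv.S for name in SCALED_STAT_NAMES}
    return ScaledSummaryVector(**vals)
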