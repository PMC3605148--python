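"""Closed-form coalescent expectations bounding the power to see old recombination.

Under Kingman's coalescent with constant population size, the time ``T_i``
during which exactly ``i`` ancestral lineages exist is exponentially
distributed.  In units of ``N`` generations for a haploid locus (``2N``
generations for an autosomal locus),

    E[T_i]   = 2 / (i (i - 1)),        i = 2, ..., m
    Var[T_i] = (2 / (i (i - 1)))**2

so coalescence of the final two lineages takes on average half of the total
tree height.  Recombination events older than the subsample's own root are
invisible, which makes the probability that a subsample spans the basal
split of the genealogy the natural power bound for subsampling methods:

    P(root | n) = (n - 1) / (n + 1)

averaged over tree shapes, and, for a *fixed* basal split with ``a`` and
``b`` descendants,

    P = 1 - [C(a, k) + C(b, k)] / C(a + b, k)

for a uniform subsample of size ``k``.
"""

from __future__ import annotations

from math import comb

__all__ = [
    "expected_ti",
    "var_ti",
    "total_expected_depth",
    "p_root",
    "p_root_split",
    "n_gens_to_generations",
]


def expected_ti(i: int) -> float:
    """Expected duration with exactly ``i`` lineages, units of N generations
    (haploid locus; 2N generations for autosomal loci)."""
    if i < 2:
        raise ValueError("expected_ti requires i >= 2")
    return 2.0 / (i * (i - 1))


def var_ti(i: int) -> float:
    """Variance of the inter-coalescent time T_i (exponential: mean squared)."""
    if i < 2:
        raise ValueError("var_ti requires i >= 2")
    return expected_ti(i) ** 2


def total_expected_depth(m: int) -> float:
    """Expected height of the genealogy of ``m`` lineages: sum of E[T_i].

    Telescopes to ``2 (1 - 1/m)``; approaches 2 as the sample grows, half of
    which is the final two-lineage interval.
    """
    if m < 2:
        raise ValueError("total_expected_depth requires m >= 2")
    return 2.0 * (1.0 - 1.0 / m)


def p_root(n: int) -> float:
    """Probability a random n-subsample observes both sides of the basal split,
    averaged over coalescent tree shapes: (n - 1)/(n + 1)."""
    if n < 2:
        raise ValueError("p_root requires n >= 2")
    return (n - 1) / (n + 1)


def p_root_split(a: int, b: int, k: int) -> float:
    """P(a uniform k-subset spans a fixed basal split with sides of size a and b).

    Equals ``1 - [C(a,k) + C(b,k)] / C(a+b,k)``.  ``comb`` returns 0 when
    ``k`` exceeds a side, so one-sided subsets are handled automatically.
    """
    if a < 1 or b < 1:
        raise ValueError("both sides of the split must be non-empty")
    if k < 2 or k > a + b:
        raise ValueError("subsample size must satisfy 2 <= k <= a + b")
    return 1.0 - (comb(a, k) + comb(b, k)) / comb(a + b, k)


def n_gens_to_generations(t: float, ne: float, ploidy: int = 2) -> float:
    """Convert a time in N-generation (haploid) coalescent units to generations.

    For autosomal (diploid) loci one unit is ``2 Ne`` generations.
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    return t * ploidy * ne
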