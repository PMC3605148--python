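"""Coalescent simulation with a recombination rate that changes through time.

This is a backward-time simulator of Kingman's n-coalescent with
recombination (an ancestral recombination graph, ARG) in which the
population recombination rate follows a :class:`~recombpast.profiles.RateProfile`.
The profile is discretized into piecewise-constant epochs; within an epoch
the competing exponential waiting times are exact, and a drawn time that
overshoots the epoch boundary is discarded and redrawn from the boundary
(valid by memorylessness), so the scheme is exact for the discretized
trajectory.

Rates, in coalescent time units of 2N generations:

* coalescence: ``k (k - 1) / 2`` among ``k`` extant lineages;
* recombination: ``(rho_epoch / 2) * span`` per lineage, where ``span`` is
  the breakable length between the leftmost and rightmost ancestral
  material carried by the lineage (events falling in trapped non-ancestral
  material are counted, following the ms convention);
* mutation: infinite-sites Poisson process at rate ``theta / 2`` per unit
  coalescent time per unit sequence length along ancestral branches.

Here ``rho = 4 Ne r L`` and ``theta = 4 Ne mu L`` for a locus of ``L`` bp.
Ancestral segments are dropped as soon as they reach their marginal MRCA,
so the simulation terminates when no ancestral material remains.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Iterator, List, Sequence, Tuple, Union

import numpy as np

from .profiles import RateProfile, make_profile

__all__ = [
    "SimulationConfig",
    "HaplotypeDataset",
    "simulate",
    "simulate_replicates",
    "simulate_at_timepoint",
    "EventCapExceeded",
]

_EVENT_CAP = 10_000_000  # guard against runaway parameterizations

Segment = Tuple[float, float, int]  # (left, right, carrier bitmask)

SeedLike = Union[int, np.random.SeedSequence, None]


class EventCapExceeded(RuntimeError):
    """Raised when a single replicate exceeds the ARG event budget."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated locus.

    theta and rho are derived (``4 Ne mu L`` and ``4 Ne r̄ L``), never stored:
    with the defaults both equal 15, mimicking a 10-kb human locus in a
    region of very strong recombination.
    """

    ne: float = 1.0e4  # diploid effective size
    sample_n: int = 100  # haploid sample size
    locus_L: float = 1.0e4  # bp
    mu: float = 3.75e-8  # mutations/bp/generation
    profile: RateProfile = field(default_factory=lambda: make_profile("constant"))
    seed: int = 0
    replicates: int = 1
    step_gens: float = 20.0  # epoch width used to discretize the profile

    @property
    def theta(self) -> float:
        return 4.0 * self.ne * self.mu * self.locus_L

    @property
    def rho_bar(self) -> float:
        return 4.0 * self.ne * self.profile.mean_rate * self.locus_L


@dataclass
class HaplotypeDataset:
    """A binary sample-by-segregating-site matrix with relative positions."""

    matrix: np.ndarray  # (sample_n, S) uint8
    positions: np.ndarray  # (S,) floats in [0, 1), strictly increasing
    sample_n: int
    locus_L: float = 1.0e4
    provenance: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.sample_n:
            raise ValueError("matrix must be sample_n x S")
        if self.positions.shape != (self.matrix.shape[1],):
            raise ValueError("positions must match the number of columns")


# ---------------------------------------------------------------------------
# ARG machinery


def _merge_segments(sa: List[Segment], sb: List[Segment], full_mask: int
                    ) -> List[Segment]:
    """Union of two disjoint sorted segment lists, OR-ing carrier masks on
    overlap and dropping any stretch whose carriers reach the full sample
    (marginal MRCA)."""
    bounds = sorted({p for l, r, _ in sa for p in (l, r)} |
                    {p for l, r, _ in sb for p in (l, r)})
    out: List[Segment] = []
    ia = ib = 0
    na, nb = len(sa), len(sb)
    for x, y in zip(bounds, bounds[1:]):
        m = 0
        while ia < na and sa[ia][1] <= x:
            ia += 1
        if ia < na and sa[ia][0] <= x:
            m |= sa[ia][2]
        while ib < nb and sb[ib][1] <= x:
            ib += 1
        if ib < nb and sb[ib][0] <= x:
            m |= sb[ib][2]
        if m and m != full_mask:
            if out and out[-1][1] == x and out[-1][2] == m:
                out[-1] = (out[-1][0], y, m)
            else:
                out.append((x, y, m))
    return out


def _split_segments(segs: List[Segment], x: float
                    ) -> Tuple[List[Segment], List[Segment]]:
    left: List[Segment] = []
    right: List[Segment] = []
    for l, r, m in segs:
        if r <= x:
            left.append((l, r, m))
        elif l >= x:
            right.append((l, r, m))
        else:
            left.append((l, x, m))
            right.append((x, r, m))
    return left, right


def _run_arg(n: int, epochs: Sequence[Tuple[float, float, float]],
             rng: random.Random
             ) -> Tuple[List[Tuple[float, List[Segment]]], int]:
    """Run the coalescent-with-recombination; return branch pieces.

    ``epochs`` are (t_start, t_end, rho) in coalescent units, the last with
    ``t_end = inf``.  Each returned piece is ``(duration, segments)`` — the
    lifetime of one lineage between two events, during which its ancestral
    segments (and their carrier sets) are constant.  Mutations are laid down
    on these pieces afterwards.
    """
    full_mask = (1 << n) - 1
    lineages: List[List[Segment]] = [[(0.0, 1.0, 1 << i)] for i in range(n)]
    births: List[float] = [0.0] * n
    pieces: List[Tuple[float, List[Segment]]] = []
    t = 0.0
    e = 0
    n_events = 0
    n_recomb = 0

    while lineages:
        k = len(lineages)
        spans = [segs[-1][1] - segs[0][0] for segs in lineages]
        total_span = math.fsum(spans)
        # Lineages persist only while ancestral material remains, and carrier
        # masks partition the sample at every position, so k >= 2 here.
        while True:
            rho = epochs[e][2]
            coal_rate = 0.5 * k * (k - 1)
            rec_rate = 0.5 * rho * total_span
            total_rate = coal_rate + rec_rate
            dt = rng.expovariate(total_rate)
            if t + dt > epochs[e][1]:
                t = epochs[e][1]
                e += 1
                continue
            t += dt
            break

        n_events += 1
        if n_events > _EVENT_CAP:
            raise EventCapExceeded(
                f"replicate exceeded {_EVENT_CAP} ARG events; "
                "check the rate parameterization")

        if rng.random() * total_rate < coal_rate:
            i = rng.randrange(k)
            j = rng.randrange(k - 1)
            if j >= i:
                j += 1
            if i > j:
                i, j = j, i
            pieces.append((t - births[i], lineages[i]))
            pieces.append((t - births[j], lineages[j]))
            merged = _merge_segments(lineages[i], lineages[j], full_mask)
            # remove j first (j > i) to keep indices valid
            del lineages[j], births[j]
            del lineages[i], births[i]
            if merged:
                lineages.append(merged)
                births.append(t)
        else:
            n_recomb += 1
            u = rng.random() * total_span
            i = 0
            while u > spans[i] and i < k - 1:
                u -= spans[i]
                i += 1
            segs = lineages[i]
            x = segs[0][0] + u
            # Degenerate draws at an exact segment boundary are measure-zero;
            # nudge into the open interval if they occur.
            if x <= segs[0][0] or x >= segs[-1][1]:
                x = segs[0][0] + 0.5 * (segs[-1][1] - segs[0][0])
            pieces.append((t - births[i], segs))
            left, right = _split_segments(segs, x)
            lineages[i] = left
            births[i] = t
            lineages.append(right)
            births.append(t)
    return pieces, n_recomb


def place_mutations(pieces: Sequence[Tuple[float, List[Segment]]],
                    theta: float, rng: np.random.Generator, n: int
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Drop infinite-sites mutations on ARG branch pieces.

    Poisson at rate ``theta / 2`` per unit coalescent time per unit length;
    each mutation lands uniformly on its piece's ancestral material and
    flips the carriers recorded there.  Returns (matrix, positions) with
    columns sorted by position; every column segregates by construction
    (carrier masks are never empty or complete).
    """
    lens = np.array([math.fsum(r - l for l, r, _ in segs)
                     for _, segs in pieces])
    durs = np.array([dur for dur, _ in pieces])
    counts = rng.poisson(0.5 * theta * lens * durs) if len(pieces) else np.array([], int)
    positions: List[float] = []
    masks: List[int] = []
    for (dur, segs), c, L in zip(pieces, counts, lens):
        if c == 0:
            continue
        for u in rng.random(c) * L:
            for l, r, m in segs:
                w = r - l
                if u < w:
                    positions.append(l + u)
                    masks.append(m)
                    break
                u -= w
    if not positions:
        return np.zeros((n, 0), dtype=np.uint8), np.zeros(0)
    order = np.argsort(positions)
    pos = np.asarray(positions)[order]
    nbytes = (n + 7) // 8
    packed = np.frombuffer(
        b"".join(masks[i].to_bytes(nbytes, "little") for i in order),
        dtype=np.uint8).reshape(len(order), nbytes)
    bits = np.unpackbits(packed, axis=1, bitorder="little")[:, :n]
    return np.ascontiguousarray(bits.T), pos


def _epochs_for(profile: RateProfile, step_gens: float, ne: float,
                locus_L: float, sample_time: float = 0.0
                ) -> List[Tuple[float, float, float]]:
    """Epoch list (t0, t1, rho) in coalescent units (2N generations),
    for a sample taken ``sample_time`` generations before present."""
    if sample_time < 0:
        raise ValueError("sample_time must be >= 0")
    T = profile.window_T
    unit = 2.0 * ne  # generations per coalescent unit
    scale = 4.0 * ne * locus_L  # rate -> rho
    epochs: List[Tuple[float, float, float]] = []
    t = 0.0
    horizon = max(0.0, T - sample_time)
    while t < horizon - 1e-9:
        t1 = min(t + step_gens, horizon)
        rate = profile.rate(sample_time + 0.5 * (t + t1))
        epochs.append((t / unit, t1 / unit, scale * rate))
        t = t1
    epochs.append((horizon / unit, math.inf, scale * profile.rate(T)))
    return epochs


def _resolve_rngs(config: SimulationConfig, rng: SeedLike, rep: int = 0
                  ) -> Tuple[random.Random, np.random.Generator]:
    if rng is None:
        ss = np.random.SeedSequence((config.seed, rep))
    elif isinstance(rng, np.random.SeedSequence):
        ss = rng
    else:
        ss = np.random.SeedSequence(int(rng))
    ev_seed, mut_child = ss.generate_state(1)[0], ss.spawn(1)[0]
    return random.Random(int(ev_seed)), np.random.default_rng(mut_child)


def simulate(config: SimulationConfig, rng: SeedLike = None,
             sample_time: float = 0.0, replicate_index: int = 0
             ) -> HaplotypeDataset:
    """Simulate one haplotype dataset under the config's rate profile.

    ``rng`` may be an integer seed or a ``numpy SeedSequence``; when omitted
    the stream is derived deterministically from ``(config.seed,
    replicate_index)`` so that replicates are independently reproducible.
    """
    ev_rng, mut_rng = _resolve_rngs(config, rng, replicate_index)
    epochs = _epochs_for(config.profile, config.step_gens, config.ne,
                         config.locus_L, sample_time)
    pieces, n_recomb = _run_arg(config.sample_n, epochs, ev_rng)
    matrix, positions = place_mutations(pieces, config.theta, mut_rng,
                                        config.sample_n)
    return HaplotypeDataset(
        matrix=matrix, positions=positions, sample_n=config.sample_n,
        locus_L=config.locus_L,
        provenance={"profile": config.profile.label(), "seed": config.seed,
                    "replicate": replicate_index, "sample_time": sample_time,
                    "n_recomb_events": n_recomb})


def simulate_at_timepoint(config: SimulationConfig, sample_time: float,
                          rng: SeedLike = None, replicate_index: int = 0
                          ) -> HaplotypeDataset:
    """Simulate as if the sample were drawn ``sample_time`` generations ago:
    the profile is read at ``sample_time + t`` instead of ``t``."""
    return simulate(config, rng=rng, sample_time=sample_time,
                    replicate_index=replicate_index)


def simulate_replicates(config: SimulationConfig,
                        sample_time: float = 0.0
                        ) -> Iterator[HaplotypeDataset]:
    """Yield ``config.replicates`` independent datasets, replicate ``i``
    seeded from ``(config.seed, i)``."""
    for i in range(config.replicates):
        yield simulate(config, sample_time=sample_time, replicate_index=i)
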