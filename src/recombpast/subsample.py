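"""n-tuple subsampling: summary-statistic distributions over lineage subsets.

Repeatedly drawing ``tuple_n`` lineages from a dataset and recomputing the
summary suite on each subset turns one dataset into a distribution of
summaries.  Young subsamples (few segregating sites) reflect recent
recombination; old subsamples mix old and recent signal, so the mean,
variance and maximum of each statistic over many subsamples carry
information about how recombination was apportioned through time.  A
quartet (``tuple_n = 4``) is the minimum subsample that can span distinct
tree topologies.

Subsamples are drawn independently and uniformly without replacement
within each draw (a lineage may appear in many subsamples, and duplicate
subsamples are allowed).  Sites monomorphic within a subsample are dropped
before computing statistics.  Undefined statistics (NaN) are skipped in the
aggregation; the count of defined values per statistic is retained for
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .coalsim import HaplotypeDataset
from .sumstats import (SCALED_STAT_NAMES, STAT_NAMES, SummaryVector,
                       scale_by_s, summarize)

__all__ = [
    "SubsampleSpec",
    "FEATURE_COLUMNS",
    "draw_subsample",
    "subsample_summaries",
    "feature_vector",
    "feature_matrix",
]

_AGGS = ("mean", "var", "max")

#: Fixed schema of the classification features: mean/variance/maximum of the
#: nine unscaled summaries (27) then of the eight S-scaled summaries (24).
FEATURE_COLUMNS: Tuple[str, ...] = tuple(
    f"{agg}_{stat}" for stat in STAT_NAMES for agg in _AGGS
) + tuple(
    f"{agg}_{stat}_scaled" for stat in SCALED_STAT_NAMES for agg in _AGGS
)

_NDEF_COLUMNS: Tuple[str, ...] = tuple(
    f"ndef_{stat}" for stat in STAT_NAMES) + tuple(
    f"ndef_{stat}_scaled" for stat in SCALED_STAT_NAMES)


@dataclass(frozen=True)
class SubsampleSpec:
    """How to subsample one dataset: quartet defaults, 10^3 draws at paper
    scale (desk runs use fewer)."""

    tuple_n: int = 4
    n_subsamples: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.tuple_n < 4:
            raise ValueError("tuple_n must be >= 4 (a quartet is the minimum)")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")


def draw_subsample(dataset: HaplotypeDataset, tuple_n: int,
                   rng: np.random.Generator) -> HaplotypeDataset:
    """Uniform subsample of ``tuple_n`` distinct rows; columns monomorphic
    within the subsample are dropped, positions preserved for the rest."""
    if tuple_n > dataset.sample_n:
        raise ValueError("tuple_n exceeds the sample size")
    rows = rng.choice(dataset.sample_n, size=tuple_n, replace=False)
    sub = dataset.matrix[rows]
    c = sub.sum(axis=0)
    keep = (c > 0) & (c < tuple_n)
    return HaplotypeDataset(
        matrix=sub[:, keep], positions=dataset.positions[keep],
        sample_n=tuple_n, locus_L=dataset.locus_L,
        provenance=dict(dataset.provenance, subsample=True))


def subsample_summaries(dataset: HaplotypeDataset, spec: SubsampleSpec,
                        rng: Optional[np.random.Generator] = None
                        ) -> pd.DataFrame:
    """One row per subsample: the 9 unscaled + 8 scaled summary values."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.rng_seed))
    mat = dataset.matrix
    n = dataset.sample_n
    rows = np.empty((spec.n_subsamples, len(STAT_NAMES) + len(SCALED_STAT_NAMES)))
    for b in range(spec.n_subsamples):
        idx = rng.choice(n, size=spec.tuple_n, replace=False)
        sub = mat[idx]
        c = sub.sum(axis=0)
        sub = sub[:, (c > 0) & (c < spec.tuple_n)]
        sv = summarize(sub)
        sc = scale_by_s(sv)
        rows[b] = np.concatenate([sv.as_array(), sc.as_array()])
    cols = list(STAT_NAMES) + [f"{s}_scaled" for s in SCALED_STAT_NAMES]
    return pd.DataFrame(rows, columns=cols)


def _aggregate(values: np.ndarray) -> Tuple[float, float, float, int]:
    v = values[~np.isnan(values)]
    ndef = len(v)
    if ndef == 0:
        return np.nan, np.nan, np.nan, 0
    mean = float(v.mean())
    # unbiased sample variance; a single defined value has zero spread
    var = float(v.var(ddof=1)) if ndef > 1 else 0.0
    return mean, var, float(v.max()), ndef


def feature_vector(dataset: HaplotypeDataset, spec: SubsampleSpec,
                   rng: Optional[np.random.Generator] = None) -> pd.Series:
    """Mean/variance/maximum of each summary over the subsample draws,
    skipping undefined values, plus per-statistic defined counts."""
    table = subsample_summaries(dataset, spec, rng=rng)
    out = {}
    for col in table.columns:
        mean, var, mx, ndef = _aggregate(table[col].to_numpy())
        out[f"mean_{col}"] = mean
        out[f"var_{col}"] = var
        out[f"max_{col}"] = mx
        out[f"ndef_{col}"] = ndef
    return pd.Series(out)[list(FEATURE_COLUMNS) + list(_NDEF_COLUMNS)]


def feature_matrix(datasets: Iterable[Tuple[str, HaplotypeDataset]],
                   spec: SubsampleSpec) -> pd.DataFrame:
    """Design matrix for classification: one row per labeled dataset.

    Dataset ``i`` uses the subsample stream derived from
    ``(spec.rng_seed, i)`` so rows are reproducible independently.
    """
    records: List[pd.Series] = []
    labels: List[str] = []
    for i, (label, ds) in enumerate(datasets):
        rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, i)))
        records.append(feature_vector(ds, spec, rng=rng))
        labels.append(label)
    out = pd.DataFrame(records).reset_index(drop=True)
    out["label"] = labels
    return out
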