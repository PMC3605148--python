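"""End-to-end computational experiments.

Drivers for the five studies the package supports:

* ``run_correlation`` — pairwise Pearson correlations among the summary
  statistics over an equal mix of constant / linearly increasing /
  linearly decreasing datasets;
* ``run_constant_sweep`` — summary response curves over a grid of constant
  recombination rates (0–10 rho/kb);
* ``run_time_series`` — summary trajectories for samples taken at a grid
  of past time points under a changing rate profile;
* ``run_three_model`` / ``run_four_model`` — jackknife LDA/QDA assignment
  accuracy of datasets to recombination-history models from n-tuple
  subsampling features;
* ``run_ntuple_sweep`` — three-model accuracy as a function of the
  subsample size.

Paper-scale designs (10^4 datasets per model, 10^3 subsamples each) are
configurable; the desk-scale defaults (300 datasets per model, 200
subsamples) keep a full run on one CPU in minutes while preserving the
qualitative ordering of the feature subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classify import (FOUR_MODEL_LABELS, THREE_MODEL_LABELS, AccuracyReport,
                       loocv_accuracy)
from .coalsim import HaplotypeDataset, SimulationConfig, simulate
from .profiles import preset_profile
from .subsample import FEATURE_COLUMNS, SubsampleSpec, feature_matrix
from .sumstats import SCALED_STAT_NAMES, STAT_NAMES, scale_by_s, summarize

__all__ = [
    "ExperimentConfig",
    "simulate_model_datasets",
    "dataset_summary_table",
    "features_for_models",
    "table1_subsets",
    "run_three_model",
    "run_four_model",
    "run_ntuple_sweep",
    "run_correlation",
    "run_constant_sweep",
    "run_time_series",
    "smooth_curve",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Scales and seeds shared by the experiment drivers."""

    datasets_per_model: int = 300
    n_subsamples: int = 200
    tuple_n: int = 4
    seed: int = 0
    ne: float = 1.0e4
    sample_n: int = 100
    locus_L: float = 1.0e4
    mu: float = 3.75e-8
    mean_rate: float = 3.75e-8
    window_T: float = 1.0e4
    step_gens: float = 20.0

    def sim_config(self, preset: str) -> SimulationConfig:
        return SimulationConfig(
            ne=self.ne, sample_n=self.sample_n, locus_L=self.locus_L,
            mu=self.mu, profile=preset_profile(
                preset, mean_rate=self.mean_rate, window_T=self.window_T),
            seed=self.seed, step_gens=self.step_gens)


def _model_seed(seed: int, model_idx: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence((seed, model_idx, rep))


def simulate_model_datasets(cfg: ExperimentConfig, models: Sequence[str],
                            n_per_model: Optional[int] = None
                            ) -> List[Tuple[str, HaplotypeDataset]]:
    """Simulate ``n_per_model`` labeled datasets under each named profile
    preset.  Streams are derived from (seed, model index, replicate) so any
    single dataset can be regenerated in isolation."""
    n_per_model = n_per_model or cfg.datasets_per_model
    out: List[Tuple[str, HaplotypeDataset]] = []
    for mi, name in enumerate(models):
        sim = cfg.sim_config(name)
        for r in range(n_per_model):
            ds = simulate(sim, rng=_model_seed(cfg.seed, mi, r))
            out.append((name, ds))
    return out


def dataset_summary_table(datasets: Iterable[Tuple[str, HaplotypeDataset]]
                          ) -> pd.DataFrame:
    """Full-sample summary statistics, one row per labeled dataset."""
    rows = []
    for label, ds in datasets:
        sv = summarize(ds)
        sc = scale_by_s(sv)
        row = {s: getattr(sv, s) for s in STAT_NAMES}
        row.update({f"{s}_scaled": getattr(sc, s) for s in SCALED_STAT_NAMES})
        row["label"] = label
        rows.append(row)
    return pd.DataFrame(rows)


def features_for_models(cfg: ExperimentConfig,
                        datasets: Sequence[Tuple[str, HaplotypeDataset]],
                        tuple_n: Optional[int] = None,
                        n_subsamples: Optional[int] = None) -> pd.DataFrame:
    spec = SubsampleSpec(tuple_n=tuple_n or cfg.tuple_n,
                         n_subsamples=n_subsamples or cfg.n_subsamples,
                         rng_seed=cfg.seed + 1)
    return feature_matrix(datasets, spec)


# ---------------------------------------------------------------------------
# feature subsets (the rows of the assignment-accuracy table)


def table1_subsets() -> Dict[str, List[str]]:
    """Named feature subsets: each statistic's mean/variance/maximum alone,
    the per-aggregate and combined 'all unscaled'/'all scaled' sets, and the
    full 51-feature combination."""
    subsets: Dict[str, List[str]] = {}
    for stat in STAT_NAMES:
        for agg in ("mean", "var", "max"):
            subsets[f"{agg} {stat}"] = [f"{agg}_{stat}"]
    for stat in SCALED_STAT_NAMES:
        for agg in ("mean", "var", "max"):
            subsets[f"{agg} {stat} scaled"] = [f"{agg}_{stat}_scaled"]
    unscaled = [c for c in FEATURE_COLUMNS if not c.endswith("_scaled")]
    scaled = [c for c in FEATURE_COLUMNS if c.endswith("_scaled")]
    for agg in ("mean", "var", "max"):
        subsets[f"all unscaled {agg}"] = [c for c in unscaled if c.startswith(agg)]
        subsets[f"all scaled {agg}"] = [c for c in scaled if c.startswith(agg)]
    subsets["all unscaled"] = unscaled
    subsets["all scaled"] = scaled
    subsets["all combined"] = list(FEATURE_COLUMNS)
    subsets["S only"] = ["mean_S", "var_S", "max_S"]
    return subsets


def _accuracy_by_subset(features: pd.DataFrame, labels_order,
                        subsets: Dict[str, List[str]], method: str
                        ) -> Dict[str, AccuracyReport]:
    y = features["label"].to_list()
    out = {}
    for name, cols in subsets.items():
        out[name] = loocv_accuracy(features[cols], y, method=method,
                                   labels=labels_order)
    return out


def run_three_model(cfg: ExperimentConfig, method: str = "lda",
                    subsets: Optional[Dict[str, List[str]]] = None,
                    features: Optional[pd.DataFrame] = None
                    ) -> Dict[str, AccuracyReport]:
    """Constant vs linearly increasing vs linearly decreasing recombination
    (equal total recombination): LOOCV assignment accuracy per feature
    subset.  Chance is 1/3."""
    if features is None:
        data = simulate_model_datasets(cfg, THREE_MODEL_LABELS)
        features = features_for_models(cfg, data)
    if subsets is None:
        subsets = table1_subsets()
    return _accuracy_by_subset(features, THREE_MODEL_LABELS, subsets, method)


def run_four_model(cfg: ExperimentConfig, method: str = "lda",
                   subsets: Optional[Dict[str, List[str]]] = None,
                   features: Optional[pd.DataFrame] = None
                   ) -> Dict[str, AccuracyReport]:
    """Constant-low / constant-high (15% and 85% of the linear maximum) vs
    linearly increasing / decreasing.  Chance is 1/4."""
    if features is None:
        data = simulate_model_datasets(cfg, FOUR_MODEL_LABELS)
        features = features_for_models(cfg, data)
    if subsets is None:
        subsets = {"all combined": list(FEATURE_COLUMNS)}
    return _accuracy_by_subset(features, FOUR_MODEL_LABELS, subsets, method)


def run_ntuple_sweep(cfg: ExperimentConfig, sizes: Sequence[int],
                     method: str = "lda",
                     datasets: Optional[Sequence[Tuple[str, HaplotypeDataset]]] = None,
                     n_subsamples: Optional[int] = None) -> pd.DataFrame:
    """Three-model accuracy (full feature set) per subsample size, the LDA
    transform refitted for each size."""
    if datasets is None:
        datasets = simulate_model_datasets(cfg, THREE_MODEL_LABELS)
    rows = []
    for n in sizes:
        feats = features_for_models(cfg, datasets, tuple_n=n,
                                    n_subsamples=n_subsamples)
        rep = loocv_accuracy(feats[list(FEATURE_COLUMNS)],
                             feats["label"].to_list(), method=method,
                             labels=THREE_MODEL_LABELS)
        rows.append({"tuple_n": n, "accuracy": rep.overall})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# correlation and response-curve studies


def run_correlation(cfg: ExperimentConfig,
                    summaries: Optional[pd.DataFrame] = None) -> dict:
    """Pearson correlation matrices over the pooled three-model mix.

    Returns matrices for the nine summaries ("with_S"), the eight
    recombination summaries ("without_S") and the scaled set, along with
    the mean and range of the off-diagonal |r| for each.
    """
    if summaries is None:
        data = simulate_model_datasets(cfg, THREE_MODEL_LABELS)
        summaries = dataset_summary_table(data)
    out = {}
    for key, cols in (("with_S", list(STAT_NAMES)),
                      ("without_S", [c for c in STAT_NAMES if c != "S"]),
                      ("scaled", [f"{s}_scaled" for s in SCALED_STAT_NAMES])):
        corr = summaries[cols].corr()  # pairwise-complete Pearson
        vals = corr.to_numpy()[np.triu_indices(len(cols), 1)]
        vals = vals[~np.isnan(vals)]
        out[key] = {
            "matrix": corr,
            "mean_abs_offdiag": float(np.mean(np.abs(vals))),
            "range_abs_offdiag": (float(np.min(np.abs(vals))),
                                  float(np.max(np.abs(vals)))),
        }
    m = out["with_S"]["matrix"]
    out["hudsonC_vs_ZnS"] = float(m.loc["HudsonC", "ZnS"])
    return out


def _summary_quantile_row(svs: pd.DataFrame) -> dict:
    row = {}
    for col in svs.columns:
        v = svs[col].to_numpy()
        v = v[~np.isnan(v)]
        row[f"mean_{col}"] = v.mean() if len(v) else np.nan
        row[f"q025_{col}"] = np.quantile(v, 0.025) if len(v) else np.nan
        row[f"q975_{col}"] = np.quantile(v, 0.975) if len(v) else np.nan
    return row


def run_constant_sweep(cfg: ExperimentConfig, rho_per_kb: Sequence[float],
                       replicates: int = 1000) -> pd.DataFrame:
    """Mean and 95% quantile band of each summary at each constant rate.

    ``rho_per_kb`` is the population rate per kb (the default locus carries
    rho/kb = 1.5); rates are converted through r = rho_total/(4 Ne L).
    """
    rows = []
    for gi, rk in enumerate(rho_per_kb):
        rho_total = rk * cfg.locus_L / 1000.0
        r = rho_total / (4.0 * cfg.ne * cfg.locus_L)
        c = replace(cfg, mean_rate=r)
        sim = c.sim_config("constant")
        svs = []
        for rep in range(replicates):
            ds = simulate(sim, rng=np.random.SeedSequence((cfg.seed, 101, gi, rep)))
            sv = summarize(ds)
            svs.append({s: getattr(sv, s) for s in STAT_NAMES})
        row = _summary_quantile_row(pd.DataFrame(svs))
        row["rho_per_kb"] = rk
        rows.append(row)
    return pd.DataFrame(rows)


def run_time_series(cfg: ExperimentConfig, preset: str,
                    sample_times: Sequence[float],
                    replicates: int = 500) -> pd.DataFrame:
    """Track the summaries for samples taken at past time points.

    For each sampling time the profile is read shifted into the past, so
    the table traces how each summary's mean and 95% band respond — with a
    lag — to the changing recombination rate.  Also records the rate at the
    sampling instant, in rho per kb.
    """
    sim = cfg.sim_config(preset)
    rows = []
    for ti, t in enumerate(sample_times):
        svs = []
        for rep in range(replicates):
            ds = simulate(sim, rng=np.random.SeedSequence((cfg.seed, 202, ti, rep)),
                          sample_time=float(t))
            sv = summarize(ds)
            svs.append({s: getattr(sv, s) for s in STAT_NAMES})
        row = _summary_quantile_row(pd.DataFrame(svs))
        row["sample_time"] = float(t)
        row["rate_rho_per_kb"] = (4.0 * cfg.ne * sim.profile.rate(float(t))
                                  * 1000.0)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# presentation smoother


def _sph_kernel(q: np.ndarray) -> np.ndarray:
    """Cubic-spline smoothing kernel (the standard SPH kernel), support 2."""
    w = np.zeros_like(q)
    m1 = q <= 1.0
    m2 = (q > 1.0) & (q <= 2.0)
    w[m1] = 1.0 - 1.5 * q[m1] ** 2 + 0.75 * q[m1] ** 3
    w[m2] = 0.25 * (2.0 - q[m2]) ** 3
    return w


def smooth_curve(x: Sequence[float], y: Sequence[float],
                 grid: Optional[Sequence[float]] = None,
                 nn_frac: float = 0.5, const_frac: float = 0.1,
                 degree: int = 2) -> pd.DataFrame:
    """Local polynomial regression (degree 2) with an SPH kernel.

    The bandwidth at each evaluation point is the distance to its
    ``nn_frac``-fraction nearest neighbour plus ``const_frac`` of the data
    range (a 50% nearest-neighbour bandwidth with a 10% constant component
    by default).  Presentation only — never used for inference.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < max(5, degree + 1):
        raise ValueError("need at least 5 points")
    if grid is None:
        grid = x
    grid = np.asarray(grid, float)
    span = x.max() - x.min()
    k = max(degree + 1, int(np.ceil(nn_frac * len(x))))
    fitted = np.empty(len(grid))
    for i, g in enumerate(grid):
        d = np.abs(x - g)
        h = np.sort(d)[min(k, len(x)) - 1] + const_frac * span
        w = _sph_kernel(d / max(h, 1e-300))
        use = w > 0
        if use.sum() < degree + 1:
            use = np.argsort(d)[:degree + 1]
            w = np.ones(len(x))
            mask = np.zeros(len(x), bool)
            mask[use] = True
            use = mask
        coeffs = np.polyfit(x[use] - g, y[use], degree, w=np.sqrt(w[use]))
        fitted[i] = coeffs[-1]
    return pd.DataFrame({"x": grid, "fitted": fitted})
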