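"""Subsampling mechanics and feature aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recombpast import (FEATURE_COLUMNS, SimulationConfig, SubsampleSpec,
                        draw_subsample, feature_matrix, feature_vector,
                        simulate, summarize)
from recombpast.coalsim import HaplotypeDataset


def make_ds(rows, positions=None):
    m = np.array([[int(c) for c in r] for r in rows], dtype=np.uint8)
    pos = np.asarray(positions if positions is not None
                     else np.linspace(0.1, 0.9, m.shape[1]))
    return HaplotypeDataset(matrix=m, positions=pos, sample_n=m.shape[0])


def test_feature_schema():
    assert len(FEATURE_COLUMNS) == 51
    assert FEATURE_COLUMNS[:3] == ("mean_S", "var_S", "max_S")
    assert "mean_ZnS_scaled" in FEATURE_COLUMNS


def test_draw_subsample_drops_monomorphic_columns():
    ds = make_ds(["00", "01", "10", "11"])
    rng = np.random.default_rng(0)
    seen = set()
    for _ in range(50):
        sub = draw_subsample(ds, 2, rng)
        assert sub.sample_n == 2
        cols = sub.matrix.sum(axis=0)
        assert np.all((cols > 0) & (cols < 2))
        seen.add(sub.n_sites)
    assert 1 in seen  # e.g. rows {00,01} keep exactly one segregating site
    with pytest.raises(ValueError):
        draw_subsample(ds, 5, rng)


def test_full_size_subsample_is_identity():
    cfg = SimulationConfig(seed=21, sample_n=10)
    ds = simulate(cfg)
    spec = SubsampleSpec(tuple_n=10, n_subsamples=25, rng_seed=3)
    fv = feature_vector(ds, spec)
    full = summarize(ds)
    for stat in ("S", "Rmin", "nHaps", "HapDiv", "ZnS"):
        assert fv[f"var_{stat}"] == pytest.approx(0.0, abs=1e-12)
        assert fv[f"mean_{stat}"] == pytest.approx(getattr(full, stat))
        assert fv[f"max_{stat}"] == pytest.approx(getattr(full, stat))


def test_single_subsample_has_zero_variance_features():
    ds = simulate(SimulationConfig(seed=22, sample_n=8))
    fv = feature_vector(ds, SubsampleSpec(tuple_n=4, n_subsamples=1, rng_seed=0))
    var_cols = [c for c in FEATURE_COLUMNS if c.startswith("var_")]
    assert all(fv[c] == 0.0 or np.isnan(fv[c]) for c in var_cols)


def test_zero_segregating_sites_dataset():
    ds = make_ds(["0000", "0000", "0000", "0000", "0000"])
    ds = HaplotypeDataset(matrix=np.zeros((5, 0), np.uint8),
                          positions=np.zeros(0), sample_n=5)
    fv = feature_vector(ds, SubsampleSpec(tuple_n=4, n_subsamples=10, rng_seed=0))
    assert fv["mean_S"] == 0.0 and fv["max_S"] == 0.0
    assert np.isnan(fv["mean_nHaps_scaled"])
    assert fv["ndef_nHaps_scaled"] == 0


def test_reproducible_with_fixed_seed():
    ds = simulate(SimulationConfig(seed=23))
    spec = SubsampleSpec(tuple_n=4, n_subsamples=30, rng_seed=17)
    a = feature_vector(ds, spec)
    b = feature_vector(ds, spec)
    pd.testing.assert_series_equal(a, b)


def test_mean_s_matches_exhaustive_quartet_enumeration():
    """Independent oracle: average subsample S over all C(6,4) quartets."""
    ds = make_ds(["00011", "00101", "01001", "10001", "11110", "01110"])
    expected = np.mean([
        summarize(ds.matrix[list(rows)]).S
        for rows in itertools.combinations(range(6), 4)])
    fv = feature_vector(ds, SubsampleSpec(tuple_n=4, n_subsamples=4000,
                                          rng_seed=5))
    assert fv["mean_S"] == pytest.approx(expected, rel=0.05)


def test_subsample_s_increases_stochastically_with_tuple_size():
    ds = simulate(SimulationConfig(seed=24))
    rng = np.random.default_rng(6)
    s = {n: [draw_subsample(ds, n, rng).n_sites for _ in range(120)]
         for n in (4, 20, 77)}
    assert stats.mannwhitneyu(s[4], s[20], alternative="less").pvalue < 1e-6
    assert stats.mannwhitneyu(s[20], s[77], alternative="less").pvalue < 1e-6


def test_feature_matrix_schema_and_determinism():
    cfg = SimulationConfig(seed=25, sample_n=12)
    data = [("a", simulate(cfg, replicate_index=0)),
            ("b", simulate(cfg, replicate_index=1)),
            ("a", simulate(cfg, replicate_index=2))]
    spec = SubsampleSpec(tuple_n=4, n_subsamples=20, rng_seed=9)
    fm = feature_matrix(data, spec)
    assert fm.shape[0] == 3
    assert list(fm["label"]) == ["a", "b", "a"]
    assert set(FEATURE_COLUMNS) <= set(fm.columns)
    pd.testing.assert_frame_equal(fm, feature_matrix(data, spec))


def test_spec_validation():
    with pytest.raises(ValueError):
        SubsampleSpec(tuple_n=3)
    with pytest.raises(ValueError):
        SubsampleSpec(n_subsamples=0)
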