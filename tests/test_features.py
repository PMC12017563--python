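"""Aggregation, dimension pruning, robust scaling, and label handling."""

from __future__ import annotations

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import reefscape as rs
from reefscape.embeddings import EmbeddingVector
from reefscape.features import SampleRecord, label_from_samples


def _vectors(matrix: np.ndarray) -> list[EmbeddingVector]:
    names = [f"d{j}" for j in range(matrix.shape[1])]
    return [EmbeddingVector(row, names) for row in matrix]


def _feature_matrix(values: np.ndarray) -> rs.FeatureMatrix:
    t0 = datetime(2022, 11, 16, 12, 5)
    samples = [
        SampleRecord(None, t0 + timedelta(seconds=15 * i), 15.0, {"site": f"s{i % 2}"})
        for i in range(values.shape[0])
    ]
    return rs.FeatureMatrix(values, samples, [f"d{j}" for j in range(values.shape[1])])


class TestAggregate:
    def test_sixty_seconds_at_fifteen_gives_four_samples(self):
        rng = np.random.default_rng(0)
        out = rs.aggregate(_vectors(rng.standard_normal((60, 5))), 15)
        assert len(out) == 4
        starts = [rec.window_start for rec, _ in out]
        assert starts == sorted(starts)
        assert (starts[1] - starts[0]).total_seconds() == 15

    def test_integration_one_is_identity(self):
        m = np.arange(12.0).reshape(4, 3)
        out = rs.aggregate(_vectors(m), 1)
        np.testing.assert_array_equal(np.vstack([v for _, v in out]), m)

    def test_full_window_is_plain_mean(self):
        m = np.random.default_rng(1).standard_normal((60, 4))
        out = rs.aggregate(_vectors(m), 60)
        assert len(out) == 1
        np.testing.assert_allclose(out[0][1], m.mean(axis=0))

    def test_trailing_partial_block_dropped(self):
        m = np.ones((17, 2))
        assert len(rs.aggregate(_vectors(m), 5)) == 3

    @pytest.mark.parametrize("bad", [0, -3, 2.5])
    def test_non_integer_integration_rejected(self, bad):
        with pytest.raises(ValueError):
            rs.aggregate(_vectors(np.ones((4, 2))), bad)


class TestPruneDims:
    def test_planted_constant_columns_removed(self):
        # brute-force oracle: plant 17 constant columns among 6400 and check
        # the survivor set column by column
        rng = np.random.default_rng(42)
        values = rng.standard_normal((5, 6400))
        planted = rng.choice(6400, size=17, replace=False)
        values[:, planted] = rng.standard_normal(17)  # constant per column
        fm = _feature_matrix(values)
        pruned = rs.prune_dims(fm)
        assert pruned.n_dims == 6383
        expected_kept = [
            j for j in range(6400) if values[:, j].max() - values[:, j].min() > 1e-12
        ]
        assert pruned.dim_names == [f"d{j}" for j in expected_kept]
        assert sorted(pruned.pruned_dims) == sorted(f"d{j}" for j in planted)

    def test_no_constant_columns_is_identity(self):
        fm = _feature_matrix(np.random.default_rng(0).standard_normal((6, 8)))
        pruned = rs.prune_dims(fm)
        np.testing.assert_array_equal(pruned.values, fm.values)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="no informative"):
            rs.prune_dims(_feature_matrix(np.ones((4, 3))))


class TestRobustScale:
    def test_hand_column(self):
        fm = _feature_matrix(np.array([[1.0], [2.0], [3.0], [4.0], [5.0]]))
        scaled = rs.robust_scale(fm)
        np.testing.assert_allclose(scaled.values[:, 0], [-1, -0.5, 0, 0.5, 1])
        assert scaled.scaling_params.loc["d0", "median"] == 3.0
        assert scaled.scaling_params.loc["d0", "scale"] == 2.0

    def test_idempotent(self):
        fm = _feature_matrix(np.random.default_rng(3).standard_normal((20, 4)))
        once = rs.robust_scale(fm)
        twice = rs.robust_scale(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)

    def test_degenerate_iqr_falls_back_to_range(self):
        fm = _feature_matrix(np.array([[0.0], [0.0], [0.0], [0.0], [1.0]]))
        scaled = rs.robust_scale(fm)
        assert np.all(np.isfinite(scaled.values))
        assert bool(scaled.scaling_params.loc["d0", "range_fallback"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            st.tuples(st.integers(5, 30), st.integers(1, 6)),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        )
    )
    def test_scaled_columns_have_zero_median_unit_iqr(self, values):
        span = values.max(axis=0) - values.min(axis=0)
        if not np.all(span > 1e-9):
            return  # constant columns are the pruner's business
        scaled = rs.robust_scale(_feature_matrix(values))
        med = np.median(scaled.values, axis=0)
        np.testing.assert_allclose(med, 0.0, atol=1e-9)
        q1, q3 = np.quantile(scaled.values, [0.25, 0.75], axis=0)
        ok = ~scaled.scaling_params["range_fallback"].to_numpy()
        np.testing.assert_allclose((q3 - q1)[ok], 1.0, rtol=1e-9)

    def test_row_and_label_alignment_preserved(self):
        values = np.random.default_rng(5).standard_normal((8, 5))
        values[:, 2] = 7.0  # constant, will be pruned
        fm = _feature_matrix(values)
        out = rs.robust_scale(rs.prune_dims(fm))
        assert [s.labels["site"] for s in out.samples] == [
            s.labels["site"] for s in fm.samples
        ]
        # rows still correspond: ordering of any kept column is unchanged
        np.testing.assert_array_equal(
            np.argsort(out.values[:, 0]), np.argsort(values[:, 0])
        )


class TestPipelineOrder:
    def test_aggregate_then_scale_differs_from_scale_then_aggregate(self):
        # regression guard for the fixed default order: the two orders are
        # not interchangeable in general
        rng = np.random.default_rng(9)
        m = rng.lognormal(size=(30, 3))
        agg_first = rs.robust_scale(
            _feature_matrix(np.vstack([v for _, v in rs.aggregate(_vectors(m), 5)]))
        ).values
        scaled = rs.robust_scale(_feature_matrix(m)).values
        scale_first = np.vstack([v for _, v in rs.aggregate(_vectors(scaled), 5)])
        assert not np.allclose(agg_first, scale_first, atol=1e-6)


class TestLabels:
    def _samples(self):
        recs = []
        for site in ("und", "tour", "boat"):
            for rep in ("1", "2", "3"):
                for period in ("day", "night"):
                    recs.append(
                        SampleRecord(
                            None,
                            datetime(2022, 11, 16),
                            15.0,
                            {"site": site, "replicate": rep, "period": period},
                        )
                    )
        return recs

    def test_composite_label_has_all_combinations(self):
        label = label_from_samples(self._samples(), ["site", "replicate", "period"])
        assert label.n_categories == 18
        assert label.name == "site/replicate/period"
        assert "und/1/day" in label.categories

    def test_single_label(self):
        label = label_from_samples(self._samples(), "site")
        assert label.categories == ["und", "tour", "boat"]
        assert len(label.indices("boat")) == 6

    def test_unknown_category_lookup_rejected(self):
        label = label_from_samples(self._samples(), "site")
        with pytest.raises(KeyError):
            label.indices("lagoon")
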