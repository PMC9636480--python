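"""Correlation QC, complexity curves, fingerprints, enrichment, pooling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from damkit.peaks import PeakRecord
from damkit.qc import (
    PoolingInput,
    QcThresholds,
    complexity_curve,
    correlation_matrix,
    enrichment_profile,
    fingerprint_curve,
    flag_libraries,
    pooling_plan,
)
from damkit.tracks import ScoredTrack


def _track(values, label=""):
    n = len(values)
    iv = np.stack([np.arange(n) * 100, np.arange(n) * 100 + 100], axis=1)
    return ScoredTrack(intervals={"c": iv}, values={"c": np.array(values, float)}, label=label)


class TestCorrelationMatrix:
    def test_diagonal_and_symmetry(self):
        m = correlation_matrix({"a": _track([1, 2, 3]), "b": _track([3, 1, 2])})
        assert m.loc["a", "a"] == pytest.approx(1.0)
        assert m.loc["a", "b"] == pytest.approx(m.loc["b", "a"])

    def test_negation_gives_minus_one(self):
        m = correlation_matrix({"a": _track([1, 2, 3]), "b": _track([-1, -2, -3])})
        assert m.loc["a", "b"] == pytest.approx(-1.0)

    def test_linear_scaling_gives_one(self):
        m = correlation_matrix({"a": _track([1, 2, 3]), "b": _track([2, 4, 6])})
        assert m.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_variance_flagged_as_missing(self):
        m = correlation_matrix({"a": _track([1, 1, 1]), "b": _track([1, 2, 3])})
        assert np.isnan(m.loc["a", "b"]) and np.isnan(m.loc["a", "a"])


class TestFlagLibraries:
    def _matrix(self, names, r):
        m = pd.DataFrame(r, index=names, columns=names)
        return m

    def test_good_replicate_kept(self):
        names = ["f1", "f2", "f3"]
        m = self._matrix(names, [[1, 0.95, 0.95], [0.95, 1, 0.95], [0.95, 0.95, 1]])
        out = flag_libraries(m, {n: "fusion" for n in names})
        assert set(out["decision"]) == {"kept"}

    def test_poorly_correlated_replicate_flagged(self):
        # one of four replicates correlates at 0.7 with everything else
        names = ["f1", "f2", "f3", "f4"]
        r = np.full((4, 4), 0.95)
        r[0, :] = r[:, 0] = 0.7
        np.fill_diagonal(r, 1.0)
        out = flag_libraries(self._matrix(names, r), {n: "fusion" for n in names})
        out = out.set_index("sample")
        assert out.loc["f1", "decision"] == "flagged"
        assert (out.loc[["f2", "f3", "f4"], "decision"] == "kept").all()

    def test_boundary_is_inclusive(self):
        names = ["f1", "f2"]
        m = self._matrix(names, [[1, 0.9], [0.9, 1]])
        out = flag_libraries(m, {n: "fusion" for n in names})
        assert set(out["decision"]) == {"kept"}

    def test_ratio_tracks_use_pairwise_threshold(self):
        names = ["r1", "r2"]
        m = self._matrix(names, [[1, 0.8], [0.8, 1]])
        out = flag_libraries(m, {n: "ratio" for n in names})
        assert set(out["decision"]) == {"kept"}
        m2 = self._matrix(names, [[1, 0.79], [0.79, 1]])
        out2 = flag_libraries(m2, {n: "ratio" for n in names})
        assert set(out2["decision"]) == {"flagged"}

    def test_singleton_group(self):
        m = self._matrix(["a", "b"], [[1, 0.5], [0.5, 1]])
        out = flag_libraries(m, {"a": "fusion", "b": "damonly"}).set_index("sample")
        assert (out["decision"] == "insufficient_replicates").all()


class TestComplexityCurve:
    def _brute_force(self, multiset, n):
        """Average distinct count over all C(N, n) subsets."""
        idx = range(len(multiset))
        total, count = 0, 0
        for combo in itertools.combinations(idx, n):
            total += len({multiset[i] for i in combo})
            count += 1
        return total / count

    def test_aab_example(self):
        curve = complexity_curve(["a", "a", "b"], n_points=3)
        assert list(curve.depths) == [1, 2, 3]
        np.testing.assert_allclose(curve.expected_distinct, [1.0, 5 / 3, 2.0])

    def test_all_unique(self):
        curve = complexity_curve(list(range(10)), n_points=10)
        np.testing.assert_allclose(curve.expected_distinct, curve.depths)

    def test_single_class(self):
        curve = complexity_curve(["x"] * 7, n_points=7)
        np.testing.assert_allclose(curve.expected_distinct, 1.0)

    def test_matches_exhaustive_enumeration_all_small_multisets(self):
        """Exact agreement with subset enumeration for every multiset
        shape of up to 8 reads (one representative per partition)."""
        def partitions(n, largest=None):
            if n == 0:
                yield []
                return
            largest = n if largest is None else largest
            for first in range(min(n, largest), 0, -1):
                for rest in partitions(n - first, first):
                    yield [first] + rest

        for total in range(1, 9):
            for shape in partitions(total):
                multiset = [
                    f"u{i}" for i, c in enumerate(shape) for _ in range(c)
                ]
                curve = complexity_curve(multiset, n_points=total)
                for n, d in zip(curve.depths, curve.expected_distinct):
                    assert d == pytest.approx(self._brute_force(multiset, int(n)))

    def test_monotone_and_bounded(self):
        curve = complexity_curve(["a", "a", "b", "c", "c", "c"], n_points=6)
        d = curve.expected_distinct
        assert np.all(np.diff(d) >= -1e-12)
        assert np.all(d <= curve.depths + 1e-9)
        assert d[-1] == pytest.approx(3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            complexity_curve([])


class TestFingerprintCurve:
    def test_concentrated_counts(self):
        curve = fingerprint_curve([0, 0, 10])
        np.testing.assert_allclose(curve.x, [1 / 3, 2 / 3, 1.0])
        np.testing.assert_allclose(curve.y, [0.0, 0.0, 1.0])

    def test_uniform_is_diagonal(self):
        curve = fingerprint_curve([5, 5, 5, 5])
        np.testing.assert_allclose(curve.y, curve.x)

    def test_endpoint_and_monotonicity_and_convexity(self):
        rng = np.random.default_rng(2)
        curve = fingerprint_curve(rng.poisson(20, size=200))
        assert curve.y[-1] == pytest.approx(1.0)
        assert np.all(np.diff(curve.y) >= -1e-12)
        assert np.all(np.diff(np.diff(curve.y)) >= -1e-12)  # sorted ascending => convex

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fingerprint_curve([0, 0, 0])


class TestEnrichmentProfile:
    def _peaks(self, centers, half=100):
        return [
            PeakRecord("c", c - half, c + half, f"p{i}", 0, ".", 1.0, 2.0, 1.0)
            for i, c in enumerate(centers)
        ]

    def test_constant_track_flat_profile(self):
        track = _track([4.0] * 50)
        prof = enrichment_profile(track, self._peaks([2500]), half_width=1000, n_positions=21)
        np.testing.assert_allclose(prof.mean_value, 4.0)

    def test_center_peak_maximal_at_zero(self):
        values = np.zeros(50)
        values[25] = 1.0  # value 1 only on the peak-center fragment
        prof = enrichment_profile(
            _track(values), self._peaks([2550]), half_width=1000, n_positions=41
        )
        assert prof.central_value == pytest.approx(1.0)
        assert prof.mean_value[0] == 0.0 and prof.mean_value[-1] == 0.0

    def test_linearity_over_replicates(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=50), rng.normal(size=50)
        peaks = self._peaks([1500, 3200])
        prof_mean = enrichment_profile(_track((a + b) / 2), peaks, 800, 21)
        pa = enrichment_profile(_track(a), peaks, 800, 21)
        pb = enrichment_profile(_track(b), peaks, 800, 21)
        np.testing.assert_allclose(
            prof_mean.mean_value, (pa.mean_value + pb.mean_value) / 2, atol=1e-12
        )

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            enrichment_profile(_track([1.0]), [])


class TestPoolingPlan:
    def test_molarity_formula(self):
        lib = PoolingInput("l1", fragment_size=300, concentration=30)
        assert lib.molarity == pytest.approx(150.0)

    def test_three_equal_libraries(self):
        libs = [PoolingInput(f"l{i}", 300, 30) for i in range(3)]
        plan = pooling_plan(libs)
        np.testing.assert_allclose(plan["volume_uL"], 2.22222, rtol=1e-5)
        assert plan.attrs["water_uL"] == pytest.approx(43.3333, abs=1e-3)

    def test_mass_balance_gives_target(self):
        libs = [PoolingInput(f"l{i}", 300, 30) for i in range(3)]
        plan = pooling_plan(libs)
        assert plan.attrs["achieved_concentration_nM"] == pytest.approx(20.0)

    def test_infeasible_plan_rejected(self):
        # very dilute library: needed volume exceeds the final volume
        with pytest.raises(ValueError):
            pooling_plan([PoolingInput("weak", 300, 0.1)])

    def test_input_validation(self):
        with pytest.raises(ValueError):
            PoolingInput("bad", -1, 30)
        with pytest.raises(ValueError):
            QcThresholds(within_type=0.0)
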