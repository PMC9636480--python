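"""Poisson broad-peak calling, BH q-values, consensus and reproducibility."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import damkit
from damkit.counts import FragmentCounts
from damkit.gatcmap import build_fragment_map
from damkit.peaks import (
    ConsensusConfig,
    PeakCallParams,
    PeakRecord,
    PeakSet,
    bh_qvalues,
    call_broad_peaks,
    default_fdr_thresholds,
    fragment_pvalues,
    merge_intervals,
    read_broadpeak,
    reproducible_peaks,
    threshold_consensus,
    write_broadpeak,
)


def _raw_map(frags, length):
    """Synthetic fragment map with the given tiling (GATC positions implied)."""
    from damkit.gatcmap import GatcFragmentMap

    return GatcFragmentMap(fragments=frags, chrom_lengths={"c": length})


def _counts(fmap, weights, library=None):
    w = np.asarray(weights, dtype=float)
    return FragmentCounts(
        fmap=fmap, weights={"c": w}, library_size=int(library if library is not None else w.sum())
    )


def _peak(start, end, q, chrom="c", name="p"):
    return PeakRecord(
        chrom=chrom, start=start, end=end, name=name,
        score=min(1000, int(round(10 * q))), strand=".",
        signal_value=1.0, p_value=q + 1, q_value=q,
    )


class TestBhQvalues:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        np.testing.assert_allclose(bh_qvalues([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.5])

    def _naive_bh(self, p):
        """O(n^2) reference: q_i = min over j with p_j >= p_i of p_j * n / rank_j."""
        p = np.asarray(p)
        n = len(p)
        order = np.argsort(p, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(1, n + 1)
        q = np.empty(n)
        for i in range(n):
            q[i] = min(
                min(p[j] * n / ranks[j] for j in range(n) if p[j] >= p[i]), 1.0
            )
        return q

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=60))
    def test_matches_naive_reference(self, pvals):
        np.testing.assert_allclose(bh_qvalues(pvals), self._naive_bh(pvals), rtol=1e-9)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, size=500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_qvalues(p), q_sm, rtol=1e-9)


class TestFragmentPvalues:
    def test_zero_count_gives_p_one(self):
        fmap = _raw_map({"c": [(0, 100), (100, 200), (200, 300)]}, 300)
        exp = _counts(fmap, [0, 5, 5], library=10)
        ctrl = _counts(fmap, [3, 3, 4], library=10)
        p = fragment_pvalues(exp, ctrl)
        assert p["c"][0] == pytest.approx(1.0)

    def test_null_uniform_counts_not_significant(self):
        fmap = _raw_map({"c": [(i * 100, (i + 1) * 100) for i in range(60)]}, 6000)
        w = np.full(60, 20.0)
        exp, ctrl = _counts(fmap, w), _counts(fmap, w)
        p = np.concatenate(list(fragment_pvalues(exp, ctrl).values()))
        assert np.all(p >= 0.4)  # Poisson median property
        assert np.all(bh_qvalues(p) > 0.05)

    def test_extreme_enrichment_tiny_p(self):
        # one fragment with 100 reads where the control predicts ~1
        fmap = _raw_map({"c": [(i * 100, (i + 1) * 100) for i in range(100)]}, 10_000)
        w = np.ones(100)
        w_exp = w.copy()
        w_exp[50] = 100.0
        exp = _counts(fmap, w_exp)
        ctrl = _counts(fmap, w, library=int(w_exp.sum()))
        params = PeakCallParams(control_scaling="library_size", dispersion=1.0)
        p = fragment_pvalues(exp, ctrl, params)
        assert p["c"][50] < 1e-100

    def test_mismatched_maps_rejected(self):
        m1 = _raw_map({"c": [(0, 100)]}, 100)
        m2 = _raw_map({"c": [(0, 50), (50, 100)]}, 100)
        with pytest.raises(ValueError):
            fragment_pvalues(_counts(m1, [1]), _counts(m2, [1, 1]))


class TestCallBroadPeaks:
    def test_null_yields_no_peaks(self):
        fmap = _raw_map({"c": [(i * 100, (i + 1) * 100) for i in range(60)]}, 6000)
        w = np.full(60, 20.0)
        peaks = call_broad_peaks(_counts(fmap, w), _counts(fmap, w))
        assert len(peaks) == 0

    def test_isolated_enriched_fragment_single_peak(self):
        fmap = _raw_map({"c": [(i * 100, (i + 1) * 100) for i in range(100)]}, 10_000)
        w = np.full(100, 10.0)
        w_exp = w.copy()
        w_exp[40] = 200.0
        peaks = call_broad_peaks(
            _counts(fmap, w_exp), _counts(fmap, w, library=int(w_exp.sum())),
            PeakCallParams(control_scaling="library_size", dispersion=1.0, max_link_gap=0),
        )
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end) == (4000, 4100)
        assert peaks[0].q_value > 10
        assert peaks[0].score == min(1000, round(10 * peaks[0].q_value))

    def test_two_seeds_linked_through_moderate_fragment(self):
        fmap = _raw_map({"c": [(i * 100, (i + 1) * 100) for i in range(200)]}, 20_000)
        w = np.full(200, 10.0)
        w_exp = w.copy()
        w_exp[[80, 82]] = 200.0   # strong seeds
        w_exp[81] = 28.0          # linking-level only
        peaks = call_broad_peaks(
            _counts(fmap, w_exp), _counts(fmap, w, library=int(w_exp.sum())),
            PeakCallParams(control_scaling="library_size", dispersion=1.0, max_link_gap=0),
        )
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end) == (8000, 8300)

    def test_gap_bridging_spans_subresolution_fragment(self):
        frags = [(0, 500), (500, 520), (520, 1020), (1020, 5020)]
        fmap = _raw_map({"c": frags}, 5020)
        w = np.array([5.0, 0.2, 5.0, 40.0])
        w_exp = np.array([200.0, 0.2, 200.0, 40.0])
        params = PeakCallParams(control_scaling="library_size", dispersion=1.0)
        split = call_broad_peaks(
            _counts(fmap, w_exp), _counts(fmap, w, library=int(w_exp.sum())),
            PeakCallParams(control_scaling="library_size", dispersion=1.0, max_link_gap=0),
        )
        bridged = call_broad_peaks(
            _counts(fmap, w_exp), _counts(fmap, w, library=int(w_exp.sum())), params
        )
        assert len(split) == 2
        assert len(bridged) == 1 and (bridged[0].start, bridged[0].end) == (0, 1020)


class TestDefaultThresholds:
    def test_ladder_shape(self):
        t = default_fdr_thresholds()
        assert len(t) == 41
        assert t == sorted(t)
        assert t[0] == 0 and t[-1] == 2000
        for anchor in (1, 2, 3, 4, 5, 10, 100, 125, 1900):
            assert anchor in t


class TestConsensus:
    def _sets(self):
        return {
            "p1": [_peak(0, 100, 3.0), _peak(500, 600, 0.5)],
            "p2": [_peak(50, 150, 2.0)],
        }

    def test_threshold_zero_is_union(self):
        cfg = ConsensusConfig(fdr_thresholds=(0.0,))
        out = threshold_consensus(self._sets(), cfg)[0.0]
        assert [(p.start, p.end) for p in out] == [(0, 150), (500, 600)]

    def test_threshold_filters_by_qvalue(self):
        cfg = ConsensusConfig(fdr_thresholds=(1.0,))
        out = threshold_consensus(self._sets(), cfg)[1.0]
        assert [(p.start, p.end) for p in out] == [(0, 150)]

    def test_overlapping_survivors_merged(self):
        sets = {"p1": [_peak(0, 100, 5.0)], "p2": [_peak(50, 150, 5.0)]}
        out = threshold_consensus(sets, ConsensusConfig(fdr_thresholds=(1.0,)))[1.0]
        assert [(p.start, p.end) for p in out] == [(0, 150)]

    def test_default_produces_41_sets(self):
        out = threshold_consensus(self._sets())
        assert len(out) == 41

    def test_empty_threshold_list_rejected(self):
        with pytest.raises(ValueError):
            ConsensusConfig(fdr_thresholds=())

    def test_nestedness_of_covered_bp(self):
        rng = np.random.default_rng(3)
        sets = {
            f"p{i}": [
                _peak(int(s), int(s) + rng.integers(50, 300), float(rng.uniform(0, 50)))
                for s in rng.integers(0, 10_000, size=20)
            ]
            for i in range(4)
        }
        out = threshold_consensus(sets, ConsensusConfig(fdr_thresholds=(0.0, 5.0, 20.0, 45.0)))
        covered = [PeakSet(out[f]).total_bp() for f in (0.0, 5.0, 20.0, 45.0)]
        assert covered == sorted(covered, reverse=True)


class TestReproduciblePeaks:
    def _four_sets(self):
        shared = _peak(1000, 1200, 30.0)
        rare = _peak(5000, 5200, 30.0)
        return {
            "a": [shared, rare],
            "b": [_peak(1100, 1300, 30.0)],
            "c": [_peak(9000, 9100, 30.0)],
            "d": [_peak(9000, 9100, 30.0)],
        }

    def test_exactly_half_retained(self):
        out = reproducible_peaks(self._four_sets(), at_threshold=10.0)
        spans = [(p.start, p.end) for p in out]
        assert (1000, 1300) in spans  # present in 2/4 = exactly 50%
        assert (9000, 9100) in spans

    def test_below_half_removed(self):
        out = reproducible_peaks(self._four_sets(), at_threshold=10.0)
        assert not any(p.start == 5000 for p in out)  # 1/4 < 50%

    def test_present_in_all_retained_at_any_fraction(self):
        sets = {k: [_peak(0, 100, 20.0)] for k in "abcd"}
        out = reproducible_peaks(sets, ConsensusConfig(reproducible_fraction=1.0), 10.0)
        assert len(out) == 1

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            ConsensusConfig(reproducible_fraction=0.0)

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            reproducible_peaks({"a": [_peak(0, 1, 1.0)]})


class TestBroadPeakIO:
    def test_round_trip(self, tmp_path):
        peaks = [_peak(0, 100, 12.3456, name="x"), _peak(200, 300, 0.001234, name="y")]
        path = tmp_path / "p.broadPeak"
        write_broadpeak(peaks, path)
        back = read_broadpeak(path)
        assert [(p.chrom, p.start, p.end, p.name) for p in back] == [
            ("c", 0, 100, "x"), ("c", 200, 300, "y")
        ]
        assert back[0].q_value == pytest.approx(12.3456, rel=1e-4)
        assert back[1].q_value == pytest.approx(0.001234, rel=1e-3)

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="9"):
            read_broadpeak(io.StringIO("c\t0\t100\tx\t5\t.\n"))

    def test_unsorted_input_rejected(self):
        buf = io.StringIO()
        write_broadpeak([_peak(200, 300, 1.0), _peak(0, 100, 1.0)], buf)
        lines = buf.getvalue().splitlines(keepends=True)
        with pytest.raises(ValueError, match="sorted"):
            read_broadpeak(io.StringIO("".join(reversed(lines))))


def test_merge_intervals():
    merged = merge_intervals([("c", 0, 100), ("c", 50, 150), ("c", 200, 250)])
    assert merged == [("c", 0, 150), ("c", 200, 250)]


def test_null_calibration_on_simulation():
    """With p_bound == p_open there is no binding signal; the fraction of
    fragments reaching q <= 0.05 stays at or below the FDR level."""
    fractions = []
    for seed in (3, 4, 5):
        cfg = damkit.SimConfig(
            chromosome_length=50_000, n_binding_sites=5, p_bound=0.05, p_open=0.05,
            n_molecules=8_000, seed=seed,
        )
        genome, fmap, truth, reads, roles = damkit.simulate_experiment(
            cfg, n_fusion=1, n_damonly=1
        )
        index = damkit.GenomeIndex(genome)
        counts = {}
        for sid, rs in reads.items():
            trimmed = [damkit.trim_read(r) for r in rs]
            kept, _ = damkit.length_filter(trimmed)
            alns, _ = damkit.align_exact(kept, index)
            counts[sid] = damkit.count_fragments(alns, fmap)
        from damkit.peaks import fragment_log10_pq

        _, lq = fragment_log10_pq(counts["fusion_R1"], counts["damonly_R1"])
        q = np.concatenate(list(lq.values()))
        fractions.append(float(np.mean(q <= np.log10(0.05))))
    assert np.mean(fractions) <= 0.05
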