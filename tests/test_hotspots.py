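"""Hann smoothing and hot-spot calling, checked against brute force.

A 3-bp Hann window has weights [0, 1, 0] (the raised cosine is zero at
its endpoints), so ``window_bp=3`` smoothing is the identity map; the
merge/filter boundary tests exploit this to reason about exact per-base
values.
"""

import numpy as np
import pytest

from spo11map import (
    GenomeAssembly,
    HotspotCallParams,
    Hotspot,
    HotspotSet,
    IntegrityError,
    NormState,
    SignalMap,
    call_hotspots,
    compare_hotspot_sets,
    hann_smooth,
    hann_window,
    hotspot_fold_change,
)

from conftest import make_map
from oracle import oracle_call, oracle_hann_smooth

IDENT = HotspotCallParams(window_bp=3, fixed_threshold=1.0)


class TestHannSmooth:
    def test_constant_preserved_everywhere(self):
        for w in (3, 21, 201):
            out = hann_smooth(np.full(500, 4.2), w)
            np.testing.assert_allclose(out, 4.2, rtol=1e-12)

    def test_impulse_reproduces_weight_vector(self):
        """Interior impulse response equals the normalized Hann weights,
        maximal and symmetric about the impulse."""
        w = 21
        arr = np.zeros(200)
        arr[100] = 1.0
        out = hann_smooth(arr, w)
        weights = hann_window(w)
        np.testing.assert_allclose(out[90:111], weights, atol=1e-15)
        assert out.argmax() == 100
        np.testing.assert_allclose(out[90:100], out[110:100:-1], atol=1e-15)

    def test_interior_impulse_mass_preserved(self):
        arr = np.zeros(1000)
        arr[500] = 1.0
        assert hann_smooth(arr, 201).sum() == pytest.approx(1.0, rel=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(IntegrityError):
            hann_smooth(np.zeros(10), 200)

    def test_matches_direct_evaluation(self, rng):
        """Convolution path equals per-position windowed averaging,
        including truncated re-normalized edges."""
        for _ in range(5):
            arr = rng.gamma(0.5, 2.0, size=int(rng.integers(300, 1500)))
            for w in (5, 51):
                np.testing.assert_allclose(
                    hann_smooth(arr, w), oracle_hann_smooth(arr, w), rtol=1e-10
                )


def _one_chrom_map(values, length=None, state=NormState.NRPM):
    length = length or len(values)
    asm = GenomeAssembly(("chrT",), {"chrT": length}, {})
    arr = np.zeros(length)
    arr[: len(values)] = values
    return SignalMap(asm, {"chrT": arr}, state)


def _block_map(blocks, length=5000):
    """Map with value-10 blocks at given 1-based closed intervals."""
    arr = np.zeros(length)
    for s, e in blocks:
        arr[s - 1 : e] = 10.0
    return _one_chrom_map(arr)


class TestCallHotspots:
    def test_all_zero_chromosome(self):
        assert len(call_hotspots(_one_chrom_map(np.zeros(2000)), params=IDENT)) == 0

    def test_raw_map_rejected(self):
        with pytest.raises(IntegrityError):
            call_hotspots(_one_chrom_map(np.ones(100), state=NormState.RAW),
                          params=IDENT)

    @pytest.mark.parametrize(
        "gap, expected", [(150, 1), (200, 1), (201, 2), (250, 2)]
    )
    def test_merge_gap_boundary(self, gap, expected):
        blocks = [(1001, 1100), (1101 + gap, 1200 + gap)]
        hs = call_hotspots(_block_map(blocks), params=IDENT)
        assert len(hs) == expected
        if expected == 1:
            (h,) = hs
            assert (h.start, h.end) == (1001, 1200 + gap)
            assert h.total_signal == pytest.approx(2000.0)

    def test_transitive_merge_chains(self):
        blocks = [(1001, 1100), (1250, 1350), (1500, 1600)]  # gaps 149, 149
        hs = call_hotspots(_block_map(blocks), params=IDENT)
        assert len(hs) == 1
        assert (hs.hotspots[0].start, hs.hotspots[0].end) == (1001, 1600)

    @pytest.mark.parametrize(
        "width, kept", [(24, False), (25, True)]
    )
    def test_min_width_boundary(self, width, kept):
        hs = call_hotspots(_block_map([(1001, 1000 + width)]), params=IDENT)
        assert (len(hs) == 1) is kept

    @pytest.mark.parametrize(
        "width, value, kept",
        [(30, 0.333, False), (25, 0.4, True)],  # totals 9.99 and exactly 10
    )
    def test_min_total_boundary(self, width, value, kept):
        arr = np.zeros(2000)
        arr[1000 : 1000 + width] = value
        params = HotspotCallParams(window_bp=3, fixed_threshold=value / 2)
        hs = call_hotspots(_one_chrom_map(arr), params=params)
        assert (len(hs) == 1) is kept

    def test_plateau_exactly_at_threshold_never_called(self):
        arr = np.full(2000, 0.193)
        params = HotspotCallParams(window_bp=3, fixed_threshold=0.193)
        assert len(call_hotspots(_one_chrom_map(arr), params=params)) == 0

    def test_default_threshold_is_fold_over_genome_mean(self):
        arr = np.full(1000, 2.0)
        arr[100:200] = 50.0
        smap = _one_chrom_map(arr)
        hs = call_hotspots(smap, params=HotspotCallParams(window_bp=3))
        mean = smap.total_included / smap.assembly.included_length
        assert hs.params["threshold"] == pytest.approx(2.3 * mean)
        assert len(hs) == 1

    def test_monotone_in_threshold(self, rng):
        arr = rng.gamma(0.5, 3.0, size=20_000)
        smap = _one_chrom_map(arr)
        called = []
        for thr in (0.5, 1.0, 2.0, 4.0):
            hs = call_hotspots(
                smap, params=HotspotCallParams(window_bp=51, fixed_threshold=thr)
            )
            called.append(sum(h.width for h in hs))
        assert called == sorted(called, reverse=True)

    def test_deterministic(self, rng):
        arr = rng.gamma(0.5, 3.0, size=10_000)
        smap = _one_chrom_map(arr)
        a = call_hotspots(smap, params=HotspotCallParams(window_bp=51,
                                                         fixed_threshold=1.0))
        b = call_hotspots(smap, params=HotspotCallParams(window_bp=51,
                                                         fixed_threshold=1.0))
        assert [(h.start, h.end, h.total_signal) for h in a] == [
            (h.start, h.end, h.total_signal) for h in b
        ]

    def test_oracle_equivalence_sample(self, rng):
        """Vectorized caller equals the per-base brute-force oracle on
        random spiky maps (larger-scale run in the acceptance suite)."""
        from spo11map.hotspots import hann_smooth as smooth

        for trial in range(100):
            n = int(rng.integers(1_000, 20_000))
            arr = np.zeros(n)
            for _ in range(int(rng.integers(0, 20))):
                s = int(rng.integers(0, n))
                w = int(rng.integers(5, 400))
                arr[s : s + w] += rng.gamma(1.0, 2.0)
            params = HotspotCallParams(
                window_bp=int(rng.choice([3, 51, 201])),
                fixed_threshold=float(rng.uniform(0.2, 2.0)) if trial % 2 else None,
                merge_gap_bp=int(rng.choice([50, 200])),
                min_width_bp=25,
                min_total=10.0,
            )
            smap = _one_chrom_map(arr)
            got = [
                (h.start, h.end, h.total_signal)
                for h in call_hotspots(smap, params=params)
            ]
            thr = (
                params.fixed_threshold
                if params.fixed_threshold is not None
                else 2.3 * arr.sum() / n
            )
            smoothed = smooth(arr, params.window_bp)
            expected = oracle_call(
                arr.tolist(), smoothed.tolist(), thr,
                params.merge_gap_bp, params.min_width_bp, params.min_total,
            )
            assert [(s, e) for s, e, _ in got] == [(s, e) for s, e, _ in expected]
            np.testing.assert_allclose(
                [t for _, _, t in got], [t for _, _, t in expected], rtol=1e-9
            )


class TestCompareSets:
    def test_identical_sets_all_shared(self):
        hs = HotspotSet([Hotspot("chrT", 10, 20), Hotspot("chrT", 50, 80)])
        c = compare_hotspot_sets(hs, hs)
        assert (c.shared_a, c.shared_b, c.only_a, c.only_b) == (2, 2, 0, 0)

    def test_disjoint_sets(self):
        a = HotspotSet([Hotspot("chrT", 10, 20)])
        b = HotspotSet([Hotspot("chrT", 30, 40)])
        c = compare_hotspot_sets(a, b)
        assert (c.n_shared, c.only_a, c.only_b) == (0, 1, 1)

    def test_nested_counts_shared_both_ways(self):
        a = HotspotSet([Hotspot("chrT", 10, 100)])
        b = HotspotSet([Hotspot("chrT", 40, 60)])
        c = compare_hotspot_sets(a, b)
        assert (c.shared_a, c.shared_b) == (1, 1)

    def test_single_bp_overlap_is_shared(self):
        a = HotspotSet([Hotspot("chrT", 10, 20)])
        b = HotspotSet([Hotspot("chrT", 20, 30)])
        assert compare_hotspot_sets(a, b).n_shared == 1


class TestFoldChange:
    def _sets_and_maps(self):
        asm = GenomeAssembly(("chrT",), {"chrT": 10_000}, {})
        hs = HotspotSet(
            [Hotspot("chrT", 100 + i * 500, 300 + i * 500) for i in range(10)]
        )
        den = make_map(asm, {"chrT": np.ones(10_000)}, state=NormState.NRPM)
        return asm, hs, den

    def test_doubled_numerator_gives_ratio_two(self):
        asm, hs, den = self._sets_and_maps()
        num = make_map(asm, {"chrT": np.full(10_000, 2.0)}, state=NormState.NRPM)
        df = hotspot_fold_change(hs, num, den)
        np.testing.assert_allclose(df["ratio"], 2.0, rtol=1e-12)
        np.testing.assert_allclose(df["trend"], 2.0, rtol=1e-9)

    def test_zero_denominator_flagged_not_dropped(self):
        asm, hs, den = self._sets_and_maps()
        den.data["chrT"][99:300] = 0.0  # first hotspot now empty in denominator
        num = make_map(asm, {"chrT": np.ones(10_000)}, state=NormState.NRPM)
        df = hotspot_fold_change(hs, num, den)
        assert len(df) == 10
        assert df["flagged"].tolist() == [True] + [False] * 9
        assert np.isnan(df.loc[0, "ratio"]) and np.isnan(df.loc[0, "trend"])

    def test_empty_set_empty_table(self):
        asm, _, den = self._sets_and_maps()
        df = hotspot_fold_change(HotspotSet([]), den, den)
        assert len(df) == 0
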