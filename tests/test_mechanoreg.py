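import numpy as np
import pandas as pd
import pytest

from scaffsim.loading import LoadProtocol
from scaffsim.mechanoreg import (
    LABELS,
    NodalFieldFrame,
    PhenotypeThresholds,
    StimulusParams,
    classify,
    detect_peaks,
    distribution,
    generate_reduced_order_frames,
    oss_average,
    phenotype_map_at,
    run_parameter_study,
    run_single_amplitude,
    s_avg_series,
    stimulus,
    viability_flags,
    wss_average,
)


def make_frame(oss, wss, area=None, time=0.0):
    oss = np.asarray(oss, float)
    area = np.ones_like(oss) if area is None else np.asarray(area, float)
    return NodalFieldFrame(time=time, oss=oss, wss_mpa=np.asarray(wss, float), node_area=area)


class TestStimulus:
    def test_zero_fields_zero_stimulus(self):
        assert stimulus(0.0, 0.0) == 0.0

    def test_unit_contributions(self):
        # each term contributes exactly 1 at its normalisation constant
        assert stimulus(0.0375, 10.0) == pytest.approx(2.0)

    def test_pure_strain_at_10pct_affine(self):
        assert stimulus(0.14527985257604953, 0.0) == pytest.approx(3.874, abs=1e-3)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            stimulus(-0.1, 0.0)
        with pytest.raises(ValueError):
            stimulus(0.1, -1.0)

    def test_strictly_increasing_in_each_argument(self, rng):
        o = rng.uniform(0, 0.2, 100)
        w = rng.uniform(0, 50, 100)
        s0 = stimulus(o, w)
        assert np.all(stimulus(o + 1e-6, w) > s0)
        assert np.all(stimulus(o, w + 1e-6) > s0)


class TestClassification:
    @pytest.mark.parametrize(
        "s,label",
        [
            (0.005, "none_low"),
            (0.01, "none_low"),  # boundary closed above: still too low
            (0.5, "bone"),
            (1.0, "bone"),
            (2.0, "cartilage"),
            (3.0, "cartilage"),
            (4.0, "fibrous"),
            (6.0, "fibrous"),
            (7.0, "none_high"),
        ],
    )
    def test_band_boundaries(self, s, label):
        assert classify(s) == label

    def test_every_finite_value_gets_exactly_one_label(self, rng):
        s = np.concatenate([rng.uniform(0, 10, 1000), [0, 0.01, 1, 3, 6]])
        labels = classify(s)
        assert set(labels) <= set(LABELS)
        assert labels.shape == s.shape

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            classify(np.nan)

    def test_label_index_monotone_in_stimulus(self, rng):
        s = np.sort(rng.uniform(0, 8, 500))
        idx = np.array([LABELS.index(l) for l in classify(s)])
        assert np.all(np.diff(idx) >= 0)

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeThresholds(s_bone=4.0, s_cartilage=3.0)


class TestAveraging:
    def test_arithmetic_mean(self):
        assert oss_average(make_frame([0.1, 0.2, 0.3], [0, 0, 0])) == pytest.approx(0.2)

    def test_area_weighted_mean(self):
        fr = make_frame([0, 0], [2.0, 4.0], area=[1.0, 3.0])
        assert wss_average(fr) == pytest.approx(3.5)

    def test_uniform_area_reduces_to_arithmetic(self, rng):
        w = rng.uniform(0, 30, 50)
        fr = make_frame(np.zeros(50), w, area=np.full(50, 2.5))
        assert wss_average(fr) == pytest.approx(w.mean())

    def test_matches_bruteforce_loops_on_random_frames(self, rng):
        for _ in range(100):
            n = rng.integers(2, 40)
            fr = make_frame(
                rng.uniform(0, 0.3, n), rng.uniform(0, 60, n), area=rng.uniform(0.1, 2, n)
            )
            o = sum(fr.oss) / n
            w = sum(fr.wss_mpa[i] * fr.node_area[i] for i in range(n)) / sum(fr.node_area)
            assert oss_average(fr) == pytest.approx(o, rel=1e-12)
            assert wss_average(fr) == pytest.approx(w, rel=1e-12)


class TestSeriesAndPeaks:
    def test_average_then_combine_identity(self, rng):
        frames = [
            make_frame(rng.uniform(0, 0.2, 30), rng.uniform(0, 40, 30), time=t)
            for t in np.linspace(0, 1, 11)
        ]
        series = s_avg_series(frames)
        for fr, s in zip(frames, series["s_avg"]):
            assert s == pytest.approx(stimulus(oss_average(fr), wss_average(fr)), rel=1e-12)

    def test_single_frame_unit_values(self):
        fr = make_frame([0.0375], [10.0], time=0.0)
        assert s_avg_series([fr])["s_avg"].iloc[0] == pytest.approx(2.0)

    def _series(self, t, s):
        return pd.DataFrame({"t_s": t, "oss_avg": 0.0, "wss_avg_mpa": 0.0, "s_avg": s})

    def test_symmetric_series_equal_peaks(self):
        p = LoadProtocol(dt=0.01)
        t = np.linspace(0, 1, 101)
        s = np.sin(2 * np.pi * t) ** 2  # equal interior peaks at t = 0.25, 0.75
        peaks = detect_peaks(self._series(t, s), p)
        assert peaks.s_max1.value == pytest.approx(peaks.s_max2.value)
        assert peaks.s_max1.time == pytest.approx(1.0 - peaks.s_max2.time)

    def test_global_max_in_upstroke(self):
        p = LoadProtocol(dt=0.01)
        t = np.linspace(0, 1, 101)
        s = np.exp(-40 * (t - 0.75) ** 2)
        peaks = detect_peaks(self._series(t, s), p)
        assert peaks.s_max2.time == pytest.approx(0.75)
        assert peaks.s_max1.value < peaks.s_max2.value

    def test_monotone_decreasing_series_hits_phase_boundary(self):
        p = LoadProtocol(dt=0.01)
        t = np.linspace(0, 1, 101)
        s = 1.0 - t
        peaks = detect_peaks(self._series(t, s), p)
        assert peaks.s_max1.time == 0.0
        assert peaks.s_max2.time == pytest.approx(0.5)  # turning point is upward

    def test_agrees_with_exhaustive_search(self, rng):
        p = LoadProtocol(dt=0.01)
        t = np.round(np.linspace(0, 1, 101), 10)
        for _ in range(50):
            s = rng.uniform(0, 5, t.size)
            peaks = detect_peaks(self._series(t, s), p)
            down = [i for i in range(t.size) if (t[i] % 1.0) < 0.5]
            up = [i for i in range(t.size) if i not in down]
            bd = max(down, key=lambda i: (s[i], -t[i]))
            bu = max(up, key=lambda i: (s[i], -t[i]))
            assert peaks.s_max1.value == s[bd] and peaks.s_max2.value == s[bu]

    def test_partial_cycle_rejected(self):
        p = LoadProtocol(dt=0.01)
        t = np.linspace(0, 0.6, 61)
        with pytest.raises(ValueError):
            detect_peaks(self._series(t, np.ones_like(t)), p)


class TestPhenotypeMapAndDistribution:
    def test_uniform_bone_map(self):
        frames = [make_frame([0.0375 / 2] * 4, [0.0] * 4, time=0.5)]
        pmap = phenotype_map_at(frames, 0.5)
        assert set(pmap.labels) == {"bone"}
        d = distribution(pmap)
        assert d.percentages["bone"] == pytest.approx(100.0)

    def test_mixed_labels_from_node_stimuli(self):
        # S = 0.5, 0.5, 2, 4 via pure WSS: 5, 5, 20, 40 mPa
        frames = [make_frame([0] * 4, [5.0, 5.0, 20.0, 40.0], time=0.1)]
        pmap = phenotype_map_at(frames, 0.1)
        assert list(pmap.labels) == ["bone", "bone", "cartilage", "fibrous"]
        d = distribution(pmap)
        assert d.percentages == {
            "none_low": 0.0,
            "bone": 50.0,
            "cartilage": 25.0,
            "fibrous": 25.0,
            "none_high": 0.0,
        }

    def test_area_weighting(self):
        frames = [make_frame([0] * 4, [5.0, 5.0, 20.0, 40.0], area=[1, 1, 1, 5], time=0.0)]
        pmap = phenotype_map_at(frames, 0.0)
        d = distribution(pmap, weighting="area", node_area=np.array([1.0, 1, 1, 5]))
        assert d.percentages["bone"] == pytest.approx(25.0)
        assert d.percentages["cartilage"] == pytest.approx(12.5)
        assert d.percentages["fibrous"] == pytest.approx(62.5)

    def test_percentages_sum_to_100(self, rng):
        for weighting in ("node_count", "area"):
            area = rng.uniform(0.1, 3, 200)
            frames = [make_frame(rng.uniform(0, 0.3, 200), rng.uniform(0, 80, 200), area=area, time=0.0)]
            pmap = phenotype_map_at(frames, 0.0)
            d = distribution(pmap, weighting=weighting, node_area=area)
            assert sum(d.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_map_invariant_to_node_permutation(self, rng):
        oss, wss = rng.uniform(0, 0.2, 30), rng.uniform(0, 50, 30)
        perm = rng.permutation(30)
        m1 = phenotype_map_at([make_frame(oss, wss, time=0.0)], 0.0)
        m2 = phenotype_map_at([make_frame(oss[perm], wss[perm], time=0.0)], 0.0)
        assert list(m1.labels[perm]) == list(m2.labels)

    def test_unknown_time_rejected(self):
        with pytest.raises(ValueError):
            phenotype_map_at([make_frame([0.1], [1.0], time=0.0)], 0.3)


class TestViability:
    def test_flag_thresholds(self):
        fr = make_frame([0.3, 0.1, 0.1], [5.0, 58.0, 5.0])
        flags = viability_flags(fr)
        assert flags["oss_death"].tolist() == [True, False, False]
        assert flags["wss_apoptosis"].tolist() == [False, True, False]
        assert not flags["wss_outside_window"].iloc[2]

    def test_wss_window_bounds(self):
        fr = make_frame([0.0] * 3, [0.005, 30.0, 61.0])
        w = viability_flags(fr)["wss_outside_window"]
        assert w.tolist() == [True, False, True]

    def test_flags_never_change_classification(self):
        # a node flagged for apoptosis (WSS 58 > 57 mPa) still gets its S-band label
        fr = make_frame([0.0], [58.0], time=0.0)
        assert viability_flags(fr)["wss_apoptosis"].iloc[0]
        pmap = phenotype_map_at([fr], 0.0)
        assert pmap.labels[0] == "fibrous"  # S = 5.8 stays in the fibrous band


class TestPipeline:
    def test_single_amplitude_end_to_end(self, coarse_mesh):
        p = LoadProtocol(amplitude_fraction=0.06, dt=0.02)
        res = run_single_amplitude(coarse_mesh, p, seed=3)
        assert res.peaks.s_max2.time > 0.5
        assert sum(res.dist.percentages.values()) == pytest.approx(100.0, abs=1e-9)

    def test_study_rows_sum_and_bone_monotone(self, coarse_mesh):
        amps = [0.02, 0.05, 0.08, 0.10]
        res = run_parameter_study(amps, coarse_mesh, dt=0.02, seed=3)
        pivot = res.pivot()
        assert np.allclose(pivot.sum(axis=1), 100.0, atol=1e-9)
        bone = pivot["bone"].to_numpy()
        assert np.all(np.diff(bone) <= 1e-12)

    def test_study_deterministic_given_seed(self, coarse_mesh):
        amps = [0.03, 0.09]
        r1 = run_parameter_study(amps, coarse_mesh, dt=0.02, seed=5)
        r2 = run_parameter_study(amps, coarse_mesh, dt=0.02, seed=5)
        pd.testing.assert_frame_equal(r1.distribution_table, r2.distribution_table)
        pd.testing.assert_frame_equal(r1.peaks_table, r2.peaks_table)

    def test_empty_amplitudes_rejected(self, coarse_mesh):
        with pytest.raises(ValueError):
            run_parameter_study([], coarse_mesh)

    def test_oss_avg_peaks_at_lowest_piston_position(self, coarse_mesh, protocol_10pct):
        frames = generate_reduced_order_frames(coarse_mesh, protocol_10pct, seed=4)
        series = s_avg_series(frames)
        t_peak = series.loc[series["oss_avg"].idxmax(), "t_s"]
        assert t_peak == pytest.approx(0.5)
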