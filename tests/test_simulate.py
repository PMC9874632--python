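"""Simulator unit and property tests."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nmrmultiplet as nm
from nmrmultiplet.evaluation import label_runs
from nmrmultiplet.simulate import (
    LineshapeParams,
    MultipletSpec,
    _draw_region_count,
    label_interval,
)


def _spec(class_id=3, center=100.0, j=10.0, gamma=1.0, ls=0.0, amp=1.0, tilt=0.0):
    return MultipletSpec(
        class_id=class_id,
        center=center,
        j=j,
        lineshape=LineshapeParams(gamma=gamma, ls_mix=ls),
        amplitude=amp,
        rooftop_tilt=tilt,
    )


class TestBinomialAmplitudes:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (1, [1.0]),
            (2, [1.0, 1.0]),
            (3, [0.5, 1.0, 0.5]),  # Pascal row 1:2:1, max-normalized
            (4, [1 / 3, 1.0, 1.0, 1 / 3]),
        ],
    )
    def test_small_rows(self, n, expected):
        np.testing.assert_allclose(nm.binomial_amplitudes(n), expected)

    def test_septet_ratios(self):
        amps = nm.binomial_amplitudes(7)
        np.testing.assert_allclose(amps * 20, [1, 6, 15, 20, 15, 6, 1])

    @pytest.mark.parametrize("bad", [0, 8, -1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            nm.binomial_amplitudes(bad)


class TestRooftop:
    def test_zero_tilt_is_identity(self):
        np.testing.assert_allclose(nm.apply_rooftop([1.0, 1.0], 0.0), [1.0, 1.0])

    def test_doublet_tilt(self):
        np.testing.assert_allclose(nm.apply_rooftop([1.0, 1.0], 0.2), [0.8, 1.2])

    def test_singlet_unchanged(self):
        np.testing.assert_allclose(nm.apply_rooftop([1.0], 0.2), [1.0])

    def test_overtilt_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            nm.apply_rooftop([1.0, 1.0], 1.5)

    @settings(max_examples=100, derandomize=True)
    @given(
        n=st.integers(2, 7),
        tilt=st.floats(-0.2, 0.2),
    )
    def test_tilt_preserves_total_symmetrically(self, n, tilt):
        """The tilt factors average to 1 so a symmetric row keeps its mean."""
        base = nm.binomial_amplitudes(n)
        tilted = nm.apply_rooftop(base, tilt)
        assert tilted.sum() == pytest.approx(base.sum(), rel=1e-9)
        assert np.all(tilted > 0)


class TestRenderMultiplet:
    def test_singlet_interval_centered_on_apex(self, default_config):
        axis = default_config.make_axis()
        spec = _spec(class_id=1, center=100.0, gamma=1.0)
        curve, (lo, hi) = nm.render_multiplet(spec, axis)
        apex = np.argmax(curve)
        assert lo <= apex < hi
        mid_hz = axis[(lo + hi) // 2]
        assert abs(mid_hz - 100.0) <= default_config.dwell_hz

    def test_resolved_triplet_heights(self, default_config):
        """Well-separated triplet shows three maxima with heights near 1:2:1."""
        axis = default_config.make_axis()
        spec = _spec(class_id=3, center=102.4, j=20.0, gamma=1.0, amp=2.0)
        curve, _ = nm.render_multiplet(spec, axis)
        peak_idx = [np.argmin(np.abs(axis - c)) for c in spec.peak_centers()]
        heights = curve[peak_idx]
        np.testing.assert_allclose(heights / heights[1], [0.5, 1.0, 0.5], rtol=0.01)
        assert heights[1] == pytest.approx(2.0, rel=0.01)

    def test_zero_amplitude_renders_zero(self, default_config):
        axis = default_config.make_axis()
        curve, _ = nm.render_multiplet(_spec(amp=0.0), axis)
        assert np.all(curve == 0)

    def test_out_of_range_rejected(self, default_config):
        axis = default_config.make_axis()
        with pytest.raises(ValueError, match="does not fit"):
            nm.render_multiplet(_spec(center=1.0), axis)

    def test_label_interval_extent(self, default_config):
        """The labeled span covers the outer peaks plus two FWHM per side."""
        axis = default_config.make_axis()
        spec = _spec(class_id=2, center=100.0, j=8.0, gamma=1.0)
        lo, hi = label_interval(spec, axis, label_extent_factor=2.0)
        dwell = default_config.dwell_hz
        assert axis[lo] >= 100.0 - 4.0 - 2 * 2 * 1.0 - dwell
        assert axis[hi - 1] <= 100.0 + 4.0 + 2 * 2 * 1.0 + dwell


class TestNoise:
    def test_noise_std_matches_snr(self, default_config):
        """Baseline std approximates peak/snr at SNR 10."""
        axis = default_config.make_axis()
        spec = _spec(class_id=1, center=180.0, gamma=1.0, amp=100.0)
        curve, (lo, hi) = nm.render_multiplet(spec, axis)
        seg = nm.SpectrumSegment(
            axis=axis, intensity=curve, labels=np.zeros(len(axis), dtype=int),
            sweep_width=default_config.sweep_hz, base_frequency=400.0,
            meta={"multiplets": [spec.to_dict()]},
        )
        noisy = nm.add_noise(seg, 10.0, np.random.default_rng(5))
        baseline = noisy.intensity[: lo - 50] - curve[: lo - 50]
        assert len(baseline) >= 500
        assert np.std(baseline) == pytest.approx(10.0, rel=0.05)

    def test_noise_deterministic_under_seed(self, default_config):
        axis = default_config.make_axis()
        curve, _ = nm.render_multiplet(_spec(center=100.0), axis)
        seg = nm.SpectrumSegment(
            axis=axis, intensity=curve, labels=np.zeros(len(axis), dtype=int),
            sweep_width=default_config.sweep_hz, base_frequency=400.0,
        )
        a = nm.add_noise(seg, 10.0, np.random.default_rng(3))
        b = nm.add_noise(seg, 10.0, np.random.default_rng(3))
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_all_zero_segment_rejected(self, default_config):
        axis = default_config.make_axis()
        seg = nm.SpectrumSegment(
            axis=axis, intensity=np.zeros(len(axis)),
            labels=np.zeros(len(axis), dtype=int),
            sweep_width=default_config.sweep_hz, base_frequency=400.0,
        )
        with pytest.raises(ValueError, match="SNR"):
            nm.add_noise(seg, 10.0, np.random.default_rng(0))


class TestPhaseAndBaseline:
    def _segment(self, default_config, ls=0.0):
        axis = default_config.make_axis()
        spec = _spec(class_id=1, center=102.4, gamma=2.0, ls=ls, amp=10.0)
        curve, (lo, hi) = nm.render_multiplet(spec, axis)
        labels = np.zeros(len(axis), dtype=int)
        labels[lo:hi] = 1
        return nm.SpectrumSegment(
            axis=axis, intensity=curve, labels=labels,
            sweep_width=default_config.sweep_hz, base_frequency=400.0,
            meta={"multiplets": [spec.to_dict()]},
        ), spec

    def test_zero_phase_is_identity(self, default_config):
        seg, _ = self._segment(default_config)
        out = nm.apply_phase_distortion(seg, 0.0, 0.0)
        np.testing.assert_allclose(out.intensity, seg.intensity, atol=1e-12)

    def test_ninety_degree_pure_lorentzian_is_dispersion(self, default_config):
        seg, spec = self._segment(default_config)
        out = nm.apply_phase_distortion(seg, 90.0, 0.0)
        center_idx = np.argmin(np.abs(seg.axis - spec.center))
        # dispersion profile: ~0 at the former apex, antisymmetric around it
        assert abs(out.intensity[center_idx]) < 1e-6 * seg.intensity.max()
        x = seg.axis - spec.center
        expected = 10.0 * x * 2.0 / (x**2 + 4.0)
        np.testing.assert_allclose(out.intensity, expected, atol=1e-9)

    def test_small_phase_reduces_apex_by_cosine(self, default_config):
        seg, spec = self._segment(default_config)
        out = nm.apply_phase_distortion(seg, 5.0, 0.0)
        center_idx = np.argmin(np.abs(seg.axis - spec.center))
        ratio = out.intensity[center_idx] / seg.intensity[center_idx]
        assert ratio == pytest.approx(np.cos(np.deg2rad(5.0)), abs=1e-3)

    def test_phase_keeps_labels(self, default_config):
        seg, _ = self._segment(default_config)
        out = nm.apply_phase_distortion(seg, 4.0, -3.0)
        np.testing.assert_array_equal(out.labels, seg.labels)

    def test_baseline_bounded(self, default_config):
        seg, _ = self._segment(default_config)
        out = nm.apply_baseline_distortion(seg, np.random.default_rng(11), 0.02, 3)
        added = out.intensity - seg.intensity
        assert np.max(np.abs(added)) <= 0.02 * np.max(np.abs(seg.intensity)) + 1e-12

    def test_zero_cap_is_identity(self, default_config):
        seg, _ = self._segment(default_config)
        out = nm.apply_baseline_distortion(seg, np.random.default_rng(1), 0.0, 3)
        np.testing.assert_array_equal(out.intensity, seg.intensity)


class TestGenerateSegment:
    def test_default_geometry(self, default_config):
        seg = nm.generate_segment(default_config, np.random.default_rng(0))
        assert seg.n_points == 1024
        assert seg.sweep_width == pytest.approx(204.8)
        assert seg.base_frequency == 400.0
        assert default_config.points_per_hz == pytest.approx(5.0)

    def test_forced_single_singlet(self):
        cfg = nm.SimulationConfig(region_count_decay=1e-9, max_regions=1)
        found = False
        for seed in range(20):
            seg = nm.generate_segment(cfg, np.random.default_rng(seed))
            runs = [r for r in label_runs(seg.labels) if r[0] != 0]
            if runs and runs[0][0] == 1:
                found = True
                assert len(runs) == 1
        assert found  # singlets occur and always yield exactly one run

    def test_label_run_spec_bijection(self, segment_batch_10k):
        """Each nonzero run corresponds 1:1 to a multiplet, separated by baseline."""
        for seg in segment_batch_10k[:2000]:
            runs = [r for r in label_runs(seg.labels) if r[0] != 0]
            specs = seg.meta["multiplets"]
            assert len(runs) == len(specs)
            by_start = sorted(zip(runs, sorted(seg.meta["intervals"])), key=lambda p: p[0][1])
            for (lab, a, b), (lo, hi) in by_start:
                assert (a, b) == (lo, hi)
            classes_runs = sorted(r[0] for r in runs)
            classes_specs = sorted(s["class_id"] for s in specs)
            assert classes_runs == classes_specs

    def test_regions_never_touch(self, segment_batch_10k):
        for seg in segment_batch_10k[:2000]:
            runs = [r for r in label_runs(seg.labels) if r[0] != 0]
            runs.sort(key=lambda r: r[1])
            for (l1, a1, b1), (l2, a2, b2) in zip(runs, runs[1:]):
                assert a2 > b1  # at least one baseline point between regions

    def test_region_count_decay_is_truncated_geometric(self, default_config):
        rng = np.random.default_rng(8)
        draws = np.array([_draw_region_count(default_config, rng) for _ in range(20000)])
        assert draws.min() >= 1 and draws.max() <= default_config.max_regions
        # P(2)/P(1) should be near the decay ratio 0.5
        p1 = np.mean(draws == 1)
        p2 = np.mean(draws == 2)
        assert p2 / p1 == pytest.approx(0.5, abs=0.05)


class TestGenerateDataset:
    def test_split_counts(self, default_config):
        cfg = dataclasses.replace(default_config, n_points=512)
        ds = nm.generate_dataset(cfg, 4, (0.75, 0.25), seed=0)
        assert ds.split == ["train"] * 3 + ["validation"]

    def test_deterministic_given_seed(self, default_config):
        a = nm.generate_dataset(default_config, 5, (0.75, 0.25), seed=17)
        b = nm.generate_dataset(default_config, 5, (0.75, 0.25), seed=17)
        np.testing.assert_array_equal(a.intensity_matrix(), b.intensity_matrix())
        np.testing.assert_array_equal(a.label_matrix(), b.label_matrix())

    def test_invalid_fractions_rejected(self, default_config):
        with pytest.raises(ValueError, match="sum to 1"):
            nm.generate_dataset(default_config, 4, (0.6, 0.25), seed=0)

    def test_multiplet_class_uniformity(self, segment_batch_10k):
        """Multiplet-level class counts are uniform within 3 sigma (multinomial)."""
        counts = np.zeros(8, dtype=int)
        for seg in segment_batch_10k:
            for d in seg.meta["multiplets"]:
                counts[d["class_id"]] += 1
        n = counts[1:].sum()
        expected = n / 7
        sigma = np.sqrt(n * (1 / 7) * (6 / 7))
        assert np.all(np.abs(counts[1:] - expected) <= 3 * sigma), counts[1:]

    def test_point_label_frequency_grows_with_class(self, segment_batch_10k):
        """Wider multiplets occupy more points, so point-level frequency rises."""
        totals = np.zeros(8, dtype=np.int64)
        for seg in segment_batch_10k:
            totals += np.bincount(seg.labels, minlength=8)
        assert totals[7] > totals[1]
        # monotone trend on a coarse split (allow local wobble): compare halves
        assert totals[5:8].sum() > totals[1:4].sum()
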