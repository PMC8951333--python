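"""Hemodynamic pipeline: downsampling, vessel masking, segmentation, tracking, traces."""

import dataclasses
import warnings

import numpy as np
import pytest

from strokekit import hemodynamics as hemo
from strokekit.phantoms import PhantomSpec, generate_perfusion_phantom


def make_stack(frames, injection=0, reperfusion=1, signal="flow", fps=1.0):
    frames = np.asarray(frames, dtype=float)
    return hemo.PerfusionStack(
        frames=frames,
        timestamps=np.arange(frames.shape[0]) / fps,
        injection_frame=injection,
        reperfusion_frame=reperfusion,
        pixel_size_mm=0.08,
        signal=signal,
    )


def simple_geometry(h=4, w=6, midline=3):
    labels = np.full((h, w), hemo.HEALTHY, dtype=np.int8)
    labels[:, :midline] = hemo.ISCHEMIC
    return hemo.HemisphereGeometry(labels, "left")


def no_vessels(shape):
    return hemo.VesselMask(np.zeros(shape, dtype=bool), np.inf, "none")


class TestStackValidation:
    def test_rejects_negative_flow(self):
        with pytest.raises(ValueError, match="nonnegative"):
            make_stack(-np.ones((3, 2, 2)))

    def test_allows_signed_hemoglobin(self):
        stack = make_stack(-np.ones((3, 2, 2)), signal="oxyhb")
        assert stack.n_frames == 3

    def test_rejects_injection_after_reperfusion(self):
        with pytest.raises(ValueError, match="precede"):
            make_stack(np.ones((3, 2, 2)), injection=2, reperfusion=1)

    def test_rejects_event_outside_range(self):
        with pytest.raises(ValueError, match="outside frame range"):
            make_stack(np.ones((3, 2, 2)), injection=0, reperfusion=5)


class TestDownsampling:
    def test_240_frames_become_4_minutes(self):
        stack = make_stack(np.ones((240, 2, 2)), injection=60, reperfusion=180)
        out = hemo.downsample_to_minutes(stack)
        assert out.n_frames == 4
        assert out.injection_frame == 1
        assert out.reperfusion_frame == 3

    def test_constant_stack_preserved(self):
        stack = make_stack(np.full((120, 2, 2), 7.5), reperfusion=60)
        out = hemo.downsample_to_minutes(stack)
        assert np.all(out.frames == 7.5)

    def test_minute_of_0_to_59_averages_to_29_5(self):
        frames = np.concatenate([np.arange(60.0), np.zeros(60)]).reshape(120, 1, 1)
        stack = make_stack(frames, injection=30, reperfusion=60)
        out = hemo.downsample_to_minutes(stack)
        assert out.frames[0, 0, 0] == 29.5

    def test_trailing_partial_minute_dropped(self):
        stack = make_stack(np.ones((130, 2, 2)), reperfusion=60)
        assert hemo.downsample_to_minutes(stack).n_frames == 2

    def test_bit_exact_against_brute_force_on_integer_frames(self):
        rng = np.random.default_rng(0)
        frames = rng.integers(0, 500, size=(180, 5, 4)).astype(float)
        stack = make_stack(frames, injection=10, reperfusion=90)
        out = hemo.downsample_to_minutes(stack)
        for k in range(3):
            brute = frames[k * 60 : (k + 1) * 60].mean(axis=0)
            assert out.frames[k].tobytes() == brute.tobytes()

    def test_too_few_frames_rejected(self):
        stack = make_stack(np.ones((59, 2, 2)), reperfusion=30)
        with pytest.raises(ValueError, match="at least 60"):
            hemo.downsample_to_minutes(stack)


class TestVesselDetection:
    def test_phantom_vessels_captured_with_few_false_positives(self, noisy_phantom):
        _, stack, truth = noisy_phantom
        ds = hemo.downsample_to_minutes(stack)
        vessels = hemo.detect_vessels(hemo.reference_map(ds), truth.geometry, 95)
        capture = (vessels.mask & truth.vessel_mask).sum() / truth.vessel_mask.sum()
        parenchyma = truth.geometry.brain & ~truth.vessel_mask
        fp = (vessels.mask & parenchyma).sum() / parenchyma.sum()
        assert capture >= 0.90
        assert fp <= 0.02

    def test_constant_image_gives_empty_mask_with_warning(self):
        geometry = simple_geometry()
        with pytest.warns(UserWarning, match="constant reference"):
            vessels = hemo.detect_vessels(np.ones((4, 6)), geometry, 95)
        assert not vessels.mask.any()

    def test_higher_percentile_yields_subset(self, noisy_phantom):
        _, stack, truth = noisy_phantom
        ref = hemo.reference_map(hemo.downsample_to_minutes(stack))
        m95 = hemo.detect_vessels(ref, truth.geometry, 95).mask
        m99 = hemo.detect_vessels(ref, truth.geometry, 99).mask
        assert np.all(m99 <= m95)

    def test_percentile_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hemo.detect_vessels(np.ones((4, 6)), simple_geometry(), 40)


class TestBaseline:
    def test_noiseless_baseline_is_healthy_level(self, noiseless_phantom):
        stack, truth = noiseless_phantom
        ds = hemo.downsample_to_minutes(stack)
        vessels = hemo.VesselMask(truth.vessel_mask, 0.0, "truth")
        assert hemo.compute_baseline(ds, truth.geometry, vessels) == 100.0

    def test_mean_of_two_preperfusion_frames(self):
        frames = np.stack([np.full((2, 4), 90.0), np.full((2, 4), 110.0),
                           np.full((2, 4), 55.0)])
        stack = make_stack(frames, injection=0, reperfusion=2)
        geometry = simple_geometry(2, 4, 2)
        assert hemo.compute_baseline(stack, geometry, no_vessels((2, 4))) == 100.0

    def test_vessel_pixels_do_not_shift_baseline(self):
        frames = np.full((3, 2, 4), 100.0)
        frames[:, 0, 3] = 300.0  # bright vessel in healthy hemisphere
        stack = make_stack(frames, injection=0, reperfusion=2)
        geometry = simple_geometry(2, 4, 2)
        vessels = hemo.VesselMask(frames[0] > 200, 200.0, "test")
        assert hemo.compute_baseline(stack, geometry, vessels) == 100.0

    def test_rejects_non_flow_signal(self):
        stack = make_stack(np.ones((3, 2, 4)), signal="oxyhb")
        with pytest.raises(ValueError, match="flow"):
            hemo.compute_baseline(stack, simple_geometry(2, 4, 2), no_vessels((2, 4)))


class TestRegionMasks:
    @pytest.mark.parametrize(
        "ref_value,region",
        [(32.9, "core"), (33.0, "penumbra"), (70.0, "penumbra"), (70.1, "normal")],
    )
    def test_boundary_classification_at_baseline_100(self, ref_value, region):
        # core < 33 %, penumbra 33-70 % (closed), normal > 70 % of baseline
        frames = np.full((2, 2, 4), ref_value)
        stack = make_stack(frames, injection=0, reperfusion=1)
        geometry = simple_geometry(2, 4, 2)
        masks = hemo.build_region_masks(stack, geometry, no_vessels((2, 4)), 100.0)
        assert masks[region].sum() == geometry.ischemic.sum()

    def test_all_at_baseline_everything_normal(self):
        stack = make_stack(np.full((2, 2, 4), 100.0), reperfusion=1)
        geometry = simple_geometry(2, 4, 2)
        masks = hemo.build_region_masks(stack, geometry, no_vessels((2, 4)), 100.0)
        assert not masks.core.any()
        assert not masks.penumbra.any()
        assert masks.normal.sum() == geometry.ischemic.sum()

    def test_jaccard_against_phantom_truth(self, noisy_phantom):
        _, stack, truth = noisy_phantom
        result = hemo.analyze_flow(stack, truth.geometry)
        for region in ("core", "penumbra", "normal"):
            t, m = truth.region_mask(region), result.masks[region]
            jaccard = (t & m).sum() / (t | m).sum()
            assert jaccard >= 0.95, region

    def test_partition_exact(self, noisy_phantom):
        _, stack, truth = noisy_phantom
        result = hemo.analyze_flow(stack, truth.geometry)
        parenchyma = truth.geometry.ischemic & ~result.vessels.mask
        assert np.array_equal(result.masks.union, parenchyma)
        assert not (result.masks.core & result.masks.penumbra).any()
        assert not (result.masks.core & result.masks.normal).any()
        assert not (result.masks.penumbra & result.masks.normal).any()

    def test_raising_theta_core_never_shrinks_core(self, noisy_phantom):
        _, stack, truth = noisy_phantom
        lo = hemo.analyze_flow(stack, truth.geometry, theta_core=0.25)
        hi = hemo.analyze_flow(stack, truth.geometry, theta_core=0.40)
        assert np.all(lo.masks.core <= hi.masks.core)

    def test_nonpositive_baseline_rejected(self):
        stack = make_stack(np.full((2, 2, 4), 50.0), reperfusion=1)
        with pytest.raises(ValueError, match="baseline"):
            hemo.build_region_masks(stack, simple_geometry(2, 4, 2),
                                    no_vessels((2, 4)), 0.0)


class TestCoreTracking:
    def test_noiseless_fraction_matches_truth_pre_reperfusion(self, noiseless_phantom):
        stack, truth = noiseless_phantom
        result = hemo.analyze_flow(stack, truth.geometry)
        pre = result.track.fractions[: result.stack.reperfusion_frame]
        np.testing.assert_allclose(pre, truth.core_fraction[0], atol=1e-12)

    def test_core_vanishes_after_recovery_step(self, noiseless_phantom):
        # core recovers to 60 % of baseline, far above the 33 % threshold
        stack, truth = noiseless_phantom
        result = hemo.analyze_flow(stack, truth.geometry)
        assert result.track.fractions[-1] == 0.0

    def test_time_axis_zero_at_reperfusion(self, noiseless_phantom):
        stack, truth = noiseless_phantom
        result = hemo.analyze_flow(stack, truth.geometry)
        assert result.track.time_min[result.stack.reperfusion_frame] == 0.0

    def test_lower_penumbra_perfusion_grows_core_counts(self):
        base = PhantomSpec(seed=9, penumbra_perfusion=0.5)
        low = dataclasses.replace(base, penumbra_perfusion=0.3)
        counts = {}
        for name, spec in (("base", base), ("low", low)):
            stack, truth = generate_perfusion_phantom(spec)
            counts[name] = hemo.analyze_flow(stack, truth.geometry).track.counts
        assert np.all(counts["low"] >= counts["base"])

    def test_core_fraction_recovery_error_over_seeds(self):
        # mean absolute error of the recovered core fraction at 2 % noise
        errors = []
        for seed in range(5):
            spec = PhantomSpec(seed=seed)
            stack, truth = generate_perfusion_phantom(spec)
            result = hemo.analyze_flow(stack, truth.geometry)
            errors.append(abs(result.track.fractions[0] - truth.core_fraction[0]))
        assert np.mean(errors) <= 0.02


class TestTraces:
    def test_first_element_exactly_one(self, noisy_phantom):
        _, stack, truth = noisy_phantom
        result = hemo.analyze_flow(stack, truth.geometry)
        traces = hemo.extract_region_traces({"flow": result.stack}, result.masks)
        for values in traces.traces.values():
            assert values[0] == 1.0

    def test_constant_stack_gives_constant_unit_traces(self):
        stack = make_stack(np.full((4, 2, 4), 42.0), reperfusion=2)
        geometry = simple_geometry(2, 4, 2)
        masks = hemo.build_region_masks(stack, geometry, no_vessels((2, 4)), 42.0)
        traces = hemo.extract_region_traces({"flow": stack}, masks)
        np.testing.assert_array_equal(traces[("flow", "normal")], 1.0)

    def test_programmed_plateau_ratio_recovered(self, noiseless_phantom):
        # core flow 0.2 B before reperfusion relaxing to 0.6 B: ratio 3
        stack, truth = noiseless_phantom
        result = hemo.analyze_flow(stack, truth.geometry)
        traces = hemo.extract_region_traces({"flow": result.stack}, result.masks)
        assert traces[("flow", "core")][-1] == pytest.approx(3.0, rel=0.02)

    def test_time_axis_aligned_to_reperfusion(self, noiseless_phantom):
        stack, truth = noiseless_phantom
        result = hemo.analyze_flow(stack, truth.geometry)
        traces = hemo.extract_region_traces({"flow": result.stack}, result.masks)
        assert traces.time_min[result.stack.reperfusion_frame] == 0.0

    def test_empty_mask_omitted_with_warning(self):
        stack = make_stack(np.full((4, 2, 4), 100.0), reperfusion=2)
        geometry = simple_geometry(2, 4, 2)
        masks = hemo.build_region_masks(stack, geometry, no_vessels((2, 4)), 100.0)
        with pytest.warns(UserWarning, match="empty core mask"):
            traces = hemo.extract_region_traces({"flow": stack}, masks)
        assert ("flow", "core") not in traces.traces
        assert ("flow", "normal") in traces.traces

    def test_zero_first_value_rejected(self):
        frames = np.full((4, 2, 4), 100.0)
        stack = make_stack(frames, reperfusion=2, signal="oxyhb")
        stack.frames[0] = 0.0
        geometry = simple_geometry(2, 4, 2)
        masks = hemo.RegionMasks(
            core=np.zeros((2, 4), bool), penumbra=np.zeros((2, 4), bool),
            normal=geometry.ischemic, baseline=100.0)
        with pytest.raises(ValueError, match="cannot scale"):
            hemo.extract_region_traces({"oxyhb": stack}, masks)

    def test_vessel_brightness_does_not_leak_into_statistics(self, noiseless_phantom):
        # arbitrarily bright pixels inside the vessel mask change nothing
        stack, truth = noiseless_phantom
        result = hemo.analyze_flow(stack, truth.geometry)
        bright = dataclasses.replace(
            stack, frames=stack.frames.copy(), timestamps=stack.timestamps)
        bright.frames[:, result.vessels.mask] *= 50
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            redo = hemo.analyze_flow(bright, truth.geometry)
        assert redo.baseline == result.baseline
        assert np.array_equal(redo.masks.core, result.masks.core)
        assert np.array_equal(redo.track.counts, result.track.counts)
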