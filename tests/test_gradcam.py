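"""Grad-CAM: gradient-weighted maps, thresholded highlights, overlap
reporting against ground-truth P-wave windows."""

import numpy as np
import pytest

from ecgxai.gradcam import CamMap, cam_overlap_report, gradcam, highlight_regions
from ecgxai.model import ModelConfig, build_model
from ecgxai.records import EcgRecord, GroundTruth, Rhythm
from ecgxai.synth import SynthConfig, synth_record

FS = 300.0


def _cam(activation, quantile=0.8, mask=None, fs=FS):
    activation = np.asarray(activation, dtype=float)
    if mask is None:
        if activation.max() > 0:
            mask = activation >= np.quantile(activation, quantile)
        else:
            mask = np.zeros(activation.size, dtype=bool)
    return CamMap(
        activation=activation,
        target_class=Rhythm.AFIB,
        layer_id=0,
        highlight_mask=mask,
        threshold_quantile=quantile,
        fs=fs,
    )


def _matched_filter_model():
    """One-channel network hand-wired to detect a 5-sample bump."""
    cfg = ModelConfig(
        n_blocks=1, base_channels=1, max_channels=1, kernel_size=5,
        stem_stride=1, stem_pool=1, seed=0,
    )
    model = build_model(cfg)
    template = np.array([0.2, 0.5, 1.0, 0.5, 0.2], dtype=np.float32)
    delta = np.zeros(5, dtype=np.float32)
    delta[2] = 1.0
    model.stem_conv.w[0, 0] = delta
    model.stem_conv.b[...] = 0.0
    block = model.blocks[0]
    block.conv1.w[0, 0] = template
    block.conv1.b[...] = 0.0
    block.conv2.w[0, 0] = delta
    block.conv2.b[...] = 0.0
    model.head.w[...] = np.array([[-1.0, 1.0]], dtype=np.float32)
    model.head.b[...] = 0.0
    # neutralize every batch norm (eval mode uses running stats)
    for bn in [model.stem_bn, block.bn1, block.bn2]:
        bn.gamma[...] = 1.0
        bn.beta[...] = 0.0
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 1.0
    return model, template


class TestGradcamMaps:
    def test_zero_head_gives_zero_map(self, tiny_model_config, normal_record):
        model = build_model(tiny_model_config)
        model.head.w[...] = 0.0
        model.head.b[...] = 0.0
        cam = gradcam(model, normal_record[0])
        assert cam.activation.max() == 0.0
        assert not cam.highlight_mask.any()

    def test_planted_bump_is_localized(self):
        """Hand-computed matched-filter network: the map peaks at the
        planted bump within half a receptive field."""
        model, template = _matched_filter_model()
        x = np.zeros(1200)
        center = 700
        x[center - 2 : center + 3] = template * 0.8
        # distractor noise floor well below the bump
        x += 0.01
        record = EcgRecord("bump", x, fs=FS)
        cam = gradcam(model, record, layer_id=0)
        receptive_field = 13  # three stacked k=5 convolutions
        assert abs(int(cam.activation.argmax()) - center) <= receptive_field // 2

    def test_contract_nonnegative_and_normalized(self, trained_desk_model, afib_record):
        model, _ = trained_desk_model
        from ecgxai.preprocessing import preprocess

        cam = gradcam(model, preprocess(afib_record[0]))
        assert cam.activation.min() >= 0.0
        assert cam.activation.max() in (0.0, 1.0)
        assert cam.activation.size == afib_record[0].n_samples

    def test_invalid_layer_rejected(self, tiny_model_config, normal_record):
        model = build_model(tiny_model_config)
        with pytest.raises(ValueError, match="layer"):
            gradcam(model, normal_record[0], layer_id=99)


class TestHighlightRegions:
    def test_constant_map_is_one_run(self):
        cam = _cam(np.ones(600))
        assert highlight_regions(cam, 0.5) == [(0, 600)]

    def test_zero_map_has_no_regions(self):
        cam = _cam(np.zeros(600))
        assert highlight_regions(cam, 0.5) == []

    def test_triangular_bump_single_region_contains_apex(self):
        n = 900
        apex = 450
        act = np.maximum(0, 1 - np.abs(np.arange(n) - apex) / 200.0)
        regions = highlight_regions(_cam(act), 0.9)
        assert len(regions) == 1
        start, end = regions[0]
        assert start <= apex < end

    def test_regions_nest_as_quantile_rises(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            act = np.abs(rng.normal(size=1200))
            act = np.convolve(act, np.ones(30) / 30, mode="same")
            act /= act.max()
            cam = _cam(act)
            low = highlight_regions(cam, 0.6)
            high = highlight_regions(cam, 0.9)
            for hs, he in high:
                assert any(ls <= hs and he <= le for ls, le in low)

    def test_short_slivers_discarded(self):
        act = np.full(600, 0.3)
        act[100:104] = 1.0  # 4 samples = 13 ms < 20 ms floor
        assert highlight_regions(_cam(act), 0.999) == []


class TestOverlapReport:
    def _truth(self, rhythm=Rhythm.NORMAL):
        if rhythm is Rhythm.NORMAL:
            return GroundTruth(
                r_times=(1.0, 2.0), p_windows=((0.79, 0.89), (1.79, 1.89)),
                rhythm=rhythm,
            )
        return GroundTruth(r_times=(1.0, 2.0), p_windows=(), rhythm=rhythm)

    def test_exact_window_match_scores_one(self):
        mask = np.zeros(900, dtype=bool)
        mask[int(0.79 * FS) : int(0.89 * FS)] = True
        cam = _cam(mask.astype(float), mask=mask)
        report = cam_overlap_report(cam, self._truth(), duration=3.0)
        assert report.fraction_in_windows == 1.0

    def test_disjoint_highlight_scores_zero(self):
        mask = np.zeros(900, dtype=bool)
        mask[0:30] = True
        act = mask.astype(float)
        report = cam_overlap_report(_cam(act, mask=mask), self._truth(), duration=3.0)
        assert report.fraction_in_windows == 0.0

    def test_afib_uses_pre_r_windows(self):
        report = cam_overlap_report(
            _cam(np.ones(900)), self._truth(Rhythm.AFIB), duration=3.0
        )
        assert report.window_family == "pre_r_windows"
        assert report.window_coverage > 0

    def test_random_mask_matches_coverage_baseline(self):
        """A randomly placed mask overlaps the windows at the coverage
        rate — the chance level that localization must beat."""
        record, truth = synth_record(SynthConfig(seed=31))
        n = record.n_samples
        base_mask = np.zeros(n, dtype=bool)
        base_mask[: n // 5] = True
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(200):
            mask = np.roll(base_mask, rng.integers(0, n))
            cam = _cam(mask.astype(float), mask=mask)
            rep = cam_overlap_report(cam, truth, duration=record.duration)
            fracs.append(rep.fraction_in_windows)
        coverage = rep.window_coverage
        assert np.mean(fracs) == pytest.approx(coverage, abs=0.02)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            cam_overlap_report(
                _cam(np.ones(900)),
                GroundTruth(r_times=(), p_windows=(), rhythm=Rhythm.AFIB),
                duration=3.0,
            )
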