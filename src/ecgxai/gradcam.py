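"""Gradient-weighted class-activation mapping for the 1D classifier.

The class score is backpropagated to a convolutional stage's feature maps;
per-channel weights are the time-averaged gradients, and the rectified
weighted sum of the maps — upsampled linearly to signal resolution and
max-normalized — localizes the evidence the network used.  A quantile
threshold turns the map into highlight regions analogous to the shaded
overlays clinicians annotate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .model import ResNet1D, _standardize
from .records import EcgRecord, GroundTruth, Rhythm
from .synth import pre_r_windows

__all__ = [
    "CamMap",
    "gradcam",
    "gradcam_multi",
    "highlight_regions",
    "cam_overlap_report",
    "OverlapReport",
]

MIN_REGION_S = 0.02


@dataclass(frozen=True)
class CamMap:
    """Per-sample non-negative activation with a thresholded highlight mask."""

    activation: np.ndarray
    target_class: Rhythm
    layer_id: int
    highlight_mask: np.ndarray
    threshold_quantile: float
    fs: float

    def __post_init__(self) -> None:
        act = np.asarray(self.activation, dtype=float)
        object.__setattr__(self, "activation", act)
        if np.any(act < 0):
            raise ValueError("activation must be non-negative")
        peak = act.max() if act.size else 0.0
        if peak > 0 and not np.isclose(peak, 1.0):
            raise ValueError("activation must be max-normalized (or all zero)")


def _threshold_mask(activation: np.ndarray, quantile: float) -> np.ndarray:
    if activation.max() == 0:
        return np.zeros(activation.size, dtype=bool)
    return activation >= np.quantile(activation, quantile)


def gradcam(
    model: ResNet1D,
    record: EcgRecord,
    target_class: Rhythm = Rhythm.AFIB,
    layer_id: int | None = None,
    threshold_quantile: float = 0.8,
) -> CamMap:
    """Compute the class-activation map at one residual stage.

    ``layer_id`` is the 0-based residual-block index; the default is the
    final block, whose maps are the coarsest but most class-discriminative.
    Earlier blocks give finer temporal resolution.
    """
    if layer_id is None:
        layer_id = len(model.blocks) - 1
    if not 0 <= layer_id < len(model.blocks):
        raise ValueError(
            f"layer_id {layer_id} outside the {len(model.blocks)} residual blocks"
        )
    x = _standardize(record.samples)[None, :]
    logits = model.forward(x, training=False, capture=[layer_id])
    class_idx = 1 if target_class is Rhythm.AFIB else 0
    dlogits = np.zeros_like(logits)
    dlogits[0, class_idx] = 1.0
    model.backward(dlogits)

    feats = model.captured_activations[layer_id][0]   # (C, Lf)
    grads = model.captured_gradients[layer_id][0]     # (C, Lf)
    weights = grads.mean(axis=1)                      # pooled gradient per channel
    cam = np.maximum(weights @ feats, 0.0)

    n = record.n_samples
    lf = cam.size
    centers = (np.arange(lf) + 0.5) * (n / lf)        # feature -> sample position
    upsampled = np.interp(np.arange(n), centers, cam, left=cam[0], right=cam[-1])
    peak = upsampled.max()
    if peak > 0:
        upsampled = upsampled / peak
    return CamMap(
        activation=upsampled,
        target_class=target_class,
        layer_id=layer_id,
        highlight_mask=_threshold_mask(upsampled, threshold_quantile),
        threshold_quantile=threshold_quantile,
        fs=record.fs,
    )


def gradcam_multi(
    model: ResNet1D,
    record: EcgRecord,
    target_class: Rhythm = Rhythm.AFIB,
    layer_ids: "List[int] | None" = None,
    threshold_quantile: float = 0.8,
) -> "dict[int, CamMap]":
    """Class-activation maps at several stages from one backward pass.

    Equivalent to calling :func:`gradcam` per layer, but the network runs
    forward and backward only once.
    """
    if layer_ids is None:
        layer_ids = list(range(len(model.blocks)))
    x = _standardize(record.samples)[None, :]
    logits = model.forward(x, training=False, capture=layer_ids)
    class_idx = 1 if target_class is Rhythm.AFIB else 0
    dlogits = np.zeros_like(logits)
    dlogits[0, class_idx] = 1.0
    model.backward(dlogits)
    n = record.n_samples
    out = {}
    for layer in layer_ids:
        feats = model.captured_activations[layer][0]
        grads = model.captured_gradients[layer][0]
        cam = np.maximum(grads.mean(axis=1) @ feats, 0.0)
        centers = (np.arange(cam.size) + 0.5) * (n / cam.size)
        upsampled = np.interp(np.arange(n), centers, cam, left=cam[0], right=cam[-1])
        peak = upsampled.max()
        if peak > 0:
            upsampled = upsampled / peak
        out[layer] = CamMap(
            activation=upsampled,
            target_class=target_class,
            layer_id=layer,
            highlight_mask=_threshold_mask(upsampled, threshold_quantile),
            threshold_quantile=threshold_quantile,
            fs=record.fs,
        )
    return out


def highlight_regions(cam: CamMap, quantile: float = 0.8) -> List[Tuple[int, int]]:
    """Maximal half-open sample runs where activation clears the quantile.

    Runs shorter than 0.02 s are discarded as interpolation slivers.
    """
    mask = _threshold_mask(cam.activation, quantile)
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    min_len = int(round(MIN_REGION_S * cam.fs))
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


@dataclass(frozen=True)
class OverlapReport:
    """How much of the highlighted signal falls inside the stated windows."""

    fraction_in_windows: float
    window_coverage: float  # fraction of the record covered by the windows
    n_highlighted: int
    window_family: str


def cam_overlap_report(cam: CamMap, truth: GroundTruth, duration: float | None = None) -> OverlapReport:
    """Overlap of highlight regions with the P-wave window family.

    Sinus records use the true P-wave windows; AFib records (which have
    none) use fixed-width pre-R windows where P-waves would sit.  The
    ``window_coverage`` field is the expected overlap of a mask placed
    uniformly at random — the chance baseline for localization claims.
    """
    if not truth.r_times:
        raise ValueError("ground truth contains no beats")
    n = cam.activation.size
    duration = duration if duration is not None else n / cam.fs
    if truth.rhythm is Rhythm.NORMAL:
        windows, family = list(truth.p_windows), "p_windows"
    else:
        windows, family = pre_r_windows(np.array(truth.r_times), duration), "pre_r_windows"
    in_window = np.zeros(n, dtype=bool)
    for s, e in windows:
        in_window[int(round(s * cam.fs)) : int(round(e * cam.fs))] = True
    mask = cam.highlight_mask
    n_high = int(mask.sum())
    frac = float((mask & in_window).sum() / n_high) if n_high else 0.0
    return OverlapReport(
        fraction_in_windows=frac,
        window_coverage=float(in_window.mean()),
        n_highlighted=n_high,
        window_family=family,
    )
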