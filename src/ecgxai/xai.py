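"""Point-wise attribution for a trained rhythm classifier.

Two model-agnostic routes produce one signed importance value per signal
sample (positive = evidence for the target class):

* **LIME** — perturb the signal with Gaussian noise on random subsets of
  short segments, record the class probability of each perturbation, and
  fit a locality-weighted ridge surrogate from the perturbation masks to
  the probabilities.  A segment whose perturbation lowers the probability
  is important, so the surrogate coefficients enter negated.
* **Kernel SHAP** — replace random coalitions of segments by a background
  signal and solve the Shapley-kernel-weighted regression.  The additivity
  (local accuracy) identity sum(values) = f(x) − f(background) is enforced
  exactly by eliminating one coefficient against the constraint; with all
  2^M − 2 proper coalitions enumerated the solution equals the exact
  Shapley values.

Both methods attribute at segment granularity (default 0.1 s — perturbing
single samples at 300 Hz moves the classifier too little to identify a
surrogate) and spread each segment's score evenly over its member samples,
so sums over whole segments — and hence over RR intervals downstream —
preserve total attribution mass.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple, Union

import numpy as np

from .model import ResNet1D, softmax, _standardize
from .records import EcgRecord, Rhythm

__all__ = ["ImportanceVector", "SegmentPartition", "lime_explain", "shap_explain"]

PredictFn = Callable[[np.ndarray], np.ndarray]
Model = Union[ResNet1D, PredictFn]


@dataclass(frozen=True)
class SegmentPartition:
    """Contiguous equal-length index ranges covering a record.

    The last segment may be shorter.  ``bounds[i]``/``bounds[i+1]`` delimit
    segment ``i`` (half-open).
    """

    n_samples: int
    segment_length: int

    def __post_init__(self) -> None:
        if self.segment_length < 1 or self.n_samples < 1:
            raise ValueError("need positive lengths")

    @property
    def n_segments(self) -> int:
        return -(-self.n_samples // self.segment_length)

    @property
    def bounds(self) -> np.ndarray:
        edges = np.arange(0, self.n_samples + self.segment_length, self.segment_length)
        edges[-1] = min(edges[-1], self.n_samples)
        return edges[: self.n_segments + 1]

    def lengths(self) -> np.ndarray:
        b = self.bounds
        return np.diff(b)

    def spread(self, segment_values: np.ndarray) -> np.ndarray:
        """Per-sample vector: each segment's value divided evenly across it."""
        out = np.empty(self.n_samples)
        b = self.bounds
        for i, v in enumerate(segment_values):
            out[b[i] : b[i + 1]] = v / (b[i + 1] - b[i])
        return out

    def segment_sums(self, per_sample: np.ndarray) -> np.ndarray:
        b = self.bounds
        return np.add.reduceat(per_sample, b[:-1])


@dataclass(frozen=True)
class ImportanceVector:
    """One attribution value per signal sample, aligned to its record."""

    values: np.ndarray
    target_class: Rhythm
    method: str
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if not np.all(np.isfinite(vals)):
            raise ValueError("importance values must be finite")


def _batch_proba(model: Model, signals: np.ndarray) -> np.ndarray:
    """(N, L) raw signals to (N, n_classes) probabilities."""
    if isinstance(model, ResNet1D):
        x = np.stack([_standardize(s) for s in signals])
        return softmax(model.forward(x, training=False).astype(np.float64))
    return np.asarray(model(signals), dtype=float)


def _batch_response(model: Model, signals: np.ndarray, class_idx: int, link: str) -> np.ndarray:
    """Explained response per signal: probability or log-odds.

    For the network the log-odds is taken directly from the logits
    (logit_c − logit_other), which stays informative even when the softmax
    probability saturates at 1.0; for generic probability-returning models
    it is computed from clipped probabilities.
    """
    if link not in ("identity", "logit"):
        raise ValueError(f"unknown link {link!r}")
    if isinstance(model, ResNet1D) and link == "logit":
        x = np.stack([_standardize(s) for s in signals])
        logits = model.forward(x, training=False).astype(np.float64)
        return logits[:, class_idx] - logits[:, 1 - class_idx]
    return _link_response(_batch_proba(model, signals)[:, class_idx], link)


def _class_index(target_class: Rhythm) -> int:
    return 1 if target_class is Rhythm.AFIB else 0


def _link_response(probs: np.ndarray, link: str) -> np.ndarray:
    """Map class probabilities to the explained response.

    ``identity`` explains the probability itself; ``logit`` explains the
    log-odds, which stays informative when a confident classifier saturates
    the probability at 1.0 and small perturbations no longer move it.
    """
    if link == "identity":
        return probs
    if link == "logit":
        p = np.clip(probs, 1e-12, 1.0 - 1e-12)
        return np.log(p / (1.0 - p))
    raise ValueError(f"unknown link {link!r}")


def _chunked_proba(model: Model, signals: np.ndarray, chunk: int = 32) -> np.ndarray:
    return np.concatenate(
        [_batch_proba(model, signals[i : i + chunk]) for i in range(0, len(signals), chunk)]
    )


def _chunked_response(
    model: Model, signals: np.ndarray, class_idx: int, link: str, chunk: int = 32
) -> np.ndarray:
    return np.concatenate(
        [
            _batch_response(model, signals[i : i + chunk], class_idx, link)
            for i in range(0, len(signals), chunk)
        ]
    )


def lime_explain(
    model: Model,
    record: EcgRecord,
    target_class: Rhythm = Rhythm.AFIB,
    n_perturb: int = 500,
    noise_sd: float | None = None,
    kernel_width: float = 0.25,
    seed: int = 0,
    segment_length: int | None = None,
    link: str = "logit",
) -> ImportanceVector:
    """Perturbation-surrogate attribution.

    Each of ``n_perturb`` perturbations flips an independent coin per
    segment and adds Gaussian noise (sd ``noise_sd``, default 0.2x the
    signal sd) to the chosen segments.  A ridge surrogate weighted by
    exp(-h^2 / kernel_width^2), h = fraction of segments perturbed, maps
    mask vectors to the target-class response (log-odds by default; see
    ``link``); negated coefficients are the segment importances.
    """
    if n_perturb < 50:
        raise ValueError("need at least 50 perturbations for a stable surrogate")
    x = record.samples
    part = SegmentPartition(x.size, segment_length or int(round(0.1 * record.fs)))
    m = part.n_segments
    rng = np.random.default_rng(seed)
    if noise_sd is None:
        noise_sd = 0.2 * float(x.std())

    masks = rng.random((n_perturb, m)) < 0.5
    noise = rng.normal(0.0, noise_sd, size=(n_perturb, x.size))
    sample_mask = np.repeat(masks, part.lengths(), axis=1)
    perturbed = x[None, :] + noise * sample_mask
    probs = _chunked_response(model, perturbed, _class_index(target_class), link)

    meta = {
        "n_perturbations": n_perturb,
        "noise_sd": float(noise_sd),
        "kernel_width": kernel_width,
        "seed": seed,
        "segment_length": part.segment_length,
        "link": link,
    }
    if probs.std() < 1e-12:
        warnings.warn("degenerate LIME surrogate: model response is constant")
        return ImportanceVector(np.zeros(x.size), target_class, "lime", meta)

    h = masks.mean(axis=1)
    w = np.exp(-(h**2) / kernel_width**2)
    z = np.column_stack([np.ones(n_perturb), masks.astype(float)])
    wz = z * w[:, None]
    ridge = 1e-3 * np.eye(m + 1)
    ridge[0, 0] = 0.0  # intercept unpenalized
    beta = np.linalg.solve(z.T @ wz + ridge, wz.T @ probs)
    segment_importance = -beta[1:]
    return ImportanceVector(part.spread(segment_importance), target_class, "lime", meta)


def _shapley_kernel_weights(m: int, sizes: np.ndarray) -> np.ndarray:
    # pi(s) = (m - 1) / (C(m, s) * s * (m - s))
    from scipy.special import comb

    return (m - 1) / (comb(m, sizes) * sizes * (m - sizes))


def shap_explain(
    model: Model,
    record: EcgRecord,
    target_class: Rhythm = Rhythm.AFIB,
    n_coalitions: int = 1000,
    background: str = "zeros",
    seed: int = 0,
    segment_length: int | None = None,
    link: str = "logit",
) -> ImportanceVector:
    """Kernel-SHAP attribution over the segment partition.

    When ``n_coalitions`` covers all 2^M − 2 proper coalitions they are
    enumerated exhaustively (exact Shapley values); otherwise coalition
    sizes are drawn proportionally to the Shapley kernel.  ``background``
    is the off-state signal: ``"zeros"`` (baseline-free, appropriate after
    preprocessing) or ``"flat_mean"`` (constant at the signal mean).
    """
    x = record.samples
    part = SegmentPartition(x.size, segment_length or int(round(0.1 * record.fs)))
    m = part.n_segments
    if m < 2:
        raise ValueError("need at least two segments")
    if n_coalitions < m + 2:
        raise ValueError(f"need n_coalitions >= n_segments + 2 = {m + 2}")
    if background == "zeros":
        bg = np.zeros_like(x)
    elif background == "flat_mean":
        bg = np.full_like(x, x.mean())
    else:
        raise ValueError(f"unknown background {background!r}")

    rng = np.random.default_rng(seed)
    exhaustive = m <= 20 and 2**m - 2 <= n_coalitions
    if exhaustive:
        zs = np.array(
            [mask for mask in itertools.product([0, 1], repeat=m)][1:-1], dtype=float
        )
    else:
        sizes = np.arange(1, m)
        size_probs = (m - 1) / (sizes * (m - sizes))
        size_probs = size_probs / size_probs.sum()
        draw_sizes = rng.choice(sizes, size=n_coalitions, p=size_probs)
        zs = np.zeros((n_coalitions, m))
        for row, s in zip(zs, draw_sizes):
            row[rng.choice(m, size=int(s), replace=False)] = 1.0
    weights = _shapley_kernel_weights(m, zs.sum(axis=1))
    if not exhaustive:
        # sizes were importance-sampled with the kernel's size profile;
        # the remaining weight is uniform within a size class
        weights = np.ones(len(zs))

    sample_on = np.repeat(zs.astype(bool), part.lengths(), axis=1)
    signals = np.where(sample_on, x[None, :], bg[None, :])
    ci = _class_index(target_class)
    probs = _chunked_response(model, signals, ci, link)
    f_x = float(_batch_response(model, x[None, :], ci, link)[0])
    f_bg = float(_batch_response(model, bg[None, :], ci, link)[0])
    delta = f_x - f_bg

    # eliminate phi_m against the additivity constraint sum(phi) = delta
    y = probs - f_bg
    z_red = zs[:, :-1] - zs[:, -1:]
    y_red = y - zs[:, -1] * delta
    sw = np.sqrt(weights)
    a = np.column_stack([np.ones(len(zs)), z_red]) * sw[:, None]
    b = y_red * sw
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    phi = np.empty(m)
    phi[:-1] = coef[1:]
    phi[-1] = delta - phi[:-1].sum()

    meta = {
        "n_coalitions": len(zs),
        "exhaustive": bool(exhaustive),
        "background": background,
        "seed": seed,
        "segment_length": part.segment_length,
        "link": link,
        "f_x": f_x,
        "f_background": f_bg,
    }
    return ImportanceVector(part.spread(phi), target_class, "shap", meta)
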