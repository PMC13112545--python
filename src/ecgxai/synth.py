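"""Synthetic single-lead ECG generator with analytic ground truth.

The generator exists so that every downstream stage — denoising, R-peak
detection, the classifier, the attribution methods and their RR-interval
aggregation — can be exercised against signals whose diagnostic content is
known exactly.  It encodes the two contrasts that distinguish atrial
fibrillation from sinus rhythm on a single lead:

* **morphology** — sinus beats carry a P-wave before each QRS complex;
  AFib replaces it with a low-amplitude fibrillatory (f-wave) oscillation
  in the 4–10 Hz band;
* **timing** — sinus RR intervals are nearly constant (coefficient of
  variation of a few percent) while AFib intervals are irregularly
  irregular (cv well above 0.15).

Each beat is a sum of Gaussian bumps for the P, Q, R, S and T deflections
(an additive simplification of the ECGSYN dynamical model): the test suite
needs exact fiducials, not maximal realism.  Additive noise covers the three
standard contaminants: baseline wander, powerline interference and white
sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np

from .records import EcgRecord, GroundTruth, Rhythm

__all__ = [
    "NoiseConfig",
    "SynthConfig",
    "sample_rr_sequence",
    "synth_record",
    "synth_dataset",
    "pre_r_windows",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Additive noise model (all amplitudes in millivolts).

    ``baseline_freq`` ~0.3 Hz emulates respiratory drift; ``powerline_freq``
    is mains interference (50 or 60 Hz); ``white_sd`` is broadband sensor
    noise.
    """

    white_sd: float = 0.02
    baseline_amp: float = 0.10
    baseline_freq: float = 0.3
    powerline_amp: float = 0.02
    powerline_freq: float = 50.0

    def __post_init__(self) -> None:
        for name in ("white_sd", "baseline_amp", "powerline_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of one synthetic record.

    Widths are Gaussian half-windows in seconds: a deflection of width ``w``
    is a Gaussian bump with standard deviation ``w/2``, so the interval
    ``center ± w`` holds ~95% of its energy.  Offsets are relative to the
    R-peak center.  Amplitudes are millivolts.
    """

    fs: float = 300.0
    duration: float = 30.0
    rhythm: Rhythm = Rhythm.NORMAL
    rr_mean: float = 0.8
    rr_cv: float = 0.03
    p_amp: float = 0.20
    q_amp: float = -0.10
    r_amp: float = 1.0
    s_amp: float = -0.15
    t_amp: float = 0.30
    p_width: float = 0.05
    qrs_width: float = 0.08
    t_width: float = 0.14
    p_offset: float = -0.16
    t_offset: float = 0.30
    fwave_amp: float = 0.0
    fwave_freq: float = 6.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite([self.rr_mean, self.rr_cv]).all():
            raise ValueError("rr_mean and rr_cv must be finite")
        if not 0.3 <= self.rr_mean <= 2.0:
            raise ValueError("rr_mean must lie in [0.3, 2.0] s")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be non-negative")
        for name in ("p_width", "qrs_width", "t_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rhythm is Rhythm.NORMAL:
            if self.p_amp <= 0 or self.fwave_amp != 0:
                raise ValueError("normal rhythm requires p_amp > 0 and fwave_amp = 0")
            if self.rr_cv > 0.05:
                raise ValueError("normal rhythm requires rr_cv <= 0.05")
        else:
            if self.p_amp != 0 or self.fwave_amp < 0:
                raise ValueError("afib requires p_amp = 0 and fwave_amp >= 0")
            if self.rr_cv < 0.15:
                raise ValueError("afib requires rr_cv >= 0.15")


def afib_config(**overrides) -> SynthConfig:
    """Convenience: AFib defaults (no P-wave, f-waves, irregular RR)."""
    params = dict(
        rhythm=Rhythm.AFIB,
        p_amp=0.0,
        fwave_amp=0.05,
        rr_cv=0.25,
        t_amp=0.35,  # pronounced T-waves accompany the arrhythmic phenotype
    )
    params.update(overrides)
    return SynthConfig(**params)


# RR floor: keeps adjacent beat templates from overlapping (ventricular
# refractoriness also makes shorter intervals unphysiological).
_RR_FLOOR = 0.3


def sample_rr_sequence(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw RR-interval durations (seconds) summing past ``config.duration``.

    Sinus rhythm: i.i.d. Gaussian around ``rr_mean`` with sd ``rr_cv *
    rr_mean``, truncated at ±3 sd.  AFib: i.i.d. log-normal with matching
    mean and coefficient of variation, capturing the heavy-tailed,
    uncorrelated spacing of fibrillatory conduction.  Draws below 0.3 s are
    floored there.
    """
    m, cv = config.rr_mean, config.rr_cv
    if cv == 0:
        n = int(np.ceil(config.duration / m)) + 1
        return np.full(n, m)
    out: List[float] = []
    total = 0.0
    sd = cv * m
    if config.rhythm is Rhythm.AFIB:
        sigma2 = np.log1p(cv**2)
        mu = np.log(m) - sigma2 / 2.0
        sigma = np.sqrt(sigma2)
    while total < config.duration:
        block = max(16, int((config.duration - total) / m) + 2)
        if config.rhythm is Rhythm.AFIB:
            draws = rng.lognormal(mean=mu, sigma=sigma, size=block)
        else:
            draws = np.clip(rng.normal(m, sd, size=block), m - 3 * sd, m + 3 * sd)
        draws = np.maximum(draws, _RR_FLOOR)
        out.extend(draws.tolist())
        total += float(draws.sum())
    return np.asarray(out)


def _add_bump(
    signal: np.ndarray, t: np.ndarray, center: float, amp: float, sigma: float
) -> None:
    # evaluate only within ±5 sigma for speed; tails are < 4e-6 of amp
    fs = 1.0 / (t[1] - t[0])
    lo = max(0, int((center - 5 * sigma) * fs))
    hi = min(t.size, int((center + 5 * sigma) * fs) + 2)
    if hi <= lo:
        return
    window = t[lo:hi]
    signal[lo:hi] += amp * np.exp(-((window - center) ** 2) / (2.0 * sigma**2))


def synth_record(config: SynthConfig, record_id: str = "synth") -> tuple[EcgRecord, GroundTruth]:
    """Synthesize one labelled record plus its exact fiducials.

    The returned ground truth lists every R-bump center and, for sinus
    rhythm, one P-window ``[R + p_offset - p_width, R + p_offset + p_width]``
    per beat.  AFib records get an amplitude-modulated sinusoidal f-wave at
    ``fwave_freq`` with random phase instead of P-waves.
    """
    if not 5.0 <= config.duration <= 120.0:
        raise ValueError("duration must lie in [5, 120] s")
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    signal = np.zeros(n)

    rr = sample_rr_sequence(config, rng)
    # first beat starts a little into the strip so the initial P-wave fits
    r_times = np.concatenate([[0.25], 0.25 + np.cumsum(rr)])
    r_times = r_times[r_times < config.duration - 0.1]

    p_windows: List[Tuple[float, float]] = []
    for r in r_times:
        _add_bump(signal, t, r + config.p_offset, config.p_amp, config.p_width / 2)
        _add_bump(signal, t, r - config.qrs_width / 2, config.q_amp, config.qrs_width / 4)
        _add_bump(signal, t, r, config.r_amp, config.qrs_width / 4)
        _add_bump(signal, t, r + config.qrs_width / 2, config.s_amp, config.qrs_width / 4)
        _add_bump(signal, t, r + config.t_offset, config.t_amp, config.t_width / 2)
        if config.rhythm is Rhythm.NORMAL:
            start = r + config.p_offset - config.p_width
            end = r + config.p_offset + config.p_width
            if start >= 0 and end <= config.duration:
                p_windows.append((start, end))

    if config.rhythm is Rhythm.AFIB and config.fwave_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        mod_phase = rng.uniform(0, 2 * np.pi)
        envelope = 0.7 + 0.3 * np.sin(2 * np.pi * 0.6 * t + mod_phase)
        signal += config.fwave_amp * envelope * np.sin(2 * np.pi * config.fwave_freq * t + phase)

    noise = config.noise
    if noise.baseline_amp > 0:
        signal += noise.baseline_amp * np.sin(
            2 * np.pi * noise.baseline_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.powerline_amp > 0:
        signal += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t + rng.uniform(0, 2 * np.pi)
        )
    if noise.white_sd > 0:
        signal += rng.normal(0.0, noise.white_sd, size=n)

    truth = GroundTruth(
        r_times=tuple(float(r) for r in r_times),
        p_windows=tuple(p_windows),
        rhythm=config.rhythm,
    )
    record = EcgRecord(
        record_id=record_id,
        samples=signal,
        fs=config.fs,
        label=config.rhythm,
        annotations=truth,
    )
    return record, truth


_JITTERED = (
    "p_amp", "q_amp", "r_amp", "s_amp", "t_amp",
    "p_width", "qrs_width", "t_width", "rr_mean",
)


def synth_dataset(
    n: int,
    class_balance: float,
    base_config: SynthConfig | None = None,
    seed: int = 0,
    afib_base: SynthConfig | None = None,
) -> List[tuple[EcgRecord, GroundTruth]]:
    """Generate ``n`` records, a ``class_balance`` fraction of them AFib.

    Per-record morphology (amplitudes, widths, mean rate) is jittered ±10%
    from independent substreams so no two records coincide; the
    rhythm-defining parameters (rr_cv, P presence, f-waves) stay at their
    class values.  ``afib_base`` overrides the AFib-class template, e.g. to
    build a P-wave-contrast dataset where the classes differ only in P-wave
    presence and RR irregularity (``afib_config(fwave_amp=0, t_amp=0.3)``).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 < class_balance < 1:
        raise ValueError("class_balance must lie strictly between 0 and 1")
    n_afib = int(round(n * class_balance))
    if n_afib < 1:
        raise ValueError("n * class_balance must be at least 1")
    base = base_config or SynthConfig()
    children = np.random.SeedSequence(seed).spawn(n)
    dataset = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        is_afib = i < n_afib
        if is_afib:
            cfg = afib_base if afib_base is not None else afib_config()
        else:
            cfg = base if base.rhythm is Rhythm.NORMAL else SynthConfig()
        jitter = {
            name: getattr(cfg, name) * (1.0 + rng.uniform(-0.1, 0.1))
            for name in _JITTERED
            if getattr(cfg, name) != 0
        }
        if "rr_mean" in jitter:
            jitter["rr_mean"] = float(np.clip(jitter["rr_mean"], 0.3, 2.0))
        cfg = replace(cfg, **jitter, seed=int(rng.integers(2**31)), duration=base.duration, fs=base.fs)
        label = "afib" if is_afib else "normal"
        dataset.append(synth_record(cfg, record_id=f"{label}_{i:04d}"))
    return dataset


def pre_r_windows(
    r_times: np.ndarray | Tuple[float, ...],
    duration: float,
    p_offset: float = -0.16,
    p_width: float = 0.05,
) -> List[Tuple[float, float]]:
    """Fixed-width windows where P-waves would sit, one per R-peak.

    For AFib records (no P-waves) these are the matched comparison windows
    used by energy-contrast and Grad-CAM overlap checks.
    """
    windows = []
    for r in np.asarray(r_times, dtype=float):
        start, end = r + p_offset - p_width, r + p_offset + p_width
        if start >= 0 and end <= duration:
            windows.append((float(start), float(end)))
    return windows
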