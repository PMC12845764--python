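"""Synthetic three-class hive-audio fixtures.

Real beehive recordings concentrate almost all acoustic energy below
2 kHz, and the two bee classes differ in their harmonic structure and
slow amplitude modulation, while no-bee recordings are broadband noise
without spectral lines.  The generator here emulates exactly those
properties so the whole pipeline is exercisable without any external
dataset: it is *not* a physical bee-sound model (see docs/methods.md).

Each clip is deterministic given ``(label, config, seed, clip_index)``;
per-clip RNG streams are derived by seed-sequence spawning so parallel
generation cannot reorder randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from .containers import EVENT_CLASSES, SegmentSet, Waveform
from .preprocess import PreprocessConfig, preprocess_waveform, write_wav


@dataclass
class FixtureConfig:
    """Acoustic parameters of the synthetic classes.

    Fundamentals, AM rates and SNR are design choices of the fixture,
    selected so that MFCC features separate the three classes the way
    the real hive classes do.  Harmonics are capped below ``band_limit``
    so that bee-class clips keep >= 95 % of their spectral energy below
    2 kHz.
    """

    rate: int = 32000
    duration: float = 10.0
    fundamentals: Mapping[str, float] = field(
        default_factory=lambda: {"QueenPresent": 250.0, "QueenAbsent": 330.0}
    )
    n_harmonics: int = 7
    harmonic_decay: float = 0.7
    am_rates: Mapping[str, float] = field(
        default_factory=lambda: {"QueenPresent": 4.0, "QueenAbsent": 9.0}
    )
    am_depth: float = 0.5
    noise_snr_db: float = 10.0
    band_limit: float = 2000.0
    nobee_cutoff: float = 4000.0
    # per-clip natural variability (real hives differ clip to clip;
    # without it every clip is acoustically identical and the feature
    # distributions downstream collapse to points)
    f0_jitter: float = 0.04        # fractional fundamental jitter
    decay_jitter: float = 0.05     # absolute jitter on harmonic_decay
    snr_jitter_db: float = 3.0     # SNR jitter, dB
    am_rate_jitter: float = 0.2    # fractional AM-rate jitter

    def __post_init__(self) -> None:
        if self.duration <= 1.0:
            raise ValueError("fixture clips must be longer than 1 s")
        for label, f0 in self.fundamentals.items():
            if f0 >= self.band_limit:
                raise ValueError(f"fundamental for {label} exceeds the band limit")


def _clip_rng(seed: int, label: str, clip_index: int) -> np.random.Generator:
    class_id = (EVENT_CLASSES.index(label) if label in EVENT_CLASSES else len(EVENT_CLASSES))
    return np.random.default_rng(np.random.SeedSequence([int(seed), class_id, int(clip_index)]))


def gen_clip(label: str, cfg: FixtureConfig | None = None, seed: int = 0,
             clip_index: int = 0) -> Waveform:
    """One synthetic clip of ``cfg.duration`` seconds at ``cfg.rate``.

    Bee classes are a decaying harmonic stack under a slow AM envelope
    plus band-limited noise at ``noise_snr_db``; NoBee is low-pass
    shaped noise with no line structure.  Peak-normalized to 0.9.
    """
    cfg = cfg or FixtureConfig()
    if label not in EVENT_CLASSES:
        raise ValueError(f"unknown event label {label!r}")
    rng = _clip_rng(seed, label, clip_index)
    n = int(round(cfg.duration * cfg.rate))
    t = np.arange(n) / cfg.rate

    if label == "NoBee":
        sos = butter(2, cfg.nobee_cutoff, btype="lowpass", fs=cfg.rate, output="sos")
        x = sosfilt(sos, rng.standard_normal(n))
    else:
        f0 = cfg.fundamentals[label] * (1.0 + cfg.f0_jitter * rng.uniform(-1, 1))
        decay = np.clip(cfg.harmonic_decay + cfg.decay_jitter * rng.uniform(-1, 1), 0.1, 0.95)
        am_rate = cfg.am_rates[label] * (1.0 + cfg.am_rate_jitter * rng.uniform(-1, 1))
        snr_db = cfg.noise_snr_db + cfg.snr_jitter_db * rng.uniform(-1, 1)
        x = np.zeros(n)
        for k in range(1, cfg.n_harmonics + 1):
            fk = k * f0
            if fk >= cfg.band_limit:
                break
            phase = rng.uniform(0, 2 * np.pi)
            x += decay ** (k - 1) * np.sin(2 * np.pi * fk * t + phase)
        am = 1.0 + cfg.am_depth * np.sin(2 * np.pi * am_rate * t + rng.uniform(0, 2 * np.pi))
        x *= am
        # additive noise, low-passed at the band limit, scaled to the SNR
        sos = butter(6, cfg.band_limit, btype="lowpass", fs=cfg.rate, output="sos")
        noise = sosfilt(sos, rng.standard_normal(n))
        sig_p = np.mean(x**2)
        noise_p = np.mean(noise**2)
        if noise_p > 0:
            x += noise * np.sqrt(sig_p / noise_p * 10.0 ** (-snr_db / 10.0))

    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.9 / peak
    return Waveform(x, cfg.rate, source_id=f"fixture-{label}-{clip_index}", label=label)


def _counts_from_ratio(total: int, ratios: Sequence[float]) -> list[int]:
    """Integer class counts approximating ``ratios`` that sum to ``total``."""
    weights = np.asarray(ratios, dtype=float)
    weights = weights / weights.sum()
    raw = weights * total
    counts = np.floor(raw).astype(int)
    # hand out the remainder by largest fractional part
    for i in np.argsort(raw - counts)[::-1][: total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def gen_dataset(
    n_per_class: int | None = None,
    cfg: FixtureConfig | None = None,
    seed: int = 0,
    preprocess: PreprocessConfig | None = None,
    ratios: Sequence[float] | None = None,
    total_clips: int | None = None,
    classes: Sequence[str] = EVENT_CLASSES,
) -> SegmentSet:
    """Generate fixture clips and run them through the preprocessing pipeline.

    Either ``n_per_class`` (balanced) or ``ratios`` with ``total_clips``
    (e.g. 40:20:40) selects the per-class clip counts.  Returns one
    standardized :class:`SegmentSet`.
    """
    cfg = cfg or FixtureConfig()
    preprocess = preprocess or PreprocessConfig()
    if ratios is not None:
        if total_clips is None:
            raise ValueError("ratios require total_clips")
        counts = _counts_from_ratio(total_clips, ratios)
    else:
        if n_per_class is None or n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        counts = [n_per_class] * len(classes)
    pieces = []
    for label, count in zip(classes, counts):
        for i in range(count):
            w = gen_clip(label, cfg, seed=seed, clip_index=i)
            pieces.append(preprocess_waveform(w, preprocess))
    return SegmentSet.concatenate(pieces)


def write_fixture_dir(out_dir, n_per_class: int, cfg: FixtureConfig | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Write fixture WAVs plus a labels CSV; returns the label table."""
    cfg = cfg or FixtureConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for label in EVENT_CLASSES:
        for i in range(n_per_class):
            w = gen_clip(label, cfg, seed=seed, clip_index=i)
            name = f"{label}_{i:04d}.wav"
            write_wav(out_dir / name, w)
            rows.append({"file": name, "label": label})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "labels.csv", index=False)
    return table
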