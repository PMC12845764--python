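"""Acoustic feature maps and the Gaussian prior of the refinement chain.

Two feature spaces are used downstream:

* the *refinement* vector θ fed to the Metropolis-Hastings stage — a
  22-dimensional summary of amplitude variation, spectral energy
  distribution, and short-term temporal structure (16 log-spaced band
  energies over the hive band plus six envelope/spectral statistics);
* a 20-coefficient MFCC vector per 1-s segment for the LDA-SVM
  reference classifier (frame-level MFCCs averaged over frames).

The Gaussian prior p(.) is a diagonal Gaussian fitted by moments with a
variance floor; only density *ratios* enter the acceptance rule, so the
normalization constant never matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import SegmentSet, Waveform

LOG_ENERGY_FLOOR_DB = -80.0
VARIANCE_FLOOR = 1e-6


@dataclass
class FeatureConfig:
    """Geometry of both feature maps.

    ``n_bands`` log-spaced band-energy bins span ``[band_low, band_high]``
    Hz; frame statistics use ``frame_len``/``hop``; ``mfcc_n`` MFCC
    coefficients (including the 0th) represent each segment for the
    classifier; ``n_mels`` mel filters feed the cepstral transform.
    """

    n_bands: int = 16
    band_low: float = 20.0
    band_high: float = 2000.0
    frame_len: int = 1024
    hop: int = 512
    mfcc_n: int = 20
    n_mels: int = 26

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if self.mfcc_n < 1:
            raise ValueError("mfcc_n must be >= 1")
        if self.mfcc_n > self.n_mels:
            raise ValueError("mfcc_n cannot exceed n_mels")

    @property
    def dim(self) -> int:
        """Dimension of the refinement feature vector."""
        return self.n_bands + 6


def desk_feature_config() -> FeatureConfig:
    """Feature geometry matching the 1024 Hz desk pipeline rate."""
    return FeatureConfig(band_high=480.0, frame_len=256, hop=128)


def _frames(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    """(n_frames, frame) view of x; short tail frame dropped."""
    n = (len(x) - frame) // hop + 1
    if n < 1:
        return x[np.newaxis, :] if len(x) else np.zeros((1, frame))
    idx = np.arange(frame)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def _spectral_centroids(x: np.ndarray, rate: float, frame: int, hop: int) -> np.ndarray:
    """Per-frame amplitude-weighted mean frequency; silent frame -> 0."""
    fr = _frames(x, frame, hop)
    mag = np.abs(rfft(fr * np.hanning(fr.shape[1]), axis=1))
    freqs = np.fft.rfftfreq(fr.shape[1], d=1.0 / rate)
    denom = mag.sum(axis=1)
    cent = np.zeros(len(fr))
    ok = denom > 0
    cent[ok] = (mag[ok] * freqs).sum(axis=1) / denom[ok]
    return cent


def extract_refinement_features(w: Waveform, cfg: FeatureConfig | None = None) -> np.ndarray:
    """The 22-dim refinement vector θ for one standardized segment.

    Coordinates: ``n_bands`` log band energies in dB (floored at -80),
    frame-RMS mean and std, spectral-centroid mean and std,
    zero-crossing rate, and the normalized autocorrelation peak at lags
    of 2-50 ms.  Deterministic; log energies shift by +6.02 dB when the
    signal is doubled while centroid coordinates are scale-invariant.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(w.samples, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("refinement features require a mono segment")
    rate = w.rate

    # --- spectral energy distribution: log-spaced band energies
    spec = np.abs(rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate)
    edges = np.geomspace(cfg.band_low, cfg.band_high, cfg.n_bands + 1)
    band_db = np.full(cfg.n_bands, LOG_ENERGY_FLOOR_DB)
    for i in range(cfg.n_bands):
        mask = (freqs >= edges[i]) & (freqs < edges[i + 1])
        e = spec[mask].sum()
        if e > 0:
            band_db[i] = max(10.0 * np.log10(e), LOG_ENERGY_FLOOR_DB)

    # --- amplitude variation: frame RMS statistics
    fr = _frames(x, cfg.frame_len, cfg.hop)
    rms = np.sqrt((fr**2).mean(axis=1))
    rms_mean, rms_std = rms.mean(), rms.std()

    # --- spectral centroid statistics
    cent = _spectral_centroids(x, rate, cfg.frame_len, cfg.hop)
    cent_mean, cent_std = cent.mean(), cent.std()

    # --- short-term temporal structure
    zcr = np.mean(np.abs(np.diff(np.signbit(x)))) if len(x) > 1 else 0.0
    lo, hi = int(0.002 * rate), int(0.050 * rate)
    ac_peak = 0.0
    if len(x) > hi and np.any(x):
        # autocorrelation via FFT, normalized by lag-0
        nfft = int(2 ** np.ceil(np.log2(2 * len(x))))
        ps = np.abs(np.fft.rfft(x, nfft)) ** 2
        ac = np.fft.irfft(ps)[: hi + 1]
        if ac[0] > 0:
            ac_peak = float(np.max(ac[lo : hi + 1]) / ac[0])

    return np.concatenate(
        [band_db, [rms_mean, rms_std, cent_mean, cent_std, zcr, ac_peak]]
    )


# ---------------------------------------------------------------------------
# MFCC


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, nfft: int, rate: float) -> np.ndarray:
    """Triangular mel filters over [0, rate/2], shape (n_mels, nfft//2+1)."""
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(rate / 2.0), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((nfft + 1) * hz_pts / rate).astype(int)
    fb = np.zeros((n_mels, nfft // 2 + 1))
    for m in range(1, n_mels + 1):
        left, center, right = bins[m - 1], bins[m], bins[m + 1]
        if center == left:
            center += 1
        if right == center:
            right += 1
        fb[m - 1, left:center] = (np.arange(left, center) - left) / (center - left)
        fb[m - 1, center:right] = (right - np.arange(center, right)) / (right - center)
    return fb


def extract_mfcc(w: Waveform, cfg: FeatureConfig | None = None) -> np.ndarray:
    """One ``mfcc_n``-vector per segment: frame MFCCs averaged over frames."""
    cfg = cfg or FeatureConfig()
    x = np.asarray(w.samples, dtype=np.float64)
    fr = _frames(x, cfg.frame_len, cfg.hop)
    window = np.hanning(fr.shape[1])
    power = np.abs(rfft(fr * window, axis=1)) ** 2
    fb = mel_filterbank(cfg.n_mels, fr.shape[1], w.rate)
    mel_energy = power @ fb.T
    log_mel = np.log(np.maximum(mel_energy, 1e-10))
    cepstra = dct(log_mel, type=2, axis=1, norm="ortho")[:, : cfg.mfcc_n]
    return cepstra.mean(axis=0)


def mfcc_matrix(segments: SegmentSet, cfg: FeatureConfig | None = None) -> np.ndarray:
    """(n_segments, mfcc_n) MFCC matrix for a whole set."""
    cfg = cfg or FeatureConfig()
    return np.stack([extract_mfcc(segments.waveform(i), cfg) for i in range(len(segments))])


def refinement_matrix(segments: SegmentSet, cfg: FeatureConfig | None = None) -> np.ndarray:
    """(n_segments, dim) refinement-feature matrix for a whole set."""
    cfg = cfg or FeatureConfig()
    return np.stack(
        [extract_refinement_features(segments.waveform(i), cfg) for i in range(len(segments))]
    )


# ---------------------------------------------------------------------------
# Gaussian prior


class GaussianPrior:
    """Diagonal Gaussian density p(.) over feature-space vectors.

    Fitted by sample moments (population variance), with every variance
    floored at 1e-6 so the density is strictly positive everywhere even
    when a coordinate is degenerate in the fitting sample.
    """

    def __init__(self, mean: np.ndarray, var: np.ndarray, fitted_on: int = 0):
        self.mean_ = np.asarray(mean, dtype=np.float64)
        self.var_ = np.maximum(np.asarray(var, dtype=np.float64), VARIANCE_FLOOR)
        self.fitted_on_ = int(fitted_on)
        if self.mean_.shape != self.var_.shape:
            raise ValueError("mean and variance must have the same shape")

    @property
    def dim(self) -> int:
        return self.mean_.shape[0]

    def logpdf(self, x: np.ndarray) -> float:
        """Log density (including the normalization constant)."""
        x = np.asarray(x, dtype=np.float64)
        if not np.all(np.isfinite(x)):
            raise ValueError("logpdf input must be finite")
        z = (x - self.mean_) ** 2 / self.var_
        return float(-0.5 * (z.sum() + np.log(2 * np.pi * self.var_).sum()))


def fit_gaussian_prior(vectors: np.ndarray) -> GaussianPrior:
    """Moment fit of the diagonal Gaussian prior from >= 2 feature vectors."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=np.float64))
    if vectors.shape[0] < 2:
        raise ValueError("fitting the prior requires at least 2 vectors")
    mean = vectors.mean(axis=0)
    var = vectors.var(axis=0)  # population convention
    return GaussianPrior(mean, var, fitted_on=vectors.shape[0])


# ---------------------------------------------------------------------------
# sklearn-style transformer fronts


class MfccExtractor(BaseEstimator, TransformerMixin):
    """Transformer: (n, segment_len) waveform array -> (n, mfcc_n) MFCCs."""

    def __init__(self, rate: float = 16384.0, config: FeatureConfig | None = None):
        self.rate = rate
        self.config = config

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        cfg = self.config or FeatureConfig()
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return np.stack([extract_mfcc(Waveform(x, self.rate), cfg) for x in X])


class RefinementFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer: (n, segment_len) waveform array -> (n, dim) θ vectors."""

    def __init__(self, rate: float = 16384.0, config: FeatureConfig | None = None):
        self.rate = rate
        self.config = config

    def fit(self, X, y=None):
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        cfg = self.config or FeatureConfig()
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return np.stack(
            [extract_refinement_features(Waveform(x, self.rate), cfg) for x in X]
        )
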