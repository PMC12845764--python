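"""Core in-memory containers: waveforms and labeled segment sets.

A :class:`Waveform` is a sampled audio signal (mono ``(n,)`` or
channel-major ``(channels, n)``) with its sampling rate, an opaque
source identifier, and an optional event label.  A :class:`SegmentSet`
is the standardized product of preprocessing: a dense ``(n, L)`` array
of equal-length 1-s clips with parallel label / provenance arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: The three hive-event classes plus the tag attached to generated audio.
EVENT_CLASSES = ("QueenPresent", "QueenAbsent", "NoBee")
SYNTHETIC_LABEL = "synthetic"

_VALID_LABELS = frozenset(EVENT_CLASSES) | {SYNTHETIC_LABEL}


@dataclass
class Waveform:
    """A sampled audio signal.

    Parameters
    ----------
    samples : ndarray
        Amplitudes, nominally in ``[-1, 1]``.  Shape ``(n,)`` for mono or
        ``(channels, n)`` for multi-channel audio.
    rate : float
        Sampling rate in Hz; must be positive.
    source_id : str
        Opaque provenance string (typically the originating file name).
    label : str or None
        Event label, one of ``EVENT_CLASSES`` or ``"synthetic"``.
    """

    samples: np.ndarray
    rate: float
    source_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.ndim not in (1, 2):
            raise ValueError(
                f"samples must be 1-D (mono) or 2-D (channels, n), got shape {self.samples.shape}"
            )
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.label is not None and self.label not in _VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {sorted(_VALID_LABELS)}")

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[-1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.rate

    def with_samples(self, samples: np.ndarray, rate: float | None = None) -> "Waveform":
        """Copy of this waveform with new sample data (provenance kept)."""
        return replace(self, samples=samples, rate=self.rate if rate is None else rate)


@dataclass
class SegmentSet:
    """A collection of fixed-length segments with parallel metadata.

    ``segments`` has shape ``(n, segment_len)``; ``labels``,
    ``source_ids`` and ``segment_indices`` are parallel arrays of
    length ``n``.
    """

    segments: np.ndarray
    labels: np.ndarray
    rate: float
    source_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    segment_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.segments = np.atleast_2d(np.asarray(self.segments, dtype=np.float64))
        n = self.segments.shape[0]
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (n,):
            raise ValueError(f"labels shape {self.labels.shape} does not match {n} segments")
        if self.source_ids is None:
            self.source_ids = np.asarray([""] * n, dtype=object)
        else:
            self.source_ids = np.asarray(self.source_ids, dtype=object)
        if self.segment_indices is None:
            self.segment_indices = np.arange(n)
        else:
            self.segment_indices = np.asarray(self.segment_indices, dtype=int)
        if self.source_ids.shape != (n,) or self.segment_indices.shape != (n,):
            raise ValueError("provenance arrays must parallel the segment array")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return self.segments.shape[0]

    @property
    def segment_len(self) -> int:
        return self.segments.shape[1]

    def waveform(self, i: int) -> Waveform:
        """The ``i``-th segment as a standalone :class:`Waveform`."""
        return Waveform(
            self.segments[i],
            self.rate,
            source_id=str(self.source_ids[i]),
            label=self.labels[i] if self.labels[i] in _VALID_LABELS else None,
        )

    def subset(self, idx) -> "SegmentSet":
        idx = np.asarray(idx)
        return SegmentSet(
            self.segments[idx],
            self.labels[idx],
            self.rate,
            self.source_ids[idx],
            self.segment_indices[idx],
        )

    def filter_label(self, label: str) -> "SegmentSet":
        return self.subset(np.flatnonzero(self.labels == label))

    def manifest(self) -> pd.DataFrame:
        """Per-segment manifest (source_id, segment_index, label, n_samples, rate)."""
        return pd.DataFrame(
            {
                "source_id": self.source_ids,
                "segment_index": self.segment_indices,
                "label": self.labels,
                "n_samples": self.segment_len,
                "rate": self.rate,
            }
        )

    @staticmethod
    def concatenate(sets: Sequence["SegmentSet"]) -> "SegmentSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValueError("cannot concatenate zero non-empty segment sets")
        rate = sets[0].rate
        seg_len = sets[0].segment_len
        for s in sets[1:]:
            if s.rate != rate or s.segment_len != seg_len:
                raise ValueError("segment sets differ in rate or segment length")
        return SegmentSet(
            np.concatenate([s.segments for s in sets], axis=0),
            np.concatenate([s.labels for s in sets]),
            rate,
            np.concatenate([s.source_ids for s in sets]),
            np.concatenate([s.segment_indices for s in sets]),
        )


def empty_segment_set(segment_len: int, rate: float) -> SegmentSet:
    return SegmentSet(
        np.empty((0, segment_len)), np.empty((0,), dtype=object), rate,
        np.empty((0,), dtype=object), np.empty((0,), dtype=int),
    )
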