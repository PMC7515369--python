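"""Uniformly sampled time-series container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: A regime annotation: (start time s, end time s, description).
Segment = tuple[float, float, str]


@dataclass
class Signal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    samples : ndarray
        Sample values, arbitrary units.
    fs : float
        Sampling rate in Hz; must be positive.
    label : str
        Free-text description.
    segments : list of (start, end, description), optional
        Regime annotations. When present they must tile
        ``[0, duration)`` without overlap.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    segments: list[Segment] | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.segments is not None:
            self._check_segments()

    def _check_segments(self) -> None:
        segs = sorted(self.segments, key=lambda s: s[0])
        if not segs:
            return
        if segs[0][0] != 0.0:
            raise ValueError("segments must start at t = 0")
        for (s0, e0, _), (s1, _, _) in zip(segs, segs[1:]):
            if not np.isclose(e0, s1):
                raise ValueError("segments must tile the duration without gaps or overlap")
        if not np.isclose(segs[-1][1], self.duration):
            raise ValueError("segments must cover the full duration")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds (t = k / fs)."""
        return np.arange(self.samples.size) / self.fs

    def segment_samples(self, index: int) -> np.ndarray:
        """Samples of the ``index``-th annotated regime."""
        if self.segments is None:
            raise ValueError("signal has no segment annotations")
        start, end, _ = self.segments[index]
        i0 = int(round(start * self.fs))
        i1 = int(round(end * self.fs))
        return self.samples[i0:i1]
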