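"""Fixed-length heartbeat segmentation anchored on annotated R-peaks.

Each beat window is ``length`` samples (default 200, ~0.56 s at 360 Hz),
with ``pre`` samples before the R-peak (default 99: 99 before + R + 100
after, a symmetric window covering P and T waves).  Beats whose window
would cross a record edge are dropped rather than padded — padding would
distort the wavelet coefficients downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import BeatAnnotation


@dataclass
class BeatSegment:
    """One fixed-length denoised heartbeat window."""

    samples: np.ndarray
    r_offset: int          # index of the R-peak within the window
    beat_index: int        # position in the record's annotation list
    symbol: str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not 0 <= self.r_offset < len(self.samples):
            raise ValueError("r_offset outside the segment")


def segment_beats(
    signal,
    annotations: Sequence[BeatAnnotation],
    length: int = 200,
    pre: int = 99,
) -> tuple[list[BeatSegment], int]:
    """Cut one window per annotation; report how many were dropped at edges.

    Parameters
    ----------
    signal : DenoisedSignal or array-like
    annotations : sequence of BeatAnnotation
    length, pre : int
        Window size and number of samples before the R-peak
        (``0 <= pre < length``); the window is
        ``samples[r - pre : r - pre + length]``.

    Returns
    -------
    (segments, n_dropped)
        ``segments[k].beat_index`` indexes the *original* annotation list,
        so RR-interval context stays aligned after edge drops.
    """
    if not 0 <= pre < length:
        raise ValueError("require 0 <= pre < length")
    x = np.asarray(getattr(signal, "samples", signal), dtype=float)
    post = length - pre
    segments: list[BeatSegment] = []
    dropped = 0
    for i, ann in enumerate(annotations):
        start = ann.sample_index - pre
        if start < 0 or ann.sample_index + post > len(x):
            dropped += 1
            continue
        segments.append(
            BeatSegment(x[start : start + length].copy(), r_offset=pre,
                        beat_index=i, symbol=ann.symbol)
        )
    return segments, dropped
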