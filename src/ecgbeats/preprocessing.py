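"""Baseline-wander removal.

The denoising step is expected-value subtraction: ``x[n] = x_r[n] - mu``
with ``mu`` the arithmetic mean of the record.  Subtracting a constant
preserves all waveform shape (every pairwise sample difference) and is
idempotent.  A per-window moving-average variant is available for long
records with slow drift, but constant subtraction is the default method.
No power-line notch filter is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d


@dataclass
class DenoisedSignal:
    """A zero-mean signal plus the expected value that was subtracted."""

    samples: np.ndarray
    mu: float
    source_record_id: str = ""

    def __len__(self) -> int:
        return len(self.samples)


def remove_baseline(record, window_seconds: float | None = None) -> DenoisedSignal:
    """Subtract the signal's expected value (or a moving average) from it.

    Parameters
    ----------
    record : ECGRecord, DenoisedSignal or array-like
        Anything with a ``.samples`` attribute, or a plain sample sequence.
    window_seconds : float, optional
        If given (requires a record with ``.fs``), subtract a centred
        moving average of this duration instead of the global mean.
        ``mu`` then reports the mean of the subtracted baseline estimate.

    Returns
    -------
    DenoisedSignal
        Same length as the input; annotations (if any) are untouched on
        the source record.
    """
    samples = np.asarray(getattr(record, "samples", record), dtype=float)
    if samples.ndim != 1:
        raise ValueError("expected a one-dimensional sample sequence")
    if samples.size == 0:
        raise ValueError("cannot denoise an empty signal")
    rid = getattr(record, "record_id", getattr(record, "source_record_id", ""))
    if window_seconds is not None:
        fs = getattr(record, "fs", None)
        if fs is None:
            raise ValueError("window_seconds requires a record with a sampling rate")
        size = max(int(round(window_seconds * fs)), 1)
        baseline = uniform_filter1d(samples, size=size, mode="nearest")
        return DenoisedSignal(samples - baseline, mu=float(baseline.mean()),
                              source_record_id=rid)
    mu = float(samples.mean())
    return DenoisedSignal(samples - mu, mu=mu, source_record_id=rid)
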