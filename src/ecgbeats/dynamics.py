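"""Dynamic (rhythm and nonlinear-energy) features per heartbeat.

Four RR-interval features describe the local rhythm around beat ``i``:

* ``rr_pre``   — R(i) - R(i-1)
* ``rr_post``  — R(i+1) - R(i)
* ``rr_local`` — mean of the up-to-10 intervals nearest the beat
  (5 preceding, 5 following; truncated at record edges, normalised by the
  actual count)
* ``rr_ave``   — mean RR interval over the whole record segment,
  (1/N_RR) * sum(RR)

All RR features are in seconds (annotation samples divided by fs), so
values transfer across sampling rates.  Edge beats fall back to the
nearest defined interval for ``rr_pre``/``rr_post``.

The Teager–Kaiser energy operator supplies a nonlinear energy measure of
the beat waveform: ``NE[n] = x[n]^2 - x[n-1]*x[n+1]``, and ANE is its
per-beat average with the normaliser ``N`` = total samples in the beat
(only N-2 interior NE terms exist; ``normalizer="n-2"`` switches to the
interior count).  For a sinusoid ``A*cos(Omega*n + phi)`` the operator is
constant: ``NE = A^2 * sin(Omega)^2`` — it tracks amplitude *and*
frequency, which is why it separates fast abnormal activations from slow
ones at equal amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import BeatAnnotation
from .segmentation import BeatSegment


@dataclass
class RRSequence:
    """R-peak times (seconds) and successive RR intervals of one record."""

    r_times: np.ndarray
    rr: np.ndarray

    @classmethod
    def from_annotations(cls, annotations: Sequence[BeatAnnotation], fs: float) -> "RRSequence":
        if fs <= 0:
            raise ValueError("fs must be positive")
        if len(annotations) < 2:
            raise ValueError("need at least 2 annotations to form RR intervals")
        r_times = np.asarray([a.sample_index for a in annotations], dtype=float) / fs
        return cls(r_times=r_times, rr=np.diff(r_times))

    @classmethod
    def from_times(cls, r_times: Sequence[float]) -> "RRSequence":
        r_times = np.asarray(r_times, dtype=float)
        if len(r_times) < 2:
            raise ValueError("need at least 2 R-peak times")
        rr = np.diff(r_times)
        if np.any(rr <= 0):
            raise ValueError("R-peak times must be strictly increasing")
        return cls(r_times=r_times, rr=rr)

    @property
    def n_rr(self) -> int:
        return len(self.rr)


@dataclass(frozen=True)
class DynamicFeatures:
    """The five dynamic features of one beat, in fixed order."""

    rr_pre: float
    rr_post: float
    rr_local: float
    rr_ave: float
    ane: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rr_pre, self.rr_post, self.rr_local, self.rr_ave, self.ane])


def rr_features(seq: RRSequence, i: int) -> tuple[float, float, float, float]:
    """The four RR features of beat ``i`` (index into ``seq.r_times``)."""
    n = len(seq.r_times)
    if not 0 <= i < n:
        raise IndexError(f"beat index {i} out of range for {n} beats")
    # rr[j] is the interval between beats j and j+1.
    rr_pre = seq.rr[i - 1] if i >= 1 else seq.rr[0]
    rr_post = seq.rr[i] if i < seq.n_rr else seq.rr[-1]
    local = seq.rr[max(i - 5, 0) : min(i + 5, seq.n_rr)]
    rr_local = float(local.mean())
    rr_ave = float(seq.rr.mean())
    return float(rr_pre), float(rr_post), rr_local, rr_ave


def teager_ne(x) -> np.ndarray:
    """Teager–Kaiser nonlinear energy at every interior sample.

    ``NE[n] = x[n]^2 - x[n-1]*x[n+1]`` for n = 1 .. len(x)-2; the two
    endpoints are excluded, so the output has ``len(x) - 2`` values.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-d sequence of at least 3 samples")
    return x[1:-1] ** 2 - x[:-2] * x[2:]


def teager_ane(x, normalizer: str = "n") -> float:
    """Average nonlinear energy of a beat.

    ``normalizer="n"`` divides the interior-sample NE sum by the total
    sample count N (the printed convention); ``"n-2"`` divides by the
    number of NE terms actually summed.
    """
    ne = teager_ne(x)
    if normalizer == "n":
        denom = len(ne) + 2
    elif normalizer == "n-2":
        denom = len(ne)
    else:
        raise ValueError("normalizer must be 'n' or 'n-2'")
    return float(ne.sum() / denom)


def dynamic_features(beat: BeatSegment, seq: RRSequence, normalizer: str = "n") -> DynamicFeatures:
    """Bundle the four RR features and ANE for one segmented beat."""
    pre, post, local, ave = rr_features(seq, beat.beat_index)
    return DynamicFeatures(pre, post, local, ave, teager_ane(beat.samples, normalizer))
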