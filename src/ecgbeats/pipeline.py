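"""End-to-end orchestration: records -> beats -> 17-feature vectors.

The flow is: baseline removal (mean subtraction) -> 200-sample beat
segmentation on annotated R-peaks -> level-4 dmey DWT -> per-subband ICA
(6 components each) -> concatenation with the four RR features and the
Teager average nonlinear energy, giving one 17-dimensional hybrid feature
vector per beat:

    [a4-ICA x6, d4-ICA x6, rr_pre, rr_post, rr_local, rr_ave, ane]

Wavelet coefficients and dynamic features are precomputed once per
dataset (they involve no fitting); only the ICA models — and, inside the
classifier, feature standardization — are fold-dependent and fitted on
training beats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .dynamics import RRSequence, dynamic_features
from .io import ECGRecord, resample_record
from .morphology import (
    DEFAULT_MODE,
    DEFAULT_WAVELET,
    SubbandICAReducer,
    dwt_level4,
)
from .preprocessing import remove_baseline
from .segmentation import BeatSegment, segment_beats

TARGET_FS = 360.0
FEATURE_NAMES = (
    [f"ica_a4_{i + 1}" for i in range(6)]
    + [f"ica_d4_{i + 1}" for i in range(6)]
    + ["rr_pre", "rr_post", "rr_local", "rr_ave", "ane"]
)


@dataclass
class BeatDataset:
    """Segmented beats from one or more records, with precomputed subband
    coefficient matrices and dynamic features."""

    beats: list[BeatSegment]
    symbols: np.ndarray          # (n,) class symbol per beat
    record_ids: np.ndarray       # (n,) source record per beat
    a4: np.ndarray               # (n, d_a4) level-4 approximation coefficients
    d4: np.ndarray               # (n, d_d4) level-4 detail coefficients
    dyn: np.ndarray              # (n, 5) rr_pre, rr_post, rr_local, rr_ave, ane
    fs: float
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.beats)


def build_dataset(
    records: ECGRecord | list[ECGRecord],
    length: int = 200,
    pre: int = 99,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
    target_fs: float = TARGET_FS,
    normalizer: str = "n",
) -> BeatDataset:
    """Denoise, segment and pre-featurise one or more ECG records.

    Records sampled at a different rate are polyphase-resampled to
    ``target_fs`` first so the fixed window and subband edges are
    rate-consistent.  Beats too close to a record edge are dropped and
    counted in ``n_dropped``.
    """
    if isinstance(records, ECGRecord):
        records = [records]
    if not records:
        raise ValueError("no records given")
    beats: list[BeatSegment] = []
    symbols: list[str] = []
    rec_ids: list[str] = []
    a4_rows, d4_rows, dyn_rows = [], [], []
    n_dropped = 0
    for rec in records:
        if rec.fs != target_fs:
            rec = resample_record(rec, target_fs)
        den = remove_baseline(rec)
        segs, dropped = segment_beats(den, rec.annotations, length=length, pre=pre)
        n_dropped += dropped
        if len(rec.annotations) < 2:
            n_dropped += len(segs)
            continue  # no RR context at all: beats unusable for classification
        seq = RRSequence.from_annotations(rec.annotations, rec.fs)
        for seg in segs:
            coeffs = dwt_level4(seg, wavelet, mode)
            a4_rows.append(coeffs.a4)
            d4_rows.append(coeffs.d4)
            dyn_rows.append(dynamic_features(seg, seq, normalizer).as_array())
            beats.append(seg)
            symbols.append(seg.symbol)
            rec_ids.append(rec.record_id)
    if not beats:
        raise ValueError("no usable beats after segmentation")
    return BeatDataset(
        beats=beats,
        symbols=np.array(symbols),
        record_ids=np.array(rec_ids),
        a4=np.array(a4_rows),
        d4=np.array(d4_rows),
        dyn=np.array(dyn_rows),
        fs=target_fs,
        n_dropped=n_dropped,
    )


class HybridFeatureExtractor(BaseEstimator):
    """Fit the two subband ICA models; transform beats to 17-d features.

    ``fit`` accepts the training-row indices and an optional per-beat
    ``is_test`` mask; passing any test-flagged beat raises (leakage
    guard).  ``transform`` returns the (n, 17) hybrid feature matrix for
    the requested rows.
    """

    def __init__(self, n_components: int = 6, random_state: int = 0,
                 max_iter: int = 500, tol: float = 1e-4, normalizer: str = "n"):
        self.n_components = n_components
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.normalizer = normalizer

    def fit(self, dataset: BeatDataset, y=None, indices=None, is_test=None):
        if indices is None:
            indices = np.arange(len(dataset))
        indices = np.asarray(indices, dtype=int)
        if is_test is not None:
            flags = np.asarray(is_test, dtype=bool)[indices]
            if flags.any():
                raise RuntimeError(
                    "leakage guard: feature models must be fitted on training beats only"
                )
        common = dict(n_components=self.n_components, random_state=self.random_state,
                      max_iter=self.max_iter, tol=self.tol)
        self.ica_a4_ = SubbandICAReducer(subband_tag="a4", **common).fit(dataset.a4[indices])
        self.ica_d4_ = SubbandICAReducer(subband_tag="d4", **common).fit(dataset.d4[indices])
        return self

    def transform(self, dataset: BeatDataset, indices=None) -> np.ndarray:
        if indices is None:
            indices = np.arange(len(dataset))
        indices = np.asarray(indices, dtype=int)
        morph = np.hstack(
            [self.ica_a4_.transform(dataset.a4[indices]),
             self.ica_d4_.transform(dataset.d4[indices])]
        )
        return np.hstack([morph, dataset.dyn[indices]])


def extract_features(
    records,
    n_components: int = 6,
    seed: int = 0,
    length: int = 200,
    pre: int = 99,
    normalizer: str = "n",
) -> tuple[np.ndarray, np.ndarray, HybridFeatureExtractor, BeatDataset]:
    """Whole-dataset convenience: build the dataset, fit ICA on *all* beats
    and return ``(X, labels, extractor, dataset)``.

    Intended for exploration and the CLI ``extract`` command; the
    evaluation protocols refit ICA per training fold instead.
    """
    dataset = build_dataset(records, length=length, pre=pre, normalizer=normalizer)
    extractor = HybridFeatureExtractor(n_components=n_components, random_state=seed)
    extractor.fit(dataset)
    return extractor.transform(dataset), dataset.symbols.copy(), extractor, dataset
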