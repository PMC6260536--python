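"""Morphological features: level-4 DWT subbands reduced by ICA.

Each 200-sample beat is decomposed with a 4-level dyadic discrete wavelet
transform using the FIR approximation of the discrete Meyer wavelet
(PyWavelets ``"dmey"``); only the level-4 approximation (a4) and level-4
detail (d4) coefficient vectors are kept.  At 360 Hz the a4 subband spans
0–11.25 Hz (fs/32) and d4 spans 11.25–22.5 Hz (fs/32 .. fs/16), i.e. the
band that carries most QRS morphology.  Boundary handling is symmetric
(half-point) extension, so coefficient lengths are constant across beats
of equal length (69 per subband for 200-sample beats with the 62-tap dmey
filter).

Each subband's coefficient matrix is then reduced to 6 independent
components (FastICA, logcosh contrast, seeded), giving 12 morphological
features per beat.  Components are ordered by descending |excess
kurtosis| of their training-set source estimates — the most non-Gaussian
directions first, ICA's natural notion of a "major" component.  ICA
models are fitted on training-fold beats only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pywt
from scipy.stats import kurtosis
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.utils.validation import check_is_fitted

from .segmentation import BeatSegment

DEFAULT_WAVELET = "dmey"
DEFAULT_MODE = "symmetric"
DWT_LEVEL = 4


def subband_edges(fs: float, level: int = DWT_LEVEL) -> tuple[float, float]:
    """(upper edge of a<level>, upper edge of d<level>) in Hz: fs/2^(L+1), fs/2^L."""
    return fs / 2 ** (level + 1), fs / 2 ** level


@dataclass
class SubbandCoefficients:
    """Level-4 approximation and detail coefficient vectors of one beat."""

    a4: np.ndarray
    d4: np.ndarray


def dwt_level4(
    beat,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> SubbandCoefficients:
    """4-level DWT of a beat; keep (a4, d4), discard detail levels 1-3."""
    x = np.asarray(getattr(beat, "samples", beat), dtype=float)
    if x.ndim != 1 or len(x) < 16:
        raise ValueError("beat must be a 1-d sequence of at least 16 samples")
    with warnings.catch_warnings():
        # pywt warns when level exceeds dwt_max_level for a long filter; the
        # decomposition is still exact/invertible, which is what matters here.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, wavelet, mode=mode, level=DWT_LEVEL)
    a4, d4 = coeffs[0], coeffs[1]
    return SubbandCoefficients(a4=a4, d4=d4)


def coefficient_matrix(
    beats: Sequence[BeatSegment],
    subband: str,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> np.ndarray:
    """Stack one subband ('a4' or 'd4') over beats into a (n_beats, d) matrix."""
    if subband not in ("a4", "d4"):
        raise ValueError("subband must be 'a4' or 'd4'")
    return np.array(
        [getattr(dwt_level4(b, wavelet, mode), subband) for b in beats]
    )


class SubbandICAReducer(BaseEstimator, TransformerMixin):
    """Per-subband ICA dimensionality reduction (center -> whiten -> unmix).

    Parameters
    ----------
    n_components : int
        Independent components retained (default 6).
    random_state : int
        Seed for the FastICA fixed-point iteration; fixed seed implies an
        identical fitted model for identical training data.
    max_iter, tol : FastICA stopping controls (negentropy maximisation
        with the logcosh contrast).
    subband_tag : 'a4' | 'd4', bookkeeping only.

    Attributes
    ----------
    ica_ : fitted ``sklearn.decomposition.FastICA``
    order_ : component permutation, descending |excess kurtosis| of the
        training source estimates.
    mean_ : per-coefficient training mean (centering vector).
    components_ : (n_components, d) combined unmix@whiten map, in
        ``order_``; ``transform(X) = (X - mean_) @ components_.T``.
    """

    def __init__(
        self,
        n_components: int = 6,
        random_state: int = 0,
        max_iter: int = 500,
        tol: float = 1e-4,
        subband_tag: str = "a4",
    ):
        self.n_components = n_components
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.subband_tag = subband_tag

    def fit(self, X, y=None, is_test=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a (n_beats, d) coefficient matrix")
        if is_test is not None and np.any(np.asarray(is_test, dtype=bool)):
            raise RuntimeError(
                "leakage guard: ICA must be fitted on training-fold beats only"
            )
        n, d = X.shape
        if n < self.n_components:
            raise ValueError(
                f"need at least {self.n_components} beats to fit ICA, got {n}"
            )
        if n < 10 * self.n_components:
            warnings.warn(
                f"fitting {self.n_components}-component ICA on only {n} beats",
                UserWarning, stacklevel=2,
            )
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        if rank < self.n_components:
            raise ValueError(
                f"coefficient matrix rank {rank} < n_components={self.n_components}"
            )
        ica = FastICA(
            n_components=self.n_components,
            fun="logcosh",
            whiten="unit-variance",
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # convergence warnings
            sources = ica.fit_transform(X)
        self.ica_ = ica
        # "major" components first: rank by non-Gaussianity of the sources
        self.order_ = np.argsort(-np.abs(kurtosis(sources, axis=0)))
        self.mean_ = ica.mean_
        self.components_ = ica.components_[self.order_]
        self.n_features_in_ = d
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} coefficients, got {X.shape[1]}"
            )
        return (X - self.mean_) @ self.components_.T

    # persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Serialize the fitted model (versioned .npz schema)."""
        check_is_fitted(self, "components_")
        np.savez(
            path,
            schema_version=np.array([1]),
            subband_tag=np.array([self.subband_tag]),
            n_components=np.array([self.n_components]),
            random_state=np.array([self.random_state]),
            mean=self.mean_,
            components=self.components_,
            order=self.order_,
        )

    @classmethod
    def load(cls, path) -> "SubbandICAReducer":
        with np.load(path, allow_pickle=False) as z:
            if int(z["schema_version"][0]) != 1:
                raise ValueError("unsupported ICA model schema version")
            model = cls(
                n_components=int(z["n_components"][0]),
                random_state=int(z["random_state"][0]),
                subband_tag=str(z["subband_tag"][0]),
            )
            model.mean_ = z["mean"]
            model.components_ = z["components"]
            model.order_ = z["order"]
            model.n_features_in_ = model.mean_.shape[0]
        return model


def fit_ica(
    coeff_matrix, n_components: int = 6, seed: int = 0, subband_tag: str = "a4",
    is_test=None,
) -> SubbandICAReducer:
    """Fit a per-subband ICA reduction model on a training coefficient matrix."""
    return SubbandICAReducer(
        n_components=n_components, random_state=seed, subband_tag=subband_tag
    ).fit(coeff_matrix, is_test=is_test)


def project_ica(model: SubbandICAReducer, coeffs) -> np.ndarray:
    """Project coefficient vector(s) through a fitted model -> 6 features each."""
    out = model.transform(coeffs)
    return out[0] if np.asarray(coeffs).ndim == 1 else out


def morphological_features(
    beats: Sequence[BeatSegment],
    model_a4: SubbandICAReducer,
    model_d4: SubbandICAReducer,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> np.ndarray:
    """(n_beats, 12) matrix: 6 a4-ICA features then 6 d4-ICA features."""
    A = coefficient_matrix(beats, "a4", wavelet, mode)
    D = coefficient_matrix(beats, "d4", wavelet, mode)
    return np.hstack([model_a4.transform(A), model_d4.transform(D)])
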