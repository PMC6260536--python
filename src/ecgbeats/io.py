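"""Reading and writing ECG records and beat annotations.

The on-disk layout follows the PhysioNet WFDB convention: a text header
(``<record>.hea``), a binary signal file (``<record>.dat``, format 16 or
212) and a beat annotation stream.  Annotations are read either from a
plain-text CSV sidecar (``<record>.ann.csv`` with columns
``sample_index,symbol`` — the format the synthetic writer emits) or, if
that is absent, from a standard MIT ``<record>.atr`` file.

Only single-channel extraction is supported; sample indices are 0-based
throughout.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

#: The 18 beat-class symbols of the class-oriented taxonomy.  The isolated
#: QRS-like artifact (printed as an em-dash in some sources) is stored under
#: its WFDB symbol '|'.
BEAT_SYMBOLS: frozenset[str] = frozenset(
    ["N", "A", "F", "L", "Q", "V", "R", "!", "e", "f", "J", "|", "a", "E", "j", "x", "/", "S"]
)

#: Human-readable names, one per symbol (documentation / report labels).
SYMBOL_NAMES: dict[str, str] = {
    "N": "normal beat (NOR)",
    "A": "atrial premature contraction (APC)",
    "F": "fusion of ventricular and normal beat (FVN)",
    "L": "left bundle branch block (LBBB)",
    "Q": "unclassifiable beat (UN)",
    "V": "premature ventricular contraction (PVC)",
    "R": "right bundle branch block (RBBB)",
    "!": "ventricular flutter wave (VF)",
    "e": "atrial escape beat (AE)",
    "f": "fusion of paced and normal beat (FPN)",
    "J": "nodal (junctional) premature beat (NP)",
    "|": "isolated QRS-like artifact",
    "a": "aberrated atrial premature beat (AP)",
    "E": "ventricular escape beat (VE)",
    "j": "nodal (junctional) escape beat (NE)",
    "x": "nonconducted P-wave (blocked APB)",
    "/": "paced beat (PACE)",
    "S": "supraventricular premature beat (SP)",
}

# MIT annotation-code -> symbol, restricted to codes that can denote beats.
_ATR_CODE_TO_SYMBOL: dict[int, str] = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A", 9: "S",
    10: "E", 11: "j", 12: "/", 13: "Q", 16: "|", 31: "!", 34: "e", 37: "x", 38: "f",
}


class FormatError(ValueError):
    """Raised when a record's on-disk representation is malformed."""


@dataclass(frozen=True)
class BeatAnnotation:
    """One annotated heartbeat: R-peak sample index plus class symbol."""

    sample_index: int
    symbol: str

    def __post_init__(self) -> None:
        if self.symbol not in BEAT_SYMBOLS:
            raise ValueError(f"unknown beat symbol {self.symbol!r}")
        if self.sample_index < 0:
            raise ValueError("sample_index must be non-negative")


@dataclass
class ECGRecord:
    """A sampled single-lead ECG signal with beat annotations.

    Attributes
    ----------
    record_id : str
        Name of the record (file stem on disk).
    samples : ndarray
        Raw signal values ``x_r[n]`` (units arbitrary, typically mV).
    fs : float
        Sampling frequency in Hz.
    annotations : list of BeatAnnotation
        Strictly increasing by sample index; every index in ``[0, len)``.
    """

    record_id: str
    samples: np.ndarray
    fs: float
    annotations: list[BeatAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        idx = [a.sample_index for a in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotations must be strictly increasing by sample index")
        if idx and (idx[0] < 0 or idx[-1] >= len(self.samples)):
            raise ValueError("annotation index outside the record")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def symbols(self) -> list[str]:
        return [a.symbol for a in self.annotations]


# ---------------------------------------------------------------------------
# writing


def write_record(record: ECGRecord, directory: str | os.PathLike, gain: float = 8000.0) -> str:
    """Write *record* as a WFDB-compatible triple plus a CSV annotation dump.

    Emits ``<id>.hea`` (text header), ``<id>.dat`` (format 16, little-endian
    int16, ``adc = round(gain * physical)``) and ``<id>.ann.csv``.  Returns
    the record path stem.  Values outside the int16 range are clipped.
    """
    os.makedirs(directory, exist_ok=True)
    stem = os.path.join(os.fspath(directory), record.record_id)
    adc = np.clip(np.rint(record.samples * gain), -32768, 32767).astype("<i2")
    fs_txt = f"{record.fs:g}"
    first = int(adc[0]) if len(adc) else 0
    with open(stem + ".hea", "w") as fh:
        fh.write(f"{record.record_id} 1 {fs_txt} {len(adc)}\n")
        fh.write(f"{record.record_id}.dat 16 {gain:g}(0)/mV 16 0 {first} 0 0 ECG\n")
    adc.tofile(stem + ".dat")
    pd.DataFrame(
        {"sample_index": [a.sample_index for a in record.annotations],
         "symbol": [a.symbol for a in record.annotations]}
    ).to_csv(stem + ".ann.csv", index=False)
    return stem


# ---------------------------------------------------------------------------
# reading


def _parse_header(path: str) -> tuple[str, int, float, int, list[dict]]:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise FormatError(f"empty header {path}")
    head = lines[0].split()
    if len(head) < 3:
        raise FormatError(f"malformed header line {lines[0]!r}")
    name = head[0].split("/")[0]
    try:
        n_sig = int(head[1])
        fs = float(head[2].split("/")[0])
        n_samp = int(head[3]) if len(head) > 3 else 0
    except ValueError as exc:
        raise FormatError(f"malformed header line {lines[0]!r}") from exc
    sigs = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        if len(parts) < 2:
            raise FormatError(f"malformed signal line {ln!r}")
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_txt = gain_field.split("/")[0]
        baseline = 0
        if "(" in gain_txt:
            gain_txt, base_txt = gain_txt.split("(")
            baseline = int(base_txt.rstrip(")"))
        gain = float(gain_txt) if gain_txt else 200.0
        if gain == 0:
            gain = 200.0
        adc_zero = int(parts[4]) if len(parts) > 4 else 0
        sigs.append({"file": parts[0], "fmt": fmt, "gain": gain,
                     "baseline": baseline if "(" in gain_field else adc_zero})
    return name, n_sig, fs, n_samp, sigs


def _read_dat(path: str, fmt: int, n_sig: int) -> np.ndarray:
    """Return an (n_frames, n_sig) integer matrix from a .dat file."""
    raw = np.fromfile(path, dtype=np.uint8)
    if fmt == 16:
        data = raw.view("<i2").astype(np.int32)
        n = len(data) // n_sig
        return data[: n * n_sig].reshape(n, n_sig)
    if fmt == 212:
        n_trip = len(raw) // 3
        b = raw[: n_trip * 3].reshape(n_trip, 3).astype(np.int32)
        s0 = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
        s1 = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
        out = np.empty(2 * n_trip, dtype=np.int32)
        out[0::2], out[1::2] = s0, s1
        out[out > 2047] -= 4096
        n = len(out) // n_sig
        return out[: n * n_sig].reshape(n, n_sig)
    raise FormatError(f"unsupported signal format {fmt}")


def read_atr(path: str) -> tuple[list[BeatAnnotation], int]:
    """Decode a MIT-format annotation file.

    Returns ``(beats, n_dropped)`` where dropped entries are annotation codes
    outside the 18-symbol beat set (rhythm markers, noise labels, ...).
    """
    words = np.fromfile(path, dtype="<u2")
    beats: list[BeatAnnotation] = []
    dropped = 0
    t = 0
    i = 0
    while i < len(words):
        w = int(words[i])
        code, data = w >> 10, w & 0x3FF
        if code == 0 and data == 0:  # EOF
            break
        if code == 59:  # SKIP: 4-byte interval, high word first
            if i + 2 >= len(words):
                break
            t += int(np.int32((int(words[i + 1]) << 16) | int(words[i + 2])))
            i += 3
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            i += 1
            continue
        if code == 63:  # AUX: data = byte count, padded to even
            i += 1 + (data + 1) // 2
            continue
        t += data
        sym = _ATR_CODE_TO_SYMBOL.get(code)
        if sym is None:
            dropped += 1
        else:
            beats.append(BeatAnnotation(t, sym))
        i += 1
    return beats, dropped


def _read_ann_csv(path: str) -> tuple[list[BeatAnnotation], int]:
    df = pd.read_csv(path, dtype={"symbol": str})
    beats, dropped = [], 0
    for s, sym in zip(df["sample_index"], df["symbol"]):
        if sym in BEAT_SYMBOLS:
            beats.append(BeatAnnotation(int(s), sym))
        else:
            dropped += 1
    return beats, dropped


def read_record(path: str | os.PathLike, channel: int = 0) -> ECGRecord:
    """Read a WFDB-style record (header + signal + annotations).

    Parameters
    ----------
    path : str
        Record path stem (with or without the ``.hea`` extension).
    channel : int
        Signal channel to extract; default 0 (MLII in most MITDB records).
    """
    stem = os.fspath(path)
    if stem.endswith(".hea"):
        stem = stem[:-4]
    hea = stem + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(hea)
    name, n_sig, fs, n_samp, sigs = _parse_header(hea)
    if not 0 <= channel < n_sig:
        raise FormatError(f"channel {channel} out of range for {n_sig} signal(s)")
    sig_info = sigs[channel]
    dat = os.path.join(os.path.dirname(stem), sig_info["file"])
    if not os.path.exists(dat):
        raise FileNotFoundError(dat)
    mat = _read_dat(dat, sig_info["fmt"], n_sig)
    if n_samp:
        mat = mat[:n_samp]
    physical = (mat[:, channel] - sig_info["baseline"]) / sig_info["gain"]

    ann_csv, atr = stem + ".ann.csv", stem + ".atr"
    if os.path.exists(ann_csv):
        beats, dropped = _read_ann_csv(ann_csv)
    elif os.path.exists(atr):
        beats, dropped = read_atr(atr)
    else:
        raise FileNotFoundError(f"no annotations ({ann_csv} or {atr})")
    if dropped:
        logger.info("%s: dropped %d non-beat annotation(s)", name, dropped)
    beats = [b for b in beats if b.sample_index < len(physical)]
    return ECGRecord(record_id=name, samples=physical, fs=fs, annotations=beats)


def resample_record(record: ECGRecord, target_fs: float) -> ECGRecord:
    """Polyphase-resample a record (signal and annotation indices) to *target_fs*.

    Used to bring e.g. 128 Hz recordings onto the 360 Hz grid the fixed
    200-sample beat window and subband-edge statements assume.
    """
    if record.fs == target_fs:
        return record
    frac = Fraction(target_fs / record.fs).limit_denominator(1000)
    samples = resample_poly(record.samples, frac.numerator, frac.denominator)
    scale = target_fs / record.fs
    anns = []
    last = -1
    for a in record.annotations:
        idx = min(int(round(a.sample_index * scale)), len(samples) - 1)
        if idx > last:  # resampling must not collapse two beats onto one index
            anns.append(BeatAnnotation(idx, a.symbol))
            last = idx
    return ECGRecord(record.record_id, samples, target_fs, anns)


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(
    features: Sequence[Sequence[float]] | np.ndarray,
    labels: Sequence[str],
    path: str | os.PathLike,
) -> None:
    """Write a beats x 17 feature matrix with labels as CSV (f1..f17, label)."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X.reshape(0, 17) if X.size == 0 else X.reshape(1, -1)
    if len(X) != len(labels):
        raise ValueError(f"{len(X)} feature rows but {len(labels)} labels")
    ncol = X.shape[1] if X.size else 17
    df = pd.DataFrame(X, columns=[f"f{i + 1}" for i in range(ncol)])
    df["label"] = list(labels)
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, dtype={"label": str})
    labels = df.pop("label").tolist()
    return df.to_numpy(dtype=float), labels
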