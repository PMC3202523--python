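"""Readers/writers and run configuration.

The package's native interchange format is two delimited text files per
record — a samples file (one mV value per line) and an annotations file
(``sample_index,label`` with a header) — which both the synthetic
generator and the WFDB adapter emit.

The WFDB adapter reads MIT-BIH arrhythmia database records directly:
signal files in format 212 (two 12-bit two's-complement samples packed
into three bytes) with their text headers, and binary MIT annotation
files.  Annotation symbols are mapped to the three-class scheme:
``N`` -> normal, ``V`` -> pvc, every other *beat* symbol -> other;
non-beat annotations are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .synthetic import CLASS_NAMES

log = logging.getLogger(__name__)

NORMAL, PVC, OTHER = 0, 1, 2

#: MIT annotation codes for beat annotations, code -> conventional symbol
_BEAT_CODES = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 25: "L", 34: "e",
    35: "n", 38: "f", 30: "[", 31: "]",
}
#: annotation codes that are not beats (rhythm changes, noise, etc.)
_NON_BEAT_CODES = {0, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 26, 27,
                   28, 29, 32, 33, 36, 37, 39, 40}

BEAT_SYMBOLS = set(_BEAT_CODES.values()) | {"N", "V"}


def map_symbol(symbol: str) -> int:
    """'N' -> normal, 'V' -> pvc, anything else -> other (logged if unknown)."""
    if symbol == "N":
        return NORMAL
    if symbol == "V":
        return PVC
    if symbol not in BEAT_SYMBOLS:
        log.warning("unknown beat symbol %r classified as 'other'", symbol)
    return OTHER


# delimited-text record format ---------------------------------------------

def read_samples(path) -> np.ndarray:
    """One-column text file of mV values."""
    return np.atleast_1d(np.loadtxt(path, dtype=float))


def write_samples(path, samples) -> None:
    np.savetxt(path, np.asarray(samples, float), fmt="%.6f")


def read_annotations(path) -> tuple[np.ndarray, np.ndarray]:
    """Delimited annotation file -> (sample indices, class codes).

    Rows are ``sample_index,label`` where label is a class name
    (normal/pvc/other) or a single WFDB beat symbol.  An optional header
    row is skipped.  An empty file yields empty arrays.
    """
    indices: list[int] = []
    codes: list[int] = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if ln == 0 and not parts[0].lstrip("-").isdigit():
                continue  # header
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed annotation line {ln + 1}")
            indices.append(int(parts[0]))
            label = parts[1]
            if label in CLASS_NAMES:
                codes.append(CLASS_NAMES.index(label))
            else:
                codes.append(map_symbol(label))
    return np.asarray(indices, dtype=int), np.asarray(codes, dtype=int)


def write_annotations(path, indices, codes) -> None:
    with open(path, "w") as fh:
        fh.write("sample_index,label\n")
        for i, c in zip(indices, codes):
            fh.write(f"{int(i)},{CLASS_NAMES[int(c)]}\n")


# WFDB format 212 -----------------------------------------------------------

@dataclass
class WFDBHeader:
    record_name: str
    n_signals: int
    fs: float
    n_samples: int
    signal_file: str
    fmt: int
    gains: list[float]
    baselines: list[int]


def _parse_header(path: Path) -> WFDBHeader:
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty header")
    rec = lines[0].split()
    if len(rec) < 2:
        raise ValueError(f"{path}: malformed record line")
    name = rec[0].split("/")[0]
    n_sig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    n_samp = int(rec[3]) if len(rec) > 3 else 0
    gains, baselines, fmts, sig_file = [], [], [], None
    for ln in lines[1:1 + n_sig]:
        parts = ln.split()
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed signal line {ln!r}")
        sig_file = sig_file or parts[0]
        fmts.append(int(parts[1].split("x")[0].split(":")[0].split("+")[0]))
        gain_field = parts[2].split("/")[0]
        if "(" in gain_field:
            g, b = gain_field.split("(")
            gains.append(float(g))
            baselines.append(int(b.rstrip(")")))
        else:
            gains.append(float(gain_field))
            # ADC zero (field 5) is the default baseline when present
            baselines.append(int(parts[4]) if len(parts) > 4 else 0)
    if any(f != fmts[0] for f in fmts):
        raise ValueError(f"{path}: mixed signal formats unsupported")
    return WFDBHeader(record_name=name, n_signals=n_sig, fs=fs,
                      n_samples=n_samp, signal_file=sig_file, fmt=fmts[0],
                      gains=gains, baselines=baselines)


def decode_format212(raw: bytes, n_samples: int | None = None) -> np.ndarray:
    """Unpack format-212 bytes into 12-bit two's-complement integers.

    Every 3 bytes hold two samples: byte 0 carries the low 8 bits of
    sample 1, the low nibble of byte 1 its high 4 bits; the high nibble
    of byte 1 carries the high 4 bits of sample 2, byte 2 its low 8 bits.
    """
    if len(raw) % 3:
        usable = len(raw) - len(raw) % 3
        raise ValueError(
            f"format-212 stream length {len(raw)} is not a multiple of 3 "
            f"(truncated after byte {usable}?)")
    b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3).astype(np.int32)
    s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(2 * len(b), dtype=np.int32)
    out[0::2] = s1
    out[1::2] = s2
    out[out > 2047] -= 4096  # 12-bit two's complement
    if n_samples is not None:
        out = out[:n_samples]
    return out


def read_wfdb_record(path, lead: int = 0) -> tuple[np.ndarray, float]:
    """Read a WFDB format-212 record; returns (samples in mV, fs).

    ``path`` is the record path without extension (header ``.hea`` and
    the signal file it names must sit next to each other).  ``lead``
    selects the signal (0 = first signal, the modified limb lead II in
    MIT-BIH records).  Amplitudes are converted to mV via
    ``(adc - baseline) / gain``.
    """
    path = Path(path)
    header = _parse_header(path.with_suffix(".hea"))
    if header.fmt != 212:
        raise ValueError(f"unsupported WFDB signal format {header.fmt}")
    if not 0 <= lead < header.n_signals:
        raise ValueError(f"lead {lead} out of range for {header.n_signals} signals")
    raw = (path.parent / header.signal_file).read_bytes()
    total = header.n_samples * header.n_signals if header.n_samples else None
    flat = decode_format212(raw, total)
    sig = flat[lead::header.n_signals].astype(float)
    mv = (sig - header.baselines[lead]) / header.gains[lead]
    return mv, header.fs


def read_wfdb_annotations(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a binary MIT annotation file (e.g. ``.atr``).

    Returns (sample indices, class codes) for beat annotations only.
    The MIT format stores 2-byte little-endian words: the top 6 bits are
    the annotation code, the low 10 bits the sample increment; codes
    59-63 are pseudo-annotations (SKIP/NUM/SUB/CHN/AUX).
    """
    raw = Path(path).read_bytes()
    words = np.frombuffer(raw[:len(raw) - len(raw) % 2], dtype="<u2")
    indices, codes = [], []
    t = 0
    i = 0
    while i < len(words):
        word = int(words[i])
        code = word >> 10
        inc = word & 0x3FF
        if word == 0:  # EOF
            break
        if code == 59:  # SKIP: next two words are a 4-byte interval
            if i + 2 >= len(words):
                raise ValueError(f"{path}: truncated SKIP pseudo-annotation")
            t += (int(words[i + 1]) << 16) + int(words[i + 2])
            i += 3
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN
            i += 1
            continue
        if code == 63:  # AUX: inc = byte count, padded to even
            i += 1 + (inc + 1) // 2
            continue
        t += inc
        if code in _BEAT_CODES:
            indices.append(t)
            codes.append(map_symbol(_BEAT_CODES[code]))
        elif code not in _NON_BEAT_CODES:
            log.warning("unknown annotation code %d at sample %d treated as "
                        "'other' beat", code, t)
            indices.append(t)
            codes.append(OTHER)
        i += 1
    return np.asarray(indices, dtype=int), np.asarray(codes, dtype=int)


# run configuration ---------------------------------------------------------

@dataclass
class RunConfig:
    """Validated pipeline parameters; unknown keys are rejected."""

    wavelet: str = "db1"
    wavelet_level: int = 5
    sg_window: int = 15
    sg_order: int = 3
    half_width: int = 40
    mode: str = "msg"
    experts: int = 3
    combiner_width: int = 45
    combiner_epochs: int = 2000
    seed: int = 0
    noise_sigma: float = 0.10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
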