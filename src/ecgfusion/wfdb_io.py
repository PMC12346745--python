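"""Minimal WFDB (PhysioNet waveform database) support.

Reads and writes the subset of WFDB actually used by PTB-XL-style corpora:
a text header (``<record>.hea``) plus a single binary signal file
(``<record>.dat``) in format 16 — little-endian 16-bit integers, channels
interleaved per frame. Physical units are recovered as
``(digital - baseline) / gain``; signals are stored with a gain of 1000
ADU/mV, i.e. 1 µV amplitude resolution.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

import numpy as np

DEFAULT_GAIN = 1000.0  # ADU per millivolt
FORMAT = 16

_GAIN_RE = re.compile(
    r"^(?P<gain>[-+0-9.eE]+)(?:\((?P<baseline>[-+0-9]+)\))?(?:/(?P<units>\S+))?$"
)


class WFDBFormatError(ValueError):
    """Raised when a header/signal pair cannot be interpreted."""


@dataclass
class _SignalSpec:
    file_name: str
    fmt: int
    gain: float
    baseline: int
    name: str


def _parse_header(hea_path: str) -> tuple[str, int, float, int, list[_SignalSpec]]:
    with open(hea_path, "r") as fh:
        lines = [
            ln.strip()
            for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]
    if not lines:
        raise WFDBFormatError(f"empty header {hea_path}")
    head = lines[0].split()
    if len(head) < 4:
        raise WFDBFormatError(f"malformed record line in {hea_path}: {lines[0]!r}")
    record_name = head[0]
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    specs: list[_SignalSpec] = []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        if len(parts) < 2:
            raise WFDBFormatError(f"malformed signal line in {hea_path}: {ln!r}")
        fmt = int(parts[1].split("x")[0].split(":")[0].split("+")[0])
        gain, baseline = DEFAULT_GAIN, 0
        if len(parts) >= 3:
            m = _GAIN_RE.match(parts[2])
            if m:
                gain = float(m.group("gain")) or DEFAULT_GAIN
                baseline = int(m.group("baseline") or 0)
        # ADC zero (field 5) doubles as baseline when no (baseline) given
        if len(parts) >= 5 and "(" not in parts[2]:
            try:
                baseline = int(parts[4])
            except ValueError:
                pass
        name = parts[-1] if len(parts) >= 9 else f"ch{len(specs)}"
        specs.append(_SignalSpec(parts[0], fmt, gain, baseline, name))
    if len(specs) != n_sig:
        raise WFDBFormatError(
            f"{hea_path}: header promises {n_sig} signals, lists {len(specs)}"
        )
    return record_name, n_sig, fs, n_samples, specs


def read_wfdb(record_path: str) -> tuple[np.ndarray, float, list[str]]:
    """Read a WFDB record (path without extension).

    Returns ``(signal, fs, channel_names)`` with signal shaped
    (samples, channels) in physical units (millivolts for ECG).
    """
    hea_path = record_path + ".hea"
    if not os.path.exists(hea_path):
        raise FileNotFoundError(hea_path)
    _, n_sig, fs, n_samples, specs = _parse_header(hea_path)
    for s in specs:
        if s.fmt != FORMAT:
            raise WFDBFormatError(
                f"unsupported WFDB format {s.fmt} (only format {FORMAT})"
            )
    dat_files = {s.file_name for s in specs}
    if len(dat_files) != 1:
        raise WFDBFormatError("multi-file records are not supported")
    dat_path = os.path.join(os.path.dirname(record_path), specs[0].file_name)
    if not os.path.exists(dat_path):
        raise FileNotFoundError(dat_path)
    raw = np.fromfile(dat_path, dtype="<i2")
    if raw.size != n_samples * n_sig:
        raise WFDBFormatError(
            f"{dat_path}: expected {n_samples * n_sig} samples, got {raw.size}"
        )
    digital = raw.reshape(n_samples, n_sig).astype(np.float64)
    gains = np.array([s.gain for s in specs])
    baselines = np.array([s.baseline for s in specs])
    physical = (digital - baselines) / gains
    return physical, fs, [s.name for s in specs]


def write_wfdb(
    record_path: str,
    signal: np.ndarray,
    fs: int,
    channel_names: list[str],
    gain: float = DEFAULT_GAIN,
) -> None:
    """Write a format-16 WFDB record (path without extension).

    ``signal`` is (samples, channels) in physical units; values are quantized
    to ``round(x * gain)`` 16-bit integers, so round-trip error is bounded by
    ``0.5 / gain`` per sample.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 2:
        raise ValueError("signal must be 2-D (samples, channels)")
    n_samples, n_sig = signal.shape
    if len(channel_names) != n_sig:
        raise ValueError("channel_names length must match channel count")
    digital = np.round(signal * gain)
    if np.any(np.abs(digital) > 32767):
        raise ValueError("signal exceeds int16 range at this gain")
    digital = digital.astype("<i2")
    record_name = os.path.basename(record_path)
    dat_name = record_name + ".dat"
    digital.tofile(record_path + ".dat")
    checksums = digital.astype(np.int64).sum(axis=0) % 65536
    with open(record_path + ".hea", "w") as fh:
        fh.write(f"{record_name} {n_sig} {fs} {n_samples}\n")
        for ch in range(n_sig):
            first = int(digital[0, ch]) if n_samples else 0
            fh.write(
                f"{dat_name} {FORMAT} {gain:g}(0)/mV 16 0 "
                f"{first} {int(checksums[ch])} 0 {channel_names[ch]}\n"
            )
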