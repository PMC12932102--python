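"""Waveform record I/O: a plain-text array container and minimal WFDB support.

Two on-disk record formats are supported:

* **array container** — a single text file: line 1 lists the channel names
  (comma-separated), line 2 the sampling rate in Hz, then one row of
  comma-separated values per sample (columns = channels).
* **WFDB** — PhysioNet-style header (`.hea`) + signal (`.dat`) pairs,
  restricted to format 16 (interleaved little-endian int16 with a per-signal
  gain).  This covers the common diagnostic-ECG layout; exotic formats are
  out of scope.

Channel labels are mapped through a case-insensitive alias table
("MLII" -> II, "PLETH" -> PPG, ...); unrecognized channels are dropped with
a warning, and a record with no recognizable channel is an error.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .channels import canonical_name
from .signals import SignalRecord

WFDB_FORMAT = 16
_DEFAULT_GAIN = 200.0


# ----------------------------------------------------------------------
# array container
def write_array_record(record: SignalRecord, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(record.channel_names) + "\n")
        fh.write(f"{record.sampling_rate}\n")
        np.savetxt(fh, record.values.T, delimiter=",", fmt="%.9g")


def read_array_record(path) -> SignalRecord:
    path = Path(path)
    with open(path) as fh:
        names = [n.strip() for n in fh.readline().split(",")]
        try:
            fs = float(fh.readline())
        except ValueError as exc:
            raise ValueError(f"{path}:2: cannot parse sampling rate") from exc
        values = np.loadtxt(fh, delimiter=",", ndmin=2).T
    return _canonicalize(values, names, fs, str(path))


# ----------------------------------------------------------------------
# minimal WFDB (format 16)
def write_wfdb_record(record: SignalRecord, record_name: str, directory) -> None:
    """Write `<record_name>.hea` + `<record_name>.dat` (format 16)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    C, T = record.values.shape
    digital = np.clip(np.round(record.values * _DEFAULT_GAIN), -32768, 32767)
    digital = digital.astype("<i2")
    interleaved = digital.T.reshape(-1)
    (directory / f"{record_name}.dat").write_bytes(interleaved.tobytes())
    lines = [f"{record_name} {C} {record.sampling_rate:g} {T}"]
    for i, name in enumerate(record.channel_names):
        first = int(digital[i, 0])
        checksum = int(np.sum(digital[i], dtype=np.int64) % 65536)
        lines.append(
            f"{record_name}.dat {WFDB_FORMAT} {_DEFAULT_GAIN:g}/mV 16 0 "
            f"{first} {checksum} 0 {name}")
    (directory / f"{record_name}.hea").write_text("\n".join(lines) + "\n")


def read_wfdb_record(header_path) -> SignalRecord:
    header_path = Path(header_path)
    if header_path.suffix != ".hea":
        header_path = header_path.with_suffix(".hea")
    lines = [ln.strip() for ln in header_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    try:
        rec_fields = lines[0].split()
        n_sig = int(rec_fields[1])
        fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
        n_samples = int(rec_fields[3]) if len(rec_fields) > 3 else -1
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{header_path}:1: corrupt WFDB record line") from exc
    names, gains, dat_files = [], [], []
    for lineno, line in enumerate(lines[1:1 + n_sig], start=2):
        fields = line.split()
        try:
            dat_files.append(fields[0])
            fmt = int(fields[1])
            gain_field = fields[2] if len(fields) > 2 else f"{_DEFAULT_GAIN:g}"
            gains.append(float(gain_field.split("/")[0].split("(")[0]))
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{header_path}:{lineno}: corrupt signal line") from exc
        if fmt != WFDB_FORMAT:
            raise ValueError(
                f"{header_path}:{lineno}: unsupported WFDB format {fmt} "
                f"(only format {WFDB_FORMAT} is supported)")
        names.append(fields[-1])
    if len(set(dat_files)) != 1:
        raise ValueError(f"{header_path}: multi-file records are not supported")
    raw = np.frombuffer((header_path.parent / dat_files[0]).read_bytes(),
                        dtype="<i2")
    values = raw.reshape(-1, n_sig).T.astype(np.float64)
    if n_samples > 0:
        values = values[:, :n_samples]
    values /= np.array(gains)[:, None]
    return _canonicalize(values, names, fs, str(header_path))


def _canonicalize(values: np.ndarray, names: list[str], fs: float,
                  source: str) -> SignalRecord:
    keep_rows, keep_names = [], []
    for i, name in enumerate(names):
        canon = canonical_name(name)
        if canon is None:
            warnings.warn(f"{source}: dropping unrecognized channel {name!r}",
                          stacklevel=3)
        elif canon in keep_names:
            warnings.warn(f"{source}: dropping duplicate channel {name!r}",
                          stacklevel=3)
        else:
            keep_rows.append(i)
            keep_names.append(canon)
    if not keep_rows:
        raise ValueError(f"{source}: no recognizable channel among {names}")
    return SignalRecord(values[keep_rows], keep_names, fs)


def read_waveform_record(path, fmt: str = "auto") -> SignalRecord:
    """Read a record as WFDB or array container; `fmt='auto'` picks by suffix."""
    path = Path(path)
    if fmt == "auto":
        fmt = "wfdb" if path.suffix in (".hea", ".dat") else "array"
    if fmt == "wfdb":
        return read_wfdb_record(path)
    if fmt == "array":
        return read_array_record(path)
    raise ValueError(f"unknown format {fmt!r}; choose 'wfdb' or 'array'")


# ----------------------------------------------------------------------
def save_matrix(matrix: np.ndarray, path, meta: dict | None = None) -> None:
    """Portable matrix container: CSV + JSON sidecar describing the contents."""
    import json
    path = Path(path)
    np.savetxt(path, matrix, delimiter=",", fmt="%.9g")
    if meta is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"shape": list(matrix.shape), **meta}, indent=1))


__all__ = [
    "read_waveform_record", "read_array_record", "write_array_record",
    "read_wfdb_record", "write_wfdb_record", "save_matrix",
]
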