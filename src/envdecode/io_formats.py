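"""File formats: EDF and CSV-matrix EEG, WAV audio, CSV result tables, YAML config.

EDF (European Data Format) is the interchange format for scalp EEG; reading
goes through MNE's native EDF reader, while writing uses a small built-in
writer for the 16-bit continuous-recording subset of the format (one data
record per second, per-channel physical scaling, fixed epoch start date so
identical data produce byte-identical files).  A CSV-matrix escape hatch with
a JSON metadata sidecar exists for small text fixtures.  Audio moves through
16-bit PCM WAV.  Result tables are RFC-4180 CSV with a header row.
"""

from __future__ import annotations

import json
import logging
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AnalysisConfig, AudioStimulus, MultichannelRecording

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_eeg",
    "write_eeg",
    "read_audio",
    "write_audio",
    "write_results_table",
    "read_results_table",
    "load_config",
    "save_config",
    "RESULT_COLUMNS",
]


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the requested format."""


RESULT_COLUMNS = [
    "subject", "band", "condition", "mean_r", "sd_r", "lambda_opt", "p_vs_null",
]

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF field {s!r} exceeds {width} ascii characters")
    return s.ljust(width).encode("ascii")


def _edf_number(value: float, width: int = 8) -> str:
    """Format a float to fit an 8-character EDF ascii field, round-trip safe."""
    for prec in range(6, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return s
    return f"{value:.0e}"[:width]


def _phys_limit(x: np.ndarray) -> float:
    """Per-channel symmetric physical range, padded and 8-char printable."""
    peak = float(np.max(np.abs(x))) if x.size else 0.0
    if peak == 0:
        return 1.0
    pm = peak * 1.001
    for _ in range(4):
        printed = float(_edf_number(pm))
        if printed >= peak:
            return printed
        pm *= 1.01
    return printed


def write_eeg(rec: MultichannelRecording, path, format: str = "edf") -> None:
    """Write a recording as EDF (default) or CSV matrix with JSON sidecar."""
    path = Path(path)
    if format == "edf":
        _write_edf(rec, path)
    elif format == "csv_matrix":
        _write_csv_matrix(rec, path)
    else:
        raise ValueError(f"unknown EEG format {format!r}")


def _write_edf(rec: MultichannelRecording, path: Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("the EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n = rec.n_channels, rec.n_samples
    n_records = -(-n // fs)  # ceil: final record zero-padded if needed
    if n_records * fs != n:
        logger.warning("EDF write: padding last record with %d zero samples",
                       n_records * fs - n)
    data = np.zeros((n_ch, n_records * fs))
    data[:, :n] = rec.data
    phys = np.array([_phys_limit(data[j]) for j in range(n_ch)])
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (2 * phys)
    digital = np.rint((data + phys[:, None]) * scale[:, None] + _EDF_DIG_MIN)
    digital = np.clip(digital, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    patient = f"{rec.subject_id or 'X'} sex=X cond={rec.condition or 'none'} " \
              f"order={rec.presentation_order or 0}"
    header = b"".join([
        _edf_field("0", 8),
        _edf_field(patient[:80], 80),
        _edf_field("Startdate 01-JAN-2000 envdecode", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_ch), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(lbl[:16], 16) for lbl in rec.channel_labels),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_field(_edf_number(-p), 8) for p in phys),
        b"".join(_edf_field(_edf_number(p), 8) for p in phys),
        b"".join(_edf_field(_EDF_DIG_MIN, 8) for _ in range(n_ch)),
        b"".join(_edf_field(_EDF_DIG_MAX, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(fs, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        # records: for each second, all samples of signal 0, then signal 1, ...
        for r in range(n_records):
            fh.write(digital[:, r * fs:(r + 1) * fs].tobytes())
    logger.info("wrote EDF %s: %d channels x %d samples at %d Hz",
                path, n_ch, n, fs)


def _parse_edf_patient(path: Path) -> dict:
    with open(path, "rb") as fh:
        fh.seek(8)
        patient = fh.read(80).decode("ascii", errors="replace").strip()
    meta = {"subject_id": "", "condition": "", "presentation_order": None}
    tokens = patient.split()
    if tokens:
        if tokens[0] not in ("X", ""):
            meta["subject_id"] = tokens[0]
        for tok in tokens[1:]:
            if tok.startswith("cond=") and tok[5:] in ("aided", "unaided"):
                meta["condition"] = tok[5:]
            elif tok.startswith("order=") and tok[6:] in ("1", "2"):
                meta["presentation_order"] = int(tok[6:])
    return meta


def _read_edf(path: Path) -> MultichannelRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various types on malformed input
        raise FormatError(f"cannot read {path} as EDF: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # MNE converts EEG to volts internally
    meta = _parse_edf_patient(path)
    return MultichannelRecording(data_uv, raw.info["sfreq"], raw.ch_names, **meta)


def _write_csv_matrix(rec: MultichannelRecording, path: Path) -> None:
    frame = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    frame.to_csv(path, index=False)
    sidecar = {
        "fs": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "presentation_order": rec.presentation_order,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def _read_csv_matrix(path: Path) -> MultichannelRecording:
    meta_path = Path(str(path) + ".meta.json")
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as CSV matrix: {exc}") from exc
    if frame.empty and frame.columns.size == 0:
        raise FormatError(f"{path} contains no data")
    labels = meta["channel_labels"]
    if list(frame.columns) != list(labels):
        raise FormatError("CSV header disagrees with sidecar channel labels")
    return MultichannelRecording(
        frame.to_numpy().T, meta["fs"], labels,
        subject_id=meta.get("subject_id", ""),
        condition=meta.get("condition", ""),
        presentation_order=meta.get("presentation_order"),
    )


def read_eeg(path, format: str = "edf") -> MultichannelRecording:
    """Read and validate a multichannel recording.

    ``format`` is ``edf`` or ``csv_matrix`` (the latter expects a
    ``<path>.meta.json`` sidecar carrying fs and channel labels).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path} is empty")
    if format == "edf":
        rec = _read_edf(path)
    elif format == "csv_matrix":
        rec = _read_csv_matrix(path)
    else:
        raise ValueError(f"unknown EEG format {format!r}")
    logger.info("read %s: %d channels x %d samples at %g Hz",
                path, rec.n_channels, rec.n_samples, rec.fs)
    return rec


def write_audio(audio: AudioStimulus, path) -> None:
    """Write mono 16-bit PCM WAV."""
    from scipy.io import wavfile

    # 32768-based scaling matches the integer-read convention, so a write
    # followed by a read is off by at most half a quantization step
    wave = np.clip(audio.waveform, -1.0, 1.0)
    pcm = np.clip(np.rint(wave * 32768), -32768, 32767).astype("<i2")
    wavfile.write(str(path), int(round(audio.fs)), pcm)


def read_audio(path) -> AudioStimulus:
    """Read a WAV file; stereo input is averaged to mono.

    Integer PCM is rescaled to [-1, 1); the whole file forms one segment
    (callers may re-segment afterwards).
    """
    from scipy.io import wavfile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        fs, data = wavfile.read(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read {path} as WAV: {exc}") from exc
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(-np.iinfo(data.dtype).min)
    else:
        data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioStimulus(data, float(fs))


def write_results_table(rows, path) -> None:
    """Write result records as CSV with a header row.

    ``rows`` may be a DataFrame or a list of dicts; an empty list yields a
    header-only file with the canonical result schema.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        frame = pd.DataFrame(rows, columns=RESULT_COLUMNS if not rows else None)
    frame.to_csv(path, index=False)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_config(cfg: AnalysisConfig, path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def load_config(path) -> AnalysisConfig:
    import yaml

    return AnalysisConfig.from_dict(yaml.safe_load(Path(path).read_text()))
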