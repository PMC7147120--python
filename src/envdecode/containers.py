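"""Core data containers shared across the pipeline.

The pipeline relates two time series sampled on a common grid: a multichannel
scalp EEG recording and the temporal envelope of the speech stimulus the
subject listened to.  Everything downstream (filtering, lag embedding, ridge
decoding) operates on these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "BandSpec",
    "BANDS",
    "MultichannelRecording",
    "AudioStimulus",
    "Envelope",
    "AnalysisConfig",
]

CONDITIONS = ("aided", "unaided")


@dataclass(frozen=True)
class BandSpec:
    """A band-pass specification for slow neural oscillations.

    Parameters
    ----------
    name : str
        Conventional band name (``delta``, ``theta``, ``wide`` for the three
        canonical analysis bands; arbitrary names are allowed).
    f_lo, f_hi : float
        Lower and upper corner frequencies in Hz.
    tbw_lo, tbw_hi : float
        Transition bandwidths in Hz below ``f_lo`` and above ``f_hi``.
    """

    name: str
    f_lo: float
    f_hi: float
    tbw_lo: float
    tbw_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"require 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")
        if self.tbw_lo <= 0 or self.tbw_hi <= 0:
            raise ValueError("transition bandwidths must be positive")


#: Canonical analysis bands: delta 1-4 Hz, theta 4-8 Hz, wideband 1-20 Hz.
BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0, 1.0, 2.0),
    "theta": BandSpec("theta", 4.0, 8.0, 2.0, 2.0),
    "wide": BandSpec("wide", 1.0, 20.0, 1.0, 5.0),
}


def _as_2d_float(data: np.ndarray) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a channels x samples matrix, got shape {arr.shape}")
    return arr


@dataclass
class MultichannelRecording:
    """Scalp EEG on a channels x samples grid.

    ``data`` holds microvolt values, one row per electrode, all sharing one
    sampling rate ``fs``.  ``condition`` distinguishes the aided / unaided
    listening conditions; ``presentation_order`` is 1 when this condition was
    the first one the subject heard.
    """

    data: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    subject_id: str = ""
    condition: str = ""
    presentation_order: int | None = None

    def __post_init__(self) -> None:
        self.data = _as_2d_float(self.data)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.condition and self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.presentation_order not in (None, 1, 2):
            raise ValueError("presentation_order must be 1 or 2")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **changes) -> "MultichannelRecording":
        return replace(self, **changes)


@dataclass
class AudioStimulus:
    """Mono audio waveform with contiguous segment boundaries.

    ``segment_ids`` is an ordered list of half-open ``[start, stop)`` sample
    intervals that tile the waveform; the stimulus of the study design is
    presented in eight roughly 3-minute segments, but a single whole-file
    segment is the default.
    """

    waveform: np.ndarray
    fs: float
    segment_ids: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.waveform.size
        if not self.segment_ids:
            self.segment_ids = [(0, n)]
        cursor = 0
        for start, stop in self.segment_ids:
            if start != cursor or stop <= start:
                raise ValueError("segments must tile the waveform without gaps or overlap")
            cursor = stop
        if cursor != n:
            raise ValueError("segments must cover the full waveform")

    @property
    def duration(self) -> float:
        return self.waveform.size / self.fs


@dataclass
class Envelope:
    """Temporal amplitude envelope of the speech stimulus.

    A raw envelope (magnitude of the analytic signal) is nonnegative; after
    band-pass filtering the DC component is removed so samples may be signed,
    which is why nonnegativity is only enforced for ``band == "raw"``.
    """

    samples: np.ndarray
    fs: float
    band: BandSpec | str = "raw"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.band == "raw" and self.samples.size and self.samples.min() < 0:
            raise ValueError("a raw envelope must be nonnegative")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def time_reversed(self) -> "Envelope":
        return Envelope(self.samples[::-1].copy(), self.fs, self.band)


def default_lambda_grid(n: int = 50, lo_exp: float = -15, hi_exp: float = 15) -> np.ndarray:
    """Log-spaced ridge penalty grid, 50 values spanning 1e-15 .. 1e15."""
    return np.logspace(lo_exp, hi_exp, n)


@dataclass
class AnalysisConfig:
    """All tunable parameters of the decoding analysis.

    Defaults reproduce the canonical analysis: decoder lags -100..+400 ms at a
    64 Hz working rate, five-fold cross-validation on 10-second scoring
    segments, and a 50-point ridge penalty sweep over 1e-15..1e15.
    """

    bands: list[BandSpec] = field(default_factory=lambda: list(BANDS.values()))
    tau_min: float = -0.100
    tau_max: float = 0.400
    target_fs: float = 64.0
    n_folds: int = 5
    segment_length: float = 10.0
    lambda_grid: np.ndarray = field(default_factory=default_lambda_grid)
    alpha: float = 0.05
    seed: int = 0
    # behavioural switches (defaults match the primary analysis path)
    include_mastoids: bool = False
    valid_rows_only: bool = False
    trim_fold_margins: bool = False
    reverse_raw_audio: bool = False
    envelope_decimate_first: bool = False

    def __post_init__(self) -> None:
        if self.tau_min >= self.tau_max:
            raise ValueError("tau_min must be < tau_max")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        grid = np.asarray(self.lambda_grid, dtype=float)
        if grid.size == 0 or np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ValueError("lambda_grid must be strictly increasing and positive")
        self.lambda_grid = grid
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "bands": [
                {"name": b.name, "f_lo": b.f_lo, "f_hi": b.f_hi,
                 "tbw_lo": b.tbw_lo, "tbw_hi": b.tbw_hi}
                for b in self.bands
            ],
            "lag_window": {"tau_min": self.tau_min, "tau_max": self.tau_max},
            "target_fs": self.target_fs,
            "n_folds": self.n_folds,
            "segment_length": self.segment_length,
            "lambda_grid": {
                "n": int(self.lambda_grid.size),
                "lo_exp": float(np.log10(self.lambda_grid[0])),
                "hi_exp": float(np.log10(self.lambda_grid[-1])),
            },
            "alpha": self.alpha,
            "seed": self.seed,
            "flags": {
                "include_mastoids": self.include_mastoids,
                "valid_rows_only": self.valid_rows_only,
                "trim_fold_margins": self.trim_fold_margins,
                "reverse_raw_audio": self.reverse_raw_audio,
                "envelope_decimate_first": self.envelope_decimate_first,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs: dict = {}
        if "bands" in d:
            kwargs["bands"] = [BandSpec(**b) for b in d["bands"]]
        if "lag_window" in d:
            kwargs["tau_min"] = d["lag_window"]["tau_min"]
            kwargs["tau_max"] = d["lag_window"]["tau_max"]
        for key in ("target_fs", "n_folds", "segment_length", "alpha", "seed"):
            if key in d:
                kwargs[key] = d[key]
        if "lambda_grid" in d:
            g = d["lambda_grid"]
            kwargs["lambda_grid"] = default_lambda_grid(g["n"], g["lo_exp"], g["hi_exp"])
        for key, val in d.get("flags", {}).items():
            kwargs[key] = val
        return cls(**kwargs)
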