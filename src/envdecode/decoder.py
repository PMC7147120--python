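"""Lagged design matrix and the ridge-regression backward decoder.

The backward (stimulus-reconstruction) model estimates the speech envelope
y(t_n) as a linear combination of the EEG channels x_j at a set of delays
tau_k spanning -100..+400 ms:

    y_hat(t_n) = sum_j sum_k beta_{j,k} x_j(t_n + tau_k)

Stacking the delayed channel copies column-wise gives the design matrix X
with N*T columns (N channels, T lags); the decoder weights solve the ridge
normal equations beta = (X'X + lambda I)^-1 X'y.  Reconstruction quality is
scored as the Pearson correlation between y_hat and y over non-overlapping
10-second segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from .containers import AnalysisConfig, BandSpec, Envelope, MultichannelRecording

__all__ = [
    "LagSpec",
    "LaggedDesignMatrix",
    "DecoderWeights",
    "build_lag_matrix",
    "fit_ridge",
    "predict_envelope",
    "segment_correlations",
    "EnvelopeDecoder",
    "DecoderResults",
]


@dataclass(frozen=True)
class LagSpec:
    """Decoder lag window converted to integer sample lags.

    Negative lags let the decoder look at EEG *preceding* the stimulus sample
    (acausal margin); positive lags cover the causal cortical response.  At
    the canonical -100..+400 ms window and 64 Hz this gives integer lags
    -6..26, i.e. T = 33 lags per channel.
    """

    tau_min: float = -0.100
    tau_max: float = 0.400
    fs: float = 64.0

    def __post_init__(self) -> None:
        if self.tau_min >= self.tau_max:
            raise ValueError("tau_min must be < tau_max")

    @property
    def k_min(self) -> int:
        return int(round(self.tau_min * self.fs))

    @property
    def k_max(self) -> int:
        return int(round(self.tau_max * self.fs))

    @property
    def lag_samples(self) -> np.ndarray:
        return np.arange(self.k_min, self.k_max + 1)

    @property
    def n_lags(self) -> int:
        return self.k_max - self.k_min + 1

    @classmethod
    def from_config(cls, cfg: AnalysisConfig) -> "LagSpec":
        return cls(cfg.tau_min, cfg.tau_max, cfg.target_fs)


@dataclass
class LaggedDesignMatrix:
    """Time x (channels * lags) matrix of delayed EEG copies.

    Columns are channel-major: channel j varies slowest, lag k fastest, so
    column (j, k) holds x_j(t + tau_k).  Entries whose delayed index falls
    outside the recording are zero; ``valid_rows`` flags rows for which every
    lag is in range.
    """

    X: np.ndarray
    lags: LagSpec
    n_channels: int
    valid_rows: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]


def build_lag_matrix(eeg: MultichannelRecording, lags: LagSpec) -> LaggedDesignMatrix:
    """Embed the recording into its lagged design matrix."""
    if eeg.fs != lags.fs:
        raise ValueError(f"recording rate {eeg.fs} != lag spec rate {lags.fs}")
    data = eeg.data
    n_ch, n = data.shape
    ks = lags.lag_samples
    T = ks.size
    if n <= lags.k_max - lags.k_min:
        raise ValueError("recording shorter than the lag span")
    X = np.zeros((n, n_ch * T))
    for j in range(n_ch):
        for i, k in enumerate(ks):
            col = j * T + i
            if k >= 0:
                X[: n - k, col] = data[j, k:]
            else:
                X[-k:, col] = data[j, : n + k]
    valid = np.zeros(n, dtype=bool)
    lo = max(0, -lags.k_min)
    hi = min(n, n - lags.k_max)
    if hi > lo:
        valid[lo:hi] = True
    return LaggedDesignMatrix(X, lags, n_ch, valid)


@dataclass
class DecoderWeights:
    """Fitted decoder coefficients for one subject / band / condition.

    ``beta`` has one entry per (channel, lag) column of the design matrix;
    ``x_mean`` / ``y_mean`` store the training means removed before solving,
    restored at prediction time.
    """

    beta: np.ndarray
    lam: float
    n_channels: int
    lags: LagSpec
    band: BandSpec | str | None = None
    subject_id: str = ""
    condition: str = ""
    x_mean: np.ndarray | None = None
    y_mean: float = 0.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("decoder weights must be finite")
        if self.beta.size != self.n_channels * self.lags.n_lags:
            raise ValueError("beta length inconsistent with channels x lags")

    @property
    def by_channel_lag(self) -> np.ndarray:
        """Weights reshaped to channels x lags."""
        return self.beta.reshape(self.n_channels, self.lags.n_lags)


def _solve_ridge(G: np.ndarray, b: np.ndarray, lam: float) -> np.ndarray:
    """Solve (G + lam I) beta = b via Cholesky, with a guarded fallback."""
    A = G if lam == 0 else G + lam * np.eye(G.shape[0])
    try:
        c, low = sla.cho_factor(A, check_finite=False)
        return sla.cho_solve((c, low), b, check_finite=False)
    except np.linalg.LinAlgError:
        if lam == 0:
            raise np.linalg.LinAlgError(
                "singular normal equations at lambda = 0 (collinear design "
                "columns); use lambda > 0"
            ) from None
        return np.linalg.lstsq(A, b, rcond=None)[0]


def fit_ridge(X: LaggedDesignMatrix | np.ndarray, y: Envelope | np.ndarray,
              lam: float, center: bool = True, **meta) -> DecoderWeights:
    """Ridge solution of the decoder normal equations.

    Columns of X and the target are mean-centered before solving (band-passed
    signals are near zero-mean, so this is a numerically safe normalization
    with no modelling content); the offset is restored by
    :func:`predict_envelope`.  A single shared penalty ``lam`` multiplies the
    identity, as the closed form (X'X + lambda I)^-1 X'y implies.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if isinstance(X, LaggedDesignMatrix):
        mat, n_ch, lags = X.X, X.n_channels, X.lags
    else:
        # bare matrix: treat each column as one channel at a single zero lag
        mat = np.asarray(X, dtype=float)
        n_ch, lags = mat.shape[1], _single_lag_spec()
    yv = y.samples if isinstance(y, Envelope) else np.asarray(y, dtype=float).ravel()
    if yv.size != mat.shape[0]:
        raise ValueError("target length must equal the design row count")
    if center:
        x_mean = mat.mean(axis=0)
        y_mean = float(yv.mean())
        Xc = mat - x_mean
        yc = yv - y_mean
    else:
        x_mean = np.zeros(mat.shape[1])
        y_mean = 0.0
        Xc, yc = mat, yv
    G = Xc.T @ Xc
    b = Xc.T @ yc
    beta = _solve_ridge(G, b, lam)
    return DecoderWeights(beta, lam, n_ch, lags, x_mean=x_mean, y_mean=y_mean, **meta)


def _single_lag_spec() -> LagSpec:
    """Degenerate one-lag spec (lag 0 only) used when fitting a bare matrix."""
    return LagSpec(-1e-9, 1e-9, 64.0)


def predict_envelope(X: LaggedDesignMatrix | np.ndarray, w: DecoderWeights,
                     fs: float = 64.0) -> Envelope:
    """Reconstruct the envelope, y_hat = X beta (with the centering offset)."""
    mat = X.X if isinstance(X, LaggedDesignMatrix) else np.asarray(X, dtype=float)
    if mat.shape[1] != w.beta.size:
        raise ValueError(
            f"design has {mat.shape[1]} columns but weights have {w.beta.size}"
        )
    offset = 0.0 if w.x_mean is None else float(w.x_mean @ w.beta)
    y_hat = mat @ w.beta - offset + w.y_mean
    return Envelope(y_hat, fs, band=w.band if w.band is not None else "reconstructed")


def segment_correlations(y_hat: Envelope | np.ndarray, y: Envelope | np.ndarray,
                         segment_length: float = 10.0, fs: float = 64.0) -> np.ndarray:
    """Pearson r between reconstruction and target per 10-second window.

    Non-overlapping windows of ``segment_length`` seconds; a trailing partial
    window is dropped.  A zero-variance window contributes r = 0 (with a
    warning) so pooled distributions keep a fixed cardinality.
    """
    if isinstance(y_hat, Envelope):
        fs = y_hat.fs
        y_hat = y_hat.samples
    if isinstance(y, Envelope):
        y = y.samples
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if y_hat.size != y.size:
        raise ValueError("inputs must have equal length")
    win = int(round(segment_length * fs))
    n_seg = y_hat.size // win
    if n_seg == 0:
        return np.empty(0)
    a = y_hat[: n_seg * win].reshape(n_seg, win)
    b = y[: n_seg * win].reshape(n_seg, win)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", a, b)
    den = np.sqrt(np.einsum("ij,ij->i", a, a) * np.einsum("ij,ij->i", b, b))
    r = np.zeros(n_seg)
    ok = den > 0
    r[ok] = num[ok] / den[ok]
    if not ok.all():
        warnings.warn("zero-variance segment(s) scored as r = 0", RuntimeWarning)
    return r


# ---------------------------------------------------------------------------
# Model / Results interface


class EnvelopeDecoder:
    """Backward decoder model for one subject, band and condition.

    Built from a preprocessed recording and envelope at the common working
    rate.  ``fit(lam)`` estimates the weights on all rows; ``fit_cv()`` runs
    the full five-fold cross-validated penalty sweep (see
    :mod:`envdecode.evaluation`) and returns pooled segment correlations.

    Examples
    --------
    >>> model = EnvelopeDecoder(eeg64, env64, config)   # doctest: +SKIP
    >>> res = model.fit(lam=1.0)                        # doctest: +SKIP
    >>> print(res.summary())                            # doctest: +SKIP
    """

    def __init__(self, eeg: MultichannelRecording, envelope: Envelope,
                 config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        if eeg.fs != self.config.target_fs or envelope.fs != self.config.target_fs:
            raise ValueError(
                "EnvelopeDecoder expects inputs at the working rate "
                f"{self.config.target_fs} Hz; preprocess first "
                "(see EnvelopeDecoder.from_raw)"
            )
        if eeg.n_samples != envelope.n_samples:
            raise ValueError("EEG and envelope must be time-aligned (equal length)")
        self.eeg = eeg
        self.envelope = envelope
        self.lags = LagSpec.from_config(self.config)
        self._design: LaggedDesignMatrix | None = None

    @classmethod
    def from_raw(cls, eeg: MultichannelRecording, audio_or_env, band: BandSpec,
                 config: AnalysisConfig | None = None) -> "EnvelopeDecoder":
        """Preprocess native-rate inputs and construct the model."""
        from .preprocess import extract_envelope, preprocess_band

        config = config or AnalysisConfig()
        if isinstance(audio_or_env, Envelope):
            env_raw = audio_or_env
        else:
            env_raw = extract_envelope(audio_or_env)
        eeg64 = preprocess_band(eeg, band, config.target_fs)
        env64 = preprocess_band(env_raw, band, config.target_fs,
                                decimate_first=config.envelope_decimate_first)
        n = min(eeg64.n_samples, env64.n_samples)
        eeg64 = eeg64.copy_with(data=eeg64.data[:, :n])
        env64 = Envelope(env64.samples[:n], env64.fs, env64.band)
        return cls(eeg64, env64, config)

    @property
    def design(self) -> LaggedDesignMatrix:
        if self._design is None:
            self._design = build_lag_matrix(self.eeg, self.lags)
        return self._design

    def fit(self, lam: float) -> "DecoderResults":
        """Single-penalty fit on the full recording."""
        w = fit_ridge(self.design, self.envelope, lam,
                      band=self.envelope.band,
                      subject_id=self.eeg.subject_id,
                      condition=self.eeg.condition)
        y_hat = predict_envelope(self.design, w, fs=self.config.target_fs)
        r = segment_correlations(y_hat, self.envelope,
                                 self.config.segment_length, self.config.target_fs)
        return DecoderResults(self, w, r)

    def fit_cv(self, envelope_kind: str = "forward"):
        """Cross-validated penalty sweep; returns an EvaluationResult."""
        from .evaluation import cross_validate, evaluate_null, select_lambda

        if envelope_kind == "time_reversed":
            return evaluate_null(self.eeg, self.envelope, self.config)
        tensor = cross_validate(self.eeg, self.envelope, self.config)
        res = select_lambda(tensor, self.config.lambda_grid)
        res.band = self.envelope.band
        res.condition = self.eeg.condition
        res.subject_id = self.eeg.subject_id
        return res

    def evaluate(self):
        """Forward and time-reversed runs plus the signed-rank comparison."""
        from .evaluation import evaluate_subject

        return evaluate_subject(self.eeg, self.envelope, self.config)


@dataclass
class DecoderResults:
    """Results of a single-penalty decoder fit."""

    model: EnvelopeDecoder
    weights: DecoderWeights
    training_r: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def params(self) -> np.ndarray:
        """Fitted weights as a channels x lags array."""
        return self.weights.by_channel_lag

    def summary(self) -> str:
        w = self.weights
        lines = [
            "Backward envelope decoder (ridge)",
            "=" * 40,
            f"subject:        {w.subject_id or '-'}",
            f"condition:      {w.condition or '-'}",
            f"band:           {getattr(w.band, 'name', w.band)}",
            f"channels x lags: {w.n_channels} x {w.lags.n_lags}",
            f"lambda:         {w.lam:g}",
            f"||beta||:       {np.linalg.norm(w.beta):.4g}",
        ]
        if self.training_r.size:
            lines += [
                f"training segments: {self.training_r.size}",
                f"training mean r:   {self.training_r.mean():.4f}",
            ]
        return "\n".join(lines)

    def plot_weights(self, ax=None):
        """Heatmap of decoder weights over channels and lags."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lags_ms = self.weights.lags.lag_samples / self.weights.lags.fs * 1e3
        im = ax.imshow(self.params, aspect="auto", origin="lower",
                       extent=[lags_ms[0], lags_ms[-1], 0, self.weights.n_channels])
        ax.set_xlabel("lag (ms)")
        ax.set_ylabel("channel")
        ax.figure.colorbar(im, ax=ax, label="weight")
        return ax
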