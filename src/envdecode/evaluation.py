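"""Cross-validated penalty selection and the time-reversed null model.

The decoder is scored by five-fold cross-validation: the recording is split
into five contiguous blocks; in each iteration four blocks (~80%) estimate
the weights and the held-out block (~20%) is reconstructed.  Reconstruction
and target are cut into non-overlapping 10-second segments and one Pearson r
is recorded per segment.  A sweep over the ridge-penalty grid selects the
penalty with the largest correlation averaged over all testing folds and
segments; the segment correlations at that penalty, pooled over folds, form
the subject's performance distribution.

Chance level is estimated by running the *identical* procedure — including
the cross-validation and the penalty optimization — against the time-reversed
envelope, and the forward and null pooled distributions are compared with a
two-sided Wilcoxon signed-rank test, pairing segments by temporal index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .containers import AnalysisConfig, BandSpec, Envelope, MultichannelRecording
from .decoder import LagSpec, LaggedDesignMatrix, build_lag_matrix, segment_correlations

__all__ = [
    "EvaluationResult",
    "SubjectDetection",
    "make_folds",
    "cross_validate",
    "select_lambda",
    "evaluate_null",
    "detect_response",
    "evaluate_subject",
]


def _fold_edges(n_samples: int, n_folds: int) -> list[tuple[int, int]]:
    bounds = [round(i * n_samples / n_folds) for i in range(n_folds + 1)]
    return [(bounds[i], bounds[i + 1]) for i in range(n_folds)]


def make_folds(n_samples: int, n_folds: int = 5) -> list[tuple[np.ndarray, np.ndarray]]:
    """Contiguous, disjoint test blocks covering the recording.

    Returns ``(train_indices, test_indices)`` pairs; test blocks tile the
    index range and their sizes differ by at most one sample.
    """
    if n_samples < n_folds:
        raise ValueError(f"recording of {n_samples} samples too short for "
                         f"{n_folds} folds")
    out = []
    idx = np.arange(n_samples)
    for a, b in _fold_edges(n_samples, n_folds):
        test = idx[a:b]
        train = np.concatenate([idx[:a], idx[b:]])
        out.append((train, test))
    return out


@dataclass
class EvaluationResult:
    """Pooled cross-validated segment correlations at the selected penalty."""

    pooled_r: np.ndarray
    lambda_opt: float
    per_fold_r: list[np.ndarray]
    band: BandSpec | str | None = None
    condition: str = ""
    subject_id: str = ""
    envelope_kind: str = "forward"

    def __post_init__(self) -> None:
        self.pooled_r = np.asarray(self.pooled_r, dtype=float).ravel()
        expected = sum(len(f) for f in self.per_fold_r)
        if expected != self.pooled_r.size:
            raise ValueError("pooled_r cardinality must equal the sum of "
                             "per-fold segment counts")

    @property
    def mean_r(self) -> float:
        return float(self.pooled_r.mean())

    @property
    def sd_r(self) -> float:
        return float(self.pooled_r.std(ddof=1)) if self.pooled_r.size > 1 else 0.0

    @property
    def median_r(self) -> float:
        return float(np.median(self.pooled_r))

    def summary(self) -> str:
        band = getattr(self.band, "name", self.band)
        return "\n".join([
            f"Envelope reconstruction ({self.envelope_kind})",
            "=" * 42,
            f"subject:    {self.subject_id or '-'}",
            f"condition:  {self.condition or '-'}",
            f"band:       {band}",
            f"lambda_opt: {self.lambda_opt:g}",
            f"segments:   {self.pooled_r.size} "
            f"({len(self.per_fold_r)} folds)",
            f"mean r:     {self.mean_r:.4f}",
            f"sd r:       {self.sd_r:.4f}",
            f"median r:   {self.median_r:.4f}",
        ])

    def plot_pooled(self, ax=None, **kwargs):
        """Histogram of the pooled per-segment correlations."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.pooled_r, bins=kwargs.pop("bins", 20), **kwargs)
        ax.axvline(self.mean_r, color="k", ls="--", label=f"mean = {self.mean_r:.3f}")
        ax.set_xlabel("segment Pearson r")
        ax.set_ylabel("count")
        ax.legend()
        return ax


@dataclass
class SubjectDetection:
    """Forward-vs-null comparison for one subject / band / condition."""

    forward: EvaluationResult
    null: EvaluationResult
    p_value: float
    significant: bool
    alpha: float = 0.05

    def summary(self) -> str:
        return "\n".join([
            "Cortical response detection",
            "=" * 42,
            f"forward mean r: {self.forward.mean_r:.4f} "
            f"(lambda {self.forward.lambda_opt:g})",
            f"null mean r:    {self.null.mean_r:.4f} "
            f"(lambda {self.null.lambda_opt:g})",
            f"Wilcoxon p:     {self.p_value:.3g}",
            f"significant at alpha={self.alpha:g}: {self.significant}",
        ])


def _solve_factor(Gc: np.ndarray, lam: float):
    A = Gc + lam * np.eye(Gc.shape[0])
    try:
        return ("chol", sla.cho_factor(A, check_finite=False))
    except np.linalg.LinAlgError:
        return ("lstsq", A)


def _apply_factor(factor, B: np.ndarray) -> np.ndarray:
    kind, obj = factor
    if kind == "chol":
        return sla.cho_solve(obj, B, check_finite=False)
    return np.linalg.lstsq(obj, B, rcond=None)[0]


def _cv_tensors(design: LaggedDesignMatrix, ys: list[np.ndarray],
                cfg: AnalysisConfig) -> list[list[list[np.ndarray]]]:
    """Per-target, per-lambda, per-fold segment correlations.

    The Gram matrix of the training rows depends on the EEG only, so all
    targets (forward and time-reversed envelopes) share one factorization per
    (fold, lambda); this halves the cost of a forward + null evaluation.
    """
    X = design.X
    n, p = X.shape
    fs = cfg.target_fs
    grid = cfg.lambda_grid
    margin = int(round(0.5 * fs)) if cfg.trim_fold_margins else 0
    edges = _fold_edges(n, cfg.n_folds)
    out: list[list[list[np.ndarray]]] = [
        [[] for _ in grid] for _ in ys
    ]
    eye = np.eye(p)
    for a, b in edges:
        if cfg.valid_rows_only:
            mask = design.valid_rows.copy()
            mask[a:b] = False
            Xtr = X[mask]
            n_tr = Xtr.shape[0]
            G = Xtr.T @ Xtr
            col_sum = Xtr.sum(axis=0)
            tr_parts = None
        else:
            A1, A2 = X[:a], X[b:]
            n_tr = A1.shape[0] + A2.shape[0]
            G = A1.T @ A1
            G += A2.T @ A2
            col_sum = A1.sum(axis=0) + A2.sum(axis=0)
            tr_parts = (A1, A2)
        mu = col_sum / n_tr
        Gc = G - np.outer(mu, mu) * n_tr
        del G
        # centered cross-products for every target
        Bs = np.empty((p, len(ys)))
        y_means = np.empty(len(ys))
        for i, y in enumerate(ys):
            if cfg.valid_rows_only:
                ytr = y[mask]
                b_vec = Xtr.T @ ytr
            else:
                A1, A2 = tr_parts
                ytr_mean_sum = y[:a].sum() + y[b:].sum()
                b_vec = A1.T @ y[:a] + A2.T @ y[b:]
                ytr = None
            ybar = (ytr.mean() if ytr is not None else ytr_mean_sum / n_tr)
            Bs[:, i] = b_vec - n_tr * mu * ybar
            y_means[i] = ybar
        Xte = X[a:b]
        for il, lam in enumerate(grid):
            factor = _solve_factor(Gc, lam)
            beta = _apply_factor(factor, Bs)           # p x n_targets
            Yhat = Xte @ beta - mu @ beta + y_means    # rows x n_targets
            lo, hi = margin, Xte.shape[0] - margin
            for i, y in enumerate(ys):
                r = segment_correlations(Yhat[lo:hi, i], y[a + lo:b - margin],
                                         cfg.segment_length, fs)
                out[i][il].append(r)
        del Gc, Bs
    return out


def _assemble(per_lambda: list[list[np.ndarray]]):
    """Stack to (n_lambda, n_folds, n_segments) when fold counts agree."""
    counts = {len(r) for r in per_lambda[0]}
    if len(counts) == 1:
        return np.array([[r for r in fold_list] for fold_list in per_lambda])
    return [np.array([fold for fold in fold_list], dtype=object)
            for fold_list in per_lambda]


def cross_validate(eeg: MultichannelRecording, env: Envelope,
                   cfg: AnalysisConfig | None = None):
    """Correlation tensor (n_lambda, n_folds, segments_per_fold).

    For each penalty and fold the decoder is fitted on the training blocks
    and scored on the held-out block.  When fold segment counts are unequal
    (a non-canonical recording length) a ragged per-lambda list is returned
    instead of a 3-D array.
    """
    cfg = cfg or AnalysisConfig()
    _check_aligned(eeg, env, cfg)
    design = build_lag_matrix(eeg, LagSpec.from_config(cfg))
    tensors = _cv_tensors(design, [env.samples], cfg)
    return _assemble(tensors[0])


def select_lambda(tensor, grid: np.ndarray, **meta) -> EvaluationResult:
    """Pick the penalty maximizing the grand-mean test correlation.

    The grand mean pools every testing segment of every fold; ties break
    toward the smaller penalty (the grid is increasing and the first argmax
    wins).
    """
    grid = np.asarray(grid, dtype=float)
    if isinstance(tensor, np.ndarray) and tensor.ndim == 3:
        per_lambda = [list(tensor[i]) for i in range(tensor.shape[0])]
    else:
        per_lambda = [list(rows) for rows in tensor]
    if len(per_lambda) != grid.size:
        raise ValueError("tensor first dimension must match the lambda grid")
    means = np.array([np.mean(np.concatenate([np.asarray(f, dtype=float).ravel()
                                              for f in folds]))
                      for folds in per_lambda])
    if np.all(np.isnan(means)):
        raise ValueError("all correlations are NaN; cannot select a penalty")
    best = int(np.nanargmax(means))
    folds = [np.asarray(f, dtype=float).ravel() for f in per_lambda[best]]
    pooled = np.concatenate(folds)
    return EvaluationResult(pooled, float(grid[best]), folds, **meta)


def evaluate_null(eeg: MultichannelRecording, env: Envelope,
                  cfg: AnalysisConfig | None = None) -> EvaluationResult:
    """Chance-level evaluation against the time-reversed envelope.

    The identical pipeline — same folds, same penalty grid, independent
    penalty optimization — is run with the envelope's sample order inverted.
    """
    cfg = cfg or AnalysisConfig()
    res = cross_validate(eeg, env.time_reversed(), cfg)
    out = select_lambda(res, cfg.lambda_grid,
                        band=env.band, condition=eeg.condition,
                        subject_id=eeg.subject_id)
    out.envelope_kind = "time_reversed"
    return out


def detect_response(fwd: EvaluationResult, null: EvaluationResult,
                    alpha: float = 0.05) -> SubjectDetection:
    """Two-sided Wilcoxon signed-rank between forward and null pooled r.

    Segments are paired by temporal index (same EEG window under both
    envelope kinds).  Detection additionally requires the forward median to
    exceed the null median, so a significant *negative* difference is not
    reported as a response.
    """
    f, n = fwd.pooled_r, null.pooled_r
    if f.size != n.size:
        raise ValueError("forward and null pooled distributions must have "
                         "equal cardinality")
    diffs = f - n
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(f, n, alternative="two-sided").pvalue)
    significant = bool(p < alpha and np.median(f) > np.median(n))
    return SubjectDetection(fwd, null, p, significant, alpha)


def evaluate_subject(eeg: MultichannelRecording, env: Envelope,
                     cfg: AnalysisConfig | None = None) -> SubjectDetection:
    """Forward and time-reversed evaluations sharing one design matrix.

    Equivalent to running :func:`cross_validate` twice followed by
    :func:`detect_response`, but the training Gram matrices and their
    factorizations are computed once and reused for both envelope kinds.
    """
    cfg = cfg or AnalysisConfig()
    _check_aligned(eeg, env, cfg)
    design = build_lag_matrix(eeg, LagSpec.from_config(cfg))
    tensors = _cv_tensors(design, [env.samples, env.samples[::-1].copy()], cfg)
    meta = dict(band=env.band, condition=eeg.condition, subject_id=eeg.subject_id)
    fwd = select_lambda(_assemble(tensors[0]), cfg.lambda_grid, **meta)
    null = select_lambda(_assemble(tensors[1]), cfg.lambda_grid, **meta)
    null.envelope_kind = "time_reversed"
    return detect_response(fwd, null, cfg.alpha)


def _check_aligned(eeg: MultichannelRecording, env: Envelope,
                   cfg: AnalysisConfig) -> None:
    if eeg.fs != cfg.target_fs or env.fs != cfg.target_fs:
        raise ValueError("inputs must be preprocessed to the working rate "
                         f"{cfg.target_fs} Hz")
    if eeg.n_samples != env.n_samples:
        raise ValueError("EEG and envelope lengths differ")
    win = int(round(cfg.segment_length * cfg.target_fs))
    if eeg.n_samples < cfg.n_folds * win:
        raise ValueError("recording too short: every fold needs at least one "
                         "full scoring segment")
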