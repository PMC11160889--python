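"""Bout windowing conventions and resampled PCA over posture matrices.

Windowing rule: a bout window starts 10 frames before the detected bout start
and ends at the last frame with speed >= 4 mm/s, capped at a fixed total
length (175 frames for 700 Hz recordings; configurable).  Shorter windows are
zero-padded to the fixed length with a validity mask.

Dimensionality reduction: the covariance of flattened posture matrices is
estimated by averaging covariance matrices over random resamples of
recordings (robust to heterogeneous recording lengths), then
eigendecomposed.  The retained dimension is the smallest one reaching a
cumulative explained-variance threshold (default 0.95) unless fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort

logger = logging.getLogger(__name__)


@dataclass
class WindowConfig:
    pre_frames: int = 10
    max_frames: int = 175  # total window length cap
    speed_threshold: float = 4.0  # mm/s


@dataclass
class BoutRecord:
    """One windowed bout: fixed-length posture matrix with validity mask."""

    posture: np.ndarray  # (max_frames, n_segments), radians, zero-padded
    mask: np.ndarray  # (max_frames,), True where frames are valid
    displacement: np.ndarray | None = None  # (2,) mm
    heading: float = 0.0  # deg at bout start
    ibi: float = 0.0  # s
    fish_id: str | None = None
    bout_index: int = 0
    clamped: bool = False


@dataclass
class PCABasis:
    mean: np.ndarray  # (p,)
    components: np.ndarray  # (p, d), orthonormal columns
    eigenvalues: np.ndarray  # (p,), nonincreasing (full spectrum)
    d: int

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def window_bout(
    raw_frames: np.ndarray,
    detected_start: int,
    detected_end: int,
    speed: np.ndarray,
    cfg: WindowConfig = WindowConfig(),
    **meta,
) -> BoutRecord | None:
    """Apply the windowing rule to one detected bout.

    ``raw_frames`` is the full-recording angle time series (frames × segments)
    and ``speed`` the matching per-frame speed trace.  Returns None (with a
    logged warning) for empty windows.
    """
    clamped = False
    w0 = detected_start - cfg.pre_frames
    if w0 < 0:
        w0, clamped = 0, True
    # last frame with speed >= threshold, within [detected_start, detected_end)
    fast = np.flatnonzero(speed[detected_start:detected_end] >= cfg.speed_threshold)
    if fast.size == 0:
        logger.warning("window_bout: empty window at start=%d, skipped", detected_start)
        return None
    w1 = min(detected_start + fast[-1] + 1, w0 + cfg.max_frames)
    window = raw_frames[w0:w1]
    n_seg = raw_frames.shape[1]
    posture = np.zeros((cfg.max_frames, n_seg))
    mask = np.zeros(cfg.max_frames, dtype=bool)
    posture[: len(window)] = window
    mask[: len(window)] = True
    return BoutRecord(posture=posture, mask=mask, clamped=clamped, **meta)


def _flatten_postures(cohort: Cohort, unwrap: bool = True) -> dict[str, np.ndarray]:
    """Per-fish matrix of flattened posture bouts (n_bouts × frames·segments)."""
    out = {}
    for fid, fish in cohort.fish.items():
        post = fish.posture
        if unwrap:
            post = np.unwrap(post, axis=1)  # per tail segment along frames
        out[fid] = post.reshape(post.shape[0], -1)
    return out


def fit_resampled_pca(
    cohort: Cohort,
    n_resamples: int = 180,
    recs_per_resample: int = 25,
    seed: int = 0,
    var_threshold: float = 0.95,
    d: int | None = None,
) -> PCABasis:
    """Average covariance matrices over random resamples of recordings, then
    eigendecompose.

    Cohorts with fewer recordings than ``recs_per_resample`` are sampled with
    replacement (logged).  ``d`` fixes the retained dimension; otherwise the
    smallest dimension whose cumulative explained variance reaches
    ``var_threshold`` is kept.
    """
    rng = np.random.default_rng(seed)
    flat = _flatten_postures(cohort)
    ids = sorted(flat)
    replace = len(ids) < recs_per_resample
    if replace:
        logger.warning(
            "fit_resampled_pca: only %d recordings for resamples of %d; sampling with replacement",
            len(ids), recs_per_resample,
        )
    p = flat[ids[0]].shape[1]
    mean = np.vstack([flat[i] for i in ids]).mean(axis=0)
    cov = np.zeros((p, p))
    for _ in range(n_resamples):
        pick = rng.choice(ids, size=recs_per_resample, replace=replace)
        X = np.vstack([flat[i] for i in pick]) - mean
        cov += X.T @ X / len(X)
    cov /= n_resamples
    cov = (cov + cov.T) / 2.0
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0 or not np.isfinite(evals[0]):
        raise ValueError("degenerate covariance: data has no variance")
    evals = np.clip(evals, 0.0, None)
    if d is None:
        frac = np.cumsum(evals) / evals.sum()
        d = int(np.searchsorted(frac, var_threshold) + 1)
    return PCABasis(mean=mean, components=evecs[:, :d], eigenvalues=evals, d=d)


def project_bouts(bouts: np.ndarray, basis: PCABasis) -> np.ndarray:
    """Project flattened (or (n, frames, segments)) posture bouts onto the basis."""
    X = np.asarray(bouts, dtype=float)
    if X.ndim == 3:
        X = X.reshape(X.shape[0], -1)
    if X.shape[1] != basis.mean.shape[0]:
        raise ValueError(
            f"dimension mismatch: bouts have {X.shape[1]} features, basis {basis.mean.shape[0]}"
        )
    return (X - basis.mean) @ basis.components


def project_cohort(cohort: Cohort, basis: PCABasis, unwrap: bool = True) -> dict[str, np.ndarray]:
    """Per-fish bout coefficient matrices (n_bouts × d)."""
    flat = _flatten_postures(cohort, unwrap=unwrap)
    return {fid: (X - basis.mean) @ basis.components for fid, X in flat.items()}
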