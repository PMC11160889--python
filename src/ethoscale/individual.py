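"""Per-fish coarse-grained Markov models and their summaries.

A fish's phenotype at strategy resolution q is the row-stochastic q x q
matrix estimated from its own strategy-labeled bout sequence at lag 1.
Simulating that matrix from the fish's observed start state gives
model-predicted dwell (run-length) statistics to compare against the data;
kinematic summaries per microstate interpret the long-lived spectral modes,
and soft group posteriors turn per-fish scalars into phenotypic-group
expectations via Bayes' rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FishModel",
    "DwellSummary",
    "fit_fish",
    "simulate_fish",
    "run_lengths",
    "dwell_statistics",
    "mode_kinematics",
    "group_expectation",
]


@dataclass
class FishModel:
    fish_id: str
    q: int
    T: np.ndarray  # (q, q) row-stochastic, lag-1 strategy steps
    sequence_length: int
    start_state: int
    context: str = "default"
    flags: list[str] = field(default_factory=list)


@dataclass
class DwellSummary:
    runs: dict[int, np.ndarray]  # strategy -> run lengths (bouts)
    mean_length: dict[int, float]
    mean_ci: dict[int, tuple[float, float]]
    median_dwell_s: dict[int, float] | None = None
    source: str = "data"


def fit_fish(labels: np.ndarray, q: int, fish_id: str = "", context: str = "default",
             lag: int = 1) -> FishModel:
    """Lag-1 (configurable) count matrix over a fish's strategy labels, row-normalized.

    Rows never visited become uniform (flagged); a single-strategy sequence
    yields a flagged degenerate, identity-like model.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if len(labels) < q:
        raise ValueError(f"sequence of length {len(labels)} too short for q={q}")
    C = np.zeros((q, q))
    np.add.at(C, (labels[:-lag], labels[lag:]), 1.0)
    rowsum = C.sum(axis=1)
    flags = []
    T = np.empty_like(C)
    zero = rowsum == 0
    T[zero] = 1.0 / q
    T[~zero] = C[~zero] / rowsum[~zero, None]
    if zero.any():
        flags.append(f"uniform-imputed {int(zero.sum())} unvisited rows")
    absorbing = np.flatnonzero((np.diag(T) == 1.0) & ~zero)
    if absorbing.size:
        flags.append(f"absorbing rows {absorbing.tolist()}")
    if len(np.unique(labels)) == 1:
        flags.append("degenerate single-strategy sequence")
    return FishModel(fish_id=fish_id, q=q, T=T, sequence_length=len(labels),
                     start_state=int(labels[0]), context=context, flags=flags)


def simulate_fish(model: FishModel, length: int, n_reps: int = 100,
                  seed: int = 0) -> np.ndarray:
    """n_reps strategy sequences evolved from the fish's observed start state."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(model.T, axis=1)
    out = np.empty((n_reps, length), dtype=np.int64)
    out[:, 0] = model.start_state
    u = rng.random((n_reps, length - 1))
    for t in range(1, length):
        rows = cum[out[:, t - 1]]
        out[:, t] = (u[:, t - 1][:, None] >= rows).sum(axis=1)
    return out


def run_lengths(seq: np.ndarray) -> dict[int, np.ndarray]:
    """Run-length encoding: strategy -> array of consecutive-run lengths."""
    seq = np.asarray(seq)
    if seq.size == 0:
        return {}
    edges = np.flatnonzero(np.diff(seq) != 0) + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [len(seq)]])
    out: dict[int, list[int]] = {}
    for s, e in zip(starts, ends):
        out.setdefault(int(seq[s]), []).append(e - s)
    return {k: np.asarray(v) for k, v in out.items()}


def dwell_statistics(
    sequences: np.ndarray | list[np.ndarray],
    bout_times: np.ndarray | list[np.ndarray] | None = None,
    n_boot: int = 100,
    ci: float = 95.0,
    seed: int = 0,
    source: str = "data",
) -> DwellSummary:
    """Run-length statistics per strategy with bootstrap CIs.

    ``bout_times`` (matching inter-bout-interval streams) adds the median
    dwell in seconds: the summed ibi over each run.
    """
    if isinstance(sequences, np.ndarray) and sequences.ndim == 1:
        sequences = [sequences]
    if bout_times is not None and isinstance(bout_times, np.ndarray) and bout_times.ndim == 1:
        bout_times = [bout_times]
    rng = np.random.default_rng(seed)
    runs: dict[int, list[np.ndarray]] = {}
    dwell_s: dict[int, list[float]] = {}
    for si, seq in enumerate(sequences):
        seq = np.asarray(seq)
        edges = np.flatnonzero(np.diff(seq) != 0) + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [len(seq)]])
        for s, e in zip(starts, ends):
            runs.setdefault(int(seq[s]), []).append(np.array([e - s]))
            if bout_times is not None:
                dwell_s.setdefault(int(seq[s]), []).append(float(np.sum(bout_times[si][s:e])))
    out_runs = {k: np.concatenate(v) for k, v in runs.items()}
    mean_length, mean_ci = {}, {}
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    for k, r in out_runs.items():
        mean_length[k] = float(r.mean())
        boots = rng.choice(r, size=(n_boot, len(r))).mean(axis=1)
        mean_ci[k] = (float(np.percentile(boots, lo_q)), float(np.percentile(boots, hi_q)))
    med = ({k: float(np.median(v)) for k, v in dwell_s.items()}
           if bout_times is not None else None)
    return DwellSummary(runs=out_runs, mean_length=mean_length, mean_ci=mean_ci,
                        median_dwell_s=med, source=source)


def mode_kinematics(partition_labels: np.ndarray, window_index, cohort) -> pd.DataFrame:
    """Per-microstate mean kinematics over the member K-bout windows.

    Columns: mean |heading change| (deg), mean speed (mm/s), left/right ratio
    (fraction of positive heading changes), median ibi (s).  ``window_index``
    pairs each window with its (fish_id, start bout); the window's kinematics
    are the means over its K bouts.
    """
    heading_change = {fid: f.heading_change() for fid, f in cohort.fish.items()}
    speed = {fid: f.speed() for fid, f in cohort.fish.items()}
    ibi = {fid: f.ibi for fid, f in cohort.fish.items()}
    rows: dict[int, list[list[float]]] = {}
    labels = np.asarray(partition_labels)
    # infer K from window counts: windows per fish = n_bouts - K + 1
    n_win: dict[str, int] = {}
    for fid, _ in window_index:
        n_win[fid] = n_win.get(fid, 0) + 1
    for lab, (fid, t0) in zip(labels, window_index):
        dh = heading_change[fid]
        K = len(ibi[fid]) - n_win[fid] + 1
        sl = slice(t0, min(t0 + K, len(dh)))
        d = dh[sl]
        rows.setdefault(int(lab), []).append([
            float(np.mean(np.abs(d))) if d.size else 0.0,
            float(np.mean(speed[fid][t0:t0 + K])),
            float(np.mean(d > 0)) if d.size else 0.5,
            float(np.median(ibi[fid][t0:t0 + K])),
        ])
    recs = []
    for lab in sorted(rows):
        arr = np.asarray(rows[lab])
        recs.append({
            "microstate": lab,
            "mean_abs_heading_change": arr[:, 0].mean(),
            "mean_speed": arr[:, 1].mean(),
            "lr_ratio": arr[:, 2].mean(),
            "median_ibi": float(np.median(arr[:, 3])),
            "n_windows": len(arr),
        })
    return pd.DataFrame(recs).set_index("microstate")


def group_expectation(
    values: np.ndarray,
    posterior: np.ndarray,
    priors: np.ndarray | None = None,
    n_boot: int = 200,
    seed: int = 0,
):
    """Per-group expectation of a per-fish scalar under soft group posteriors.

    With a uniform prior over fish, Bayes' rule gives P(f|G) proportional to
    P(G|f); the expectation is sum_f values_f P(f|G), with importance-sampling
    errorbars from repeated draws f ~ P(f|G).  Groups with zero posterior
    mass are reported as NaN.
    """
    values = np.asarray(values, dtype=float)
    post = np.asarray(posterior, dtype=float)
    if not np.allclose(post.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("posterior rows must sum to 1 over groups")
    prior_f = (np.ones(post.shape[0]) if priors is None else np.asarray(priors, dtype=float))
    w = post * prior_f[:, None]
    mass = w.sum(axis=0)
    rng = np.random.default_rng(seed)
    n_groups = post.shape[1]
    means = np.full(n_groups, np.nan)
    errs = np.full(n_groups, np.nan)
    for g in range(n_groups):
        if mass[g] <= 0:
            logger.warning("group_expectation: group %d has zero posterior mass", g)
            continue
        p = w[:, g] / mass[g]
        means[g] = float(values @ p)
        draws = rng.choice(values, size=(n_boot, len(values)), p=p).mean(axis=1)
        errs[g] = float(draws.std())
    return means, errs
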