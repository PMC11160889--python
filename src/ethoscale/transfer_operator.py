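"""Transition-matrix estimation and transfer-operator spectral analysis.

Transitions are counted at lag tau within contiguous stretches of each fish's
symbol stream, the balanced ensemble operator averages row-normalized
per-seed matrices over context-balanced resamples, and spectra are taken from
the reversibilized operator (additive symmetrization with respect to the
invariant density pi), whose eigenvalues are real.  Implied timescales follow
t_imp = -tau / ln(lambda); a shuffle null gives the noise floor for the
leading non-trivial eigenvalue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .statespace import SymbolSequence

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionMatrix",
    "SpectralModes",
    "count_transitions",
    "ensemble_operator",
    "reversibilize",
    "spectrum",
    "noise_floor",
]


def _largest_component(P: np.ndarray) -> np.ndarray:
    """Indices of the largest strongly-connected communicating component."""
    n_comp, labels = connected_components(P > 0, directed=True, connection="strong")
    if n_comp == 1:
        return np.arange(P.shape[0])
    sizes = np.bincount(labels)
    return np.flatnonzero(labels == np.argmax(sizes))


def _stationary(P: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000) -> np.ndarray:
    """Invariant density as the leading left eigenvector (power iteration)."""
    n = P.shape[0]
    pi = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        new = pi @ P
        new /= new.sum()
        if np.abs(new - pi).max() < tol:
            return new
        pi = new
    logger.warning("stationary distribution: power iteration hit max_iter")
    return pi


@dataclass
class TransitionMatrix:
    P: np.ndarray  # (N, N) row-stochastic
    pi: np.ndarray  # invariant density
    tau: int
    counts: np.ndarray | None = None
    state_ids: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.state_ids is None:
            self.state_ids = np.arange(self.P.shape[0])

    @property
    def N(self) -> int:
        return self.P.shape[0]

    @classmethod
    def from_P(cls, P, tau: int = 1, **kw) -> "TransitionMatrix":
        P = np.asarray(P, dtype=float)
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows must sum to 1")
        return cls(P=P, pi=_stationary(P), tau=tau, **kw)


@dataclass
class SpectralModes:
    lambdas: np.ndarray  # real eigenvalues, descending; lambdas[0] == 1
    phis: np.ndarray  # (N, n_modes) right eigenvectors of the reversibilized operator
    timescales: np.ndarray  # implied timescales for 0 < lambda_k < 1 (NaN otherwise)
    tau: int
    noise_floor: np.ndarray | None = None


def count_transitions(
    seqs: list[SymbolSequence] | SymbolSequence, tau: int, N: int,
) -> TransitionMatrix:
    """Count lag-tau transitions over contiguous symbol pairs and row-normalize.

    Zero-count rows are replaced by the uniform row (flagged): the chain stays
    stochastic, and such states carry no invariant mass in practice.
    """
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    if isinstance(seqs, SymbolSequence):
        seqs = [seqs]
    if not seqs or all(len(s.symbols) == 0 for s in seqs):
        raise ValueError("no symbol sequences given")
    C = np.zeros((N, N))
    for s in seqs:
        pairs = s.contiguous_pairs(tau)
        if len(pairs):
            np.add.at(C, (pairs[:, 0], pairs[:, 1]), 1.0)
    rowsum = C.sum(axis=1)
    flags = []
    P = np.empty_like(C)
    zero = rowsum == 0
    if zero.any():
        flags.append(f"uniform-imputed {int(zero.sum())} zero-count rows")
    P[zero] = 1.0 / N
    P[~zero] = C[~zero] / rowsum[~zero, None]
    return TransitionMatrix(P=P, pi=_stationary(P), tau=tau, counts=C, flags=flags)


def ensemble_operator(
    seqs: list[SymbolSequence],
    contexts: dict[str, str],
    N: int,
    per_context_n: int,
    n_seeds: int,
    tau: int,
    seed: int = 0,
) -> TransitionMatrix:
    """Context-balanced ensemble operator.

    Per seed, fish are drawn per context until ~per_context_n symbols are
    gathered, a lag-tau matrix is estimated from them, and the row-normalized
    matrices are averaged across seeds and row-normalized again.
    """
    rng = np.random.default_rng(seed)
    by_ctx: dict[str, list[SymbolSequence]] = {}
    for s in seqs:
        by_ctx.setdefault(contexts.get(s.fish_id, "default"), []).append(s)
    for ctx, group in by_ctx.items():
        if sum(len(s.symbols) for s in group) < per_context_n:
            logger.warning("ensemble_operator: context %r has fewer than %d symbols; "
                           "sampling with replacement", ctx, per_context_n)
    acc = np.zeros((N, N))
    for _ in range(n_seeds):
        chosen: list[SymbolSequence] = []
        for ctx, group in by_ctx.items():
            order = rng.permutation(len(group))
            total, i = 0, 0
            while total < per_context_n:
                s = group[order[i % len(order)]]
                chosen.append(s)
                total += len(s.symbols)
                i += 1
        acc += count_transitions(chosen, tau=tau, N=N).P
    P = acc / n_seeds
    P /= P.sum(axis=1, keepdims=True)
    return TransitionMatrix(P=P, pi=_stationary(P), tau=tau)


def reversibilize(T: TransitionMatrix, pi_tol: float = 1e-12) -> TransitionMatrix:
    """Additive reversibilization P_rev = (P + diag(pi)^-1 P^T diag(pi)) / 2.

    States with vanishing invariant mass are dropped first (flagged); the
    result satisfies detailed balance with respect to pi.
    """
    P, pi = T.P, T.pi
    keep = np.flatnonzero(pi > pi_tol)
    flags = list(T.flags)
    if len(keep) < len(pi):
        flags.append(f"dropped {len(pi) - len(keep)} states with pi ~ 0")
        P = P[np.ix_(keep, keep)]
        P = P / P.sum(axis=1, keepdims=True)
        pi = _stationary(P)
    Prev = 0.5 * (P + (P.T * pi[None, :]) / pi[:, None])
    return TransitionMatrix(P=Prev, pi=pi, tau=T.tau, state_ids=T.state_ids[keep], flags=flags)


def spectrum(T_rev: TransitionMatrix, tau: int | None = None,
             imag_tol: float = 1e-6) -> SpectralModes:
    """Eigen-decomposition of a reversible operator via its symmetric conjugate.

    Eigenvectors are sign-fixed so each one's largest-magnitude entry is
    positive; implied timescales t_imp = -tau/ln(lambda) are reported for
    0 < lambda < 1.
    """
    tau = T_rev.tau if tau is None else tau
    P, pi = T_rev.P, T_rev.pi
    sq = np.sqrt(pi)
    S = (sq[:, None] * P) / sq[None, :]
    asym = np.abs(S - S.T).max()
    if asym > imag_tol:
        raise np.linalg.LinAlgError(
            f"operator is not reversible (symmetrized residue {asym:.2e})")
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    phis = evecs / sq[:, None]
    # sign convention: largest-magnitude entry positive
    idx = np.argmax(np.abs(phis), axis=0)
    phis *= np.where(phis[idx, np.arange(phis.shape[1])] < 0, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        ts = np.where((evals > 0) & (evals < 1), -tau / np.log(np.clip(evals, 1e-300, None)), np.nan)
    return SpectralModes(lambdas=evals, phis=phis, timescales=ts, tau=tau)


def noise_floor(
    seqs: list[SymbolSequence], tau: int, N: int, n_shuffles: int, seed: int = 0,
) -> np.ndarray:
    """Distribution of the largest non-trivial eigenvalue after within-fish shuffling."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = [
            SymbolSequence(fish_id=s.fish_id, symbols=rng.permutation(s.symbols),
                           breaks=s.breaks)
            for s in seqs
        ]
        T = count_transitions(shuffled, tau=tau, N=N)
        modes = spectrum(reversibilize(T))
        out[k] = modes.lambdas[1] if len(modes.lambdas) > 1 else np.nan
    return out
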