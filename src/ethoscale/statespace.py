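"""Maximally predictive state spaces from bout coefficient streams.

Bout coefficients are delay-embedded into overlapping K-bout windows (never
spanning two fish or recordings), the window space is partitioned into N
microstates with k-means++, and (K*, N*) is chosen from the short-time
entropy rate h of the resulting Markov chain: K* is the smallest K at which
the forward difference of h in K enters the bootstrap noise band (the entropy
rate stops decreasing), N* the N that maximizes h at K* (the peak before
finite-size effects suppress it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "DelayEmbedding",
    "Partition",
    "SymbolSequence",
    "delay_embed",
    "partition_microstates",
    "entropy_rate",
    "select_K_N",
]


@dataclass
class DelayEmbedding:
    K: int
    windows: np.ndarray  # (n_windows, d*K) across all fish
    index: list[tuple[str, int]]  # (fish_id, start bout) per window
    fish_slices: dict[str, slice] = field(default_factory=dict)


@dataclass
class Partition:
    N: int
    centroids: np.ndarray  # (N, d*K)
    labels: np.ndarray  # microstate id per window
    seed: int
    reduced: bool = False  # True when N was reduced to the distinct-point count


@dataclass
class SymbolSequence:
    fish_id: str
    symbols: np.ndarray  # ordered microstate ids
    breaks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    """Positions b such that the pair (symbols[b-1], symbols[b]) is not contiguous."""

    def contiguous_pairs(self, tau: int = 1) -> np.ndarray:
        """(n_pairs, 2) array of (s_t, s_{t+tau}) pairs not crossing a break."""
        n = len(self.symbols)
        if n <= tau:
            return np.empty((0, 2), dtype=np.int64)
        ok = np.ones(n - tau, dtype=bool)
        for b in self.breaks:
            ok[max(0, b - tau): b] = False
        return np.stack([self.symbols[:-tau][ok], self.symbols[tau:][ok]], axis=1)


def delay_embed(coeffs: dict[str, np.ndarray], K: int) -> DelayEmbedding:
    """Stack K consecutive bouts into overlapping windows, per fish."""
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    blocks, index, slices = [], [], {}
    pos = 0
    for fid in sorted(coeffs):
        X = np.atleast_2d(np.asarray(coeffs[fid], dtype=float))
        if X.ndim == 2 and X.shape[0] < K:
            logger.warning("delay_embed: fish %s has %d < K=%d bouts, dropped", fid, X.shape[0], K)
            continue
        l, d = X.shape
        win = sliding_window_view(X, (K, d)).reshape(l - K + 1, K * d)
        blocks.append(win)
        index.extend((fid, t) for t in range(l - K + 1))
        slices[fid] = slice(pos, pos + len(win))
        pos += len(win)
    if not blocks:
        raise ValueError("no fish long enough for the requested K")
    return DelayEmbedding(K=K, windows=np.vstack(blocks), index=index, fish_slices=slices)


def partition_microstates(
    embedding: DelayEmbedding, N: int, seed: int = 0, n_init: int = 10,
) -> Partition:
    """k-means++ partition of the window space into N microstates.

    If the embedding holds fewer distinct windows than N (exact symbolic
    fixtures), N is reduced to the distinct count and flagged.
    """
    X = embedding.windows
    if N < 1 or N > len(X):
        raise ValueError(f"invalid N={N} for {len(X)} windows")
    uniq, inv = np.unique(X, axis=0, return_inverse=True)
    reduced = False
    if len(uniq) <= N:
        if len(uniq) < N:
            logger.warning(
                "partition_microstates: %d distinct windows < N=%d; using N=%d",
                len(uniq), N, len(uniq),
            )
            reduced = True
        return Partition(N=len(uniq), centroids=uniq, labels=inv.astype(np.int64),
                         seed=seed, reduced=reduced)
    km = KMeans(n_clusters=N, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return Partition(N=N, centroids=km.cluster_centers_, labels=labels.astype(np.int64), seed=seed)


def symbol_sequences(embedding: DelayEmbedding, partition: Partition) -> list[SymbolSequence]:
    """Per-fish microstate label streams from a fitted partition."""
    return [
        SymbolSequence(fish_id=fid, symbols=partition.labels[sl])
        for fid, sl in embedding.fish_slices.items()
    ]


def entropy_rate(T, bias_correction: bool = False) -> float:
    """Short-time entropy rate h = -sum_ij pi_i T_ij log T_ij (nats per bout).

    For reducible chains the invariant density of the largest communicating
    component is used (flagged via log).  0 log 0 := 0.

    ``bias_correction`` applies the Miller-Madow correction per row,
    pi_i (m_i - 1) / (2 n_i) with m_i the observed branching and n_i the row
    count, which removes the leading finite-sample downward bias; it requires
    a count-bearing transition matrix and is used during model selection so
    that h(K) surfaces at different state counts are comparable.
    """
    from .transfer_operator import TransitionMatrix, _stationary, _largest_component

    correction = 0.0
    if isinstance(T, TransitionMatrix):
        P, pi = T.P, T.pi
        if bias_correction:
            if T.counts is None:
                raise ValueError("bias correction requires transition counts")
            n_i = T.counts.sum(axis=1)
            m_i = (T.counts > 0).sum(axis=1)
            valid = n_i > 0
            correction = float(np.sum(
                pi[valid] * (m_i[valid] - 1) / (2.0 * n_i[valid])))
    else:
        P = np.asarray(T, dtype=float)
        comp = _largest_component(P)
        if len(comp) < P.shape[0]:
            logger.warning("entropy_rate: reducible chain, using largest communicating component")
            P = P[np.ix_(comp, comp)]
            P = P / P.sum(axis=1, keepdims=True)
        pi = _stationary(P)
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
    return float(-np.sum(pi[:, None] * P * logP)) + correction


def _sample_fish(
    coeffs: dict[str, np.ndarray], contexts: dict[str, str],
    bouts_per_context: int, rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Context-balanced fish resample totalling ~bouts_per_context bouts each."""
    by_ctx: dict[str, list[str]] = {}
    for fid in coeffs:
        by_ctx.setdefault(contexts.get(fid, "default"), []).append(fid)
    chosen: set[str] = set()
    for ctx, fids in by_ctx.items():
        order = rng.permutation(fids)
        total, i = 0, 0
        while total < bouts_per_context and i < 10 * len(order):
            fid = order[i % len(order)]
            chosen.add(fid)
            total += len(coeffs[fid])
            i += 1
    return {fid: coeffs[fid] for fid in chosen}


def _estimate_h(
    sub: dict[str, np.ndarray], K: int, N: int, seed: int, n_init: int = 3,
) -> float:
    """h(K, N) on one fish resample (Miller-Madow corrected)."""
    from .transfer_operator import count_transitions

    emb_s = delay_embed(sub, K)
    part = partition_microstates(emb_s, min(N, len(emb_s.windows)), seed=seed,
                                 n_init=n_init)
    seqs = symbol_sequences(emb_s, part)
    T = count_transitions(seqs, tau=1, N=part.N)
    return entropy_rate(T, bias_correction=True)


def select_K_N(
    coeffs: dict[str, np.ndarray],
    contexts: dict[str, str] | None,
    K_grid,
    N_grid,
    bouts_per_context: int = 7500,
    n_seeds: int = 10,
    seed: int = 0,
    n_init: int = 3,
):
    """Entropy-rate model selection over a (K, N) grid.

    Returns ``(K_star, N_star, surface)`` where ``surface`` is a dict
    ``(K, N) -> (mean, lo, hi)`` of the bootstrap distribution of h.  Each
    bootstrap resample of fish is evaluated at every grid point (paired
    design, which stabilizes the h(K) curve).  K* is the smallest K whose
    |mean forward difference h(K+1) - h(K)| (averaged over the N grid) falls
    inside the bootstrap noise band of the h estimates themselves (mean 95%
    CI half-width of h at K and K+1); N* maximizes mean h at K*.
    """
    K_grid, N_grid = list(K_grid), list(N_grid)
    if not K_grid or not N_grid:
        raise ValueError("K_grid and N_grid must be nonempty")
    if contexts is None:
        contexts = {fid: "default" for fid in coeffs}
    rng = np.random.default_rng(seed)
    samples: dict[tuple[int, int], np.ndarray] = {
        (K, N): np.empty(n_seeds) for K in K_grid for N in N_grid
    }
    for s in range(n_seeds):
        sub = _sample_fish(coeffs, contexts, bouts_per_context, rng)
        km_seed = int(rng.integers(2**31))
        for K in K_grid:
            for N in N_grid:
                samples[(K, N)][s] = _estimate_h(sub, K, N, seed=km_seed, n_init=n_init)
    surface = {
        kn: (float(hs.mean()), float(np.percentile(hs, 2.5)),
             float(np.percentile(hs, 97.5)))
        for kn, hs in samples.items()
    }
    def _half_width(K):
        # 1.96 sigma of the bootstrap h distribution, averaged over the N grid
        return float(np.mean([1.96 * samples[(K, N)].std(ddof=1) for N in N_grid]))

    K_star = None
    for i, K in enumerate(K_grid[:-1]):
        K1 = K_grid[i + 1]
        diff = np.mean([samples[(K1, N)].mean() - samples[(K, N)].mean()
                        for N in N_grid])
        if abs(diff) <= max(_half_width(K), _half_width(K1)):
            K_star = K
            break
    if K_star is None:
        logger.warning("select_K_N: h(K) did not plateau over the grid; returning grid max")
        K_star = K_grid[-1]
    N_star = max(N_grid, key=lambda N: surface[(K_star, N)][0])
    return K_star, N_star, surface
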