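"""Metastable motor strategies by spectral coarse-graining of the operator.

The coherence of a microstate set S is the fraction of its invariant-measure-
weighted probability that remains in S after one application of the lag-tau
operator.  A two-way cut thresholds the leading non-trivial eigenvector phi_1
at the value maximizing the minimum coherence of the two sides; deeper cuts
(q-way) run invariant-measure-weighted k-means on rank-normalized,
kinetically rescaled eigenvectors psi_k.  Repeating over an ascending list of
q values yields a nested hierarchy of Markov models of the dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .transfer_operator import TransitionMatrix, reversibilize, spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "MacroSet",
    "CoarseGraining",
    "coherence",
    "two_way_cut",
    "transform_eigvector",
    "kinetic_map",
    "q_way_cut",
    "build_hierarchy",
]


@dataclass
class MacroSet:
    members: np.ndarray  # microstate indices
    coherence: float


@dataclass
class CoarseGraining:
    q: int
    assignment: np.ndarray  # microstate -> strategy in [0, q)
    thresholds: dict[int, float] = field(default_factory=dict)  # eigvec index -> phi_kc
    transformed_eigs: np.ndarray | None = None  # (N, n_modes) psi matrix
    labels_meaning: dict[int, str] | None = None
    strategy_coherence: np.ndarray | None = None


def coherence(T, pi: np.ndarray | None = None, S=None, n_steps: int = 1) -> float:
    """chi(S) = sum_{i,j in S} pi_i T_ij / sum_{i in S} pi_i, in [0, 1].

    ``T`` is the operator at the lag of interest; ``n_steps`` applies a matrix
    power for evaluating coherence at a multiple of that lag.
    """
    if isinstance(T, TransitionMatrix):
        P = T.P
        pi = T.pi if pi is None else pi
    else:
        P = np.asarray(T, dtype=float)
        if pi is None:
            raise ValueError("pi is required when T is a bare matrix")
    if n_steps != 1:
        P = np.linalg.matrix_power(P, n_steps)
    S = np.asarray(S)
    if S.dtype == bool:
        S = np.flatnonzero(S)
    mass = pi[S].sum()
    if S.size == 0 or mass <= 0:
        raise ValueError("coherence undefined for a set with no invariant mass")
    return float(np.sum(pi[S, None] * P[np.ix_(S, S)]) / mass)


def two_way_cut(phi: np.ndarray, T, pi: np.ndarray | None = None, n_steps: int = 1):
    """Optimal metastable 2-partition along an eigenvector.

    Scans all N-1 midpoint thresholds of the sorted phi values and returns
    ``(phi_c, S_plus, S_minus, chi_star)`` maximizing
    min(chi(S+), chi(S-)); S+ = {phi >= phi_c}.  Ties break toward the more
    balanced invariant-mass split.
    """
    if isinstance(T, TransitionMatrix):
        P = T.P
        pi = T.pi if pi is None else pi
    else:
        P = np.asarray(T, dtype=float)
    if n_steps != 1:
        P = np.linalg.matrix_power(P, n_steps)
    phi = np.asarray(phi, dtype=float)
    if np.ptp(phi) == 0:
        raise ValueError("two_way_cut requires a non-constant eigenvector")
    n = len(phi)
    order = np.argsort(phi)  # ascending; threshold moves states into S-
    F = pi[:, None] * P  # pi-weighted flow
    # start with S- empty, S+ everything; move states across in phi order
    mass_m, flow_mm = 0.0, 0.0
    mass_p, flow_pp = float(pi.sum()), float(F.sum())
    in_minus = np.zeros(n, dtype=bool)
    best = (-1.0, -1.0, 0)  # (chi_star, balance, cut position)
    uniq_ok = np.diff(phi[order]) > 0
    for k in range(n - 1):
        i = order[k]
        cross = F[i, in_minus].sum() + F[in_minus, i].sum()
        flow_mm += cross + F[i, i]
        flow_pp -= (F[i, :].sum() + F[:, i].sum() - F[i, i] - cross)
        in_minus[i] = True
        mass_m += pi[i]
        mass_p -= pi[i]
        if not uniq_ok[k]:  # threshold must separate distinct phi values
            continue
        if mass_m <= 0 or mass_p <= 0:
            continue
        chi = min(flow_mm / mass_m, flow_pp / mass_p)
        balance = -abs(mass_m - mass_p)
        if (chi, balance) > best[:2]:
            best = (chi, balance, k)
    if best[0] < 0:
        raise ValueError("no threshold produces two nonempty sets")
    k = best[2]
    phi_c = 0.5 * (phi[order[k]] + phi[order[k + 1]])
    S_minus = np.sort(order[: k + 1])
    S_plus = np.sort(order[k + 1:])
    return float(phi_c), S_plus, S_minus, float(best[0])


def transform_eigvector(phi: np.ndarray, phi_c: float) -> np.ndarray:
    """Center an eigenvector at its optimal cut and rank-space each side.

    After subtracting phi_c, negative entries are replaced by equal spacing
    on [-1, 0) (rank order preserved) and positive entries on (0, 1]; entries
    exactly at the cut map to 0.  The result is invariant to monotone
    transformations of phi.
    """
    phi = np.asarray(phi, dtype=float)
    if np.ptp(phi) == 0:
        raise ValueError("cannot transform a constant eigenvector")
    x = phi - phi_c
    out = np.zeros_like(x)
    neg, pos = np.flatnonzero(x < 0), np.flatnonzero(x > 0)
    if neg.size:
        ranks = np.empty(neg.size, dtype=int)
        ranks[np.argsort(x[neg])] = np.arange(neg.size)  # 0 = most negative
        out[neg] = -(neg.size - ranks) / neg.size
    if pos.size:
        ranks = np.empty(pos.size, dtype=int)
        ranks[np.argsort(x[pos])] = np.arange(pos.size)
        out[pos] = (ranks + 1) / pos.size
    return out


def kinetic_map(
    phi_transformed: np.ndarray,
    lambdas: np.ndarray | float,
    tau_star: int,
    variant: str = "linear",
    cap_factor: float = 10.0,
) -> np.ndarray:
    """Scale transformed eigenvectors by timescale-derived weights.

    Default weight for mode k: -tau*/(2 ln lambda_k) (the ``sqrt`` variant
    takes its square root); slower modes (lambda closer to 1) thus dominate
    Euclidean distance.  Weights diverging as lambda -> 1 are capped at
    ``cap_factor`` times the largest finite weight; modes with lambda <= 0 or
    >= 1 are excluded (NaN column) with a warning.
    """
    phi = np.atleast_2d(np.asarray(phi_transformed, dtype=float).T).T  # (N, m)
    lams = np.atleast_1d(np.asarray(lambdas, dtype=float))
    ok = (lams > 0) & (lams < 1)
    if not ok.all():
        logger.warning("kinetic_map: excluding %d modes with lambda outside (0, 1)",
                       int((~ok).sum()))
    with np.errstate(divide="ignore"):
        scale = np.where(ok, -tau_star / (2.0 * np.log(np.where(ok, lams, 0.5))), np.nan)
    if variant == "sqrt":
        scale = np.sqrt(scale)
    elif variant != "linear":
        raise ValueError(f"unknown kinetic map variant {variant!r}")
    finite = np.isfinite(scale) & (scale > 0)
    if finite.sum() > 1:
        top = np.sort(scale[finite])[::-1]
        cap = cap_factor * top[1]  # relative to the next-slowest mode
        if top[0] > cap:
            scale = np.minimum(scale, cap)
    psi = phi * scale[None, :]
    return psi if np.asarray(phi_transformed).ndim > 1 else psi[:, 0]


def q_way_cut(
    psi_matrix: np.ndarray, pi: np.ndarray, q: int, seed: int = 0, n_init: int = 50,
) -> CoarseGraining:
    """Invariant-measure-weighted k-means over microstates in psi space.

    For q = 2 the assignment is the sign of the first transformed eigenvector,
    which by construction equals the coherence-optimal threshold cut.
    """
    psi = np.atleast_2d(np.asarray(psi_matrix, dtype=float).T).T
    N = psi.shape[0]
    if q < 2 or q > N:
        raise ValueError(f"invalid q={q} for N={N} microstates")
    if q == 2:
        assignment = (psi[:, 0] < 0).astype(np.int64)  # 0: S+, 1: S-
        return CoarseGraining(q=2, assignment=assignment, transformed_eigs=psi)
    km = KMeans(n_clusters=q, init="k-means++", n_init=n_init, random_state=seed)
    assignment = km.fit_predict(psi, sample_weight=pi)
    return CoarseGraining(q=q, assignment=assignment.astype(np.int64), transformed_eigs=psi)


def build_hierarchy(
    T_ensemble: TransitionMatrix,
    tau_star: int,
    q_list=(2, 4, 7),
    seed: int = 0,
    kinetic_variant: str = "linear",
) -> dict[int, CoarseGraining]:
    """Nested coarse-grainings over an ascending list of strategy counts q.

    Each eigenvector of the reversibilized ensemble operator is cut at its
    coherence-optimal threshold, rank-normalized, and kinetically rescaled;
    q strategies come from a pi-weighted k-means on the first ceil(log2 q)
    such modes.  Per-strategy coherence is attached to every level.
    """
    q_list = sorted(q_list)
    if q_list[0] < 2:
        raise ValueError("q must be >= 2")
    Trev = reversibilize(T_ensemble)
    modes = spectrum(Trev, tau=tau_star)
    n_modes = max(int(np.ceil(np.log2(q))) for q in q_list)
    psi_cols, thresholds = [], {}
    for k in range(1, n_modes + 1):
        phi = modes.phis[:, k]
        phi_c, _, _, _ = two_way_cut(phi, Trev.P, Trev.pi)
        thresholds[k] = phi_c
        psi_cols.append(
            kinetic_map(transform_eigvector(phi, phi_c), modes.lambdas[k], tau_star,
                        variant=kinetic_variant)
        )
    psi = np.stack(psi_cols, axis=1)
    out: dict[int, CoarseGraining] = {}
    for q in q_list:
        m = int(np.ceil(np.log2(q)))
        cg = q_way_cut(psi[:, :m], Trev.pi, q, seed=seed)
        cg.thresholds = {k: thresholds[k] for k in range(1, m + 1)}
        cg.strategy_coherence = np.array([
            coherence(Trev.P, Trev.pi, np.flatnonzero(cg.assignment == s))
            for s in range(q)
        ])
        out[q] = cg
    return out


def block_ordered_view(T: TransitionMatrix, assignment: np.ndarray):
    """Permutation sorting microstates by strategy, and the permuted operator."""
    perm = np.argsort(assignment, kind="stable")
    return perm, T.P[np.ix_(perm, perm)]


def name_strategies(assignment: np.ndarray, mean_abs_heading: np.ndarray) -> dict[int, str]:
    """Label strategies cruising/wandering by mean |heading change| of members (low -> cruising)."""
    q = int(assignment.max()) + 1
    means = np.array([mean_abs_heading[assignment == s].mean() for s in range(q)])
    names = {}
    order = np.argsort(means)
    base = ["cruising", "wandering"] if q == 2 else [f"strategy_{r}" for r in range(q)]
    for rank, s in enumerate(order):
        names[int(s)] = base[rank] if q == 2 else (
            "cruising-like" if rank < q / 2 else "wandering-like")
    return names
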