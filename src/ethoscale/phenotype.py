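"""Phenotypic structure from individual transition matrices.

Fish are compared through the row-averaged Manhattan distance between their
coarse-grained transition matrices,

    d(T, T') = (1/q) sum_i sum_j |T_ij - T'_ij|,

which is a metric.  The pairwise distance matrix is embedded exactly into
Euclidean space by Constant Shift Embedding (CSE): double-center, shift the
spectrum so it is nonnegative, and scale eigenvectors by the square roots of
the shifted eigenvalues.  Each fish also carries a significance scale
eps_f — the mean self-distance between its matrix and re-estimates from
finite simulations of it — quantifying finite-recording uncertainty.

Hierarchical Multiplicative Diffusive (HMD) clustering searches for
metastability in the diffusion process defined by the uncertainty-rescaled
kernel k(i, j) = exp(-D_ij / sqrt(eps_i eps_j)): at each level the most
metastable cluster (max-min coherence along the Fiedler vector of its
intra-cluster diffusion operator) is soft-split by 1-D fuzzy c-means,
producing per-level posteriors P(G | fish).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.metrics import confusion_matrix as _sk_confusion

from .individual import FishModel, fit_fish, simulate_fish

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeSpace",
    "ClusterNode",
    "ClusterTree",
    "tm_distance",
    "distance_matrix",
    "cse_embed",
    "classify_contexts",
    "significance_scale",
    "fuzzy_cmeans_1d",
    "hmd_cluster",
]


@dataclass
class PhenotypeSpace:
    D: np.ndarray  # (n, n) pairwise distances
    fish_ids: list[str]
    q: int
    eps: np.ndarray | None = None  # significance scale per fish
    embedding: np.ndarray | None = None  # CSE coordinates
    weights: np.ndarray | None = None  # CSE eigenvalue weights


@dataclass
class ClusterNode:
    id: int
    level: int  # level at which this node was created
    parent: int | None
    children: tuple[int, int] | None = None
    split_score: float | None = None  # metastability of this node when split


@dataclass
class ClusterTree:
    fish_ids: list[str]
    nodes: list[ClusterNode]
    posteriors: list[np.ndarray]  # per level: (n_fish, n_groups_at_level)
    leaves_by_level: list[list[int]]
    stopped_reason: str = ""

    @property
    def n_levels(self) -> int:
        return len(self.posteriors)

    def hard_labels(self, level: int = -1) -> np.ndarray:
        return np.argmax(self.posteriors[level], axis=1)

    def to_dict(self) -> dict:
        return {
            "fish_ids": self.fish_ids,
            "nodes": [
                {"id": n.id, "level": n.level, "parent": n.parent,
                 "children": list(n.children) if n.children else None,
                 "split_score": n.split_score}
                for n in self.nodes
            ],
            "posteriors": [p.tolist() for p in self.posteriors],
            "leaves_by_level": self.leaves_by_level,
            "stopped_reason": self.stopped_reason,
        }


def tm_distance(T: np.ndarray, T_prime: np.ndarray) -> float:
    """Row-averaged Manhattan distance between row-stochastic matrices."""
    T = np.asarray(T, dtype=float)
    T_prime = np.asarray(T_prime, dtype=float)
    if T.shape != T_prime.shape:
        raise ValueError(f"shape mismatch {T.shape} vs {T_prime.shape}")
    return float(np.abs(T - T_prime).sum() / T.shape[0])


def distance_matrix(models: list[FishModel]) -> PhenotypeSpace:
    """Full symmetric pairwise Eq.-style distance matrix over fish models."""
    qs = {m.q for m in models}
    if len(qs) != 1:
        raise ValueError(f"all models must share q, got {sorted(qs)}")
    q = qs.pop()
    stack = np.stack([m.T for m in models])  # (n, q, q)
    D = np.abs(stack[:, None] - stack[None, :]).sum(axis=(2, 3)) / q
    return PhenotypeSpace(D=D, fish_ids=[m.fish_id for m in models], q=q)


def cse_embed(D: np.ndarray, tol: float = 1e-12):
    """Constant Shift Embedding of a dissimilarity matrix.

    Returns ``(coords, weights)``: double-center S = -1/2 Q D Q, shift the
    spectrum by its minimum eigenvalue within the centered subspace so all
    weights are nonnegative, and scale eigenvectors by sqrt(weight).
    Pairwise squared Euclidean distances in the full embedding equal
    D_ij - 2 lambda_min off the diagonal (the shifted dissimilarities);
    dimensions with weight <= tol are dropped.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("D must be a symmetric square matrix")
    n = D.shape[0]
    Q = np.eye(n) - np.ones((n, n)) / n
    S = -0.5 * Q @ D @ Q
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # centered subspace: drop the constant direction (eigenvalue ~ 0 by construction)
    lam_min = evals.min()
    shifted = evals - min(lam_min, 0.0)
    keep = shifted > tol
    coords = evecs[:, keep] * np.sqrt(shifted[keep])[None, :]
    return coords, shifted


def significance_scale(
    model: FishModel, n_sims: int = 100, seed: int = 0, length: int | None = None,
) -> float:
    """Finite-recording uncertainty radius eps_f = <d(T_hat, T)> over simulations.

    Each simulation evolves the fish's matrix for its recorded sequence
    length; T_hat is re-estimated from the simulated sequence, with rows
    never visited imputed from the reference matrix itself (an unvisited row
    carries no evidence of deviation).
    """
    length = model.sequence_length if length is None else length
    sims = simulate_fish(model, length=length, n_reps=n_sims, seed=seed)
    q = model.q
    total = 0.0
    for s in range(n_sims):
        seq = sims[s]
        C = np.zeros((q, q))
        np.add.at(C, (seq[:-1], seq[1:]), 1.0)
        rowsum = C.sum(axis=1)
        T_hat = model.T.copy()
        vis = rowsum > 0
        T_hat[vis] = C[vis] / rowsum[vis, None]
        total += tm_distance(T_hat, model.T)
    eps = total / n_sims
    if model.flags:
        logger.info("significance_scale: model %s flagged (%s); eps=%.3g",
                    model.fish_id, "; ".join(model.flags), eps)
    return float(eps)


def classify_contexts(
    space: PhenotypeSpace,
    labels: list[str] | np.ndarray,
    n_shuffles: int = 100,
    seed: int = 0,
    test_size: float = 0.2,
    Cs=(0.001, 0.01, 0.1, 1.0, 10.0),
):
    """Context-classification harness on CSE coordinates.

    Per shuffle: stratified 80/20 split, L2 multinomial logistic regression
    with the regularization strength chosen by stratified k-fold CV on the
    training set, class-balanced loss and class-balanced (weighted) accuracy.
    Returns a dict with train/test accuracy arrays and the mean row-normalized
    confusion matrix.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    usable = classes[counts >= 2]
    if len(usable) < len(classes):
        logger.warning("classify_contexts: excluding %d contexts with < 2 fish",
                       len(classes) - len(usable))
    mask = np.isin(labels, usable)
    if len(usable) < 2:
        raise ValueError("need at least 2 contexts with >= 2 fish")
    if space.embedding is None:
        coords, w = cse_embed(space.D)
    else:
        coords, w = space.embedding, space.weights
    X, y = coords[mask], labels[mask]
    rng = np.random.default_rng(seed)
    train_acc, test_acc, confusions = [], [], []
    for _ in range(n_shuffles):
        rs = int(rng.integers(2**31))
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_size, stratify=y, random_state=rs)
        n_folds = max(2, min(5, np.bincount(np.searchsorted(usable, ytr)).min()))
        grid = GridSearchCV(
            LogisticRegression(class_weight="balanced", max_iter=2000),  # L2 by default
            {"C": list(Cs)},
            cv=StratifiedKFold(n_folds, shuffle=True, random_state=rs),
        )
        grid.fit(Xtr, ytr)
        clf = grid.best_estimator_

        def _wacc(Xs, ys):
            w_s = np.ones(len(ys))
            for c in usable:
                m = ys == c
                if m.any():
                    w_s[m] = 1.0 / m.sum()
            pred = clf.predict(Xs)
            return float(np.sum(w_s * (pred == ys)) / w_s.sum())

        train_acc.append(_wacc(Xtr, ytr))
        test_acc.append(_wacc(Xte, yte))
        cm = _sk_confusion(yte, clf.predict(Xte), labels=usable).astype(float)
        cm /= np.clip(cm.sum(axis=1, keepdims=True), 1, None)
        confusions.append(cm)
    return {
        "train_accuracy": np.asarray(train_acc),
        "test_accuracy": np.asarray(test_acc),
        "confusion": np.mean(confusions, axis=0),
        "classes": usable,
    }


def fuzzy_cmeans_1d(
    x: np.ndarray, c: int = 2, m: float = 2.0, seed: int = 0,
    max_iter: int = 300, tol: float = 1e-8,
):
    """Classic fuzzy c-means (Bezdek) on a 1-D coordinate.

    Returns ``(memberships (n, c), centers (c,))`` with centers sorted
    ascending.  Membership of a point coinciding with a center is 1 there.
    """
    x = np.asarray(x, dtype=float)
    # deterministic quantile init (seed kept for interface stability / jitter on ties)
    centers = np.percentile(x, np.linspace(10, 90, c))
    if len(np.unique(centers)) < c:
        rng = np.random.default_rng(seed)
        centers = centers + 1e-9 * rng.standard_normal(c)
    u = _fcm_memberships(x, centers, m)
    for _ in range(max_iter):
        um = u**m
        centers_new = (um * x[:, None]).sum(axis=0) / um.sum(axis=0)
        u_new = _fcm_memberships(x, centers_new, m)
        if np.abs(u_new - u).max() < tol:
            u, centers = u_new, centers_new
            break
        u, centers = u_new, centers_new
    order = np.argsort(centers)
    return u[:, order], centers[order]


def _fcm_memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d = np.abs(x[:, None] - centers[None, :])
    return fuzzy_memberships_from_distances(d, m)


def fuzzy_memberships_from_distances(d: np.ndarray, m: float = 2.0) -> np.ndarray:
    """u_ic = 1 / sum_k (d_ic/d_ik)^(2/(m-1)), with exact-hit handling."""
    d = np.asarray(d, dtype=float)
    u = np.zeros_like(d)
    zero = d <= 0
    hit = zero.any(axis=1)
    if hit.any():
        u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    rest = ~hit
    if rest.any():
        ratio = (d[rest][:, :, None] / d[rest][:, None, :]) ** (2.0 / (m - 1.0))
        u[rest] = 1.0 / ratio.sum(axis=2)
    return u


def _diffusion_operator(Dsub: np.ndarray, eps_sub: np.ndarray):
    """Row-normalized uncertainty-rescaled kernel and its invariant density."""
    R = Dsub / np.sqrt(np.outer(eps_sub, eps_sub))
    K = np.exp(-R)
    deg = K.sum(axis=1)
    P = K / deg[:, None]
    pi = deg / deg.sum()
    return P, pi, R


def _fiedler(P: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Second eigenvector of the diffusion operator via its symmetric conjugate."""
    sq = np.sqrt(pi)
    S = (sq[:, None] * P) / sq[None, :]
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)
    return evecs[:, -2] / sq


def _cluster_metastability(Dsub: np.ndarray, eps_sub: np.ndarray) -> float:
    """Max-min coherence along the Fiedler vector of the intra-cluster operator."""
    from .coarse_grain import two_way_cut

    P, pi, _ = _diffusion_operator(Dsub, eps_sub)
    phi = _fiedler(P, pi)
    if np.ptp(phi) < 1e-14:
        return -np.inf
    try:
        _, _, _, chi = two_way_cut(phi, P, pi)
    except ValueError:
        return -np.inf
    return chi


def _between_cluster_statistic(R: np.ndarray, labels: np.ndarray) -> float:
    """Mean rescaled distance over pairs of fish in different clusters."""
    diff = labels[:, None] != labels[None, :]
    return float(R[diff].mean()) if diff.any() else 0.0


def hmd_cluster(
    D: np.ndarray,
    eps: np.ndarray,
    max_levels: int = 6,
    stop_rel_gain: float = 0.05,
    fuzziness: float = 2.0,
    seed: int = 0,
    min_split_size: int = 3,
) -> ClusterTree:
    """Hierarchical Multiplicative Diffusive clustering of the phenotype space.

    Level 1 soft-splits all fish along the Fiedler coordinate of the rescaled
    diffusion operator by 1-D fuzzy c-means.  Deeper levels split the cluster
    with the highest metastability; posteriors of non-member fish toward the
    new children come from their rescaled distances to the children's
    membership-weighted centers, converted to fuzzy memberships.  Stops at
    ``max_levels``, when no cluster of size >= ``min_split_size`` remains, or
    when the relative gain in mean rescaled between-cluster distance drops
    below ``stop_rel_gain``.
    """
    D = np.asarray(D, dtype=float)
    eps = np.asarray(eps, dtype=float)
    n = D.shape[0]
    if eps.shape[0] != n:
        raise ValueError("D and eps sizes are inconsistent")
    if np.any(eps <= 0):
        raise ValueError("eps must be positive")
    _, _, R = _diffusion_operator(D, eps)
    fish_ids = [str(i) for i in range(n)]

    nodes = [ClusterNode(id=0, level=0, parent=None)]
    node_of_group = [0]  # current group column -> node id
    posterior = np.ones((n, 1))
    posteriors: list[np.ndarray] = []
    leaves_by_level: list[list[int]] = []
    tree = ClusterTree(fish_ids=fish_ids, nodes=nodes, posteriors=posteriors,
                       leaves_by_level=leaves_by_level)
    prev_stat = None

    for level in range(1, max_levels + 1):
        hard = np.argmax(posterior, axis=1)
        # choose which group to split
        candidates = []
        for g in range(posterior.shape[1]):
            members = np.flatnonzero(hard == g)
            if len(members) < min_split_size:
                continue
            score = _cluster_metastability(D[np.ix_(members, members)], eps[members])
            if np.isfinite(score):
                candidates.append((score, g, members))
        if not candidates:
            tree.stopped_reason = "no splittable cluster"
            break
        score, g, members = max(candidates, key=lambda t: t[0])

        # locate the barrier: fuzzy c-means along the intra-cluster Fiedler
        # coordinate defines the two children ...
        P_g, pi_g, _ = _diffusion_operator(D[np.ix_(members, members)], eps[members])
        phi = _fiedler(P_g, pi_g)
        u_members, _ = fuzzy_cmeans_1d(phi, c=2, m=fuzziness, seed=seed + level)
        # ... but posteriors (members and non-members alike) come from the
        # rescaled distances to the membership-weighted child centers, so that
        # confidence is expressed in units of the significance scale: when
        # between-child distances are comparable to eps, memberships stay soft
        um = u_members**fuzziness
        d_child = np.stack([
            R[:, members] @ um[:, c] / um[:, c].sum() for c in (0, 1)
        ], axis=1)
        # two estimates of the same matrix sit ~sqrt(2) apart in rescaled
        # units (independent errors of one significance scale each), so that
        # radius is the indistinguishability floor before converting kernel
        # affinities to probabilities
        d_eff = np.clip(d_child - np.sqrt(2.0), 0.0, None)
        aff = np.exp(-d_eff)
        split_w = aff / aff.sum(axis=1, keepdims=True)

        # grow the tree: replace group column g by two children columns
        parent_id = node_of_group[g]
        nodes[parent_id].split_score = score
        c1, c2 = len(nodes), len(nodes) + 1
        nodes[parent_id].children = (c1, c2)
        nodes.append(ClusterNode(id=c1, level=level, parent=parent_id))
        nodes.append(ClusterNode(id=c2, level=level, parent=parent_id))
        new_post = np.empty((n, posterior.shape[1] + 1))
        keep_cols = [c for c in range(posterior.shape[1]) if c != g]
        new_post[:, : len(keep_cols)] = posterior[:, keep_cols]
        new_post[:, -2] = posterior[:, g] * split_w[:, 0]
        new_post[:, -1] = posterior[:, g] * split_w[:, 1]
        node_of_group = [node_of_group[c] for c in keep_cols] + [c1, c2]
        posterior = new_post
        posteriors.append(posterior.copy())
        leaves_by_level.append(list(node_of_group))

        stat = _between_cluster_statistic(R, np.argmax(posterior, axis=1))
        if prev_stat is not None and prev_stat > 0:
            gain = (stat - prev_stat) / prev_stat
            if gain < stop_rel_gain:
                tree.stopped_reason = f"scale-separation gain {gain:.3f} < {stop_rel_gain}"
                break
        prev_stat = stat
    else:
        tree.stopped_reason = tree.stopped_reason or "max_levels reached"
    if not tree.stopped_reason:
        tree.stopped_reason = "max_levels reached"
    return tree
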