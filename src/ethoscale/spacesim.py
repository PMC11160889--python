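"""Lab-space trajectories from symbolic sequences and search-efficiency curves.

Each microstate carries an empirical library of egocentric velocity vectors
(mm per bout, expressed in the frame of the bout's initial heading) paired
with realized heading changes.  Trajectories are generated by sampling a
velocity from the current symbol's library, rotating it into the lab frame,
stepping, and accumulating the heading change; a reflective box mirrors
positions and headings at the walls.

Resource-gathering efficiency follows two regimes: *capture* (target inside a
60-degree forward cone within half a body length) and *find* (target within
an isotropic encounter radius of half a body length), both evaluated at
bout-start positions of 1000-bout trajectories repeated a few thousand times
from random initial states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .transfer_operator import TransitionMatrix, _stationary

logger = logging.getLogger(__name__)

__all__ = [
    "VelocityLibrary",
    "Trajectory",
    "build_velocity_library",
    "simulate_trajectory",
    "restricted_strategy_operator",
    "simulate_symbols",
    "efficiency_curves",
    "msd",
]


@dataclass
class VelocityLibrary:
    """Per-microstate egocentric velocity samples (mm per bout) and heading changes (deg)."""

    velocities: dict[int, np.ndarray]  # state -> (n_samples, 2)
    heading_changes: dict[int, np.ndarray]  # state -> (n_samples,)
    centroids: dict[int, np.ndarray] | None = None  # for nearest-centroid fallback
    fallback_states: list[int] = field(default_factory=list)

    def ensure_states(self, states: np.ndarray) -> None:
        """Fallback for empty microstates: borrow the nearest centroid's library."""
        missing = [s for s in np.unique(states) if int(s) not in self.velocities]
        if not missing:
            return
        if not self.centroids:
            raise KeyError(f"no velocity samples for states {missing} and no centroids")
        have = [s for s in self.centroids if s in self.velocities]
        for s in missing:
            near = min(have, key=lambda t: np.linalg.norm(self.centroids[int(s)] - self.centroids[t]))
            self.velocities[int(s)] = self.velocities[near]
            self.heading_changes[int(s)] = self.heading_changes[near]
            self.fallback_states.append(int(s))
            logger.warning("velocity library: state %d empty, borrowed state %d", s, near)


@dataclass
class Trajectory:
    positions: np.ndarray  # (n_bouts + 1, 2) mm, lab frame
    headings: np.ndarray  # (n_bouts + 1,) degrees
    boundary: tuple[float, float] | None = None  # (W, H) of a reflective box


def _rot(theta_deg: np.ndarray) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    return np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])


def build_velocity_library(cohort, labels_per_fish: dict[str, np.ndarray]) -> VelocityLibrary:
    """Pool per-bout displacement vectors per microstate, rotated egocentrically.

    ``labels_per_fish`` maps fish id to the microstate label of each bout (or
    window start); label t is paired with bout t's displacement and heading
    change.  The last bout of each fish has no following heading, so it is
    skipped for the heading-change sample.
    """
    vel: dict[int, list[np.ndarray]] = {}
    dhs: dict[int, list[float]] = {}
    for fid, labels in labels_per_fish.items():
        fish = cohort.fish[fid]
        dh = fish.heading_change()
        n = min(len(labels), len(dh))  # pair label t with bout t, needs heading t+1
        h = np.deg2rad(fish.heading[:n])
        c, s = np.cos(-h), np.sin(-h)
        d = fish.displacement[:n]
        ego = np.stack([c * d[:, 0] - s * d[:, 1], s * d[:, 0] + c * d[:, 1]], axis=1)
        for t in range(n):
            st = int(labels[t])
            vel.setdefault(st, []).append(ego[t])
            dhs.setdefault(st, []).append(float(dh[t]))
    return VelocityLibrary(
        velocities={k: np.asarray(v) for k, v in vel.items()},
        heading_changes={k: np.asarray(v) for k, v in dhs.items()},
    )


def simulate_trajectory(
    symbols: np.ndarray,
    lib: VelocityLibrary,
    seed: int = 0,
    boundary: tuple[float, float] | None = None,
    start: np.ndarray | None = None,
    initial_heading: float = 0.0,
) -> Trajectory:
    """Roll a symbolic sequence into a lab-space trajectory.

    Per bout: draw a matched (egocentric velocity, heading change) sample
    from the current symbol's library, rotate to the lab frame by the current
    heading, step, and accumulate the heading change.  A reflective boundary
    (box of W x H mm centered at the origin) mirrors position and heading.
    """
    rng = np.random.default_rng(seed)
    symbols = np.asarray(symbols, dtype=np.int64)
    lib.ensure_states(symbols)
    n = len(symbols)
    # draw one (velocity, heading-change) sample per bout, grouped by symbol
    v_ego = np.empty((n, 2))
    dh = np.empty(n)
    for s in np.unique(symbols):
        m = symbols == s
        k = rng.integers(len(lib.velocities[int(s)]), size=int(m.sum()))
        v_ego[m] = lib.velocities[int(s)][k]
        dh[m] = lib.heading_changes[int(s)][k]
    head = np.empty(n + 1)
    head[0] = initial_heading
    head[1:] = initial_heading + np.cumsum(dh)
    p0 = np.zeros(2) if start is None else np.asarray(start, dtype=float)
    if boundary is None:
        t = np.deg2rad(head[:-1])
        c, s_ = np.cos(t), np.sin(t)
        v_lab = np.stack([c * v_ego[:, 0] - s_ * v_ego[:, 1],
                          s_ * v_ego[:, 0] + c * v_ego[:, 1]], axis=1)
        pos = np.vstack([p0, p0 + np.cumsum(v_lab, axis=0)])
        return Trajectory(positions=pos, headings=head, boundary=None)
    half = (boundary[0] / 2.0, boundary[1] / 2.0)
    pos = np.zeros((n + 1, 2))
    pos[0] = p0
    h = initial_heading
    for t in range(n):
        v = _rot(h) @ v_ego[t]
        p = pos[t] + v
        h = h + dh[t]
        for _ in range(100):
            done = True
            if p[0] > half[0]:
                p[0] = 2 * half[0] - p[0]; h = 180.0 - h; done = False
            elif p[0] < -half[0]:
                p[0] = -2 * half[0] - p[0]; h = 180.0 - h; done = False
            if p[1] > half[1]:
                p[1] = 2 * half[1] - p[1]; h = -h; done = False
            elif p[1] < -half[1]:
                p[1] = -2 * half[1] - p[1]; h = -h; done = False
            if done:
                break
        pos[t + 1] = p
        head[t + 1] = h
    return Trajectory(positions=pos, headings=head, boundary=boundary)


def restricted_strategy_operator(T_full: TransitionMatrix, members: np.ndarray) -> TransitionMatrix:
    """Lag-1 operator restricted to one strategy's microstates, rows renormalized."""
    members = np.asarray(members)
    if members.dtype == bool:
        members = np.flatnonzero(members)
    if members.size == 0:
        raise ValueError("member set must be nonempty")
    P = T_full.P[np.ix_(members, members)]
    rowsum = P.sum(axis=1)
    flags = []
    zero = rowsum <= 0
    if zero.any():
        flags.append(f"uniform-imputed {int(zero.sum())} rows with no within-strategy mass")
        P[zero] = 1.0
        rowsum = P.sum(axis=1)
    P = P / rowsum[:, None]
    return TransitionMatrix(P=P, pi=_stationary(P), tau=T_full.tau,
                            state_ids=T_full.state_ids[members], flags=flags)


def simulate_symbols(T: TransitionMatrix, length: int, rng: np.random.Generator,
                     start: int | None = None, n_reps: int = 1) -> np.ndarray:
    """Evolve symbolic sequences under T (initial states ~ pi unless given).

    Returns shape (length,) for ``n_reps == 1``, else (n_reps, length).
    """
    cum = np.cumsum(T.P, axis=1)
    out = np.empty((n_reps, length), dtype=np.int64)
    pi = T.pi / T.pi.sum()
    out[:, 0] = rng.choice(T.N, p=pi, size=n_reps) if start is None else start
    u = rng.random((n_reps, length - 1))
    for t in range(1, length):
        out[:, t] = (u[:, t - 1][:, None] >= cum[out[:, t - 1]]).sum(axis=1)
    return out[0] if n_reps == 1 else out


def efficiency_curves(
    T: TransitionMatrix,
    lib: VelocityLibrary,
    r_grid: np.ndarray,
    n_traj: int = 5000,
    length: int = 1000,
    body_length: float = 4.0,
    seed: int = 0,
    aperture_deg: float = 60.0,
    capture_radius_bl: float = 0.5,
) -> dict:
    """Capture- and find-probability versus target distance r.

    Per trajectory and per r, one target is placed uniformly in the disk of
    radius r around the start.  It is *captured* if at any bout start it lies
    within ``capture_radius_bl`` body lengths of the head AND within +/- half
    the aperture of the current heading; it is *found* if at any bout start
    it lies within the (isotropic) encounter radius.  Binomial standard
    errors accompany each probability.
    """
    rng = np.random.default_rng(seed)
    r_grid = np.asarray(r_grid, dtype=float)
    rc = capture_radius_bl * body_length
    half_ap = aperture_deg / 2.0
    cap_hits = np.zeros(len(r_grid))
    find_hits = np.zeros(len(r_grid))
    sym_mat = simulate_symbols(T, length, rng, n_reps=n_traj)
    sym_mat = sym_mat.reshape(n_traj, length)
    for i in range(n_traj):
        # map library symbols to original microstate ids if T is a restriction
        state_syms = T.state_ids[sym_mat[i]] if T.state_ids is not None else sym_mat[i]
        traj = simulate_trajectory(state_syms, lib, seed=int(rng.integers(2**31)))
        pos = traj.positions[:-1]
        heads = traj.headings[:-1]
        for j, r in enumerate(r_grid):
            rho = r * np.sqrt(rng.random(2))
            ang = rng.random(2) * 2 * np.pi
            targets = pos[0] + rho[:, None] * np.stack([np.cos(ang), np.sin(ang)], axis=1)
            # capture: target 0; find: target 1 (independent placements)
            dvec = targets[0] - pos
            dist = np.linalg.norm(dvec, axis=1)
            bearing = np.rad2deg(np.arctan2(dvec[:, 1], dvec[:, 0])) - heads
            bearing = (bearing + 180.0) % 360.0 - 180.0
            if np.any((dist <= rc) & (np.abs(bearing) <= half_ap)):
                cap_hits[j] += 1
            if np.any(np.linalg.norm(targets[1] - pos, axis=1) <= rc):
                find_hits[j] += 1
    p_cap = cap_hits / n_traj
    p_find = find_hits / n_traj
    se = lambda p: np.sqrt(np.clip(p * (1 - p), 0, None) / n_traj)
    return {
        "r": r_grid,
        "capture_probability": p_cap,
        "capture_se": se(p_cap),
        "find_probability": p_find,
        "find_se": se(p_find),
        "n_traj": n_traj,
    }


def msd(trajectories: list[Trajectory] | Trajectory, max_lag: int,
        n_boot: int = 100, seed: int = 0):
    """Time-and-ensemble averaged mean squared displacement per bout lag.

    Returns ``(lags, msd, (lo, hi))`` with a bootstrap CI over trajectories.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("need at least one trajectory")
    lags = np.arange(1, max_lag + 1)
    per_traj = np.empty((len(trajectories), max_lag))
    for i, tr in enumerate(trajectories):
        x = tr.positions
        for j, lag in enumerate(lags):
            d = x[lag:] - x[:-lag]
            per_traj[i, j] = np.mean(np.sum(d * d, axis=1))
    m = per_traj.mean(axis=0)
    if len(trajectories) > 1:
        rng = np.random.default_rng(seed)
        idx = rng.integers(len(trajectories), size=(n_boot, len(trajectories)))
        boots = per_traj[idx].mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    else:
        lo = hi = m
    return lags, m, (lo, hi)
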