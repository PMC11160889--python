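"""Synthetic cohorts with metastable strategy-switching bout streams.

The generator emulates the statistical structure the downstream method
assumes: each fish switches among a small set of latent motor strategies
according to a row-stochastic Markov chain; each strategy has its own bout
kinematics (per-bout heading change, speed, inter-bout interval, and a signed
left/right egocentric bias); phenotypic groups are planted by giving groups of
fish different switching chains.

Distribution choices: heading changes are wrapped-normal (degrees), speeds
log-normal (mm/s), inter-bout intervals gamma (s).  A coefficient of variation
of zero degenerates to a point mass, which the fixture tests rely on.  The
posture matrix of each bout is a damped two-harmonic traveling tail wave plus
a turn offset proportional to the realized heading change; the waveform is a
fixture convention, not a scientific claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, FishData

__all__ = [
    "StrategySpec",
    "CohortSpec",
    "InvalidModelError",
    "generate_strategy_sequence",
    "emit_bouts",
    "generate_cohort",
    "stationary_distribution",
]


class InvalidModelError(ValueError):
    """Raised for non-stochastic chains or empty cohort specs."""


def _check_chain(chain: np.ndarray) -> np.ndarray:
    chain = np.asarray(chain, dtype=float)
    if chain.ndim != 2 or chain.shape[0] != chain.shape[1]:
        raise InvalidModelError(f"chain must be square, got shape {chain.shape}")
    if np.any(chain < 0) or not np.allclose(chain.sum(axis=1), 1.0, atol=1e-12):
        raise InvalidModelError("chain rows must be nonnegative and sum to 1")
    return chain


def stationary_distribution(chain: np.ndarray) -> np.ndarray:
    """Invariant density of a row-stochastic matrix (leading left eigenvector)."""
    chain = np.asarray(chain, dtype=float)
    w, v = np.linalg.eig(chain.T)
    pi = np.real(v[:, np.argmax(np.real(w))])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class StrategySpec:
    """Kinematic profile of one latent motor strategy.

    heading_mu/heading_sigma parameterize a wrapped normal over per-bout
    heading change (degrees); speed_mean/speed_cv a log-normal over bout speed
    (mm/s); ibi_mean/ibi_cv a gamma over inter-bout intervals (s); lr_bias in
    [-1, 1] sets the probability of a rightward (positive) turn to
    (1 + lr_bias) / 2.
    """

    label: int
    heading_mu: float = 0.0
    heading_sigma: float = 30.0
    speed_mean: float = 10.0
    speed_cv: float = 0.3
    ibi_mean: float = 0.8
    ibi_cv: float = 0.3
    lr_bias: float = 0.0

    def __post_init__(self):
        if not -1.0 <= self.lr_bias <= 1.0:
            raise ValueError(f"|lr_bias| must be <= 1, got {self.lr_bias}")
        if self.speed_mean < 0 or self.ibi_mean < 0:
            raise ValueError("speed and ibi distributions must have nonnegative support")

    def sample_heading_change(self, rng: np.random.Generator, n: int) -> np.ndarray:
        mag = np.abs(self.heading_mu + self.heading_sigma * rng.standard_normal(n))
        sign = np.where(rng.random(n) < (1.0 + self.lr_bias) / 2.0, 1.0, -1.0)
        dh = sign * mag
        return (dh + 180.0) % 360.0 - 180.0  # wrap

    def sample_speed(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.speed_cv == 0:
            return np.full(n, self.speed_mean)
        sig2 = np.log1p(self.speed_cv**2)
        mu = np.log(self.speed_mean) - sig2 / 2.0
        return rng.lognormal(mu, np.sqrt(sig2), n)

    def sample_ibi(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.ibi_cv == 0:
            return np.full(n, self.ibi_mean)
        shape = 1.0 / self.ibi_cv**2
        return rng.gamma(shape, self.ibi_mean / shape, n)


@dataclass
class CohortSpec:
    """Plan for a planted-group synthetic cohort.

    ``strategy_chains`` maps planted group id -> row-stochastic switching
    matrix over the strategies in ``strategies``; ``group_assignment`` gives
    one group id per fish (length n_fish), ``context_labels`` one context
    string per fish (defaults to a single context).
    """

    n_fish: int
    bouts_per_fish: int
    strategies: list[StrategySpec]
    strategy_chains: dict[int, np.ndarray]
    group_assignment: list[int] | None = None
    context_labels: list[str] | None = None
    frames_per_bout: int = 20
    n_tail_segments: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_fish < 1 or self.bouts_per_fish < 1:
            raise InvalidModelError("cohort needs at least one fish and one bout")
        if self.group_assignment is None:
            self.group_assignment = [sorted(self.strategy_chains)[0]] * self.n_fish
        if len(self.group_assignment) != self.n_fish:
            raise InvalidModelError("group_assignment must cover all fish")
        for g in set(self.group_assignment):
            if g not in self.strategy_chains:
                raise InvalidModelError(f"no strategy chain for planted group {g}")
            _check_chain(self.strategy_chains[g])
        if self.context_labels is None:
            self.context_labels = ["default"] * self.n_fish
        if len(self.context_labels) != self.n_fish:
            raise InvalidModelError("context_labels must cover all fish")


def generate_strategy_sequence(
    chain: np.ndarray, n_bouts: int, seed: int | np.random.Generator,
    start: int | None = None,
) -> np.ndarray:
    """Sample a latent strategy label sequence from a Markov chain.

    The initial state is drawn from the chain's invariant density unless
    ``start`` is given.
    """
    chain = _check_chain(chain)
    if n_bouts < 1:
        raise InvalidModelError("n_bouts must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_states = chain.shape[0]
    cum = np.cumsum(chain, axis=1)
    labels = np.empty(n_bouts, dtype=np.int64)
    if start is None:
        labels[0] = rng.choice(n_states, p=stationary_distribution(chain))
    else:
        labels[0] = start
    u = rng.random(n_bouts - 1)
    for t in range(1, n_bouts):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t - 1], side="right")
    return labels


def _tail_wave(frames: int, segments: int) -> np.ndarray:
    """Zero-mean damped two-harmonic traveling wave, (frames, segments)."""
    t = np.linspace(0.0, 1.0, frames)[:, None]
    s = np.linspace(0.0, 1.0, segments)[None, :]
    env = np.sin(np.pi * t) * s  # amplitude grows toward the tail tip
    wave = env * (0.6 * np.sin(2 * np.pi * (2.0 * t - s)) + 0.25 * np.sin(2 * np.pi * (4.0 * t - s)))
    return wave - wave.mean()


def emit_bouts(
    labels: np.ndarray,
    specs: dict[int, StrategySpec] | list[StrategySpec],
    seed: int | np.random.Generator,
    frames_per_bout: int = 20,
    n_tail_segments: int = 8,
    initial_heading: float = 0.0,
) -> FishData:
    """Turn a latent strategy sequence into a bout stream.

    Per bout, the heading change, speed and inter-bout interval are sampled
    from the bout's strategy spec.  Displacement magnitude is speed × ibi,
    directed along the post-turn heading; the posture matrix is the common
    traveling wave plus a turn offset whose mean angle equals the realized
    heading change (radians).
    """
    labels = np.asarray(labels, dtype=np.int64)
    if isinstance(specs, list):
        specs = {s.label: s for s in specs}
    for lab in np.unique(labels):
        if int(lab) not in specs:
            raise KeyError(f"no StrategySpec for label {lab}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(labels)
    dh = np.empty(n)
    speed = np.empty(n)
    ibi = np.empty(n)
    for lab in np.unique(labels):
        m = labels == lab
        sp = specs[int(lab)]
        k = int(m.sum())
        dh[m] = sp.sample_heading_change(rng, k)
        speed[m] = sp.sample_speed(rng, k)
        ibi[m] = sp.sample_ibi(rng, k)

    heading = initial_heading + np.concatenate([[0.0], np.cumsum(dh[:-1])])
    post_turn = np.deg2rad(heading + dh)
    displacement = (speed * ibi)[:, None] * np.stack([np.cos(post_turn), np.sin(post_turn)], axis=1)

    wave = _tail_wave(frames_per_bout, n_tail_segments)
    turn_shape = np.outer(
        np.sin(np.pi * np.linspace(0, 1, frames_per_bout)),
        np.linspace(0.2, 1.0, n_tail_segments),
    )
    turn_shape /= turn_shape.mean()  # mean posture angle == heading change (rad)
    posture = wave[None] + np.deg2rad(dh)[:, None, None] * turn_shape[None]
    return FishData(
        posture=posture, displacement=displacement, heading=heading, ibi=ibi,
        latent_labels=labels,
    )


def demo_strategies() -> list[StrategySpec]:
    """Four motor strategies: slow/fast variants of cruising and wandering.

    Cruising reorients little per bout; wandering reorients strongly; the
    slow/fast axis separates bout speeds.  Values are chosen as realistic
    larval-zebrafish bout kinematics (speeds of a few to ~20 mm/s, inter-bout
    intervals under a second, heading-change spreads of ~10 vs ~70 degrees).
    """
    return [
        StrategySpec(label=0, heading_sigma=8.0, speed_mean=4.0, ibi_mean=0.9),   # slow cruise
        StrategySpec(label=1, heading_sigma=10.0, speed_mean=16.0, ibi_mean=0.5), # fast cruise
        StrategySpec(label=2, heading_sigma=60.0, speed_mean=4.0, ibi_mean=0.9),  # slow wander
        StrategySpec(label=3, heading_sigma=70.0, speed_mean=16.0, ibi_mean=0.5), # fast wander
    ]


def metastable_chain(n_states: int, dwell: float = 0.9,
                     block_sizes: list[int] | None = None,
                     block_dwell: float | None = None) -> np.ndarray:
    """Row-stochastic chain with self-dwell ``dwell`` and uniform leakage.

    With ``block_sizes``/``block_dwell``, leakage prefers the own block:
    the chain keeps ``block_dwell`` of its outgoing mass inside the block,
    giving a nested (strategy within super-strategy) timescale structure.
    """
    T = np.full((n_states, n_states), 0.0)
    for i in range(n_states):
        T[i, i] = dwell
        out = 1.0 - dwell
        if block_sizes is None or block_dwell is None:
            T[i, np.arange(n_states) != i] = out / (n_states - 1)
        else:
            bounds = np.cumsum([0] + list(block_sizes))
            b = np.searchsorted(bounds, i, side="right") - 1
            own = np.arange(bounds[b], bounds[b + 1])
            own = own[own != i]
            other = np.setdiff1d(np.arange(n_states), np.arange(bounds[b], bounds[b + 1]))
            if own.size:
                T[i, own] = out * block_dwell / own.size
                T[i, other] = out * (1 - block_dwell) / other.size
            else:
                T[i, other] = out / other.size
    return T


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort per ``spec`` (deterministic in spec.seed)."""
    root = np.random.default_rng(spec.seed)
    specs = {s.label: s for s in spec.strategies}
    cohort = Cohort(seed=spec.seed)
    width = len(str(spec.n_fish - 1))
    for i in range(spec.n_fish):
        g = spec.group_assignment[i]
        fish_rng = np.random.default_rng(root.integers(2**31))
        labels = generate_strategy_sequence(spec.strategy_chains[g], spec.bouts_per_fish, fish_rng)
        fish = emit_bouts(
            labels, specs, fish_rng,
            frames_per_bout=spec.frames_per_bout, n_tail_segments=spec.n_tail_segments,
        )
        fish.context = spec.context_labels[i]
        fish.planted_group = g
        cohort.fish[f"fish{i:0{width}d}"] = fish
    return cohort
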