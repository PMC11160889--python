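# Methods

This note records the models, estimators, numerical conventions and design
choices behind `ethoscale`, and what the synthetic fixtures do and do not
establish about real data.

## The behavioral model

The package treats behavior as a discrete-time stochastic process over swim
bouts. The working assumptions are:

- after stacking K consecutive bouts, the dynamics are approximately Markov
  (delay embedding restores memory lost by bout-level discretization);
- the slow spectrum of the resulting transfer operator is low-dimensional:
  a handful of eigenvalues near 1 separate from a bulk, and their
  eigenvectors order microstates along interpretable kinematic axes
  (reorientation, speed, egocentric bias);
- an individual's long-run behavior is summarized by its transition matrix
  among coarse-grained strategies, up to finite-recording uncertainty.

None of these are verified for any particular dataset by this package's
tests; they are the modeling commitments the estimators are built on.

## Estimators and conventions

**Windowing.** A bout window opens 10 frames before the detected bout start
and closes at the last frame with speed ≥ 4 mm/s, capped at a fixed total
length (default 175 frames); shorter windows are zero-padded with a validity
mask. Angles are unwrapped per tail segment before flattening. Units: degrees
in I/O, radians internally, positions in mm, 0-based bout indices, half-open
windows.

**Resampled PCA.** Covariance matrices are computed on random resamples of
recordings (default 180 resamples of 25 recordings) and averaged before
eigendecomposition, so that long recordings do not dominate. The retained
dimension is the smallest reaching 95% cumulative explained variance unless
fixed by the caller. Cohorts smaller than the resample size are resampled
with replacement (logged).

**Entropy-rate model selection.** h = −Σ πᵢTᵢⱼ log Tᵢⱼ with π the leading
left eigenvector of T (power iteration, tolerance 1e−12) and 0·log 0 := 0.
During model selection the per-row Miller–Madow correction
πᵢ(mᵢ−1)/(2nᵢ) is added (mᵢ = observed branching, nᵢ = row count):
without it, h estimated at larger state counts is biased low by a term that
scales with N/n, which systematically distorts the h(K) comparison at fixed
data volume. Each bootstrap resample of fish is evaluated at every (K, N)
grid point (paired design); K* is the smallest K whose forward difference
|h(K+1) − h(K)| lies inside the bootstrap noise band, operationalized as the
95% half-width (1.96 σ) of the h estimates at the two K values; N* maximizes
mean h at K*. When the delay-embedded windows have fewer distinct points than
the requested N (exact symbolic sources), N is reduced to the distinct count
— k-means cannot populate more clusters than there are distinct points.

**Operator estimation.** Transitions are counted at lag τ only across
contiguous positions of each fish's stream (never across recording breaks or
fish boundaries). Zero-count rows become uniform rows (flagged); such states
carry no invariant mass downstream. The ensemble operator averages
row-normalized per-resample matrices over context-balanced resamples and
renormalizes (normalize → average → renormalize, in that order).
Reversibilization is the additive construction
P_rev = ½(P + diag(π)⁻¹ Pᵀ diag(π)), which preserves π and yields a real
spectrum; states with π ≈ 0 are dropped first. Spectra are computed through
the symmetric conjugate diag(√π) P diag(√π)⁻¹ for numerical stability;
eigenvectors are sign-fixed so the largest-magnitude entry is positive.
Implied timescales t = −τ/ln λ are reported for 0 < λ < 1. The noise floor
permutes symbols within fish and records the largest non-trivial eigenvalue
of the re-estimated reversibilized operator.

**Coarse-graining.** The coherence χ(S) of a microstate set is the
π-weighted probability of remaining in S after one lag. The two-way cut scans
all N−1 midpoint thresholds of the sorted eigenvector values with an O(N)
incremental update and maximizes min(χ(S₊), χ(S₋)); ties break toward the
more balanced π-mass split. Eigenvectors are then centered at their optimal
cut and rank-normalized to equal spacing on [−1, 0) and (0, 1] (invariant to
monotone transforms), and scaled by the kinetic-map weight −τ*/(2 ln λₖ) — a
square-root variant is available behind a flag; the linear form is the
default. Weights diverging as λ → 1 are capped at 10× the next-slowest
mode's weight. q strategies come from π-weighted k-means on the first
⌈log₂ q⌉ rescaled modes; at q = 2 the assignment is the sign of the
transformed leading eigenvector, which makes the q-way and threshold cuts
agree by construction (k-means on rank-spaced loadings need not). Strategy
naming (cruising vs wandering) follows mean |heading change| of member
microstates, low → cruising.

**Individual models.** Per-fish matrices are lag-1 counts over the fish's
own strategy sequence, row-normalized, with unvisited rows uniform
(flagged). Simulations start from the fish's first observed strategy. Dwell
statistics are run-length encodings with bootstrap CIs over runs (CIs over
simulations are also available, since the two resampling bases differ).

**Phenotype space.** The matrix metric d(T, T′) = (1/q)Σᵢⱼ|Tᵢⱼ−T′ᵢⱼ| is a
genuine metric (tested on random ensembles). Constant Shift Embedding
double-centers −½QDQ (applied to the dissimilarities directly, not their
squares), shifts the centered spectrum by its minimum eigenvalue, and scales
eigenvectors by square roots of the shifted eigenvalues; the full embedding
reproduces the shifted dissimilarities to machine precision — this exactness
is the method's defining contract and is asserted in the tests. The
significance scale ε̂_f re-estimates matrices from simulations of the fish's
own length; rows never visited in a simulation are imputed from the reference
matrix (they carry no evidence of deviation — uniform imputation would assign
positive self-distance to a deterministic chain).

**Context classification.** Stratified 80/20 splits, L2 multinomial logistic
regression on the positive-eigenvalue CSE coordinates, regularization chosen
by stratified k-fold CV on the training set, class-balanced loss and
class-balanced (weighted) accuracy. The regularization grid includes strong
values (C down to 10⁻³) so that unstructured cohorts can fall back to a
near-constant model and score at chance rather than below it.

**HMD clustering.** The kernel is exp(−D_ij/√(ε̂ᵢε̂ⱼ)) — decaying with
distance; a printed source formula with the opposite sign is treated as an
erratum, since a similarity kernel must decay. The diffusion operator is the
row-normalized kernel; its Fiedler vector (second eigenvector, computed via
the symmetric conjugate) locates the barrier; 1-D fuzzy c-means (classic
Bezdek updates, fuzziness m = 2, deterministic quantile initialization)
splits the coordinate. Cluster-level metastability is the max–min coherence
along the intra-cluster Fiedler vector — the same functional as the dynamical
two-way cut, applied to the diffusion operator and its invariant density —
and the most metastable cluster of size ≥ 3 is split at each level.
Posteriors for *all* fish (members and non-members of the split cluster) come
from rescaled distances to the membership-weighted child centers: the
distance is floored at √2 — two independent estimates of the same matrix sit
≈ √(ε̂ᵢ² + ε̂ⱼ²) apart, i.e. √2 in units of the geometric-mean scale — and
converted to probabilities through the same exponential kernel. This keeps
posteriors soft (≈ ½) when between-child separations are at the significance
scale and hard when they are far beyond it; fuzzy-membership conversion on
raw coordinates was rejected because it is always confident near centers,
even for unstructured cohorts. Splitting stops at max_levels (default 6),
when no cluster is splittable, or when the relative gain in mean rescaled
between-cluster distance falls below 0.05 — the scale-separation statistic is
a declared operationalization, as no closed form is standard.

**Space simulation.** Velocity vectors are stored egocentrically (rotated by
the bout's initial heading) and re-rotated by the simulated heading, which
keeps long synthetic trajectories rotationally consistent; a lab-frame mode
is available for literal re-sampling of observed vectors. Capture: target
within 0.5 body lengths (default body length 4 mm) of the head *and* within
±30° of the heading, evaluated at bout-start positions only (no intra-bout
interpolation). Find: isotropic encounter radius of 0.5 body lengths. One
target per trajectory per radius, uniform in the disk of that radius around
the start. Reflective boundaries mirror both position and heading at the
walls of a box centered at the origin. MSD is time-and-ensemble averaged
with a bootstrap CI over trajectories.

## The synthetic generator

The generator emulates exactly the structure the method assumes: latent
Markov switching among strategies (geometric dwells), wrapped-normal heading
changes, log-normal speeds, gamma inter-bout intervals, a signed left/right
bias, and planted groups via group-specific switching chains. Defaults are
realistic larval-zebrafish scales: bout speeds of ~4–16 mm/s, inter-bout
intervals of 0.5–0.9 s, heading-change spreads of ~10° (cruising) vs ~60–70°
(wandering), strategy dwells of ~10 bouts. The posture emission — a zero-mean
damped two-harmonic traveling tail wave plus a turn offset whose mean equals
the realized heading change — is a fixture convention that ties posture to
kinematics invertibly; it makes no claim about real tail mechanics.

What passing tests therefore show: the estimators recover the quantities
they define, at the stated problem sizes, when the model class is correct.
What they do not show: robustness to tracking noise, non-Markov memory,
drifting kinematics within a recording, or misdetected bouts — none of which
the generator produces.

## Problem sizes and tolerances

Test and acceptance problem sizes are chosen so the whole suite runs in a
couple of minutes on one core: symbolic sources of 3–9×10³ bouts for model
selection (20 repetitions), 10⁵-bout chains for spectral estimation (±0.01 on
λ₁), cohorts of 20–60 fish with 2–3×10³ bouts each for phenotyping, 2×10⁴
Monte-Carlo trials for capture geometry (3 binomial standard errors). The
end-to-end smoke run uses 10 fish × 2000 bouts and completes in seconds.
Known limitations at these scales: coarse-grained dwell times are biased
short by microstate misassignment (visible in the README example), and ε̂
slightly underestimates the self-distance of strongly non-stationary fish.

## CLI

The command-line interface is a thin wrapper over `run_pipeline`; stage
subcommands share the same driver and configuration schema, so re-running a
stage reproduces its upstream artifacts deterministically from the recorded
seeds rather than reloading partial state.
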