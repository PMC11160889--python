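# ethoscale

Multiscale Markov models of larval zebrafish swimming: from bout sequences to
metastable motor strategies to individual behavioral phenotypes.

Larval zebrafish move in discrete swim bouts. At the finest scale each bout is
a tail-posture trajectory; over seconds fish alternate between longer-lived
*motor strategies* (e.g. low-reorientation "cruising" vs high-reorientation
"wandering"); over the length of an experiment each fish expresses an
individual mixture of those strategies — its behavioral phenotype. `ethoscale`
implements the full chain of analysis for this picture, for anyone working
with bout-resolved behavioral recordings (or simulated ones):

1. **Maximally predictive state space.** Bout posture matrices are reduced by
   resampled PCA, stacked into overlapping windows of K consecutive bouts, and
   partitioned into N microstates by k-means++. The pair (K\*, N\*) is chosen
   from the short-time entropy rate of the resulting Markov chain,
   h = −Σ<sub>ij</sub> π<sub>i</sub> T<sub>ij</sub> log T<sub>ij</sub>:
   K\* where h(K) stops decreasing (within the bootstrap noise band), N\* at
   the peak of h(N) before finite-size effects suppress it.
2. **Transfer-operator coarse-graining.** A context-balanced ensemble
   transition matrix T(τ) is estimated, reversibilized, and its slow
   eigenvectors φ<sub>k</sub> are cut at the threshold maximizing the
   coherence χ(S) = Σ<sub>i,j∈S</sub> π<sub>i</sub>T<sub>ij</sub> / Σ<sub>i∈S</sub> π<sub>i</sub>
   (the probability of remaining in S after one lag). Rank-normalized,
   kinetically rescaled eigenvectors ψ<sub>k</sub> = −τ\*/(2 ln λ<sub>k</sub>)·φ<sub>k</sub>
   feed a π-weighted k-means that yields q metastable strategies per level of
   a nested hierarchy.
3. **Individual phenotyping.** Each fish's strategy sequence gives a q×q
   transition matrix T<sup>f</sup><sub>q</sub>. Fish are compared with the
   row-averaged Manhattan metric
   d(T, T′) = (1/q) Σ<sub>ij</sub> |T<sub>ij</sub> − T′<sub>ij</sub>|,
   embedded exactly into Euclidean space by Constant Shift Embedding, and
   classified into sensory contexts by a regularized logistic-regression
   harness. Each fish also carries a significance scale
   ε̂<sub>f</sub> = ⟨d(T̂, T)⟩ — the finite-recording uncertainty of its own
   matrix, estimated by re-fitting simulations of it.
4. **HMD clustering.** Hierarchical Multiplicative Diffusive clustering
   searches for metastability in the diffusion process defined by the
   uncertainty-rescaled kernel k(f<sub>i</sub>, f<sub>j</sub>) ∝
   exp(−D<sub>ij</sub>/√(ε̂<sub>i</sub>ε̂<sub>j</sub>)), splitting the most
   metastable cluster level by level and reporting per-fish group posteriors.
5. **Space simulation.** Microstate-conditioned velocity libraries roll
   symbolic sequences into lab-space trajectories (optionally in a reflective
   arena), giving MSD curves and capture/find efficiency versus target
   distance for individual strategies or phenotypic groups.

A first-class synthetic-cohort generator (metastable strategy switching,
strategy-specific kinematics, planted phenotypic groups) makes every stage
testable without any recordings.

## Worked example

```python
import numpy as np
from ethoscale import (CohortSpec, StrategySpec, generate_cohort,
                       fit_resampled_pca, project_cohort, delay_embed,
                       partition_microstates, symbol_sequences,
                       count_transitions, reversibilize, spectrum,
                       build_hierarchy, dwell_statistics)

# two motor strategies -- cruising (small heading changes) vs wandering --
# switching with a mean dwell of 10 bouts
strategies = [StrategySpec(label=0, heading_sigma=8.0, speed_mean=10.0),
              StrategySpec(label=1, heading_sigma=65.0, speed_mean=10.0)]
chain = np.array([[0.9, 0.1], [0.1, 0.9]])
cohort = generate_cohort(CohortSpec(n_fish=8, bouts_per_fish=1500,
                                    strategies=strategies,
                                    strategy_chains={0: chain}, seed=42))

basis = fit_resampled_pca(cohort, n_resamples=20, recs_per_resample=5, seed=0, d=3)
emb = delay_embed(project_cohort(cohort, basis), K=3)
part = partition_microstates(emb, N=20, seed=0)
seqs = symbol_sequences(emb, part)

T = count_transitions(seqs, tau=3, N=part.N)
modes = spectrum(reversibilize(T))
print(f"leading eigenvalues: {np.round(modes.lambdas[:4], 3)}")
print(f"implied timescale of mode 1: {modes.timescales[1]:.1f} bouts")

cg = build_hierarchy(T, tau_star=3, q_list=[2])[2]
print(f"strategy coherence: {np.round(cg.strategy_coherence, 3)}")

state_to_strategy = dict(zip(T.state_ids.tolist(), cg.assignment.tolist()))
lab = np.array([state_to_strategy[s] for s in seqs[0].symbols])
dw = dwell_statistics(lab)
for s, mean in sorted(dw.mean_length.items()):
    lo, hi = dw.mean_ci[s]
    print(f"strategy {s}: mean dwell {mean:.1f} bouts (95% CI {lo:.1f}-{hi:.1f})")
```

Output:

```
leading eigenvalues: [1.    0.468 0.054 0.048]
implied timescale of mode 1: 3.9 bouts
strategy coherence: [0.738 0.72 ]
strategy 0: mean dwell 8.6 bouts (95% CI 7.4-10.3)
strategy 1: mean dwell 7.0 bouts (95% CI 5.5-8.7)
```

The spectrum shows one slow mode well separated from the rest — the planted
cruise/wander alternation. Its implied timescale (−τ/ln λ₁ ≈ 3.9 bouts at
τ = 3) and the coarse-grained dwell times (≈ 7–9 bouts against a planted mean
of 10) are attenuated by microstate misassignment at this small problem size;
both sharpen as N and the recording length grow.

## Command line

The same pipeline runs from a YAML configuration:

```bash
ethoscale run -c config.yaml         # all stages
ethoscale cluster -c config.yaml     # through HMD clustering
```

Artifacts (HDF5 cohort, symbol tables, spectra, coarse-grainings, dwell
statistics, cluster tree JSON, efficiency curves, provenance with config hash
and seeds) are written to the configured output directory.

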