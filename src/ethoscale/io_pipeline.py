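"""Configuration, provenance and the end-to-end analysis driver.

The pipeline chains every stage: synthetic-cohort generation (or reading a
provided cohort), resampled PCA, delay embedding and entropy-rate model
selection, ensemble-operator estimation and spectra, coarse-graining into
metastable strategies, per-fish models, the phenotype space (distances,
significance scales, CSE, optional context classification), HMD clustering,
and lab-space simulation.  Every artifact directory carries a provenance
record (config hash, seeds, package version).  All angles are degrees in
I/O and radians internally; positions are mm; bout indices 0-based.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .cohort import Cohort, read_cohort_hdf5, read_fish_csv, write_cohort
from .coarse_grain import build_hierarchy
from .individual import dwell_statistics, fit_fish
from .phenotype import (classify_contexts, cse_embed, distance_matrix,
                        hmd_cluster, significance_scale)
from .preprocess import fit_resampled_pca, project_cohort
from .spacesim import (build_velocity_library, efficiency_curves, msd,
                       restricted_strategy_operator, simulate_symbols,
                       simulate_trajectory)
from .statespace import delay_embed, partition_microstates, select_K_N, symbol_sequences
from .synthetic import CohortSpec, demo_strategies, generate_cohort, metastable_chain
from .transfer_operator import ensemble_operator, noise_floor, reversibilize, spectrum

logger = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenerateConfig(_Strict):
    n_fish: int = 10
    bouts_per_fish: int = 2000
    n_groups: int = 2
    dwell: float = 0.9
    dwell_alt: float = 0.8  # self-dwell of the second planted group's chain
    frames_per_bout: int = 20
    n_contexts: int = 1


class PCAConfig(_Strict):
    n_resamples: int = 30
    recs_per_resample: int = 5
    var_threshold: float = 0.95
    d: int | None = None


class EmbedConfig(_Strict):
    K_grid: list[int] = [1, 2, 3]
    N_grid: list[int] = [10, 20]
    bouts_per_context: int = 2000
    n_seeds: int = 5
    K: int | None = None  # fix to skip selection
    N: int | None = None


class OperatorConfig(_Strict):
    tau_star: int = 3
    per_context_n: int = 2000
    n_seeds: int = 10
    n_shuffles: int = 10


class CoarsenConfig(_Strict):
    q_list: list[int] = [2, 4]


class FishConfig(_Strict):
    q: int | None = None  # default: max of q_list


class PhenotypeConfig(_Strict):
    n_sims: int = 50
    classify: bool = False
    n_shuffles: int = 20


class ClusterConfig(_Strict):
    max_levels: int = 6
    stop_rel_gain: float = 0.05
    fuzziness: float = 2.0


class SimulateConfig(_Strict):
    enabled: bool = True
    n_traj: int = 200
    length: int = 300
    r_grid: list[float] = [2.0, 5.0, 10.0, 20.0, 40.0]
    body_length: float = 4.0
    box: list[float] | None = None
    max_lag: int = 50


class RunConfig(_Strict):
    schema_version: int = 1
    seed: int = 0
    input: str | None = None  # cohort HDF5; None -> generate synthetically
    input_dialect: str = "hdf5"
    output_dir: str = "ethoscale_out"
    generate: GenerateConfig = GenerateConfig()
    pca: PCAConfig = PCAConfig()
    embed: EmbedConfig = EmbedConfig()
    operator: OperatorConfig = OperatorConfig()
    coarsen: CoarsenConfig = CoarsenConfig()
    fish: FishConfig = FishConfig()
    phenotype: PhenotypeConfig = PhenotypeConfig()
    cluster: ClusterConfig = ClusterConfig()
    simulate: SimulateConfig = SimulateConfig()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_cohort(path, dialect: str = "hdf5") -> Cohort:
    """Read a cohort from HDF5 (canonical) or a directory of per-fish CSVs."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort input not found: {path}")
    if dialect == "hdf5":
        return read_cohort_hdf5(path)
    if dialect == "csv":
        cohort = Cohort()
        for p in sorted(path.glob("*.csv")):
            cohort.fish[p.stem] = read_fish_csv(p, fish_id=p.stem)
        if not cohort.fish:
            raise ValueError(f"no per-fish CSV files under {path}")
        return cohort
    raise ValueError(f"unknown dialect {dialect!r}")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _synthetic_cohort(cfg: RunConfig) -> Cohort:
    g = cfg.generate
    strategies = demo_strategies()
    chains = {}
    for grp in range(g.n_groups):
        dwell = g.dwell if grp % 2 == 0 else g.dwell_alt
        chains[grp] = metastable_chain(len(strategies), dwell=dwell,
                                       block_sizes=[2, 2], block_dwell=0.7)
    spec = CohortSpec(
        n_fish=g.n_fish,
        bouts_per_fish=g.bouts_per_fish,
        strategies=strategies,
        strategy_chains=chains,
        group_assignment=[i % g.n_groups for i in range(g.n_fish)],
        context_labels=[f"ctx{i % g.n_contexts}" for i in range(g.n_fish)],
        frames_per_bout=g.frames_per_bout,
        seed=cfg.seed,
    )
    return generate_cohort(spec)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the artifact dict and writes files.

    A stage failure raises :class:`PipelineError` tagged with the stage name;
    artifacts written by earlier stages are left in place.
    """
    if config.input is not None and not Path(config.input).exists():
        raise FileNotFoundError(f"cohort input not found: {config.input}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    stage = "init"
    try:
        stage = "generate"
        if config.input is None:
            cohort = _synthetic_cohort(config)
            write_cohort(out / "cohort.h5", cohort)
        else:
            cohort = read_cohort(config.input, config.input_dialect)
        artifacts["cohort"] = cohort
        contexts = {fid: f.context for fid, f in cohort.fish.items()}

        stage = "pca"
        basis = fit_resampled_pca(
            cohort, n_resamples=config.pca.n_resamples,
            recs_per_resample=config.pca.recs_per_resample,
            seed=config.seed, var_threshold=config.pca.var_threshold, d=config.pca.d,
        )
        coeffs = project_cohort(cohort, basis)
        np.savez(out / "pca_basis.npz", mean=basis.mean, components=basis.components,
                 eigenvalues=basis.eigenvalues, d=basis.d)
        artifacts["basis"] = basis

        stage = "embed"
        ec = config.embed
        if ec.K is not None and ec.N is not None:
            K_star, N_star, surface = ec.K, ec.N, {}
        else:
            K_star, N_star, surface = select_K_N(
                coeffs, contexts, ec.K_grid, ec.N_grid,
                bouts_per_context=ec.bouts_per_context, n_seeds=ec.n_seeds,
                seed=config.seed,
            )
            rows = [{"K": K, "N": N, "mean": m, "lo": lo, "hi": hi}
                    for (K, N), (m, lo, hi) in surface.items()]
            pd.DataFrame(rows).to_csv(out / "entropy_surface.csv", index=False)
        embedding = delay_embed(coeffs, K_star)
        partition = partition_microstates(embedding, N_star, seed=config.seed)
        seqs = symbol_sequences(embedding, partition)
        pd.DataFrame({
            "fish_id": [f for f, _ in embedding.index],
            "start_bout": [t for _, t in embedding.index],
            "microstate": partition.labels,
        }).to_csv(out / "symbols.csv", index=False)
        artifacts.update(K_star=K_star, N_star=N_star, surface=surface,
                         embedding=embedding, partition=partition, seqs=seqs)

        stage = "operator"
        oc = config.operator
        T_ens = ensemble_operator(seqs, contexts, N=partition.N,
                                  per_context_n=oc.per_context_n,
                                  n_seeds=oc.n_seeds, tau=oc.tau_star, seed=config.seed)
        Trev = reversibilize(T_ens)
        modes = spectrum(Trev)
        modes.noise_floor = noise_floor(seqs, tau=oc.tau_star, N=partition.N,
                                        n_shuffles=oc.n_shuffles, seed=config.seed)
        pd.DataFrame({
            "lambda": modes.lambdas,
            "timescale": modes.timescales,
        }).to_csv(out / "spectrum.csv", index=False)
        artifacts.update(T_ensemble=T_ens, T_rev=Trev, modes=modes)

        stage = "coarsen"
        q_list = [q for q in config.coarsen.q_list if q <= Trev.N]
        hierarchy = build_hierarchy(T_ens, tau_star=oc.tau_star, q_list=q_list,
                                    seed=config.seed)
        pd.concat([
            pd.DataFrame({"microstate": Trev.state_ids, "q": q,
                          "strategy": cg.assignment})
            for q, cg in hierarchy.items()
        ]).to_csv(out / "coarse_grainings.csv", index=False)
        artifacts["hierarchy"] = hierarchy

        stage = "fish"
        q_fish = config.fish.q or max(hierarchy)
        cg = hierarchy[q_fish]
        state_to_strategy = dict(zip(Trev.state_ids.tolist(), cg.assignment.tolist()))
        models, dwell_rows = [], []
        strategy_labels: dict[str, np.ndarray] = {}
        for s in seqs:
            lab = np.array([state_to_strategy.get(int(x), -1) for x in s.symbols])
            lab = lab[lab >= 0]
            if len(lab) < q_fish:
                logger.warning("fish %s: too few labeled bouts, skipped", s.fish_id)
                continue
            strategy_labels[s.fish_id] = lab
            m = fit_fish(lab, q_fish, fish_id=s.fish_id, context=contexts[s.fish_id])
            models.append(m)
            dw = dwell_statistics(lab, seed=config.seed)
            for strat, mean in dw.mean_length.items():
                dwell_rows.append({"fish_id": s.fish_id, "strategy": strat,
                                   "mean_run": mean, "ci_lo": dw.mean_ci[strat][0],
                                   "ci_hi": dw.mean_ci[strat][1]})
        pd.DataFrame(dwell_rows).to_csv(out / "dwell_statistics.csv", index=False)
        artifacts.update(models=models, strategy_labels=strategy_labels)

        stage = "phenotype"
        space = distance_matrix(models)
        space.eps = np.array([
            significance_scale(m, n_sims=config.phenotype.n_sims,
                               seed=config.seed + i)
            for i, m in enumerate(models)
        ])
        space.embedding, space.weights = cse_embed(space.D)
        artifacts["space"] = space
        if config.phenotype.classify and len(set(contexts.values())) >= 2:
            labels = [m.context for m in models]
            artifacts["classification"] = classify_contexts(
                space, labels, n_shuffles=config.phenotype.n_shuffles,
                seed=config.seed)

        stage = "cluster"
        eps = np.clip(space.eps, 1e-9, None)
        tree = hmd_cluster(space.D, eps, max_levels=config.cluster.max_levels,
                           stop_rel_gain=config.cluster.stop_rel_gain,
                           fuzziness=config.cluster.fuzziness, seed=config.seed)
        tree.fish_ids = space.fish_ids
        with open(out / "cluster_tree.json", "w") as fh:
            json.dump(tree.to_dict(), fh, indent=1, sort_keys=True)
        artifacts["tree"] = tree

        if config.simulate.enabled:
            stage = "simulate"
            sc = config.simulate
            labels_per_fish = {
                fid: partition.labels[sl] for fid, sl in embedding.fish_slices.items()
            }
            lib = build_velocity_library(cohort, labels_per_fish)
            from .transfer_operator import count_transitions
            T1 = count_transitions(seqs, tau=1, N=partition.N)
            rng = np.random.default_rng(config.seed)
            rows = []
            for strat in range(cg.q):
                members = np.flatnonzero(cg.assignment == strat)
                Tr = restricted_strategy_operator(T1, Trev.state_ids[members])
                eff = efficiency_curves(Tr, lib, np.asarray(sc.r_grid),
                                        n_traj=sc.n_traj, length=sc.length,
                                        body_length=sc.body_length,
                                        seed=int(rng.integers(2**31)))
                for j, r in enumerate(eff["r"]):
                    rows.append({"strategy": strat, "r": r,
                                 "capture": eff["capture_probability"][j],
                                 "find": eff["find_probability"][j]})
            pd.DataFrame(rows).to_csv(out / "efficiency.csv", index=False)
            trajs = [
                simulate_trajectory(
                    simulate_symbols(T1, sc.length, rng), lib,
                    seed=int(rng.integers(2**31)),
                    boundary=tuple(sc.box) if sc.box else None)
                for _ in range(20)
            ]
            lags, m, (lo, hi) = msd(trajs, max_lag=min(sc.max_lag, sc.length - 1))
            pd.DataFrame({"lag": lags, "msd": m, "lo": lo, "hi": hi}).to_csv(
                out / "msd.csv", index=False)
            artifacts["msd"] = (lags, m)

        stage = "report"
        with open(out / "provenance.json", "w") as fh:
            json.dump({"config_hash": config.hash(), "seed": config.seed,
                       "version": __version__,
                       "config": config.model_dump()}, fh, indent=1, sort_keys=True)
    except Exception as exc:  # noqa: BLE001 - tag and re-raise with stage context
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return artifacts
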