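"""Population-based domain assembly.

A pool of candidate torsion vectors is evolved under the ACD potential:
each generation, every pool slot produces one offspring by uniform
crossover with a random mate followed by per-gene Gaussian mutation, and
the slot keeps whichever of parent/offspring has the lower energy. This
pairwise elitism makes the best pool energy non-increasing by
construction. Defaults mirror the published protocol: 1,000 initial
models, 500 iterations, top 10 models by energy, eight movable linker
residues per boundary.

The optimizer is memetic: every ``refine_every`` generations the current
best slot is polished by a bounded quasi-Newton local search (L-BFGS-B
with numerical gradients) on the same objective, and keeps the refined
vector only when it improves. Linker torsions couple through long lever
arms, so the ACD landscape is a narrow curved valley that pure
crossover/mutation moves descend very slowly; the gradient polish follows
the valley while the population supplies basin diversity. Refinement is
deterministic and slot-elitist, so reproducibility and the monotone
best-energy trace are unaffected.

Everything runs on the coarse-grained backbone+CB representation; no
full-atom (side-chain) refinement stage is included, so ranking is by
F_ACD alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .frames import wrap_angle
from .interactions import InteractionMap, decode_distributions
from .kinematics import (LinkerSpec, TorsionPlan, apply_torsions,
                         build_base_full_length, linker_residues,
                         sample_initial_genes)
from .potential import ACDContext, acd, build_acd_context
from .structure import BackboneStructure, DomainLayout, write_pdb


@dataclass
class AssemblyConfig:
    """Optimizer settings. Defaults are the published protocol constants
    (pool 1000, 500 iterations, top 10, 8 linker residues); operator
    constants (crossover/mutation rates and widths) are package choices."""

    pool_size: int = 1000
    iterations: int = 500
    top_k: int = 10
    linker_width: int = 8
    crossover_rate: float = 0.5
    mutation_rate: float = 0.1
    mutation_sd_angle: float = np.deg2rad(30.0)
    mutation_sd_trans: float = 2.0
    rng_seed: int = 0
    r_max: float = 40.0
    steric_weight: float = 0.0
    clamp: float | None = None
    refine_every: int = 50
    refine_maxfun: int = 1500

    def __post_init__(self):
        if self.pool_size < 2:
            raise ValidationError("pool_size must be >= 2")
        if self.iterations < 0:
            raise ValidationError("iterations must be >= 0")
        if not 0 < self.top_k <= self.pool_size:
            raise ValidationError("top_k must be in [1, pool_size]")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.refine_every < 0 or self.refine_maxfun < 0:
            raise ValidationError("refinement settings must be >= 0")


@dataclass
class Individual:
    """One pool member: a decision vector with its cached energy."""
    genes: np.ndarray
    energy: float | None = None
    structure: BackboneStructure | None = None


class AssemblyProblem:
    """Compiled evaluation pipeline: genes -> conformation -> F_ACD."""

    def __init__(self, base: BackboneStructure, spec: LinkerSpec,
                 ctx: ACDContext):
        self.base = base
        self.spec = spec
        self.ctx = ctx
        self._plan = TorsionPlan(base, spec)

    @classmethod
    def from_inputs(cls, domains: list[BackboneStructure],
                    layout: DomainLayout, interactions: InteractionMap,
                    cfg: AssemblyConfig) -> "AssemblyProblem":
        if interactions.dialect == "dist":
            interactions = decode_distributions(interactions)
        base = build_base_full_length(domains, layout)
        spec = linker_residues(layout, width=cfg.linker_width)
        ctx = build_acd_context(interactions, clamp=cfg.clamp,
                                steric_weight=cfg.steric_weight)
        return cls(base, spec, ctx)

    def realize(self, genes: np.ndarray) -> BackboneStructure:
        return apply_torsions(self.base, self.spec, genes, plan=self._plan)

    def evaluate(self, genes: np.ndarray) -> float:
        return acd(self.realize(genes), self.ctx)


# ---------------------------------------------------------------------------
# Operators


def crossover(a: np.ndarray, b: np.ndarray, rng: np.random.Generator,
              rate: float = 0.5) -> np.ndarray:
    """Uniform crossover: each gene comes from ``a`` with probability
    ``rate``, else from ``b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("crossover parents differ in length")
    take_a = rng.random(a.shape) < rate
    return np.where(take_a, a, b)


def mutate(v: np.ndarray, rng: np.random.Generator, rate: float,
           sd_angle: float, sd_trans: float,
           angle_mask: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian mutation with probability ``rate``; angle genes
    get wrapped-Gaussian noise of sd ``sd_angle`` and are re-wrapped to
    [-pi, pi), translation genes plain Gaussian of sd ``sd_trans``."""
    v = np.asarray(v, dtype=float).copy()
    hit = rng.random(v.shape) < rate
    noise = rng.normal(0.0, 1.0, v.shape)
    sd = np.where(angle_mask, sd_angle, sd_trans)
    v = v + hit * noise * sd
    v[angle_mask] = wrap_angle(v[angle_mask])
    return v


def init_population(problem: AssemblyProblem, cfg: AssemblyConfig,
                    seed_seq: np.random.SeedSequence | None = None
                    ) -> list[Individual]:
    """Random evaluated pool; per-individual generators are spawned from
    one seed sequence so results are reproducible at any pool size."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.rng_seed)
    pool = []
    for child in seed_seq.spawn(cfg.pool_size):
        rng = np.random.default_rng(child)
        genes = sample_initial_genes(problem.base, problem.spec, rng)
        pool.append(Individual(genes, energy=problem.evaluate(genes)))
    return pool


def evolve_step(pool: list[Individual], problem: AssemblyProblem,
                cfg: AssemblyConfig,
                rng: np.random.Generator) -> list[Individual]:
    """One generation: per slot, offspring = mutate(crossover(parent,
    random distinct mate)); keep the lower-energy of parent and offspring
    (ties keep the parent)."""
    n = len(pool)
    angle_mask = problem.spec.angle_gene_mask()
    out: list[Individual] = []
    for i, parent in enumerate(pool):
        j = int(rng.integers(n - 1))
        if j >= i:
            j += 1
        child_genes = crossover(parent.genes, pool[j].genes, rng,
                                cfg.crossover_rate)
        child_genes = mutate(child_genes, rng, cfg.mutation_rate,
                             cfg.mutation_sd_angle, cfg.mutation_sd_trans,
                             angle_mask)
        e = problem.evaluate(child_genes)
        if e < parent.energy:
            out.append(Individual(child_genes, energy=e))
        else:
            out.append(parent)
    return out


def refine_individual(ind: Individual, problem: AssemblyProblem,
                      maxfun: int = 1500) -> Individual:
    """Deterministic local polish of one individual (L-BFGS-B, numerical
    gradients); returns the refined individual only if strictly better."""
    from scipy.optimize import minimize
    res = minimize(problem.evaluate, ind.genes, method="L-BFGS-B",
                   options={"maxfun": int(maxfun), "eps": 1e-6})
    if res.fun < ind.energy:
        return Individual(np.asarray(res.x, dtype=float).copy(),
                          energy=float(res.fun))
    return ind


@dataclass
class AssemblyResult:
    """Ranked models plus the per-iteration energy trace."""
    models: list[Individual]
    trace: list[dict]
    config: AssemblyConfig
    problem: AssemblyProblem = field(repr=False, default=None)

    @property
    def best_energy(self) -> float:
        return self.models[0].energy


def run_assembly(domains: list[BackboneStructure], layout: DomainLayout,
                 interactions: InteractionMap,
                 cfg: AssemblyConfig | None = None) -> AssemblyResult:
    """Full pipeline: initialize, evolve ``cfg.iterations`` generations,
    return the ``cfg.top_k`` lowest-energy models with realized structures.
    Bit-reproducible for a fixed (inputs, seed, config)."""
    cfg = cfg or AssemblyConfig()
    problem = AssemblyProblem.from_inputs(domains, layout, interactions, cfg)
    root = np.random.SeedSequence(cfg.rng_seed)
    init_ss, evolve_ss = root.spawn(2)
    pool = init_population(problem, cfg, init_ss)
    rng = np.random.default_rng(evolve_ss)

    trace: list[dict] = []
    energies = np.array([ind.energy for ind in pool])
    trace.append({"iteration": 0, "best": float(energies.min()),
                  "mean": float(energies.mean())})
    for it in range(1, cfg.iterations + 1):
        pool = evolve_step(pool, problem, cfg, rng)
        if cfg.refine_every and it % cfg.refine_every == 0:
            k = int(np.argmin([ind.energy for ind in pool]))
            pool[k] = refine_individual(pool[k], problem,
                                        maxfun=cfg.refine_maxfun)
        energies = np.array([ind.energy for ind in pool])
        trace.append({"iteration": it, "best": float(energies.min()),
                      "mean": float(energies.mean())})

    order = np.argsort([ind.energy for ind in pool], kind="stable")
    top = []
    for rank in order[: cfg.top_k]:
        ind = pool[rank]
        top.append(Individual(ind.genes.copy(), energy=ind.energy,
                              structure=problem.realize(ind.genes)))
    return AssemblyResult(top, trace, cfg, problem)


def write_assembly_outputs(result: AssemblyResult, out_dir) -> dict:
    """Ranked model PDBs plus energies.tsv and trace.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"models": []}
    for rank, ind in enumerate(result.models, start=1):
        p = out_dir / f"model_{rank:02d}.pdb"
        write_pdb(ind.structure, p)
        paths["models"].append(p)
    paths["energies"] = out_dir / "energies.tsv"
    with open(paths["energies"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["rank", "energy", "seed"])
        for rank, ind in enumerate(result.models, start=1):
            w.writerow([rank, f"{ind.energy:.6f}", result.config.rng_seed])
    paths["trace"] = out_dir / "trace.tsv"
    with open(paths["trace"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["iteration", "best", "mean"])
        for row in result.trace:
            w.writerow([row["iteration"], f"{row['best']:.6f}",
                        f"{row['mean']:.6f}"])
    return paths


def config_as_dict(cfg: AssemblyConfig) -> dict:
    d = asdict(cfg)
    d["mutation_sd_angle_deg"] = float(np.rad2deg(d.pop("mutation_sd_angle")))
    return d
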