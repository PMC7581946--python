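"""Genetic-algorithm calibration of link operators against training data.

Training data are binary steady-state activities for a subset of nodes
(in real applications inferred from omics; here possibly synthetic).
The GA never touches topology: it only flips link operators between the
``(...) AND NOT (...)`` and ``(...) OR NOT (...)`` rule forms, the one
alteration compatible with the fixed rule template.  Selection is
elitist mutation-selection without crossover.  Several independent runs
each contribute their best model, giving an ensemble of equally
plausible models over one topology.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .logic_engine import fixed_points
from .network_io import (
    AND_NOT,
    OR_NOT,
    BooleanModel,
    LogicalNetwork,
    default_model,
)

__all__ = [
    "TrainingProfile",
    "GAConfig",
    "ModelEnsemble",
    "EmptyEnsembleError",
    "fitness",
    "mutate",
    "evolve",
    "restrict_to_common",
    "read_training_profile",
]


@dataclass(frozen=True)
class TrainingProfile:
    """Observed binary steady-state activities with per-node weights."""

    observations: Mapping[str, int]
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError("training profile must observe at least one node")
        for node, state in self.observations.items():
            if state not in (0, 1):
                raise ValueError(f"observed state of {node!r} must be 0 or 1")
        for node, w in self.weights.items():
            if node not in self.observations:
                raise ValueError(f"weight for unobserved node {node!r}")
            if w <= 0:
                raise ValueError(f"weight for {node!r} must be positive")

    def weight(self, node: str) -> float:
        return self.weights.get(node, 1.0)

    def digest(self) -> str:
        items = sorted((n, s, self.weight(n)) for n, s in self.observations.items())
        return hashlib.sha256(repr(items).encode()).hexdigest()[:16]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    ``runs`` independent restarts each evolve ``population`` models for
    ``generations`` generations, carrying the top ``elite`` unchanged
    and refilling with children mutated at ``mutations_per_child``
    uniformly chosen loci.  Each run's best model joins the ensemble if
    its fitness reaches ``fitness_threshold``.  ``fitness_aggregate``
    chooses how multi-attractor models are scored (mean or max over
    fixed points).
    """

    population: int = 20
    generations: int = 20
    elite: int = 3
    mutations_per_child: int = 3
    runs: int = 50
    fitness_threshold: float = 0.0
    seed: int = 0
    fitness_aggregate: str = "mean"

    def __post_init__(self) -> None:
        if not (0 < self.elite <= self.population):
            raise ValueError("need 0 < elite <= population")
        if self.generations < 1 or self.runs < 1:
            raise ValueError("generations and runs must be >= 1")
        if not (0.0 <= self.fitness_threshold <= 1.0):
            raise ValueError("fitness_threshold must lie in [0, 1]")
        if self.fitness_aggregate not in ("mean", "max"):
            raise ValueError("fitness_aggregate must be 'mean' or 'max'")


@dataclass
class ModelEnsemble:
    """Best-per-run models over one topology with their fitnesses."""

    models: list[BooleanModel]
    fitnesses: list[float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.models) != len(self.fitnesses):
            raise ValueError("models and fitnesses must be parallel")

    def __len__(self) -> int:
        return len(self.models)

    @property
    def mean_fitness(self) -> float:
        return float(np.mean(self.fitnesses))


class EmptyEnsembleError(RuntimeError):
    pass


def fitness(model: BooleanModel, profile: TrainingProfile, aggregate: str = "mean") -> float:
    """Agreement of a model's fixed points with the training profile.

    Per fixed point: weighted fraction of observed nodes whose state
    matches the observation.  The model score aggregates over fixed
    points (mean by default); a model with no fixed point scores 0.
    """
    node_set = set(model.network.nodes)
    for node in profile.observations:
        if node not in node_set:
            raise ValueError(f"profile node {node!r} not in network")
    fps = fixed_points(model)
    if not fps:
        return 0.0
    total_w = sum(profile.weight(n) for n in profile.observations)
    matches = []
    for fp in fps:
        w = sum(
            profile.weight(n)
            for n, obs in profile.observations.items()
            if fp[n] == obs
        )
        matches.append(w / total_w)
    return float(max(matches) if aggregate == "max" else np.mean(matches))


def mutate(
    model: BooleanModel,
    n: int,
    rng: np.random.Generator,
    model_id: Optional[str] = None,
) -> BooleanModel:
    """Toggle the link operator at ``n`` uniformly drawn mutable loci.

    Loci are drawn with replacement, so an even number of hits on one
    locus restores its operator.  The input model is left unchanged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    loci = model.mutable_targets()
    if not loci:
        raise ValueError("model has no mutable equation (no node with both "
                         "activators and inhibitors)")
    child = model.copy(model_id=model_id)
    for _ in range(n):
        target = loci[int(rng.integers(len(loci)))]
        child.equations[target] = child.equations[target].toggled()
    return child


def _randomized_init(network: LogicalNetwork, rng: np.random.Generator,
                     model_id: str) -> BooleanModel:
    model = default_model(network, model_id=model_id)
    for target in model.mutable_targets():
        op = AND_NOT if rng.integers(2) == 0 else OR_NOT
        model.equations[target] = model.equations[target].with_operator(op)
    return model


def evolve(
    network: LogicalNetwork,
    profile: TrainingProfile,
    config: GAConfig,
) -> ModelEnsemble:
    """Evolve link operators to match a training profile; return the ensemble.

    Fully reproducible from ``config.seed``: every run draws from its own
    child stream of the seed sequence.  Raises
    :class:`EmptyEnsembleError` (reporting the best fitness achieved)
    when no run reaches the fitness threshold.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.runs)
    ensemble_models: list[BooleanModel] = []
    ensemble_fits: list[float] = []
    best_overall = 0.0
    history: list[list[float]] = []

    for run_idx, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        pop: list[tuple[BooleanModel, float]] = []
        for i in range(config.population):
            m = _randomized_init(network, rng, model_id=f"r{run_idx}_g0_i{i}")
            pop.append((m, fitness(m, profile, config.fitness_aggregate)))
        run_history = []
        counter = config.population
        for gen in range(1, config.generations + 1):
            pop.sort(key=lambda mf: (-mf[1], mf[0].model_id))
            elites = pop[: config.elite]
            run_history.append(elites[0][1])
            if gen == config.generations:
                pop = elites
                break
            children = []
            while len(elites) + len(children) < config.population:
                parent = elites[int(rng.integers(len(elites)))][0]
                child = mutate(parent, config.mutations_per_child, rng,
                               model_id=f"r{run_idx}_g{gen}_i{counter}")
                counter += 1
                children.append((child, fitness(child, profile,
                                                config.fitness_aggregate)))
            pop = list(elites) + children
        best_model, best_fit = pop[0]
        best_overall = max(best_overall, best_fit)
        history.append(run_history)
        if best_fit >= config.fitness_threshold:
            ensemble_models.append(best_model.copy(model_id=f"run{run_idx}_best"))
            ensemble_fits.append(best_fit)

    if not ensemble_models:
        raise EmptyEnsembleError(
            f"no run reached fitness threshold {config.fitness_threshold}; "
            f"best achieved fitness was {best_overall:.4f}"
        )
    provenance = {
        "config": config,
        "profile_digest": profile.digest(),
        "best_fitness_history": history,
    }
    return ModelEnsemble(models=ensemble_models, fitnesses=ensemble_fits,
                         provenance=provenance)


def restrict_to_common(a: TrainingProfile, b: TrainingProfile) -> TrainingProfile:
    """Training-set reduction: restrict ``a`` to the nodes ``b`` also observes.

    Used to compare training sets of different breadth on equal footing:
    the larger profile is cut down to the nodes for which the smaller
    one also predicts a state.
    """
    common = set(a.observations) & set(b.observations)
    if not common:
        raise ValueError("profiles share no observed node")
    return TrainingProfile(
        observations={n: a.observations[n] for n in common},
        weights={n: a.weights[n] for n in common if n in a.weights},
    )


def read_training_profile(path: str | Path) -> TrainingProfile:
    """Read a profile TSV: columns node, state, optional weight."""
    obs: dict[str, int] = {}
    weights: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if lineno == 1 and fields[0].lower() == "node":
            continue
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected at least 2 columns")
        obs[fields[0]] = int(fields[1])
        if len(fields) >= 3 and fields[2]:
            weights[fields[0]] = float(fields[2])
    return TrainingProfile(observations=obs, weights=weights)
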