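"""Grammar-guided genetic programming over FNT topologies.

Every generation/crossover/mutation operator is constrained by the grammar
(:class:`cfnforest.fnt.GrammarSpec`), so no invalid individual is ever
produced. Structure search (here) alternates with parameter search
(:mod:`cfnforest.pso`) in :func:`train_fnt`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fnt import (
    FlexibleNeuralTree,
    FunctionNode,
    GrammarSpec,
    Leaf,
    TreeNode,
    _copy_node,
    _depth,
    fitness,
)
from .pso import PSOConfig, optimize_params

__all__ = [
    "GGGPConfig",
    "Population",
    "random_tree",
    "crossover",
    "mutate",
    "select",
    "evolve_structure",
    "train_fnt",
]

logger = logging.getLogger(__name__)

# Probability that a non-depth-capped symbol expands to a function node.
# Kept well below 1/E[arity] so random trees stay sparse: sparse trees keep
# the PSO parameter vector short and force leaf-level feature selection,
# which is where the classification signal lives.
_P_FUNCTION = 0.55


@dataclass
class GGGPConfig:
    population_size: int = 30
    generations: int = 20
    crossover_prob: float = 0.8
    mutation_prob: float = 0.2
    tournament_size: int = 3
    max_depth: int = 5
    fitness_tol: float = 1e-4
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tournament_size > self.population_size:
            raise ValueError("tournament_size must not exceed population_size")
        if min(self.population_size, self.generations,
               self.tournament_size, self.max_depth) < 1:
            raise ValueError("population/generations/tournament/depth must be >= 1")


@dataclass
class Population:
    individuals: list[FlexibleNeuralTree]
    fitnesses: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fitnesses and len(self.fitnesses) != len(self.individuals):
            raise ValueError("individuals and fitnesses must have equal lengths")


def _random_subtree(grammar: GrammarSpec, rng: np.random.Generator,
                    depth_budget: int) -> TreeNode:
    if depth_budget <= 1 or rng.uniform() >= _P_FUNCTION:
        return Leaf(int(rng.integers(grammar.input_dim)))
    arity = int(rng.choice(grammar.function_set.arities))
    children = [_random_subtree(grammar, rng, depth_budget - 1) for _ in range(arity)]
    weights = rng.uniform(-1.0, 1.0, size=arity)
    bias = float(rng.uniform(-1.0, 1.0))
    return FunctionNode(children, weights, bias)


def random_tree(grammar: GrammarSpec, rng: np.random.Generator) -> FlexibleNeuralTree:
    """Draw a grammar-valid tree; weights and biases ~ U(-1, 1).

    The root is a function node whenever the depth bound allows one, so
    random individuals are proper networks rather than bare leaves (a bare
    leaf remains legal and can still arise through crossover).
    """
    if grammar.max_depth == 1:
        root: TreeNode = Leaf(int(rng.integers(grammar.input_dim)))
    else:
        arity = int(rng.choice(grammar.function_set.arities))
        children = [
            _random_subtree(grammar, rng, grammar.max_depth - 1) for _ in range(arity)
        ]
        root = FunctionNode(
            children, rng.uniform(-1.0, 1.0, size=arity), float(rng.uniform(-1.0, 1.0))
        )
    return FlexibleNeuralTree(root, grammar.function_set, grammar.input_dim)


def _paths(node: TreeNode, prefix: tuple[int, ...] = ()) -> list[tuple[tuple[int, ...], TreeNode]]:
    out = [(prefix, node)]
    if isinstance(node, FunctionNode):
        for i, c in enumerate(node.children):
            out.extend(_paths(c, prefix + (i,)))
    return out


def _get(node: TreeNode, path: tuple[int, ...]) -> TreeNode:
    for i in path:
        node = node.children[i]
    return node


def _replace(node: TreeNode, path: tuple[int, ...], sub: TreeNode) -> TreeNode:
    if not path:
        return sub
    new = FunctionNode([_copy_node(c) for c in node.children],
                       node.weights.copy(), node.bias)
    new.children[path[0]] = _replace(node.children[path[0]], path[1:], sub)
    return new


def crossover(
    a: FlexibleNeuralTree,
    b: FlexibleNeuralTree,
    rng: np.random.Generator,
    max_depth: int | None = None,
    max_attempts: int = 20,
) -> tuple[FlexibleNeuralTree, FlexibleNeuralTree]:
    """Swap a uniformly chosen subtree of each parent.

    Swap points are resampled until both offspring respect the depth bound;
    if no legal swap is found within ``max_attempts``, copies of the parents
    are returned. Parents are never modified.
    """
    if a.input_dim != b.input_dim or a.function_set != b.function_set:
        raise ValueError("parents must share grammar and input_dim")
    if max_depth is None:
        max_depth = max(a.depth(), b.depth())
    paths_a = _paths(a.root)
    paths_b = _paths(b.root)
    for _ in range(max_attempts):
        pa, sub_a = paths_a[int(rng.integers(len(paths_a)))]
        pb, sub_b = paths_b[int(rng.integers(len(paths_b)))]
        depth_a = len(pa) + _depth(sub_b)
        depth_b = len(pb) + _depth(sub_a)
        if depth_a <= max_depth and depth_b <= max_depth:
            child_a = FlexibleNeuralTree(
                _replace(a.root, pa, _copy_node(sub_b)), a.function_set, a.input_dim
            )
            child_b = FlexibleNeuralTree(
                _replace(b.root, pb, _copy_node(sub_a)), b.function_set, b.input_dim
            )
            return child_a, child_b
    return a.copy(), b.copy()


def mutate(
    t: FlexibleNeuralTree,
    rng: np.random.Generator,
    mutation_prob: float,
    max_depth: int | None = None,
) -> FlexibleNeuralTree:
    """With probability ``mutation_prob`` replace a uniformly chosen node by
    a fresh grammar-valid random subtree fitting the depth budget."""
    if rng.uniform() >= mutation_prob:
        return t.copy()
    if max_depth is None:
        max_depth = t.depth()
    grammar = GrammarSpec(t.function_set, t.input_dim, max_depth)
    paths = _paths(t.root)
    path, _ = paths[int(rng.integers(len(paths)))]
    budget = max_depth - len(path)
    sub = _random_subtree(grammar, rng, max(budget, 1))
    return FlexibleNeuralTree(_replace(t.root, path, sub), t.function_set, t.input_dim)


def select(
    pop: Population, rng: np.random.Generator, tournament_size: int
) -> FlexibleNeuralTree:
    """Tournament selection: best (lowest fitness) of a uniform sample of
    ``tournament_size`` distinct individuals."""
    if not pop.individuals:
        raise ValueError("empty population")
    idx = rng.choice(len(pop.individuals), size=tournament_size, replace=False)
    best = min(idx, key=lambda i: pop.fitnesses[i])
    return pop.individuals[int(best)]


def evolve_structure(
    X: np.ndarray,
    y: np.ndarray,
    grammar: GrammarSpec,
    cfg: GGGPConfig,
    rng: np.random.Generator,
    seed_trees: list[FlexibleNeuralTree] | None = None,
    trace: list[float] | None = None,
) -> FlexibleNeuralTree:
    """Generational GP loop with elitism of one; returns the best-ever tree.

    ``seed_trees`` (optional) are injected into the initial population so the
    outer training loop can resume from an incumbent topology. ``trace``, if
    given, accumulates the best-ever fitness after each generation.
    """
    individuals: list[FlexibleNeuralTree] = []
    if seed_trees:
        individuals.extend(t.copy() for t in seed_trees[: cfg.population_size])
    while len(individuals) < cfg.population_size:
        individuals.append(random_tree(grammar, rng))
    fits = [fitness(t, X, y) for t in individuals]
    pop = Population(individuals, fits)
    best_i = int(np.argmin(fits))
    best_tree, best_fit = pop.individuals[best_i].copy(), fits[best_i]
    if trace is not None:
        trace.append(best_fit)
    for gen in range(cfg.generations):
        if best_fit < cfg.fitness_tol:
            break
        offspring: list[FlexibleNeuralTree] = [best_tree.copy()]  # elitism of 1
        while len(offspring) < cfg.population_size:
            p1 = select(pop, rng, cfg.tournament_size)
            p2 = select(pop, rng, cfg.tournament_size)
            if rng.uniform() < cfg.crossover_prob:
                c1, c2 = crossover(p1, p2, rng, max_depth=cfg.max_depth)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                if len(offspring) < cfg.population_size:
                    offspring.append(
                        mutate(child, rng, cfg.mutation_prob, max_depth=cfg.max_depth)
                    )
        fits = [fitness(t, X, y) for t in offspring]
        pop = Population(offspring, fits)
        gen_best = int(np.argmin(fits))
        if fits[gen_best] < best_fit:
            best_fit = fits[gen_best]
            best_tree = pop.individuals[gen_best].copy()
        if trace is not None:
            trace.append(best_fit)
        logger.info("gggp generation %d best fitness %.6g", gen + 1, best_fit)
    return best_tree


def train_fnt(
    X: np.ndarray,
    y: np.ndarray,
    grammar: GrammarSpec,
    gggp_cfg: GGGPConfig,
    pso_cfg: PSOConfig,
    outer_rounds: int = 3,
    rng: np.random.Generator | None = None,
    rel_tol: float = 1e-3,
) -> FlexibleNeuralTree:
    """Alternate topology search (GGGP) and parameter search (PSO).

    Each round evolves structures — later rounds seeding the population with
    the incumbent best tree — then refines the winner's parameters with PSO.
    Stops after ``outer_rounds`` rounds, when fitness drops below the GGGP
    tolerance, or when the relative improvement falls under ``rel_tol``.
    Returns the tree whose post-PSO fitness is minimal over all rounds.
    """
    if outer_rounds < 1:
        raise ValueError("outer_rounds must be >= 1")
    if rng is None:
        rng = np.random.default_rng(gggp_cfg.seed)
    best_tree: FlexibleNeuralTree | None = None
    best_fit = np.inf
    seeds: list[FlexibleNeuralTree] | None = None
    for rnd in range(outer_rounds):
        tree = evolve_structure(X, y, grammar, gggp_cfg, rng, seed_trees=seeds)
        tree = optimize_params(tree, X, y, pso_cfg, rng)
        fit = fitness(tree, X, y)
        improved = fit < best_fit
        rel_gain = (best_fit - fit) / best_fit if np.isfinite(best_fit) and best_fit > 0 else np.inf
        if improved:
            best_tree, best_fit = tree, fit
        logger.info("train_fnt round %d fitness %.6g (best %.6g)", rnd + 1, fit, best_fit)
        if best_fit < gggp_cfg.fitness_tol or rel_gain < rel_tol:
            break
        # reseed the next structure search with the refined incumbent and a
        # handful of its mutants so PSO-tuned weights propagate via crossover
        seeds = [best_tree] + [
            mutate(best_tree, rng, 1.0, max_depth=gggp_cfg.max_depth)
            for _ in range(max(1, gggp_cfg.population_size // 5))
        ]
    assert best_tree is not None
    return best_tree
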