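"""Penalized-likelihood rate smoothing: substitution lengths -> node ages.

The criterion maximised is a Poisson log-likelihood of the observed branch
lengths given rate x duration, minus a smoothness penalty: ``lambda`` times
the sum of squared rate differences between each branch and its parent
branch, plus (for the root's children, which have no parent branch) the
variance of their rates.  Ages are constrained by a min/max table that is
first propagated along the tree; optimisation is SLSQP over internal node
ages and log branch rates, with seeded random restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .errors import ConstraintConflictError, ValidationError
from .trees import AgeConstraintTable, DatedTree, Node

__all__ = [
    "PenalizedLikelihoodConfig",
    "Chronogram",
    "pl_objective",
    "propagate_constraints",
    "date_tree",
]

_EPS = 1e-6  # strict parent > child margin, Ga


@dataclass
class PenalizedLikelihoodConfig:
    lambda_smoothing: float = 10.0
    site_count: int = 1000  # alignment length L; scales the Poisson counts
    n_restarts: int = 5
    seed: int = 1
    tol: float = 1e-10
    max_iter: int = 500

    def __post_init__(self):
        if self.lambda_smoothing < 0:
            raise ValidationError("lambda_smoothing must be >= 0")


@dataclass
class Chronogram:
    tree: DatedTree
    rates: dict[frozenset[str], float]  # branch above node, keyed by leafset
    objective: float
    seed: int


def _nodes_postorder(tree: DatedTree) -> list[Node]:
    return list(tree.postorder())


def pl_objective(
    tree: DatedTree,
    ages: dict[frozenset[str], float],
    rates: dict[frozenset[str], float],
    lambda_smoothing: float,
    site_count: int = 1000,
) -> float:
    """Penalised log-likelihood of branch lengths at the given ages and rates.

    ``ages`` maps each node's subtended leafset to its age (leaves may be
    omitted and default to 0); ``rates`` maps each non-root node's leafset to
    the rate on the branch above it.
    """
    loglik = 0.0
    penalty = 0.0
    root_child_rates = []
    for node in tree.postorder():
        key = tree.leafset(node)
        if node.parent is None:
            continue
        parent_key = tree.leafset(node.parent)
        age = ages.get(key, 0.0)
        parent_age = ages[parent_key]
        duration = parent_age - age
        if duration < 0:
            return -math.inf
        if node.length is None:
            raise ValidationError("branch without length; cannot compute objective")
        rate = rates[key]
        if rate <= 0:
            return -math.inf
        x = node.length * site_count
        mu = rate * duration * site_count
        if mu <= 0:
            if x > 0:
                return -math.inf  # zero duration cannot explain nonzero length
            contrib = 0.0
        else:
            contrib = x * math.log(mu) - mu - float(gammaln(x + 1.0))
        loglik += contrib
        if node.parent.parent is None:
            root_child_rates.append(rate)
        else:
            penalty += (rate - rates[parent_key]) ** 2
    if len(root_child_rates) > 1:
        arr = np.array(root_child_rates)
        penalty += float(np.var(arr))
    return loglik - lambda_smoothing * penalty


def propagate_constraints(
    tree: DatedTree, constraints: AgeConstraintTable
) -> dict[frozenset[str], tuple[float, float]]:
    """Per-node [lo, hi] age bounds after propagating the constraint table.

    A node's upper bound is tightened by every ancestor's maximum; its lower
    bound by every descendant's minimum.  Leaves are pinned at age 0.
    Raises :class:`ConstraintConflictError` on infeasibility.
    """
    lo: dict[int, float] = {}
    hi: dict[int, float] = {}
    names: dict[int, str] = {}
    for node in tree.postorder():
        lo[id(node)] = 0.0
        hi[id(node)] = math.inf
        if node.is_leaf:
            hi[id(node)] = 0.0
    for constraint in constraints:
        taxa = tree.resolve_clade(constraint.clade_name)
        node = tree.mrca(taxa)
        if constraint.min_age is not None:
            lo[id(node)] = max(lo[id(node)], constraint.min_age)
        if constraint.max_age is not None:
            hi[id(node)] = min(hi[id(node)], constraint.max_age)
        names[id(node)] = constraint.clade_name
    # descendants' minima push ancestors up
    for node in tree.postorder():
        if not node.is_leaf:
            for child in node.children:
                lo[id(node)] = max(lo[id(node)], lo[id(child)])
    # ancestors' maxima push descendants down
    for node in tree.preorder():
        if node.parent is not None:
            hi[id(node)] = min(hi[id(node)], hi[id(node.parent)])
    out: dict[frozenset[str], tuple[float, float]] = {}
    for node in tree.postorder():
        l, h = lo[id(node)], hi[id(node)]
        if l > h + 1e-12:
            involved = tuple(
                sorted(
                    names.get(id(n), "<unnamed>")
                    for n in tree.postorder()
                    if id(n) in names
                )
            )
            raise ConstraintConflictError(
                f"infeasible age constraints: node bound [{l}, {h}] "
                f"(clades involved: {involved})",
                clades=involved,
            )
        out[tree.leafset(node)] = (l, h)
    return out


def _initial_ages(
    tree: DatedTree,
    bounds: dict[frozenset[str], tuple[float, float]],
    root_age: float,
) -> dict[frozenset[str], float]:
    """Scale root-to-tip path-length depths into [0, root_age], then repair."""
    depth: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = max(
                depth[id(c)] + (c.length or 0.0) for c in node.children
            )
    max_depth = depth[id(tree.root)] or 1.0
    ages: dict[frozenset[str], float] = {}
    for node in tree.postorder():
        key = tree.leafset(node)
        if node.is_leaf:
            ages[key] = 0.0
            continue
        age = root_age * depth[id(node)] / max_depth
        l, h = bounds[key]
        ages[key] = min(max(age, l), h if math.isfinite(h) else age)
    # enforce strict parent > child bottom-up
    for node in tree.postorder():
        if node.is_leaf:
            continue
        key = tree.leafset(node)
        child_max = max(ages[tree.leafset(c)] for c in node.children)
        if ages[key] <= child_max:
            ages[key] = child_max + _EPS
    return ages


def date_tree(
    tree: DatedTree,
    constraints: AgeConstraintTable,
    config: PenalizedLikelihoodConfig | None = None,
) -> Chronogram:
    """Estimate node ages and branch rates by penalised likelihood.

    Requires branch lengths everywhere and at least one finite constraint to
    fix the absolute time scale.  Returns the best of ``n_restarts`` seeded
    starts; constraint satisfaction is re-asserted on the result.
    """
    config = config or PenalizedLikelihoodConfig()
    for node in tree.postorder():
        if node.parent is not None and node.length is None:
            raise ValidationError("all branch lengths are required for dating")
    bounds = propagate_constraints(tree, constraints)
    root_key = tree.leafset(tree.root)
    root_lo, root_hi = bounds[root_key]
    if not math.isfinite(root_hi) and all(
        lo == 0.0 for lo, _ in bounds.values()
    ):
        raise ValidationError(
            "no informative age constraint: nothing fixes the absolute time scale"
        )

    internal = [n for n in tree.postorder() if not n.is_leaf]
    non_root = [n for n in tree.postorder() if n.parent is not None]
    keys_internal = [tree.leafset(n) for n in internal]
    keys_branch = [tree.leafset(n) for n in non_root]
    n_ages = len(internal)

    total_length = sum(n.length for n in non_root)

    def unpack(x: np.ndarray):
        ages = {k: 0.0 for k in (tree.leafset(l) for l in tree.leaves())}
        for k, v in zip(keys_internal, x[:n_ages]):
            ages[k] = float(v)
        rates = {k: float(math.exp(v)) for k, v in zip(keys_branch, x[n_ages:])}
        return ages, rates

    def neg_objective(x: np.ndarray) -> float:
        ages, rates = unpack(x)
        val = pl_objective(
            tree, ages, rates, config.lambda_smoothing, config.site_count
        )
        return 1e12 if not math.isfinite(val) else -val

    # inequality constraints: parent age - child age >= EPS
    index_of = {k: i for i, k in enumerate(keys_internal)}
    cons = []
    for node in internal:
        i = index_of[tree.leafset(node)]
        for child in node.children:
            if child.is_leaf:
                cons.append({"type": "ineq", "fun": (lambda x, i=i: x[i] - _EPS)})
            else:
                j = index_of[tree.leafset(child)]
                cons.append(
                    {"type": "ineq", "fun": (lambda x, i=i, j=j: x[i] - x[j] - _EPS)}
                )

    x_bounds = []
    root_guess = root_hi if math.isfinite(root_hi) else max(root_lo, 1.0) * 2
    for k in keys_internal:
        l, h = bounds[k]
        x_bounds.append((l, h if math.isfinite(h) else root_guess * 10))
    for _ in keys_branch:
        x_bounds.append((math.log(1e-10), math.log(1e6)))

    rng = np.random.default_rng(config.seed)
    root_init = (
        0.5 * (root_lo + root_hi) if math.isfinite(root_hi) else max(root_lo, root_guess)
    )
    best = None
    for restart in range(max(config.n_restarts, 1)):
        ages0 = _initial_ages(tree, bounds, root_init)
        if restart > 0:
            jittered = {}
            for k, v in ages0.items():
                if len(k) == 1:
                    jittered[k] = v
                    continue
                l, h = bounds[k]
                h = h if math.isfinite(h) else root_guess * 10
                jittered[k] = min(max(v * rng.uniform(0.8, 1.2), l), h)
            ages0 = jittered
            # repair ordering after jitter
            for node in tree.postorder():
                if node.is_leaf:
                    continue
                k = tree.leafset(node)
                child_max = max(ages0[tree.leafset(c)] for c in node.children)
                if ages0[k] <= child_max:
                    ages0[k] = child_max + _EPS
        total_time = sum(
            max(ages0[tree.leafset(n.parent)] - ages0[tree.leafset(n)], _EPS)
            for n in non_root
        )
        rate0 = max(total_length / total_time, 1e-9)
        x0 = np.concatenate(
            [
                np.array([ages0[k] for k in keys_internal]),
                np.full(len(keys_branch), math.log(rate0)),
            ]
        )
        res = minimize(
            neg_objective,
            x0,
            method="SLSQP",
            bounds=x_bounds,
            constraints=cons,
            options={"maxiter": config.max_iter, "ftol": config.tol},
        )
        candidate = (res.fun, res.x)
        if best is None or candidate[0] < best[0]:
            best = candidate

    ages, rates = unpack(best[1])
    dated = tree.copy()
    dated.clade_labels = dict(tree.clade_labels)
    for node in dated.postorder():
        node.age = ages[dated.leafset(node)]
    # hard post-hoc assertions: every constraint row satisfied
    tol = 1e-6
    for constraint in constraints:
        taxa = tree.resolve_clade(constraint.clade_name)
        node = dated.mrca(taxa)
        if constraint.min_age is not None and node.age < constraint.min_age - tol:
            raise ConstraintConflictError(
                f"optimised age {node.age} violates min {constraint.min_age} "
                f"for {constraint.clade_name!r}"
            )
        if constraint.max_age is not None and node.age > constraint.max_age + tol:
            raise ConstraintConflictError(
                f"optimised age {node.age} violates max {constraint.max_age} "
                f"for {constraint.clade_name!r}"
            )
    return Chronogram(
        tree=dated, rates=rates, objective=-best[0], seed=config.seed
    )
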