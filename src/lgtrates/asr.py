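"""Binary-trait ancestral state reconstruction under the one-rate Mk model.

The model has a single rate ``q`` governing both 0->1 and 1->0 change, so
the transition probability along a branch of duration ``t`` is

    P(stay)   = (1 + exp(-2 q t)) / 2
    P(change) = (1 - exp(-2 q t)) / 2

Likelihoods are computed with the pruning algorithm; per-node marginal
probabilities come from a standard down-pass/up-pass.  Branch durations
are taken from node ages when the tree is dated (q then has units of
events per Gy), otherwise from branch lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ValidationError
from .trees import DatedTree, Node, Tree

__all__ = [
    "Mk1Model",
    "AsrResult",
    "GainEdge",
    "mk1_transition",
    "mk1_loglik",
    "fit_q",
    "marginal_asr",
    "candidate_gain_edges",
]

LOGLIK_FLOOR = -1e10
_Q_MIN = 1e-8


@dataclass(frozen=True)
class Mk1Model:
    q: float
    root_prior: float = 0.5  # probability of state 1 at the root

    def __post_init__(self):
        if self.q <= 0:
            raise ValidationError(f"rate q must be positive, got {self.q}")
        if not (0.0 <= self.root_prior <= 1.0):
            raise ValidationError(f"root_prior {self.root_prior} outside [0, 1]")


def mk1_transition(q: float, t: float) -> np.ndarray:
    """2x2 transition probability matrix for the symmetric binary model."""
    if t < 0:
        raise ValidationError(f"negative branch duration {t}")
    if q < 0:
        raise ValidationError(f"negative rate {q}")
    stay = 0.5 * (1.0 + math.exp(-2.0 * q * t))
    change = 0.5 * (1.0 - math.exp(-2.0 * q * t))
    return np.array([[stay, change], [change, stay]])


def _branch_durations(tree: Tree) -> dict[int, float]:
    """Duration of the branch above each non-root node, keyed by id(node)."""
    use_ages = all(
        n.age is not None for n in tree.postorder()
    )
    out: dict[int, float] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        if use_ages:
            out[id(node)] = node.parent.age - node.age
        else:
            if node.length is None:
                raise ValidationError(
                    f"branch above {node.label or 'internal node'} has no length and tree is undated"
                )
            out[id(node)] = node.length
    return out


def _check_tips(tree: Tree, tips: dict[str, int]) -> None:
    missing = [l for l in tree.leaf_labels() if l not in tips]
    if missing:
        raise ValidationError(f"leaves without a state: {sorted(missing)}")
    bad = {k: v for k, v in tips.items() if v not in (0, 1)}
    if bad:
        raise ValidationError(f"non-binary tip states: {bad}")


def _down_pass(
    tree: Tree, tips: dict[str, int], model: Mk1Model, durations: dict[int, float]
) -> tuple[dict[int, np.ndarray], float]:
    """Conditional likelihoods of data below each node, with log scaling.

    Returns (partials keyed by id(node), accumulated log scaling factor).
    """
    partials: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.zeros(2)
            vec[tips[node.label]] = 1.0
            partials[id(node)] = vec
            continue
        vec = np.ones(2)
        for child in node.children:
            P = mk1_transition(model.q, durations[id(child)])
            vec = vec * (P @ partials[id(child)])
        total = vec.sum()
        if total > 0:
            # rescale to dodge underflow on deep trees
            vec = vec / total
            log_scale += math.log(total)
        partials[id(node)] = vec
    return partials, log_scale


def mk1_loglik(tree: Tree, tips: dict[str, int], model: Mk1Model) -> float:
    """Log-likelihood of the tip states under the Mk1 model (pruning)."""
    _check_tips(tree, tips)
    durations = _branch_durations(tree)
    partials, log_scale = _down_pass(tree, tips, model, durations)
    prior = np.array([1.0 - model.root_prior, model.root_prior])
    lik = float(prior @ partials[id(tree.root)])
    if lik <= 0.0:
        return LOGLIK_FLOOR
    return max(math.log(lik) + log_scale, LOGLIK_FLOOR)


@dataclass
class FitResult:
    model: Mk1Model
    loglik: float
    converged: bool
    at_boundary: bool


def _tree_depth(tree: Tree) -> float:
    durations = _branch_durations(tree)

    def depth(node: Node) -> float:
        if node.is_leaf:
            return 0.0
        return max(depth(c) + durations[id(c)] for c in node.children)

    return depth(tree.root)


def fit_q(
    tree: Tree,
    tips: dict[str, int],
    root_prior: float = 0.5,
    q_max: float | None = None,
) -> FitResult:
    """Maximum-likelihood estimate of the Mk1 rate.

    If all tips share one state the likelihood is maximised at the q -> 0
    boundary; the lower bound is returned with ``at_boundary`` set.
    """
    _check_tips(tree, tips)
    states = {tips[l] for l in tree.leaf_labels()}
    depth = _tree_depth(tree)
    if depth <= 0:
        raise ValidationError("tree has zero depth; cannot fit a rate")
    if q_max is None:
        q_max = 100.0 / depth
    if len(states) == 1:
        model = Mk1Model(q=_Q_MIN, root_prior=root_prior)
        return FitResult(model, mk1_loglik(tree, tips, model), True, True)

    def negloglik(q: float) -> float:
        return -mk1_loglik(tree, tips, Mk1Model(q=max(q, _Q_MIN), root_prior=root_prior))

    # restarts: coarse log-grid seeded around {0.01, 0.1, 1.0}/depth, then
    # a bounded Brent refinement
    grid = np.concatenate(
        [
            np.array([0.01, 0.1, 1.0]) / depth,
            np.geomspace(_Q_MIN * 10, q_max, 25),
        ]
    )
    best_q = min(grid, key=negloglik)
    converged = True
    res = minimize_scalar(
        negloglik, bounds=(_Q_MIN, q_max), method="bounded",
        options={"xatol": 1e-8},
    )
    if res.success and negloglik(res.x) <= negloglik(best_q):
        best_q = float(res.x)
    else:
        # refine around the best grid point
        lo = max(best_q / 10, _Q_MIN)
        hi = min(best_q * 10, q_max)
        res = minimize_scalar(
            negloglik, bounds=(lo, hi), method="bounded", options={"xatol": 1e-8}
        )
        if res.success:
            best_q = float(res.x)
        converged = bool(res.success)
    at_boundary = best_q <= _Q_MIN * 1.01 or best_q >= q_max * 0.999
    model = Mk1Model(q=best_q, root_prior=root_prior)
    return FitResult(model, mk1_loglik(tree, tips, model), converged, at_boundary)


@dataclass
class AsrResult:
    """Per-node marginal reconstruction, keyed by subtended leaf set."""

    marginal_p1: dict[frozenset[str], float]
    decisions: dict[frozenset[str], str]  # present | absent | ambiguous
    model: Mk1Model
    loglik: float
    present_threshold: float = 0.7
    absent_threshold: float = 0.3

    def p1(self, taxa) -> float:
        return self.marginal_p1[frozenset(taxa)]

    def decision(self, taxa) -> str:
        return self.decisions[frozenset(taxa)]


def _decide(p1: float, present_threshold: float, absent_threshold: float) -> str:
    if p1 >= present_threshold:
        return "present"
    if p1 <= absent_threshold:
        return "absent"
    return "ambiguous"


def marginal_asr(
    tree: Tree,
    tips: dict[str, int],
    model: Mk1Model,
    present_threshold: float = 0.7,
    absent_threshold: float = 0.3,
) -> AsrResult:
    """Marginal probability of state 1 at every node (down-pass + up-pass)."""
    _check_tips(tree, tips)
    durations = _branch_durations(tree)
    down, log_scale = _down_pass(tree, tips, model, durations)
    prior = np.array([1.0 - model.root_prior, model.root_prior])

    up: dict[int, np.ndarray] = {id(tree.root): prior.copy()}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        # message from each child's siblings, seen from the parent state
        child_msgs = {}
        for child in node.children:
            P = mk1_transition(model.q, durations[id(child)])
            child_msgs[id(child)] = P @ down[id(child)]
        for child in node.children:
            sibling_prod = up[id(node)].copy()
            for other in node.children:
                if other is child:
                    continue
                sibling_prod = sibling_prod * child_msgs[id(other)]
            P = mk1_transition(model.q, durations[id(child)])
            vec = P.T @ sibling_prod
            total = vec.sum()
            if total > 0:
                vec = vec / total
            up[id(child)] = vec

    marginal: dict[frozenset[str], float] = {}
    decisions: dict[frozenset[str], str] = {}
    for node in tree.postorder():
        joint = down[id(node)] * up[id(node)]
        total = joint.sum()
        p1 = float(joint[1] / total) if total > 0 else 0.5
        key = tree.leafset(node)
        marginal[key] = p1
        decisions[key] = _decide(p1, present_threshold, absent_threshold)
    loglik = mk1_loglik(tree, tips, model)
    return AsrResult(
        marginal_p1=marginal,
        decisions=decisions,
        model=model,
        loglik=loglik,
        present_threshold=present_threshold,
        absent_threshold=absent_threshold,
    )


@dataclass(frozen=True)
class GainEdge:
    """An edge on which the trait was plausibly gained."""

    parent_taxa: frozenset[str]
    child_taxa: frozenset[str]
    parent_p1: float
    child_p1: float

    @property
    def taxa(self) -> frozenset[str]:
        return self.child_taxa


def candidate_gain_edges(tree: Tree, asr: AsrResult) -> list[GainEdge]:
    """Edges whose parent is called absent/ambiguous and child present.

    The returned edges carry the child's subtended taxon set; leaf edges are
    eligible (a leaf's decision follows its observed state).
    """
    edges: list[GainEdge] = []
    for node in tree.postorder():
        if node.parent is None:
            continue
        child_key = tree.leafset(node)
        parent_key = tree.leafset(node.parent)
        if asr.decisions[parent_key] in ("absent", "ambiguous") and (
            asr.decisions[child_key] == "present"
        ):
            edges.append(
                GainEdge(
                    parent_taxa=parent_key,
                    child_taxa=child_key,
                    parent_p1=asr.marginal_p1[parent_key],
                    child_p1=asr.marginal_p1[child_key],
                )
            )
    edges.sort(key=lambda e: (-len(e.child_taxa), sorted(e.child_taxa)))
    return edges
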