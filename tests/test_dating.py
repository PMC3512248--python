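import math

import numpy as np
import pytest
from scipy.special import gammaln

from lgtrates.dating import (
    PenalizedLikelihoodConfig,
    date_tree,
    pl_objective,
    propagate_constraints,
)
from lgtrates.errors import ConstraintConflictError, ValidationError
from lgtrates.simulate import SimulationConfig, simulate_reference_tree
from lgtrates.trees import AgeConstraint, AgeConstraintTable, parse_tree


def _four_taxon_tree():
    tree = parse_tree("(((A:0.1,B:0.1):0.1,C:0.2):0.1,D:0.3);")
    tree.clade_labels = {
        "root": frozenset("ABCD"),
        "abc": frozenset("ABC"),
        "ab": frozenset("AB"),
    }
    return tree


def _clock_instance(seed=5, n_taxa=12, rate=0.02, root_age=3.5):
    """Dated birth-death tree re-expressed with strict-clock branch lengths."""
    config = SimulationConfig(n_taxa=n_taxa, seed=seed, root_age=root_age)
    tree = simulate_reference_tree(config)
    true_ages = {tree.leafset(n): n.age for n in tree.postorder() if not n.is_leaf}
    for node in tree.postorder():
        if node.parent is not None:
            node.length = rate * (node.parent.age - node.age)
        node_age = node.age
    for node in tree.postorder():
        node.age = None
    tree.clade_labels = {"root": frozenset(tree.leaf_labels())}
    return tree, true_ages


class TestObjective:
    def test_clock_rates_zero_penalty(self):
        tree = _four_taxon_tree()
        rate = 0.5
        ages = {
            frozenset("ABCD"): 0.3,
            frozenset("ABC"): 0.2,
            frozenset("AB"): 0.1,
        }
        for leaf in "ABCD":
            ages[frozenset(leaf)] = 0.0
        rates = {k: rate for k in [frozenset("ABC"), frozenset("AB"),
                                   frozenset("A"), frozenset("B"),
                                   frozenset("C"), frozenset("D")]}
        with_pen = pl_objective(tree, ages, rates, lambda_smoothing=1000.0)
        without = pl_objective(tree, ages, rates, lambda_smoothing=0.0)
        assert with_pen == pytest.approx(without)  # penalty exactly zero

    def test_hand_computed_value(self):
        # independent arithmetic: Poisson terms + squared-difference penalty
        tree = _four_taxon_tree()
        L = 1000
        ages = {
            frozenset("ABCD"): 0.3,
            frozenset("ABC"): 0.2,
            frozenset("AB"): 0.1,
            frozenset("A"): 0.0,
            frozenset("B"): 0.0,
            frozenset("C"): 0.0,
            frozenset("D"): 0.0,
        }
        rates = {
            frozenset("ABC"): 1.0,
            frozenset("AB"): 1.1,
            frozenset("A"): 0.9,
            frozenset("B"): 1.0,
            frozenset("C"): 1.2,
            frozenset("D"): 1.0,
        }
        durations = {
            frozenset("ABC"): 0.1,
            frozenset("AB"): 0.1,
            frozenset("A"): 0.1,
            frozenset("B"): 0.1,
            frozenset("C"): 0.2,
            frozenset("D"): 0.3,
        }
        lengths = {
            frozenset("ABC"): 0.1,
            frozenset("AB"): 0.1,
            frozenset("A"): 0.1,
            frozenset("B"): 0.1,
            frozenset("C"): 0.2,
            frozenset("D"): 0.3,
        }
        expected_ll = 0.0
        for key in rates:
            x = lengths[key] * L
            mu = rates[key] * durations[key] * L
            expected_ll += x * math.log(mu) - mu - float(gammaln(x + 1))
        # non-root branches with a parent branch: AB (parent ABC), A, B
        # (parent AB), C (parent ABC); root children: ABC, D
        expected_pen = (
            (rates[frozenset("AB")] - rates[frozenset("ABC")]) ** 2
            + (rates[frozenset("A")] - rates[frozenset("AB")]) ** 2
            + (rates[frozenset("B")] - rates[frozenset("AB")]) ** 2
            + (rates[frozenset("C")] - rates[frozenset("ABC")]) ** 2
            + float(np.var([rates[frozenset("ABC")], rates[frozenset("D")]]))
        )
        lam = 7.0
        got = pl_objective(tree, ages, rates, lambda_smoothing=lam, site_count=L)
        assert got == pytest.approx(expected_ll - lam * expected_pen, abs=1e-10)

    def test_zero_duration_nonzero_length_rejected(self):
        tree = _four_taxon_tree()
        ages = {
            frozenset("ABCD"): 0.3,
            frozenset("ABC"): 0.2,
            frozenset("AB"): 0.2,  # zero duration above AB's children? no: AB branch
            frozenset("A"): 0.0,
            frozenset("B"): 0.0,
            frozenset("C"): 0.0,
            frozenset("D"): 0.0,
        }
        # branch above AB has duration 0 but length 0.1
        rates = {k: 1.0 for k in [frozenset("ABC"), frozenset("AB"), frozenset("A"),
                                  frozenset("B"), frozenset("C"), frozenset("D")]}
        assert pl_objective(tree, ages, rates, 1.0) == -math.inf


class TestPropagateConstraints:
    def test_child_max_under_parent_min_feasible(self):
        tree = _four_taxon_tree()
        constraints = AgeConstraintTable(
            [
                AgeConstraint("root", min_age=2.7, max_age=None),
                AgeConstraint("ab", min_age=None, max_age=1.0),
            ]
        )
        bounds = propagate_constraints(tree, constraints)
        assert bounds[frozenset("AB")] == (0.0, 1.0)
        assert bounds[frozenset("ABCD")][0] == 2.7
        assert math.isinf(bounds[frozenset("ABCD")][1])

    def test_nested_contradiction_detected(self):
        tree = _four_taxon_tree()
        constraints = AgeConstraintTable(
            [
                AgeConstraint("root", max_age=2.32),
                AgeConstraint("ab", min_age=3.0),
            ]
        )
        with pytest.raises(ConstraintConflictError):
            propagate_constraints(tree, constraints)

    def test_ancestor_max_propagates_down(self):
        tree = _four_taxon_tree()
        constraints = AgeConstraintTable([AgeConstraint("root", max_age=2.32)])
        bounds = propagate_constraints(tree, constraints)
        assert bounds[frozenset("ABC")][1] == 2.32
        assert bounds[frozenset("AB")][1] == 2.32

    def test_no_constraints_dating_refuses(self):
        tree = _four_taxon_tree()
        bounds = propagate_constraints(tree, AgeConstraintTable())
        for key, (lo, hi) in bounds.items():
            if len(key) > 1:
                assert lo == 0.0 and math.isinf(hi)
        with pytest.raises(ValidationError):
            date_tree(tree, AgeConstraintTable())


class TestDateTree:
    def test_strict_clock_recovery_within_one_percent(self):
        tree, true_ages = _clock_instance()
        constraints = AgeConstraintTable([AgeConstraint("root", 3.5, 3.5)])
        for lam in (0.1, 10.0):
            chronogram = date_tree(
                tree, constraints, PenalizedLikelihoodConfig(lambda_smoothing=lam, n_restarts=2)
            )
            for taxa, true_age in true_ages.items():
                got = chronogram.tree.mrca(taxa).age
                assert abs(got - true_age) / true_age < 0.01

    def test_root_within_declared_interval(self):
        tree, _ = _clock_instance(seed=9)
        constraints = AgeConstraintTable([AgeConstraint("root", 2.7, 3.8)])
        chronogram = date_tree(tree, constraints, PenalizedLikelihoodConfig(n_restarts=2))
        assert 2.7 - 1e-6 <= chronogram.tree.root.age <= 3.8 + 1e-6

    def test_internal_max_age_respected(self):
        tree, true_ages = _clock_instance(seed=13)
        # constrain some non-root internal clade below its unconstrained age
        internal = [k for k in true_ages if 1 < len(k) < len(tree.leaf_labels())]
        clade = max(internal, key=len)
        tree.clade_labels["constrained"] = clade
        constraints = AgeConstraintTable(
            [
                AgeConstraint("root", 2.7, 3.8),
                AgeConstraint("constrained", max_age=2.32),
            ]
        )
        chronogram = date_tree(tree, constraints, PenalizedLikelihoodConfig(n_restarts=2))
        assert chronogram.tree.mrca(clade).age <= 2.32 + 1e-6

    def test_missing_lengths_rejected(self):
        tree, _ = _clock_instance()
        tree.leaves()[0].length = None
        with pytest.raises(ValidationError):
            date_tree(tree, AgeConstraintTable([AgeConstraint("root", 3.5, 3.5)]))

    def test_rescaling_lengths_rescales_rates_not_ages(self):
        tree, _ = _clock_instance(seed=21, n_taxa=8)
        constraints = AgeConstraintTable([AgeConstraint("root", 3.5, 3.5)])
        config = PenalizedLikelihoodConfig(n_restarts=2)
        chrono1 = date_tree(tree, constraints, config)
        scale = 3.0
        for node in tree.postorder():
            if node.length is not None:
                node.length *= scale
        chrono2 = date_tree(tree, constraints, config)
        for node in chrono1.tree.postorder():
            if node.is_leaf:
                continue
            taxa = chrono1.tree.leafset(node)
            assert chrono2.tree.mrca(taxa).age == pytest.approx(node.age, rel=1e-3)
        r1 = np.array([chrono1.rates[k] for k in sorted(chrono1.rates, key=sorted)])
        r2 = np.array([chrono2.rates[k] for k in sorted(chrono2.rates, key=sorted)])
        assert np.allclose(r2, scale * r1, rtol=1e-3)

    def test_large_lambda_clock_rates_converge(self):
        tree, _ = _clock_instance(seed=30, n_taxa=8)
        constraints = AgeConstraintTable([AgeConstraint("root", 3.5, 3.5)])
        chronogram = date_tree(
            tree, constraints,
            PenalizedLikelihoodConfig(lambda_smoothing=1e4, n_restarts=2),
        )
        rates = np.array(list(chronogram.rates.values()))
        assert rates.max() / rates.min() < 1.01

    def test_doubling_lambda_weakly_decreases_rate_variance(self):
        # perturb clock lengths so rates genuinely vary, then compare optima
        tree, _ = _clock_instance(seed=17, n_taxa=8)
        rng = np.random.default_rng(17)
        for node in tree.postorder():
            if node.length is not None:
                node.length *= rng.uniform(0.7, 1.3)
        constraints = AgeConstraintTable([AgeConstraint("root", 3.5, 3.5)])
        variances = []
        for lam in (5.0, 10.0):
            chronogram = date_tree(
                tree, constraints,
                PenalizedLikelihoodConfig(lambda_smoothing=lam, n_restarts=2),
            )
            variances.append(float(np.var(list(chronogram.rates.values()))))
        assert variances[1] <= variances[0] + 1e-12

    def test_predated_tree_bypasses_module(self):
        # the pipeline accepts trees that already carry ages
        from lgtrates import datasets

        tree = datasets.reference_tree()
        assert tree.is_dated
        assert tree.root.age == pytest.approx(3.5)
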