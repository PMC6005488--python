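"""Neighborhood indiscernibility, positive regions, cores and reducts.

The enumeration oracle here recomputes everything with plain loops over
all pairs and all subsets, independently of the package's vectorized
path and of its branch-and-bound search.
"""

from itertools import combinations

import numpy as np
import pytest

import costfs as cf
from conftest import random_system


# ---------------------------------------------------------------- oracle

def oracle_pos(system, B, cfg):
    """Positive region by direct per-pair threshold loops."""
    thr = {a: cfg.multiplier * cfg.e[a] for a in system.features}
    idx = {a: system.features.index(a) for a in system.features}
    members = set()
    for i in range(system.n_instances):
        consistent = True
        for j in range(system.n_instances):
            if all(abs(system.values[i, idx[a]] - system.values[j, idx[a]]) <= thr[a]
                   for a in B):
                if system.decisions[j] != system.decisions[i]:
                    consistent = False
                    break
        if consistent:
            members.add(i)
    return frozenset(members)


def oracle_reducts(system, cfg):
    """All reducts by exhaustive subset enumeration (|C| <= 6)."""
    C = system.features
    full = oracle_pos(system, C, cfg)
    covering = [B for r in range(len(C) + 1) for B in combinations(C, r)
                if oracle_pos(system, B, cfg) == full]
    cov_sets = [frozenset(B) for B in covering]
    return [B for B, Bs in zip(covering, cov_sets)
            if not any(o < Bs for o in cov_sets)]


# ----------------------------------------------------------------- tests

class TestIndiscernible:
    def test_reflexive(self, liver_system, liver_nbr_cfg):
        for i in range(liver_system.n_instances):
            assert cf.indiscernible(liver_system, i, i,
                                    liver_system.features, liver_nbr_cfg)

    def test_close_pair_within_all_thresholds(self, liver_system, liver_nbr_cfg):
        # x1 vs x5 on everything except Sgpt: each gap <= 2 e(a)
        B = ("Mcv", "Alkphos", "Sgot", "Gammagt")
        assert cf.indiscernible(liver_system, 0, 4, B, liver_nbr_cfg)

    def test_pair_separated_by_one_feature(self, liver_system, liver_nbr_cfg):
        # x1 vs x2: the Mcv gap 0.15 exceeds 2 e(Mcv) ~ 0.13
        assert not cf.indiscernible(liver_system, 0, 1,
                                    liver_system.features, liver_nbr_cfg)

    def test_empty_subset_blurs_everything(self, liver_system, liver_nbr_cfg):
        assert cf.indiscernible(liver_system, 0, 5, (), liver_nbr_cfg)


class TestPositiveRegion:
    def test_empty_subset_with_mixed_classes_is_empty(self, liver_system,
                                                      liver_nbr_cfg):
        assert cf.positive_region(liver_system, (), liver_nbr_cfg).members == frozenset()

    def test_full_feature_set_classifies_all_liver_instances(self, liver_system,
                                                             liver_nbr_cfg):
        pos = cf.positive_region(liver_system, liver_system.features, liver_nbr_cfg)
        assert pos.members == frozenset(range(6))

    def test_zero_error_ranges_give_identity_relation(self):
        rng = np.random.default_rng(4)
        sys_ = random_system(rng, n_instances=10)
        cfg = cf.NeighborhoodConfig(
            e=cf.ErrorRangeVector(e={a: 0.0 for a in sys_.features}))
        pos = cf.positive_region(sys_, sys_.features, cfg)
        assert pos.members == frozenset(range(10))

    def test_monotone_in_subset(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            sys_ = random_system(rng)
            cfg = cf.NeighborhoodConfig.for_system(sys_)
            feats = list(sys_.features)
            k = rng.integers(0, len(feats))
            B2 = list(rng.choice(feats, size=max(k, 1), replace=False))
            B1 = B2[: max(len(B2) - 1, 0)]
            pos1 = cf.positive_region(sys_, B1, cfg).members
            pos2 = cf.positive_region(sys_, B2, cfg).members
            assert pos1 <= pos2

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            sys_ = random_system(rng)
            cfg = cf.NeighborhoodConfig.for_system(sys_)
            B = tuple(rng.choice(sys_.features,
                                 size=rng.integers(1, 6), replace=False))
            assert cf.positive_region(sys_, B, cfg).members == oracle_pos(sys_, B, cfg)


class TestCoreAndReducts:
    def test_single_separating_feature_is_core(self):
        sys_ = cf.synthetic_system(n_instances=20, n_features=1, n_informative=1,
                                   n_redundant=0, noise_sd=0.0, class_sep=5.0,
                                   seed=1)
        cfg = cf.NeighborhoodConfig.for_system(sys_)
        assert cf.core(sys_, cfg) == sys_.features

    @pytest.mark.parametrize("multiplier", [1.0, 2.0])
    def test_liver_core_pinned_by_brute_force(self, liver_system, multiplier):
        """Regression: exhaustive enumeration puts Sgpt (and only Sgpt) in
        every reduct of the liver subtable under both threshold multipliers."""
        cfg = cf.NeighborhoodConfig.for_system(liver_system, multiplier=multiplier)
        assert cf.core(liver_system, cfg) == ("Sgpt",)
        reducts = {frozenset(B) for B in oracle_reducts(liver_system, cfg)}
        assert reducts == {frozenset({"Alkphos", "Sgpt"}),
                           frozenset({"Sgpt", "Sgot"})}

    def test_core_equals_reduct_intersection_on_random_systems(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            sys_ = random_system(rng)
            cfg = cf.NeighborhoodConfig.for_system(sys_)
            reducts = oracle_reducts(sys_, cfg)
            expected = frozenset(sys_.features).intersection(*map(frozenset, reducts)) \
                if reducts else frozenset()
            assert frozenset(cf.core(sys_, cfg)) == expected

    def test_is_reduct_accepts_enumerated_and_rejects_padded(self, liver_system,
                                                             liver_nbr_cfg):
        for B in oracle_reducts(liver_system, liver_nbr_cfg):
            assert cf.is_reduct(liver_system, B, liver_nbr_cfg)
        # the full feature set contains removable features here
        assert not cf.is_reduct(liver_system, liver_system.features, liver_nbr_cfg)

    def test_empty_subset_is_not_a_reduct_when_pos_nonempty(self, liver_system,
                                                            liver_nbr_cfg):
        assert not cf.is_reduct(liver_system, (), liver_nbr_cfg)


class TestMinCostReduct:
    def test_unique_reduct_is_returned_with_its_cost(self):
        sys_ = cf.synthetic_system(n_instances=20, n_features=1, n_informative=1,
                                   n_redundant=0, noise_sd=0.0, class_sep=5.0,
                                   seed=1)
        cfg = cf.NeighborhoodConfig.for_system(sys_)
        costs = cf.TestCostVector(cost={sys_.features[0]: 7.0})
        assert cf.min_cost_reduct(sys_, costs, cfg) == (sys_.features, 7.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            sys_ = random_system(rng)
            cfg = cf.NeighborhoodConfig.for_system(sys_)
            costs = cf.TestCostVector(cost={
                a: float(c) for a, c in zip(
                    sys_.features, rng.integers(1, 101, len(sys_.features)))})
            subset, cost = cf.min_cost_reduct(sys_, costs, cfg)
            reducts = oracle_reducts(sys_, cfg)
            best = min(cf.subset_cost(B, costs) for B in reducts)
            assert cost == pytest.approx(best)
            assert frozenset(subset) in {frozenset(B) for B in reducts}
            assert cf.is_reduct(sys_, subset, cfg)

    def test_cost_scale_equivariance(self, liver_system, liver_costs, liver_nbr_cfg):
        subset, cost = cf.min_cost_reduct(liver_system, liver_costs, liver_nbr_cfg)
        doubled = cf.TestCostVector(cost={a: 2 * liver_costs[a]
                                          for a in liver_system.features})
        subset2, cost2 = cf.min_cost_reduct(liver_system, doubled, liver_nbr_cfg)
        assert subset2 == subset
        assert cost2 == pytest.approx(2 * cost)

    def test_guard_refuses_wide_systems(self):
        sys_ = cf.synthetic_system(n_instances=10, n_features=8, n_informative=3,
                                   n_redundant=0, seed=2)
        cfg = cf.NeighborhoodConfig.for_system(sys_)
        costs = cf.TestCostVector(cost={a: 1.0 for a in sys_.features})
        with pytest.raises(ValueError, match="guard"):
            cf.min_cost_reduct(sys_, costs, cfg, max_features_guard=5)
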