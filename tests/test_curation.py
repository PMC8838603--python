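import math

import numpy as np
import pytest

from rxnsa.curation import (ES, HS, LabeledCompound, build_unbalanced_test,
                            diversity_downsample, label_compounds,
                            leader_clusters, split_dataset)


def _compounds(smiles_list, label=ES, srp=1):
    return [LabeledCompound(key=s, smiles=s, srp=srp, label=label)
            for s in smiles_list]


class TestLabeling:
    def test_threshold_rule(self):
        table = {"a": 1, "b": 3, "c": 4}
        labeled = {c.key: c.label for c in label_compounds(table, 3)}
        assert labeled == {"a": ES, "b": ES, "c": HS}

    def test_tighter_cutoff_moves_boundary(self):
        table = {"a": 1, "b": 3, "c": 4}
        labeled = {c.key: c.label for c in label_compounds(table, 2)}
        assert labeled == {"a": ES, "b": HS, "c": HS}

    def test_boundary_is_inclusive(self):
        labeled = label_compounds({"a": 3, "b": 3}, 3)
        assert all(c.label == ES for c in labeled)

    def test_unreachable_dropped(self):
        labeled = label_compounds({"a": 1, "b": math.inf}, 3)
        assert [c.key for c in labeled] == ["a"]

    def test_relabeling_is_idempotent_and_order_independent(self):
        table = {"a": 1, "b": 2, "c": 5, "d": 3}
        first = label_compounds(table, 3)
        second = label_compounds({c.key: c.srp for c in first}, 3)
        assert [(c.key, c.label) for c in first] == \
            [(c.key, c.label) for c in second]
        shuffled = dict(reversed(list(table.items())))
        assert {(c.key, c.label) for c in label_compounds(shuffled, 3)} == \
            {(c.key, c.label) for c in first}

    def test_empty_table(self):
        assert label_compounds({}, 3) == []

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            label_compounds({"a": 1}, 0)


class TestDownsample:
    def test_copies_collapse_to_one_representative(self):
        comps = _compounds(["CCO"] * 100)
        assert len(diversity_downsample(comps, 0.6, 10, seed=0)) == 1

    def test_distinct_molecules_all_kept(self):
        from rxnsa.fixtures import generate_clustered_compounds

        smiles, _ = generate_clustered_compounds(24, 1, seed=1)
        comps = _compounds(smiles)
        kept = diversity_downsample(comps, 0.6, len(comps), seed=0)
        assert len(kept) == len(comps)

    def test_planted_clusters_one_representative_each(self):
        from rxnsa.fixtures import generate_clustered_compounds

        smiles, cluster_ids = generate_clustered_compounds(20, 4, seed=2)
        cluster_of = dict(zip(smiles, cluster_ids))
        comps = _compounds(smiles)
        kept = diversity_downsample(comps, 0.5, 20, seed=0)
        assert len(kept) == 20
        assert {cluster_of[c.key] for c in kept} == set(range(20))

    def test_target_above_population_returns_all(self):
        comps = _compounds(["CCO", "CCN"])
        assert len(diversity_downsample(comps, 0.6, 10, seed=0)) == 2

    def test_seeded_subsample_deterministic(self):
        from rxnsa.fixtures import generate_clustered_compounds

        smiles, _ = generate_clustered_compounds(24, 1, seed=3)
        comps = _compounds(smiles)
        a = diversity_downsample(comps, 0.9, 10, seed=5)
        b = diversity_downsample(comps, 0.9, 10, seed=5)
        assert [c.key for c in a] == [c.key for c in b]
        assert len(a) == 10


class TestLeaderClustering:
    def test_first_compound_founds_cluster_zero(self):
        assign = leader_clusters(["CCO", "CCO", "c1ccccc1"], 0.6)
        assert assign == [0, 0, 1]

    def test_threshold_controls_granularity(self):
        from rxnsa.fixtures import generate_clustered_compounds

        smiles, _ = generate_clustered_compounds(10, 4, seed=4)
        loose = len(set(leader_clusters(smiles, 0.2)))
        tight = len(set(leader_clusters(smiles, 0.95)))
        assert loose <= 10 <= tight


class TestSplit:
    def _balanced(self, n):
        half = n // 2
        es = _compounds([f"C{'C' * i}O" for i in range(half)], ES)
        hs = _compounds([f"C{'C' * i}N" for i in range(n - half)], HS, srp=9)
        return es + hs

    def test_exact_division(self):
        split = split_dataset(self._balanced(100), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == \
            (80, 10, 10)

    def test_remainder_goes_to_test(self):
        comps = self._balanced(100) + _compounds(["CBr"], ES)
        split = split_dataset(comps, seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == \
            (80, 10, 11)

    def test_same_seed_same_membership(self):
        comps = self._balanced(60)
        a, b = split_dataset(comps, seed=4), split_dataset(comps, seed=4)
        for pa, pb in (("train",) * 2, ("validation",) * 2, ("test",) * 2):
            assert [c.key for c in getattr(a, pa)] == \
                [c.key for c in getattr(b, pb)]

    def test_stratification_preserves_class_fraction(self):
        comps = self._balanced(200)
        split = split_dataset(comps, seed=1)
        whole = sum(c.label == ES for c in comps) / len(comps)
        for part in (split.train, split.validation, split.test):
            frac = sum(c.label == ES for c in part) / len(part)
            assert abs(frac - whole) <= 0.01 + 1e-9

    def test_no_leakage_across_seeds(self):
        comps = self._balanced(97)
        for seed in range(20):
            split = split_dataset(comps, seed=seed)
            keys = [{c.key for c in part} for part in
                    (split.train, split.validation, split.test)]
            assert not (keys[0] & keys[1] or keys[0] & keys[2]
                        or keys[1] & keys[2])
            assert len(keys[0] | keys[1] | keys[2]) == len(comps)

    def test_too_few_compounds_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._balanced(8), seed=0)


class TestUnbalancedTest:
    def test_union_of_disjoint_sets(self):
        split = split_dataset(
            TestSplit()._balanced(100), seed=0)
        extra = _compounds([f"C{'N' * i}CO" for i in range(1, 91)], ES)
        split = build_unbalanced_test(split, extra)
        assert len(split.unbalanced_test) == len(split.test) + 90

    def test_leakage_into_train_rejected(self):
        split = split_dataset(TestSplit()._balanced(100), seed=0)
        poison = [split.train[0]]
        with pytest.raises(ValueError):
            build_unbalanced_test(split, poison)

    def test_empty_remainder_is_identity(self):
        split = split_dataset(TestSplit()._balanced(100), seed=0)
        split = build_unbalanced_test(split, [])
        assert [c.key for c in split.unbalanced_test] == \
            [c.key for c in split.test]
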