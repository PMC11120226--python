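import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from modbarcode import (
    ModuleAssignment,
    average_rank,
    core_members,
    discretize,
    generate_block_scores,
    generate_subtype_cohort,
    median_split,
    module_conservation,
    nmf_subtype,
)


def _scores(rows: dict[int, list[float]]) -> pd.DataFrame:
    frame = pd.DataFrame(rows).T.astype(float)
    frame.columns = [f"S{j}" for j in range(frame.shape[1])]
    return frame


class TestDiscretize:
    def test_constant_row_is_all_mid_and_flagged(self):
        table = discretize(_scores({1: [2.0, 2.0, 2.0, 2.0]}))
        assert (table.levels[1] == "MID").all()
        assert table.flat_modules == [1]

    def test_symmetric_spread_maps_to_lo_mid_hi(self):
        table = discretize(_scores({1: [-3.0, 0.0, 3.0]}), z_hi=0.5)
        assert table.levels[1].tolist() == ["LO", "MID", "HI"]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_affine_rescaling_invariance(self, scale, shift):
        base = _scores({1: [-2.0, -0.5, 0.1, 0.7, 3.0], 2: [1.0, 4.0, 2.0, 0.0, -1.0]})
        rescaled = base * scale + shift
        assert discretize(base).levels.equals(discretize(rescaled).levels)

    def test_subtype_rule_recovers_exclusive_activation_groups(self):
        # confident subtype calls use a strict HI threshold (z >= 2)
        scores, labels = generate_subtype_cohort(seed=2)
        table = discretize(scores, z_hi=2.0)
        calls = table.call_subtypes({1: "EMT", 2: "MEL", 3: "ERK"}, fallback="Low")
        assert (calls == labels).mean() >= 0.95

    def test_barcode_is_one_level_per_module(self):
        scores, _ = generate_subtype_cohort(seed=0)
        table = discretize(scores)
        code = table.barcode("S000")
        assert len(code) == scores.shape[0]
        assert set(code) <= {"HI", "MID", "LO"}


class TestMedianSplit:
    def test_even_split(self):
        low, high = median_split(_scores({1: [1.0, 2.0, 3.0, 4.0]}), 1)
        assert low == ["S0", "S1"] and high == ["S2", "S3"]

    def test_tie_at_median_goes_low(self):
        low, high = median_split(_scores({1: [1.0, 2.0, 2.0, 3.0, 4.0]}), 1)
        assert "S1" in low and "S2" in low
        assert high == ["S3", "S4"]

    def test_constant_scores_all_low_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            low, high = median_split(_scores({1: [5.0, 5.0, 5.0]}), 1)
        assert high == [] and len(low) == 3

    def test_unknown_module_errors(self):
        with pytest.raises(KeyError):
            median_split(_scores({1: [1.0, 2.0]}), 99)


class TestNMFSubtype:
    def test_block_structure_recovered_perfectly(self):
        scores, labels = generate_block_scores(seed=5)
        _, concordance = nmf_subtype(scores, k=3, labels=labels, seed=5)
        assert concordance == 1.0

    def test_k_one_gives_majority_class_concordance(self):
        scores, labels = generate_block_scores(n_groups=2, samples_per_group=10, seed=1)
        clusters, concordance = nmf_subtype(scores, k=1, labels=labels, seed=1)
        assert clusters.nunique() == 1
        assert concordance == pytest.approx(0.5)  # two equal-size groups

    def test_label_permutation_invariance(self):
        scores, labels = generate_block_scores(seed=9)
        _, c1 = nmf_subtype(scores, k=3, labels=labels, seed=9)
        renamed = labels.map({"group1": "B", "group2": "C", "group3": "A"})
        _, c2 = nmf_subtype(scores, k=3, labels=renamed, seed=9)
        assert c1 == c2

    def test_k_beyond_samples_errors(self):
        scores, _ = generate_block_scores(n_groups=2, samples_per_group=2, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            nmf_subtype(scores, k=5)


class TestAverageRank:
    def test_single_sample_equals_its_ranks(self):
        m = pd.DataFrame({"s": [3.0, 1.0, 2.0]}, index=["a", "b", "c"])
        assert average_rank(m).tolist() == [3.0, 1.0, 2.0]

    def test_identical_orderings_preserved(self):
        m = pd.DataFrame(
            {"s1": [1.0, 5.0, 3.0], "s2": [10.0, 50.0, 30.0]}, index=["a", "b", "c"]
        )
        assert average_rank(m).tolist() == [1.0, 3.0, 2.0]

    def test_matches_brute_force_per_sample_sort(self):
        rng = np.random.default_rng(17)
        m = pd.DataFrame(rng.random((6, 3)), index=[f"g{i}" for i in range(6)])
        expected = np.mean(
            [m[c].rank(method="average").to_numpy() for c in m.columns], axis=0
        )
        assert np.allclose(average_rank(m).to_numpy(), expected)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 1000))
    def test_monotone_within_sample_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.random((8, 4)), index=[f"g{i}" for i in range(8)])
        transformed = np.exp(3 * m) + 1  # strictly increasing per value
        assert np.allclose(
            average_rank(m).to_numpy(), average_rank(transformed).to_numpy()
        )


@pytest.fixture(scope="module")
def three_datasets():
    shared = [f"CC{i:02d}" for i in range(30)]
    assignments = []
    for d in range(3):
        genes = shared + [f"D{d}_{i}" for i in range(5)]
        assignments.append(ModuleAssignment(pd.Series(1, index=genes)))
    return assignments, shared


class TestCoreMembers:
    def test_strict_threshold_returns_exactly_the_shared_genes(self, three_datasets):
        assignments, shared = three_datasets
        result = core_members(assignments, [1, 1, 1], threshold=3)
        assert sorted(result.genes) == sorted(shared)

    def test_threshold_one_is_the_union(self, three_datasets):
        assignments, _ = three_datasets
        assert len(core_members(assignments, [1, 1, 1], threshold=1).genes) == 45

    def test_monotone_in_threshold(self, three_datasets):
        assignments, _ = three_datasets
        sets = [
            set(core_members(assignments, [1, 1, 1], threshold=t).genes)
            for t in (1, 2, 3)
        ]
        assert sets[2] <= sets[1] <= sets[0]

    def test_unknown_module_errors(self, three_datasets):
        assignments, _ = three_datasets
        with pytest.raises(KeyError):
            core_members(assignments, [1, 1, 99], threshold=1)


class TestModuleConservation:
    def _assignment(self, blocks: dict[int, list[str]]):
        series = pd.concat(
            [pd.Series(mid, index=genes) for mid, genes in blocks.items()]
        )
        return ModuleAssignment(series, min_report_size=1)

    def test_identical_assignments_give_unit_jaccard_blocks(self):
        a = self._assignment({1: ["g1", "g2"], 2: ["g3", "g4"]})
        result = module_conservation([a, a], names=["x", "y"], min_size=1)
        assert result.jaccard.loc["x:1", "y:1"] == 1.0
        assert result.jaccard.loc["x:1", "y:2"] == 0.0
        assert result.clusters["x:1"] == result.clusters["y:1"]

    def test_disjoint_universes_warn_and_zero(self):
        a = self._assignment({1: ["a1", "a2"]})
        b = self._assignment({1: ["b1", "b2"]})
        with pytest.warns(UserWarning, match="overlap"):
            result = module_conservation([a, b], min_size=1)
        assert result.jaccard.loc["d0:1", "d1:1"] == 0.0

    def test_shared_module_across_five_datasets_forms_one_cluster(self):
        shared = [f"S{i:02d}" for i in range(20)]
        assignments = []
        for d in range(5):
            blocks = {1: shared, 2: [f"P{d}_{i}" for i in range(10)]}
            assignments.append(self._assignment(blocks))
        result = module_conservation(assignments, min_size=1)
        shared_labels = [f"d{d}:1" for d in range(5)]
        groups = {result.clusters[lab] for lab in shared_labels}
        assert len(groups) == 1
        private = [f"d{d}:2" for d in range(5)]
        assert all(result.clusters[p] not in groups for p in private)

    def test_needs_two_assignments(self):
        a = self._assignment({1: ["g1"]})
        with pytest.raises(ValueError):
            module_conservation([a])
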