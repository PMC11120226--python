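import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from modbarcode import (
    ModuleAssignment,
    collapse_all,
    collapse_module,
    gene_module_correlation,
)

from .conftest import make_centered


def coherent_plus_noise(seed=7, n=200, n_coherent=10, n_noise=3, noise_sd=0.28):
    """Ten genes tracking one latent factor (rho ~0.95 each) plus appended noise."""
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n)
    rows = {f"C{i:02d}": latent + rng.normal(0, noise_sd, n) for i in range(n_coherent)}
    rows |= {f"N{i}": rng.standard_normal(n) for i in range(n_noise)}
    return make_centered(rows), latent


class TestCollapseModule:
    def test_identical_profiles_converge_immediately(self):
        profile = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        cm = make_centered({f"g{i}": profile.copy() for i in range(5)})
        ms = collapse_module(cm, cm.gene_ids)
        assert ms.converged and ms.iterations == 1
        assert sorted(ms.retained) == cm.gene_ids
        assert np.array_equal(ms.score.to_numpy(), profile)

    def test_noise_members_are_shed(self):
        cm, latent = coherent_plus_noise()
        ms = collapse_module(cm, cm.gene_ids)
        assert sorted(ms.retained) == [f"C{i:02d}" for i in range(10)]
        assert ms.converged
        assert spearmanr(ms.score, latent).statistic >= 0.99

    def test_incoherent_module_falls_back_to_plain_median(self):
        rng = np.random.default_rng(0)
        cm = make_centered({f"X{i}": rng.standard_normal(100) for i in range(4)})
        ms = collapse_module(cm, cm.gene_ids)
        assert not ms.converged
        assert sorted(ms.retained) == cm.gene_ids
        expected = np.median(cm.data.to_numpy(), axis=0)
        assert np.array_equal(ms.score.to_numpy(), expected)

    def test_fixed_point_is_stable_under_reapplication(self):
        cm, _ = coherent_plus_noise()
        first = collapse_module(cm, cm.gene_ids)
        again = collapse_module(cm, first.retained)
        assert sorted(again.retained) == sorted(first.retained)
        assert np.array_equal(again.score.to_numpy(), first.score.to_numpy())

    def test_invariant_to_sample_and_member_order(self):
        cm, _ = coherent_plus_noise(seed=3)
        rng = np.random.default_rng(1)
        shuffled_samples = rng.permutation(cm.data.columns)
        cm_perm = make_centered(
            {g: cm.data.loc[g, shuffled_samples].to_numpy() for g in cm.gene_ids}
        )
        members_perm = list(rng.permutation(cm.gene_ids))
        a = collapse_module(cm, cm.gene_ids)
        b = collapse_module(cm_perm, members_perm)
        assert sorted(a.retained) == sorted(b.retained)
        # same score values, just in permuted sample order
        assert np.allclose(a.score[shuffled_samples].to_numpy(), b.score.to_numpy())

    def test_absent_members_dropped_all_absent_errors(self):
        cm, _ = coherent_plus_noise()
        ms = collapse_module(cm, cm.gene_ids + ["ghost"])
        assert "ghost" not in ms.retained
        with pytest.raises(ValueError):
            collapse_module(cm, ["ghost1", "ghost2"])

    def test_strict_inequality_at_the_threshold(self):
        # a member correlating exactly at r_keep is NOT retained
        profile = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        cm = make_centered({"a": profile, "b": profile.copy()})
        ms = collapse_module(cm, ["a", "b"], r_keep=1.0)
        assert not ms.converged  # rho == 1.0 fails the strict > 1.0 test -> fallback


class TestCollapseAll:
    def test_recovers_all_planted_factors(self, default_dataset, fitted):
        cs = fitted.collapse()
        for mid in fitted.assignment.reported_modules():
            rho = abs(
                spearmanr(
                    cs.scores.loc[mid], default_dataset.factors.loc[mid]
                ).statistic
            )
            assert rho >= 0.95
            assert cs.converged[mid]

    def test_single_module_assignment_equals_collapse_module(self):
        cm, _ = coherent_plus_noise(seed=5)
        a = ModuleAssignment(pd.Series(1, index=cm.gene_ids))
        cs = collapse_all(cm, a)
        ms = collapse_module(cm, cm.gene_ids)
        assert np.array_equal(cs.scores.loc[1].to_numpy(), ms.score.to_numpy())
        assert cs.retained_genes[1] == ms.retained

    def test_empty_assignment_gives_empty_scores(self):
        cm, _ = coherent_plus_noise()
        a = ModuleAssignment(pd.Series(0, index=cm.gene_ids))  # all unclustered
        cs = collapse_all(cm, a)
        assert cs.scores.shape[0] == 0


class TestGeneModuleCorrelation:
    def test_gene_identical_to_score_has_rho_one(self, fitted):
        cs = fitted.collapse()
        mid = cs.module_ids[0]
        cm = fitted.centered
        extra = cm.data.copy()
        extra.loc["clone"] = cs.scores.loc[mid].to_numpy()
        cm2 = make_centered({g: extra.loc[g].to_numpy() for g in extra.index})
        cm2.data.columns = cm.data.columns
        table = gene_module_correlation(cm2, cs)
        assert table.loc["clone", mid] == pytest.approx(1.0)

    def test_negated_ranks_give_minus_one(self, fitted):
        cs = fitted.collapse()
        mid = cs.module_ids[0]
        cm = fitted.centered
        extra = cm.data.copy()
        extra.loc["anti"] = -cs.scores.loc[mid].to_numpy()
        cm2 = make_centered({g: extra.loc[g].to_numpy() for g in extra.index})
        cm2.data.columns = cm.data.columns
        table = gene_module_correlation(cm2, cs)
        assert table.loc["anti", mid] == pytest.approx(-1.0)

    def test_dual_loading_gene_tops_both_parent_modules(self, default_dataset, fitted):
        cs = fitted.collapse()
        f = default_dataset.factors
        rng = np.random.default_rng(8)
        dual = 0.7 * f.loc[1] + 0.7 * f.loc[2] + rng.normal(0, 0.2, f.shape[1])
        cm = fitted.centered
        extra = cm.data.copy()
        extra.loc["dual"] = dual.to_numpy()
        cm2 = make_centered({g: extra.loc[g].to_numpy() for g in extra.index})
        cm2.data.columns = cm.data.columns
        table = gene_module_correlation(cm2, cs)
        planted = table.loc["dual", fitted.assignment.reported_modules()]
        assert set(planted.sort_values(ascending=False).index[:2]) == {1, 2}

    def test_own_module_column(self, fitted):
        table = gene_module_correlation(
            fitted.centered, fitted.collapse(), fitted.assignment
        )
        member = fitted.assignment.members(1)[0]
        assert table.loc[member, "own_module"] == 1
        assert table.loc[member, "own_module_rho"] > 0.6

    def test_sample_mismatch_errors(self, fitted):
        cs = fitted.collapse()
        wrong = make_centered({"g": np.arange(5.0)})
        with pytest.raises(ValueError, match="sample"):
            gene_module_correlation(wrong, cs)
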