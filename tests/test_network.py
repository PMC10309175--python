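"""Paired correlation, soft threshold, TOM, modules, eigengenes, LMM assoc."""

import warnings

import numpy as np
import pandas as pd
import pytest

from steroidmir.lcl import DEX, SHAM, PairedExprSet
from steroidmir.network import (
    GREY,
    adjacency_from_correlation,
    cut_modules,
    module_eigengene,
    module_mirna_assoc,
    module_trait_assoc,
    paired_correlation,
    pick_soft_power,
    topological_overlap,
)
from steroidmir.simulate import LclConfig, generate_lcl
from steroidmir.stats import DegenerateInputError


class TestPairedCorrelation:
    def test_unpaired_equals_pearson(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(6, 20)))
        ours = paired_correlation(df).to_numpy()
        np.testing.assert_allclose(ours, np.corrcoef(df.to_numpy()), atol=1e-12)

    def test_duplicate_probe_correlation_one(self, toy_paired):
        x = toy_paired
        x.values.loc["g1"] = x.values.loc["g0"]
        c = paired_correlation(x)
        assert c.loc["g0", "g1"] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_unit_diagonal_bounded(self, small_paired):
        x, _ = small_paired
        c = paired_correlation(x).to_numpy()
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert np.abs(c).max() <= 1.0 + 1e-12

    def test_beats_naive_pearson_under_subject_offsets(self):
        """Shared per-subject offsets inflate pooled Pearson; the paired
        estimate stays nearer the generating within-module correlation."""
        rho = 0.5
        wins = 0
        n_seeds = 25
        for seed in range(n_seeds):
            x, truth = generate_lcl(
                LclConfig(
                    n_probes=40, n_modules=1, module_size_range=(40, 40),
                    n_pairs=60, subject_sd=1.0, within_module_cor=rho, seed=seed,
                )
            )
            iu = np.triu_indices(40, 1)
            paired = paired_correlation(x).to_numpy()[iu].mean()
            naive = paired_correlation(x, method="pearson").to_numpy()[iu].mean()
            wins += abs(paired - rho) < abs(naive - rho)
        assert wins >= int(0.9 * n_seeds)


class TestSoftPower:
    def test_no_structure_warns_and_falls_back(self):
        c = np.eye(30)
        with pytest.warns(UserWarning, match="scale-free"):
            power, table = pick_soft_power(c)
        assert power in table.index

    def test_perfect_block_fixed_point(self):
        c = np.ones((4, 4))
        a = adjacency_from_correlation(c, power=1)
        np.testing.assert_allclose(a, 1.0)

    def test_planted_modules_reach_scale_free_target(self):
        for seed in (2, 3):
            x, _ = generate_lcl(
                LclConfig(n_probes=300, n_modules=3, module_size_range=(40, 60),
                          n_pairs=44, seed=seed)
            )
            power, table = pick_soft_power(paired_correlation(x))
            assert table.loc[power, "r2"] >= 0.8

    def test_non_finite_rejected(self):
        c = np.eye(4)
        c[0, 1] = np.nan
        with pytest.raises(DegenerateInputError):
            pick_soft_power(c)


class TestTom:
    def test_isolated_connected_pair(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        t = topological_overlap(a)
        assert t[0, 1] == pytest.approx(1.0)

    def test_zero_adjacency(self):
        t = topological_overlap(np.zeros((5, 5)))
        assert np.all(t[~np.eye(5, dtype=bool)] == 0.0)
        assert np.all(np.diag(t) == 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            t = topological_overlap(a)
            k = a.sum(axis=1)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    num = sum(a[i, u] * a[u, j] for u in range(n)) + a[i, j]
                    den = min(k[i], k[j]) + 1 - a[i, j]
                    assert t[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_asymmetric_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            topological_overlap(a)


class TestCutModules:
    def _block_tom(self, seed=0):
        """Two perfect 50-probe blocks plus 40 noise probes."""
        rng = np.random.default_rng(seed)
        n = 140
        c = rng.uniform(0, 0.05, size=(n, n))
        c = (c + c.T) / 2
        c[:50, :50] = 0.95
        c[50:100, 50:100] = 0.95
        np.fill_diagonal(c, 1.0)
        return topological_overlap(adjacency_from_correlation(c, 6))

    def test_two_perfect_blocks_recovered(self):
        from sklearn.metrics import rand_score

        tom = self._block_tom()
        asg = cut_modules(tom, min_module_size=30)
        truth = np.r_[np.zeros(50), np.ones(50), np.full(40, 2)]
        non_grey = asg[asg != GREY]
        assert non_grey.nunique() == 2
        assert rand_score(truth, asg.to_numpy()) >= 0.95

    def test_min_size_above_n_everything_grey(self):
        tom = self._block_tom()
        asg = cut_modules(tom, min_module_size=200)
        assert (asg == GREY).all()

    def test_probe_permutation_equivariance(self):
        tom = self._block_tom(seed=3)
        perm = np.random.default_rng(4).permutation(tom.shape[0])
        a1 = cut_modules(tom, min_module_size=30)
        a2 = cut_modules(tom[np.ix_(perm, perm)], min_module_size=30)
        # same partition structure (labels may swap by size ties)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(a1.to_numpy()[perm], a2.to_numpy()) == 1.0

    def test_min_module_size_validation(self):
        with pytest.raises(ValueError):
            cut_modules(self._block_tom(), min_module_size=1)

    def test_planted_partition_recovery(self):
        from sklearn.metrics import rand_score

        x, truth = generate_lcl(
            LclConfig(n_probes=300, n_modules=3, module_size_range=(40, 60),
                      n_pairs=88, seed=5)
        )
        cor = paired_correlation(x)
        power, _ = pick_soft_power(cor)
        tom = topological_overlap(adjacency_from_correlation(cor, power))
        asg = cut_modules(
            tom, min_module_size=20, values=x.paired_differences(),
            probe_ids=cor.index,
        )
        t = np.array([truth["module_assignment"][p] for p in cor.index])
        assert rand_score(t, asg.to_numpy()) >= 0.9


class TestEigengene:
    def test_identical_probes_give_common_profile(self, toy_paired):
        x = toy_paired
        vals = pd.concat([x.values.loc[["g0"]]] * 3)
        vals.index = ["a", "b", "c"]
        asg = pd.Series("mod", index=vals.index)
        eig = module_eigengene(vals, asg)
        z = (x.values.loc["g0"] - x.values.loc["g0"].mean()) / x.values.loc[
            "g0"
        ].std(ddof=1)
        np.testing.assert_allclose(eig.loc["mod"], z, atol=1e-10)

    def test_single_probe_module(self, toy_paired):
        x = toy_paired
        asg = pd.Series("solo", index=["g0"])
        eig = module_eigengene(x.values.loc[["g0"]], asg)
        z = (x.values.loc["g0"] - x.values.loc["g0"].mean()) / x.values.loc[
            "g0"
        ].std(ddof=1)
        np.testing.assert_allclose(eig.loc["solo"], z, atol=1e-10)

    def test_matches_svd_oracle_and_unit_variance(self, small_paired):
        x, truth = small_paired
        asg = pd.Series(
            {p: f"m{v}" if v >= 0 else GREY for p, v in truth["module_assignment"].items()}
        )
        eig = module_eigengene(x.values, asg)
        assert np.allclose(eig.var(axis=1, ddof=1), 1.0)
        mod = "m0"
        sub = x.values.loc[asg.index[asg == mod]].to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, ddof=1, keepdims=True)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        pc = vt[0] / vt[0].std(ddof=1)
        ours = eig.loc[mod].to_numpy()
        assert min(
            np.abs(ours - pc).max(), np.abs(ours + pc).max()
        ) < 1e-10

    def test_first_pc_explains_most_variance(self, small_paired):
        x, truth = small_paired
        asg = pd.Series(
            {p: f"m{v}" if v >= 0 else GREY for p, v in truth["module_assignment"].items()}
        )
        eig = module_eigengene(x.values, asg)
        sub = x.values.loc[asg.index[asg == "m1"]].to_numpy()
        z = (sub - sub.mean(1, keepdims=True)) / sub.std(1, ddof=1, keepdims=True)
        me = eig.loc["m1"].to_numpy()
        var_me = np.mean((z @ me) ** 2) / (me @ me)
        rng = np.random.default_rng(0)
        for _ in range(20):
            r = rng.normal(size=len(me))
            assert var_me >= np.mean((z @ r) ** 2) / (r @ r) - 1e-9


class TestModuleAssoc:
    def _setup(self, coupling, seed=0):
        rng = np.random.default_rng(seed + 1000)
        lv = rng.normal(size=60)
        x, truth = generate_lcl(
            LclConfig(n_probes=200, n_modules=3, module_size_range=(30, 50),
                      n_pairs=60, coupled_module_index=0 if coupling else None,
                      coupling_strength=coupling, seed=seed),
            mirna_levels=lv,
        )
        asg = pd.Series(
            {p: f"m{v}" if v >= 0 else GREY for p, v in truth["module_assignment"].items()}
        )
        eig = module_eigengene(x.values, asg)
        ml = pd.DataFrame([lv], index=["miR-x"], columns=x.subjects)
        return x, eig, ml

    def test_planted_coupling_flagged(self):
        x, eig, ml = self._setup(coupling=1.0)
        tab = module_mirna_assoc(eig, ml, None, x.samples, fdr=0.10)
        assert tab[tab["module"] == "m0"]["significant"].all()
        np.testing.assert_allclose(tab["exp_coef"], np.exp(tab["coef"]), rtol=1e-12)

    def test_null_modules_rarely_flagged(self):
        flags = total = 0
        for seed in range(8):
            x, eig, ml = self._setup(coupling=0.0, seed=seed)
            tab = module_mirna_assoc(eig, ml, None, x.samples, fdr=0.10)
            flags += int(tab["significant"].sum())
            total += len(tab)
        assert flags / total <= 0.15

    def test_trait_self_association_flagged_and_constant_rejected(self):
        x, eig, ml = self._setup(coupling=0.0)
        rng = np.random.default_rng(5)
        me = eig.loc["m1"]
        subj_level = x.paired_means().T.groupby(
            x.samples["subject_id"]
        ).mean()  # placeholder to get subject index ordering
        subjects = x.subjects
        # trait = subject-average eigengene + small noise
        me_subj = me.groupby(x.samples.loc[me.index, "subject_id"]).mean()
        traits = pd.DataFrame({
            "echo": me_subj.loc[subjects] + 0.05 * rng.normal(size=len(subjects)),
        }, index=subjects)
        tab = module_trait_assoc(eig, traits, None, x.samples, fdr=0.05)
        assert tab[(tab["module"] == "m1") & (tab["trait"] == "echo")][
            "significant"
        ].all()
        const = pd.DataFrame({"flat": 1.0}, index=subjects)
        with pytest.raises(DegenerateInputError):
            module_trait_assoc(eig, const, None, x.samples)
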