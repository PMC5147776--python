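"""GRM against brute force, REML parameter recovery, spike-in series,
BLUP-ridge equivalence and risk scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sexgwas as sg
from sexgwas.heritability import (
    Grm,
    blup_snp_effects,
    compute_grm,
    grm_relatedness_filter,
    group_compare,
    reml_h2,
    risk_scores,
    spike_in_counts,
    spike_in_series,
)
from sexgwas.simulate import ArchitectureSpec, CausalSet, GenotypeTable, null_spec


def _pop(n, m, seed=0):
    return sg.simulate_population(null_spec(m, seed=seed), n)


def _quant_trait(pop, h2, seed=0):
    rng = np.random.default_rng(seed)
    W = pop.standardized()
    if h2 == 0:
        return rng.standard_normal(pop.n)
    beta = rng.normal(0, 1, pop.m)
    g = W @ beta
    g = g / g.std() * np.sqrt(h2)
    return g + rng.normal(0, np.sqrt(1 - h2), pop.n)


class TestGrm:
    def test_brute_force_equality(self):
        """10 x 20 GRM equals the double-loop definition to 1e-12."""
        pop = _pop(10, 20, seed=3)
        grm = compute_grm(pop)
        f = pop.cohort_freqs()
        D = pop.dosages.astype(float)
        m = grm.m
        keep = [s in set(grm.snps) for s in pop.snp_info["snp"]]
        A = np.zeros((10, 10))
        for i in range(10):
            for k in range(10):
                acc = 0.0
                for j, use in enumerate(keep):
                    if not use:
                        continue
                    p = f[j]
                    acc += (D[i, j] - 2 * p) * (D[k, j] - 2 * p) / (2 * p * (1 - p))
                A[i, k] = acc / m
        assert np.abs(grm.matrix - A).max() < 1e-12

    def test_single_snp_hets_at_half_give_zero(self):
        info = pd.DataFrame(
            {"snp": ["s"], "chrom": ["1"], "pos": [1], "a1": "A", "a2": "G", "freq": [0.5]}
        )
        meta = pd.DataFrame(
            {"iid": ["a", "b"], "sex": "female", "role": "control", "batch": "B1",
             "design": "case-control", "affection": 1, "family": ["a", "b"],
             "father": "0", "mother": "0"}
        )
        g = GenotypeTable(info, np.array([[1], [1]], dtype=np.int8), meta)
        grm = compute_grm(g)
        assert grm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_individual_off_diagonal_equals_diagonal(self):
        pop = _pop(20, 100, seed=4)
        pop.dosages[1] = pop.dosages[0]
        grm = compute_grm(pop)
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0], abs=1e-12)

    def test_symmetry(self):
        grm = compute_grm(_pop(30, 200, seed=5))
        assert np.abs(grm.matrix - grm.matrix.T).max() < 1e-12

    @pytest.mark.parametrize("binary", [True, False])
    def test_gcta_layout_round_trip(self, tmp_path, binary):
        from sexgwas.heritability import read_grm, write_grm

        grm = compute_grm(_pop(15, 80, seed=9))
        write_grm(grm, tmp_path / "g", binary=binary)
        back = read_grm(tmp_path / "g")
        assert back.ids == grm.ids
        tol = 1e-6 if binary else 1e-12  # float32 on disk in the binary layout
        assert np.abs(back.matrix - grm.matrix).max() < tol
        if binary:
            assert back.m == grm.m


class TestRelatednessFilter:
    def test_unrelated_cohort_mostly_retained(self):
        grm = compute_grm(_pop(200, 2_000, seed=6))
        kept = grm_relatedness_filter(grm, cutoff=0.1)
        assert len(kept) >= 0.99 * 200

    def test_duplicate_pair_loses_one_member(self):
        pop = _pop(40, 300, seed=7)
        pop.dosages[5] = pop.dosages[4]
        grm = compute_grm(pop)
        kept = grm_relatedness_filter(grm, cutoff=0.1)
        both = {pop.meta["iid"][4], pop.meta["iid"][5]}
        assert len(both & set(kept)) == 1

    def test_high_cutoff_is_identity(self):
        grm = compute_grm(_pop(50, 200, seed=8))
        off = grm.matrix - np.diag(np.diag(grm.matrix))
        kept = grm_relatedness_filter(grm, cutoff=off.max() + 0.01)
        assert kept == grm.ids


class TestReml:
    @pytest.mark.parametrize("h2", [0.0, 0.5])
    def test_parameter_recovery_within_3_se(self, h2):
        pop = _pop(600, 600, seed=10)
        y = _quant_trait(pop, h2, seed=11)
        est = reml_h2(compute_grm(pop), y)
        assert est.converged
        assert abs(est.h2_obs - h2) < 3 * est.se_h2

    def test_noiseless_genetic_value_estimates_one(self):
        pop = _pop(400, 400, seed=12)
        rng = np.random.default_rng(13)
        y = pop.standardized() @ rng.normal(0, 1, pop.m)
        est = reml_h2(compute_grm(pop), y)
        assert abs(est.h2_obs - 1.0) < max(3 * est.se_h2, 0.02)

    def test_unconstrained_vg_can_go_negative(self):
        # a phenotype anti-correlated with relatedness: Vg < 0 is reachable
        pop = _pop(200, 150, seed=14)
        found_negative = False
        for s in range(6):
            y = np.random.default_rng(20 + s).standard_normal(pop.n)
            est = reml_h2(compute_grm(pop), y)
            if est.V_g < 0:
                found_negative = True
        assert found_negative

    def test_orthogonal_covariate_shift_is_order_vp_over_n(self):
        """Adding a covariate orthogonal to phenotype, genotypes and the
        intercept changes the restricted df by one; the estimate moves by
        O(Vp/n), the exact-arithmetic contract of REML."""
        pop = _pop(300, 100, seed=15)
        y = _quant_trait(pop, 0.4, seed=16)
        grm = compute_grm(pop)
        base = reml_h2(grm, y)
        rng = np.random.default_rng(17)
        z = rng.standard_normal(pop.n)
        M = np.column_stack([np.ones(pop.n), y, pop.standardized()])
        z -= M @ np.linalg.lstsq(M, z, rcond=None)[0]
        adj = reml_h2(grm, y, covariates=z)
        vp = base.V_g + base.V_e
        assert abs(adj.h2_obs - base.h2_obs) < 5 * vp / pop.n

    def test_rank_deficient_covariates_rejected(self):
        pop = _pop(100, 50, seed=18)
        y = _quant_trait(pop, 0.3, seed=19)
        with pytest.raises(ValueError, match="rank"):
            reml_h2(compute_grm(pop), y, covariates=np.ones((100, 1)))


class TestSpikeIn:
    def test_set_counting(self):
        assert len(spike_in_counts(953, 10)) == 97
        assert spike_in_counts(20, 10) == [0, 10, 20]
        assert spike_in_counts(953, 10)[-1] == 953

    def test_pseudo_control_only_series_dilutes_h2(self):
        """Adding phenotype-noise pairs (pseudo-control vs pseudo-control)
        drives the heritability estimate down: negative Spearman rho."""
        idx = tuple(range(0, 200, 2))
        beta = tuple(1.0 for _ in idx)
        spec = ArchitectureSpec(
            n_snps_by_chrom={str(c): 10 for c in range(1, 21)},
            causal_sets=(CausalSet(idx, beta, beta),), h2_liability=0.5, seed=55,
        )
        trios = sg.simulate_trios(spec, 260, 0.5)
        pc = sg.make_pseudo_controls(trios)
        fams = pc.meta["family"].unique()
        base = [f"{f}_c" for f in fams[:180]] + [f"{f}_pc" for f in fams[:180]]
        pool_pc = [f"{f}_pc" for f in fams[180:]]
        pairs = [(pool_pc[2 * i], pool_pc[2 * i + 1]) for i in range(len(pool_pc) // 2)]
        for a, _ in pairs:  # one of each pseudo-pair plays the 'case'
            pc.meta.loc[pc.meta["iid"] == a, "affection"] = 2
        sets, rho, _ = spike_in_series(pc, base, pairs, pairs_per_step=10)
        assert len(sets) == 5
        assert sets["converged"].all()
        assert rho < 0

    def test_overlapping_pool_rejected(self):
        pop = _pop(60, 30, seed=31)
        ids = list(pop.meta["iid"])
        with pytest.raises(ValueError, match="overlap"):
            spike_in_series(pop, ids[:10], [(ids[5], ids[20])])


@pytest.fixture(scope="module")
def trained():
    pop = _pop(150, 100, seed=40)
    y = _quant_trait(pop, 0.5, seed=41)
    grm = compute_grm(pop)
    est = reml_h2(grm, y)
    eff = blup_snp_effects(grm, pop, y, est)
    return pop, y, grm, est, eff


class TestBlup:

    def test_training_scores_reproduce_individual_blups(self, trained):
        pop, y, grm, est, eff = trained
        n = pop.n
        V = est.V_g * grm.matrix + est.V_e * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        ghat = est.V_g * grm.matrix @ (Vi @ (y - X @ b))
        scores = risk_scores(eff, pop)["score"].to_numpy()
        assert np.abs(scores - ghat).max() < 1e-6

    def test_ridge_equivalence(self):
        """BLUP SNP solutions equal ridge regression with penalty m*Ve/Vg."""
        pop = _pop(50, 100, seed=42)
        y = _quant_trait(pop, 0.5, seed=43)
        grm = compute_grm(pop)
        est = reml_h2(grm, y)
        assert est.V_g > 0
        eff = blup_snp_effects(grm, pop, y, est)
        W = pop.standardized()
        lam = grm.m * est.V_e / est.V_g
        resid = y - y.mean()  # GLS intercept equals the mean here (row sums tie)
        n = pop.n
        V = est.V_g * grm.matrix + est.V_e * np.eye(n)
        Vi = np.linalg.inv(V)
        X = np.ones((n, 1))
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        resid = y - (X @ b).ravel()
        u_ridge = np.linalg.solve(W.T @ W + lam * np.eye(pop.m), W.T @ resid)
        assert np.abs(u_ridge - eff.table["u"].to_numpy()).max() < 1e-6

    def test_null_phenotype_effects_shrink(self):
        pop = _pop(300, 100, seed=2)
        grm = compute_grm(pop)
        y_sig = _quant_trait(pop, 0.5, seed=45)
        est_sig = reml_h2(grm, y_sig)
        eff_sig = blup_snp_effects(grm, pop, y_sig, est_sig)
        y_null = np.random.default_rng(102).standard_normal(pop.n)
        est_null = reml_h2(grm, y_null)
        assert est_null.V_g > 0  # this seed lands slightly above zero
        eff_null = blup_snp_effects(grm, pop, y_null, est_null)
        assert np.abs(eff_null.table["u"]).mean() < 0.1 * np.abs(eff_sig.table["u"]).mean()

    def test_negative_vg_refused(self, trained):
        pop, y, grm, est, _ = trained
        from dataclasses import replace

        bad = replace(est, V_g=-0.1)
        with pytest.raises(ValueError, match="V_g"):
            blup_snp_effects(grm, pop, y, bad)


class TestRiskScores:
    def test_all_zero_effects_score_zero(self):
        pop = _pop(30, 40, seed=50)
        eff_table = pd.DataFrame(
            {"snp": pop.snp_info["snp"], "a1": "A", "u": 0.0}
        )
        from sexgwas.heritability import SnpEffects

        eff = SnpEffects(eff_table, pop.cohort_freqs(), list(pop.meta["iid"]))
        assert (risk_scores(eff, pop)["score"] == 0).all()

    def test_invariant_to_target_snp_order(self):
        pop = _pop(60, 80, seed=51)
        y = _quant_trait(pop, 0.5, seed=52)
        grm = compute_grm(pop)
        eff = blup_snp_effects(grm, pop, y, reml_h2(grm, y))
        target = _pop(20, 80, seed=53)
        perm = np.random.default_rng(54).permutation(target.m)
        shuffled = target.subset_snps(target.snp_info["snp"].to_numpy()[perm])
        a = risk_scores(eff, target)["score"].to_numpy()
        b = risk_scores(eff, shuffled)["score"].to_numpy()
        assert np.abs(a - b).max() < 1e-12

    def test_low_overlap_is_hard_error(self):
        pop = _pop(60, 80, seed=55)
        y = _quant_trait(pop, 0.5, seed=56)
        grm = compute_grm(pop)
        eff = blup_snp_effects(grm, pop, y, reml_h2(grm, y))
        target = pop.subset_snps(pop.snp_info["snp"][:30])
        with pytest.raises(ValueError, match="50%"):
            risk_scores(eff, target)


class TestGroupCompare:
    def test_identical_groups_t_zero(self):
        s = pd.DataFrame({"score": np.tile([0.1, 0.2, 0.3], 2)})
        diff, t, p = group_compare(s, [True, True, True, False, False, False])
        assert diff == pytest.approx(0.0)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_single_member_group_rejected(self):
        s = pd.DataFrame({"score": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="two members"):
            group_compare(s, [True, False, False])
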