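"""TDT against closed forms and an allele-level brute-force oracle;
logistic regression against the 2x2 table; PCA covariates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sexgwas as sg
from sexgwas.assoc import encode_x, logistic_assoc, pca_covariates, tdt, tdt_scan
from sexgwas.simulate import GenotypeTable


def _meta(iids, sexes, roles, affection, families=None, fathers=None, mothers=None):
    n = len(iids)
    return pd.DataFrame(
        {
            "iid": iids,
            "sex": sexes,
            "role": roles,
            "batch": "B1",
            "design": ["trio" if r in ("father", "mother", "proband") else "case-control" for r in roles],
            "affection": affection,
            "family": families if families is not None else iids,
            "father": fathers if fathers is not None else ["0"] * n,
            "mother": mothers if mothers is not None else ["0"] * n,
        }
    )


def _trio_cohort(dosage_triples, chrom="1", child_sexes=None):
    """Build a trio table from a list of (father, mother, child) dosages."""
    k = len(dosage_triples)
    child_sexes = child_sexes or ["male"] * k
    info = pd.DataFrame(
        {"snp": ["s1"], "chrom": [chrom], "pos": [100], "a1": "A", "a2": "G", "freq": [0.2]}
    )
    iids, sexes, roles, aff, fams, fas, mos, rows = [], [], [], [], [], [], [], []
    for i, (f, m, c) in enumerate(dosage_triples):
        fam = f"fam{i}"
        iids += [f"{fam}_f", f"{fam}_m", f"{fam}_c"]
        sexes += ["male", "female", child_sexes[i]]
        roles += ["father", "mother", "proband"]
        aff += [1, 1, 2]
        fams += [fam] * 3
        fas += ["0", "0", f"{fam}_f"]
        mos += ["0", "0", f"{fam}_m"]
        rows += [[f], [m], [c]]
    return GenotypeTable(
        info, np.array(rows, dtype=np.int8), _meta(iids, sexes, roles, aff, fams, fas, mos)
    )


class TestTdt:
    def test_symmetric_transmissions(self):
        # 10 het-father trios transmitting a1, 10 not
        trios = _trio_cohort([(1, 0, 1)] * 10 + [(1, 0, 0)] * 10)
        rec = tdt(trios, "s1")
        assert rec.b == 10 and rec.c == 10
        assert rec.p == pytest.approx(1.0)
        assert rec.beta == pytest.approx(0.0)

    def test_closed_form_b15_c5(self):
        trios = _trio_cohort([(1, 0, 1)] * 15 + [(1, 0, 0)] * 5)
        rec = tdt(trios, "s1")
        assert (rec.b, rec.c) == (15, 5)
        scan = tdt_scan(trios)
        assert scan["stat"][0] == pytest.approx(5.0)
        assert rec.p == pytest.approx(stats.chi2.sf(5.0, 1), abs=1e-10)
        assert rec.p == pytest.approx(0.02535, abs=1e-4)
        assert rec.beta == pytest.approx(np.log(3), abs=1e-10)
        assert rec.se == pytest.approx(np.sqrt(1 / 15 + 1 / 5), abs=1e-10)

    def test_untestable_snp_flagged(self):
        trios = _trio_cohort([(0, 0, 0), (2, 2, 2)])
        rec = tdt(trios, "s1")
        assert rec.n_eff == 0 and not rec.converged

    def test_x_father_never_informative(self):
        """Hemizygous fathers contribute nothing; het mothers everything."""
        # het mother, father carrier; sons and daughters
        trios = _trio_cohort(
            [(1, 1, 1), (1, 1, 0)], chrom="X", child_sexes=["male", "male"]
        )
        rec = tdt(trios, "s1")
        assert rec.b + rec.c == 2  # one maternal transmission per son
        # hom mothers: nothing is informative even with carrier fathers
        trios2 = _trio_cohort([(1, 0, 1), (1, 2, 2)], chrom="X", child_sexes=["female", "female"])
        rec2 = tdt(trios2, "s1")
        assert rec2.n_eff == 0

    def test_brute_force_allele_level_oracle(self):
        """TDT counts equal bookkeeping from an allele-level generator that
        records which parental allele was transmitted."""
        rng = np.random.default_rng(99)
        for chrom, sex_pool in (("1", ["male", "female"]), ("X", ["male", "female"])):
            triples, b_true, c_true = [], 0, 0
            child_sexes = []
            for _ in range(50):
                fa = rng.binomial(1, 0.3, size=2)  # father's two autosomal alleles
                ma = rng.binomial(1, 0.3, size=2)
                tf_i, tm_i = rng.integers(2), rng.integers(2)
                sex = sex_pool[rng.integers(2)]
                if chrom == "X":
                    f = int(fa[0])  # hemizygous
                    m = int(ma.sum())
                    mat = int(ma[tm_i])
                    c = mat if sex == "male" else f + mat
                    if m == 1:  # het mother informative
                        b_true += mat
                        c_true += 1 - mat
                else:
                    f, m = int(fa.sum()), int(ma.sum())
                    tf, tm = int(fa[tf_i]), int(ma[tm_i])
                    c = tf + tm
                    if f == 1:
                        b_true += tf
                        c_true += 1 - tf
                    if m == 1:
                        b_true += tm
                        c_true += 1 - tm
                triples.append((f, m, c))
                child_sexes.append(sex)
            trios = _trio_cohort(triples, chrom=chrom, child_sexes=child_sexes)
            rec = tdt(trios, "s1")
            assert (rec.b, rec.c) == (b_true, c_true), chrom

    def test_minor_allele_orientation(self):
        """When a1 is the major allele, b/c swap so effects refer to the minor."""
        trios = _trio_cohort([(1, 2, 2)] * 15 + [(1, 2, 1)] * 5)  # a1 freq > 0.5
        rec = tdt(trios, "s1")
        assert (rec.b, rec.c) == (5, 15)

    def test_type_one_error_under_null(self, null_trios):
        scan = tdt_scan(null_trios)
        ok = scan["testable"]
        rej = (scan.loc[ok, "p"] < 0.05).mean()
        assert abs(rej - 0.05) < 3 * np.sqrt(0.05 * 0.95 / ok.sum())


def _cc_table(dosages, affection, sexes=None, chrom="1"):
    n = len(dosages)
    sexes = sexes if sexes is not None else ["female"] * n
    info = pd.DataFrame(
        {"snp": ["s1"], "chrom": [chrom], "pos": [100], "a1": "A", "a2": "G", "freq": [0.3]}
    )
    meta = _meta(
        [f"i{k}" for k in range(n)], sexes,
        ["case" if a == 2 else "control" for a in affection], affection,
    )
    return GenotypeTable(info, np.array(dosages, dtype=np.int8).reshape(-1, 1), meta)


class TestLogistic:
    def test_2x2_closed_form(self):
        """Unadjusted logistic MLE equals the 2x2 table log-odds."""
        dos = [1] * 40 + [0] * 60 + [1] * 20 + [0] * 80
        aff = [2] * 100 + [1] * 100
        rec = logistic_assoc(_cc_table(dos, aff), "s1")
        assert rec.beta == pytest.approx(np.log(40 * 80 / (60 * 20)), abs=1e-5)
        assert rec.se == pytest.approx(np.sqrt(1 / 40 + 1 / 60 + 1 / 20 + 1 / 80), abs=1e-4)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        n = 600
        ps = []
        aff = np.array([2] * (n // 2) + [1] * (n // 2))
        for _ in range(250):
            dos = rng.binomial(2, 0.3, size=n)
            rec = logistic_assoc(_cc_table(dos, aff), "s1")
            ps.append(rec.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_orthogonal_covariate_leaves_beta(self):
        rng = np.random.default_rng(7)
        n = 400
        dos = rng.binomial(2, 0.3, size=n)
        aff = np.where(rng.random(n) < 0.5, 2, 1)
        g = _cc_table(dos, aff)
        base = logistic_assoc(g, "s1")
        # a covariate orthogonal to the fitted residuals leaves the MLE fixed
        import statsmodels.api as sm

        X = sm.add_constant(dos.astype(float))
        fit = sm.Logit((aff == 2).astype(float), X).fit(disp=0)
        resid = (aff == 2).astype(float) - fit.predict(X)
        z = rng.standard_normal(n)
        z -= resid * (z @ resid) / (resid @ resid)
        adj = logistic_assoc(g, "s1", covariates=z)
        assert adj.beta == pytest.approx(base.beta, abs=1e-6)

    @pytest.mark.filterwarnings("ignore::Warning")
    def test_separation_flagged(self):
        dos = [2] * 20 + [0] * 20
        aff = [2] * 20 + [1] * 20
        rec = logistic_assoc(_cc_table(dos, aff), "s1")
        assert not rec.converged

    def test_vectorized_scan_matches_statsmodels(self):
        """The batched IRLS path agrees with statsmodels per-SNP fits."""
        import sexgwas as sg
        from sexgwas.assoc import logistic_scan
        from sexgwas.simulate import null_spec

        pop = sg.simulate_population(null_spec(60, n_x=10, seed=33), 400)
        rng = np.random.default_rng(34)
        case = rng.permutation(pop.n) < 200
        pop.meta.loc[case, "affection"] = 2
        cov = rng.standard_normal((pop.n, 2))
        scan = logistic_scan(pop, covariates=cov)
        for j in [0, 10, 59, 62, 69]:  # autosomal and X
            snp = pop.snp_info["snp"].iloc[j]
            oracle = logistic_assoc(pop, snp, covariates=cov)
            row = scan[scan["snp"] == snp].iloc[0]
            assert row["beta"] == pytest.approx(oracle.beta, abs=1e-8)
            assert row["se"] == pytest.approx(oracle.se, abs=1e-8)

    def test_requires_both_classes(self):
        with pytest.raises(ValueError, match="both"):
            logistic_assoc(_cc_table([0, 1, 2], [2, 2, 2]), "s1")


class TestEncodeX:
    def test_codings(self):
        g = _cc_table([1, 1, 2], [2, 1, 1], sexes=["male", "female", "female"], chrom="X")
        d = encode_x(g, "s1")
        assert list(d) == [1, 1, 2]  # male carrier 1; female het 1; female hom 2

    def test_male_dosage_two_is_hard_error(self):
        g = _cc_table([1, 1], [2, 1], sexes=["male", "female"], chrom="X")
        g.dosages[0, 0] = 2  # corrupt after validation
        with pytest.raises(ValueError, match="i0"):
            encode_x(g, "s1")

    def test_all_female_matches_autosomal(self):
        g = _cc_table([0, 1, 2], [2, 1, 1], sexes=["female"] * 3, chrom="X")
        assert list(encode_x(g, "s1")) == [0, 1, 2]


class TestPca:
    def _pop(self, freq_a, freq_b, n_each=120, m=80, seed=3):
        rng = np.random.default_rng(seed)
        dos = np.vstack(
            [rng.binomial(2, freq_a, size=(n_each, m)), rng.binomial(2, freq_b, size=(n_each, m))]
        ).astype(np.int8)
        info = pd.DataFrame(
            {"snp": [f"s{i}" for i in range(m)], "chrom": "1",
             "pos": 100 * (1 + np.arange(m)), "a1": "A", "a2": "G", "freq": 0.5}
        )
        meta = _meta(
            [f"i{k}" for k in range(2 * n_each)], ["female"] * 2 * n_each,
            ["control"] * 2 * n_each, [1] * 2 * n_each,
        )
        return GenotypeTable(info, dos, meta), np.array([0] * n_each + [1] * n_each)

    def test_divergent_subpopulations_separate_on_pc1(self):
        g, label = self._pop(0.1, 0.6)
        V = pca_covariates(g, k=2)
        r = np.corrcoef(V[:, 0], label)[0, 1]
        assert abs(r) > 0.9

    def test_homogeneous_population_no_structure(self):
        g, _ = self._pop(0.3, 0.3, n_each=500, seed=11)
        V = pca_covariates(g, k=3)
        rng = np.random.default_rng(13)
        lab = rng.integers(2, size=g.n)
        for j in range(V.shape[1]):
            assert abs(np.corrcoef(V[:, j], lab)[0, 1]) < 0.1

    def test_orthonormal_and_sign_fixed(self):
        g, _ = self._pop(0.2, 0.5)
        V = pca_covariates(g, k=5)
        assert np.allclose(V.T @ V, np.eye(5), atol=1e-8)
        for j in range(5):
            assert V[np.argmax(np.abs(V[:, j])), j] > 0
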