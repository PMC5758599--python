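"""Genotype QC, LD pruning, kinship, GWAS, heritability, prediction."""

import numpy as np
import pytest

from leafscape.errors import ParameterError, ShapeError
from leafscape.genomics import (
    GenotypeMatrix,
    filter_genotypes,
    greml_h2,
    kinship,
    ld_prune,
    mlm_gwas,
    random_phenotype_null,
    rrblup_cv,
    rrblup_marker_predict,
    simple_m,
    structure_pca,
)
from leafscape.genomics import _gblup_predict
from leafscape.synthetic import (
    GeneticArchitecture,
    simulate_genotypes,
    simulate_phenotype,
)


def _gm(codes, chrom=None, pos=None):
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    return GenotypeMatrix(
        codes=codes,
        sample_ids=[f"i{i}" for i in range(n)],
        snp_ids=[f"s{j}" for j in range(m)],
        chrom=np.array(["1"] * m, dtype=object) if chrom is None else chrom,
        pos=np.arange(1, m + 1, dtype=np.int64) if pos is None else pos,
    )


@pytest.fixture(scope="module")
def sim_500x2000():
    arch = GeneticArchitecture(
        n_individuals=500, n_snps=2000, n_causal=200, h2_true=0.7, seed=1
    )
    G = simulate_genotypes(arch)
    y, bv = simulate_phenotype(G, arch)
    return G, y, bv, kinship(G)


class TestFilters:
    def test_maf_and_het_rules_on_toy_matrix(self):
        # 5 SNPs with hand-computed MAFs on 10 individuals
        codes = np.zeros((10, 5), dtype=np.int8)
        codes[0, 0] = 1  # MAF 0.05 -> keep at 0.05 threshold
        codes[0, 1] = 0  # monomorphic, MAF 0 -> drop
        codes[:3, 2] = 1  # MAF 0.15 -> keep
        codes[:, 3] = 1  # all het -> drop by het rule
        codes[:5, 4] = 2  # MAF 0.5 -> keep
        G, log = filter_genotypes(_gm(codes), maf_min=0.05, het_max=0.90)
        assert G.snp_ids == ["s0", "s2", "s4"]
        assert log["n_kept"] == 3

    def test_maf_below_threshold_removed(self):
        codes = np.zeros((50, 2), dtype=np.int8)
        codes[:2, 0] = 1  # MAF 0.02
        codes[:20, 1] = 1  # MAF 0.2
        G, _ = filter_genotypes(_gm(codes), maf_min=0.05)
        assert G.snp_ids == ["s1"]

    def test_high_heterozygosity_removed(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, size=(40, 2)).astype(np.int8)
        codes[:38, 0] = 1  # 95% het
        G, log = filter_genotypes(_gm(codes), het_max=0.90)
        assert "s0" not in G.snp_ids
        assert log["n_het_fail"] >= 1

    def test_all_removed_raises(self):
        codes = np.zeros((10, 2), dtype=np.int8)
        with pytest.raises(ShapeError):
            filter_genotypes(_gm(codes), maf_min=0.05)


def brute_force_prune(X, window, step, r2_max):
    """Independent re-implementation of the windowed pruning rule."""
    m = X.shape[1]
    removed = set()
    start = 0
    while True:
        members = [j for j in range(start, min(start + window, m)) if j not in removed]
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                a, b = members[ai], members[bi]
                if a in removed or b in removed:
                    continue
                r = np.corrcoef(X[:, a], X[:, b])[0, 1]
                if r * r > r2_max:
                    removed.add(b)
        if start + window >= m:
            break
        start += step
    return [j for j in range(m) if j not in removed]


class TestLDPrune:
    def test_duplicated_snp_keeps_exactly_one(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=(50, 1)).astype(np.int8)
        codes = np.hstack([col, col])
        kept = ld_prune(_gm(codes), window=10, step=3, r2_max=0.5)
        assert kept.tolist() == [0]

    def test_independent_snps_all_kept(self):
        arch = GeneticArchitecture(
            n_individuals=400, n_snps=30, n_causal=10, ld_block_size=1, seed=2
        )
        G = simulate_genotypes(arch)
        kept = ld_prune(G)
        assert len(kept) == 30

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_toy_sets(self, seed):
        arch = GeneticArchitecture(
            n_individuals=120, n_snps=30, n_causal=10, ld_block_size=5, seed=seed
        )
        G = simulate_genotypes(arch)
        kept = ld_prune(G, window=10, step=3, r2_max=0.5)
        expected = brute_force_prune(G.dosage(), 10, 3, 0.5)
        assert kept.tolist() == expected


class TestKinship:
    def test_duplicated_individuals_share_kinship(self):
        rng = np.random.default_rng(3)
        codes = rng.integers(0, 3, size=(20, 300)).astype(np.int8)
        codes[1] = codes[0]
        K = kinship(_gm(codes))
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_hwe_diagonal_near_one(self):
        arch = GeneticArchitecture(
            n_individuals=500, n_snps=5000, n_causal=0, ld_block_size=1, seed=4
        )
        K = kinship(simulate_genotypes(arch))
        assert K.diagonal().mean() == pytest.approx(1.0, abs=0.05)

    def test_symmetric(self, sim_500x2000):
        K = sim_500x2000[3]
        np.testing.assert_allclose(K, K.T, atol=1e-12)

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ShapeError):
            kinship(_gm(np.zeros((10, 5), dtype=np.int8)))

    def test_individual_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=(30, 200)).astype(np.int8)
        K = kinship(_gm(codes))
        perm = rng.permutation(30)
        Kp = kinship(_gm(codes[perm]))
        np.testing.assert_allclose(Kp, K[np.ix_(perm, perm)], atol=1e-12)


class TestStructurePCA:
    def test_two_subpopulations_separate_on_pc1(self):
        rng = np.random.default_rng(6)
        m = 500
        p1, p2 = rng.uniform(0.1, 0.9, m), None
        # divergent allele frequencies (high differentiation)
        p2 = np.clip(p1 + rng.normal(0, 0.25, m), 0.05, 0.95)
        a = rng.binomial(2, p1, size=(60, m))
        b = rng.binomial(2, p2, size=(60, m))
        G = _gm(np.vstack([a, b]).astype(np.int8))
        scores = structure_pca(G, k=2)
        labels = np.r_[np.zeros(60), np.ones(60)]
        r = np.corrcoef(scores[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_duplicated_individuals_identical_scores(self):
        rng = np.random.default_rng(7)
        codes = rng.integers(0, 3, size=(25, 300)).astype(np.int8)
        codes[2] = codes[0]
        scores = structure_pca(_gm(codes), k=3)
        np.testing.assert_allclose(scores[2], scores[0], atol=1e-8)

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(8)
        codes = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        with pytest.raises(ParameterError):
            structure_pca(_gm(codes), k=10)


class TestSimpleM:
    def test_identity_correlation_gives_199_of_200(self):
        assert simple_m(np.eye(200)) == 199

    def test_duplicate_pairs_give_rank(self):
        rng = np.random.default_rng(9)
        base = rng.integers(0, 3, size=(300, 5)).astype(np.int8)
        dup = np.repeat(base, 2, axis=1)
        assert simple_m(_gm(dup)) == 5

    def test_meff_bounded_by_snp_count(self, sim_500x2000):
        G = sim_500x2000[0]
        sub = G.subset_snps(np.arange(100))
        assert simple_m(sub) <= 100

    def test_c_equal_one_gives_rank(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(50, 8))
        corr = np.corrcoef(X, rowvar=False)
        assert simple_m(corr, c=1.0) == np.linalg.matrix_rank(corr)

    def test_meff_monotone_in_c(self, sim_500x2000):
        sub = sim_500x2000[0].subset_snps(np.arange(200))
        meffs = [simple_m(sub, c=c) for c in (0.9, 0.95, 0.995)]
        assert meffs == sorted(meffs)

    def test_blockwise_equals_sum_of_blocks(self, sim_500x2000):
        sub = sim_500x2000[0].subset_snps(np.arange(300))
        whole_in_blocks = simple_m(sub, block_size=100)
        parts = sum(
            simple_m(sub.subset_snps(np.arange(s, s + 100)))
            for s in (0, 100, 200)
        )
        assert whole_in_blocks == parts


class TestGREML:
    def test_h2_recovery_at_07(self):
        """Target h2 recovered within 2 SE in most replicate simulations."""
        covered = 0
        for seed in range(5):
            arch = GeneticArchitecture(
                n_individuals=500, n_snps=2000, n_causal=200, h2_true=0.7,
                seed=40 + seed,
            )
            G = simulate_genotypes(arch)
            y, _ = simulate_phenotype(G, arch)
            est = greml_h2(y, kinship(G))
            if abs(est.h2 - 0.7) <= 2 * est.se:
                covered += 1
        assert covered >= 4

    def test_random_phenotype_h2_near_zero(self, sim_500x2000):
        K = sim_500x2000[3]
        rng = np.random.default_rng(11)
        y = rng.normal(size=K.shape[0])
        est = greml_h2(y, K)
        assert est.h2 <= 2 * est.se + 1e-9

    def test_zero_variance_phenotype_rejected(self, sim_500x2000):
        with pytest.raises(ParameterError):
            greml_h2(np.ones(500), sim_500x2000[3])

    def test_non_psd_k_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ShapeError):
            greml_h2(np.array([0.1, -0.2]), K)


class TestGWAS:
    def test_identity_kinship_matches_ols(self):
        rng = np.random.default_rng(12)
        arch = GeneticArchitecture(
            n_individuals=200, n_snps=50, n_causal=0, ld_block_size=1, seed=13
        )
        G = simulate_genotypes(arch)
        y = rng.normal(size=200)  # pure noise: Vg estimates ~0
        res = mlm_gwas(G, y, K=np.eye(200), n_pcs=0)
        from scipy import stats as st

        X = G.dosage()
        j = 7
        sl = st.linregress(X[:, j], y)
        assert res["p"].iloc[j] == pytest.approx(sl.pvalue, abs=1e-6)

    def test_power_on_large_effect_snp(self):
        hits = 0
        for seed in range(10):
            arch = GeneticArchitecture(
                n_individuals=500, n_snps=500, n_causal=0, ld_block_size=1,
                seed=100 + seed,
            )
            G = simulate_genotypes(arch)
            rng = np.random.default_rng(seed)
            x = G.dosage()[:, 250]
            beta = np.sqrt(0.2 / x.var())
            y = beta * x + rng.normal(scale=np.sqrt(0.8), size=500)
            res = mlm_gwas(G, y, n_pcs=3)
            if int(res["p"].idxmin()) == 250:
                hits += 1
        assert hits >= 9

    def test_type_i_error_under_polygenic_null(self):
        """Tested SNPs are not causal; the kinship term absorbs the
        polygenic background, so p-values should be uniform."""
        arch = GeneticArchitecture(
            n_individuals=500, n_snps=2400, n_causal=0, ld_block_size=10, seed=14
        )
        G = simulate_genotypes(arch)
        causal = GeneticArchitecture(
            n_individuals=500, n_snps=2400, n_causal=400, h2_true=0.5,
            ld_block_size=10, seed=14,
        )
        y, _ = simulate_phenotype(G, causal)
        causal_idx = np.random.default_rng([14, 202]).choice(2400, 400, replace=False)
        tested = np.setdiff1d(np.arange(2400), causal_idx)[:2000]
        Gt = G.subset_snps(tested)
        res = mlm_gwas(Gt, y, n_pcs=3)
        frac = float((res["p"] < 0.05).mean())
        assert frac == pytest.approx(0.05, abs=0.02)


class TestPrediction:
    def test_marker_ridge_equals_gblup(self, sim_500x2000):
        G, y, _, _ = sim_500x2000
        X = G.dosage()
        tr, te = np.arange(400), np.arange(400, 500)
        marker = rrblup_marker_predict(X[tr], y[tr], X[te])
        p = X[tr].mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        Z = X[:, poly] - 2 * p[poly]
        c = 2 * np.sum(p[poly] * (1 - p[poly]))
        K = (Z @ Z.T) / c
        gblup = _gblup_predict(K, y[tr], tr, te)
        np.testing.assert_allclose(marker, gblup, atol=1e-6)

    def test_prediction_accuracy_at_high_h2(self, sim_500x2000):
        """Accuracy approaches the sqrt(h2) ceiling, averaged over sims."""
        rs = []
        for seed in range(3):
            arch = GeneticArchitecture(
                n_individuals=500, n_snps=2000, n_causal=200, h2_true=0.7,
                seed=50 + seed,
            )
            G = simulate_genotypes(arch)
            y, _ = simulate_phenotype(G, arch)
            res = rrblup_cv(G, y, folds=5, reps=1, seed=seed)
            assert res.fold_r.shape == (1, 5)
            rs.append(res.mean_r)
        assert np.mean(rs) > 0.5

    def test_same_seed_reproducible(self, sim_500x2000):
        G, y, _, K = sim_500x2000
        a = rrblup_cv(G, y, folds=5, reps=1, seed=3, K=K)
        b = rrblup_cv(G, y, folds=5, reps=1, seed=3, K=K)
        assert a.mean_r == b.mean_r
        np.testing.assert_array_equal(a.fold_r, b.fold_r)

    def test_random_phenotype_null_centered_at_zero(self):
        arch = GeneticArchitecture(
            n_individuals=300, n_snps=1000, n_causal=100, seed=15
        )
        G = simulate_genotypes(arch)
        null = random_phenotype_null(G, n_pheno=60, folds=5, reps=1, seed=16)
        assert abs(null["mean_r"].mean()) < 0.05
        lo, hi = null["mean_r"].quantile([0.025, 0.975])
        assert lo < 0 < hi


class TestHeritabilityPredictionAssociation:
    def test_h2_and_accuracy_rise_together(self):
        """Traits of increasing heritability should show increasing
        prediction accuracy (rank correlation across the h2 ladder)."""
        from scipy.stats import spearmanr

        h2_grid = [0.1, 0.3, 0.5, 0.7, 0.9]
        h2_est, acc = [], []
        for i, h2 in enumerate(h2_grid):
            arch = GeneticArchitecture(
                n_individuals=400, n_snps=1500, n_causal=150, h2_true=h2,
                seed=30 + i,
            )
            G = simulate_genotypes(arch)
            y, _ = simulate_phenotype(G, arch)
            K = kinship(G)
            h2_est.append(greml_h2(y, K).h2)
            acc.append(rrblup_cv(G, y, folds=5, reps=1, seed=i, K=K).mean_r)
        rho = spearmanr(h2_est, acc).statistic
        assert rho > 0.8
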