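import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hilex import de as hde
from hilex import io as hio
from conftest import toy_matrix


def bh_bruteforce(p):
    """Naive O(n^2) BH step-up, written independently of the implementation."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = toy_matrix([[5, 5], [9, 9], [2, 2]])
        assert np.allclose(hde.size_factors(m), 1.0)

    def test_median_of_ratios_toy(self):
        # per-gene geometric means 14.142, 42.426, 70.711;
        # all column-1 ratios 0.7071 -> pre-rescale factors (0.7071, 1.4142),
        # whose geometric mean is already 1
        m = toy_matrix([[10, 20], [30, 60], [50, 100]])
        sf = hde.size_factors(m)
        assert np.allclose(sf, [np.sqrt(0.5), np.sqrt(2.0)], atol=1e-4)

    def test_column_scaling_homogeneity(self):
        base = toy_matrix([[10, 20], [30, 60], [50, 100]])
        scaled = toy_matrix([[30, 20], [90, 60], [150, 100]])
        f0 = hde.size_factors(base)
        f1 = hde.size_factors(scaled)
        # pre-rescale factor of column 0 triples; ratios of factors expose it
        assert np.isclose((f1.iloc[0] / f1.iloc[1]) / (f0.iloc[0] / f0.iloc[1]), 3.0)

    def test_requires_a_fully_observed_gene(self):
        m = toy_matrix([[0, 5], [5, 0]])
        with pytest.raises(hde.DEError, match="pseudo-reference"):
            hde.size_factors(m)

    def test_reference_sample_anchoring(self):
        m = toy_matrix([[10, 20, 10], [30, 60, 30], [50, 100, 50]])
        sf = hde.size_factors(m, reference_samples=["s0", "s2"])
        assert np.isclose(sf.iloc[1] / sf.iloc[0], 2.0)


class TestDispersion:
    @staticmethod
    def _matrix(rng, mu, alpha, n_genes, n_samples):
        if alpha == 0:
            counts = rng.poisson(mu, size=(n_genes, n_samples))
        else:
            size = 1 / alpha
            counts = rng.negative_binomial(size, size / (size + mu), (n_genes, n_samples))
        return toy_matrix(counts)

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(0)
        m = self._matrix(rng, 200.0, 0.0, 2000, 6)
        sf = pd.Series(1.0, index=m.sample_ids)
        alpha = hde.estimate_dispersion(m, sf, {"A": list(m.sample_ids)})
        assert float(alpha.median()) <= 0.01

    def test_constant_gene_floored(self):
        m = toy_matrix([[100, 100, 100], [80, 120, 100]])
        sf = pd.Series(1.0, index=m.sample_ids)
        alpha = hde.estimate_dispersion(m, sf, {"A": list(m.sample_ids)})
        assert alpha.iloc[0] == pytest.approx(hde.ALPHA_FLOOR)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        m = self._matrix(rng, 1000.0, 0.5, 2000, 20)
        sf = pd.Series(1.0, index=m.sample_ids)
        groups = {"A": list(m.sample_ids[:10]), "B": list(m.sample_ids[10:])}
        alpha = hde.estimate_dispersion(m, sf, groups)
        assert 0.3 <= float(alpha.median()) <= 0.7

    def test_single_replicate_everywhere_rejected(self):
        m = toy_matrix([[1, 2], [3, 4]])
        sf = pd.Series(1.0, index=m.sample_ids)
        with pytest.raises(hde.DEError, match="replicates"):
            hde.estimate_dispersion(m, sf, {"A": ["s0"], "B": ["s1"]})


class TestBH:
    def test_hand_computed_stepup(self):
        assert np.allclose(hde.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert hde.bh_adjust([0.123]) == pytest.approx([0.123])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            hde.bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_bruteforce_and_statsmodels(self, p):
        ours = hde.bh_adjust(p)
        assert np.allclose(ours, bh_bruteforce(p))
        from statsmodels.stats.multitest import multipletests

        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        direct = hde.bh_adjust([p[i] for i in perm])
        permuted = hde.bh_adjust(p)
        assert np.allclose(direct, [permuted[i] for i in perm])


class TestWaldContrast:
    @staticmethod
    def _fixture(rng, mu_a, mu_b, n=3, alpha=0.05, n_genes=400):
        size = 1 / alpha
        a = rng.negative_binomial(size, size / (size + mu_a), (n_genes, n))
        b = rng.negative_binomial(size, size / (size + mu_b), (n_genes, n))
        m = toy_matrix(np.hstack([a, b]))
        sf = pd.Series(1.0, index=m.sample_ids)
        al = pd.Series(alpha, index=m.gene_ids)
        ga, gb = list(m.sample_ids[:n]), list(m.sample_ids[n:])
        return m, sf, al, ga, gb

    def test_identical_groups_null(self):
        m = toy_matrix([[10, 12, 10, 12], [100, 90, 100, 90]])
        sf = pd.Series(1.0, index=m.sample_ids)
        al = pd.Series(0.05, index=m.gene_ids)
        res = hde.nb_wald_contrast(m, sf, al, ["s0", "s1"], ["s2", "s3"])
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["p"] > 0.9).all()

    def test_direction_contract(self):
        m = toy_matrix([[400, 400, 380, 100, 104, 98]])
        sf = pd.Series(1.0, index=m.sample_ids)
        al = pd.Series(0.01, index=m.gene_ids)
        res = hde.nb_wald_contrast(m, sf, al, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert res["log2fc"].iloc[0] > 0

    def test_relabeling_flips_sign_keeps_p(self):
        rng = np.random.default_rng(3)
        m, sf, al, ga, gb = self._fixture(rng, 300, 120)
        ab = hde.nb_wald_contrast(m, sf, al, ga, gb)
        ba = hde.nb_wald_contrast(m, sf, al, gb, ga)
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["p"], ba["p"])

    def test_all_zero_genes_are_null(self):
        m = toy_matrix([[0, 0, 0, 0], [5, 6, 5, 6]])
        sf = pd.Series(1.0, index=m.sample_ids)
        al = pd.Series(0.05, index=m.gene_ids)
        res = hde.nb_wald_contrast(m, sf, al, ["s0", "s1"], ["s2", "s3"])
        assert res.loc["g0", "p"] == 1.0 and res.loc["g0", "log2fc"] == 0.0

    def test_trans_only_pattern_power_at_fourfold_shift(self):
        """Genes where B and H share a 4-fold shift from N: the parental
        contrast fires and the H-vs-B contrast stays quiet for >=90%."""
        rng = np.random.default_rng(8)
        n_genes, n, alpha, d = 1000, 5, 0.05, 2.0
        mu0 = np.exp(rng.uniform(np.log(20), np.log(2000), n_genes))
        mu_b = mu0 * 2.0 ** (rng.choice([-1, 1], n_genes) * d)
        size = 1 / alpha

        def draw(mu):
            return rng.negative_binomial(size, size / (size + mu[:, None]), (n_genes, n))

        counts = np.hstack([draw(mu_b), draw(mu0), draw(mu_b)])
        cols = [f"{g}{i}" for g in "BNH" for i in range(n)]
        m = toy_matrix(counts, samples=cols)
        sf = hde.size_factors(m)
        groups = {g: [f"{g}{i}" for i in range(n)] for g in "BNH"}
        al = hde.estimate_dispersion(m, sf, groups)
        bvn = hde.nb_wald_contrast(m, sf, al, groups["B"], groups["N"])
        hvb = hde.nb_wald_contrast(m, sf, al, groups["H"], groups["B"])
        ok = (bvn["padj"] < 0.05) & (hvb["padj"] >= 0.05)
        assert float(ok.mean()) >= 0.90

    def test_padj_never_below_p(self):
        rng = np.random.default_rng(4)
        m, sf, al, ga, gb = self._fixture(rng, 200, 200)
        res = hde.nb_wald_contrast(m, sf, al, ga, gb)
        assert (res["padj"] >= res["p"] - 1e-12).all()
        assert res["p"].between(0, 1).all() and res["padj"].between(0, 1).all()


class TestBuildTriplet:
    def test_gene_sets_aligned(self, fitted):
        trip = fitted.triplets["HIL1"]
        assert trip.bvn.index.equals(trip.hvn.index)
        assert trip.hvn.index.equals(trip.hvb.index)

    def test_missing_group_rejected(self):
        m = toy_matrix(np.arange(12).reshape(2, 6))
        samples = pd.DataFrame(
            {"group": ["species_B"] * 3 + ["species_N"] * 3, "replicate": [1, 2, 3] * 2},
            index=m.sample_ids,
        )
        with pytest.raises(hde.DEError, match="HIL9"):
            hde.build_triplet(m, samples, "HIL9")

    def test_monotone_in_effect_size(self):
        from hilex.model import HilExpressionModel
        from hilex.simulate import SimConfig, null_config, simulate_experiment

        counts = []
        for d in (1e-12, 1.0, 2.0, 3.0):
            cfg = SimConfig(n_genes=800, effect_size=d, seed=21)
            exp = simulate_experiment(cfg)
            res = HilExpressionModel(
                exp["refB"], exp["refN"], exp["samples"], exp["annotation"], exp["orthologs"]
            ).fit()
            trip = res.triplets["HIL1"]
            shared = trip.gene_ids.difference(sorted(res.introgressed_genes("HIL1")))
            counts.append(int((trip.hvn.loc[shared, "padj"] < 0.05).sum()))
        assert counts == sorted(counts)


class TestAdapters:
    def test_contrast_tsv_round_trip(self, tmp_path, fitted):
        trip = fitted.triplets["HIL1"]
        p = tmp_path / "c.tsv"
        hde.write_contrast(trip.hvn, p)
        back = hde.read_contrast(p)
        pd.testing.assert_frame_equal(
            back, trip.hvn[["log2fc", "se", "p", "padj", "base_mean"]],
            check_exact=False,
        )

    def test_deseq2_shaped_table(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "gene\tbaseMean\tlog2FoldChange\tlfcSE\tpvalue\tpadj\n"
            "g1\t100.0\t1.5\t0.3\t0.001\t0.01\n"
            "g2\t5.0\t0.1\t0.4\t0.8\tNA\n"
        )
        res = hde.read_deseq2_results(p)
        assert res.loc["g1", "log2fc"] == 1.5
        assert res.loc["g2", "padj"] == 1.0  # NA means filtered, not significant

    def test_missing_padj_column_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\tbaseMean\tlog2FoldChange\tlfcSE\tpvalue\ng1\t1\t0\t1\t0.5\n")
        with pytest.raises(hde.DEError, match="padj"):
            hde.read_deseq2_results(p)
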