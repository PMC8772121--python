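import numpy as np
import pytest

from beepop.genotype_io import MISSING, GenomicWindow, PopulationMap, make_windows
from beepop.popgen_stats import (
    FstMatrix,
    fst_matrix_summary,
    genome_fst,
    genotype_pca,
    het_and_inbreeding,
    ld_r2_decay,
    pairwise_fst_matrix,
    wc_fst_window,
    window_pi,
)
from beepop.reference_tables import changbai_fst_table, regional_fst_table
from beepop.synthetic_data import GenoSimSpec, simulate_genotypes
from conftest import matrix_from_dosage
from _oracles import pi_window_oracle, wc_fst_oracle


def two_pop_map(n1, n2):
    names = [f"s{i+1}" for i in range(n1 + n2)]
    return names, PopulationMap(
        {n: ("p1" if i < n1 else "p2") for i, n in enumerate(names)}
    )


class TestWindowPi:
    def test_single_site_hand_value(self, make_matrix):
        # 4 non-missing alleles split 2/2: pi_site = 4/C(4,2) ... = 2*2/6
        g = make_matrix(np.array([[1, 1, MISSING]]), spacing=5)
        w = GenomicWindow("chr1", 0, 10)
        stats = window_pi(g, [w])
        assert stats[0].pi == pytest.approx((2 * 2 / 6) / 10, abs=1e-12)
        assert stats[0].n_sites == 1

    def test_monomorphic_window_is_zero(self, make_matrix):
        g = make_matrix(np.zeros((3, 4), dtype=np.int8))
        stats = window_pi(g, [GenomicWindow("chr1", 0, 1000)])
        assert stats[0].pi == 0.0

    def test_denominator_scales_with_window(self, make_matrix):
        g = make_matrix(np.array([[0, 1, 2]]), spacing=5)
        small = window_pi(g, [GenomicWindow("chr1", 0, 10)])[0].pi
        large = window_pi(g, [GenomicWindow("chr1", 0, 20)])[0].pi
        assert large == pytest.approx(small / 2)

    def test_matches_exhaustive_enumeration(self, make_matrix):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_sites = rng.integers(1, 21)
            n_samples = rng.integers(2, 7)
            d = rng.integers(-1, 3, size=(n_sites, n_samples))
            g = make_matrix(d, spacing=10)
            end = (n_sites + 1) * 10
            got = window_pi(g, [GenomicWindow("chr1", 0, end)])[0].pi
            assert got == pytest.approx(pi_window_oracle(d, end), abs=1e-12)

    def test_invariant_under_sample_reordering(self, make_matrix):
        rng = np.random.default_rng(1)
        d = rng.integers(-1, 3, size=(15, 6))
        g = make_matrix(d)
        w = [GenomicWindow("chr1", 0, 2000)]
        base = window_pi(g, w)[0].pi
        perm = list(rng.permutation(g.samples))
        assert window_pi(g.subset_samples(perm), w)[0].pi == pytest.approx(base)


class TestWcFst:
    def test_fixed_difference_is_one(self, make_matrix):
        d = np.array([[0, 0, 0, 2, 2, 2]] * 4)
        g = make_matrix(d)
        _, pm = two_pop_map(3, 3)
        assert genome_fst(g, pm) == pytest.approx(1.0)

    def test_duplicated_population_is_non_positive(self, make_matrix):
        rng = np.random.default_rng(7)
        col = rng.integers(0, 3, size=(12, 4))
        d = np.hstack([col, col])
        g = make_matrix(d)
        _, pm = two_pop_map(4, 4)
        assert genome_fst(g, pm) <= 0.0

    def test_published_formula_case(self, make_matrix):
        # 2 pops x 5 diploids: p1=0.9, p2=0.1, h1=h2=0.2
        d = np.array([[2, 2, 2, 2, 1, 0, 0, 0, 0, 1]])
        g = make_matrix(d)
        _, pm = two_pop_map(5, 5)
        expected = wc_fst_oracle(d, [[0, 1, 2, 3, 4], [5, 6, 7, 8, 9]])
        assert genome_fst(g, pm) == pytest.approx(expected, abs=1e-12)

    def test_matches_oracle_on_small_instances(self, make_matrix):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n_pops = rng.integers(2, 4)
            sizes = [int(rng.integers(2, 7)) for _ in range(n_pops)]
            n_sites = int(rng.integers(1, 11))
            d = rng.integers(-1, 3, size=(n_sites, sum(sizes)))
            g = make_matrix(d)
            cols, labels, start = [], {}, 0
            for k, sz in enumerate(sizes):
                cols.append(list(range(start, start + sz)))
                for j in range(start, start + sz):
                    labels[g.samples[j]] = f"p{k}"
                start += sz
            got = genome_fst(g, PopulationMap(labels))
            want = wc_fst_oracle(d, cols)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_windowed_ratio_of_sums_and_nan_flag(self, make_matrix):
        d = np.array([[0, 1, 2, 1], [0, 0, 2, 2]])
        g = make_matrix(d, spacing=100)
        _, pm = two_pop_map(2, 2)
        wins = [GenomicWindow("chr1", 0, 300), GenomicWindow("chr1", 500, 600)]
        stats = wc_fst_window(g, pm, wins)
        sa, sb, sc = stats[0].components
        assert stats[0].fst == pytest.approx(sa / (sa + sb + sc))
        assert np.isnan(stats[1].fst)  # empty window flagged NaN

    def test_invariant_under_population_relabeling(self, make_matrix):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(40, 10))
        g = make_matrix(d)
        names, pm = two_pop_map(5, 5)
        renamed = PopulationMap(
            {s: {"p1": "east", "p2": "west"}[l] for s, l in pm.assignments.items()}
        )
        assert genome_fst(g, renamed) == pytest.approx(genome_fst(g, pm))

    def test_label_permutation_destroys_structure(self):
        spec = GenoSimSpec(n_pops=2, n_per_pop=20, n_snps=5000, fst=0.2, seed=9)
        g, pm, _ = simulate_genotypes(spec)
        rng = np.random.default_rng(10)
        labels = list(pm.assignments.values())
        shuffled = list(rng.permutation(labels))
        pm_perm = PopulationMap(dict(zip(pm.assignments.keys(), shuffled)))
        assert abs(genome_fst(g, pm_perm)) < 0.01


class TestPairwiseMatrix:
    def test_three_identical_populations_near_zero(self):
        spec = GenoSimSpec(n_pops=3, n_per_pop=10, n_snps=2000, fst=0.0, seed=2)
        g, pm, _ = simulate_genotypes(spec)
        m = pairwise_fst_matrix(g, pm)
        off = m.values[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.02)

    def test_symmetry_and_fixed_difference(self, make_matrix):
        d = np.array([[0, 0, 2, 2]] * 5)
        g = make_matrix(d)
        _, pm = two_pop_map(2, 2)
        m = pairwise_fst_matrix(g, pm)
        assert m.value("p1", "p2") == pytest.approx(1.0)
        assert np.allclose(m.values, m.values.T, equal_nan=True)

    def test_small_population_excluded_with_warning(self, make_matrix):
        d = np.array([[0, 1, 2, 1, 0]] * 4)
        g = make_matrix(d)
        pm = PopulationMap(
            {"s1": "a", "s2": "a", "s3": "b", "s4": "b", "s5": "tiny"}
        )
        with pytest.warns(UserWarning, match="tiny"):
            m = pairwise_fst_matrix(g, pm)
        assert m.labels == ["a", "b"]


class TestFstMatrixSummary:
    def test_regional_table_mean_matches_survey(self):
        m = regional_fst_table()
        s = fst_matrix_summary(m)
        assert s["n_pairs"] == 10
        assert s["mean"] == pytest.approx(0.1133, abs=5e-5)
        assert (s["min"], s["max"]) == (0.0094, 0.2609)

    def test_focal_row_mean(self):
        s = fst_matrix_summary(regional_fst_table(), focal="Changbai Mountain")
        assert s["n_pairs"] == 4
        assert s["mean"] == pytest.approx(0.2294, abs=5e-5)

    def test_changbai_table_range_and_partner_sets(self):
        m = changbai_fst_table()
        s = fst_matrix_summary(m)
        assert s["n_pairs"] == 15
        assert (s["min"], s["max"]) == (-0.0031, 0.2030)
        jl = ["JL-BS", "JL-JL", "JL-TH", "JL-YB"]
        assert fst_matrix_summary(m, focal="HL", partners=jl)["mean"] == pytest.approx(
            0.1002, abs=5e-5
        )
        assert fst_matrix_summary(m, focal="LN")["mean"] == pytest.approx(
            0.1506, abs=5e-5
        )

    def test_unknown_focal_lists_known_labels(self):
        with pytest.raises(KeyError, match="Changbai Mountain"):
            fst_matrix_summary(regional_fst_table(), focal="Atlantis")


class TestHetAndInbreeding:
    def test_single_site_hand_values(self, make_matrix):
        g = make_matrix(np.array([[0, 1, 2]]))
        pm = PopulationMap({"s1": "a", "s2": "a", "s3": "a"})
        stats = het_and_inbreeding(g, pm)["a"]
        assert stats.he == pytest.approx(0.5)
        assert stats.ho == pytest.approx(1 / 3)

    def test_fully_homozygous_individual_has_f_one(self, make_matrix):
        d = np.array([[0, 1, 1], [2, 1, 0], [0, 1, 1]])
        g = make_matrix(d)
        pm = PopulationMap({"s1": "a", "s2": "a", "s3": "a"})
        table = het_and_inbreeding(g, pm)["a"].per_individual
        row = table[table["sample"] == "s1"].iloc[0]
        assert row.observed_hom == row.n_sites_used
        assert row.f == pytest.approx(1.0)

    def test_hwe_population_mean_f_near_zero(self):
        spec = GenoSimSpec(n_pops=1, n_per_pop=50, n_snps=5000, fst=0.0, seed=6)
        g, pm, _ = simulate_genotypes(spec)
        stats = het_and_inbreeding(g, pm)["pop1"]
        assert abs(stats.f) < 0.02


class TestLdDecay:
    def test_identical_columns_give_r2_one(self, make_matrix):
        d = np.array([[0, 1, 2, 1, 0], [0, 1, 2, 1, 0]])
        g = matrix_from_dosage(d, spacing=500)
        curve = ld_r2_decay(g, max_dist=1000, bin_width=1000)
        assert curve.mean_r2[0] == pytest.approx(1.0)
        assert curve.n_pairs[0] == 1

    def test_independent_sites_mean_r2_near_one_over_n(self):
        rng = np.random.default_rng(8)
        n, n_sites = 100, 60
        freqs = rng.uniform(0.2, 0.8, size=n_sites)
        d = rng.binomial(2, freqs[:, None], size=(n_sites, n)).astype(np.int8)
        g = matrix_from_dosage(d, spacing=100)
        curve = ld_r2_decay(g, max_dist=10_000, bin_width=10_000)
        assert curve.mean_r2[0] == pytest.approx(1 / n, abs=0.01)

    def test_decay_distance_nan_when_never_crossed(self, make_matrix):
        d = np.array([[0, 1, 2, 1], [0, 1, 2, 1]])
        g = matrix_from_dosage(d, spacing=500)
        curve = ld_r2_decay(g, max_dist=2000, bin_width=1000, threshold=0.1)
        assert np.isnan(curve.decay_distance)

    def test_decay_distance_is_first_crossing_midpoint(self):
        rng = np.random.default_rng(12)
        # tight pair in perfect LD, then a distant independent site:
        # bin [0,500) holds only the r2=1 pair, bin [500,1000) only a
        # near-zero pair, so decay is declared at the second midpoint
        base = rng.binomial(2, 0.5, size=50).astype(np.int8)
        indep = rng.binomial(2, 0.5, size=50).astype(np.int8)
        g = matrix_from_dosage(np.array([base, base, indep]), spacing=1)
        g.sites = [
            s.__class__("chr1", p, "A", "T") for s, p in zip(g.sites, (100, 200, 1100))
        ]
        curve = ld_r2_decay(g, max_dist=1500, bin_width=500, threshold=0.5)
        assert curve.mean_r2[0] == pytest.approx(1.0)
        assert curve.decay_distance == pytest.approx(750.0)


class TestGenotypePca:
    def test_structured_populations_separate_on_pc1(self):
        spec = GenoSimSpec(n_pops=2, n_per_pop=20, n_snps=2000, fst=0.3, seed=4)
        g, pm, _ = simulate_genotypes(spec)
        res = genotype_pca(g, n_components=2)
        pc1 = res.scores["PC1"].to_numpy()
        a, b = pc1[:20], pc1[20:]
        assert a.max() < b.min() or b.max() < a.min()  # zero overlap

    def test_scores_centered_and_fractions_ordered(self):
        spec = GenoSimSpec(n_pops=2, n_per_pop=10, n_snps=500, fst=0.1, seed=5)
        g, _, _ = simulate_genotypes(spec)
        res = genotype_pca(g, n_components=5)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-8)
        evr = res.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1.0 + 1e-12

    def test_component_clipping_warns(self, make_matrix):
        rng = np.random.default_rng(11)
        g = make_matrix(rng.integers(0, 3, size=(50, 4)))
        with pytest.warns(UserWarning, match="clipped"):
            res = genotype_pca(g, n_components=10)
        assert res.scores.shape[1] == 3
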