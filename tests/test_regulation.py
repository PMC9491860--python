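"""Spearman oracle, regulation profiles, density slope, groups, pathways."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dosagecomp.datamodel import DataModelError, GeneSetCollection
from dosagecomp.regulation import (
    define_regulation_groups,
    density_slope,
    enrichment_table,
    filter_low_dna_variance,
    gene_regulation_profiles,
    group_contrast,
    overrepresentation_test,
    pathway_regulation,
    regulation_pipeline,
    spearman_rho,
)
from dosagecomp.simulate import SimulationConfig, pathway_gene_sets, simulate_dataset


def hand_spearman(x, y):
    """Independent oracle: explicit average-rank assignment + Pearson."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3], [1, 2, 3], min_pairs=3) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1], min_pairs=3) == pytest.approx(-1.0)

    def test_tied_example(self):
        rho = spearman_rho([1, 2, 2, 3], [1, 2, 3, 4], min_pairs=4)
        assert rho == pytest.approx(0.9486832980505138, abs=1e-10)

    def test_matches_hand_oracle_on_random_tied_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = rng.integers(3, 13)
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert spearman_rho(x, y, min_pairs=3) == pytest.approx(
                hand_spearman(x, y), abs=1e-12
            )

    def test_agrees_with_scipy(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        assert spearman_rho(x, y) == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_missing_pairs_dropped(self):
        x = [1, 2, 3, np.nan, 5, 6, 7, 8, 9, 10, 11]
        y = [1, 2, 3, 4, np.nan, 6, 7, 8, 9, 10, 11]
        assert spearman_rho(x, y, min_pairs=5) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DataModelError, match="constant"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4], min_pairs=3)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(-1000, 1000), min_size=10, max_size=20, unique=True))
    def test_monotone_transform_invariance(self, xs):
        # integer inputs keep exp(x/50) strictly monotone in float arithmetic
        xs = np.asarray(xs, dtype=float)
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2**31)
        y = rng.normal(size=len(xs))
        if len(set(y)) < 2:
            return
        a = spearman_rho(xs, y)
        b = spearman_rho(np.exp(xs / 50), y)
        assert a == pytest.approx(b, abs=1e-12)


class TestDnaVarianceFilter:
    def _dataset_with_dna(self, row):
        from dosagecomp.datamodel import OmicsMatrix, align_dataset

        n = len(row)
        samples = [f"S{i}" for i in range(n)]
        dna = OmicsMatrix("dna_log2_ratio", "log2",
                          pd.DataFrame([row], index=["A"], columns=samples, dtype=float))
        rna = OmicsMatrix("rna_abundance", "linear",
                          pd.DataFrame(8.0, index=["A"], columns=samples))
        prot = OmicsMatrix("protein_abundance", "log2",
                           pd.DataFrame(0.1, index=["A"], columns=samples))
        return align_dataset(dna, rna, prot)

    def test_eight_of_ten_inert_removed(self):
        ds = self._dataset_with_dna([0.0] * 8 + [0.5, 0.5])
        assert filter_low_dna_variance(ds)["all"] == ["A"]

    def test_exactly_seventy_percent_kept(self):
        ds = self._dataset_with_dna([0.0] * 7 + [0.5, 0.5, 0.5])
        assert filter_low_dna_variance(ds)["all"] == []

    def test_variable_gene_kept(self):
        ds = self._dataset_with_dna([0.05, -0.05, 0.1, -0.1, 0.2, 0.3, -0.3, 0.4, 0.5, -0.5])
        assert filter_low_dna_variance(ds)["all"] == []

    def test_bad_frac_rejected(self, small_cohort):
        _, ds, _, _ = small_cohort
        with pytest.raises(DataModelError):
            filter_low_dna_variance(ds, frac=0.0)


class TestProfiles:
    def test_uncoupled_layers_decorrelate_protein(self):
        """c_rna=0, c_prot=1, tiny RNA noise: DNA-RNA rho high, RNA-protein ~ 0."""
        cfg = SimulationConfig(
            n_genes=60, n_samples_per_type=80, n_tumor_types=1, n_pathways=5,
            c_rna_fixed=0.0, c_prot_fixed=1.0, dna_noise_sd=0.01,
            sigma_rna_range=(0.01, 0.01), sigma_prot_range=(0.3, 0.3), seed=31,
        )
        ds, _, _ = simulate_dataset(cfg)
        prof = gene_regulation_profiles(ds)
        # ranks inside the tight neutral cluster scramble a little, so the
        # DNA-RNA rho sits below 1 even at near-zero noise
        assert prof["dr_rho"].median() > 0.8
        assert abs(prof["rp_rho"].median()) < 0.15

    def test_pan_cancer_is_mean_over_types(self, small_cohort):
        _, ds, _, _ = small_cohort
        prof = gene_regulation_profiles(ds)
        per_type = prof[[c for c in prof.columns if c.startswith("dr_rho__")]]
        np.testing.assert_allclose(prof["dr_rho"], per_type.mean(axis=1), atol=1e-12)

    def test_rho_in_range(self, small_cohort):
        _, ds, _, _ = small_cohort
        prof = gene_regulation_profiles(ds)
        assert prof["dr_rho"].between(-1, 1).all()
        assert prof["rp_rho"].between(-1, 1).all()


class TestDensitySlope:
    def test_exact_line_recovered(self, rng):
        dr = rng.uniform(-1, 1, 10_000)
        rep = density_slope(dr, -0.33 * dr + 0.5)
        assert rep.slope == pytest.approx(-0.33, abs=0.01)
        assert rep.rho == pytest.approx(-1.0)

    @pytest.mark.parametrize("slope", [-1.0, 0.0, 0.5])
    def test_slope_grid(self, slope, rng):
        dr = rng.uniform(-1, 1, 5000)
        rep = density_slope(dr, slope * dr + 0.1)
        # one grid cell of RP resolution per unit DR
        tol = max(0.02, 2.0 / 100)
        assert rep.slope == pytest.approx(slope, abs=tol)

    def test_independent_cloud_is_flat(self):
        slopes = []
        for seed in range(20):
            xy = np.random.default_rng(seed).multivariate_normal([0, 0], np.eye(2), 2000)
            slopes.append(density_slope(xy[:, 0], xy[:, 1]).slope)
        assert abs(np.mean(slopes)) < 0.05

    def test_degenerate_input_rejected(self):
        with pytest.raises(DataModelError, match="degenerate"):
            density_slope(np.zeros(500), np.zeros(500))

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(DataModelError):
            density_slope(rng.normal(size=50), rng.normal(size=50))


class TestRegulationGroups:
    def test_perfect_anticorrelation(self):
        n = 100
        rank = np.arange(1, n + 1)
        prof = pd.DataFrame(
            {"dr_rho": rank / n, "rp_rho": 1 - rank / n},
            index=[f"G{i:03d}" for i in range(n)],
        )
        groups = define_regulation_groups(prof, q=0.35)
        top = set(prof.sort_values("dr_rho").index[-35:])
        assert set(groups.group1) == top
        assert set(groups.group1).isdisjoint(groups.group2)

    def test_independent_uniform_group_size(self):
        rng = np.random.default_rng(5)
        n = 10_000
        prof = pd.DataFrame(
            {"dr_rho": rng.uniform(size=n), "rp_rho": rng.uniform(size=n)},
            index=[f"G{i}" for i in range(n)],
        )
        groups = define_regulation_groups(prof, q=0.35)
        expected = 0.35**2 * n
        assert abs(len(groups.group1) - expected) < 4 * np.sqrt(expected)

    def test_disjoint_for_any_q(self, small_cohort):
        _, ds, _, _ = small_cohort
        prof = regulation_pipeline(ds)
        for q in (0.1, 0.25, 0.49):
            g = define_regulation_groups(prof, q=q)
            assert set(g.group1).isdisjoint(g.group2)

    def test_q_half_rejected(self, small_cohort):
        _, ds, _, _ = small_cohort
        prof = regulation_pipeline(ds)
        with pytest.raises(DataModelError):
            define_regulation_groups(prof, q=0.5)


class TestPathwayRegulation:
    def test_median_aggregation(self):
        prof = pd.DataFrame(
            {"dr_rho": [0.1, 0.2, 0.3, 0.8, 0.9, 0.7, 0.6, 0.5, 0.55, 0.65],
             "rp_rho": [0.5, 0.6, 0.7, 0.1, 0.2, 0.3, 0.4, 0.45, 0.35, 0.25]},
            index=[f"G{i}" for i in range(10)],
        )
        sets = GeneSetCollection({"pw1": ["G0", "G1", "G2", "G3", "G4"],
                                  "pw2": ["G5", "G6", "G7", "G8", "G9"]})
        res = pathway_regulation(prof, sets, min_pathway_genes=5)
        assert res.table.loc["pw1", "dr_rho"] == pytest.approx(0.3)

    def test_outlier_robustness(self):
        rng = np.random.default_rng(8)
        vals = np.sort(rng.normal(size=11))
        prof = pd.DataFrame({"dr_rho": vals, "rp_rho": vals},
                            index=[f"G{i}" for i in range(11)])
        sets = GeneSetCollection({"pw": list(prof.index), "pw2": list(prof.index)})
        base = pathway_regulation(prof, sets).table.loc["pw", "dr_rho"]
        prof.loc["G0", "dr_rho"] = 1e6  # outlier replaces the minimum
        moved = pathway_regulation(prof, sets).table.loc["pw", "dr_rho"]
        assert abs(moved - base) <= vals[6] - vals[5] + 1e-12

    def test_coupling_sign_recovery(self):
        for coupling, sign in ((-1.0, -1), (1.0, 1)):
            cfg = SimulationConfig(n_genes=600, n_samples_per_type=80,
                                   n_tumor_types=1, n_pathways=30,
                                   pathway_coupling=coupling, seed=17)
            ds, truth, _ = simulate_dataset(cfg)
            prof = regulation_pipeline(ds)
            res = pathway_regulation(prof, pathway_gene_sets(truth))
            assert sign * res.spearman > 0.5

    def test_no_pathway_passes_rejected(self, small_cohort):
        _, ds, _, _ = small_cohort
        prof = regulation_pipeline(ds)
        sets = GeneSetCollection({"tiny": ["G00001"]})
        with pytest.raises(DataModelError):
            pathway_regulation(prof, sets, min_pathway_genes=5)


class TestGroupContrast:
    def test_identical_classes_give_zero(self, small_cohort):
        _, ds, _, _ = small_cohort
        prof = regulation_pipeline(ds)
        half = pd.Series(
            [i % 2 == 0 for i in range(len(prof))], index=prof.index
        )
        mirrored = prof.copy()
        mirrored.loc[:, "rp_rho"] = 0.5
        res = group_contrast(mirrored, half, "rp_rho", n_boot=500, seed=0)
        assert res.statistic == 0

    def test_complex_contrast_direction(self, small_cohort):
        _, ds, _, _ = small_cohort
        prof = regulation_pipeline(ds)
        is_complex = prof["is_complex"].astype(bool)
        rp = group_contrast(prof, is_complex, "rp_rho", n_boot=2000, seed=1)
        dr = group_contrast(prof, is_complex, "dr_rho", n_boot=2000, seed=1)
        assert rp.statistic < 0  # complex genes: stronger protein-level regulation
        assert dr.statistic > 0  # complex genes: weaker RNA-level regulation

    def test_small_class_rejected(self, small_cohort):
        _, ds, _, _ = small_cohort
        prof = regulation_pipeline(ds)
        tiny = pd.Series(False, index=prof.index)
        tiny.iloc[:3] = True
        with pytest.raises(DataModelError):
            group_contrast(prof, tiny, "rp_rho", n_boot=500, seed=0)


class TestOverrepresentation:
    def test_exact_enumeration_oracle(self):
        universe = [f"G{i}" for i in range(10)]
        reference = universe[:4]
        query = universe[:4] + [universe[5]]
        p, fold = overrepresentation_test(query, reference, universe)
        assert p == pytest.approx(6 / 252)  # C(4,4) C(6,1) / C(10,5)
        assert fold == pytest.approx((4 / 5) / (4 / 10))

    def test_no_overlap_has_p_near_one(self):
        universe = [f"G{i}" for i in range(100)]
        p, _ = overrepresentation_test(universe[:5], universe[50:55], universe)
        assert p > 0.7

    def test_query_equals_universe_fold_one(self):
        universe = [f"G{i}" for i in range(20)]
        p, fold = overrepresentation_test(universe, universe[:7], universe)
        assert fold == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_enrichment_table_bh(self):
        universe = [f"G{i}" for i in range(50)]
        sets = GeneSetCollection({"a": universe[:10], "b": universe[40:]})
        tab = enrichment_table(universe[:10], sets, universe)
        assert tab.loc["a", "p_value"] < tab.loc["b", "p_value"]
        assert (tab["fdr"] >= tab["p_value"] - 1e-15).all()
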