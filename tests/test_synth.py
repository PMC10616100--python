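"""Synthetic-data generator: LD structure, kinship, planted truth, phenotypes
and summary statistics, checked against independent small-scale oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlshare.config import (
    CATEGORY_TISSUES,
    MODULE_CATEGORIES,
    TISSUES,
    ConfigurationError,
    SimulationConfig,
    flip_prob_for_r2,
)
from eqtlshare.synth import (
    CapacityError,
    DegenerateInputError,
    GenotypePanel,
    KinshipMatrix,
    ReferentialIntegrityError,
    compute_kinship,
    plant_sharing_structure,
    simulate_genotype_panel,
    simulate_gwas_stats,
    simulate_phenotypes,
    simulate_summary_stats,
)


def _r2_matrix(dosages: np.ndarray) -> np.ndarray:
    return np.corrcoef(dosages, rowvar=False) ** 2


class TestGenotypePanel:
    def test_dosages_are_0_half_1(self, small_panel):
        assert set(np.unique(small_panel.dosages)) <= {0.0, 0.5, 1.0}

    def test_positions_strictly_increasing_within_chromosome(self, small_panel):
        for _, sub in small_panel.variants.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing
            assert sub["pos"].nunique() == len(sub)

    def test_identifiers_unique(self, small_panel):
        assert small_panel.variants["id"].is_unique

    def test_zero_flip_prob_gives_perfect_within_block_ld(self):
        cfg = SimulationConfig(
            n_samples=100, n_blocks=2, variants_per_block=4,
            within_block_flip_prob=0.0, category_counts={"null": 1}, seed=3,
        )
        panel = simulate_genotype_panel(cfg)
        block0 = panel.dosages[:, :4]
        r2 = _r2_matrix(block0)
        assert np.allclose(r2, 1.0)

    def test_same_seed_reproduces_identical_panel(self, small_config):
        a = simulate_genotype_panel(small_config)
        b = simulate_genotype_panel(small_config)
        assert np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_panel_index_gives_independent_draw(self, small_config):
        a = simulate_genotype_panel(small_config, panel_index=0)
        b = simulate_genotype_panel(small_config, panel_index=1)
        assert not np.array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_maf_matches_binomial_sampling_oracle(self):
        # at maf_range (0.3, 0.3) every variant's empirical MAF is a binomial
        # mean with sd sqrt(0.3*0.7/(2n)) ~ 0.015 at n=500; full re-draw
        # (flip 0.5) must leave the marginal MAF untouched
        cfg = SimulationConfig(
            n_samples=500, n_blocks=4, variants_per_block=5,
            maf_range=(0.3, 0.3), within_block_flip_prob=0.5,
            category_counts={"null": 1}, seed=5,
        )
        panel = simulate_genotype_panel(cfg)
        f = panel.dosages.mean(axis=0)
        maf = np.minimum(f, 1 - f)
        assert abs(maf.mean() - 0.3) < 0.05

    def test_within_block_r2_tracks_flip_probability(self):
        target = 0.9
        cfg = SimulationConfig(
            n_samples=2000, n_blocks=3, variants_per_block=6,
            maf_range=(0.3, 0.5), within_block_flip_prob=flip_prob_for_r2(target),
            category_counts={"null": 1}, seed=9,
        )
        panel = simulate_genotype_panel(cfg)
        r2s = []
        for b in range(3):
            block = panel.dosages[:, b * 6 : (b + 1) * 6]
            r2 = _r2_matrix(block)
            r2s.append(r2[np.triu_indices(6, 1)].mean())
        assert abs(np.mean(r2s) - target) < 0.05

    def test_across_block_independence(self, small_panel):
        a = small_panel.dosages[:, 0]
        b = small_panel.dosages[:, 5]  # first variant of the next block
        assert abs(np.corrcoef(a, b)[0, 1]) < 0.2

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="maf_range"):
            SimulationConfig(maf_range=(0.0, 0.3))
        with pytest.raises(ConfigurationError, match="flip_prob"):
            SimulationConfig(within_block_flip_prob=0.7)
        with pytest.raises(ConfigurationError, match="category_counts"):
            SimulationConfig(category_counts={"nonsense": 1})


class TestKinship:
    def test_symmetric_with_unit_diagonal(self):
        cfg = SimulationConfig(
            n_samples=150, n_blocks=40, variants_per_block=10,
            maf_range=(0.2, 0.5), within_block_flip_prob=0.5,
            category_counts={"null": 2}, seed=8,
        )
        k = compute_kinship(simulate_genotype_panel(cfg)).values
        assert np.allclose(k, k.T)
        assert np.all((k.diagonal() > 0.8) & (k.diagonal() < 1.5))

    def test_unrelated_samples_have_near_zero_offdiagonal_mean(self, small_kinship):
        k = small_kinship.values
        off = k[np.triu_indices_from(k, 1)]
        assert abs(off.mean()) < 0.05

    def test_duplicated_sample_rows_match_diagonal(self, small_panel):
        dosages = np.vstack([small_panel.dosages, small_panel.dosages[:1]])
        panel = GenotypePanel(
            small_panel.sample_ids + ["dup"],
            small_panel.variants,
            dosages,
            small_panel.genes,
        )
        k = compute_kinship(panel).values
        assert k[0, -1] == pytest.approx(k[0, 0])
        assert k[0, -1] == pytest.approx(k[-1, -1])

    def test_hand_computed_standardized_cross_product(self):
        # 4 samples x 3 variants, worked by hand: X_ij = (d_ij - f_j) / sd_j,
        # sd_j = sqrt(f_j (1-f_j) / 2), K = X X^T / 3
        d = np.array(
            [[0.0, 0.5, 1.0], [0.5, 0.5, 0.0], [1.0, 0.0, 0.5], [0.0, 1.0, 0.5]]
        )
        f = d.mean(axis=0)
        x = (d - f) / np.sqrt(f * (1 - f) / 2)
        expected = x @ x.T / 3
        panel = GenotypePanel(
            [f"s{i}" for i in range(4)],
            pd.DataFrame(
                {"id": ["a", "b", "c"], "chrom": "1", "pos": [1, 2, 3],
                 "ref": "A", "alt": "G", "gene": "g", "block": 0}
            ),
            d,
            pd.DataFrame({"gene": ["g"], "chrom": ["1"], "body_start": [1], "body_end": [3]}),
        )
        np.testing.assert_allclose(compute_kinship(panel).values, expected, atol=1e-12)

    def test_monomorphic_panel_is_degenerate(self, small_panel):
        panel = GenotypePanel(
            small_panel.sample_ids,
            small_panel.variants,
            np.zeros_like(small_panel.dosages),
            small_panel.genes,
        )
        with pytest.raises(DegenerateInputError):
            compute_kinship(panel)

    def test_sibling_pairs_raise_relatedness(self):
        cfg = SimulationConfig(
            n_samples=100, n_blocks=10, variants_per_block=10,
            n_sibling_pairs=5, category_counts={"null": 1}, seed=2,
        )
        k = compute_kinship(simulate_genotype_panel(cfg)).values
        sib = np.mean([k[2 * i, 2 * i + 1] for i in range(5)])
        other = k[np.triu_indices_from(k, 1)].mean()
        assert sib > other + 0.1


class TestPlantedTruth:
    def _category_predicate(self, rows: pd.DataFrame, category: str) -> bool:
        """Independent predicate oracle for a planted gene's rows."""
        active = rows[rows["causal_variant"].notna()]
        tissues = frozenset(active["tissue"])
        if category == "null":
            return len(active) == 0
        if category == "singleton-unique":
            return len(tissues) == 1 and active["causal_variant"].nunique() == 1
        if tissues != CATEGORY_TISSUES[category]:
            return False
        return active["causal_variant"].nunique() == 1  # same causal variant

    def test_fetal_adult_shares_one_variant_across_three_tissues(self, small_panel):
        cfg = SimulationConfig(category_counts={"fetal-adult": 1}, seed=4)
        panel = simulate_genotype_panel(cfg)
        truth = plant_sharing_structure(cfg, panel)
        assert len(truth) == 3
        assert truth["causal_variant"].nunique() == 1
        assert truth["causal_variant"].notna().all()

    def test_fetal_unique_plants_one_tissue_only(self):
        cfg = SimulationConfig(category_counts={"iPSC-PPC-unique": 1}, seed=4)
        panel = simulate_genotype_panel(cfg)
        truth = plant_sharing_structure(cfg, panel)
        assert len(truth) == 3
        active = truth[truth["causal_variant"].notna()]
        assert list(active["tissue"]) == ["iPSC-PPC"]

    def test_mixed_categories_satisfy_predicate_oracle(self):
        counts = {c: 3 for c in MODULE_CATEGORIES}
        counts["singleton-unique"] = 3
        counts["null"] = 3
        cfg = SimulationConfig(category_counts=counts, seed=12)
        panel = simulate_genotype_panel(cfg)
        truth = plant_sharing_structure(cfg, panel)
        for gene, rows in truth.groupby("gene"):
            category = rows["category"].iloc[0]
            assert self._category_predicate(rows, category), (gene, category)

    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(category_counts={"fetal-islet": 2}, seed=6)
        panel = simulate_genotype_panel(cfg)
        a = plant_sharing_structure(cfg, panel)
        b = plant_sharing_structure(cfg, panel)
        pd.testing.assert_frame_equal(a, b)

    def test_capacity_error_when_genes_exceed_panel(self):
        cfg = SimulationConfig(category_counts={"null": 1}, seed=6)
        panel = simulate_genotype_panel(cfg)
        big = SimulationConfig(category_counts={"null": 5}, seed=6)
        with pytest.raises(CapacityError):
            plant_sharing_structure(big, panel)


class TestPhenotypes:
    def test_null_model_variance_matches_noise(self, small_panel):
        cfg = SimulationConfig(
            n_samples=200, n_blocks=6, variants_per_block=5, noise_sd=1.0,
            polygenic_sd=0.0, category_counts={"null": 1}, seed=11,
        )
        panel = simulate_genotype_panel(cfg)
        kin = KinshipMatrix(np.eye(panel.n_samples), list(panel.sample_ids))
        truth = plant_sharing_structure(cfg, panel)
        y = simulate_phenotypes(panel, truth, kin, cfg, TISSUES[0])
        assert y.to_numpy().var() == pytest.approx(1.0, rel=0.2)

    def test_noiseless_limit_is_rank_correlated_with_dosage(self):
        cfg = SimulationConfig(
            n_samples=100, n_blocks=4, variants_per_block=5, noise_sd=1e-9,
            polygenic_sd=0.0, effect_size=1.0,
            category_counts={"iPSC-PPC-unique": 1}, seed=13,
        )
        panel = simulate_genotype_panel(cfg)
        kin = KinshipMatrix(np.eye(panel.n_samples), list(panel.sample_ids))
        truth = plant_sharing_structure(cfg, panel)
        y = simulate_phenotypes(panel, truth, kin, cfg, "iPSC-PPC")
        causal = truth["causal_variant"].dropna().iloc[0]
        effect = truth.loc[truth["causal_variant"].notna(), "effect"].iloc[0]
        d = panel.dosage_of(causal)
        rho = stats.spearmanr(y.iloc[:, 0], d).statistic
        assert rho * np.sign(effect) > 0.9
        # dosage groups are perfectly ordered in the noiseless limit
        signed = y.iloc[:, 0].to_numpy() * np.sign(effect)
        assert signed[d == 1.0].min() > signed[d == 0.5].max() > signed[d == 0.0].max()

    def test_ols_slope_lands_in_its_confidence_interval(self):
        # sampling-distribution oracle: the OLS slope on the standardized
        # causal dosage should cover the planted effect in >= 90% of draws
        hits = 0
        reps = 100
        for rep in range(reps):
            cfg = SimulationConfig(
                n_samples=150, n_blocks=2, variants_per_block=3, effect_size=0.8,
                polygenic_sd=0.0, category_counts={"iPSC-PPC-unique": 1}, seed=100 + rep,
            )
            panel = simulate_genotype_panel(cfg)
            kin = KinshipMatrix(np.eye(panel.n_samples), list(panel.sample_ids))
            truth = plant_sharing_structure(cfg, panel)
            y = simulate_phenotypes(panel, truth, kin, cfg, "iPSC-PPC").iloc[:, 0]
            d = panel.dosage_of(truth["causal_variant"].dropna().iloc[0])
            g = (d - d.mean()) / d.std()
            res = stats.linregress(g, y)
            effect = truth.loc[truth["causal_variant"].notna(), "effect"].iloc[0]
            half = stats.t.ppf(0.975, len(y) - 2) * res.stderr
            hits += abs(res.slope - effect) <= half
        assert hits >= 90

    def test_missing_causal_variant_is_referential_error(self, small_panel, small_kinship, small_config):
        truth = pd.DataFrame(
            [{"gene": small_panel.genes["gene"].iloc[0], "tissue": TISSUES[0],
              "causal_variant": "nope", "effect": 1.0, "category": "fetal-adult",
              "planted_overlap": ""}]
        )
        with pytest.raises(ReferentialIntegrityError):
            simulate_phenotypes(small_panel, truth, small_kinship, small_config, TISSUES[0])


class TestSummaryStats:
    def test_null_gene_pvalues_are_uniform(self):
        cfg = SimulationConfig(
            n_samples=400, n_blocks=1000, variants_per_block=1,
            within_block_flip_prob=0.0, category_counts={"null": 1}, seed=21,
        )
        panel = simulate_genotype_panel(cfg)
        truth = plant_sharing_structure(cfg, panel)
        tables = simulate_summary_stats(panel, truth, n=500, seed=21, tissue=TISSUES[0])
        p = tables[panel.genes["gene"].iloc[0]]["p"]
        assert len(p) == 1000
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_top_association_lands_in_ld_with_causal(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_samples=400, n_blocks=8, variants_per_block=10,
                within_block_flip_prob=flip_prob_for_r2(0.9), effect_size=0.12,
                category_counts={"iPSC-PPC-unique": 1}, seed=300 + seed,
            )
            panel = simulate_genotype_panel(cfg)
            truth = plant_sharing_structure(cfg, panel)
            gene = panel.genes["gene"].iloc[0]
            t = simulate_summary_stats(panel, truth, n=10000, seed=seed)[gene]
            top = t.loc[t["p"].idxmin(), "variant"]
            causal = truth["causal_variant"].dropna().iloc[0]
            r = np.corrcoef(panel.dosage_of(top), panel.dosage_of(causal))[0, 1]
            hits += r * r >= 0.9
        assert hits >= 19

    def test_shared_causal_variant_colocalizes_downstream(self):
        from eqtlshare.coloc import coloc_pair

        cfg = SimulationConfig(
            n_samples=400, n_blocks=24, variants_per_block=25,
            within_block_flip_prob=flip_prob_for_r2(0.9), effect_size=0.8,
            category_counts={"fetal-islet": 1}, seed=31,
        )
        panel = simulate_genotype_panel(cfg)
        truth = plant_sharing_structure(cfg, panel)
        gene = panel.genes["gene"].iloc[0]
        t1 = simulate_summary_stats(panel, truth, n=10000, seed=31, tissue="iPSC-PPC")[gene]
        t2 = simulate_summary_stats(panel, truth, n=10000, seed=32, tissue="adult-islet")[gene]
        res = coloc_pair(t1, t2)
        assert res.pp_h4 >= 0.9

    def test_small_n_rejected(self, small_panel, small_truth):
        with pytest.raises(ConfigurationError):
            simulate_summary_stats(small_panel, small_truth, n=1, seed=1)

    def test_gwas_trait_generator_hits_genomewide_significance(self, small_panel, small_truth):
        gene = small_panel.genes["gene"].iloc[0]
        causal = small_truth["causal_variant"].dropna().iloc[0]
        t = simulate_gwas_stats(small_panel, gene, causal, effect=0.05, n=50_000, seed=8)
        assert t["p"].min() <= 5e-8
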