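"""Synthetic-study generator: determinism, LD structure, planted signals."""

import numpy as np
import pytest

import isletqtl as iq
from isletqtl.simulate import LdBlock, GeneSpec, PlantedEqtl, SimConfig, block_variant_ids


def _genotype_config(n_samples=200, n_variants=20, target_r2=0.8, maf=0.3, seed=0):
    return SimConfig(
        n_samples=n_samples,
        ld_blocks=[LdBlock(n_variants=n_variants, target_r2=target_r2, maf=maf)],
        genes=[],
        planted_eqtls=[],
        n_hidden_factors=0,
        seed=seed,
    )


class TestGenotypes:
    def test_same_seed_identical(self):
        cfg = _genotype_config(seed=5)
        a = iq.simulate_genotypes(cfg)
        b = iq.simulate_genotypes(_genotype_config(seed=5))
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.variants.equals(b.variants)

    def test_different_seed_differs(self):
        a = iq.simulate_genotypes(_genotype_config(seed=5))
        b = iq.simulate_genotypes(_genotype_config(seed=6))
        assert not np.array_equal(a.dosages, b.dosages)

    def test_perfect_ld_block_gives_r2_one(self):
        gm = iq.simulate_genotypes(_genotype_config(target_r2=1.0, n_variants=5))
        for j in range(1, 5):
            assert iq.compute_ld_r2(gm.dosages[:, 0], gm.dosages[:, j]) == pytest.approx(1.0)

    def test_dosages_are_hard_calls(self):
        gm = iq.simulate_genotypes(_genotype_config())
        assert set(np.unique(gm.dosages)) <= {0.0, 1.0, 2.0}

    def test_allele_frequency_converges(self):
        """At n = 10,000 the realized alt frequency sits within +/-0.02."""
        gm = iq.simulate_genotypes(_genotype_config(n_samples=10_000, maf=0.3, seed=2))
        freqs = gm.dosages.mean(axis=0) / 2.0
        assert np.all(np.abs(freqs - 0.3) < 0.02)

    def test_pairwise_r2_concentrates_on_target(self):
        gm = iq.simulate_genotypes(
            _genotype_config(n_samples=10_000, n_variants=12, target_r2=0.8, seed=3)
        )
        r = np.corrcoef(gm.dosages.T)
        off = (r**2)[np.triu_indices(12, k=1)]
        assert np.mean(off) == pytest.approx(0.8, abs=0.03)

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError, match="MAF"):
            _genotype_config(maf=0.0)
        with pytest.raises(ValueError, match="MAF"):
            _genotype_config(maf=0.6)


class TestExpression:
    def _study(self, beta, seed=0, n=200, k=0, flipped=()):
        block = LdBlock(n_variants=11, target_r2=0.9, maf=0.3, start=4_990_000, spacing=2_000)
        # decoy genes keep the per-sample totals (hence depth scaling)
        # unaffected by the planted gene's shared shift
        genes = [GeneSpec(gene_id="g1", n_exons=4, tss=5_000_000)] + [
            GeneSpec(gene_id=f"null{j}", n_exons=4, tss=5_000_000 + (j + 1) * 3_000_000)
            for j in range(29)
        ]
        vid = block_variant_ids(block)[5]
        cfg = SimConfig(
            n_samples=n,
            ld_blocks=[block],
            genes=genes,
            planted_eqtls=[PlantedEqtl("g1", vid, beta, flipped_exons=flipped)]
            if beta is not None
            else [],
            n_hidden_factors=k,
            seed=seed,
        )
        gm = iq.simulate_genotypes(cfg)
        counts, truth = iq.simulate_expression(gm, cfg)
        return cfg, gm, counts, truth, vid

    def test_null_genes_uncorrelated_with_genotype(self):
        _, gm, counts, _, vid = self._study(beta=None, seed=1)
        expr = iq.normalize_counts(counts)
        dose = gm.dosage(vid)
        rs = [np.corrcoef(row, dose)[0, 1] for row in expr.values]
        assert abs(np.mean(rs)) < 0.15

    def test_planted_beta_recovered_after_normalization(self):
        """beta = 1 at MAF 0.3, n = 200, no hidden factors: the OLS estimate on
        the rank-normal scale lands within +/-0.25 of the planted value (the
        marginal standardization shrinks it toward beta/sd(latent) ~ 0.84)."""
        betas = []
        for seed in range(6):
            _, gm, counts, _, vid = self._study(beta=1.0, seed=seed)
            expr = iq.normalize_counts(counts)
            g1 = np.flatnonzero((expr.exons["gene_id"] == "g1").to_numpy())
            est = [
                iq.fit_additive_model(expr.values[i], gm.dosage(vid)).beta for i in g1
            ]
            betas.append(np.mean(est))
        assert np.mean(betas) == pytest.approx(1.0, abs=0.25)

    def test_hidden_factor_recoverable(self):
        """A strong hidden factor is captured by the leading inferred factors.

        Depth renormalization of convex count means adds a |factor|-shaped
        technical component of its own, so the true factor may arrive as the
        first or second singular vector; one of the top two must match."""
        cfg, gm, counts, truth, _ = self._study(beta=None, seed=4, k=1)
        cfg.factor_sd = 2.0
        counts, truth = iq.simulate_expression(gm, cfg)
        expr = iq.normalize_counts(counts)
        cov = iq.infer_hidden_factors(expr, k=2)
        r = max(
            abs(np.corrcoef(cov[c], truth.factors[0])[0, 1]) for c in cov.columns
        )
        assert r > 0.9

    def test_flipped_exons_change_sign(self):
        _, gm, counts, _, vid = self._study(beta=1.0, seed=2, flipped=(3,))
        expr = iq.normalize_counts(counts)
        g1 = np.flatnonzero((expr.exons["gene_id"] == "g1").to_numpy())
        est = [iq.fit_additive_model(expr.values[i], gm.dosage(vid)).beta for i in g1]
        assert est[3] < 0 < min(est[:3])

    def test_unknown_planted_variant_errors(self):
        block = LdBlock(n_variants=3)
        cfg = SimConfig(
            n_samples=50,
            ld_blocks=[block],
            genes=[GeneSpec("g1", 2, 1_000_000)],
            planted_eqtls=[PlantedEqtl("g1", "rs_nowhere", 1.0)],
            seed=0,
        )
        gm = iq.simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="rs_nowhere"):
            iq.simulate_expression(gm, cfg)

    def test_determinism(self):
        _, _, a, _, _ = self._study(beta=1.0, seed=9)
        _, _, b, _, _ = self._study(beta=1.0, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestGwasLoci:
    def _study(self, seed=0, target_r2=0.9):
        cfg = iq.paired_study_config(
            n_samples=200, n_genes=4, planted_fraction=0.5, target_r2=target_r2,
            n_hidden_factors=0, seed=seed,
        )
        gm = iq.simulate_genotypes(cfg)
        _, truth = iq.simulate_expression(gm, cfg)
        return gm, truth

    def test_shared_causal_lead_is_planted_variant(self):
        gm, truth = self._study()
        (locus,) = iq.simulate_gwas_loci(gm, truth, [True], seed=1)
        assert locus.variant_id == truth.planted[0].variant_id
        assert truth.sharing[locus.locus] == locus.variant_id

    def test_shared_proxy_mode_r2_above_threshold(self):
        gm, truth = self._study(target_r2=1.0)
        (locus,) = iq.simulate_gwas_loci(gm, truth, [True], seed=1, lead_choice="proxy")
        causal = truth.planted[0].variant_id
        assert locus.variant_id != causal
        assert iq.compute_ld_r2(gm.dosage(locus.variant_id), gm.dosage(causal)) == pytest.approx(1.0)

    def test_independent_lead_unlinked_to_all_planted(self):
        gm, truth = self._study()
        (locus,) = iq.simulate_gwas_loci(gm, truth, [False], seed=1)
        for p in truth.planted:
            r2 = iq.compute_ld_r2(gm.dosage(locus.variant_id), gm.dosage(p.variant_id))
            assert r2 < 0.05
        assert truth.sharing[locus.locus] is None

    def test_no_independent_candidate_errors(self):
        cfg = _genotype_config(n_variants=4, target_r2=1.0)
        cfg.genes = [GeneSpec("g1", 2, 1_000_000)]
        vid = block_variant_ids(cfg.ld_blocks[0])[0]
        cfg.planted_eqtls = [PlantedEqtl("g1", vid, 1.0)]
        gm = iq.simulate_genotypes(cfg)
        _, truth = iq.simulate_expression(gm, cfg)
        with pytest.raises(ValueError, match="independent"):
            iq.simulate_gwas_loci(gm, truth, [False], seed=0)


class TestChromatin:
    def _study(self, seed=0, n_genes=8):
        cfg = iq.paired_study_config(
            n_samples=60, n_genes=n_genes, variants_per_block=40, planted_fraction=0.5,
            n_hidden_factors=0, seed=seed,
        )
        gm = iq.simulate_genotypes(cfg)
        _, truth = iq.simulate_expression(gm, cfg)
        return gm, truth

    def test_null_fold_rates_match(self):
        gm, truth = self._study()
        ann = iq.simulate_chromatin(gm, truth, enrichment_fold=1.0, background_rate=0.3, seed=5)
        planted = {p.variant_id for p in truth.planted}
        flags = iq.overlap_variants(
            gm.variants["chrom"].to_numpy(), gm.variants["pos"].to_numpy(), ann
        )
        in_p = np.array([v in planted for v in gm.variants["variant_id"]])
        assert abs(flags[in_p].mean() - flags[~in_p].mean()) < 0.25

    def test_zero_background_no_overlap(self):
        gm, truth = self._study()
        ann = iq.simulate_chromatin(gm, truth, enrichment_fold=2.0, background_rate=0.0, seed=5)
        flags = iq.overlap_variants(
            gm.variants["chrom"].to_numpy(), gm.variants["pos"].to_numpy(), ann
        )
        assert not flags.any()

    def test_impossible_rate_rejected(self):
        gm, truth = self._study()
        with pytest.raises(ValueError, match="exceeds 1"):
            iq.simulate_chromatin(gm, truth, enrichment_fold=4.0, background_rate=0.3)

    def test_planted_fold_recovered(self):
        """fold = 2 at background 0.15 over many variants lands near 2."""
        rates = {"fg": [], "bg": []}
        for seed in range(10):
            gm, truth = self._study(seed=seed, n_genes=100)
            ann = iq.simulate_chromatin(
                gm, truth, enrichment_fold=2.0, background_rate=0.15, seed=seed
            )
            planted = {p.variant_id for p in truth.planted}
            flags = iq.overlap_variants(
                gm.variants["chrom"].to_numpy(), gm.variants["pos"].to_numpy(), ann
            )
            in_p = np.array([v in planted for v in gm.variants["variant_id"]])
            rates["fg"].append(flags[in_p].mean())
            rates["bg"].append(flags[~in_p].mean())
        fold = np.mean(rates["fg"]) / np.mean(rates["bg"])
        assert fold == pytest.approx(2.0, abs=0.4)


class TestConfigValidation:
    def test_library_sizes_positive(self):
        with pytest.raises(ValueError, match="library"):
            SimConfig(n_samples=10, library_size_range=(0, 100))

    def test_beta_finite(self):
        with pytest.raises(ValueError, match="beta"):
            SimConfig(
                n_samples=10,
                genes=[GeneSpec("g", 1, 100)],
                planted_eqtls=[PlantedEqtl("g", "v", float("inf"))],
            )

    def test_min_samples(self):
        with pytest.raises(ValueError):
            SimConfig(n_samples=1)
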