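"""LD, conditional analysis, and the effector nomination cascade."""

import numpy as np
import pandas as pd
import pytest

import isletqtl as iq
from isletqtl.coloc import consistency_string
from isletqtl.core import ChromatinAnnotation, ExpressionMatrix, GenotypeMatrix, GwasLocus


class TestLd:
    def test_identical_vectors(self, rng):
        g = rng.binomial(2, 0.3, 50).astype(float)
        assert iq.compute_ld_r2(g, g) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        a = np.array([0.0, 1.0, 2.0, 0.0])
        b = np.array([2.0, 1.0, 0.0, 2.0])
        assert iq.compute_ld_r2(a, b) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        a = np.array([0.0, 0.0, 1.0, 1.0])
        b = np.array([0.0, 1.0, 0.0, 1.0])
        assert iq.compute_ld_r2(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            iq.compute_ld_r2(np.ones(5), np.array([0.0, 1, 2, 1, 0]))


class TestConditional:
    def test_identical_lead_absorbs_signal(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        y = g + rng.standard_normal(100)
        res = iq.conditional_test(y, g, g.copy())
        assert res.collinear and res.conditional_p == 1.0

    def test_shared_causal_lead_kills_proxy_signal(self, rng):
        """Conditioning an r^2~0.9 proxy on the causal lead leaves no signal."""
        n = 200
        hits = 0
        reps = 60
        for _ in range(reps):
            causal_h = rng.random((n, 2)) < 0.3
            switch = rng.random((n, 2)) < (1 - 0.9**0.5)
            proxy_h = np.where(switch, rng.random((n, 2)) < 0.3, causal_h)
            g_causal = causal_h.sum(1).astype(float)
            g_proxy = proxy_h.sum(1).astype(float)
            if np.ptp(g_proxy) == 0:
                continue
            y = g_causal + rng.standard_normal(n)
            res = iq.conditional_test(y, g_proxy, g_causal)
            if res.conditional_p > 0.05:
                hits += 1
        assert hits / reps >= 0.90

    def test_independent_causal_signal_survives(self, rng):
        """Conditioning on an unlinked lead leaves the eQTL signal intact."""
        n = 200
        hits = 0
        reps = 60
        for _ in range(reps):
            g_e = rng.binomial(2, 0.3, n).astype(float)
            g_l = rng.binomial(2, 0.3, n).astype(float)
            y = g_e + g_l + rng.standard_normal(n)
            res = iq.conditional_test(y, g_e, g_l)
            if res.conditional_p < 0.001:
                hits += 1
        assert hits / reps >= 0.95

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 120
        g_e = rng.binomial(2, 0.3, n).astype(float)
        g_l = np.clip(g_e + rng.binomial(2, 0.2, n) - rng.binomial(2, 0.2, n), 0, 2).astype(float)
        C = rng.standard_normal((n, 2))
        y = 0.5 * g_e + rng.standard_normal(n)
        res = iq.conditional_test(y, g_e, g_l, C)
        X = sm.add_constant(np.column_stack([g_e, g_l, C]))
        fit = sm.OLS(y, X).fit()
        assert res.conditional_p == pytest.approx(fit.pvalues[1], abs=1e-10)
        assert res.conditional_beta == pytest.approx(fit.params[1], abs=1e-10)


class TestDirectionalConsistency:
    def test_sign_count(self):
        pairs = pd.DataFrame(
            {"exon_id": ["a", "b", "c", "d"], "beta": [0.2, 0.3, 0.1, -0.05]}
        )
        assert iq.directional_consistency(pairs, "b") == (3, 4)

    def test_all_same_sign(self):
        pairs = pd.DataFrame({"exon_id": ["a", "b"], "beta": [0.2, 0.3]})
        assert iq.directional_consistency(pairs, "a") == (2, 2)

    def test_report_string_format(self):
        assert consistency_string(23, 24) == "23/24"


def _toy_nomination_inputs(rng, r2_scenarios):
    """Hand-built study: one gene per locus, controlled r^2 / q / overlap."""
    n = 120
    samples = [f"s{i}" for i in range(n)]
    variants, dosage_cols, loci, fdr_rows, expr_rows, exon_rows = [], [], [], [], [], []
    annotation_rows = []
    for k, sc in enumerate(r2_scenarios):
        base = 10_000_000 * (k + 1)
        g_causal = rng.binomial(2, 0.3, n).astype(float)
        if sc["r2"] >= 1.0:
            g_lead = g_causal.copy()
        elif sc["r2"] <= 0.0:
            g_lead = rng.binomial(2, 0.3, n).astype(float)
        else:
            switch = rng.random((n,)) < 0.2
            g_lead = np.where(switch, rng.binomial(2, 0.3, n), g_causal).astype(float)
        eqtl_id, lead_id = f"eqtl{k}", f"lead{k}"
        for vid, pos, col in [(eqtl_id, base + 1000, g_causal), (lead_id, base + 2000, g_lead)]:
            variants.append(
                {"variant_id": vid, "chrom": "1", "pos": pos, "ref": "A", "alt": "G",
                 "genotyped": True, "info": 1.0}
            )
            dosage_cols.append(col)
        y = sc.get("beta", 1.0) * g_causal + rng.standard_normal(n)
        gene = f"gene{k}"
        exon = f"{gene}_e1"
        exon_rows.append(
            {"exon_id": exon, "gene_id": gene, "chrom": "1", "start": base, "end": base + 100,
             "strand": "+", "tss": base}
        )
        expr_rows.append((y - y.mean()) / y.std())
        fdr_rows.append(
            {"exon_id": exon, "gene_id": gene, "chrom": "1", "tss": base,
             "index_variant": eqtl_id, "min_p": sc.get("min_p", 1e-6),
             "beta": sc.get("beta", 1.0), "empirical_p": sc["empirical_p"], "q": sc["q"]}
        )
        loci.append(
            GwasLocus(locus=f"L{k}", trait="T2D", variant_id=lead_id, chrom="1",
                      pos=base + 2000, risk_allele="G", other_allele="A")
        )
        if sc.get("overlap", True):
            annotation_rows.append(
                {"chrom": "1", "start": base + 999 - 50, "end": base + 999 + 51,
                 "state": "enhancer", "dataset": "map1"}
            )
    gm = GenotypeMatrix(
        samples=samples, variants=pd.DataFrame(variants), dosages=np.column_stack(dosage_cols)
    )
    expr = ExpressionMatrix(
        exons=pd.DataFrame(exon_rows), samples=samples, values=np.array(expr_rows)
    )
    annotation = ChromatinAnnotation(
        intervals=pd.DataFrame(
            annotation_rows, columns=["chrom", "start", "end", "state", "dataset"]
        )
    )
    return pd.DataFrame(fdr_rows), loci, gm, expr, annotation


class TestNominationCascade:
    def test_rule_application(self, rng):
        scenarios = [
            # study-wide tier, shared variant, overlap -> emitted
            {"r2": 1.0, "q": 0.01, "empirical_p": 0.001},
            # strong LD but only nominal significance -> emitted as nominal
            {"r2": 1.0, "q": 0.2, "empirical_p": 0.03},
            # weak LD -> dropped
            {"r2": 0.0, "q": 0.01, "empirical_p": 0.001},
            # no chromatin overlap -> dropped
            {"r2": 1.0, "q": 0.01, "empirical_p": 0.001, "overlap": False},
            # not even nominal -> dropped
            {"r2": 1.0, "q": 0.9, "empirical_p": 0.5},
        ]
        fdr, loci, gm, expr, annotation = _toy_nomination_inputs(rng, scenarios)
        calls = iq.nominate_effectors(fdr, loci, gm, expr, None, annotation)
        assert list(calls["locus"]) == ["L0", "L1"]
        assert list(calls["tier"]) == ["study_wide", "nominal"]
        assert calls["collinear_with_lead"].all()
        assert (calls["r2_with_lead"] > 0.8).all()

    def test_missing_lead_skipped_with_warning(self, rng):
        fdr, loci, gm, expr, annotation = _toy_nomination_inputs(
            rng, [{"r2": 1.0, "q": 0.01, "empirical_p": 0.001}]
        )
        loci[0].variant_id = "rs_absent"
        with pytest.warns(UserWarning, match="absent"):
            calls = iq.nominate_effectors(fdr, loci, gm, expr, None, annotation)
        assert len(calls) == 0

    def test_risk_allele_direction(self, rng):
        fdr, loci, gm, expr, annotation = _toy_nomination_inputs(
            rng, [{"r2": 1.0, "q": 0.01, "empirical_p": 0.001, "beta": 1.0}]
        )
        calls = iq.nominate_effectors(fdr, loci, gm, expr, None, annotation)
        # risk allele is alt and beta positive -> expression up on risk allele
        assert calls.loc[0, "direction"] == "up"
        assert calls.loc[0, "directional_consistency"] == "1/1"

    def test_allele_flip_invariance(self, rng):
        """Relabeling ref/alt (dosage -> 2 - dosage) flips nothing downstream."""
        fdr, loci, gm, expr, annotation = _toy_nomination_inputs(
            rng, [{"r2": 1.0, "q": 0.01, "empirical_p": 0.001, "beta": 1.0}]
        )
        base = iq.nominate_effectors(fdr, loci, gm, expr, None, annotation)

        flipped = GenotypeMatrix(
            samples=gm.samples,
            variants=gm.variants.assign(
                ref=gm.variants["alt"], alt=gm.variants["ref"]
            ),
            dosages=2.0 - gm.dosages,
        )
        # the scan on flipped dosages reports the sign-flipped beta
        fdr_flipped = fdr.assign(beta=-fdr["beta"])
        got = iq.nominate_effectors(fdr_flipped, loci, flipped, expr, None, annotation)
        assert got.loc[0, "direction"] == base.loc[0, "direction"]
        assert got.loc[0, "beta_risk_allele"] == pytest.approx(
            base.loc[0, "beta_risk_allele"]
        )
        assert got.loc[0, "r2_with_lead"] == pytest.approx(base.loc[0, "r2_with_lead"])
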