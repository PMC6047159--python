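import numpy as np
import pandas as pd
import pytest

import milkgwas as mg
from milkgwas.association import AssocResult
from milkgwas.simulate import GeneticEffect


def _assoc(beta, se, variant=None, phenotype="AA", n=100):
    v = se ** -2
    return AssocResult(
        variant, phenotype, n, beta * v, v, beta, se, (beta / se) ** 2,
        0.5, "+" if beta >= 0 else "-",
    )


class TestMetaFixedEffects:
    def test_equal_se_two_study_closed_form(self):
        rec = mg.meta_fixed_effects([_assoc(0.1, 0.1), _assoc(0.3, 0.1)])
        assert rec.beta == pytest.approx(0.2)
        assert rec.se == pytest.approx(0.1 / np.sqrt(2))

    def test_single_study_identity(self):
        rec = mg.meta_fixed_effects([_assoc(0.25, 0.05)])
        assert rec.beta == pytest.approx(0.25)
        assert rec.se == pytest.approx(0.05)

    def test_opposite_signs_cancel(self):
        rec = mg.meta_fixed_effects([_assoc(0.2, 0.1), _assoc(-0.2, 0.1)])
        assert rec.beta == pytest.approx(0.0, abs=1e-12)
        assert rec.direction == "+-"

    def test_k_identical_studies(self):
        k = 4
        rec = mg.meta_fixed_effects([_assoc(0.15, 0.08) for _ in range(k)])
        assert rec.beta == pytest.approx(0.15)
        assert rec.se == pytest.approx(0.08 / np.sqrt(k))

    def test_agreeing_directions_increase_z(self):
        same = mg.meta_fixed_effects([_assoc(0.2, 0.1), _assoc(0.2, 0.1)])
        lone = mg.meta_fixed_effects([_assoc(0.2, 0.1)])
        assert abs(same.z) > abs(lone.z)

    def test_allele_mismatch_rejected(self):
        v1 = mg.Variant("1", 100, "A", "G", snp_id="x")
        v2 = mg.Variant("1", 100, "G", "A", snp_id="x")
        with pytest.raises(ValueError, match="allele mismatch"):
            mg.meta_fixed_effects([_assoc(0.1, 0.1, v1), _assoc(0.1, 0.1, v2)])

    def test_cross_check_against_metafor_style_formula(self, rng):
        # independent check: weighted.mean with w = 1/se^2
        betas = rng.normal(size=5)
        ses = rng.uniform(0.05, 0.3, 5)
        rec = mg.meta_fixed_effects([_assoc(b, s) for b, s in zip(betas, ses)])
        w = ses ** -2.0
        assert rec.beta == pytest.approx(np.average(betas, weights=w))
        assert rec.se == pytest.approx(w.sum() ** -0.5)


def _two_studies(seed=1, n1=532, n2=610, factor=0.85, extra_variants=()):
    variants = [
        mg.Variant("11", 61_580_635, "T", "C", raf=0.17, snp_id="rs_lead"),
        mg.Variant("11", 61_600_000, "A", "G", raf=0.30, snp_id="rs_null_cis"),
        mg.Variant("2", 10_000_000, "A", "G", raf=0.40, snp_id="rs_null_trans"),
        *extra_variants,
    ]
    effects = [GeneticEffect(0, "AA", factor)]
    studies = []
    for name, n, s in (("URBAN", n1, seed), ("RURAL", n2, seed + 500)):
        cfg = mg.SimConfig(n_dyads=n, variants=variants, seed=s, genetic_effects=effects)
        cohort, table = mg.simulate_study(cfg)
        studies.append(mg.Study.from_simulation(name, cohort, table))
    return studies


class TestGenomeScan:
    def test_causal_variant_ranks_first_with_consistent_directions(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            df = mg.genome_scan(_two_studies(seed=100 + seed), phenotype_names=["AA"])
            top = df.iloc[0]
            if top["snp_id"] == "rs_lead" and top["direction"] in ("--", "++"):
                hits += 1
        assert hits >= 9

    def test_effect_reported_on_multiplicative_scale(self):
        df = mg.genome_scan(_two_studies(seed=7), phenotype_names=["AA"])
        top = df[df["snp_id"] == "rs_lead"].iloc[0]
        assert 0.75 < top["beta_reported"] < 0.95

    def test_null_scan_no_experiment_wise_hit(self):
        variants = [
            mg.Variant("1", 1000 + 10 * i, "A", "G", raf=0.3, snp_id=f"n{i}")
            for i in range(400)
        ]
        cfg = mg.SimConfig(n_dyads=300, variants=variants, seed=11)
        cohort, table = mg.simulate_study(cfg)
        df = mg.genome_scan(
            [mg.Study.from_simulation("S", cohort, table)], phenotype_names=["AA", "DHA"]
        )
        assert (df["p_meta"] > 4.2e-9).all()

    def test_region_bounds_honoured_exactly(self):
        extra = (
            mg.Variant("11", 61_546_999, "A", "G", raf=0.3, snp_id="rs_out_left"),
            mg.Variant("11", 61_547_000, "A", "G", raf=0.3, snp_id="rs_in_left"),
            mg.Variant("11", 61_673_000, "A", "G", raf=0.3, snp_id="rs_in_right"),
            mg.Variant("11", 61_673_001, "A", "G", raf=0.3, snp_id="rs_out_right"),
        )
        studies = _two_studies(seed=3, n1=200, n2=200, extra_variants=extra)
        df = mg.genome_scan(
            studies, phenotype_names=["AA"], region=("11", 61_547_000, 61_673_000)
        )
        ids = set(df["snp_id"])
        assert {"rs_in_left", "rs_in_right", "rs_lead"} <= ids
        assert not {"rs_out_left", "rs_out_right", "rs_null_trans"} & ids

    def test_output_invariant_to_variant_order(self):
        studies = _two_studies(seed=5, n1=250, n2=250)
        df1 = mg.genome_scan(studies, phenotype_names=["AA"])
        flipped = [
            mg.Study(s.name, s.variants[::-1], s.infant_triples[::-1], s.phenotypes)
            for s in studies
        ]
        df2 = mg.genome_scan(flipped, phenotype_names=["AA"])
        pd.testing.assert_frame_equal(df1, df2)

    def test_deterministic_under_fixed_inputs(self):
        studies = _two_studies(seed=6, n1=200, n2=200)
        df1 = mg.genome_scan(studies, phenotype_names=["AA"])
        df2 = mg.genome_scan(studies, phenotype_names=["AA"])
        pd.testing.assert_frame_equal(df1, df2)

    def test_empty_post_filter_set_reports_explicitly(self, caplog):
        # rare variant present in one study only fails the MAF > 0.1 rule
        variants = [mg.Variant("1", 500, "A", "G", raf=0.05, snp_id="rare")]
        cfg = mg.SimConfig(n_dyads=300, variants=variants, seed=2)
        cohort, table = mg.simulate_study(cfg)
        with caplog.at_level("WARNING"):
            df = mg.genome_scan(
                [mg.Study.from_simulation("S", cohort, table)], phenotype_names=["AA"]
            )
        assert df.empty
        assert "no variant passed" in caplog.text


class TestConditionalScan:
    REGION = ("11", 61_547_000, 61_673_000)

    def test_conditioning_on_causal_dosage_annihilates_own_signal(self):
        studies = _two_studies(seed=8)
        plain = mg.regional_conditional_scan(studies, self.REGION, None,
                                             phenotype_names=["AA"])
        cond = mg.regional_conditional_scan(
            studies, self.REGION, ("variant", "rs_lead"), phenotype_names=["AA"]
        )
        p_plain = plain.set_index("snp_id").loc["rs_lead", "p_meta"]
        p_cond = cond.set_index("snp_id").loc["rs_lead", "p_meta"]
        assert p_plain < 1e-3
        # conditioned on itself the variant carries no residual signal:
        # p collapses to ~1 (or the pair is flagged untestable -> NaN)
        assert not (p_cond < 0.99)

    def test_conditioning_phenotype_on_itself_untestable(self, caplog):
        studies = _two_studies(seed=9, n1=200, n2=200)
        with caplog.at_level("WARNING"):
            df = mg.regional_conditional_scan(
                studies, self.REGION, ("phenotype", "AA"), phenotype_names=["AA"]
            )
        assert df.empty or df["p_meta"].isna().all()

    def test_phenotype_conditioning_removes_mediated_signal(self):
        """A phenotype that tracks AA (and has no direct genetic effect)
        shows a variant signal only through AA; conditioning on log(AA)
        removes it."""
        studies = _two_studies(seed=12)
        rng = np.random.default_rng(0)
        for st in studies:
            tab = st.phenotypes.copy()
            # DPA6 rebuilt as a noisy multiplicative function of AA
            tab["DPA6"] = 0.2 * tab["AA"] * np.exp(
                rng.normal(0, 0.05, len(tab))
            )
            st.phenotypes = tab
        plain = mg.regional_conditional_scan(
            studies, self.REGION, None, phenotype_names=["DPA6"]
        )
        cond = mg.regional_conditional_scan(
            studies, self.REGION, ("phenotype", "AA"), phenotype_names=["DPA6"]
        )
        p_plain = plain.set_index("snp_id").loc["rs_lead", "p_meta"]
        p_cond = cond.set_index("snp_id").loc["rs_lead", "p_meta"]
        assert p_plain < 1e-3
        assert p_cond > 1e-3 * 10  # signal collapses once AA is adjusted for
        assert p_cond > p_plain

    def test_conditioning_variant_must_pass_filters(self):
        studies = _two_studies(seed=13, n1=200, n2=200)
        with pytest.raises(ValueError, match="unknown conditioning variant"):
            mg.regional_conditional_scan(
                studies, self.REGION, ("variant", "rs_not_there"),
                phenotype_names=["AA"],
            )

    def test_conditioning_variant_failing_filters_rejected(self):
        rare = mg.Variant("11", 61_550_000, "A", "G", raf=0.03, snp_id="rs_rare")
        studies = _two_studies(seed=14, n1=400, n2=400, extra_variants=(rare,))
        with pytest.raises(ValueError, match="fails the active filters"):
            mg.regional_conditional_scan(
                studies, self.REGION, ("variant", "rs_rare"),
                phenotype_names=["AA"],
            )


class TestGroupLoci:
    def _frame(self, rows):
        cols = ["phenotype", "snp_id", "chrom", "pos", "p_meta"]
        return pd.DataFrame(rows, columns=cols)

    def test_desaturase_style_cluster_merges_to_one_locus(self):
        rows = [
            ("AA", f"rs{i}", "11", 61_547_000 + int(i * 126_000 / 23), 1e-10)
            for i in range(24)
        ]
        loci = mg.group_loci(self._frame(rows), threshold=4.2e-9, merge_window=500_000)
        assert len(loci) == 1
        assert loci[0].n_primary == 24
        assert loci[0].end - loci[0].start <= 126_000

    def test_distant_variants_split(self):
        rows = [
            ("AA", "a", "11", 1_000_000, 1e-10),
            ("AA", "b", "11", 3_000_000, 1e-11),
        ]
        loci = mg.group_loci(self._frame(rows), threshold=4.2e-9, merge_window=500_000)
        assert len(loci) == 2
        assert loci[0].lead_snp == "b"  # sorted by lead p

    def test_empty_significant_set(self):
        rows = [("AA", "a", "11", 1_000_000, 1e-3)]
        assert mg.group_loci(self._frame(rows), threshold=4.2e-9) == []

    def test_secondary_threshold_counts(self):
        rows = [
            ("AA", "a", "11", 1_000_000, 1e-10),
            ("AA", "b", "11", 1_010_000, 1e-8),   # genome-wide but not experiment-wise
        ]
        loci = mg.group_loci(self._frame(rows), threshold=4.2e-9, merge_window=500_000)
        assert len(loci) == 1
        assert loci[0].n_primary == 1 and loci[0].n_secondary == 2


class TestLambdaGc:
    def test_uniform_p_values_near_one(self, rng):
        lam = mg.lambda_gc(rng.uniform(size=50_000))
        assert lam == pytest.approx(1.0, abs=0.03)
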