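import numpy as np
import pandas as pd
import pytest

from rohdep.io import GenotypeMatrix
from rohdep.pedigree import UNKNOWN
from rohdep.simulate import (
    ChromosomeSpec,
    DeleteriousLocus,
    SimConfig,
    TraitModelParams,
    gene_drop,
    life_stage_from_age,
    make_snp_table,
    simulate_cohort,
    simulate_pedigree,
    simulate_survival,
)


def sib_pedigree(n_offspring):
    rows = [
        {"id": 1, "sire": UNKNOWN, "dam": UNKNOWN},
        {"id": 2, "sire": UNKNOWN, "dam": UNKNOWN},
        {"id": 3, "sire": 1, "dam": 2},
        {"id": 4, "sire": 1, "dam": 2},
    ]
    rows += [{"id": 5 + i, "sire": 3, "dam": 4} for i in range(n_offspring)]
    return pd.DataFrame(rows)


class TestGeneDrop:
    def test_zero_cm_map_transmits_intact_haplotypes(self):
        cfg = SimConfig(chromosomes=[ChromosomeSpec(10.0, 0.0, 50)], seed=1)
        snps = make_snp_table(cfg.chromosomes)
        ped = sib_pedigree(30)
        g, truth = gene_drop(ped, snps, cfg)
        # without recombination every IBD tract spans the whole chromosome
        assert set(truth.realised_ibd.round(9).unique()) <= {0.0, 1.0}

    def test_fullsib_offspring_ibd_near_quarter(self):
        # independent families: offspring of one realised sib pair share
        # the sibs' meioses and are not independent draws
        from rohdep.experiments import fullsib_ibd

        out = fullsib_ibd(400, seed=2)
        assert out["mean_ibd"] == pytest.approx(0.25, abs=0.03)

    def test_ibd_tracts_are_homozygous(self):
        cfg = SimConfig(chromosomes=[ChromosomeSpec(50.0, 64.0, 500)], seed=3)
        snps = make_snp_table(cfg.chromosomes)
        ped = sib_pedigree(20)
        g, truth = gene_drop(ped, snps, cfg)
        for r in truth.ibd_tracts.itertuples():
            i = g.ids.index(str(r.id))
            mask = (
                (g.snps["chromosome"] == r.chromosome)
                & (g.snps["bp"] >= r.start_bp)
                & (g.snps["bp"] <= r.end_bp)
            )
            codes = g.codes[i, mask.to_numpy()]
            assert np.isin(codes, [0, 2]).all()

    def test_deterministic_under_seed(self):
        cfg = SimConfig(chromosomes=[ChromosomeSpec(30.0, 40.0, 200)], seed=9)
        snps = make_snp_table(cfg.chromosomes)
        ped = sib_pedigree(10)
        g1, t1 = gene_drop(ped, snps, cfg, np.random.default_rng(9))
        g2, t2 = gene_drop(ped, snps, cfg, np.random.default_rng(9))
        np.testing.assert_array_equal(g1.codes, g2.codes)
        pd.testing.assert_frame_equal(t1.ibd_tracts, t2.ibd_tracts)

    def test_missing_cm_rejected(self):
        cfg = SimConfig(chromosomes=[ChromosomeSpec(10.0, 10.0, 10)], seed=1)
        snps = make_snp_table(cfg.chromosomes)
        snps.loc[3, "cM"] = np.nan
        with pytest.raises(ValueError, match="cM"):
            gene_drop(sib_pedigree(2), snps, cfg)

    def test_pedigree_f_matches_path_counting(self):
        cfg = SimConfig(chromosomes=[ChromosomeSpec(10.0, 10.0, 10)], seed=4)
        snps = make_snp_table(cfg.chromosomes)
        g, truth = gene_drop(sib_pedigree(5), snps, cfg)
        assert truth.pedigree_f.loc[5] == pytest.approx(0.25)
        assert truth.pedigree_f.loc[1] == 0.0


class TestCalledRohTrackTruth:
    def test_called_segments_overlap_true_ibd_far_above_chance(self):
        """Called ROH are almost entirely inside true IBD tracts, and
        long true tracts are mostly recovered; chance overlap would be
        near the mean IBD fraction (~0.1-0.2)."""
        from rohdep.roh import RohParams, call_roh

        rng = np.random.default_rng(17)
        chroms = [ChromosomeSpec(50.0, 64.0, 2000)] * 2
        cfg = SimConfig(
            n_founders=20, n_generations=10, n_per_generation=40,
            chromosomes=chroms, seed=17,
        )
        ped = simulate_pedigree(cfg, rng)
        snps = make_snp_table(chroms)
        g, truth = gene_drop(ped, snps, cfg, rng)
        segs = call_roh(g, RohParams())
        assert len(segs) > 100
        tr = truth.ibd_tracts

        def overlap(outer, inner_set):
            total = covered = 0
            for r in outer.itertuples():
                t = inner_set[
                    (inner_set["id"].astype(str) == str(r.id))
                    & (inner_set["chromosome"] == r.chromosome)
                ]
                total += r.end_bp - r.start_bp + 1
                ovl = np.minimum(t["end_bp"], r.end_bp) - np.maximum(t["start_bp"], r.start_bp) + 1
                covered += ovl[ovl > 0].sum()
            return covered / total

        precision = overlap(segs, tr)
        long_tracts = tr[(tr["end_bp"] - tr["start_bp"]) >= 2e6]
        recall = overlap(long_tracts, segs)
        assert precision > 0.9
        assert recall > 0.8


class TestLifeStage:
    def test_stage_deterministic_from_age(self):
        ages = np.array([0, 1, 2, 3, 4, 5, 9])
        np.testing.assert_array_equal(
            life_stage_from_age(ages),
            np.array(["lamb", "early", "early", "mid", "mid", "late", "late"], dtype=object),
        )


class TestSimulateSurvival:
    def test_null_model_half_survival(self):
        rng = np.random.default_rng(5)
        ind = simulate_cohort(4000, rng)
        p = TraitModelParams.null()
        p.var_capture_year = p.var_birth_year = p.var_id = 0.0
        surv = simulate_survival(ind, p, rng=rng)
        assert surv["survived"].mean() == pytest.approx(0.5, abs=0.02)

    def test_observations_stop_after_death(self, rng):
        ind = simulate_cohort(500, rng)
        surv = simulate_survival(ind, TraitModelParams(), rng=rng)
        for _, sub in surv.groupby("id"):
            s = sub.sort_values("year")["survived"].to_numpy()
            # a run of 1s optionally terminated by a single 0
            assert (s[:-1] == 1).all()
        assert surv.groupby(["id", "year"]).size().max() == 1

    def test_ages_consecutive_from_zero(self, rng):
        ind = simulate_cohort(200, rng)
        surv = simulate_survival(ind, TraitModelParams(), rng=rng)
        for _, sub in surv.groupby("id"):
            ages = sub.sort_values("year")["age"].to_numpy()
            np.testing.assert_array_equal(ages, np.arange(len(ages)))

    def test_log_link_caps_probability(self, rng):
        ind = simulate_cohort(2000, rng)
        p = TraitModelParams.null()
        p.beta0 = 0.5  # exp(0.5) > 1 -> capped at 1
        p.var_capture_year = p.var_birth_year = p.var_id = 0.0
        surv = simulate_survival(ind, p, link="log", rng=rng)
        assert surv["survived"].min() == 1

    def test_deleterious_locus_penalty_applies_to_ibd_homozygotes(self):
        cfg = SimConfig(chromosomes=[ChromosomeSpec(50.0, 64.0, 500)], seed=6)
        snps = make_snp_table(cfg.chromosomes)
        ped = sib_pedigree(200)
        g, truth = gene_drop(ped, snps, cfg)
        locus_bp = int(snps["bp"].iloc[250])
        locus = DeleteriousLocus(chromosome=1, bp=locus_bp, allele=1, effect=-50.0)
        ind = pd.DataFrame(
            {
                "id": g.ids,
                "froh": truth.realised_ibd.to_numpy(),
                "sex": 0,
                "twin": 0,
                "birth_year": 0,
            }
        )
        p = TraitModelParams.null()
        p.beta0 = 10.0  # survival ~1 except at the planted locus
        p.var_capture_year = p.var_birth_year = p.var_id = 0.0
        surv = simulate_survival(
            ind,
            p,
            n_years=1,
            deleterious_loci=[locus],
            ibd_tracts=truth.ibd_tracts,
            genotypes=g,
            rng=np.random.default_rng(1),
        )
        t = truth.ibd_tracts
        cover = set(
            t[(t["chromosome"] == 1) & (t["start_bp"] <= locus_bp) & (t["end_bp"] >= locus_bp)][
                "id"
            ].astype(str)
        )
        surv = surv.set_index(surv["id"].astype(str))
        for i, ind_id in enumerate(g.ids):
            hom_b = g.codes[i, 250] == 2
            expected = 0 if (hom_b and ind_id in cover) else 1
            assert surv.loc[ind_id, "survived"] == expected


class TestTraitParams:
    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            TraitModelParams(var_id=-1.0)

    def test_null_zeroes_fixed_effects_only(self):
        p = TraitModelParams.null()
        assert p.beta_froh == 0.0 and p.beta_sex == 0.0
        assert p.var_capture_year > 0
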