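import numpy as np
import pandas as pd
import pytest

from rohdep.association import (
    EffectiveTests,
    RohStatusScan,
    effective_tests,
    encode_roh_status,
    exact_binomial_p,
    grm_pcs,
    sign_enrichment,
    significance_threshold,
)
from rohdep.io import MISSING, GenotypeMatrix
from rohdep.roh import RohParams, call_roh
from rohdep.simulate import (
    ChromosomeSpec,
    DeleteriousLocus,
    SimConfig,
    TraitModelParams,
    gene_drop,
    make_snp_table,
    simulate_pedigree,
    simulate_survival,
)

from conftest import make_snps, random_genotypes


def tiny_genotypes():
    snps = make_snps(5, spacing_bp=100_000)
    codes = np.array(
        [
            [0, 1, 2, 0, MISSING],
            [2, 2, 2, 2, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["a", "b"], snps, codes)


def seg(ind, chrom, start, end):
    return pd.DataFrame(
        [
            {
                "id": ind,
                "chromosome": chrom,
                "start_bp": start,
                "end_bp": end,
                "n_snps": 50,
                "n_het": 0,
                "length_kb": (end - start + 1) / 1000,
            }
        ]
    )


class TestEncodeRohStatus:
    def test_trivial_cases(self):
        g = tiny_genotypes()
        # segment covering SNPs 1-3 of individual a (bp 100001..300001)
        segments = seg("a", 1, 100_001, 300_001)
        in_a, in_b = encode_roh_status(g, segments)
        # SNP0: hom A but outside segment
        assert not in_a[0, 0] and not in_b[0, 0]
        # SNP1: het inside segment -> (0, 0)
        assert not in_a[0, 1] and not in_b[0, 1]
        # SNP2: hom B inside segment -> (0, 1)
        assert not in_a[0, 2] and in_b[0, 2]
        # SNP3: hom A inside segment -> (1, 0)
        assert in_a[0, 3] and not in_b[0, 3]
        # individual b has no segments at all
        assert not in_a[1].any() and not in_b[1].any()

    def test_missing_genotype_gives_neither(self):
        g = tiny_genotypes()
        segments = seg("a", 1, 1, 500_000)
        in_a, in_b = encode_roh_status(g, segments)
        assert not in_a[0, 4] and not in_b[0, 4]

    def test_never_both(self, rng):
        g = random_genotypes(rng, n_ind=20, n_snps=60)
        rows = []
        for i in range(20):
            start = int(rng.integers(1, 800_000))
            rows.append(seg(f"ind{i}", 1, start, start + 500_000))
        segments = pd.concat(rows, ignore_index=True)
        in_a, in_b = encode_roh_status(g, segments)
        assert not (in_a & in_b).any()

    def test_unknown_individual_rejected(self):
        g = tiny_genotypes()
        with pytest.raises(ValueError, match="ghost"):
            encode_roh_status(g, seg("ghost", 1, 1, 100))


class TestGrmPcs:
    def test_identical_individuals_identical_coordinates(self, rng):
        g = random_genotypes(rng, n_ind=12, n_snps=80, missing_rate=0)
        codes = g.codes.copy()
        codes[1] = codes[0]
        g2 = GenotypeMatrix(g.ids, g.snps, codes)
        pcs = grm_pcs(g2, k=3)
        np.testing.assert_allclose(pcs[0], pcs[1], atol=1e-10)

    def test_matches_explicit_eigendecomposition(self, rng):
        g = random_genotypes(rng, n_ind=30, n_snps=100, missing_rate=0)
        k = 4
        pcs = grm_pcs(g, k=k)
        # brute force: build the standardised matrix with loops
        p = g.codes.mean(axis=0) / 2
        use = (p > 0) & (p < 1)
        Z = np.zeros((30, use.sum()))
        for i in range(30):
            col = 0
            for j in range(g.n_snps):
                if use[j]:
                    Z[i, col] = (g.codes[i, j] - 2 * p[j]) / np.sqrt(2 * p[j] * (1 - p[j]))
                    col += 1
        K = Z @ Z.T / use.sum()
        vals, vecs = np.linalg.eigh(K)
        ref = vecs[:, np.argsort(vals)[::-1][:k]]
        for c in range(k):
            v = ref[:, c]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(pcs[:, c], v, atol=1e-8)

    def test_row_means_near_zero(self, rng):
        g = random_genotypes(rng, n_ind=40, n_snps=200, missing_rate=0)
        p = g.allele_freq()
        use = (p > 0) & (p < 1)
        z = (g.codes[:, use] - 2 * p[use]) / np.sqrt(2 * p[use] * (1 - p[use]))
        K = z @ z.T / use.sum()
        assert np.abs(K.mean(axis=0)).max() < 1e-10

    def test_k_too_large(self, rng):
        g = random_genotypes(rng, n_ind=5, n_snps=20)
        with pytest.raises(ValueError, match="exceeds"):
            grm_pcs(g, k=6)


def block_neff(corr, C=0.995):
    vals = np.sort(np.linalg.eigvalsh(corr))[::-1]
    return int(np.searchsorted(np.cumsum(vals), C * vals.sum()) + 1)


class TestEffectiveTests:
    def test_identical_snps_one_effective_test(self, rng):
        snps = make_snps(30)
        col = rng.integers(0, 3, size=25).astype(np.int8)
        codes = np.tile(col[:, None], (1, 30))
        g = GenotypeMatrix([f"i{k}" for k in range(25)], snps, codes)
        eff = effective_tests(g, block_size=1000)
        assert eff.n_eff == 1
        assert eff.n_tests_total == 2

    def test_identity_correlation_block_formula(self):
        # uncorrelated SNPs: eigenvalues all 1 -> smallest k with
        # k >= 0.995 m, i.e. ceil
        assert block_neff(np.eye(200)) == 199

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        g = random_genotypes(rng, n_ind=50, n_snps=100, missing_rate=0.05)
        eff = effective_tests(g, block_size=1000)
        codes = g.codes.astype(float)
        codes[g.codes == MISSING] = np.nan
        corr = pd.DataFrame(codes).corr().to_numpy()
        np.fill_diagonal(corr, 1.0)
        corr = np.nan_to_num(corr)
        np.fill_diagonal(corr, 1.0)
        assert eff.n_eff == block_neff(corr)

    def test_blocks_partition_chromosomes(self, rng):
        # individuals must outnumber the block size, otherwise rank
        # deficiency caps each block's contribution
        g = random_genotypes(rng, n_ind=200, n_snps=60, chromosomes=(1, 2))
        whole = effective_tests(g, block_size=1000)
        split = effective_tests(g, block_size=15)
        # uncorrelated random SNPs: block splits change n_eff only mildly
        assert abs(whole.n_eff - split.n_eff) <= 6

    def test_monotone_in_correlation(self, rng):
        snps = make_snps(40)
        base = rng.integers(0, 3, size=(60, 40)).astype(np.int8)
        ids = [f"i{k}" for k in range(60)]
        low = GenotypeMatrix(ids, snps, base)
        correlated = base.copy()
        correlated[:, 1::2] = correlated[:, ::2]  # duplicate alternate SNPs
        high = GenotypeMatrix(ids, snps, correlated)
        assert effective_tests(high).n_eff <= effective_tests(low).n_eff


class TestSignificanceThreshold:
    def test_published_arithmetic(self):
        eff = EffectiveTests(n_eff=39184, n_snps=417_373)
        assert eff.n_tests_total == 78368
        thr = significance_threshold(eff)
        assert thr == pytest.approx(0.05 / 78368)
        assert float(f"{thr:.3g}") == pytest.approx(6.38e-07, rel=1e-3)

    def test_identity(self):
        assert significance_threshold(1, tests_per_model=1) == 0.05
        eff = EffectiveTests(n_eff=123, n_snps=1000)
        assert significance_threshold(eff, alpha=0.05) * 2 * 123 == pytest.approx(0.05)


class TestSignEnrichment:
    def make_results(self, estimates, pvals=None):
        n = len(estimates)
        return pd.DataFrame(
            {
                "snp_id": [f"s{k}" for k in range(n)],
                "term": "A",
                "estimate": estimates,
                "p": pvals if pvals is not None else np.random.default_rng(0).uniform(size=n),
                "status": "ok",
            }
        )

    def test_equal_counts_p_one(self):
        res = sign_enrichment(self.make_results(np.array([-1.0, 1.0, -0.5, 0.5])))
        assert res.binomial_p == pytest.approx(1.0)
        assert res.fraction_negative == 0.5

    def test_published_counts_overwhelming(self):
        assert exact_binomial_p(465_000, 465_000 + 354_000) <= 2.2e-16

    def test_null_glm_slopes_cover_zero(self, rng):
        est = rng.normal(0, 0.5, 4000)
        pv = rng.uniform(size=4000)
        res = sign_enrichment(self.make_results(est, pv))
        assert 0.45 < res.fraction_negative < 0.55
        lo, hi = res.estimate_glm_ci
        assert lo < 0 < hi
        lo, hi = res.pvalue_glm_ci
        assert lo < 0 < hi


def drop_dataset(seed=5, n_chrom=6, planted=None, params=None):
    rng = np.random.default_rng(seed)
    chroms = [ChromosomeSpec(25.0, 32.0, 1000)] * n_chrom
    cfg = SimConfig(
        n_founders=20,
        n_generations=14,
        n_per_generation=44,
        mating_scheme="random",
        chromosomes=chroms,
        seed=seed,
    )
    ped = simulate_pedigree(cfg, rng)
    snps = make_snp_table(chroms)
    g, truth = gene_drop(ped, snps, cfg, rng)
    segs = call_roh(g, RohParams())
    study = ped[ped["generation"] >= 6]
    ids = study["id"].astype(str).tolist()
    keep = [g.ids.index(i) for i in ids]
    gs = GenotypeMatrix(ids, g.snps, g.codes[keep])
    segs = segs[segs["id"].astype(str).isin(set(ids))].copy()
    segs["id"] = segs["id"].astype(str)
    ind = pd.DataFrame(
        {
            "id": ids,
            "froh": truth.realised_ibd.loc[study["id"]].to_numpy(),
            "sex": rng.integers(0, 2, len(ids)),
            "twin": (rng.random(len(ids)) < 0.3).astype(int),
        }
    )
    params = params or TraitModelParams(
        beta_froh=0.0, beta_froh_early=0.0, beta_froh_mid=0.0, beta_froh_late=0.0
    )
    surv = simulate_survival(
        ind,
        params,
        n_years=8,
        deleterious_loci=planted,
        ibd_tracts=truth.ibd_tracts if planted else None,
        genotypes=g if planted else None,
        rng=rng,
    )
    surv["id"] = surv["id"].astype(str)
    lengths = {c + 1: 25.0 for c in range(n_chrom)}
    return gs, segs, surv, lengths, truth


class TestRohStatusScan:
    def test_no_carrier_term_dropped_and_flagged(self):
        gs, segs, surv, lengths, _ = drop_dataset(seed=8, n_chrom=4)
        scan = RohStatusScan(surv, gs, segs, lengths, n_pcs=3, min_carriers=5)
        res = scan.run(snp_ids=gs.snps["snp_id"].iloc[:40:4])
        t = res.table
        dropped = t[t["status"] == "dropped_few_carriers"]
        ok = t[t["status"] == "ok"]
        assert len(t) == 2 * 10
        assert (dropped["n_carriers"] < 5).all()
        assert dropped["estimate"].isna().all()
        assert (ok["n_carriers"] >= 5).all()
        assert ((ok["p"] > 0) & (ok["p"] <= 1)).all()

    def test_planted_deleterious_locus_is_top_hit(self):
        from rohdep.simulate import choose_deleterious_site

        gs0, _, _, _, truth0 = drop_dataset(seed=41, n_chrom=8)
        # plant at the site with the most exposed homozygous-in-IBD
        # carriers, the scan's intended detection regime
        locus_bp, n_car = choose_deleterious_site(gs0, truth0.ibd_tracts, chromosome=5)
        assert n_car >= 20
        planted = [DeleteriousLocus(chromosome=5, bp=locus_bp, allele=1, effect=-1.5)]
        gs, segs, surv, lengths, truth = drop_dataset(seed=41, n_chrom=8, planted=planted)
        scan = RohStatusScan(surv, gs, segs, lengths, n_pcs=5)
        focal = gs.snps.loc[
            (gs.snps["chromosome"] == 5) & (gs.snps["bp"] == locus_bp), "snp_id"
        ].iloc[0]
        grid = list(dict.fromkeys(gs.snps["snp_id"].iloc[::25].tolist() + [focal]))
        res = scan.run(snp_ids=grid)
        ok = res.ok()
        best = ok.loc[ok["p"].idxmin()]
        # carriers share multi-megabase ROH, so the signal is a region:
        # the top term must be a negative effect in the planted locus's
        # LD neighbourhood
        assert best["chromosome"] == 5
        assert abs(best["bp"] - locus_bp) <= 5_000_000
        assert best["estimate"] < 0
        focal_rows = ok[(ok["snp_id"] == focal) & (ok["term"] == "B")]
        assert len(focal_rows) == 1 and focal_rows["estimate"].iloc[0] < 0

    def test_permuted_survival_rarely_significant(self):
        gs, segs, surv, lengths, _ = drop_dataset(seed=31, n_chrom=4)
        rng = np.random.default_rng(0)
        surv = surv.copy()
        surv["survived"] = rng.permutation(surv["survived"].to_numpy())
        scan = RohStatusScan(surv, gs, segs, lengths, n_pcs=3)
        res = scan.run(snp_ids=gs.snps["snp_id"].iloc[::40])
        ok = res.ok()
        eff = effective_tests(gs)
        thr = significance_threshold(eff)
        assert (ok["p"] < thr).sum() <= max(2, int(0.05 * len(ok)))

    def test_vc_modes_agree_roughly(self):
        gs, segs, surv, lengths, _ = drop_dataset(seed=12, n_chrom=4)
        ids = gs.snps["snp_id"].iloc[100:2100:400]
        fast = RohStatusScan(surv, gs, segs, lengths, n_pcs=3, vc="null-fit").run(snp_ids=ids)
        slow = RohStatusScan(surv, gs, segs, lengths, n_pcs=3, vc="per-snp").run(snp_ids=ids)
        a = fast.ok().set_index(["snp_id", "term"])["estimate"]
        b = slow.ok().set_index(["snp_id", "term"])["estimate"]
        common = a.index.intersection(b.index)
        assert len(common) > 0
        np.testing.assert_allclose(a.loc[common], b.loc[common], atol=0.15)

    def test_summary_reports_negative_fraction(self):
        gs, segs, surv, lengths, _ = drop_dataset(seed=8, n_chrom=4)
        res = RohStatusScan(surv, gs, segs, lengths, n_pcs=3).run(
            snp_ids=gs.snps["snp_id"].iloc[::100]
        )
        assert "% negative" in res.summary()
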