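import numpy as np
import pandas as pd
import pytest

from rohdep.landscape import (
    RohDensityModel,
    classify_extremes,
    islands_deserts_bed,
    make_windows,
    snp_heterozygosity,
    snp_roh_density,
)

from conftest import make_snps, random_genotypes


def segments(rows):
    df = pd.DataFrame(rows, columns=["id", "chromosome", "start_bp", "end_bp"])
    df["n_snps"] = 50
    df["n_het"] = 0
    df["length_kb"] = (df["end_bp"] - df["start_bp"] + 1) / 1000
    return df


class TestSnpRohDensity:
    def test_no_segments_all_zero(self):
        snps = make_snps(20)
        assert (snp_roh_density(segments([]), snps, 10) == 0).all()

    def test_single_genomewide_segment(self):
        snps = make_snps(20)
        seg = segments([("a", 1, 1, snps["bp"].max())])
        np.testing.assert_allclose(snp_roh_density(seg, snps, 1), 1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_point_in_interval_counting(self, seed):
        rng = np.random.default_rng(seed)
        snps = make_snps(100)
        rows = []
        for i in range(12):
            start = int(rng.integers(1, 2_000_000))
            rows.append((f"i{i}", 1, start, start + int(rng.integers(1000, 800_000))))
        seg = segments(rows)
        dens = snp_roh_density(seg, snps, 12)
        for j, bp in enumerate(snps["bp"]):
            count = sum(1 for r in rows if r[2] <= bp <= r[3])
            assert dens[j] == pytest.approx(count / 12)


class TestMakeWindows:
    def test_uniform_density_propagates(self):
        snps = make_snps(100, spacing_bp=10_000)
        win = make_windows(snps, np.full(100, 0.24), np.full(100, 0.3), window_kb=200)
        np.testing.assert_allclose(win["roh_density"], 0.24)
        np.testing.assert_allclose(win["het"], 0.3)

    def test_recomb_rate_arithmetic(self):
        # SNPs spanning 0.64 cM over 0.5 Mb -> 1.28 cM/Mb
        snps = pd.DataFrame(
            {
                "snp_id": ["a", "b"],
                "chromosome": 1,
                "bp": [1, 500_001],
                "cM": [0.0, 0.64],
                "alleleA": "A",
                "alleleB": "B",
            }
        )
        win = make_windows(snps, np.zeros(2), np.zeros(2), window_kb=600)
        assert win["recomb"].iloc[0] == pytest.approx(1.28)

    def test_windows_tile_without_overlap_and_drop_empty(self, rng):
        snps = make_snps(50, spacing_bp=400_000)  # sparse -> some empty windows
        win = make_windows(snps, rng.random(50), rng.random(50), window_kb=500)
        assert (win["n_snps"] > 0).all()
        for _, sub in win.groupby("chromosome"):
            s = sub.sort_values("start_bp")
            assert (s["start_bp"].to_numpy()[1:] > s["end_bp"].to_numpy()[:-1]).all()
            assert ((s["start_bp"] - 1) % 500_000 == 0).all()

    @pytest.mark.parametrize("seed", range(2))
    def test_matches_bruteforce_grouping(self, seed):
        rng = np.random.default_rng(seed)
        snps = make_snps(200, spacing_bp=37_000)
        dens, het = rng.random(200), rng.random(200)
        win = make_windows(snps, dens, het, window_kb=500)
        for _, w in win.iterrows():
            inside = [
                j
                for j, bp in enumerate(snps["bp"])
                if w["start_bp"] <= bp <= w["end_bp"]
            ]
            assert w["n_snps"] == len(inside)
            assert w["roh_density"] == pytest.approx(np.mean(dens[inside]))
            assert w["het"] == pytest.approx(np.mean(het[inside]))


def window_frame(densities, n_snps=50, chromosome=1):
    n = len(densities)
    return pd.DataFrame(
        {
            "chromosome": chromosome,
            "start_bp": 1 + 500_000 * np.arange(n),
            "end_bp": 500_000 * (1 + np.arange(n)),
            "n_snps": n_snps,
            "roh_density": densities,
            "het": 0.3,
            "recomb": 1.0,
        }
    )


class TestClassifyExtremes:
    def test_floor_one_island_one_desert(self, rng):
        win = window_frame(rng.random(200))
        out = classify_extremes(win, q=0.005, min_snps=35)
        assert (out["extreme"] == "island").sum() == 1
        assert (out["extreme"] == "desert").sum() == 1
        assert out.loc[out["extreme"] == "island", "roh_density"].iloc[0] == win["roh_density"].max()

    def test_sparse_windows_discarded(self, rng):
        win = window_frame(rng.random(100))
        win.loc[win["roh_density"].idxmax(), "n_snps"] = 10  # densest window ineligible
        out = classify_extremes(win, min_snps=35)
        island = out[out["extreme"] == "island"]
        assert island["n_snps"].iloc[0] >= 35

    def test_ties_break_by_genomic_order(self):
        win = window_frame(np.full(50, 0.2))
        out = classify_extremes(win)
        assert out.loc[out["extreme"] == "desert", "start_bp"].iloc[0] == 1
        assert out.loc[out["extreme"] == "island", "start_bp"].iloc[0] == out["start_bp"].max()

    def test_invariant_to_row_order(self, rng):
        win = window_frame(rng.random(80))
        shuffled = win.sample(frac=1.0, random_state=1)
        a = classify_extremes(win).sort_values("start_bp")["extreme"].tolist()
        b = classify_extremes(shuffled).sort_values("start_bp")["extreme"].tolist()
        assert a == b

    def test_matches_sort_and_slice(self, rng):
        win = window_frame(rng.random(400))
        out = classify_extremes(win, q=0.01)
        n_ext = int(0.01 * 400)
        ranked = win.sort_values("roh_density")
        assert set(out.loc[out["extreme"] == "desert", "start_bp"]) == set(
            ranked.head(n_ext)["start_bp"]
        )
        assert set(out.loc[out["extreme"] == "island", "start_bp"]) == set(
            ranked.tail(n_ext)["start_bp"]
        )

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError, match="windows"):
            classify_extremes(window_frame(np.array([0.1])), min_snps=35)

    def test_bed_output_zero_based(self, tmp_path, rng):
        win = window_frame(rng.random(60))
        out = classify_extremes(win)
        islands_deserts_bed(out, tmp_path / "x.bed")
        bed = pd.read_csv(tmp_path / "x.bed", sep="\t", header=None)
        assert (bed[1] % 500_000 == 0).all()
        assert ((bed[2] - bed[1]) == 500_000).all()


def simulated_windows(rng, n_chrom=6, per_chrom=60, b_recomb=0.0, b_het=-0.05,
                      sd_chrom=0.02, sd_resid=0.03):
    frames = []
    for c in range(1, n_chrom + 1):
        recomb = rng.gamma(4, 0.3, per_chrom)
        het = rng.uniform(0.1, 0.5, per_chrom)
        zr = (recomb - recomb.mean()) / recomb.std()
        zh = (het - het.mean()) / het.std()
        dens = (
            0.24
            + b_recomb * zr
            + b_het * zh
            + rng.normal(0, sd_chrom)
            + rng.normal(0, sd_resid, per_chrom)
        )
        f = window_frame(dens, chromosome=c)
        f["recomb"] = recomb
        f["het"] = het
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


class TestRohDensityModel:
    def test_null_predictor_has_near_zero_semipartial(self, rng):
        win = simulated_windows(rng, b_recomb=0.0, b_het=-0.06)
        res = RohDensityModel(win).fit(n_boot=0)
        assert res.semipartial_r2["recomb"] == pytest.approx(0.0, abs=0.02)
        assert res.semipartial_r2["het"] > 0.3

    def test_recovers_planted_variance_shares(self):
        rng = np.random.default_rng(5)
        # z-scale slopes chosen so fixed effects explain a known share
        win = simulated_windows(
            rng, n_chrom=10, per_chrom=150, b_recomb=0.03, b_het=-0.05,
            sd_chrom=0.01, sd_resid=0.04,
        )
        res = RohDensityModel(win).fit(n_boot=30, seed=1)
        var_fixed = 0.03**2 + 0.05**2
        expected = var_fixed / (var_fixed + 0.01**2 + 0.04**2)
        assert res.marginal_r2 == pytest.approx(expected, abs=0.07)
        lo, hi = res.bootstrap_ci["marginal_r2"]
        # percentile bootstrap brackets the planted share (point estimate
        # may sit just outside after refit shrinkage)
        assert lo < expected + 0.07 and hi > expected - 0.07 and lo < hi
        assert res.semipartial_r2["het"] > res.semipartial_r2["recomb"] > 0
        assert res.marginal_r2 >= max(res.semipartial_r2.values())

    def test_zero_chromosome_variance_matches_ols(self):
        rng = np.random.default_rng(9)
        win = simulated_windows(rng, n_chrom=8, per_chrom=100, sd_chrom=0.0)
        res = RohDensityModel(win).fit(n_boot=0)
        model = RohDensityModel(win)
        X = np.column_stack(
            [np.ones(len(model.windows)), model._z["recomb"], model._z["het"]]
        )
        ols = np.linalg.lstsq(X, model._y, rcond=None)[0]
        # the chromosome variance estimates at (essentially) zero and the
        # GLS fit collapses to OLS
        assert res.var_chromosome < 1e-4
        np.testing.assert_allclose(res.params.to_numpy(), ols, atol=1e-3)
        assert res.params.iloc[0] == pytest.approx(ols[0], abs=1e-6)

    def test_needs_two_chromosomes(self, rng):
        win = simulated_windows(rng, n_chrom=1)
        with pytest.raises(ValueError, match="chromosomes"):
            RohDensityModel(win)

    def test_summary_mentions_r2(self, rng):
        win = simulated_windows(rng)
        res = RohDensityModel(win).fit(n_boot=5, seed=0)
        assert "marginal R2" in res.summary()


class TestHeterozygosity:
    def test_observed_het_fraction(self, rng):
        g = random_genotypes(rng, n_ind=50, n_snps=30, missing_rate=0.1)
        het = snp_heterozygosity(g)
        j = 0
        col = g.codes[:, j]
        called = col[col != -1]
        assert het[j] == pytest.approx((called == 1).sum() / len(called))
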