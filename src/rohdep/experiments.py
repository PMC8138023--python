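"""Replication-style experiments on synthetic data with known truth.

Each function simulates data under the generative survival/gene-drop
model at a stated scale, runs the corresponding analysis stage, and
returns the recovered quantities.  They are the package's end-to-end
validation harness: parameter recovery for the inbreeding-depression
odds ratio and the inbreeding load, null calibration of the survival
Wald test and of the ROH-status scan, planted-locus detection, and
gene-drop IBD checks.

Problem sizes default to what a single CPU handles in minutes:
~6000 individuals for the survival models (the scale of a long-term
wild-population study) and a 26-chromosome, ~390 Mb genome with a few
hundred study individuals for scan experiments.  Child seeds derive
from one master seed, so every experiment is reproducible end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import RohStatusScan
from .io import GenotypeMatrix
from .pedigree import UNKNOWN
from .roh import RohParams, call_roh
from .simulate import (
    ChromosomeSpec,
    DeleteriousLocus,
    SimConfig,
    TraitModelParams,
    choose_deleterious_site,
    gene_drop,
    make_snp_table,
    simulate_cohort,
    simulate_pedigree,
    simulate_survival,
)
from .survival import AnnualSurvivalModel, PoissonSurvivalModel

#: scan-scale genome: 26 chromosomes x 15 Mb (20 cM) x 600 SNPs, mirroring
#: an autosome count where leaving one chromosome out of the inbreeding
#: covariate still covers ~96% of the genome
SCAN_CHROMOSOMES = [ChromosomeSpec(15.0, 20.0, 600)] * 26

#: sustained small-N_e demography giving mean F_ROH ~ 0.2 in the study
#: generations, like a long-isolated island population
SCAN_DEMOGRAPHY = dict(n_founders=20, n_generations=20, n_per_generation=48)


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


# -- survival-model parameter recovery ------------------------------------

def recover_lamb_odds_ratio(
    n_individuals: int = 6000, n_reps: int = 20, seed: int = 0
) -> dict:
    """Simulate annual survival with the default planted lamb odds ratio
    (0.40 per 10% F_ROH) and refit the mixed model per replicate.

    Returns the per-replicate lamb odds ratios, their median, and the
    planted truth.
    """
    truth = TraitModelParams()
    estimates, n_rows = [], []
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        ind = simulate_cohort(n_individuals, rng)
        surv = simulate_survival(ind, truth, rng=rng)
        froh = ind.set_index("id")["froh"].rename("f_roh")
        res = AnnualSurvivalModel.from_tables(surv, froh).fit()
        estimates.append(res.lamb_froh_or)
        n_rows.append(len(surv))
    return {
        "median_or": float(np.median(estimates)),
        "true_or": float(np.exp(truth.beta_froh)),
        "estimates": estimates,
        "n_individuals": n_individuals,
        "mean_rows": float(np.mean(n_rows)),
    }


def recover_lethal_equivalents(
    n_individuals: int = 6000, n_reps: int = 20, seed: int = 0, true_2b: float = 4.57
) -> dict:
    """Simulate survival under the log-link model with the slope implied
    by ``true_2b`` lethal equivalents and refit the Poisson-log model.

    The implied slope per 10%-unit of F_ROH is -(true_2b) * 0.10 / 2.
    Year/id variances are small on the log scale (survival is bounded by
    1, so large multiplicative year effects would be clipped).
    """
    slope = -true_2b * 0.10 / 2.0
    estimates = []
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        ind = simulate_cohort(n_individuals, rng)
        p = TraitModelParams.null()
        p.beta0 = float(np.log(0.55))
        p.beta_froh = slope
        p.var_capture_year, p.var_birth_year, p.var_id = 0.03, 0.02, 0.02
        surv = simulate_survival(ind, p, link="log", rng=rng)
        froh = ind.set_index("id")["froh"].rename("f_roh")
        res = PoissonSurvivalModel.from_tables(surv, froh).fit()
        estimates.append(res.lethal_equivalents)
    return {
        "median_2b": float(np.median(estimates)),
        "true_2b": true_2b,
        "implied_slope": slope,
        "estimates": estimates,
        "n_individuals": n_individuals,
    }


def wald_null_calibration(
    n_individuals: int = 800, n_reps: int = 200, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Type-I error of the F_ROH Wald test with the inbreeding effects
    simulated as zero (life-history structure and variances kept)."""
    null = TraitModelParams(
        beta_froh=0.0, beta_froh_early=0.0, beta_froh_mid=0.0, beta_froh_late=0.0
    )
    rejections, pvals = 0, []
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        ind = simulate_cohort(n_individuals, rng)
        surv = simulate_survival(ind, null, rng=rng)
        froh = ind.set_index("id")["froh"].rename("f_roh")
        res = AnnualSurvivalModel.from_tables(surv, froh).fit()
        p = float(res.pvalues["froh_c10"])
        pvals.append(p)
        rejections += p < alpha
    return {
        "rejection_rate": rejections / n_reps,
        "n_reps": n_reps,
        "pvalues": pvals,
        "alpha": alpha,
    }


# -- scan experiments ------------------------------------------------------

def _scan_dataset(seed: int, chromosomes=None, demography=None, planted=None):
    """One gene-dropped study population with called ROH and survival."""
    chromosomes = chromosomes or SCAN_CHROMOSOMES
    demography = demography or SCAN_DEMOGRAPHY
    rng = np.random.default_rng(seed)
    cfg = SimConfig(mating_scheme="random", chromosomes=chromosomes, seed=seed, **demography)
    ped = simulate_pedigree(cfg, rng)
    snps = make_snp_table(chromosomes)
    g, truth = gene_drop(ped, snps, cfg, rng)
    segments = call_roh(g, RohParams())
    # study individuals: generations past the inbreeding burn-in
    first_study = cfg.n_generations // 2 - 2
    study = ped[ped["generation"] >= first_study]
    ids = study["id"].astype(str).tolist()
    keep = [g.ids.index(i) for i in ids]
    gs = GenotypeMatrix(ids, g.snps, g.codes[keep])
    segments = segments[segments["id"].astype(str).isin(set(ids))].copy()
    segments["id"] = segments["id"].astype(str)
    ind = pd.DataFrame(
        {
            "id": ids,
            "froh": truth.realised_ibd.loc[study["id"]].to_numpy(),
            "sex": rng.integers(0, 2, len(ids)),
            "twin": (rng.random(len(ids)) < 0.3).astype(int),
        }
    )
    null = TraitModelParams(
        beta_froh=0.0, beta_froh_early=0.0, beta_froh_mid=0.0, beta_froh_late=0.0
    )
    surv = simulate_survival(
        ind,
        null,
        n_years=8,
        deleterious_loci=planted,
        ibd_tracts=truth.ibd_tracts if planted else None,
        genotypes=g if planted else None,
        rng=rng,
    )
    surv["id"] = surv["id"].astype(str)
    lengths = {c + 1: spec.length_mb for c, spec in enumerate(chromosomes)}
    return gs, segments, surv, lengths, truth


def null_scan(n_seeds: int = 8, seed: int = 0, thin: int = 31, n_pcs: int = 7) -> dict:
    """ROH-status scan on null survival (no inbreeding or locus effects)
    pooled over independent populations.

    Returns the pooled fraction of negative estimates and all scan
    p-values for uniformity checks.
    """
    fractions, estimates, pvalues = [], [], []
    for s in _child_seeds(seed, n_seeds):
        gs, segments, surv, lengths, _ = _scan_dataset(s)
        scan = RohStatusScan(surv, gs, segments, lengths, n_pcs=n_pcs, vc="null-fit")
        res = scan.run(snp_ids=gs.snps["snp_id"].iloc[::thin])
        ok = res.ok()
        fractions.append(float((ok["estimate"] < 0).mean()))
        estimates.extend(ok["estimate"].tolist())
        pvalues.extend(ok["p"].tolist())
    estimates = np.asarray(estimates)
    return {
        "fraction_negative": float((estimates < 0).mean()),
        "per_seed_fractions": fractions,
        "n_terms": len(estimates),
        "pvalues": np.asarray(pvalues),
    }


def planted_locus_detection(
    n_reps: int = 10, seed: int = 0, effect: float = -1.5, thin: int = 25
) -> dict:
    """Plant one strongly deleterious recessive locus per replicate (at
    the site with the most homozygous-in-IBD carriers) and test whether
    the scan's top term is a negative effect in its neighbourhood.

    Recovery: smallest-p term on the planted chromosome within 5 Mb of
    the locus with a negative estimate (carriers share multi-megabase
    ROH, so the signal is regional).
    """
    chromosomes = [ChromosomeSpec(25.0, 32.0, 1000)] * 8
    demography = dict(n_founders=20, n_generations=14, n_per_generation=44)
    target_chrom = 5
    recovered, details = 0, []
    for s in _child_seeds(seed, n_reps):
        gs0, _, _, _, truth0 = _scan_dataset(s, chromosomes, demography)
        locus_bp, n_car = choose_deleterious_site(
            gs0, truth0.ibd_tracts, chromosome=target_chrom
        )
        planted = [
            DeleteriousLocus(chromosome=target_chrom, bp=locus_bp, allele=1, effect=effect)
        ]
        gs, segments, surv, lengths, _ = _scan_dataset(s, chromosomes, demography, planted)
        scan = RohStatusScan(surv, gs, segments, lengths, n_pcs=5, vc="null-fit")
        focal = gs.snps.loc[
            (gs.snps["chromosome"] == target_chrom) & (gs.snps["bp"] == locus_bp), "snp_id"
        ].iloc[0]
        grid = list(dict.fromkeys(gs.snps["snp_id"].iloc[::thin].tolist() + [focal]))
        ok = scan.run(snp_ids=grid).ok()
        best = ok.loc[ok["p"].idxmin()]
        hit = (
            best["chromosome"] == target_chrom
            and abs(best["bp"] - locus_bp) <= 5_000_000
            and best["estimate"] < 0
        )
        recovered += bool(hit)
        details.append(
            {
                "locus_bp": locus_bp,
                "n_carriers": n_car,
                "top_snp": best["snp_id"],
                "top_p": float(best["p"]),
                "hit": bool(hit),
            }
        )
    return {"recovery_rate": recovered / n_reps, "n_reps": n_reps, "details": details}


# -- gene-drop validity ----------------------------------------------------

def fullsib_ibd(n_families: int = 2000, seed: int = 0) -> dict:
    """Realised genome fraction IBD in offspring of full-sib matings;
    the pedigree expectation is 0.25.

    Each replicate is an independent family (two founders, two sibs,
    one offspring): offspring of a single realised sib pair share the
    sibs' meioses and are not independent draws from the pedigree
    expectation.
    """
    chromosomes = [ChromosomeSpec(100.0, 100.0, 4)] * 3
    cfg = SimConfig(chromosomes=chromosomes, seed=seed)
    snps = make_snp_table(chromosomes)
    rows, focal = [], []
    next_id = 1
    for _ in range(n_families):
        f1, f2, s1, s2, off = range(next_id, next_id + 5)
        next_id += 5
        rows += [
            {"id": f1, "sire": UNKNOWN, "dam": UNKNOWN},
            {"id": f2, "sire": UNKNOWN, "dam": UNKNOWN},
            {"id": s1, "sire": f1, "dam": f2},
            {"id": s2, "sire": f1, "dam": f2},
            {"id": off, "sire": s1, "dam": s2},
        ]
        focal.append(off)
    ped = pd.DataFrame(rows)
    _, truth = gene_drop(ped, snps, cfg, np.random.default_rng(seed))
    vals = truth.realised_ibd.loc[focal]
    return {"mean_ibd": float(vals.mean()), "n": n_families}


def mrca_tract_lengths(g: int, n_reps: int = 500, seed: int = 0, length_cm: float = 500.0) -> dict:
    """Mean IBD tract length (cM) for haplotype loops whose MRCA sits
    ``g`` generations back; theory: exponential with mean 100/(2g) cM,
    shortened slightly by chromosome-end truncation.

    g=2 is a full-sib loop, g=3 a first-cousin loop, and deeper loops
    extend each branch by one unrelated-mate generation.
    """
    rows, focal = [], []
    next_id = 1
    for _ in range(n_reps):  # independent loops
        f1, f2 = next_id, next_id + 1
        next_id += 2
        rows += [
            {"id": f1, "sire": UNKNOWN, "dam": UNKNOWN},
            {"id": f2, "sire": UNKNOWN, "dam": UNKNOWN},
        ]
        left, right = next_id, next_id + 1
        rows += [
            {"id": left, "sire": f1, "dam": f2},
            {"id": right, "sire": f1, "dam": f2},
        ]
        next_id += 2
        for _g in range(g - 2):  # extend both branches with unrelated mates
            for branch in ("left", "right"):
                mate = next_id
                rows.append({"id": mate, "sire": UNKNOWN, "dam": UNKNOWN})
                next_id += 1
                parent = left if branch == "left" else right
                rows.append({"id": next_id, "sire": parent, "dam": mate})
                if branch == "left":
                    left = next_id
                else:
                    right = next_id
                next_id += 1
        rows.append({"id": next_id, "sire": left, "dam": right})
        focal.append(next_id)
        next_id += 1
    focal_start = min(focal)
    focal_set = set(focal)
    ped = pd.DataFrame(rows)
    chromosomes = [ChromosomeSpec(length_cm, length_cm, 4)]
    cfg = SimConfig(chromosomes=chromosomes, seed=seed)
    snps = make_snp_table(chromosomes)
    _, truth = gene_drop(ped, snps, cfg, np.random.default_rng(seed))
    tr = truth.ibd_tracts
    tr = tr[tr["id"].isin(focal_set)]
    lengths = (tr["end_cm"] - tr["start_cm"]).to_numpy()
    return {
        "mean_cm": float(lengths.mean()) if len(lengths) else np.nan,
        "expected_cm": 100.0 / (2 * g),
        "n_tracts": int(len(lengths)),
    }
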