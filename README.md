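# rohdep

Runs of homozygosity (ROH), genomic inbreeding and inbreeding
depression in annual survival, as a tested, reusable Python pipeline.

Wild-population genomicists studying inbreeding depression face a
standard chain of analyses: call ROH from SNP-array genotypes, turn
them into individual inbreeding coefficients F_ROH, characterise where
ROH sit in the genome, fit mixed models of annual survival on F_ROH,
convert the inbreeding slope into lethal equivalents, and scan the
genome for the loci behind the depression.  `rohdep` implements that
chain end to end, together with a gene-drop simulator that generates
data with known truth so every stage can be validated.

## What it computes

**ROH calling** — a scanning-window caller: a window of `window_snp`
consecutive SNPs qualifies if it has at most `window_het` heterozygotes
and `window_missing` missing calls; SNPs supported by at least
`hit_threshold` of their overlapping windows form candidate runs, which
are split at inter-SNP gaps over `max_gap_kb`, trimmed to homozygous
ends, and kept if they pass the SNP-count (`min_snp`), length
(`min_kb`), density (`density_kb_per_snp`) and heterozygote
(`segment_het`) filters.  Defaults: 50-SNP windows, ≥ 50 SNPs and
≥ 1200 Kb per segment, ≤ 300 Kb gaps, ≤ 200 Kb/SNP, ≤ 2 heterozygotes.

**Inbreeding coefficients** — F_ROH = total ROH length / genome length
(default 2452 Mb of autosomes), per-chromosome leave-one-out variants,
and ROH length classes indexed by time to the most recent common
ancestor: an IBD tract coalescing g generations ago has expected length
(100 / 2g) cM, converted at 1.28 cM/Mb, so g = 32, 16, 8, 2 map to
1.2, 2.4, 4.9 and 19.5 Mb.

**ROH landscape** — population ROH density (fraction of individuals
with an ROH at each SNP), heterozygosity and recombination rate in
500 Kb windows; the top/bottom 0.5 % of windows are ROH islands and
deserts; and a linear mixed model `density ~ z(recomb) + z(het) +
(1 | chromosome)` decomposed into marginal and semi-partial R² with
parametric-bootstrap intervals.

**Survival models** — a binomial-logit mixed model of annual survival

    logit Pr(surv) = b0 + F_c10 b1 + stage + sex + twin + F_c10 x stage
                     + a_capture_year + a_birth_year + a_id [+ u_ped]

with F_c10 the mean-centred F_ROH scaled ×10 (coefficients read per
10 % inbreeding increase), lamb as reference stage and an optional
pedigree ("animal-model") term u_ped ~ N(0, A σ²_A) through the
Cholesky factor of the additive relationship matrix.  Fitting is
Laplace-approximate maximum likelihood (no external mixed-model
dependency); estimates are reported as odds ratios with Wald intervals.
A simplified Poisson-log refit yields diploid lethal equivalents
2B = −(b_F)/0.10 × 2.

**ROH-status association scan** — per SNP, a binomial mixed model of
survival on two allele-specific ROH-status predictors (allele A or B
homozygous *and* inside an ROH), controlling for the additive dosage,
leave-one-chromosome-out F_ROH, age, age², sex, twin and the top
principal components of the variance-standardised genomic relationship
matrix, with capture-year/birth-year/id random intercepts.  Sign
enrichment of the per-SNP estimates is tested with an exact binomial
test and logistic models of direction on |estimate| and p-value.  The
genome-wide threshold is α / (2 × n_eff), where n_eff is the
eigenvalue-based effective number of independent tests computed from
blocks of the composite-LD (genotype-code) correlation matrix.

**Synthetic data** — multi-generation pedigrees (random or
full-sib-enriched mating), gene drop of labelled founder haplotypes
with Poisson recombination on the cM scale, exact IBD-tract truth,
planted recessive deleterious loci whose penalty applies to
homozygotes inside IBD tracts, and annual survival drawn from the
logistic model above.

## Worked example

```python
import numpy as np
from rohdep import (
    SimConfig, ChromosomeSpec, simulate_pedigree, make_snp_table, gene_drop,
    RohParams, call_roh, froh_table, AnnualSurvivalModel,
)
from rohdep.simulate import TraitModelParams, simulate_survival
import pandas as pd

rng = np.random.default_rng(1)
cfg = SimConfig(n_founders=20, n_generations=12, n_per_generation=60,
                chromosomes=[ChromosomeSpec(25.0, 32.0, 1000)] * 8, seed=1)
ped = simulate_pedigree(cfg, rng)
snps = make_snp_table(cfg.chromosomes)
genotypes, truth = gene_drop(ped, snps, cfg, rng)

segments = call_roh(genotypes, RohParams())
froh = froh_table(segments, genotypes.ids, {c + 1: 25.0 for c in range(8)})
print(len(segments), "ROH;", "mean F_ROH = %.3f" % froh["f_roh"].mean())

ind = pd.DataFrame({"id": genotypes.ids, "froh": truth.realised_ibd.to_numpy(),
                    "sex": rng.integers(0, 2, len(genotypes.ids)),
                    "twin": (rng.random(len(genotypes.ids)) < 0.3).astype(int)})
surv = simulate_survival(ind, TraitModelParams(), rng=rng)
fit = AnnualSurvivalModel.from_tables(surv, froh).fit()
print("lamb OR per 10%% F_ROH = %.3f" % fit.lamb_froh_or)
```

prints

```
1291 ROH; mean F_ROH = 0.074
lamb OR per 10% F_ROH = 0.417
```

about 1300 called ROH across the 680 simulated individuals, a mean
genomic inbreeding coefficient of 0.074 (F_ROH counts only ROH above
1200 Kb, so it undershoots the realised IBD fraction in this
small-founder population), and a fitted lamb-survival odds ratio of
0.417 per 10 % increase in F_ROH — close to the generator's planted
value of 0.40.

The same chain runs from a YAML config on the command line:

```bash
rohdep run config.yaml          # simulate -> callroh -> froh -> landscape -> depression -> gwas
rohdep callroh --bfile data --min-kb 1200 --window-snp 50 ...
```

Each run writes a `manifest.json` with the config echo, seed and
SHA-256 digests of every output, so identical config + seed gives
identical results.

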