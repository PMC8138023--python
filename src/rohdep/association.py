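"""Allele-specific ROH-status genome-wide association scan on annual
survival.

At a diallelic SNP, an ROH consists either of two IBD haplotypes
carrying allele A or two carrying allele B.  For each SNP a binomial
mixed model of annual survival is fitted with two binary ROH-status
predictors (allele A homozygous and inside an ROH; allele B homozygous
and inside an ROH), the additive dosage, the individual's inbreeding
computed from all chromosomes except the focal one, age, age^2, sex,
twin, the top principal components of the variance-standardised
genomic relationship matrix, and capture-year / birth-year / id random
intercepts.  The two ROH-status slopes and their Wald-Z p-values are
the scan output.

Multiple testing uses the eigenvalue-based effective number of
independent tests: blocks of the composite-LD (genotype-code)
correlation matrix are eigendecomposed and each block contributes the
smallest number of top eigenvalues holding >= C (default 0.995) of the
total variance; twice the summed effective number (two tests per
model) Bonferroni-corrects the significance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binomtest

from .glmm import MixedGLM
from .io import MISSING, GenotypeMatrix

SCAN_COLUMNS = [
    "snp_id",
    "chromosome",
    "bp",
    "term",
    "estimate",
    "se",
    "z",
    "p",
    "n_carriers",
    "status",
    "additive_estimate",
]


def encode_roh_status(g: GenotypeMatrix, segments: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per individual x SNP allele-specific ROH status.

    Returns boolean arrays (in_roh_alleleA, in_roh_alleleB): 1 iff the
    genotype is homozygous for that allele AND the SNP lies inside one
    of the individual's ROH.  Heterozygous or missing genotypes are
    (0, 0); the two flags are never both 1.
    """
    known = set(map(str, g.ids))
    for ind in segments["id"].astype(str).unique():
        if ind not in known:
            raise ValueError(f"individual {ind!r} has segments but no genotypes")
    covered = np.zeros(g.codes.shape, dtype=bool)
    idx_of = {ind: i for i, ind in enumerate(map(str, g.ids))}
    for chrom, sub in g.snps.groupby("chromosome", sort=False):
        cols = sub.index.to_numpy()
        bp = sub["bp"].to_numpy()
        seg = segments[segments["chromosome"] == chrom]
        for row in seg.itertuples():
            i = idx_of[str(row.id)]
            j0, j1 = np.searchsorted(bp, [row.start_bp, row.end_bp + 1])
            covered[i, cols[j0:j1]] = True
    in_a = covered & (g.codes == 0)
    in_b = covered & (g.codes == 2)
    return in_a, in_b


def grm_pcs(g: GenotypeMatrix, k: int = 7) -> np.ndarray:
    """Top-k principal components of the variance-standardised genomic
    relationship matrix.

    Genotypes are centred by 2p and scaled by sqrt(2p(1-p)) per SNP
    (allele frequencies in-sample; missing entries contribute 0), the
    relationship matrix is their cross-product over the SNP count, and
    the eigenvectors of the k largest eigenvalues are returned with the
    largest-magnitude loading of each made positive.
    """
    if k > g.n_individuals:
        raise ValueError(f"k={k} exceeds {g.n_individuals} individuals")
    p = g.allele_freq()
    use = np.isfinite(p) & (p > 0) & (p < 1)
    codes = g.codes[:, use].astype(float)
    pj = p[use]
    z = (codes - 2 * pj) / np.sqrt(2 * pj * (1 - pj))
    z[g.codes[:, use] == MISSING] = 0.0
    K = (z @ z.T) / use.sum()
    vals, vecs = np.linalg.eigh(K)
    order = np.argsort(vals)[::-1][:k]
    pcs = vecs[:, order]
    for j in range(pcs.shape[1]):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


@dataclass
class EffectiveTests:
    """Effective number of independent tests and the resulting
    Bonferroni threshold inputs."""

    n_eff: int
    n_snps: int
    C: float = 0.995
    tests_per_model: int = 2

    @property
    def n_tests_total(self) -> int:
        return self.tests_per_model * self.n_eff


def effective_tests(
    g: GenotypeMatrix, C: float = 0.995, block_size: int = 1000
) -> EffectiveTests:
    """Eigenvalue-based effective number of independent tests.

    SNPs are processed in consecutive blocks per chromosome; within a
    block the composite-LD correlation matrix (Pearson correlation of
    unphased genotype-code vectors, missing pairwise-deleted) is
    eigendecomposed and the block contributes the smallest k whose top
    eigenvalues sum to >= C of the total.  Constant SNPs contribute zero
    correlation (unit diagonal retained).
    """
    if g.n_snps < 2:
        raise ValueError("need >= 2 SNPs")
    n_eff = 0
    for _, sub in g.snps.groupby("chromosome", sort=True):
        cols = sub.index.to_numpy()
        for lo in range(0, len(cols), block_size):
            block = cols[lo : lo + block_size]
            codes = g.codes[:, block].astype(float)
            codes[g.codes[:, block] == MISSING] = np.nan
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corr = pd.DataFrame(codes).corr().to_numpy()  # pairwise deletion
            np.fill_diagonal(corr, 1.0)
            corr = np.nan_to_num(corr, nan=0.0)
            np.fill_diagonal(corr, 1.0)
            vals = np.sort(np.linalg.eigvalsh(corr))[::-1]
            total = vals.sum()
            csum = np.cumsum(vals)
            k = int(np.searchsorted(csum, C * total) + 1)
            n_eff += min(k, len(block))
    return EffectiveTests(n_eff=n_eff, n_snps=g.n_snps, C=C)


def significance_threshold(
    eff: EffectiveTests | int, alpha: float = 0.05, tests_per_model: int = 2
) -> float:
    """Bonferroni threshold alpha / (tests_per_model x n_eff)."""
    n_eff = eff.n_eff if isinstance(eff, EffectiveTests) else int(eff)
    if n_eff < 1:
        raise ValueError("n_eff must be >= 1")
    return alpha / (tests_per_model * n_eff)


class RohStatusScan:
    """Per-SNP mixed models of survival on allele-specific ROH status.

    Parameters
    ----------
    frame : DataFrame
        Survival rows with ``survived, year, birth_year, id, age, sex,
        twin`` (ids must match genotype ids as strings).
    genotypes : GenotypeMatrix
    segments : DataFrame
        Called ROH for the same individuals.
    chromosome_lengths_mb : dict
        chromosome -> Mb, for the leave-one-chromosome-out inbreeding
        covariate.
    n_pcs : int
        Principal components of the standardised relationship matrix
        entered as fixed effects in place of a pedigree term.
    min_carriers : int
        ROH-status terms with fewer carriers among analysis rows are
        dropped and flagged (guards against separation).
    vc : {"null-fit", "per-snp"}
        Variance components fixed at the no-SNP-terms null fit (fast,
        default) or re-estimated per SNP.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        genotypes: GenotypeMatrix,
        segments: pd.DataFrame,
        chromosome_lengths_mb: dict,
        n_pcs: int = 7,
        min_carriers: int = 5,
        vc: str = "null-fit",
    ):
        if vc not in ("null-fit", "per-snp"):
            raise ValueError(f"unknown vc mode {vc!r}")
        self.frame = frame.reset_index(drop=True)
        self.g = genotypes
        self.segments = segments
        self.chrom_lengths = chromosome_lengths_mb
        self.n_pcs = n_pcs
        self.min_carriers = min_carriers
        self.vc = vc

        from .froh import f_roh_excluding

        idx_of = {ind: i for i, ind in enumerate(map(str, genotypes.ids))}
        row_ids = self.frame["id"].astype(str)
        missing = sorted(set(row_ids) - set(idx_of))
        if missing:
            raise ValueError(f"survival rows without genotypes: {missing[:10]}")
        self._row_ind = row_ids.map(idx_of).to_numpy()

        # leave-one-chromosome-out inbreeding, one value per individual
        # per chromosome, then mean-centred within the analysis rows
        self._froh_excl = {}
        by_id = dict(tuple(segments.groupby("id", sort=False))) if len(segments) else {}
        empty = segments.iloc[0:0]
        for c in sorted(chromosome_lengths_mb):
            vals = np.array(
                [
                    f_roh_excluding(by_id.get(i, empty), c, chromosome_lengths_mb)
                    for i in genotypes.ids
                ]
            )
            self._froh_excl[c] = vals

        self._in_a, self._in_b = encode_roh_status(genotypes, segments)
        self._pcs = grm_pcs(genotypes, n_pcs) if n_pcs > 0 else np.zeros((genotypes.n_individuals, 0))

        f = self.frame
        base = [
            np.ones(len(f)),
            np.zeros(len(f)),  # froh_mod, filled per chromosome
            f["age"].to_numpy(dtype=float),
            f["age"].to_numpy(dtype=float) ** 2,
            f["sex"].to_numpy(dtype=float),
            f["twin"].to_numpy(dtype=float),
        ]
        base += [self._pcs[self._row_ind, j] for j in range(self._pcs.shape[1])]
        self._base = np.column_stack(base)
        self._base_names = ["const", "froh_mod", "age", "age2", "sex", "twin"] + [
            f"pc{j + 1}" for j in range(self._pcs.shape[1])
        ]
        self._groups = {
            "capture_year": f["year"].to_numpy(),
            "birth_year": f["birth_year"].to_numpy(),
            "id": f["id"].to_numpy(),
        }
        self._y = f["survived"].to_numpy(dtype=float)

    def _null_sds(self) -> np.ndarray:
        X = self._base.copy()
        # genome-wide leave-out covariate averaged over chromosomes is a
        # fine anchor for the null variance components
        mean_excl = np.mean([v for v in self._froh_excl.values()], axis=0)
        X[:, 1] = 10.0 * (mean_excl - mean_excl.mean())[self._row_ind]
        m = MixedGLM(self._y, X, self._groups, family="binomial", x_names=self._base_names)
        return m.fit().sd_components.to_numpy()

    def run(self, snp_ids=None) -> "ScanResults":
        """Fit the per-SNP models; returns one row per ROH-status term.

        ``snp_ids`` restricts the scan to a subset (e.g. a thinned grid).
        """
        snps = self.g.snps
        if snp_ids is not None:
            wanted = set(snp_ids)
            snp_rows = snps[snps["snp_id"].isin(wanted)]
        else:
            snp_rows = snps
        fixed_sd = self._null_sds() if self.vc == "null-fit" else None

        records = []
        for j, snp in zip(snp_rows.index, snp_rows.itertuples()):
            chrom = snp.chromosome
            excl = self._froh_excl[chrom]
            froh_mod = 10.0 * (excl - excl.mean())[self._row_ind]
            a = self._in_a[self._row_ind, j].astype(float)
            b = self._in_b[self._row_ind, j].astype(float)
            dose = self.g.codes[self._row_ind, j].astype(float)
            called = dose != MISSING
            if not called.all():
                dose = np.where(called, dose, dose[called].mean() if called.any() else 0.0)

            # carriers counted as individuals, not rows
            carriers_a = len(np.unique(self.frame["id"][a > 0]))
            carriers_b = len(np.unique(self.frame["id"][b > 0]))
            use_a = carriers_a >= self.min_carriers
            use_b = carriers_b >= self.min_carriers

            cols, col_names = [self._base], [*self._base_names]
            if use_a:
                cols.append(a[:, None])
                col_names.append("roh_a")
            if use_b:
                cols.append(b[:, None])
                col_names.append("roh_b")
            cols.append(dose[:, None])
            col_names.append("additive")
            X = np.column_stack(cols)
            X[:, 1] = froh_mod
            status = "ok"
            try:
                m = MixedGLM(self._y, X, self._groups, family="binomial", x_names=col_names)
                res = m.fit(fixed_sd=fixed_sd) if fixed_sd is not None else m.fit()
                if res.separation_suspected:
                    status = "separation_suspected"
                elif not res.converged:
                    status = "non_converged"
            except Exception as exc:  # keep scanning
                res = None
                status = f"error:{type(exc).__name__}"
            for term, label, used, carriers in [
                ("roh_a", "A", use_a, carriers_a),
                ("roh_b", "B", use_b, carriers_b),
            ]:
                if res is None or not used:
                    records.append(
                        {
                            "snp_id": snp.snp_id,
                            "chromosome": chrom,
                            "bp": snp.bp,
                            "term": label,
                            "estimate": np.nan,
                            "se": np.nan,
                            "z": np.nan,
                            "p": np.nan,
                            "n_carriers": carriers,
                            "status": status if res is None else "dropped_few_carriers",
                            "additive_estimate": np.nan
                            if res is None
                            else float(res.params["additive"]),
                        }
                    )
                else:
                    records.append(
                        {
                            "snp_id": snp.snp_id,
                            "chromosome": chrom,
                            "bp": snp.bp,
                            "term": label,
                            "estimate": float(res.params[term]),
                            "se": float(res.bse[term]),
                            "z": float(res.zvalues[term]),
                            "p": float(res.pvalues[term]),
                            "n_carriers": carriers,
                            "status": status,
                            "additive_estimate": float(res.params["additive"]),
                        }
                    )
        return ScanResults(pd.DataFrame(records, columns=SCAN_COLUMNS))


@dataclass
class ScanResults:
    """Per-SNP ROH-status scan output (one row per allele term)."""

    table: pd.DataFrame

    def ok(self) -> pd.DataFrame:
        """Rows with a usable estimate."""
        return self.table[self.table["status"].isin(["ok"]) & self.table["estimate"].notna()]

    def top_hits(self, threshold: float) -> pd.DataFrame:
        ok = self.ok()
        return ok[ok["p"] < threshold].sort_values("p")

    def sign_enrichment(self) -> "SignEnrichment":
        return sign_enrichment(self.table)

    def summary(self) -> str:
        ok = self.ok()
        return (
            f"ROH-status scan: {self.table['snp_id'].nunique()} SNPs, "
            f"{len(ok)} usable allele terms, "
            f"{(ok['estimate'] < 0).mean() * 100:.1f}% negative estimates"
        )


@dataclass
class SignEnrichment:
    """Direction enrichment of ROH-status effects."""

    n_negative: int
    n_positive: int
    binomial_p: float
    estimate_glm_coef: float = np.nan
    estimate_glm_ci: tuple = (np.nan, np.nan)
    pvalue_glm_coef: float = np.nan
    pvalue_glm_ci: tuple = (np.nan, np.nan)

    @property
    def fraction_negative(self) -> float:
        return self.n_negative / (self.n_negative + self.n_positive)

    def summary(self) -> str:
        return (
            f"{self.n_negative} negative vs {self.n_positive} positive ROH-status "
            f"estimates (exact binomial p = {self.binomial_p:.3g}); "
            f"sign ~ |estimate| log-OR {self.estimate_glm_coef:.3f} "
            f"{self.estimate_glm_ci}; sign ~ p log-OR {self.pvalue_glm_coef:.3f} "
            f"{self.pvalue_glm_ci}"
        )


def sign_enrichment(results: pd.DataFrame) -> SignEnrichment:
    """Two-sided exact binomial test of negative vs positive ROH-status
    estimates against 0.5, plus logistic models of effect direction
    (negative = 1) on the absolute estimate and on the p-value."""
    ok = results[results["estimate"].notna() & (results["status"] == "ok")]
    est = ok["estimate"].to_numpy()
    if len(est) < 2:
        raise ValueError("need >= 2 non-dropped estimates")
    neg = est < 0
    n_neg, n_pos = int(neg.sum()), int((~neg).sum())
    p_binom = exact_binomial_p(n_neg, n_neg + n_pos)

    out = SignEnrichment(n_negative=n_neg, n_positive=n_pos, binomial_p=p_binom)
    y = neg.astype(float)
    for attr, x in [("estimate", np.abs(est)), ("pvalue", ok["p"].to_numpy())]:
        if np.ptp(x) == 0 or y.min() == y.max():
            continue
        X = sm.add_constant(x)
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            lo, hi = fit.conf_int()[1]
            setattr(out, f"{attr}_glm_coef", float(fit.params[1]))
            setattr(out, f"{attr}_glm_ci", (float(lo), float(hi)))
        except Exception:
            continue
    return out


def exact_binomial_p(k: int, n: int, p: float = 0.5) -> float:
    """Two-sided exact binomial test p-value."""
    return float(binomtest(k, n, p, alternative="two-sided").pvalue)
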