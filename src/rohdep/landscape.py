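"""The ROH landscape: windowed population ROH density, heterozygosity
and recombination rate; island/desert classification; and a linear
mixed-model decomposition of density variance.

Population ROH density at a SNP is the proportion of individuals with
an ROH overlapping its position.  Windows are non-overlapping tiles
(default 500 Kb) from bp 1 on each chromosome; per-window values are
means over contained SNPs, and window recombination rate is the cM span
over the Mb span of the first and last SNP inside the window.  The top
and bottom 0.5% of windows by density (after discarding SNP-sparse
windows) are ROH islands and deserts.

:class:`RohDensityModel` regresses window density on z-standardised
recombination rate and heterozygosity with a chromosome random
intercept (REML via statsmodels MixedLM), and reports the marginal R2
(fixed-effect variance over total variance) plus semi-partial R2 per
predictor (marginal R2 drop when the predictor is removed), with
percentile confidence intervals from a parametric bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM

from .io import MISSING, GenotypeMatrix

WINDOW_COLUMNS = ["chromosome", "start_bp", "end_bp", "n_snps", "roh_density", "het", "recomb"]


def snp_roh_density(segments: pd.DataFrame, snps: pd.DataFrame, n_individuals: int) -> np.ndarray:
    """Fraction of individuals whose ROH cover each SNP position.

    Segments of one individual are disjoint, so counting covering
    segments counts individuals.
    """
    out = np.zeros(len(snps))
    if len(segments) == 0 or n_individuals == 0:
        return out
    for chrom, sub in snps.groupby("chromosome", sort=False):
        seg = segments[segments["chromosome"] == chrom]
        if len(seg) == 0:
            continue
        starts = np.sort(seg["start_bp"].to_numpy())
        ends = np.sort(seg["end_bp"].to_numpy())
        bp = sub["bp"].to_numpy()
        n_cover = np.searchsorted(starts, bp, side="right") - np.searchsorted(ends, bp, side="left")
        out[sub.index.to_numpy()] = n_cover / n_individuals
    return out


def snp_heterozygosity(g: GenotypeMatrix) -> np.ndarray:
    """Observed heterozygosity per SNP: fraction heterozygous among
    called genotypes."""
    called = g.codes != MISSING
    het = g.codes == 1
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, het.sum(axis=0) / n, np.nan)


def make_windows(
    snps: pd.DataFrame,
    roh_density: np.ndarray,
    het: np.ndarray,
    window_kb: float = 500.0,
) -> pd.DataFrame:
    """Tile each chromosome from bp 1 in ``window_kb`` steps and average
    per-SNP density and heterozygosity over contained SNPs.

    Window recombination rate is (cM of last SNP - cM of first SNP) /
    (Mb span of those SNPs); single-SNP windows get 0.  Windows without
    SNPs are dropped.
    """
    w_bp = int(window_kb * 1000)
    df = snps.copy()
    df["_density"] = np.asarray(roh_density, dtype=float)
    df["_het"] = np.asarray(het, dtype=float)
    df["_win"] = (df["bp"] - 1) // w_bp
    rows = []
    for (chrom, win), sub in df.groupby(["chromosome", "_win"], sort=True):
        bp_first, bp_last = sub["bp"].iloc[0], sub["bp"].iloc[-1]
        cm_span = sub["cM"].iloc[-1] - sub["cM"].iloc[0]
        mb_span = (bp_last - bp_first) / 1e6
        rows.append(
            {
                "chromosome": chrom,
                "start_bp": int(win) * w_bp + 1,
                "end_bp": (int(win) + 1) * w_bp,
                "n_snps": len(sub),
                "roh_density": sub["_density"].mean(),
                "het": sub["_het"].mean(),
                "recomb": cm_span / mb_span if mb_span > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def classify_extremes(
    windows: pd.DataFrame, q: float = 0.005, min_snps: int = 35
) -> pd.DataFrame:
    """Label the top/bottom ``q`` fraction of eligible windows by ROH
    density as islands/deserts.

    Windows with fewer than ``min_snps`` SNPs are discarded before
    ranking; ``max(1, floor(q * N))`` windows are taken at each extreme.
    Ties break by (chromosome, start_bp) order, so the output is
    invariant to input row order.
    """
    eligible = windows[windows["n_snps"] >= min_snps].copy()
    if len(eligible) < 2:
        raise ValueError(f"only {len(eligible)} windows with >= {min_snps} SNPs")
    n_ext = max(1, int(np.floor(q * len(eligible))))
    eligible = eligible.sort_values(
        ["roh_density", "chromosome", "start_bp"], kind="mergesort"
    ).reset_index(drop=True)
    out = windows.copy()
    out["extreme"] = "none"
    key = ["chromosome", "start_bp"]
    deserts = eligible.head(n_ext)[key]
    islands = eligible.tail(n_ext)[key]
    out = out.merge(deserts.assign(_d=True), on=key, how="left")
    out = out.merge(islands.assign(_i=True), on=key, how="left")
    out.loc[out["_d"].notna(), "extreme"] = "desert"
    out.loc[out["_i"].notna(), "extreme"] = "island"
    return out.drop(columns=["_d", "_i"])


@dataclass
class RohDensityResults:
    """REML fit of window ROH density on recombination and heterozygosity."""

    params: pd.Series
    bse: pd.Series
    var_chromosome: float
    var_residual: float
    marginal_r2: float
    semipartial_r2: dict
    bootstrap_ci: dict = field(default_factory=dict)
    singular: bool = False
    n_windows: int = 0

    def summary(self) -> str:
        lines = [
            f"RohDensityModel: {self.n_windows} windows, "
            f"chromosome var {self.var_chromosome:.5f}, residual var {self.var_residual:.5f}"
            + ("  [singular fit]" if self.singular else ""),
            pd.DataFrame({"estimate": self.params, "se": self.bse}).to_string(
                float_format=lambda v: f"{v: .4f}"
            ),
            f"marginal R2 = {self.marginal_r2:.3f}"
            + (
                f"  CI {self.bootstrap_ci['marginal_r2']}"
                if "marginal_r2" in self.bootstrap_ci
                else ""
            ),
        ]
        for k, v in self.semipartial_r2.items():
            ci = self.bootstrap_ci.get(f"semipartial_{k}")
            lines.append(f"semi-partial R2 ({k}) = {v:.3f}" + (f"  CI {ci}" if ci else ""))
        return "\n".join(lines)


class RohDensityModel:
    """Linear mixed model of window ROH density.

    density ~ z(recomb) + z(het) + (1 | chromosome), REML.

    Parameters
    ----------
    windows : DataFrame
        Output of :func:`make_windows` (optionally pre-filtered).
    """

    PREDICTORS = ("recomb", "het")

    def __init__(self, windows: pd.DataFrame):
        w = windows.dropna(subset=["roh_density", "het", "recomb"]).reset_index(drop=True)
        if w["chromosome"].nunique() < 2:
            raise ValueError("need >= 2 chromosomes for the chromosome random intercept")
        if len(w) < 10:
            raise ValueError("need >= 10 windows")
        self.windows = w
        self._y = w["roh_density"].to_numpy()
        self._z = {}
        for p in self.PREDICTORS:
            x = w[p].to_numpy()
            sd = x.std(ddof=0)
            self._z[p] = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        self._groups = w["chromosome"].to_numpy()

    def _fit_reml(self, y: np.ndarray, predictors) -> tuple[np.ndarray, float, float, object]:
        X = np.column_stack([np.ones(len(y))] + [self._z[p] for p in predictors])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y, X, groups=self._groups).fit(reml=True)
        beta = res.fe_params
        var_group = float(np.asarray(res.cov_re)[0, 0])
        var_resid = float(res.scale)
        return np.asarray(beta), var_group, var_resid, res

    def _marginal_r2(self, y: np.ndarray, predictors) -> float:
        beta, var_g, var_e, _ = self._fit_reml(y, predictors)
        X = np.column_stack([np.ones(len(y))] + [self._z[p] for p in predictors])
        var_f = float(np.var(X @ beta))
        return var_f / (var_f + var_g + var_e)

    def fit(self, n_boot: int = 100, seed: int = 0, alpha: float = 0.05) -> RohDensityResults:
        """REML fit with semi-partial R2 and a seeded parametric
        bootstrap (``n_boot`` refits) for percentile CIs."""
        beta, var_g, var_e, res = self._fit_reml(self._y, self.PREDICTORS)
        X = np.column_stack([np.ones(len(self._y))] + [self._z[p] for p in self.PREDICTORS])
        var_f = float(np.var(X @ beta))
        marg = var_f / (var_f + var_g + var_e)
        semi = {}
        for p in self.PREDICTORS:
            others = [q for q in self.PREDICTORS if q != p]
            semi[p] = marg - self._marginal_r2(self._y, others)
        names = ["const"] + list(self.PREDICTORS)
        singular = var_g < 1e-10 or not res.converged

        ci: dict = {}
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            _, levels = pd.factorize(self._groups, sort=True)
            gcodes = pd.factorize(self._groups, sort=True)[0]
            stats = {"marginal_r2": []}
            for p in self.PREDICTORS:
                stats[f"semipartial_{p}"] = []
            for _ in range(n_boot):
                b = rng.normal(0, np.sqrt(max(var_g, 0.0)), size=len(levels))
                ystar = X @ beta + b[gcodes] + rng.normal(0, np.sqrt(var_e), size=len(self._y))
                try:
                    m_full = self._marginal_r2(ystar, self.PREDICTORS)
                    stats["marginal_r2"].append(m_full)
                    for p in self.PREDICTORS:
                        others = [q for q in self.PREDICTORS if q != p]
                        stats[f"semipartial_{p}"].append(m_full - self._marginal_r2(ystar, others))
                except Exception:  # singular bootstrap refit
                    continue
            qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]
            for k, v in stats.items():
                if v:
                    lo, hi = np.percentile(v, qs)
                    ci[k] = (float(lo), float(hi))

        return RohDensityResults(
            params=pd.Series(beta, index=names),
            bse=pd.Series(np.asarray(res.bse_fe), index=names),
            var_chromosome=var_g,
            var_residual=var_e,
            marginal_r2=marg,
            semipartial_r2=semi,
            bootstrap_ci=ci,
            singular=singular,
            n_windows=len(self._y),
        )


def islands_deserts_bed(windows: pd.DataFrame, path) -> None:
    """Write island/desert windows as BED (0-based half-open)."""
    lab = windows[windows["extreme"] != "none"]
    bed = pd.DataFrame(
        {
            "chrom": lab["chromosome"],
            "start": lab["start_bp"] - 1,
            "end": lab["end_bp"],
            "name": lab["extreme"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
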