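"""Inbreeding depression in annual survival.

:class:`AnnualSurvivalModel` fits the binomial-logit mixed ("animal")
model of annual survival:

    logit Pr(surv) = b0 + F(c10)*b1 + stage offsets + sex + twin
                     + F(c10) x stage interactions
                     + a_capture_year + a_birth_year + a_id [+ u_ped]

where F(c10) is the genomic inbreeding coefficient mean-centred and
scaled by 10 so coefficients read per 10% increase in inbreeding; the
life-stage reference is lamb.  The optional pedigree additive effect
u_ped ~ N(0, A sigma_A^2) enters through the Cholesky factor of the
additive relationship matrix A; when its variance estimates at the
boundary, the fit degrades gracefully to the three-intercept model and
says so.  Estimation is Laplace-approximate ML; intervals are Wald on
the link scale and exponentiate to odds-ratio intervals.

:class:`PoissonSurvivalModel` is the simplified Poisson-log refit
(F, age, age^2, twin, sex; same random structure) whose inbreeding
slope converts to diploid lethal equivalents: 2B = -(b_F)/0.10 * 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .glmm import MixedGLM, MixedGLMResults
from .pedigree import additive_relationship
from .simulate import life_stage_from_age

FIXED_TERMS = [
    "const",
    "froh_c10",
    "early",
    "mid",
    "late",
    "sex",
    "twin",
    "froh_c10:early",
    "froh_c10:mid",
    "froh_c10:late",
]


def prepare_covariates(survival: pd.DataFrame, froh: pd.Series | pd.DataFrame) -> pd.DataFrame:
    """Model frame from a survival table and per-individual F_ROH.

    ``froh`` maps individual id -> F_ROH (a Series, or a DataFrame with
    ``id``/``f_roh`` columns).  Adds ``froh_c10`` = 10 x (F_ROH - mean
    over analysis rows), lamb-reference stage dummies and interaction
    columns.  Raises listing the ids of rows lacking an F_ROH value.
    """
    if isinstance(froh, pd.DataFrame):
        froh = froh.set_index("id")["f_roh"]
    frame = survival.copy()
    frame["froh"] = frame["id"].map(froh)
    if frame["froh"].isna().any():
        missing = sorted(frame.loc[frame["froh"].isna(), "id"].astype(str).unique())
        raise ValueError(f"no F_ROH for individuals: {missing[:10]}")
    if "life_stage" not in frame.columns:
        frame["life_stage"] = life_stage_from_age(frame["age"].to_numpy())
    frame["froh_c10"] = 10.0 * (frame["froh"] - frame["froh"].mean())
    for stage in ("early", "mid", "late"):
        frame[stage] = (frame["life_stage"] == stage).astype(float)
        frame[f"froh_c10:{stage}"] = frame["froh_c10"] * frame[stage]
    frame["const"] = 1.0
    return frame


def pedigree_design(ids: pd.Series, pedigree: pd.DataFrame) -> np.ndarray:
    """Rows of chol(A) mapped to observations, so spherical breeding
    values become a correlated effect with covariance A sigma_A^2."""
    A = additive_relationship(pedigree)
    # small jitter guards Cholesky of a PSD (not strictly PD) A
    L = np.linalg.cholesky(A.to_numpy() + 1e-8 * np.eye(len(A)))
    pos = {ind: k for k, ind in enumerate(A.index)}
    rows = ids.map(pos)
    if rows.isna().any():
        missing = ids[rows.isna()].unique()
        raise ValueError(f"individuals absent from pedigree: {list(missing)[:10]}")
    return L[rows.to_numpy(dtype=int)]


class AnnualSurvivalModel:
    """Binomial-logit mixed model of annual survival on inbreeding.

    Parameters
    ----------
    frame : DataFrame
        Output of :func:`prepare_covariates`; needs ``survived``,
        ``year``, ``birth_year``, ``id`` and the fixed-effect columns.
    pedigree : DataFrame, optional
        id/sire/dam table; enables the additive genetic random effect
        with covariance A sigma_A^2 (on by default when supplied).
    """

    def __init__(self, frame: pd.DataFrame, pedigree: pd.DataFrame | None = None):
        self.frame = frame.reset_index(drop=True)
        self.pedigree = pedigree
        for col in FIXED_TERMS:
            if col not in self.frame.columns:
                raise ValueError(f"model frame lacks column {col!r}; use prepare_covariates")

    @classmethod
    def from_tables(
        cls,
        survival: pd.DataFrame,
        froh: pd.Series | pd.DataFrame,
        pedigree: pd.DataFrame | None = None,
    ) -> "AnnualSurvivalModel":
        return cls(prepare_covariates(survival, froh), pedigree)

    def _design(self) -> tuple[np.ndarray, np.ndarray, dict]:
        f = self.frame
        X = f[FIXED_TERMS].to_numpy(dtype=float)
        groups = {
            "capture_year": f["year"].to_numpy(),
            "birth_year": f["birth_year"].to_numpy(),
            "id": f["id"].to_numpy(),
        }
        return f["survived"].to_numpy(dtype=float), X, groups

    def fit(self, include_pedigree: bool = True, **fit_kw) -> "AnnualSurvivalResults":
        y, X, groups = self._design()
        dense = None
        used_pedigree = False
        if include_pedigree and self.pedigree is not None:
            dense = {"additive": pedigree_design(self.frame["id"], self.pedigree)}
            used_pedigree = True
        m = MixedGLM(y, X, groups, family="binomial", dense_effects=dense, x_names=FIXED_TERMS)
        res = m.fit(**fit_kw)
        note = ""
        if used_pedigree and res.boundary.get("additive"):
            note = (
                "additive genetic variance estimated at the boundary (~0); "
                "refit without the pedigree term"
            )
            m = MixedGLM(y, X, groups, family="binomial", x_names=FIXED_TERMS)
            res = m.fit(**fit_kw)
            used_pedigree = False
        return AnnualSurvivalResults(self, res, used_pedigree=used_pedigree, note=note)


@dataclass
class AnnualSurvivalResults:
    """Fitted annual-survival model; estimates on log-odds and
    odds-ratio scales."""

    model: AnnualSurvivalModel
    glmm: MixedGLMResults
    used_pedigree: bool = False
    note: str = ""

    @property
    def params(self) -> pd.Series:
        return self.glmm.params

    @property
    def bse(self) -> pd.Series:
        return self.glmm.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.glmm.pvalues

    @property
    def variance_components(self) -> pd.Series:
        return self.glmm.variance_components

    @property
    def odds_ratios(self) -> pd.Series:
        """exp(coefficient), exactly."""
        return np.exp(self.glmm.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.glmm.conf_int(alpha)

    def odds_ratio_conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return np.exp(self.glmm.conf_int(alpha))

    @property
    def lamb_froh_or(self) -> float:
        """Odds ratio of lamb annual survival per 10% increase in F_ROH."""
        return float(np.exp(self.glmm.params["froh_c10"]))

    def stage_slopes(self) -> pd.Series:
        """Total F_ROH log-odds slope per life stage."""
        b = self.glmm.params
        return pd.Series(
            {
                "lamb": b["froh_c10"],
                "early": b["froh_c10"] + b["froh_c10:early"],
                "mid": b["froh_c10"] + b["froh_c10:mid"],
                "late": b["froh_c10"] + b["froh_c10:late"],
            }
        )

    def coefficient_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Both scales side by side, for TSV output."""
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "term": self.params.index,
                "log_odds": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "ci_low": ci["lower"].to_numpy(),
                "ci_high": ci["upper"].to_numpy(),
                "odds_ratio": np.exp(self.params.to_numpy()),
                "or_ci_low": np.exp(ci["lower"].to_numpy()),
                "or_ci_high": np.exp(ci["upper"].to_numpy()),
                "p": self.pvalues.to_numpy(),
            }
        )

    def predict(self, grid: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
        """Survival probability with Wald intervals on a covariate grid.

        ``grid`` needs ``froh_c10``, ``life_stage``, ``sex``, ``twin``;
        random effects are at zero and intervals propagate the
        fixed-effect covariance through the inverse logit.
        """
        g = grid.copy()
        for stage in ("early", "mid", "late"):
            g[stage] = (g["life_stage"] == stage).astype(float)
            g[f"froh_c10:{stage}"] = g["froh_c10"] * g[stage]
        g["const"] = 1.0
        X = g[FIXED_TERMS].to_numpy(dtype=float)
        eta, se = self.glmm.predict_linear(X)
        zq = norm.ppf(1 - alpha / 2)
        out = grid.copy()
        out["probability"] = expit(eta)
        out["ci_low"] = expit(eta - zq * se)
        out["ci_high"] = expit(eta + zq * se)
        return out

    def summary(self) -> str:
        parts = [self.glmm.summary()]
        parts.append(f"lamb odds ratio per 10% F_ROH: {self.lamb_froh_or:.3f}")
        if self.note:
            parts.append(f"note: {self.note}")
        return "\n".join(parts)


POISSON_TERMS = ["const", "froh_c10", "age", "age2", "twin", "sex"]


class PoissonSurvivalModel:
    """Simplified Poisson-log survival model for lethal equivalents.

    Fixed effects: F_ROH (centred, x10), age, age^2 (entered raw), twin,
    sex; random intercepts for capture year, birth year and id, plus the
    optional pedigree term.
    """

    def __init__(self, frame: pd.DataFrame, pedigree: pd.DataFrame | None = None):
        self.frame = frame.reset_index(drop=True)
        if "age2" not in self.frame.columns:
            self.frame["age2"] = self.frame["age"].astype(float) ** 2
        self.pedigree = pedigree

    @classmethod
    def from_tables(
        cls,
        survival: pd.DataFrame,
        froh: pd.Series | pd.DataFrame,
        pedigree: pd.DataFrame | None = None,
    ) -> "PoissonSurvivalModel":
        return cls(prepare_covariates(survival, froh), pedigree)

    def fit(self, include_pedigree: bool = True, **fit_kw) -> "LethalEquivalentsResults":
        f = self.frame
        y = f["survived"].to_numpy(dtype=float)
        X = f[POISSON_TERMS].to_numpy(dtype=float)
        groups = {
            "capture_year": f["year"].to_numpy(),
            "birth_year": f["birth_year"].to_numpy(),
            "id": f["id"].to_numpy(),
        }
        dense = None
        if include_pedigree and self.pedigree is not None:
            dense = {"additive": pedigree_design(f["id"], self.pedigree)}
        m = MixedGLM(y, X, groups, family="poisson", dense_effects=dense, x_names=POISSON_TERMS)
        return LethalEquivalentsResults(self, m.fit(**fit_kw))


def lethal_equivalents_from_slope(slope_per_10pct: float) -> float:
    """Diploid lethal equivalents from the Poisson slope per 10%-unit of
    inbreeding: 2B = -(slope)/0.10 * 2."""
    return -slope_per_10pct / 0.10 * 2.0


@dataclass
class LethalEquivalentsResults:
    """Poisson-log fit and the derived inbreeding load."""

    model: PoissonSurvivalModel
    glmm: MixedGLMResults

    @property
    def params(self) -> pd.Series:
        return self.glmm.params

    @property
    def froh_slope(self) -> float:
        return float(self.glmm.params["froh_c10"])

    @property
    def lethal_equivalents(self) -> float:
        """2B, the diploid number of lethal equivalents."""
        return lethal_equivalents_from_slope(self.froh_slope)

    def lethal_equivalents_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        ci = self.glmm.conf_int(alpha).loc["froh_c10"]
        lo = lethal_equivalents_from_slope(float(ci["upper"]))
        hi = lethal_equivalents_from_slope(float(ci["lower"]))
        return lo, hi

    def summary(self) -> str:
        lo, hi = self.lethal_equivalents_conf_int()
        return (
            self.glmm.summary()
            + f"\nlethal equivalents 2B = {self.lethal_equivalents:.2f} [{lo:.2f}, {hi:.2f}]"
        )
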