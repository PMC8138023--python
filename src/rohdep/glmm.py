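"""Generalized linear mixed models with independent random intercepts,
fitted by Laplace-approximate maximum likelihood.

This is the shared fitting machinery behind the annual-survival models
and the per-SNP association scan: a binomial (logit) or Poisson (log)
GLMM with one or more crossed random-intercept factors and, optionally,
a dense correlated effect supplied through its design matrix (used for
the pedigree additive effect via the Cholesky factor of A).

Fitting follows the standard two-level scheme: for fixed variance
parameters, penalized iteratively reweighted least squares (PIRLS)
finds the joint mode of the fixed effects and spherical random effects;
the profiled Laplace criterion

    deviance(y, mu) + u' D^{-1} u + log det(Z' W Z + D^{-1}) + log det D

is then minimized over the log standard deviations with Nelder-Mead.
Standard errors for the fixed effects come from the fixed-effect block
of the inverse penalized Hessian at the optimum (Wald).

Because every grouping factor is one-hot, the cross-product block of
the largest factor is diagonal and is eliminated analytically each
PIRLS step, leaving a small dense system over the fixed effects and the
remaining factors; fits with thousands of individual-level intercepts
therefore take milliseconds per variance evaluation.  A dense
correlated effect switches the solver to a generic dense path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

_MU_EPS = 1e-10
_BOUNDARY_SD = 1e-3


class MixedGLM:
    """Binomial-logit or Poisson-log mixed model with random intercepts.

    Parameters
    ----------
    y : array (n,)
        Response; 0/1 for the binomial family, non-negative counts for
        Poisson.
    X : array (n, p)
        Fixed-effect design including the intercept column.
    groups : dict of str -> array (n,)
        Random-intercept grouping factors (labels of any hashable type).
    family : {"binomial", "poisson"}
    dense_effects : dict of str -> array (n, q), optional
        Correlated random effects entered through a dense design whose
        spherical coefficients share one variance (e.g. rows of the
        Cholesky factor of a relationship matrix).
    x_names : sequence of str, optional
    """

    def __init__(
        self,
        y,
        X,
        groups: dict,
        family: str = "binomial",
        dense_effects: dict | None = None,
        x_names=None,
    ):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if family not in ("binomial", "poisson"):
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self.x_names = list(x_names) if x_names is not None else [
            f"x{j}" for j in range(self.X.shape[1])
        ]
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X and y lengths differ")
        if not groups and not dense_effects:
            raise ValueError("at least one random effect is required")

        factor_codes, factor_sizes, factor_names = [], [], []
        for name, labels in groups.items():
            codes, levels = pd.factorize(np.asarray(labels), sort=True)
            if len(levels) < 2:
                raise ValueError(f"random factor {name!r} has < 2 levels")
            factor_codes.append(codes)
            factor_sizes.append(len(levels))
            factor_names.append(name)

        self._dense_blocks = []
        dense_names = []
        for name, M in (dense_effects or {}).items():
            M = np.asarray(M, dtype=float)
            if M.shape[0] != n:
                raise ValueError(f"dense effect {name!r} has wrong row count")
            self._dense_blocks.append(M)
            dense_names.append(name)

        # the largest one-hot factor is eliminated analytically; the rest
        # join the fixed effects in one small dense design
        if factor_codes:
            big = int(np.argmax(factor_sizes))
        else:
            big = None
        self._big = big
        small_cols = []
        #: variance-component index per column of the small design
        #: (-1 = fixed effect, unpenalized)
        pen_comp = [-1] * self.X.shape[1]
        self.vc_names = []
        comp = 0
        for k, (codes, q, name) in enumerate(zip(factor_codes, factor_sizes, factor_names)):
            self.vc_names.append(name)
            if k == big:
                self._big_codes = codes
                self._big_q = q
                self._big_comp = comp
            else:
                Zk = np.zeros((n, q))
                Zk[np.arange(n), codes] = 1.0
                small_cols.append(Zk)
                pen_comp += [comp] * q
            comp += 1
        for M, name in zip(self._dense_blocks, dense_names):
            self.vc_names.append(name)
            small_cols.append(M)
            pen_comp += [comp] * M.shape[1]
            comp += 1
        self.M = np.column_stack([self.X] + small_cols) if small_cols else self.X.copy()
        self._pen_comp = np.asarray(pen_comp)
        self._p = self.X.shape[1]
        if big is None:
            self._big_codes = None

    # -- family internals -------------------------------------------------
    def _mu_w(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.family == "binomial":
            mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
            return mu, np.maximum(mu * (1 - mu), _MU_EPS)
        mu = np.clip(np.exp(np.clip(eta, -30, 30)), _MU_EPS, None)
        return mu, mu

    def _deviance(self, mu: np.ndarray) -> float:
        if self.family == "binomial":
            return -2.0 * float(np.sum(self.y * np.log(mu) + (1 - self.y) * np.log(1 - mu)))
        return -2.0 * float(np.sum(self.y * np.log(mu) - mu))

    def _eta(self, coef: np.ndarray, u_big: np.ndarray) -> np.ndarray:
        eta = self.M @ coef
        if self._big_codes is not None:
            eta = eta + u_big[self._big_codes]
        return eta

    # -- inner PIRLS -------------------------------------------------------
    def _pirls(self, sd: np.ndarray, state: dict, maxiter: int = 60, tol: float = 1e-10):
        """Joint penalized mode of (fixed effects, random effects) for
        fixed component standard deviations ``sd``.

        Returns (coef, u_big, pdev, logdet_uu, hess_small) where
        ``hess_small`` is the small-system penalized Hessian after
        eliminating the big factor.
        """
        y, M = self.y, self.M
        n, k = M.shape
        var = np.maximum(sd, 1e-8) ** 2
        pen = np.where(self._pen_comp >= 0, 1.0 / var[np.maximum(self._pen_comp, 0)], 0.0)
        have_big = self._big_codes is not None
        if have_big:
            codes, qb = self._big_codes, self._big_q
            inv_db = 1.0 / var[self._big_comp]
        coef = state.get("coef")
        u_big = state.get("u_big")
        if coef is None:
            coef = np.zeros(k)
            if self.family == "binomial":
                ybar = np.clip(y.mean(), 0.01, 0.99)
                coef[0] = np.log(ybar / (1 - ybar))
            else:
                coef[0] = np.log(max(y.mean(), 0.01))
            u_big = np.zeros(qb) if have_big else np.zeros(0)

        n_small = k - self._p  # penalized columns in the small system

        def penalized_dev(coef_, u_):
            mu_, _ = self._mu_w(self._eta(coef_, u_))
            val = self._deviance(mu_) + float(np.sum(coef_**2 * pen))
            if have_big:
                val += float(np.sum(u_**2) * inv_db)
            return val

        pdev = penalized_dev(coef, u_big)
        logdet_uu = 0.0
        hess_small = None
        for _ in range(maxiter):
            eta = self._eta(coef, u_big)
            mu, w = self._mu_w(eta)
            z = eta + (y - mu) / w
            Mw = M * w[:, None]
            G = M.T @ Mw + np.diag(pen)
            b_m = M.T @ (w * z)
            if have_big:
                Qdiag = np.bincount(codes, weights=w, minlength=qb) + inv_db
                H = np.empty((qb, k))
                for j in range(k):
                    H[:, j] = np.bincount(codes, weights=Mw[:, j], minlength=qb)
                b_big = np.bincount(codes, weights=w * z, minlength=qb)
                HQ = H / Qdiag[:, None]
                S = G - H.T @ HQ
                rhs = b_m - HQ.T @ b_big
            else:
                S = G
                rhs = b_m
            coef_new = np.linalg.solve(S, rhs)
            if have_big:
                u_new = (b_big - H @ coef_new) / Qdiag
            else:
                u_new = u_big
            # step-halving on the penalized deviance
            step, pdev_try = 1.0, np.inf
            for _half in range(25):
                c_try = coef + step * (coef_new - coef)
                u_try = u_big + step * (u_new - u_big)
                pdev_try = penalized_dev(c_try, u_try)
                if pdev_try <= pdev + 1e-8 or step < 1e-5:
                    break
                step *= 0.5
            coef, u_big = c_try, u_try
            done = abs(pdev - pdev_try) < tol * (abs(pdev_try) + 1.0)
            pdev = pdev_try
            # log det of the random-effect block (Z'WZ + D^-1): the big
            # factor's diagonal plus the Schur complement restricted to
            # the penalized small columns
            if n_small:
                S_uu = S[self._p :, self._p :]
                sign, ld = np.linalg.slogdet(S_uu)
                logdet_uu = ld
            else:
                logdet_uu = 0.0
            if have_big:
                logdet_uu += float(np.sum(np.log(Qdiag)))
            hess_small = S
            if done:
                break
        state["coef"], state["u_big"] = coef, u_big
        return coef, u_big, pdev, logdet_uu, hess_small

    def _criterion(self, log_sd: np.ndarray, state: dict) -> float:
        log_sd = np.clip(log_sd, -8.0, 3.0)
        sd = np.exp(log_sd)
        _, _, pdev, logdet_uu, _ = self._pirls(sd, state)
        return pdev + logdet_uu + self._logdet_d(sd)

    def _logdet_d(self, sd: np.ndarray) -> float:
        var = np.maximum(sd, 1e-8) ** 2
        ld = float(np.sum(np.log(var[self._pen_comp[self._pen_comp >= 0]])))
        if self._big_codes is not None:
            ld += self._big_q * np.log(var[self._big_comp])
        return ld

    # -- public fit --------------------------------------------------------
    def fit(
        self,
        start_sd: np.ndarray | None = None,
        fixed_sd: np.ndarray | None = None,
        maxiter: int = 200,
        xatol: float = 5e-3,
        fatol: float = 5e-3,
    ) -> "MixedGLMResults":
        """Fit by Laplace ML.

        ``fixed_sd`` fixes the random-effect standard deviations (no
        outer optimization), which the association scan uses to share
        variance components estimated once under a null model.
        """
        K = len(self.vc_names)
        state: dict = {}
        if fixed_sd is not None:
            sd = np.maximum(np.asarray(fixed_sd, dtype=float), 1e-8)
            converged = True
        else:
            x0 = np.log(np.full(K, 0.5) if start_sd is None else np.asarray(start_sd, dtype=float))
            res = minimize(
                self._criterion,
                x0,
                args=(state,),
                method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": xatol, "fatol": fatol},
            )
            sd = np.exp(np.clip(res.x, -8.0, 3.0))
            converged = bool(res.success)
        coef, u_big, pdev, logdet_uu, S = self._pirls(sd, state, maxiter=100, tol=1e-12)
        crit = pdev + logdet_uu + self._logdet_d(sd)
        cov_all = np.linalg.inv(S)
        cov_beta = cov_all[: self._p, : self._p]
        boundary = {nm: bool(s < _BOUNDARY_SD) for nm, s in zip(self.vc_names, sd)}
        return MixedGLMResults(
            model=self,
            params=pd.Series(coef[: self._p], index=self.x_names),
            cov_params_arr=cov_beta,
            sd_components=pd.Series(sd, index=self.vc_names),
            random_effects=u_big,
            loglik=-0.5 * crit,
            converged=converged,
            boundary=boundary,
        )


@dataclass
class MixedGLMResults:
    """Laplace-ML fit of a :class:`MixedGLM`."""

    model: MixedGLM
    params: pd.Series
    cov_params_arr: np.ndarray
    sd_components: pd.Series
    random_effects: np.ndarray
    loglik: float
    converged: bool
    boundary: dict = field(default_factory=dict)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params_arr)), index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided Wald-Z p-values."""
        return pd.Series(2 * norm.sf(np.abs(self.zvalues)), index=self.params.index)

    @property
    def variance_components(self) -> pd.Series:
        return self.sd_components**2

    @property
    def separation_suspected(self) -> bool:
        return bool(np.any(np.abs(self.params.to_numpy()) > 15))

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov_params_arr, index=self.params.index, columns=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        zq = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - zq * self.bse, "upper": self.params + zq * self.bse}
        )

    def predict_linear(self, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fixed-effect linear predictor and its standard error on a grid
        (random effects at zero)."""
        X_new = np.asarray(X_new, dtype=float)
        eta = X_new @ self.params.to_numpy()
        se = np.sqrt(np.einsum("ij,jk,ik->i", X_new, self.cov_params_arr, X_new))
        return eta, se

    def summary(self) -> str:
        ci = self.conf_int()
        coef = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
                "ci_low": ci["lower"],
                "ci_high": ci["upper"],
            }
        )
        lines = [
            f"MixedGLM ({self.model.family}), n={len(self.model.y)}, "
            f"logLik={self.loglik:.2f}, converged={self.converged}",
            coef.to_string(float_format=lambda v: f"{v: .4f}"),
            "Random-effect standard deviations:",
        ]
        for nm, s in self.sd_components.items():
            flag = "  (boundary)" if self.boundary.get(nm) else ""
            lines.append(f"  {nm}: {s:.4f}{flag}")
        return "\n".join(lines)
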