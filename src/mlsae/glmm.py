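"""Binomial logistic mixed models with nested area random intercepts.

The model for child ``i`` in areas ``a(i)`` is

    logit Pr(y_i = 1) = x_i' beta + sum_k  u_{k, a_k(i)},
    u_{k, j} ~ N(0, sigma2_k)  independently,

with ``k`` ranging over zero, one, or two (nested, e.g. county-in-state)
grouping factors.  Estimation is maximum likelihood under the Laplace
approximation: the marginal log-likelihood integral over the random
intercepts ``u`` is replaced by its Gaussian expansion around the conditional
mode,

    ll(beta, sigma2) = l_cond(beta, u_hat) - u_hat' D^-1 u_hat / 2
                       - log det(I + D^{1/2} Z'WZ D^{1/2}) / 2,

where ``D`` is the random-effect covariance, ``Z`` the group indicator
matrix, and ``W = diag(p(1-p))`` the Bernoulli weights at the mode.

Fitting follows the standard penalized-IRLS formulation used by lme4's
``glmer``: for each trial ``sigma2`` the fixed effects and random-intercept
modes are found jointly by Newton iteration on the penalized log-likelihood,
the Laplace objective is evaluated there, and a derivative-free outer
optimizer profiles over ``log sigma2``.  For small problems an optional
refinement pass re-optimizes the full Laplace objective over
``(beta, log sigma2)`` with the modes profiled out, which removes the small
discrepancy caused by the log-determinant's dependence on ``beta``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse, stats
from scipy.special import expit

from .design import DesignBundle, ModelSpec, build_design

LOG_S2_MIN = -15.0   # sigma2 ~ 3e-7: treated as a boundary (sigma2 = 0) fit
LOG_S2_MAX = 4.0


class ConvergenceError(RuntimeError):
    """Raised when the objective is non-finite (e.g. complete separation)."""


class SelectionError(RuntimeError):
    """Raised when model selection has no converged candidate."""


def _bernoulli_ll(y: np.ndarray, eta: np.ndarray) -> float:
    # y*eta - log(1+exp(eta)), stable for large |eta|
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


class BinomialGLMM:
    """Binomial logit model with optional nested random intercepts.

    Parameters
    ----------
    design : DesignBundle
        Response, fixed-effect matrix and group index vectors, as produced by
        :func:`mlsae.design.build_design`.
    """

    def __init__(self, design: DesignBundle):
        self.design = design
        self.y = design.y
        self.X = design.X
        self.n, self.p = self.X.shape
        self.terms = list(design.random_terms)
        self.q = [int(design.group_index[t].max()) + 1 for t in self.terms]
        for t, qk in zip(self.terms, self.q):
            if qk < 2:
                raise ValueError(f"random term {t!r} needs at least 2 areas")
        # sparse indicator matrices, one per random term
        self.Z = [
            sparse.csr_matrix(
                (np.ones(self.n), (np.arange(self.n), design.group_index[t])),
                shape=(self.n, qk),
            )
            for t, qk in zip(self.terms, self.q)
        ]
        self.q_total = int(sum(self.q))
        self._offsets = np.concatenate([[0], np.cumsum(self.q)]).astype(int)

    @classmethod
    def from_records(cls, records: pd.DataFrame, geo, spec: ModelSpec) -> "BinomialGLMM":
        return cls(build_design(records, geo, spec))

    # ------------------------------------------------------------------
    def _eta(self, beta: np.ndarray, b: np.ndarray) -> np.ndarray:
        eta = self.X @ beta
        for k, Z in enumerate(self.Z):
            eta = eta + Z @ b[self._offsets[k] : self._offsets[k + 1]]
        return eta

    def _penalized_ll(self, beta, b, sigma2) -> float:
        ll = _bernoulli_ll(self.y, self._eta(beta, b))
        for k in range(len(self.terms)):
            bk = b[self._offsets[k] : self._offsets[k + 1]]
            ll -= 0.5 * float(bk @ bk) / sigma2[k]
        return ll

    def _ZtWZ(self, w: np.ndarray) -> np.ndarray:
        """Dense q_total x q_total random-effect Hessian block Z'WZ."""
        S = np.zeros((self.q_total, self.q_total))
        for k, Zk in enumerate(self.Z):
            sk = slice(self._offsets[k], self._offsets[k + 1])
            np.fill_diagonal(S[sk, sk], Zk.T @ w)
            for l in range(k + 1, len(self.Z)):
                sl = slice(self._offsets[l], self._offsets[l + 1])
                cross = (self.Z[k].multiply(w[:, None])).T @ self.Z[l]
                S[sk, sl] = cross.toarray()
                S[sl, sk] = S[sk, sl].T
        return S

    def _joint_newton(self, sigma2, beta0=None, b0=None, tol_scale=1e-10, maxiter=80):
        """Maximize the penalized log-likelihood jointly over (beta, b)."""
        beta = np.zeros(self.p) if beta0 is None else beta0.copy()
        b = np.zeros(self.q_total) if b0 is None else b0.copy()
        tol = tol_scale * max(self.n, 100)
        ll = self._penalized_ll(beta, b, sigma2)
        if not np.isfinite(ll):
            beta, b = np.zeros(self.p), np.zeros(self.q_total)
            ll = self._penalized_ll(beta, b, sigma2)
        for _ in range(maxiter):
            eta = self._eta(beta, b)
            mu = expit(eta)
            w = mu * (1.0 - mu)
            r = self.y - mu
            grad = np.empty(self.p + self.q_total)
            grad[: self.p] = self.X.T @ r
            for k, Zk in enumerate(self.Z):
                sk = slice(self.p + self._offsets[k], self.p + self._offsets[k + 1])
                bk = b[self._offsets[k] : self._offsets[k + 1]]
                grad[sk] = Zk.T @ r - bk / sigma2[k]
            if np.max(np.abs(grad)) < tol:
                break
            H = np.zeros((self.p + self.q_total, self.p + self.q_total))
            Xw = self.X * w[:, None]
            H[: self.p, : self.p] = Xw.T @ self.X
            for k, Zk in enumerate(self.Z):
                sk = slice(self.p + self._offsets[k], self.p + self._offsets[k + 1])
                H[: self.p, sk] = Xw.T @ Zk
                H[sk, : self.p] = H[: self.p, sk].T
            H[self.p :, self.p :] = self._ZtWZ(w)
            for k in range(len(self.terms)):
                sk = slice(self.p + self._offsets[k], self.p + self._offsets[k + 1])
                H[sk, sk][np.diag_indices(self.q[k])] += 1.0 / sigma2[k]
            try:
                step = linalg.cho_solve(linalg.cho_factor(H), grad)
            except linalg.LinAlgError:
                H[np.diag_indices_from(H)] += 1e-8
                step = linalg.solve(H, grad, assume_a="pos")
            # step halving on the penalized objective
            t = 1.0
            for _half in range(40):
                beta_new = beta + t * step[: self.p]
                b_new = b + t * step[self.p :]
                ll_new = self._penalized_ll(beta_new, b_new, sigma2)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12 * abs(ll):
                    break
                t *= 0.5
            else:
                break
            beta, b, ll = beta_new, b_new, ll_new
        if not np.isfinite(ll):
            raise ConvergenceError(
                "non-finite penalized likelihood (possible complete separation); "
                "consider penalizing or simplifying the model"
            )
        return beta, b, ll

    def _b_newton(self, beta, sigma2, b0=None, maxiter=60):
        """Conditional modes of the random intercepts at fixed beta."""
        b = np.zeros(self.q_total) if b0 is None else b0.copy()
        xb = self.X @ beta
        tol = 1e-11 * max(self.n, 100)
        for _ in range(maxiter):
            eta = xb.copy()
            for k, Zk in enumerate(self.Z):
                eta += Zk @ b[self._offsets[k] : self._offsets[k + 1]]
            mu = expit(eta)
            w = mu * (1.0 - mu)
            r = self.y - mu
            grad = np.empty(self.q_total)
            for k, Zk in enumerate(self.Z):
                sk = slice(self._offsets[k], self._offsets[k + 1])
                grad[sk] = Zk.T @ r - b[sk] / sigma2[k]
            if np.max(np.abs(grad)) < tol:
                break
            H = self._ZtWZ(w)
            for k in range(len(self.terms)):
                sk = slice(self._offsets[k], self._offsets[k + 1])
                H[sk, sk][np.diag_indices(self.q[k])] += 1.0 / sigma2[k]
            try:
                step = linalg.cho_solve(linalg.cho_factor(H), grad)
            except linalg.LinAlgError:
                H[np.diag_indices_from(H)] += 1e-8
                step = linalg.solve(H, grad, assume_a="pos")
            b = b + step
        return b

    def _laplace_ll(self, beta, b, sigma2) -> float:
        """Laplace marginal log-likelihood at the conditional mode (beta, b)."""
        eta = self._eta(beta, b)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        ll = _bernoulli_ll(self.y, eta)
        for k in range(len(self.terms)):
            bk = b[self._offsets[k] : self._offsets[k + 1]]
            ll -= 0.5 * float(bk @ bk) / sigma2[k]
        if self.terms:
            S = self._ZtWZ(w)
            d = np.concatenate(
                [np.full(self.q[k], np.sqrt(sigma2[k])) for k in range(len(self.terms))]
            )
            M = np.eye(self.q_total) + (d[:, None] * S) * d[None, :]
            sign, logdet = np.linalg.slogdet(M)
            if sign <= 0:
                raise ConvergenceError("indefinite Laplace curvature")
            ll -= 0.5 * logdet
        return ll

    # ------------------------------------------------------------------
    def fit(
        self,
        start_log_sigma2: np.ndarray | None = None,
        refine: bool | None = None,
        maxiter: int = 200,
        xatol: float = 1e-6,
    ) -> "GLMMResults":
        """Fit by Laplace maximum likelihood; returns :class:`GLMMResults`.

        ``refine=None`` (auto) runs the full-objective polish when the
        problem is small (n <= 2000 and p <= 12); ``True``/``False`` force it.
        """
        if not self.terms:
            return self._fit_plain()
        if refine is None:
            refine = self.n <= 2000 and self.p <= 12

        warm = {"beta": None, "b": None}

        def profile_nll(log_s2: np.ndarray) -> float:
            sigma2 = np.exp(np.atleast_1d(log_s2))
            beta, b, _ = self._joint_newton(sigma2, warm["beta"], warm["b"])
            warm["beta"], warm["b"] = beta, b
            return -self._laplace_ll(beta, b, sigma2)

        k = len(self.terms)
        if start_log_sigma2 is None:
            start_log_sigma2 = np.full(k, np.log(0.05))
        if k == 1:
            res = optimize.minimize_scalar(
                lambda v: profile_nll(np.array([v])),
                bounds=(LOG_S2_MIN, LOG_S2_MAX),
                method="bounded",
                options={"xatol": xatol, "maxiter": maxiter},
            )
            log_s2 = np.array([res.x])
            outer_ok = bool(res.success)
        else:
            res = optimize.minimize(
                profile_nll,
                start_log_sigma2,
                method="Nelder-Mead",
                bounds=[(LOG_S2_MIN, LOG_S2_MAX)] * k,
                options={"xatol": xatol, "fatol": 1e-9, "maxiter": 400},
            )
            log_s2 = np.asarray(res.x, dtype=float)
            outer_ok = bool(res.success)

        sigma2 = np.exp(log_s2)
        beta, b, _ = self._joint_newton(sigma2, warm["beta"], warm["b"])

        if refine:
            beta, log_s2, b = self._refine_full(beta, log_s2, b)
            sigma2 = np.exp(log_s2)
            b = self._b_newton(beta, sigma2, b)

        self._check_separation(beta)
        llf = self._laplace_ll(beta, b, sigma2)
        boundary = log_s2 <= LOG_S2_MIN + 1e-6
        sigma2_rep = np.where(boundary, 0.0, sigma2)
        bse, bcov = self._beta_se(beta, b, sigma2)
        s2_se = self._sigma2_se(log_s2, boundary, beta, b)
        n_par = self.p + k
        modes = {
            t: pd.Series(
                b[self._offsets[i] : self._offsets[i + 1]],
                index=self.design.group_ids[t],
                name=f"{t}_effect",
            )
            for i, t in enumerate(self.terms)
        }
        return GLMMResults(
            model=self,
            params=self._series(beta),
            bse=self._series(bse),
            cov_params=bcov,
            sigma2={t: float(sigma2_rep[i]) for i, t in enumerate(self.terms)},
            sigma2_se={t: s2_se[i] for i, t in enumerate(self.terms)},
            boundary={t: bool(boundary[i]) for i, t in enumerate(self.terms)},
            re_modes=modes,
            llf=float(llf),
            aic=float(-2.0 * llf + 2.0 * n_par),
            n_params=n_par,
            converged=outer_ok,
        )

    def _refine_full(self, beta, log_s2, b):
        """Polish (beta, log sigma2) against the full Laplace objective."""
        k = len(self.terms)
        warm = {"b": b.copy()}

        def nll(theta):
            beta_t, ls = theta[: self.p], theta[self.p :]
            sigma2 = np.exp(ls)
            warm["b"] = self._b_newton(beta_t, sigma2, warm["b"])
            return -self._laplace_ll(beta_t, warm["b"], sigma2)

        theta0 = np.concatenate([beta, log_s2])
        f0 = nll(theta0)
        bounds = [(None, None)] * self.p + [(LOG_S2_MIN, LOG_S2_MAX)] * k
        res = optimize.minimize(
            nll, theta0, method="Nelder-Mead", bounds=bounds,
            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-10, "adaptive": True},
        )
        theta = res.x if np.isfinite(res.fun) and res.fun < f0 else theta0
        return theta[: self.p], theta[self.p :], warm["b"]

    @staticmethod
    def _check_separation(beta: np.ndarray, bound: float = 25.0) -> None:
        # a logit coefficient beyond +/-25 means fitted probabilities of
        # ~1e-11: the MLE is diverging (complete or quasi-complete separation)
        if np.max(np.abs(beta)) > bound:
            raise ConvergenceError(
                "diverging coefficients indicate (quasi-)complete separation; "
                "consider a penalized fit or collapsing sparse categories"
            )

    def _fit_plain(self) -> "GLMMResults":
        """Ordinary logistic regression (no random terms) by Newton IRLS."""
        beta = np.zeros(self.p)
        ll = _bernoulli_ll(self.y, self.X @ beta)
        converged = False
        for _ in range(100):
            eta = self.X @ beta
            mu = expit(eta)
            grad = self.X.T @ (self.y - mu)
            if np.max(np.abs(grad)) < 1e-9 * max(self.n, 100):
                converged = True
                break
            w = mu * (1.0 - mu)
            H = (self.X * w[:, None]).T @ self.X
            try:
                step = linalg.cho_solve(linalg.cho_factor(H), grad)
            except linalg.LinAlgError:
                H[np.diag_indices_from(H)] += 1e-10
                step = linalg.solve(H, grad, assume_a="pos")
            t = 1.0
            for _half in range(40):
                ll_new = _bernoulli_ll(self.y, self.X @ (beta + t * step))
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12 * abs(ll):
                    break
                t *= 0.5
            beta = beta + t * step
            ll = ll_new
        if not np.isfinite(ll):
            raise ConvergenceError("non-finite log-likelihood (possible separation)")
        self._check_separation(beta)
        mu = expit(self.X @ beta)
        w = mu * (1.0 - mu)
        H = (self.X * w[:, None]).T @ self.X
        cov = linalg.inv(H)
        return GLMMResults(
            model=self,
            params=self._series(beta),
            bse=self._series(np.sqrt(np.diag(cov))),
            cov_params=cov,
            sigma2={},
            sigma2_se={},
            boundary={},
            re_modes={},
            llf=float(ll),
            aic=float(-2.0 * ll + 2.0 * self.p),
            n_params=self.p,
            converged=converged,
        )

    # ------------------------------------------------------------------
    def _beta_se(self, beta, b, sigma2):
        """SEs of beta from the beta-block of the inverse joint Hessian."""
        eta = self._eta(beta, b)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        Xw = self.X * w[:, None]
        Hbb = Xw.T @ self.X
        Hub = np.hstack([Xw.T @ Zk for Zk in self.Z])  # p x q_total
        Huu = self._ZtWZ(w)
        for k in range(len(self.terms)):
            sk = slice(self._offsets[k], self._offsets[k + 1])
            Huu[sk, sk][np.diag_indices(self.q[k])] += 1.0 / sigma2[k]
        try:
            schur = Hbb - Hub @ linalg.cho_solve(linalg.cho_factor(Huu), Hub.T)
            cov = linalg.inv(schur)
        except linalg.LinAlgError:
            return np.full(self.p, np.nan), np.full((self.p, self.p), np.nan)
        d = np.diag(cov)
        if np.any(d <= 0):
            return np.full(self.p, np.nan), cov
        return np.sqrt(d), cov

    def _sigma2_se(self, log_s2, boundary, beta, b):
        """Delta-method SEs of sigma2 from the log-scale profile information."""
        k = len(self.terms)
        if k == 0:
            return []
        warm = {"beta": beta.copy(), "b": b.copy()}

        def pll(ls):
            sigma2 = np.exp(ls)
            bt, bb, _ = self._joint_newton(sigma2, warm["beta"], warm["b"])
            return self._laplace_ll(bt, bb, sigma2)

        h = 1e-3
        Hmat = np.zeros((k, k))
        f0 = pll(log_s2)
        for i in range(k):
            if boundary[i]:
                continue
            ei = np.zeros(k)
            ei[i] = h
            Hmat[i, i] = (pll(log_s2 + ei) - 2 * f0 + pll(log_s2 - ei)) / h**2
            for j in range(i + 1, k):
                if boundary[j]:
                    continue
                ej = np.zeros(k)
                ej[j] = h
                Hmat[i, j] = Hmat[j, i] = (
                    pll(log_s2 + ei + ej)
                    - pll(log_s2 + ei - ej)
                    - pll(log_s2 - ei + ej)
                    + pll(log_s2 - ei - ej)
                ) / (4 * h**2)
        out = []
        free = [i for i in range(k) if not boundary[i]]
        if free:
            info = -Hmat[np.ix_(free, free)]
            try:
                var_ls = np.diag(linalg.inv(info))
            except linalg.LinAlgError:
                var_ls = np.full(len(free), np.nan)
        pos = 0
        for i in range(k):
            if boundary[i]:
                out.append(float("nan"))
            else:
                v = var_ls[pos]
                pos += 1
                out.append(float(np.exp(log_s2[i]) * np.sqrt(v)) if v > 0 else float("nan"))
        return out

    def _series(self, values: np.ndarray) -> pd.Series:
        names = [t if lv == "" else f"{t}[{lv}]" for t, lv in self.design.columns]
        return pd.Series(values, index=names)


@dataclass
class GLMMResults:
    """Estimates, uncertainties and diagnostics from a Laplace GLMM fit."""

    model: BinomialGLMM
    params: pd.Series
    bse: pd.Series
    cov_params: np.ndarray
    sigma2: dict[str, float]
    sigma2_se: dict[str, float]
    boundary: dict[str, bool]
    re_modes: dict[str, pd.Series]
    llf: float
    aic: float
    n_params: int
    converged: bool

    @property
    def nobs(self) -> int:
        return self.model.n

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues.to_numpy())), index=self.params.index
        )

    def coef_frame(self) -> pd.DataFrame:
        """Coefficient table (term, level, coefficient, SE, z, p)."""
        terms, levels = zip(*self.model.design.columns)
        return pd.DataFrame(
            {
                "term": terms,
                "level": levels,
                "coefficient": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "z": self.zvalues.to_numpy(),
                "p": self.pvalues.to_numpy(),
            }
        )

    def variance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "random_term": list(self.sigma2),
                "sigma2": [self.sigma2[t] for t in self.sigma2],
                "se": [self.sigma2_se[t] for t in self.sigma2],
                "boundary": [self.boundary[t] for t in self.sigma2],
            }
        )

    def summary(self) -> str:
        lines = [
            "Binomial GLMM (Laplace maximum likelihood)",
            f"  observations: {self.nobs}   parameters: {self.n_params}",
            f"  log-likelihood: {self.llf:.4f}   AIC: {self.aic:.4f}   "
            f"converged: {self.converged}",
            "",
            self.coef_frame().to_string(
                index=False, float_format=lambda v: f"{v:10.4f}"
            ),
        ]
        if self.sigma2:
            lines += ["", "Random-intercept variances:"]
            for t in self.sigma2:
                flag = " (boundary)" if self.boundary[t] else ""
                se = self.sigma2_se[t]
                se_txt = f"{se:.4f}" if np.isfinite(se) else "--"
                lines.append(f"  {t}: sigma2 = {self.sigma2[t]:.4f} (SE {se_txt}){flag}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# module-level operations
# ----------------------------------------------------------------------

def fit_laplace(design: DesignBundle, **opts) -> GLMMResults:
    """Fit a :class:`BinomialGLMM` on a prepared design bundle."""
    return BinomialGLMM(design).fit(**opts)


def variance_explained(null: GLMMResults, full: GLMMResults, term: str) -> float:
    """Percent of null-model between-area variance removed by the fixed effects.

    ``100 * (sigma2_null - sigma2_full) / sigma2_null`` for one random term.
    """
    if term not in null.sigma2 or term not in full.sigma2:
        raise ValueError(f"random term {term!r} absent from one of the fits")
    s2n, s2f = null.sigma2[term], full.sigma2[term]
    if s2n == 0:
        raise ZeroDivisionError("null-model variance is zero; statistic undefined")
    return 100.0 * (s2n - s2f) / s2n


def is_adequate(pct_explained: float | list[float], threshold: float = 40.0) -> bool:
    """Adequacy rule: every random term explains at least ``threshold`` percent."""
    pcts = np.atleast_1d(np.asarray(pct_explained, dtype=float))
    if not np.all(np.isfinite(pcts)):
        raise ValueError("percent explained must be finite")
    return bool(np.all(pcts >= threshold))


def select_model(candidates: list[GLMMResults]) -> GLMMResults:
    """Smallest-AIC selection among converged fits.

    Ties break toward fewer parameters, then earlier declaration order.
    """
    ranked = [
        (c.aic, c.n_params, i, c) for i, c in enumerate(candidates) if c.converged
    ]
    if not ranked:
        raise SelectionError("no converged candidate model")
    return min(ranked, key=lambda t: t[:3])[3]
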