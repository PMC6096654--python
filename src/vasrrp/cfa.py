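"""Maximum-likelihood confirmatory factor analysis for the CT and CTCU
templates.

The fit minimizes the Wishart ML discrepancy

    F(S, Sigma) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

over the free parameters of ``Sigma = Lambda Phi Lambda' + Theta`` with
factor variances fixed at 1.  Optimization runs on an unconstrained
reparameterization (raw loadings; correlations through tanh; residual
variances through log) with analytic gradients and a BFGS quasi-Newton
search; the chi-square statistic is ``(n-1) F_min`` (the convention of
continuous-ML SEM software, exposed as an option).

The CT template frees p loadings, the latent correlations and p residual
variances; the CTCU template adds one residual-correlation block per
testlet.  Fit indices (RMSEA, SRMR, CFI, TLI) are computed against the
independence baseline (diagonal Sigma, free variances).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .factor_model import FactorModelSpec, model_degrees_of_freedom

__all__ = ["CFAFit", "FitIndices", "ml_discrepancy", "fit_cfa", "fit_indices"]

#: Convergence tolerance on the gradient norm.
GRADIENT_TOL = 1e-6
#: Start values: loadings 0.8, residual variances 1, correlations 0.
START_LOADING = 0.8
MAX_ITER = 1000
#: Penalty returned at parameter points with non-PD implied covariance.
_PENALTY = 1e10


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Wishart ML fit function; >= 0 with equality iff S == Sigma."""
    S = np.asarray(S, float)
    Sigma = np.asarray(Sigma, float)
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("S must be positive definite")
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return _PENALTY
    return float(logdet + np.trace(np.linalg.solve(Sigma, S)) - logdet_s - p)


@dataclass
class FitIndices:
    rmsea: float
    srmr: float
    cfi: float
    tli: float


@dataclass
class CFAFit:
    """Estimates and fit information from one ML covariance-structure fit.

    Estimates are reported in the generating parameterization (per-item
    loadings, latent correlation matrix, residual variances, and -- for the
    CTCU template only -- per-testlet residual correlation matrices).
    """

    template: str
    loadings: np.ndarray
    latent_corr: np.ndarray
    residual_vars: np.ndarray
    testlet_residual_corr: np.ndarray | None
    chi_square: float
    df: int
    n: int
    discrepancy: float
    converged: bool
    n_iter: int
    gradient_norm: float
    sigma_hat: np.ndarray
    indices: FitIndices | None = None

    def to_dict(self) -> dict:
        d = {
            "template": self.template,
            "loadings": self.loadings.tolist(),
            "latent_corr": self.latent_corr.tolist(),
            "residual_vars": self.residual_vars.tolist(),
            "testlet_residual_corr": (
                self.testlet_residual_corr.tolist()
                if self.testlet_residual_corr is not None
                else None
            ),
            "chi_square": self.chi_square,
            "df": self.df,
            "n": self.n,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        if self.indices is not None:
            d["indices"] = vars(self.indices).copy()
        return d


class _Parameterization:
    """Packs/unpacks the unconstrained parameter vector and evaluates the
    discrepancy with its analytic gradient."""

    def __init__(self, structure: FactorModelSpec, template: str):
        if template not in ("CT", "CTCU"):
            raise ValueError(f"unknown template {template!r}")
        self.template = template
        self.p = structure.n_items
        self.L = structure.n_latents
        self.T = structure.n_testlets
        self.item_to_latent = structure.item_to_latent
        self.testlet_items = [structure.items_of_testlet(t) for t in range(self.T)]
        self.tril = np.tril_indices(self.L, -1)
        self.n_corr = self.L * (self.L - 1) // 2
        self.n_params = 2 * self.p + self.n_corr
        if template == "CTCU":
            self.n_params += self.T * self.n_corr

    def start(self) -> np.ndarray:
        x0 = np.zeros(self.n_params)
        x0[: self.p] = START_LOADING
        return x0

    def unpack(self, x):
        p, L = self.p, self.L
        lam = x[:p]
        phi_off = np.tanh(x[p : p + self.n_corr])
        res_var = np.exp(x[p + self.n_corr : 2 * p + self.n_corr])
        Phi = np.eye(L)
        Phi[self.tril] = phi_off
        Phi.T[self.tril] = phi_off
        tcorr = None
        if self.template == "CTCU":
            raw = x[2 * p + self.n_corr :].reshape(self.T, self.n_corr)
            tcorr = np.empty((self.T, L, L))
            for t in range(self.T):
                R = np.eye(L)
                R[self.tril] = np.tanh(raw[t])
                R.T[self.tril] = np.tanh(raw[t])
                tcorr[t] = R
        return lam, Phi, res_var, tcorr

    def sigma(self, x) -> np.ndarray:
        lam, Phi, res_var, tcorr = self.unpack(x)
        Lam = np.zeros((self.p, self.L))
        Lam[np.arange(self.p), self.item_to_latent] = lam
        Theta = np.diag(res_var)
        if self.template == "CTCU":
            sd = np.sqrt(res_var)
            for t, idx in enumerate(self.testlet_items):
                Theta[np.ix_(idx, idx)] = tcorr[t] * np.outer(sd[idx], sd[idx])
        return Lam @ Phi @ Lam.T + Theta

    def value_and_grad(self, x, S, logdet_s):
        p, L = self.p, self.L
        lam, Phi, res_var, tcorr = self.unpack(x)
        Lam = np.zeros((p, L))
        Lam[np.arange(p), self.item_to_latent] = lam
        sd = np.sqrt(res_var)
        Theta = np.diag(res_var)
        if self.template == "CTCU":
            for t, idx in enumerate(self.testlet_items):
                Theta[np.ix_(idx, idx)] = tcorr[t] * np.outer(sd[idx], sd[idx])
        Sigma = Lam @ Phi @ Lam.T + Theta
        try:
            c = np.linalg.cholesky(Sigma)
        except np.linalg.LinAlgError:
            # non-PD iterate: flat penalty; BFGS backtracks out of it
            return _PENALTY, np.zeros_like(x)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        Sinv = np.linalg.inv(Sigma)
        F = logdet + (Sinv * S).sum() - logdet_s - p
        # dF/dSigma, symmetric
        G = Sinv - Sinv @ S @ Sinv
        g_lam = 2.0 * (G @ Lam @ Phi)[np.arange(p), self.item_to_latent]
        phi_off = Phi[self.tril]
        M = Lam.T @ G @ Lam
        g_phi = 2.0 * M[self.tril] * (1.0 - phi_off**2)
        g_var = np.diag(G).copy()
        if self.template == "CTCU":
            g_t = np.zeros((self.T, self.n_corr))
            for t, idx in enumerate(self.testlet_items):
                Gb = G[np.ix_(idx, idx)]
                Rt = tcorr[t]
                sdb = sd[idx]
                # off-diagonal Theta entries depend on both residual variances
                for a in range(L):
                    for b in range(L):
                        if a != b:
                            g_var[idx[a]] += Gb[a, b] * Rt[a, b] * sdb[b] / sdb[a]
                r_off = Rt[self.tril]
                g_t[t] = (
                    2.0
                    * Gb[self.tril]
                    * sdb[self.tril[0]]
                    * sdb[self.tril[1]]
                    * (1.0 - r_off**2)
                )
        g_var *= res_var  # chain rule for the log parameterization
        grad = np.concatenate(
            [g_lam, g_phi, g_var] + ([g_t.ravel()] if self.template == "CTCU" else [])
        )
        return F, grad


def fit_cfa(
    S: np.ndarray,
    n: int,
    template: str,
    structure: FactorModelSpec,
    chi_square_multiplier: str = "n-1",
) -> CFAFit:
    """Fit the CT or CTCU template to a sample covariance matrix.

    ``structure`` supplies only the skeleton (item-to-latent and
    item-to-testlet maps); its parameter values are ignored.  Estimates are
    returned with each factor reflected so that its loading sum is positive
    (the sign convention of the generating model).  Non-convergence is
    flagged on the returned fit, never silently dropped.
    """
    S = np.asarray(S, float)
    par = _Parameterization(structure, template)
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise ValueError("sample covariance must be positive definite")
    res = optimize.minimize(
        par.value_and_grad,
        par.start(),
        args=(S, logdet_s),
        jac=True,
        method="BFGS",
        options={"gtol": GRADIENT_TOL, "maxiter": MAX_ITER},
    )
    grad_norm = float(np.linalg.norm(res.jac, ord=np.inf))
    converged = bool(grad_norm < 1e-4 and res.fun < _PENALTY / 2)
    lam, Phi, res_var, tcorr = par.unpack(res.x)
    # resolve per-factor sign indeterminacy
    flip = np.ones(par.L)
    for l in range(par.L):
        if lam[structure.item_to_latent == l].sum() < 0:
            flip[l] = -1.0
    lam = lam * flip[structure.item_to_latent]
    Phi = Phi * np.outer(flip, flip)
    df = model_degrees_of_freedom(
        par.p, template, par.L, par.T if template == "CTCU" else None
    )
    multiplier = (n - 1) if chi_square_multiplier == "n-1" else n
    return CFAFit(
        template=template,
        loadings=lam,
        latent_corr=Phi,
        residual_vars=res_var,
        testlet_residual_corr=tcorr,
        chi_square=float(multiplier * res.fun),
        df=df,
        n=n,
        discrepancy=float(res.fun),
        converged=converged,
        n_iter=int(res.nit),
        gradient_norm=grad_norm,
        sigma_hat=par.sigma(res.x),
    )


def _baseline_chi_square(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence baseline: diagonal Sigma with free variances.  Its ML
    solution is Sigma = diag(S), so F_b = sum(ln s_ii) - ln|S|."""
    p = S.shape[0]
    _, logdet_s = np.linalg.slogdet(S)
    F_b = float(np.sum(np.log(np.diag(S))) - logdet_s)
    return (n - 1) * F_b, p * (p - 1) // 2


def fit_indices(
    chi_square: float,
    df: int,
    n: int,
    baseline_chi_square: float,
    baseline_df: int,
    S: np.ndarray,
    sigma_hat: np.ndarray,
) -> FitIndices:
    """RMSEA, SRMR, CFI and TLI for one fitted model.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))); SRMR is the root mean
    squared standardized residual over the lower triangle including the
    diagonal; CFI and TLI compare against the independence baseline and are
    capped at 1.
    """
    if df <= 0:
        raise ValueError("saturated model: indices undefined")
    rmsea = float(np.sqrt(max(chi_square - df, 0.0) / (df * (n - 1))))
    d = np.sqrt(np.diag(S))
    resid = (S - sigma_hat) / np.outer(d, d)
    il, jl = np.tril_indices(S.shape[0])
    srmr = float(np.sqrt(np.mean(resid[il, jl] ** 2)))
    num = max(chi_square - df, 0.0)
    den = max(baseline_chi_square - baseline_df, num, np.finfo(float).tiny)
    cfi = min(1.0, 1.0 - num / den)
    base_ratio = baseline_chi_square / baseline_df
    tli = (base_ratio - chi_square / df) / (base_ratio - 1.0)
    tli = min(1.0, float(tli))
    return FitIndices(rmsea=rmsea, srmr=srmr, cfi=cfi, tli=float(tli))


def fit_with_indices(
    S: np.ndarray, n: int, template: str, structure: FactorModelSpec
) -> CFAFit:
    """Convenience wrapper: fit the model and attach baseline-referenced
    fit indices."""
    fit = fit_cfa(S, n, template, structure)
    chi_b, df_b = _baseline_chi_square(S, n)
    fit.indices = fit_indices(
        fit.chi_square, fit.df, n, chi_b, df_b, S, fit.sigma_hat
    )
    return fit
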