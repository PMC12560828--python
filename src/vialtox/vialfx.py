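"""Vial-clustering diagnostics via a binomial random-intercept GLMM.

Embryos sharing a vial share an exposure micro-environment, so their
any-effect outcomes may be correlated.  Whether that clustering can be
ignored is decided per chemical by fitting

    logit P(y_ij = 1 | u_j) = beta0 + beta1 * ln(dose_ij + 1) + u_j,
    u_j ~ Normal(0, sigma2_vial),

by marginal maximum likelihood (each vial's likelihood integrated by
adaptive Gauss-Hermite quadrature), partitioning the latent-scale
variance into fixed (concentration), random (vial), and logistic
residual (pi^2/3) components, and applying two ratio rules: embryos are
treated as individual observations when fixed-R2 : random-R2 > 1, or
failing that when random-R2 : remaining-error < 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = [
    "VialEffectModel",
    "VialEffectResults",
    "scale_concentration",
    "fit_binomial_glmm",
    "partition_variance",
    "vial_decision",
]

_LOGISTIC_RESID = math.pi**2 / 3.0


def scale_concentration(dose):
    """Log-plus-one concentration scaling: ln(dose + 1)."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative")
    return np.log1p(d)


@dataclass(frozen=True)
class VialEffectResults:
    """GLMM fit, variance partition, and the treat-individually verdict."""

    beta0: float
    beta1: float
    sigma2_vial: float
    loglik: float
    converged: bool
    n_obs: int
    n_vials: int
    r2_fixed: float | None = None
    r2_random: float | None = None
    remaining: float | None = None
    ratio_fixed_random: float | None = None
    ratio_random_remaining: float | None = None
    decision: bool | None = None

    def summary(self) -> str:
        lines = [
            "Binomial GLMM vial-effect diagnostic",
            "=" * 40,
            f"obs: {self.n_obs}   vials: {self.n_vials}",
            f"beta0 (intercept)      {self.beta0:9.4f}",
            f"beta1 (ln(conc+1))     {self.beta1:9.4f}",
            f"sigma2_vial            {self.sigma2_vial:9.4f}",
            f"log-likelihood         {self.loglik:9.4f}",
        ]
        if self.r2_fixed is not None:
            lines += [
                f"R2 fixed / random / remaining  "
                f"{self.r2_fixed:.4f} / {self.r2_random:.4f} / {self.remaining:.4f}",
                f"fixed:random ratio     {self.ratio_fixed_random:9.4g}",
                f"random:remaining ratio {self.ratio_random_remaining:9.4g}",
                "decision: treat embryos as individual observations"
                if self.decision else
                "decision: vial effect non-negligible",
            ]
        return "\n".join(lines)


class VialEffectModel:
    """Logit random-intercept model for per-embryo binary outcomes.

    Parameters
    ----------
    y : array of 0/1 outcomes (any-effect endpoint)
    dose : array of nominal concentrations in uM
    vial : array of vial labels
    """

    def __init__(self, y, dose, vial):
        self.y = np.asarray(y, dtype=float)
        self.x = scale_concentration(dose)
        vial = np.asarray(vial)
        if not (self.y.size == self.x.size == vial.size):
            raise ValueError("y, dose, vial must have equal length")
        labels, self.vial_idx = np.unique(vial, return_inverse=True)
        self.n_vials = labels.size
        if self.n_vials < 2:
            raise ValueError("need at least 2 vials")
        self._vial_obs = [np.flatnonzero(self.vial_idx == j)
                          for j in range(self.n_vials)]
        # Gauss-Hermite cache keyed by node count
        self._gh = {}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, endpoint: str = "ANY",
                       dose_col: str = "conc_um", vial_col: str = "vial",
                       endpoint_col: str = "endpoint",
                       response_col: str = "response"):
        sub = df[df[endpoint_col] == endpoint] if endpoint_col in df else df
        if sub.empty:
            raise ValueError(f"no rows for endpoint {endpoint!r}")
        return cls(sub[response_col].to_numpy(), sub[dose_col].to_numpy(),
                   sub[vial_col].to_numpy())

    # -- marginal likelihood ------------------------------------------

    def _gh_nodes(self, n):
        if n not in self._gh:
            self._gh[n] = np.polynomial.hermite.hermgauss(n)
        return self._gh[n]

    def _vial_logjoint(self, eta, y, u, sigma):
        """log f(y | u) + log phi(u; 0, sigma^2) for one vial."""
        lin = eta[:, None] + u[None, :]
        ll = np.sum(y[:, None] * lin - np.logaddexp(0.0, lin), axis=0)
        return ll - 0.5 * (u / sigma) ** 2 - 0.5 * math.log(2 * math.pi) \
            - math.log(sigma)

    def loglik(self, beta0, beta1, sigma, nodes: int = 25):
        """Marginal log-likelihood by adaptive Gauss-Hermite quadrature.

        For each vial the integrand is re-centred at its mode with the
        Laplace curvature as scale; sigma=0 collapses to the plain
        logistic likelihood.  ``nodes=1`` gives the Laplace
        approximation.
        """
        eta_all = beta0 + beta1 * self.x
        if sigma < 1e-10:
            ll = np.sum(self.y * eta_all - np.logaddexp(0.0, eta_all))
            return float(ll)
        t, w = self._gh_nodes(nodes)
        total = 0.0
        for obs in self._vial_obs:
            eta = eta_all[obs]
            y = self.y[obs]
            # Newton search for the mode of the joint log-density in u
            u = 0.0
            for _ in range(50):
                p = special.expit(eta + u)
                grad = np.sum(y - p) - u / sigma**2
                hess = -np.sum(p * (1 - p)) - 1.0 / sigma**2
                step = grad / hess
                u_new = u - step
                if abs(u_new - u) < 1e-10:
                    u = u_new
                    break
                u = u_new
            p = special.expit(eta + u)
            curv = np.sum(p * (1 - p)) + 1.0 / sigma**2
            scale = 1.0 / math.sqrt(curv)
            uj = u + math.sqrt(2.0) * scale * t
            h = self._vial_logjoint(eta, y, uj, sigma)
            m = h.max()
            total += m + math.log(math.sqrt(2.0) * scale
                                  * np.sum(w * np.exp(h - m + t**2)))
        return float(total)

    def fit(self, nodes: int = 25) -> VialEffectResults:
        """Maximize the marginal likelihood over (beta0, beta1, sigma).

        sigma is optimized on its natural scale with a zero lower bound
        so that variance-free data can reach the sigma2_vial = 0
        boundary.  Complete separation leaves the slope at the box
        bound and is flagged via ``converged``.
        """
        # logistic-regression start ignoring clustering
        def nll0(b):
            eta = b[0] + b[1] * self.x
            return -np.sum(self.y * eta - np.logaddexp(0.0, eta))

        r0 = optimize.minimize(nll0, np.array([-1.0, 0.5]), method="BFGS")
        start = np.array([r0.x[0], r0.x[1], 0.3])

        def nll(theta):
            return -self.loglik(theta[0], theta[1], theta[2], nodes)

        bounds = [(-30.0, 30.0), (-30.0, 30.0), (0.0, 10.0)]
        best = None
        for s in (start, np.array([start[0], start[1], 1.0])):
            res = optimize.minimize(nll, s, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
        beta0, beta1, sigma = best.x
        at_box = abs(abs(beta1) - 30.0) < 1e-6 or abs(abs(beta0) - 30.0) < 1e-6
        fit = VialEffectResults(
            beta0=float(beta0), beta1=float(beta1),
            sigma2_vial=float(sigma**2), loglik=-float(best.fun),
            converged=bool(best.success and not at_box),
            n_obs=self.y.size, n_vials=self.n_vials)
        return partition_variance(fit, self.x)


def fit_binomial_glmm(observations: pd.DataFrame, endpoint: str = "ANY",
                      nodes: int = 25) -> VialEffectResults:
    """Fit the vial random-intercept GLMM from a long morphology table."""
    return VialEffectModel.from_dataframe(observations, endpoint).fit(nodes)


def partition_variance(fit: VialEffectResults, scaled_conc=None
                       ) -> VialEffectResults:
    """Latent-scale variance partition (fixed / vial / logistic residual).

    sigma2_f is the variance of the fixed-effect linear predictor over
    the observations; the denominator adds the vial variance and the
    standard-logistic residual pi^2/3, so the three proportions sum
    to 1 exactly.
    """
    if scaled_conc is None:
        raise ValueError("scaled concentrations required to compute sigma2_f")
    x = np.asarray(scaled_conc, dtype=float)
    sigma2_f = float(np.var(fit.beta1 * x))
    denom = sigma2_f + fit.sigma2_vial + _LOGISTIC_RESID
    r2_fixed = sigma2_f / denom
    r2_random = fit.sigma2_vial / denom
    remaining = 1.0 - r2_fixed - r2_random
    out = replace(fit, r2_fixed=r2_fixed, r2_random=r2_random,
                  remaining=remaining)
    return vial_decision(out)


def vial_decision(result: VialEffectResults) -> VialEffectResults:
    """Apply the two ratio rules to a partitioned result.

    treat-individually iff fixed:random R2 ratio > 1, or (failing that)
    random R2 : remaining error < 1.  A zero random R2 makes the first
    ratio +inf, hence treat-individually.
    """
    if result.r2_fixed is None:
        raise ValueError("variance partition required before the decision")
    fr = (math.inf if result.r2_random == 0
          else result.r2_fixed / result.r2_random)
    rr = (0.0 if result.r2_random == 0 and result.remaining > 0
          else result.r2_random / result.remaining)
    decision = fr > 1.0 or rr < 1.0
    return replace(result, ratio_fixed_random=fr,
                   ratio_random_remaining=rr, decision=decision)


def vial_effect_table(df: pd.DataFrame, endpoint: str = "ANY",
                      nodes: int = 25) -> pd.DataFrame:
    """Per-chemical decision table over a multi-chemical morphology table."""
    rows = []
    for chem, sub in df.groupby("chemical", sort=True):
        r = fit_binomial_glmm(sub, endpoint, nodes)
        rows.append((chem, r.beta0, r.beta1, r.sigma2_vial, r.r2_fixed,
                     r.r2_random, r.remaining, r.ratio_fixed_random,
                     r.ratio_random_remaining, r.decision))
    return pd.DataFrame(rows, columns=[
        "chemical", "beta0", "beta1", "sigma2_vial", "r2_fixed", "r2_random",
        "remaining", "ratio_fixed_random", "ratio_random_remaining",
        "treat_individually"])
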