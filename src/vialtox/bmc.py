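"""Benchmark-concentration modeling for dichotomous endpoints.

Fits the unrestricted three-parameter log-logistic model for binary
dose-response data,

    p(d) = g + (1 - g) / (1 + exp(-a - b ln d)),        p(0) = g,

by maximum likelihood over dose-group binomial counts, computes the
extra-risk benchmark concentration

    BMC(bmr) = exp((logit(bmr) - a) / b),

and its lower/upper confidence bounds by the profile-likelihood
(likelihood-ratio) method: each bound is the BMC value at which the
profile log-likelihood falls 1.3528 (= chi2_1(0.90)/2, one-sided 95%
per bound) below the maximum.  "Unrestricted" means the slope b is only
required to be positive, with no lower bound of 1.

Reported BMCs must lie within the tested positive dose range, have both
bounds estimable, and satisfy BMCu:BMCl < 40; otherwise the result is
flagged invalid with the failing filter named.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

__all__ = [
    "DoseGroupCounts",
    "LogLogisticFit",
    "BmcResult",
    "BenchmarkDoseModel",
    "BenchmarkDoseResults",
    "fit_loglogistic",
    "bmc_from_params",
    "profile_ci",
    "report_bmc",
]

#: Default likelihood-ratio drop for a one-sided 95% bound (chi2_1 at 0.90, halved).
LR_CUTOFF_95 = sps.chi2.ppf(0.90, df=1) / 2.0  # 1.35277...

_PCLIP = 1e-12


@dataclass(frozen=True)
class DoseGroupCounts:
    """Binomial summary of one dose group: n exposed, k affected."""

    dose: float
    n: int
    k: int

    def __post_init__(self):
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")


@dataclass(frozen=True)
class LogLogisticFit:
    """Maximum-likelihood parameters of the three-parameter log-logistic."""

    g: float
    a: float
    b: float
    loglik: float
    converged: bool
    identifiable: bool = True


@dataclass(frozen=True)
class BmcResult:
    """Benchmark concentration with likelihood-ratio bounds and verdict."""

    bmc: float
    bmcl: float
    bmcu: float
    bmr: float = 0.5
    valid: bool = False
    reason: str = ""


def response_probability(dose, g, a, b):
    """p(d) of the log-logistic model; the dose-effect term is 0 at d=0."""
    d = np.asarray(dose, dtype=float)
    eta = np.where(d > 0, a + b * np.log(np.where(d > 0, d, 1.0)), -np.inf)
    return g + (1.0 - g) * special.expit(eta)


class BenchmarkDoseModel:
    """Three-parameter log-logistic dose-response model for binomial counts.

    Parameters
    ----------
    dose, n, k : array-like
        Per-group dose (uM), number exposed, and number affected.
        Must include the 0 uM control and at least 3 distinct doses.

    Examples
    --------
    >>> m = BenchmarkDoseModel([0, 6.25, 12.5, 25, 50],
    ...                        [32, 32, 32, 32, 32],
    ...                        [1, 2, 6, 20, 30])
    >>> res = m.fit()
    >>> round(res.bmc(0.5), 1)  # doctest: +SKIP
    17.8
    """

    def __init__(self, dose, n, k):
        dose = np.asarray(dose, dtype=float)
        n = np.asarray(n, dtype=int)
        k = np.asarray(k, dtype=int)
        if not (dose.shape == n.shape == k.shape):
            raise ValueError("dose, n, k must have equal length")
        if np.unique(dose).size < 3 or 0.0 not in dose:
            raise ValueError("need >= 3 distinct doses including the 0 control")
        if np.any((k < 0) | (k > n)):
            raise ValueError("need 0 <= k <= n per group")
        if n.sum() <= 0:
            raise ValueError("no observations")
        order = np.argsort(dose)
        self.dose = dose[order]
        self.n = n[order]
        self.k = k[order]

    # -- constructors -------------------------------------------------

    @classmethod
    def from_groups(cls, groups):
        """Build from an iterable of :class:`DoseGroupCounts`."""
        groups = list(groups)
        return cls([g.dose for g in groups], [g.n for g in groups],
                   [g.k for g in groups])

    @classmethod
    def from_observations(cls, df: pd.DataFrame, endpoint: str = "ANY",
                          dose_col: str = "conc_um",
                          endpoint_col: str = "endpoint",
                          response_col: str = "response"):
        """Pool per-embryo binary outcomes into dose-group counts.

        Embryos are treated as individual observations (the vial-effect
        diagnostic justifies ignoring vial clustering), so the binomial
        likelihood of the pooled counts equals the individual-level one.
        """
        sub = df[df[endpoint_col] == endpoint]
        if sub.empty:
            raise ValueError(f"no rows for endpoint {endpoint!r}")
        grp = sub.groupby(dose_col)[response_col].agg(["count", "sum"])
        return cls(grp.index.to_numpy(), grp["count"].to_numpy(),
                   grp["sum"].to_numpy().astype(int))

    # -- likelihood ---------------------------------------------------

    def loglik(self, g, a, b):
        p = np.clip(response_probability(self.dose, g, a, b), _PCLIP, 1 - _PCLIP)
        return float(np.sum(self.k * np.log(p) + (self.n - self.k) * np.log1p(-p)))

    def _nll_unbounded(self, theta):
        g = special.expit(theta[0])
        b = np.exp(np.clip(theta[2], -20.0, 10.0))  # keep b finite
        return -self.loglik(g, theta[1], b)

    def _starts(self):
        """Moment-style starts: control rate for g, logit-linear a,b."""
        pos = self.dose > 0
        rate = (self.k + 0.5) / (self.n + 1.0)
        g0 = float(rate[~pos].mean()) if np.any(~pos) else 0.05
        g0 = min(max(g0, 1e-3), 0.5)
        extra = np.clip((rate[pos] - g0) / (1 - g0), 1e-3, 1 - 1e-3)
        x = np.log(self.dose[pos])
        yy = special.logit(extra)
        if x.size >= 2 and np.ptp(x) > 0:
            b0, a0 = np.polyfit(x, yy, 1)
        else:
            b0, a0 = 1.0, float(yy.mean())
        b0 = min(max(b0, 0.05), 20.0)
        starts = [(g0, a0, b0)]
        dmax = self.dose.max()
        for bs in (0.5, 2.0, 6.0):
            for d50 in (dmax / 4, dmax, dmax * 4):
                starts.append((g0, -bs * np.log(d50), bs))
        return starts

    def fit(self) -> "BenchmarkDoseResults":
        """Multi-start maximum-likelihood fit.

        A flat observed response (all group rates equal) is returned as a
        boundary solution flagged non-identifiable.
        """
        rates = self.k / np.maximum(self.n, 1)
        if np.allclose(rates, rates[0]):
            g = float(self.k.sum() / self.n.sum())
            fit = LogLogisticFit(g, -50.0, 1.0, self.loglik(g, -50.0, 1.0),
                                 converged=True, identifiable=False)
            return BenchmarkDoseResults(self, fit)
        best = None
        for g0, a0, b0 in self._starts():
            x0 = np.array([special.logit(g0), a0, np.log(b0)])
            try:
                res = optimize.minimize(self._nll_unbounded, x0,
                                        method="L-BFGS-B")
            except (ValueError, FloatingPointError):  # pragma: no cover
                continue
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        g = float(special.expit(best.x[0]))
        a = float(best.x[1])
        b = float(np.exp(best.x[2]))
        fit = LogLogisticFit(g, a, b, -float(best.fun), bool(best.success))
        return BenchmarkDoseResults(self, fit)


class BenchmarkDoseResults:
    """Fitted log-logistic model: point estimates, BMC, profile bounds."""

    def __init__(self, model: BenchmarkDoseModel, fit: LogLogisticFit):
        self.model = model
        self.params = fit
        self.llf = fit.loglik
        self.converged = fit.converged

    def predict(self, dose):
        f = self.params
        return response_probability(dose, f.g, f.a, f.b)

    def bmc(self, bmr: float = 0.5) -> float:
        """Extra-risk benchmark concentration, closed form."""
        return bmc_from_params(self.params, bmr)

    # -- profile likelihood -------------------------------------------

    def _profile_loglik(self, bmc_val, bmr):
        """Max log-likelihood with the BMC constrained to ``bmc_val``.

        Reparameterized with the BMC free: a = logit(bmr) - b ln(BMC),
        maximizing over (g, b).
        """
        model = self.model
        lb = np.log(bmc_val)
        qb = special.logit(bmr)

        def nll(theta):
            g = special.expit(theta[0])
            b = np.exp(theta[1])
            return -model.loglik(g, qb - b * lb, b)

        f = self.params
        x0s = [np.array([special.logit(min(max(f.g, 1e-4), 1 - 1e-4)),
                         np.log(f.b)])]
        x0s.append(np.array([special.logit(0.05), 0.0]))
        best = None
        for x0 in x0s:
            res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-10,
                                             "maxiter": 2000})
            if best is None or res.fun < best:
                best = res.fun
        return -best

    def profile_ci(self, bmr: float = 0.5, alpha: float = 0.05,
                   cutoff: float | None = None):
        """Likelihood-ratio bounds (BMCl, BMCu) on the BMC.

        Each bound solves profile(BMC) = llf_max - cutoff by monotone
        root search; cutoff defaults to 1.3528, giving one-sided 95%
        bounds per side at alpha=0.05 (BMDS convention).  A bound the
        profile never crosses within [max dose * 1e-3, max dose * 1e3]
        is returned as nan.
        """
        if cutoff is None:
            cutoff = sps.chi2.ppf(1 - 2 * alpha, df=1) / 2.0
        if not self.params.identifiable:
            return float("nan"), float("nan")
        bmc_hat = self.bmc(bmr)
        dmax = float(self.model.dose.max())
        lo_lim, hi_lim = dmax * 1e-3, dmax * 1e3
        bmc_hat = min(max(bmc_hat, lo_lim), hi_lim)
        target = self.llf - cutoff

        def f(logc):
            return self._profile_loglik(np.exp(logc), bmr) - target

        bounds = []
        for direction in (-1, +1):
            lim = np.log(lo_lim) if direction < 0 else np.log(hi_lim)
            x0 = np.log(bmc_hat)
            step = 0.25 * direction
            x1 = x0 + step
            f0 = f(x0)
            found = None
            while (x1 - lim) * direction <= 0:
                f1 = f(x1)
                if f1 <= 0:
                    found = optimize.brentq(f, min(x0, x1), max(x0, x1),
                                            xtol=1e-10)
                    break
                x0, f0 = x1, f1
                step *= 1.7
                x1 = x0 + step
            if found is None:
                flim = f(lim)
                if flim <= 0:
                    found = optimize.brentq(f, min(x0, lim), max(x0, lim),
                                            xtol=1e-10)
            bounds.append(np.exp(found) if found is not None else float("nan"))
        return bounds[0], bounds[1]

    def report(self, bmr: float = 0.5, alpha: float = 0.05,
               cutoff: float | None = None) -> BmcResult:
        """BMC with bounds and the reporting-filter verdict."""
        if not self.params.identifiable:
            return BmcResult(float("nan"), float("nan"), float("nan"), bmr,
                             valid=False, reason="no response")
        bmc = self.bmc(bmr)
        bmcl, bmcu = self.profile_ci(bmr, alpha, cutoff)
        return report_bmc(BmcResult(bmc, bmcl, bmcu, bmr), self.model.dose)

    def summary(self) -> str:
        f = self.params
        rep = self.report()
        lines = [
            "Three-parameter log-logistic benchmark-dose model",
            "=" * 49,
            f"groups: {len(self.model.dose)}   total n: {int(self.model.n.sum())}",
            f"g (background)   {f.g:10.4f}",
            f"a (intercept)    {f.a:10.4f}",
            f"b (slope)        {f.b:10.4f}",
            f"log-likelihood   {self.llf:10.4f}   converged: {self.converged}",
            f"BMC{int(rep.bmr*100):d}  {rep.bmc:10.4g}  "
            f"[{rep.bmcl:.4g}, {rep.bmcu:.4g}]",
            f"valid: {rep.valid}" + (f"   ({rep.reason})" if rep.reason else ""),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface


def fit_loglogistic(groups) -> LogLogisticFit:
    """MLE of the three-parameter log-logistic from dose-group counts."""
    return BenchmarkDoseModel.from_groups(groups).fit().params


def bmc_from_params(fit: LogLogisticFit, bmr: float = 0.5,
                    risk_type: str = "extra") -> float:
    """Closed-form BMC: extra risk ER(d) = 1/(1+exp(-a-b ln d)) = bmr."""
    if risk_type != "extra":
        raise ValueError("only extra risk is supported")
    if not 0 < bmr < 1:
        raise ValueError("bmr must lie strictly in (0, 1)")
    if fit.b <= 0:
        raise ValueError("slope must be positive")
    return float(np.exp((special.logit(bmr) - fit.a) / fit.b))


def profile_ci(groups, fit: LogLogisticFit, bmr: float = 0.5,
               alpha: float = 0.05, cutoff: float | None = None):
    """Likelihood-ratio confidence bounds for a fitted group table."""
    model = BenchmarkDoseModel.from_groups(groups)
    return BenchmarkDoseResults(model, fit).profile_ci(bmr, alpha, cutoff)


def report_bmc(result: BmcResult, tested_doses,
               max_ratio: float = 40.0) -> BmcResult:
    """Apply the reporting filters: in-range, bounds estimable, ratio < 40."""
    doses = np.asarray(tested_doses, dtype=float)
    pos = doses[doses > 0]
    if not np.isfinite(result.bmc):
        return BmcResult(result.bmc, result.bmcl, result.bmcu, result.bmr,
                         valid=False, reason="no response")
    if not (pos.min() <= result.bmc <= pos.max()):
        reason = "out of range"
        valid = False
    elif not (np.isfinite(result.bmcl) and np.isfinite(result.bmcu)):
        reason = "bound not estimable"
        valid = False
    elif result.bmcu / result.bmcl >= max_ratio:
        reason = f"BMCu:BMCl ratio {result.bmcu / result.bmcl:.3g} >= {max_ratio:g}"
        valid = False
    else:
        reason = ""
        valid = True
    return BmcResult(result.bmc, result.bmcl, result.bmcu, result.bmr,
                     valid=valid, reason=reason)
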