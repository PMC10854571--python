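"""Right-censored accelerated failure time (AFT) regression.

Families share one likelihood code path on the log-time scale. With
eta_i = mu0 + x_i' beta entering as the location of log T (so
T = T0 * exp(x_i' beta): positive coefficients lengthen survival),
z_i = (log t_i - eta_i) / sigma, the per-record contribution is
delta_i * log f(t_i) + (1 - delta_i) * log S(t_i) with

  lognormal:  log T ~ Normal(eta, sigma^2)
  weibull:    log T ~ Gumbel-min(eta, sigma)  (shape = 1/sigma on time scale)
  zbln:       T ~ ZBLN(a, eta, sigma)  — log-normal parent with gamma
              generator shape a; a = 1 is the log-normal row above

Gradients are analytic except d(log S)/d(log a) for the ZBLN censored term
(the regularized upper incomplete gamma has no parameter derivative in
closed form here), which uses a tight central difference. Standard errors
come from the inverse observed information (central differences of the
gradient) with a delta-method map back to the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import optimize, special
import pandas as pd

from .cohort import CohortTable, CovariateSpec, DegenerateDesignError, encode_design
from .zbln import ZBLNParams, zbln_quantile

__all__ = ["AFTModelSpec", "FitResult", "AFTFitError", "aft_neg_loglik",
           "aft_neg_loglik_grad", "fit_aft", "acceleration_factors",
           "wald_tests", "information_criteria", "FAMILIES"]

FAMILIES = ("zbln", "lognormal", "weibull")
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class AFTFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class AFTModelSpec:
    """Family plus the covariates (cohort variable names) entering the model."""

    family: str
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if not self.covariates:
            raise ValueError("covariates must be non-empty")


@dataclass
class FitResult:
    """A fitted AFT model with everything needed to predict and report."""

    family: str
    columns: list[str]
    covariates: tuple[str, ...]
    covariate_specs: tuple[CovariateSpec, ...]
    intercept: float
    coefficients: dict[str, float]
    ancillary: dict[str, float]
    log_likelihood: float
    n: int
    k: int
    aic: float
    bic: float
    se: dict[str, float] | None
    converged: bool
    iterations: int

    # -- prediction ------------------------------------------------------
    def linear_predictor(self, cohort: CohortTable) -> np.ndarray:
        X, names = encode_design(cohort, self.covariates)
        if names != self.columns:
            raise ValueError("cohort design columns do not match the fit")
        beta = np.array([self.coefficients[c] for c in self.columns])
        return self.intercept + X @ beta

    def _sigma_a(self) -> tuple[float, float]:
        if self.family == "weibull":
            return 1.0 / self.ancillary["shape"], 1.0
        return self.ancillary["sigma"], self.ancillary.get("a", 1.0)

    def predict_median(self, cohort: CohortTable) -> np.ndarray:
        """Predicted median survival time (months) per record."""
        eta = self.linear_predictor(cohort)
        sigma, a = self._sigma_a()
        if self.family == "lognormal":
            return np.exp(eta)
        if self.family == "weibull":
            return np.exp(eta) * np.log(2.0) ** sigma
        shift = zbln_quantile(0.5, ZBLNParams(a, 0.0, sigma))
        return np.exp(eta) * shift

    def predict_survival(self, cohort: CohortTable, t: float) -> np.ndarray:
        """S(t | x) per record, at a single time t (months)."""
        eta = self.linear_predictor(cohort)
        sigma, a = self._sigma_a()
        z = (np.log(t) - eta) / sigma
        if self.family == "lognormal":
            return special.ndtr(-z)
        if self.family == "weibull":
            return np.exp(-np.exp(np.clip(z, None, 700.0)))
        return special.gammaincc(a, -special.log_ndtr(-z))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "columns": self.columns,
            "covariates": list(self.covariates),
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "ancillary": self.ancillary,
            "log_likelihood": self.log_likelihood,
            "n": self.n,
            "k": self.k,
            "aic": self.aic,
            "bic": self.bic,
            "se": self.se,
            "converged": self.converged,
            "iterations": self.iterations,
        }


# -- likelihood ----------------------------------------------------------
# Parameter packing: theta = [mu0, beta (p), log sigma] (+ [log a] for zbln)

def _unpack(theta: np.ndarray, p: int, family: str):
    mu0 = theta[0]
    beta = theta[1 : 1 + p]
    log_sigma = theta[1 + p]
    log_a = theta[2 + p] if family == "zbln" else 0.0
    return mu0, beta, np.exp(log_sigma), np.exp(log_a)


def _terms(z, logt, sigma, a, family, events):
    """Per-record log f / log S and their derivatives wrt eta and log sigma.

    Returns (ll, d_eta, d_logsigma, d_loga) arrays where each row already
    selects the event or censored branch.
    """
    d = events
    log_phi = -0.5 * z**2 - _LOG_SQRT_2PI
    if family == "lognormal":
        logf = -logt - np.log(sigma) + log_phi
        logS = special.log_ndtr(-z)
        hazN = np.exp(log_phi - logS)
        ll = np.where(d == 1, logf, logS)
        d_eta = np.where(d == 1, z / sigma, hazN / sigma)
        d_ls = np.where(d == 1, z**2 - 1.0, z * hazN)
        return ll, d_eta, d_ls, None
    if family == "weibull":
        zc = np.clip(z, None, 700.0)
        ez = np.exp(zc)
        logf = -logt - np.log(sigma) + zc - ez
        logS = -ez
        ll = np.where(d == 1, logf, logS)
        d_eta = np.where(d == 1, (ez - 1.0) / sigma, ez / sigma)
        d_ls = np.where(d == 1, -z * (1.0 - ez) - 1.0, z * ez)
        return ll, d_eta, d_ls, None
    # zbln
    logS_par = special.log_ndtr(-z)       # parent log-survival
    H = np.clip(-logS_par, 1e-300, None)  # cumulative hazard, guarded at 0
    with np.errstate(divide="ignore"):
        logH = np.log(H)
    hazN = np.exp(log_phi - logS_par)     # parent hazard of z
    glna = special.gammaln(a)
    logf = -logt - np.log(sigma) + log_phi + (a - 1.0) * logH - glna
    Q = special.gammaincc(a, H)
    with np.errstate(divide="ignore"):
        logQ = np.log(Q)
    # r = -d logQ / dH  = H^(a-1) e^(-H) / (Gamma(a) Q); -> 1 as H -> inf
    with np.errstate(invalid="ignore", over="ignore"):
        r = np.exp((a - 1.0) * logH - H - glna - logQ)
    r = np.where(np.isfinite(r), r, 1.0)
    ll = np.where(d == 1, logf, logQ)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        d_eta = np.where(d == 1, z / sigma - (a - 1.0) * hazN / (H * sigma),
                         r * hazN / sigma)
        d_ls = np.where(d == 1, (z**2 - 1.0) - (a - 1.0) * z * hazN / H,
                        r * z * hazN)
        # d/d log a: analytic for the density branch; central FD for log Q
        h = 1e-6
        dQ = (np.log(special.gammaincc(a * np.exp(h), H))
              - np.log(special.gammaincc(a * np.exp(-h), H))) / (2.0 * h)
        d_la = np.where(d == 1, a * (logH - special.digamma(a)), dQ)
    return ll, d_eta, d_ls, d_la


def aft_neg_loglik(theta, X, times, events, family) -> float:
    """Negative censored log-likelihood; non-finite evaluations are penalized."""
    t = np.asarray(times, float)
    d = np.asarray(events, int)
    p = X.shape[1]
    mu0, beta, sigma, a = _unpack(np.asarray(theta, float), p, family)
    logt = np.log(t)
    z = (logt - (mu0 + X @ beta)) / sigma
    ll, *_ = _terms(z, logt, sigma, a, family, d)
    val = -float(np.sum(ll))
    return val if np.isfinite(val) else 1e12


def aft_neg_loglik_grad(theta, X, times, events, family) -> np.ndarray:
    """Gradient of :func:`aft_neg_loglik` in the packed coordinates."""
    t = np.asarray(times, float)
    d = np.asarray(events, int)
    p = X.shape[1]
    mu0, beta, sigma, a = _unpack(np.asarray(theta, float), p, family)
    logt = np.log(t)
    z = (logt - (mu0 + X @ beta)) / sigma
    _, d_eta, d_ls, d_la = _terms(z, logt, sigma, a, family, d)
    g = np.empty_like(np.asarray(theta, float))
    g[0] = -np.sum(d_eta)
    g[1 : 1 + p] = -(X.T @ d_eta)
    g[1 + p] = -np.sum(d_ls)
    if family == "zbln":
        g[2 + p] = -np.sum(d_la)
    return np.where(np.isfinite(g), g, 0.0)


# -- fitting -------------------------------------------------------------

_A_STARTS = (0.5, 1.0, 2.0, 4.0, 8.0)


def _median_shift(a: float, sigma: float) -> float:
    return sigma * float(special.ndtri(-np.expm1(-special.gammaincinv(a, 0.5))))


def _check_design(X: np.ndarray, names: list[str]) -> None:
    const = [n for j, n in enumerate(names) if np.ptp(X[:, j]) == 0.0]
    if const:
        raise DegenerateDesignError(f"constant design columns: {const}")
    Z = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise DegenerateDesignError("design matrix (with intercept) is rank deficient")


def fit_aft(cohort: CohortTable, spec: AFTModelSpec, seed: int = 0) -> FitResult:
    """Censored MLE of an AFT model by multi-start quasi-Newton descent.

    Starts from the log-scale least-squares fit on uncensored records
    (and, for the ZBLN family, a deterministic ladder of generator shapes
    with medians aligned), then L-BFGS-B on the packed coordinates.
    Deterministic given the data; ``seed`` is accepted for interface
    stability but the start policy involves no randomness.
    """
    X, names = encode_design(cohort, spec.covariates)
    _check_design(X, names)
    t, d = cohort.times, cohort.events
    p = X.shape[1]
    n = len(t)
    logt = np.log(t)

    # optimize on a centered/scaled design (raw covariates such as age make
    # the intercept direction badly conditioned), back-transform afterwards
    m, s = X.mean(axis=0), X.std(axis=0)
    s[s == 0] = 1.0
    Xs = (X - m) / s

    # least-squares init on uncensored log-times
    unc = d == 1
    Z = np.column_stack([np.ones(int(unc.sum())), Xs[unc]])
    coef, *_ = np.linalg.lstsq(Z, logt[unc], rcond=None)
    resid = logt[unc] - Z @ coef
    s_init = max(float(np.std(resid)), 1e-2)

    base = np.concatenate([coef, [np.log(s_init)]])
    args = (Xs, t, d, spec.family)
    if spec.family == "zbln":
        theta, fun, success, total_iter = _profile_fit_zbln(base, args)
    else:
        res = optimize.minimize(
            aft_neg_loglik, base, args=args, jac=aft_neg_loglik_grad,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-5},
        )
        theta, fun, success, total_iter = res.x, res.fun, res.success, int(res.nit)
    if not np.isfinite(fun):  # pragma: no cover
        raise AFTFitError("no start produced a finite likelihood")

    # back-transform to the raw design scale
    theta = theta.copy()
    theta[1 : 1 + p] = theta[1 : 1 + p] / s
    theta[0] = theta[0] - float(np.dot(theta[1 : 1 + p], m))
    mu0, beta, sigma, a = _unpack(theta, p, spec.family)
    ll = -float(fun)

    if spec.family == "zbln":
        ancillary = {"a": float(a), "sigma": float(sigma)}
    elif spec.family == "lognormal":
        ancillary = {"sigma": float(sigma)}
    else:
        ancillary = {"shape": float(1.0 / sigma)}
    k = p + len(ancillary) + 1
    aic, bic = information_criteria(ll, k, n)

    se = _standard_errors(theta, (X, t, d, spec.family), names, spec.family,
                          sigma, a)

    return FitResult(
        family=spec.family,
        columns=names,
        covariates=tuple(spec.covariates),
        covariate_specs=tuple(cohort.spec(c) for c in spec.covariates),
        intercept=float(mu0),
        coefficients={c: float(b) for c, b in zip(names, beta)},
        ancillary=ancillary,
        log_likelihood=ll,
        n=n,
        k=k,
        aic=aic,
        bic=bic,
        se=se,
        converged=bool(success),
        iterations=total_iter,
    )


_LOG_A_BOUNDS = (np.log(0.02), np.log(50.0))


def _profile_fit_zbln(base: np.ndarray, args) -> tuple[np.ndarray, float, bool, int]:
    """Profile-likelihood fit over log a for the ZBLN family.

    The (a, mu0, sigma) directions are strongly coupled (large a with a
    shifted location re-approximates a log-normal), which leaves a long,
    nearly flat likelihood ridge that defeats joint quasi-Newton descent.
    The inner problem — (mu0, beta, log sigma) at fixed a — is as
    well-conditioned as a log-normal fit, so we minimize the profiled
    objective over log a: a deterministic ladder of shapes first
    (0.5, 1, 2, 4, 8), then a bounded scalar refinement around the best
    bracket, warm-starting each inner solve from the previous optimum.
    """
    state = {"inner": base.copy(), "iters": 0, "ok": True}
    s_init = float(np.exp(base[-1]))
    cache: dict[float, tuple[float, np.ndarray]] = {}

    def profile(log_a: float) -> float:
        log_a = float(log_a)
        if log_a in cache:
            return cache[log_a][0]
        x0 = state["inner"].copy()
        if state["iters"] == 0:  # align medians on the very first solve
            x0[0] = base[0] - _median_shift(float(np.exp(log_a)), s_init)

        def f(inner):
            return aft_neg_loglik(np.append(inner, log_a), *args)

        def g(inner):
            return aft_neg_loglik_grad(np.append(inner, log_a), *args)[:-1]

        res = optimize.minimize(
            f, x0, jac=g, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-5},
        )
        state["iters"] += int(res.nit)
        state["ok"] = state["ok"] and bool(res.success)
        state["inner"] = res.x
        cache[log_a] = (float(res.fun), res.x.copy())
        return float(res.fun)

    grid = [np.log(a) for a in _A_STARTS]
    vals = [profile(la) for la in grid]
    j = int(np.argmin(vals))
    lo = grid[j - 1] if j > 0 else _LOG_A_BOUNDS[0]
    hi = grid[j + 1] if j < len(grid) - 1 else _LOG_A_BOUNDS[1]
    state["inner"] = cache[grid[j]][1].copy()
    res = optimize.minimize_scalar(
        profile, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-4, "maxiter": 60},
    )
    best_la, best_fun = (float(res.x), float(res.fun))
    gj, gv = grid[j], vals[j]
    if gv < best_fun:  # scalar refinement never worsens the ladder optimum
        best_la, best_fun = gj, gv
    theta = np.append(cache[best_la][1], best_la)
    return theta, best_fun, state["ok"], state["iters"]


def _standard_errors(theta, args, names, family, sigma, a):
    """Observed-information SEs: central FD of the analytic gradient."""
    m = len(theta)
    H = np.empty((m, m))
    h = 1e-5 * (1.0 + np.abs(theta))
    for j in range(m):
        e = np.zeros(m)
        e[j] = h[j]
        H[:, j] = (aft_neg_loglik_grad(theta + e, *args)
                   - aft_neg_loglik_grad(theta - e, *args)) / (2.0 * h[j])
    H = 0.5 * (H + H.T)
    try:
        np.linalg.cholesky(H)
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    sd = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(sd)):
        return None
    p = len(names)
    se = {"intercept": float(sd[0])}
    for c, s in zip(names, sd[1 : 1 + p]):
        se[c] = float(s)
    # delta method from log-scale coordinates
    if family == "zbln":
        se["sigma"] = float(sd[1 + p] * sigma)
        se["a"] = float(sd[2 + p] * a)
    elif family == "lognormal":
        se["sigma"] = float(sd[1 + p] * sigma)
    else:
        se["shape"] = float(sd[1 + p] / sigma)  # d(1/sigma)/d(log sigma) = -1/sigma
    return se


# -- reporting -----------------------------------------------------------

def acceleration_factors(fit: FitResult) -> pd.DataFrame:
    """Acceleration-factor report: (variable, term, estimate, AF, p).

    AF = exp(estimate), rounded to 3 decimals; reference levels appear as
    ``(Ref)`` rows with AF exactly 1. AF > 1 means the level lengthens
    survival relative to the reference; AF < 1 shortens it.
    """
    if not fit.converged:
        raise AFTFitError("acceleration factors require a converged fit")
    pvals = wald_tests(fit)
    rows = []
    for cs in fit.covariate_specs:
        if cs.kind == "continuous":
            b = fit.coefficients[cs.name]
            rows.append((cs.name, cs.name, b, round(float(np.exp(b)), 3),
                         pvals.get(cs.name)))
        else:
            rows.append((cs.name, f"{cs.reference} (Ref)", np.nan, 1.0, np.nan))
            for lev in cs.levels:
                if lev == cs.reference:
                    continue
                col = f"{cs.name}:{lev}"
                b = fit.coefficients[col]
                rows.append((cs.name, lev, b, round(float(np.exp(b)), 3),
                             pvals.get(col)))
    return pd.DataFrame(rows, columns=["variable", "term", "estimate", "AF", "p"])


def wald_tests(fit: FitResult) -> dict[str, float]:
    """Two-sided normal p-values, p = 2 (1 - Phi(|beta / se|)), per coefficient."""
    if fit.se is None:
        return {c: float("nan") for c in fit.columns}
    out = {}
    for c in fit.columns:
        s = fit.se.get(c, float("nan"))
        if not np.isfinite(s) or s <= 0:
            out[c] = float("nan")
        else:
            z = abs(fit.coefficients[c] / s)
            out[c] = float(2.0 * special.ndtr(-z))
    return out


def information_criteria(log_likelihood: float, k: int, n: int) -> tuple[float, float]:
    """AIC = 2k - 2l; BIC = k ln n - 2l."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    aic = 2.0 * k - 2.0 * log_likelihood
    bic = k * np.log(n) - 2.0 * log_likelihood
    return float(aic), float(bic)
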