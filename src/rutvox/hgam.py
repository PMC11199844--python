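"""Hierarchical beta GAM for hourly grunt proportions.

Model: for individual *i* at hour record *t*,

    proportion ~ Beta(mu * theta, (1 - mu) * theta)
    logit(mu)  = intercept + status_contrast * dominant
                 + f_i(day) + g_i(hour) + b_i

with g_i a per-individual cyclic cubic spline on the 24-h clock (10 basis
functions), f_i a per-individual penalized cubic spline over days relative
to the rut peak (22 basis functions), and b_i ridge-penalized individual
intercepts acting as random effects.  Each individual smooth carries its
own smoothing parameter ("varying wiggliness").

Fitting maximizes the penalized beta log-likelihood by Fisher-scoring
PIRLS, profiles the precision theta by 1-D likelihood optimization, and
selects smoothing parameters with the generalized Fellner-Schall update —
a fixed-point iteration on the Laplace-approximate (REML-type) marginal
likelihood.  Exact zeros/ones in the response are moved inside the open
unit interval by a fixed offset of 2.2e-14 before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special as sp
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .splines import CyclicCubicBasis, PSplineBasis, center_basis

__all__ = ["HGAMSpec", "HGAMFit", "HGAMConvergenceError", "fit_hgam", "predict_smooths", "diagnostics"]

STATUS_LEVELS = ("dominant", "subdominant")


class HGAMConvergenceError(RuntimeError):
    """Raised when the penalized-likelihood fit fails to converge; carries
    the iteration trace for inspection."""

    def __init__(self, message: str, trace: list):
        super().__init__(message + f" (trace: {trace[-5:]})")
        self.trace = trace


@dataclass(frozen=True)
class HGAMSpec:
    """Model structure and fitting controls."""

    k_hour: int = 10
    k_day: int = 22
    zero_offset: float = 2.2e-14
    max_outer: int = 60
    max_pirls: int = 200
    tol: float = 1e-7
    lambda_tol: float = 2e-2
    lambda_init: float = 1.0

    def __post_init__(self) -> None:
        if self.k_hour < 4 or self.k_day < 4:
            raise ValueError("basis sizes must be >= 4")
        if self.zero_offset <= 0:
            raise ValueError("zero_offset must be positive")


@dataclass
class _Block:
    name: str
    sl: slice
    S: np.ndarray | None  # penalty in block coordinates, None = unpenalized
    lam: float = 1.0
    rank: int = 0


@dataclass
class HGAMFit:
    """A fitted hierarchical beta GAM."""

    beta: np.ndarray
    V: np.ndarray  # Bayesian posterior covariance of beta
    theta: float
    blocks: list
    individuals: list
    hour_basis: CyclicCubicBasis
    day_basis: PSplineBasis
    Z_hour: np.ndarray
    Z_day: np.ndarray
    day_range: tuple
    mu_hat: np.ndarray
    y: np.ndarray
    loglik: float
    deviance: float
    null_deviance: float
    deviance_explained: float
    adjusted_r2: float
    edf: dict
    edf_total: float
    lambdas: dict
    converged: bool
    trace: list

    @property
    def status_contrast(self) -> float:
        """Dominant-minus-subdominant contrast on the logit scale."""
        return float(self.beta[self._block("status").sl][0])

    @property
    def status_se(self) -> float:
        i = self._block("status").sl.start
        return float(np.sqrt(self.V[i, i]))

    def _block(self, name: str) -> _Block:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def summary(self) -> dict:
        return {
            "status_contrast": self.status_contrast,
            "status_se": self.status_se,
            "status_z": self.status_contrast / self.status_se,
            "theta": self.theta,
            "deviance_explained": self.deviance_explained,
            "adjusted_r2": self.adjusted_r2,
            "edf": dict(self.edf),
            "lambdas": dict(self.lambdas),
            "n": int(self.y.size),
            "converged": self.converged,
        }


# --- beta log-likelihood pieces -----------------------------------------


def beta_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> np.ndarray:
    """Pointwise log-density of Beta(mu*theta, (1-mu)*theta) at y."""
    a = mu * theta
    b = (1.0 - mu) * theta
    return (
        sp.gammaln(theta)
        - sp.gammaln(a)
        - sp.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -35, 35)))


def _eta_grad_weight(y, mu, theta):
    """Gradient of the log-likelihood w.r.t. eta and the Fisher weight."""
    ystar = np.log(y) - np.log1p(-y)
    mustar = sp.digamma(mu * theta) - sp.digamma((1 - mu) * theta)
    dmu = mu * (1 - mu)
    u = theta * (ystar - mustar) * dmu
    w = theta**2 * (sp.polygamma(1, mu * theta) + sp.polygamma(1, (1 - mu) * theta)) * dmu**2
    return u, w


# --- design assembly -----------------------------------------------------


def _prepare_records(records: pd.DataFrame, spec: HGAMSpec):
    df = records[records["status"].isin(STATUS_LEVELS)].copy()
    if df.empty:
        raise ValueError("no records with dominant/subdominant status")
    individuals = sorted(df["individual"].unique())
    if len(individuals) < 2:
        raise ValueError("hierarchical fit needs at least 2 individuals")
    if set(df["status"].unique()) != set(STATUS_LEVELS):
        raise ValueError("both dominant and subdominant records are required")
    y = df["proportion"].to_numpy(dtype=float)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("proportions must lie in [0, 1]")
    y = np.where(y <= 0, spec.zero_offset, y)
    y = np.where(y >= 1, 1.0 - spec.zero_offset, y)
    return df.reset_index(drop=True), individuals, y


def _build_design(df: pd.DataFrame, individuals: list, spec: HGAMSpec):
    n = len(df)
    hour = df["hour"].to_numpy(dtype=float)
    day = df["day_rel_peak"].to_numpy(dtype=float)
    dominant = (df["status"] == "dominant").to_numpy(dtype=float)

    hour_basis = CyclicCubicBasis(k=spec.k_hour, period=24.0)
    day_basis = PSplineBasis(day, k=spec.k_day)
    Xh_all = hour_basis.design(hour)
    Xd_all = day_basis.design(day)
    Xh_c, Sh_c, Z_hour = center_basis(Xh_all, hour_basis.penalty)
    Xd_c, Sd_c, Z_day = center_basis(Xd_all, day_basis.penalty)

    cols: list[np.ndarray] = []
    blocks: list[_Block] = []
    p = 0

    def add(name, M, S):
        nonlocal p
        cols.append(M)
        blocks.append(_Block(name, slice(p, p + M.shape[1]), S))
        p += M.shape[1]

    add("intercept", np.ones((n, 1)), None)
    add("status", dominant[:, None], None)
    # ridge-penalized individual intercepts: one shared variance component
    Xre = np.zeros((n, len(individuals)))
    for j, ind in enumerate(individuals):
        Xre[df["individual"].to_numpy() == ind, j] = 1.0
    add("re_individual", Xre, np.eye(len(individuals)))
    for ind in individuals:
        mask = (df["individual"] == ind).to_numpy()
        M = np.zeros((n, Xh_c.shape[1]))
        M[mask] = Xh_c[mask]
        add(f"hour[{ind}]", M, Sh_c)
    for ind in individuals:
        mask = (df["individual"] == ind).to_numpy()
        M = np.zeros((n, Xd_c.shape[1]))
        M[mask] = Xd_c[mask]
        add(f"day[{ind}]", M, Sd_c)

    X = np.concatenate(cols, axis=1)
    for b in blocks:
        if b.S is not None:
            ev = np.linalg.eigvalsh(b.S)
            b.rank = int(np.sum(ev > 1e-10 * max(ev.max(), 1e-300)))
    return X, blocks, hour_basis, day_basis, Z_hour, Z_day


def _total_penalty(blocks: list, p: int) -> np.ndarray:
    S = np.zeros((p, p))
    for b in blocks:
        if b.S is not None:
            S[b.sl, b.sl] += b.lam * b.S
    return S


# --- fitting -------------------------------------------------------------


def _penalized_loglik(y, X, beta, theta, S_lam):
    mu = np.clip(_sigmoid(X @ beta), 1e-12, 1 - 1e-12)
    return float(beta_loglik(y, mu, theta).sum() - 0.5 * beta @ S_lam @ beta)


def _pirls(y, X, beta, theta, S_lam, max_iter, tol, trace):
    """Fisher-scoring Newton iterations for beta at fixed theta, lambda."""
    pll = _penalized_loglik(y, X, beta, theta, S_lam)
    for it in range(max_iter):
        eta = X @ beta
        mu = np.clip(_sigmoid(eta), 1e-12, 1 - 1e-12)
        u, w = _eta_grad_weight(y, mu, theta)
        grad = X.T @ u - S_lam @ beta
        H = (X * w[:, None]).T @ X + S_lam
        try:
            c = cho_factor(H + 1e-10 * np.eye(len(beta)))
        except np.linalg.LinAlgError as exc:
            raise HGAMConvergenceError(f"Hessian factorization failed: {exc}", trace)
        step = cho_solve(c, grad)
        # step halving on the penalized log-likelihood
        for _half in range(30):
            cand = beta + step
            pll_new = _penalized_loglik(y, X, cand, theta, S_lam)
            if np.isfinite(pll_new) and pll_new >= pll - 1e-12:
                break
            step = step / 2.0
        else:
            break
        improved = pll_new - pll
        beta, pll = cand, pll_new
        if improved < tol * (abs(pll) + 1.0):
            break
    return beta, pll


def _profile_theta(y, X, beta, theta):
    mu = np.clip(_sigmoid(X @ beta), 1e-12, 1 - 1e-12)

    def nll(log_theta):
        return -float(beta_loglik(y, mu, np.exp(log_theta)).sum())

    res = minimize_scalar(nll, bounds=(np.log(1e-2), np.log(1e5)), method="bounded",
                          options={"xatol": 1e-6})
    return float(np.exp(res.x))


def fit_hgam(records: pd.DataFrame, spec: HGAMSpec | None = None) -> HGAMFit:
    """Fit the hierarchical beta GAM to hourly grunt-proportion records.

    `records` needs columns individual, hour, day_rel_peak, status,
    proportion; records with unknown status are excluded.  Raises
    :class:`HGAMConvergenceError` (with trace) rather than returning a
    silent partial fit.
    """
    spec = spec or HGAMSpec()
    df, individuals, y = _prepare_records(records, spec)
    X, blocks, hour_basis, day_basis, Z_hour, Z_day = _build_design(df, individuals, spec)
    p = X.shape[1]
    for b in blocks:
        if b.S is not None:
            b.lam = spec.lambda_init

    # initial values
    beta = np.zeros(p)
    ybar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
    beta[0] = np.log(ybar / (1 - ybar))
    v = y.var()
    theta = float(np.clip(ybar * (1 - ybar) / max(v, 1e-12) - 1.0, 0.5, 1e4))

    trace: list = []
    converged = False
    for outer in range(spec.max_outer):
        S_lam = _total_penalty(blocks, p)
        for _cycle in range(2):
            beta, pll = _pirls(y, X, beta, theta, S_lam, spec.max_pirls, spec.tol, trace)
            theta = _profile_theta(y, X, beta, theta)
        # Fellner-Schall update of each smoothing parameter
        mu = np.clip(_sigmoid(X @ beta), 1e-12, 1 - 1e-12)
        _u, w = _eta_grad_weight(y, mu, theta)
        H = (X * w[:, None]).T @ X
        c = cho_factor(H + S_lam + 1e-10 * np.eye(p))
        V = cho_solve(c, np.eye(p))
        max_change = 0.0
        for b in blocks:
            if b.S is None:
                continue
            bb = beta[b.sl]
            den = float(bb @ b.S @ bb)
            num = b.rank / b.lam - float(np.trace(V[b.sl, b.sl] @ b.S))
            num = max(num, 1e-12)
            lam_new = float(np.clip(b.lam * num / max(den, 1e-12), 1e-6, 1e8))
            # a lambda at the ceiling means "smooth to its null space";
            # its march to the cap should not block convergence
            if lam_new < 1e8 or b.lam < 1e8:
                if not (lam_new == 1e8 and b.lam * num / max(den, 1e-12) >= 1e8):
                    max_change = max(max_change, abs(np.log(lam_new) - np.log(b.lam)))
            b.lam = lam_new
        trace.append({"outer": outer, "pll": pll, "theta": theta, "max_dloglam": max_change})
        if max_change < spec.lambda_tol:
            converged = True
            break
    if not converged and trace and trace[-1]["max_dloglam"] > 0.5:
        raise HGAMConvergenceError(
            "smoothing-parameter iteration did not converge", trace
        )

    # final fit and summaries at the selected lambdas
    S_lam = _total_penalty(blocks, p)
    beta, pll = _pirls(y, X, beta, theta, S_lam, spec.max_pirls, spec.tol, trace)
    theta = _profile_theta(y, X, beta, theta)
    beta, pll = _pirls(y, X, beta, theta, S_lam, spec.max_pirls, spec.tol, trace)
    mu_hat = np.clip(_sigmoid(X @ beta), 1e-12, 1 - 1e-12)
    _u, w = _eta_grad_weight(y, mu_hat, theta)
    H = (X * w[:, None]).T @ X
    c = cho_factor(H + S_lam + 1e-10 * np.eye(p))
    V = cho_solve(c, np.eye(p))
    F = V @ H
    edf = {b.name: float(np.trace(F[b.sl, b.sl])) for b in blocks}
    edf_total = float(np.trace(F))

    loglik = float(beta_loglik(y, mu_hat, theta).sum())
    ll_sat = float(beta_loglik(y, _saturated_mu(y, theta), theta).sum())
    deviance = 2.0 * (ll_sat - loglik)
    mu_null = _null_mu(y, theta)
    ll_null = float(beta_loglik(y, np.full_like(y, mu_null), theta).sum())
    null_deviance = 2.0 * (ll_sat - ll_null)
    dev_expl = 1.0 - deviance / null_deviance if null_deviance > 0 else np.nan
    r2 = float(np.corrcoef(y, mu_hat)[0, 1] ** 2) if np.std(mu_hat) > 0 else 0.0
    n = y.size
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / max(n - 1 - edf_total, 1.0)

    return HGAMFit(
        beta=beta,
        V=V,
        theta=theta,
        blocks=blocks,
        individuals=individuals,
        hour_basis=hour_basis,
        day_basis=day_basis,
        Z_hour=Z_hour,
        Z_day=Z_day,
        day_range=(float(df["day_rel_peak"].min()), float(df["day_rel_peak"].max())),
        mu_hat=mu_hat,
        y=y,
        loglik=loglik,
        deviance=deviance,
        null_deviance=null_deviance,
        deviance_explained=float(dev_expl),
        adjusted_r2=float(adj_r2),
        edf=edf,
        edf_total=edf_total,
        lambdas={b.name: b.lam for b in blocks if b.S is not None},
        converged=converged,
        trace=trace,
    )


def _saturated_mu(y: np.ndarray, theta: float) -> np.ndarray:
    """Per-observation likelihood-maximizing mean at fixed theta.

    Solves digamma(mu*theta) - digamma((1-mu)*theta) = logit(y) by Newton
    iteration on logit(mu); unlike the naive mu = y this is a true upper
    bound of the likelihood, so deviances are non-negative even at the
    offset-adjusted boundary observations.
    """
    ystar = np.log(y) - np.log1p(-y)
    x = np.clip(ystar, -30, 30)  # logit-mu iterate
    for _ in range(100):
        mu = _sigmoid(x)
        a, b = mu * theta, (1 - mu) * theta
        g = sp.digamma(a) - sp.digamma(b) - ystar
        dg = theta * (sp.polygamma(1, a) + sp.polygamma(1, b)) * mu * (1 - mu)
        step = np.clip(g / np.maximum(dg, 1e-12), -5, 5)
        x = x - step
        if np.max(np.abs(g)) < 1e-10:
            break
    return np.clip(_sigmoid(x), 1e-12, 1 - 1e-12)


def _null_mu(y, theta):
    """Common-mean MLE of the beta likelihood at fixed theta."""

    def nll(logit_mu):
        mu = _sigmoid(np.array([logit_mu]))[0]
        return -float(beta_loglik(y, np.full_like(y, mu), theta).sum())

    res = minimize_scalar(nll, bounds=(-12, 12), method="bounded")
    return float(_sigmoid(np.array([res.x]))[0])


# --- prediction and diagnostics -----------------------------------------


def predict_smooths(
    fit: HGAMFit,
    hour_grid: np.ndarray | None = None,
    day_grid: np.ndarray | None = None,
    ci: float = 0.95,
) -> dict:
    """Per-individual smooth curves with pointwise confidence bands.

    Returns ``{"hour": DataFrame, "day": DataFrame}`` with columns
    individual, x, estimate, lo, hi (and ``extrapolated`` for the day
    smooth when the grid leaves the observed span).  Curves are the
    centered smooth contributions on the logit scale.
    """
    z = stats.norm.ppf(0.5 + ci / 2.0)
    if hour_grid is None:
        hour_grid = np.linspace(0.0, 24.0, 97)
    if day_grid is None:
        day_grid = np.linspace(fit.day_range[0], fit.day_range[1], 101)
    hour_grid = np.asarray(hour_grid, dtype=float)
    day_grid = np.asarray(day_grid, dtype=float)

    Xh = fit.hour_basis.design(hour_grid) @ fit.Z_hour
    Xd = fit.day_basis.design(np.clip(day_grid, *fit.day_range)) @ fit.Z_day
    out = {}
    rows_h, rows_d = [], []
    for ind in fit.individuals:
        bh = fit._block(f"hour[{ind}]")
        est = Xh @ fit.beta[bh.sl]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xh, fit.V[bh.sl, bh.sl], Xh), 0))
        rows_h.append(
            pd.DataFrame(
                {"individual": ind, "x": hour_grid, "estimate": est,
                 "lo": est - z * se, "hi": est + z * se}
            )
        )
        bd = fit._block(f"day[{ind}]")
        est = Xd @ fit.beta[bd.sl]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xd, fit.V[bd.sl, bd.sl], Xd), 0))
        rows_d.append(
            pd.DataFrame(
                {"individual": ind, "x": day_grid, "estimate": est,
                 "lo": est - z * se, "hi": est + z * se,
                 "extrapolated": (day_grid < fit.day_range[0]) | (day_grid > fit.day_range[1])}
            )
        )
    out["hour"] = pd.concat(rows_h, ignore_index=True)
    out["day"] = pd.concat(rows_d, ignore_index=True)
    return out


def diagnostics(fit: HGAMFit, records: pd.DataFrame | None = None, max_lag: int = 10) -> dict:
    """Quantile residuals, residual-vs-fitted table and per-individual
    residual autocorrelation."""
    a = fit.mu_hat * fit.theta
    b = (1 - fit.mu_hat) * fit.theta
    u = np.clip(stats.beta.cdf(fit.y, a, b), 1e-12, 1 - 1e-12)
    resid = stats.norm.ppf(u)

    ind_of_row = None
    if records is not None:
        df = records[records["status"].isin(STATUS_LEVELS)].reset_index(drop=True)
        if len(df) == len(resid):
            ind_of_row = df["individual"].to_numpy()
    table = pd.DataFrame({"fitted": fit.mu_hat, "residual": resid})
    if ind_of_row is not None:
        table["individual"] = ind_of_row

    def acf(x, k):
        x = x - x.mean()
        denom = float(x @ x)
        if denom == 0:
            return np.zeros(k + 1)
        return np.array([1.0] + [float(x[lag:] @ x[:-lag]) / denom for lag in range(1, k + 1)])

    acfs = {}
    if ind_of_row is not None:
        for ind in fit.individuals:
            r = resid[ind_of_row == ind]
            if r.size > max_lag + 1:
                acfs[ind] = acf(r, max_lag)
    acfs["all"] = acf(resid, max_lag)
    return {"residuals": resid, "table": table, "acf": acfs}
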