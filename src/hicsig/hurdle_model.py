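"""Hurdle zero-truncated negative binomial null model for Hi-C counts.

The background distribution of an interaction-bin count ``y_ij`` is modelled
in two parts.  A Bernoulli gate decides whether the bin "drops out" (count 0,
probability ``pi0_ij``); conditional on crossing the hurdle the count follows
a zero-truncated negative binomial (ZTNB) with mean ``mu_ij`` and a single
per-chromosome dispersion ``alpha`` (NB2 parameterization, variance
``mu + alpha * mu**2``).  Both linear predictors share one design: a 6-column
B-spline basis in genomic distance (order 3, i.e. quadratic, with three inner
knots at the 25/50/75% distance quantiles and boundary knots 0 and 2 Mb) plus
standardized log GC-content and log mappability products (and, for uniform
bins, log effective sequence space).  Because the spline basis is a partition
of unity its span contains the constant function, so no separate intercept
column is added to the fitted design.

Training is two-pass: fit on a random sample of records, drop records whose
count lies in the extreme upper tail of their fitted null (``P(Y >= y) <
1 - outlier_q``, default 2.5%) as potential true interactions, then refit.
Each record then receives an upper-tail P value ``P(Y >= y)`` under its
fitted hurdle law, and BH-adjusted q values control the FDR.  Observed /
expected (O/E) ratios use the full hurdle mean as the expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.interpolate import BSpline
from statsmodels.stats.multitest import multipletests

MAX_DISTANCE = 2_000_000.0

# Below this dispersion the NB is numerically Poisson: the NB/Poisson pmf
# difference (~alpha) is smaller than gammaln round-off at r = 1/alpha.
_ALPHA_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# distance spline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineSpec:
    """B-spline basis for the distance decay.

    ``order`` is the spline order (degree + 1); the default order-3
    (quadratic) basis with three inner knots gives ``df = 6`` basis functions
    that form a partition of unity on ``[boundary[0], boundary[1]]``.
    """

    inner_knots: tuple
    order: int = 3
    boundary: tuple = (0.0, MAX_DISTANCE)

    def __post_init__(self):
        lo, hi = self.boundary
        ik = tuple(float(k) for k in self.inner_knots)
        if list(ik) != sorted(ik):
            raise ValueError("inner knots must be sorted")
        if ik and (ik[0] <= lo or ik[-1] >= hi):
            raise ValueError("inner knots must lie strictly inside boundary")
        object.__setattr__(self, "inner_knots", ik)

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def df(self) -> int:
        return len(self.inner_knots) + self.order

    @property
    def knots(self) -> np.ndarray:
        """Full knot vector with boundary multiplicity = order."""
        lo, hi = self.boundary
        return np.concatenate((np.full(self.order, lo), self.inner_knots,
                               np.full(self.order, hi)))

    @classmethod
    def from_distances(cls, d, df: int = 6, order: int = 3,
                       boundary=(0.0, MAX_DISTANCE)) -> "SplineSpec":
        """Inner knots at equally spaced quantiles of the observed distances
        (25/50/75% for the default df = 6, order 3)."""
        n_inner = df - order
        if n_inner < 0:
            raise ValueError("df must be >= order")
        qs = np.linspace(0, 1, n_inner + 2)[1:-1]
        inner = np.quantile(np.asarray(d, float), qs)
        # guard against duplicate quantiles on discrete distance grids
        eps = (boundary[1] - boundary[0]) * 1e-9
        for k in range(1, len(inner)):
            if inner[k] <= inner[k - 1]:
                inner[k] = inner[k - 1] + eps
        inner = np.clip(inner, boundary[0] + eps, boundary[1] - eps)
        return cls(tuple(inner), order=order, boundary=tuple(boundary))


def bspline_basis(d, spec: SplineSpec) -> np.ndarray:
    """Evaluate the basis at distances ``d`` -> array of shape (n, df).

    Values are >= 0 and each row sums to 1 (partition of unity).  Distances
    outside the boundary knots raise; callers clamp at the cap beforehand.
    """
    d = np.atleast_1d(np.asarray(d, float))
    lo, hi = spec.boundary
    if np.any(d < lo) or np.any(d > hi):
        raise ValueError(f"distance outside boundary knots [{lo}, {hi}]")
    at_hi = d == hi
    x = np.where(at_hi, lo, d)  # placeholder; fixed below
    B = BSpline.design_matrix(x, spec.knots, spec.degree).toarray()
    if at_hi.any():
        right = np.zeros(spec.df)
        right[-1] = 1.0
        B[at_hi] = right
    return B


def design_matrix(records: pd.DataFrame, spec: SplineSpec,
                  uniform: bool = False):
    """Design shared by both model parts: spline columns + bias covariates."""
    X = bspline_basis(records["d"].to_numpy(), spec)
    names = [f"bs{k + 1}" for k in range(spec.df)]
    cols = [X, records["log_gc_z"].to_numpy()[:, None],
            records["log_map_z"].to_numpy()[:, None]]
    names += ["gc", "map"]
    if uniform:
        cols.append(records["log_eff_z"].to_numpy()[:, None])
        names.append("eff")
    return np.hstack(cols), names


# ---------------------------------------------------------------------------
# hurdle distribution
# ---------------------------------------------------------------------------

def _nb_logpmf(y, mu, alpha):
    """log NB2 pmf; collapses to Poisson for alpha below the floor."""
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    alpha = np.asarray(alpha, float)
    pois = stats.poisson.logpmf(y, mu)
    a = np.maximum(alpha, _ALPHA_FLOOR)
    r = 1.0 / a
    nb = (special.gammaln(y + r) - special.gammaln(r)
          - special.gammaln(y + 1)
          - r * np.log1p(mu / r) + y * (np.log(mu) - np.log(r + mu)))
    return np.where(alpha < _ALPHA_FLOOR, pois, nb)


def _nb_logp0(mu, alpha):
    """log P(Y = 0) under NB2 (Poisson limit: -mu)."""
    mu = np.asarray(mu, float)
    alpha = np.asarray(alpha, float)
    a = np.maximum(alpha, _ALPHA_FLOOR)
    return np.where(alpha < _ALPHA_FLOOR, -mu, -np.log1p(mu * a) / a)


def _log1mexp(logp):
    """log(1 - exp(logp)) for logp <= 0, stable near both ends."""
    logp = np.asarray(logp, float)
    with np.errstate(divide="ignore"):
        return np.where(logp > -0.6931471805599453,
                        np.log(-np.expm1(logp)),
                        np.log1p(-np.exp(logp)))


def hurdle_pmf(y, mu, alpha, pi0):
    """P(Y = y) under the hurdle-ZTNB law (vectorized, log-space internally).

    ``P(0) = pi0``; for y >= 1,
    ``P(y) = (1 - pi0) * NB(y; mu, alpha) / (1 - NB(0; mu, alpha))``.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, float)
    pi0 = np.asarray(pi0, float)
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if np.any(pi0 < 0) or np.any(pi0 > 1):
        raise ValueError("pi0 must be in [0, 1]")
    if np.any(np.asarray(alpha, float) < 0):
        raise ValueError("alpha must be >= 0")
    y_arr, mu, pi0 = np.broadcast_arrays(y, mu, pi0)
    logp0 = _nb_logp0(mu, alpha)
    with np.errstate(divide="ignore"):
        log_pos = (np.log1p(-pi0) + _nb_logpmf(np.maximum(y_arr, 1), mu, alpha)
                   - _log1mexp(logp0))
    out = np.where(y_arr == 0, pi0, np.exp(log_pos))
    return out if out.ndim else float(out)


def hurdle_mean(mu, alpha, pi0):
    """Mean of the full hurdle distribution: (1-pi0) * mu / (1 - NB(0))."""
    return (1.0 - np.asarray(pi0, float)) * np.asarray(mu, float) \
        / -np.expm1(_nb_logp0(mu, alpha))


def interaction_pvalue(y, mu, alpha, pi0):
    """Upper-tail P value ``P(Y >= y)`` under the fitted hurdle law.

    y = 0 gives p = 1 (the empty sum); y = 1 gives ``1 - pi0``.  For y >= 2
    the NB survival function is evaluated in scipy and renormalized over the
    truncated support.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, float)
    pi0 = np.asarray(pi0, float)
    alpha = float(alpha)
    y_arr, mu, pi0 = np.broadcast_arrays(y, mu, pi0)
    logp0 = _nb_logp0(mu, alpha)
    if alpha < _ALPHA_FLOOR:
        sf = stats.poisson.sf(np.maximum(y_arr, 1) - 1, mu)
    else:
        r = 1.0 / alpha
        sf = stats.nbinom.sf(np.maximum(y_arr, 1) - 1, r, r / (r + mu))
    p = (1.0 - pi0) * sf / -np.expm1(logp0)
    p = np.where(y_arr == 0, 1.0, np.minimum(p, 1.0))
    p = np.maximum(p, np.finfo(float).tiny)
    return p if p.ndim else float(p)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values; NaNs pass through."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def oe_normalize(y, mu, alpha, pi0):
    """Observed / expected ratio, with the hurdle mean as expectation."""
    ey = hurdle_mean(mu, alpha, pi0)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.asarray(y, float) / ey
    return np.where(ey > 0, oe, np.nan)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class HurdleFit:
    """Fitted two-part null model for one chromosome."""

    beta: np.ndarray            # count-part coefficients (ZTNB, log link)
    gamma: np.ndarray           # zero-part coefficients (P(zero), logit link)
    alpha: float                # NB2 dispersion, >= 0
    colnames: list
    loglik: float
    converged: bool
    n_train: int
    family: str = "nb"          # "nb" or "poisson" (ZTP count part)
    n_outliers_removed: int = 0
    chrom: str | None = None
    spline: SplineSpec | None = None
    standardization_stats: dict | None = None
    seed: int | None = None
    beta_se: np.ndarray | None = None
    gamma_se: np.ndarray | None = None
    log_alpha_se: float | None = None
    uniform: bool = False

    def predict(self, X: np.ndarray):
        """Return (mu, pi0) for a design matrix with matching columns."""
        eta = np.clip(X @ self.beta, -30, 30)
        zeta = np.clip(X @ self.gamma, -30, 30)
        return np.exp(eta), special.expit(zeta)

    def to_json(self, path):
        d = asdict(self)
        for k in ("beta", "gamma", "beta_se", "gamma_se"):
            if d[k] is not None:
                d[k] = np.asarray(d[k]).tolist()
        if self.spline is not None:
            d["spline"] = {"inner_knots": list(self.spline.inner_knots),
                           "order": self.spline.order,
                           "boundary": list(self.spline.boundary)}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "HurdleFit":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("spline"):
            s = d["spline"]
            d["spline"] = SplineSpec(tuple(s["inner_knots"]), s["order"],
                                     tuple(s["boundary"]))
        for k in ("beta", "gamma", "beta_se", "gamma_se"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], float)
        return cls(**d)


def _logit_irls(X, z, ridge=1e-6, max_iter=200, tol=1e-10):
    """Ridge-guarded IRLS for the Bernoulli zero part (response z in {0,1}).

    The tiny ridge keeps separated data (e.g. all counts positive) finite.
    Returns (coef, cov, loglik, converged).
    """
    n, p = X.shape
    g = np.zeros(p)
    H = np.eye(p)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ g, -30, 30)
        pr = special.expit(eta)
        w = pr * (1 - pr) + 1e-12
        grad = X.T @ (z - pr) - ridge * g
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        step = np.linalg.solve(H, grad)
        g = g + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ g, -30, 30)
    ll = float(np.sum(z * eta - np.logaddexp(0.0, eta)))
    cov = np.linalg.inv(H)
    return g, cov, ll, converged


def _poisson_init(X, y):
    """Poisson IRLS on positive counts — starting values for the ZTNB part."""
    beta, *_ = np.linalg.lstsq(X, np.log(np.asarray(y, float) + 0.5),
                               rcond=None)
    for _ in range(50):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        H = (X * mu[:, None]).T @ X + 1e-8 * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-9:
            break
    return beta


def _ztnb_nll_grad(theta, X, y, family):
    """Negative log-likelihood and gradient of the zero-truncated count part.

    ``theta = (beta, log_alpha)`` for the NB family, ``theta = beta`` for the
    Poisson (ZTP) family.  All counts in ``y`` are >= 1.
    """
    if family == "nb":
        beta, la = theta[:-1], theta[-1]
        r = np.exp(-la)            # r = 1 / alpha
    else:
        beta = theta
    eta = np.clip(X @ beta, -30, 30)
    mu = np.exp(eta)
    if family == "poisson":
        em = np.exp(-mu)
        log1m = _log1mexp(-mu)
        ll = y * eta - mu - special.gammaln(y + 1) - log1m
        dll_deta = (y - mu - mu * em / (1 - em))
        grad = np.empty(len(beta))
        grad[:] = -(X.T @ dll_deta)
        return -float(np.sum(ll)), grad
    logp0 = -r * np.log1p(mu / r)
    log1m = _log1mexp(logp0)
    lognb = (special.gammaln(y + r) - special.gammaln(r)
             - special.gammaln(y + 1)
             + logp0 + y * (eta - np.log(r + mu)))
    ll = lognb - log1m
    p0 = np.exp(logp0)
    ratio = p0 / -np.expm1(logp0)
    dll_deta = (y - mu * (y + r) / (r + mu)
                - mu * r / (r + mu) * ratio)
    dlogp0_dr = np.log(r / (r + mu)) + 1 - r / (r + mu)
    dll_dr = (special.digamma(y + r) - special.digamma(r)
              + dlogp0_dr - y / (r + mu)
              + ratio * dlogp0_dr)
    grad = np.empty(len(theta))
    grad[:-1] = -(X.T @ dll_deta)
    grad[-1] = float(np.sum(dll_dr) * r)   # d/d(log alpha) = -r * d/dr; nll
    return -float(np.sum(ll)), grad


def hurdle_loglik(fit: HurdleFit, X, y) -> float:
    """Total log-likelihood of ``fit`` on data (X, y) under the written
    two-part model (Bernoulli zero part + zero-truncated count part)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    zeta = np.clip(X @ fit.gamma, -30, 30)
    z = (y == 0).astype(float)
    ll_zero = float(np.sum(z * zeta - np.logaddexp(0.0, zeta)))
    pos = y > 0
    if fit.family == "nb":
        theta = np.append(fit.beta, np.log(max(fit.alpha, _ALPHA_FLOOR)))
    else:
        theta = fit.beta
    nll, _ = _ztnb_nll_grad(theta, X[pos], np.asarray(y[pos], float),
                            fit.family)
    return ll_zero - nll


def _fd_hessian(fun_grad, theta, *args, eps=1e-5):
    p = len(theta)
    H = np.zeros((p, p))
    for k in range(p):
        tp = theta.copy()
        tp[k] += eps
        tm = theta.copy()
        tm[k] -= eps
        H[:, k] = (fun_grad(tp, *args)[1] - fun_grad(tm, *args)[1]) / (2 * eps)
    return (H + H.T) / 2


def fit_hurdle_glm(X, y, colnames=None, family: str = "nb",
                   ridge: float = 1e-6) -> HurdleFit:
    """Maximum-likelihood fit of the two separable model parts.

    The zero part (Bernoulli, logit link on P(zero)) is fit by ridge-guarded
    IRLS; the count part (ZTNB on positive counts, log link, shared
    dispersion) by L-BFGS-B on ``(beta, log alpha)`` with analytic gradient,
    polished by Newton steps.  Convergence requires per-observation gradient
    max-norm < 1e-6 and relative log-likelihood change < 1e-8.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite entries")
    if np.all(y == 0):
        raise ValueError("degenerate data: all counts are zero")
    if family not in ("nb", "poisson"):
        raise ValueError(f"unknown family {family!r}")
    n, p = X.shape
    if colnames is None:
        colnames = [f"x{k}" for k in range(p)]

    # --- zero part: model P(y == 0) ---
    z = (y == 0).astype(float)
    gamma, gcov, ll_zero, zconv = _logit_irls(X, z, ridge=ridge)

    # --- count part: ZTNB on positives ---
    pos = y > 0
    Xp, yp = X[pos], np.asarray(y[pos], float)
    beta0 = _poisson_init(Xp, yp)
    if family == "nb":
        theta = np.append(beta0, np.log(0.5))
        bounds = [(None, None)] * p + [(-20.0, 10.0)]
    else:
        theta = beta0
        bounds = [(None, None)] * p
    res = optimize.minimize(_ztnb_nll_grad, theta, args=(Xp, yp, family),
                            jac=True, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12,
                                     "gtol": 1e-9})
    theta = res.x
    nll, grad = _ztnb_nll_grad(theta, Xp, yp, family)
    H = None
    # Newton polish: quadratic convergence to the stated tolerances
    for _ in range(25):
        if np.max(np.abs(grad)) / max(len(yp), 1) < 1e-8:
            break
        H = _fd_hessian(_ztnb_nll_grad, theta, Xp, yp, family)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(len(theta)), -grad)
        except np.linalg.LinAlgError:
            break
        new = theta + step
        if family == "nb":
            new[-1] = np.clip(new[-1], -20.0, 10.0)
        new_nll, new_grad = _ztnb_nll_grad(new, Xp, yp, family)
        if not np.isfinite(new_nll) or new_nll > nll + 1e-8 * abs(nll):
            # backtrack
            ok = False
            for frac in (0.5, 0.25, 0.1, 0.01):
                cand = theta + frac * step
                c_nll, c_grad = _ztnb_nll_grad(cand, Xp, yp, family)
                if np.isfinite(c_nll) and c_nll <= nll:
                    new, new_nll, new_grad = cand, c_nll, c_grad
                    ok = True
                    break
            if not ok:
                break
        rel_change = abs(new_nll - nll) / max(abs(nll), 1.0)
        theta, nll, grad = new, new_nll, new_grad
        if rel_change < 1e-14:
            break
    if H is None:
        H = _fd_hessian(_ztnb_nll_grad, theta, Xp, yp, family)
    converged = bool(np.max(np.abs(grad)) / max(len(yp), 1) < 1e-6)

    if family == "nb":
        beta, alpha = theta[:-1], float(np.exp(theta[-1]))
        if theta[-1] <= -20.0 + 1e-9:
            alpha = 0.0
    else:
        beta, alpha = theta, 0.0

    try:
        cov = np.linalg.inv(H + 1e-12 * np.eye(len(theta)))
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(len(theta), np.nan)
    beta_se = se[:p] if family == "nb" else se
    la_se = float(se[-1]) if family == "nb" else None

    return HurdleFit(beta=beta, gamma=gamma, alpha=alpha,
                     colnames=list(colnames), loglik=float(-nll + ll_zero),
                     converged=converged and zconv, n_train=n, family=family,
                     beta_se=beta_se,
                     gamma_se=np.sqrt(np.maximum(np.diag(gcov), 0.0)),
                     log_alpha_se=la_se)


# ---------------------------------------------------------------------------
# two-pass null estimation and scoring
# ---------------------------------------------------------------------------

def estimate_null(records: pd.DataFrame, sample_frac: float = 0.01,
                  outlier_q: float = 0.975, seed: int | None = None,
                  df: int = 6, order: int = 3, uniform: bool = False,
                  max_distance: float = MAX_DISTANCE,
                  family: str = "nb") -> HurdleFit:
    """Two-pass trimmed null fit for one chromosome.

    1) draw a seeded simple random sample of ``sample_frac`` of the
       non-excluded records; 2) fit the hurdle GLM (inner knots from this
       sample's distance quantiles); 3) drop sampled records whose upper-tail
       probability under their fitted law is below ``1 - outlier_q`` (possible
       true interactions); 4) refit on the remainder with the same knots.
    """
    if not (0 < sample_frac <= 1):
        raise ValueError("sample_frac must be in (0, 1]")
    if not (0.5 < outlier_q < 1):
        raise ValueError("outlier_q must be in (0.5, 1)")
    usable = records[~records.get("excluded",
                                  pd.Series(False, index=records.index))]
    chroms = usable["chrom"].unique()
    chrom = chroms[0] if len(chroms) == 1 else None
    rng = np.random.default_rng(seed)
    n = len(usable)
    n_sample = max(int(round(sample_frac * n)), 1)
    idx = np.sort(rng.choice(n, size=n_sample, replace=False))
    sample = usable.iloc[idx]

    spec = SplineSpec.from_distances(sample["d"], df=df, order=order,
                                     boundary=(0.0, float(max_distance)))
    X, names = design_matrix(sample, spec, uniform=uniform)
    n_params = X.shape[1] + 1 + X.shape[1]  # beta + alpha + gamma
    if len(sample) < 10 * n_params:
        raise ValueError(
            f"training sample of {len(sample)} records is too small for "
            f"{n_params} parameters; increase sample_frac")
    fit1 = fit_hurdle_glm(X, sample["y"].to_numpy(), colnames=names,
                          family=family)

    mu, pi0 = fit1.predict(X)
    tail = interaction_pvalue(sample["y"].to_numpy(), mu, fit1.alpha, pi0)
    keep = tail >= (1.0 - outlier_q)   # strict < removes
    fit2 = fit_hurdle_glm(X[keep], sample["y"].to_numpy()[keep],
                          colnames=names, family=family)
    fit2.n_outliers_removed = int((~keep).sum())
    fit2.chrom = chrom
    fit2.spline = spec
    fit2.seed = seed
    fit2.uniform = uniform
    fit2.standardization_stats = records.attrs.get("standardization_stats")
    fit2.pass1 = fit1  # kept for diagnostics (likelihood ascent, trimming)
    return fit2


def score_records(records: pd.DataFrame, fit: HurdleFit) -> pd.DataFrame:
    """Attach fitted mu/pi0, tail P value and O/E to each record.

    Excluded records (degenerate bins) keep NaN everywhere.
    """
    out = records.copy()
    for col in ("mu", "pi0", "p", "oe"):
        out[col] = np.nan
    ok = ~out.get("excluded", pd.Series(False, index=out.index)).to_numpy()
    sub = out[ok]
    if len(sub):
        X, _ = design_matrix(sub, fit.spline, uniform=fit.uniform)
        mu, pi0 = fit.predict(X)
        y = sub["y"].to_numpy()
        out.loc[ok, "mu"] = mu
        out.loc[ok, "pi0"] = pi0
        out.loc[ok, "p"] = interaction_pvalue(y, mu, fit.alpha, pi0)
        out.loc[ok, "oe"] = oe_normalize(y, mu, fit.alpha, pi0)
    return out


def call_significant(records: pd.DataFrame, fdr: float = 0.01,
                     per_chromosome: bool = False) -> pd.DataFrame:
    """BH-adjust P values (pooled genome-wide by default) and flag calls."""
    out = records.copy()
    if per_chromosome:
        out["q"] = np.nan
        for _, grp in out.groupby("chrom", sort=False):
            out.loc[grp.index, "q"] = bh_adjust(grp["p"].to_numpy())
    else:
        out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    return out
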