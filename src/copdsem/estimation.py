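"""Full-information maximum likelihood estimation of RAM-parameterized models.

Each subject contributes the multivariate-normal log-density of its
*observed* subvector, so rows with missing cells are neither deleted nor
imputed.  Rows are grouped by missingness pattern once per fit; each
pattern's sufficient statistics (count, mean, scatter) make the
likelihood and its analytic gradient cheap to evaluate.

The gradient uses the chain rule through the RAM identity
``Sigma = F B S B' F'``, ``mu = F B M`` with ``B = (I - A)^{-1}``:
accumulating the per-pattern derivatives with respect to ``(mu, Sigma)``
into dense matrices ``G_mu``, ``G_Sigma`` and contracting them against
the sparse slot structure of each free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ModelSpec, RamMatrices, build_ram

__all__ = [
    "Dataset",
    "FitResult",
    "implied_moments",
    "loglik_fiml",
    "fit",
    "standard_errors",
    "standardize",
    "saturated_loglik",
    "baseline_loglik",
]

_PENALTY = -1e12  # returned to the optimizer on non-PD moments; never raises


# ----------------------------------------------------------------------
# Dataset
# ----------------------------------------------------------------------


class Dataset:
    """Rectangular subject-by-variable table with an explicit missing mask.

    Backed by a pandas DataFrame whose NaNs mark missing cells.  Columns
    not part of a model (e.g. group labels) can be carried in ``meta``.
    """

    def __init__(self, df: pd.DataFrame, meta: pd.DataFrame | None = None):
        if df.columns.duplicated().any():
            raise ValueError("duplicate column names in dataset")
        empty = [c for c in df.columns if df[c].isna().all()]
        if empty:
            raise ValueError(f"variables entirely missing: {empty}")
        self.df = df.reset_index(drop=True).astype(float)
        self.meta = meta.reset_index(drop=True) if meta is not None else None

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def observed_counts(self) -> pd.Series:
        return self.df.notna().sum()

    def values_for(self, names: list[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.df.columns]
        if missing:
            raise KeyError(f"dataset lacks variables {missing}")
        return self.df[names].to_numpy(dtype=float)

    def subset_rows(self, mask: np.ndarray) -> "Dataset":
        meta = self.meta[mask] if self.meta is not None else None
        return Dataset(self.df[mask], meta)

    # -- I/O -----------------------------------------------------------
    @classmethod
    def from_csv(cls, path, meta_columns: tuple[str, ...] = ("group",)) -> "Dataset":
        raw = pd.read_csv(path)
        meta_cols = [c for c in raw.columns if c in meta_columns]
        meta = raw[meta_cols] if meta_cols else None
        return cls(raw.drop(columns=meta_cols), meta)

    def to_csv(self, path) -> None:
        out = self.df.copy()
        if self.meta is not None:
            out = pd.concat([out, self.meta], axis=1)
        # NaN -> empty cell; 7 significant digits is far below any
        # measurement precision and keeps files compact
        out.to_csv(path, index=False, float_format="%.7g")


@dataclass
class _Pattern:
    obs: np.ndarray  # column indices observed in this pattern
    n: int
    mean: np.ndarray
    scatter: np.ndarray  # sum of outer(x - mean, x - mean)


def _group_patterns(X: np.ndarray) -> list[_Pattern]:
    mask = ~np.isnan(X)
    patterns: dict[bytes, list[int]] = {}
    for r in range(X.shape[0]):
        key = mask[r].tobytes()
        patterns.setdefault(key, []).append(r)
    out: list[_Pattern] = []
    for key, rows in patterns.items():
        obs = np.flatnonzero(np.frombuffer(key, dtype=bool))
        if obs.size == 0:
            continue  # fully-missing rows contribute nothing
        sub = X[np.ix_(rows, obs)]
        mean = sub.mean(axis=0)
        dev = sub - mean
        out.append(_Pattern(obs=obs, n=len(rows), mean=mean, scatter=dev.T @ dev))
    return out


# ----------------------------------------------------------------------
# Model-implied moments and likelihood
# ----------------------------------------------------------------------


def implied_moments(
    ram: RamMatrices, theta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance of the observed variables."""
    A, S, M = ram.materialize(theta)
    m = ram.m
    I_A = np.eye(m) - A
    try:
        B = np.linalg.inv(I_A)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"(I - A) is singular; directed coefficients imply an explosive loop: {exc}"
        ) from exc
    C = B @ S @ B.T
    mu_full = B @ M
    o = ram.obs_idx
    return mu_full[o], C[np.ix_(o, o)]


def _moments_internals(ram: RamMatrices, theta: np.ndarray):
    """B, FB, C=BSB', FC, BM and the observed-block moments, or None if singular."""
    A, S, M = ram.materialize(theta)
    m = ram.m
    I_A = np.eye(m) - A
    try:
        B = np.linalg.inv(I_A)
    except np.linalg.LinAlgError:
        return None
    o = ram.obs_idx
    FB = B[o, :]
    C = B @ S @ B.T
    FC = C[o, :]
    BM = B @ M
    mu = BM[o]
    Sigma = C[np.ix_(o, o)]
    return B, FB, C, FC, BM, mu, Sigma


def _pattern_loglik(patterns: list[_Pattern], mu: np.ndarray, Sigma: np.ndarray):
    """Log-likelihood plus per-pattern solver pieces (or None if non-PD)."""
    ll = 0.0
    pieces = []
    log2pi = np.log(2.0 * np.pi)
    for pat in patterns:
        o = pat.obs
        So = Sigma[np.ix_(o, o)]
        try:
            L = np.linalg.cholesky(So)
        except np.linalg.LinAlgError:
            return None
        logdet = 2.0 * np.log(np.diag(L)).sum()
        d = pat.mean - mu[o]
        W = np.linalg.inv(So)  # k is small; explicit inverse reused by gradient
        quad = float(np.trace(W @ pat.scatter)) + pat.n * float(d @ W @ d)
        ll += -0.5 * (pat.n * (len(o) * log2pi + logdet) + quad)
        pieces.append((pat, W, d))
    return ll, pieces


def loglik_fiml(data: Dataset, ram: RamMatrices, theta: np.ndarray) -> float:
    """FIML log-likelihood: sum over missingness patterns of MVN log-densities
    restricted to each pattern's observed columns.  Returns a large
    negative penalty (never raises) when the implied moments are not
    positive definite, so the optimizer can back away."""
    X = data.values_for(ram.spec.observed_names())
    patterns = _group_patterns(X)
    internals = _moments_internals(ram, theta)
    if internals is None:
        return _PENALTY
    *_, mu, Sigma = internals
    res = _pattern_loglik(patterns, mu, Sigma)
    if res is None:
        return _PENALTY
    return res[0]


def _loglik_and_grad(ram: RamMatrices, patterns: list[_Pattern], theta: np.ndarray):
    internals = _moments_internals(ram, theta)
    if internals is None:
        return _PENALTY, np.zeros(ram.q)
    B, FB, C, FC, BM, mu, Sigma = internals
    res = _pattern_loglik(patterns, mu, Sigma)
    if res is None:
        return _PENALTY, np.zeros(ram.q)
    ll, pieces = res

    p = ram.p
    G_S = np.zeros((p, p))  # d ll / d Sigma (symmetric convention)
    G_m = np.zeros(p)  # d ll / d mu
    for pat, W, d in pieces:
        o = pat.obs
        T = pat.scatter + pat.n * np.outer(d, d)
        dS = -0.5 * (pat.n * W - W @ T @ W)
        G_S[np.ix_(o, o)] += dS
        G_m[o] += pat.n * (W @ d)

    # chain rule: contract G_S / G_m with each free slot's derivative
    GS_FB = G_S @ FB  # p x m
    Q = FB.T @ GS_FB  # m x m : for S slots
    R = FB.T @ (G_S @ FC)  # m x m : for A slots (Sigma part)
    gmu_FB = FB.T @ G_m  # m : for M slots and A mu-part

    grad = np.empty(ram.q)
    for k, fp in enumerate(ram.free_map):
        if fp.matrix == "S":
            grad[k] = Q[fp.i, fp.j] if fp.i == fp.j else 2.0 * Q[fp.i, fp.j]
        elif fp.matrix == "A":
            g = 2.0 * R[fp.i, fp.j] + BM[fp.j] * gmu_FB[fp.i]
            grad[k] = g
        else:  # M
            grad[k] = gmu_FB[fp.i]
    return ll, grad


# ----------------------------------------------------------------------
# Fit
# ----------------------------------------------------------------------


@dataclass
class FitResult:
    """Converged (or not) FIML solution with its estimates table."""

    ram: RamMatrices
    theta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    n_obs: int
    se: np.ndarray | None = None
    vcov: np.ndarray | None = None
    estimates: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def q(self) -> int:
        return self.ram.q

    def param(self, label: str) -> float:
        return float(self.theta[self.ram.param_index(label)])

    def pvalue(self, label: str) -> float:
        if self.estimates is None:
            raise RuntimeError("estimates table not built; call with standard errors")
        row = self.estimates.loc[self.estimates["label"] == label]
        if row.empty:
            raise KeyError(label)
        return float(row["pvalue"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "n_obs": self.n_obs,
            "warnings": list(self.warnings),
            "estimates": (
                self.estimates.to_dict(orient="records") if self.estimates is not None else None
            ),
        }


def _starting_values(ram: RamMatrices, data: Dataset) -> np.ndarray:
    """Identity-style defaults: free loadings 1, paths 0, variances and
    means from per-variable observed moments, exogenous covariances from
    pairwise-complete sample covariances."""
    obs_names = ram.spec.observed_names()
    X = data.values_for(obs_names)
    col = {n: k for k, n in enumerate(obs_names)}
    means = np.nanmean(X, axis=0)
    variances = np.nanvar(X, axis=0)
    variances = np.where(variances <= 1e-8, 1.0, variances)
    first_ind = {lat: ram.spec.indicators_of(lat)[0] for lat in ram.spec.latent_names()}

    theta = np.empty(ram.q)
    for k, fp in enumerate(ram.free_map):
        name_i = ram.names[fp.i]
        name_j = ram.names[fp.j] if fp.matrix != "M" else None
        if fp.kind == "loading":
            theta[k] = 1.0
        elif fp.kind == "path":
            theta[k] = 0.0
        elif fp.kind == "variance":
            if name_i in col:
                theta[k] = variances[col[name_i]]
            else:  # latent: half the variance of its first indicator
                theta[k] = max(0.5 * variances[col[first_ind[name_i]]], 0.05)
        elif fp.kind == "covariance":
            if name_i in col and name_j in col:
                xi, xj = X[:, col[name_i]], X[:, col[name_j]]
                ok = ~np.isnan(xi) & ~np.isnan(xj)
                theta[k] = float(np.cov(xi[ok], xj[ok])[0, 1]) if ok.sum() > 2 else 0.0
            else:
                theta[k] = 0.0
        else:  # mean
            theta[k] = means[col[name_i]]
    return theta


def _param_scales(ram: RamMatrices, data: Dataset) -> np.ndarray:
    """Diagonal preconditioner: the natural magnitude of each parameter
    given the per-variable sample spreads, so quasi-Newton steps are
    comparable across raw-scale and log-scale variables."""
    obs_names = ram.spec.observed_names()
    X = data.values_for(obs_names)
    col = {n: k for k, n in enumerate(obs_names)}
    sds = np.sqrt(np.nanvar(X, axis=0))
    sds = np.where(sds <= 1e-6, 1.0, sds)
    first_ind = {lat: ram.spec.indicators_of(lat)[0] for lat in ram.spec.latent_names()}

    def sd_of(name: str) -> float:
        if name in col:
            return float(sds[col[name]])
        return float(sds[col[first_ind[name]]])

    scale = np.empty(ram.q)
    for k, fp in enumerate(ram.free_map):
        ni = ram.names[fp.i]
        nj = ram.names[fp.j] if fp.matrix != "M" else None
        if fp.kind in ("path", "loading"):
            scale[k] = sd_of(ni) / sd_of(nj)
        elif fp.kind == "variance":
            scale[k] = sd_of(ni) ** 2
        elif fp.kind == "covariance":
            scale[k] = sd_of(ni) * sd_of(nj)
        else:  # mean
            scale[k] = max(sd_of(ni), 1e-3)
    return scale


def fit(
    data: Dataset,
    spec: ModelSpec,
    starts: np.ndarray | None = None,
    max_restarts: int = 5,
    compute_se: bool = True,
    seed: int = 0,
) -> FitResult:
    """Fit a model by FIML with quasi-Newton (L-BFGS-B) iteration.

    Optimization runs in preconditioned coordinates (each parameter
    divided by its natural scale) and results are mapped back exactly.
    Non-convergence after jittered restarts is reported through the
    ``converged`` flag rather than raised; the caller decides.
    """
    ram = build_ram(spec)
    X = data.values_for(spec.observed_names())
    patterns = _group_patterns(X)
    n_obs = int(sum(pat.n for pat in patterns))
    D = _param_scales(ram, data)

    def objective(u):
        ll, g = _loglik_and_grad(ram, patterns, u * D)
        return -ll, -g * D

    theta0 = _starting_values(ram, data) if starts is None else np.asarray(starts, float)
    # gradient tolerance on the per-observation, preconditioned scale
    gtol = 1e-4 * max(1.0, n_obs)
    rng = np.random.default_rng(seed)

    best = None
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0.0, 0.1, ram.q) * (
            np.abs(theta0) + D
        )
        res = optimize.minimize(
            objective,
            start / D,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 10000, "ftol": 1e-13, "gtol": 1e-10, "maxcor": 40},
        )
        theta_try = res.x * D
        ll, g = _loglik_and_grad(ram, patterns, theta_try)
        ok = ll > _PENALTY / 2 and np.max(np.abs(g * D)) < gtol
        cand = (ll, theta_try, res.nit, float(np.max(np.abs(g * D))), ok)
        if best is None or cand[0] > best[0]:
            best = cand
        if ok:
            break

    ll, theta_hat, nit, gnorm, converged = best
    result = FitResult(
        ram=ram,
        theta=theta_hat,
        loglik=ll,
        converged=bool(converged),
        n_iter=int(nit),
        grad_norm=gnorm,
        n_obs=n_obs,
    )

    # Heywood screening
    for k, fp in enumerate(ram.free_map):
        if fp.kind == "variance" and theta_hat[k] < 0:
            result.warnings.append(
                f"Heywood case: negative variance estimate for {ram.names[fp.i]!r} "
                f"({theta_hat[k]:.4g})"
            )

    if compute_se and converged:
        standard_errors(result, data)
    else:
        result.estimates = _estimates_table(result, se=None)
    for lbl, std in zip(result.estimates["label"], result.estimates["standardized"]):
        if (lbl.startswith("path:") or lbl.startswith("loading:")) and np.isfinite(std):
            if abs(std) > 1.0 + 1e-8:
                result.warnings.append(
                    f"standardized coefficient outside [-1, 1]: {lbl} = {std:.4g}"
                )
    return result


# ----------------------------------------------------------------------
# Standard errors and standardization
# ----------------------------------------------------------------------


def _numeric_hessian(ram: RamMatrices, patterns: list[_Pattern], theta: np.ndarray):
    """Observed information: central differences of the analytic gradient."""
    q = ram.q
    H = np.empty((q, q))
    for j in range(q):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        tm = theta.copy()
        tm[j] -= h
        _, gp = _loglik_and_grad(ram, patterns, tp)
        _, gm = _loglik_and_grad(ram, patterns, tm)
        H[:, j] = -(gp - gm) / (2.0 * h)  # information = -Hessian of loglik
    return 0.5 * (H + H.T)


def standard_errors(result: FitResult, data: Dataset) -> FitResult:
    """SEs from the inverse of the numerically differentiated observed
    information at the optimum; fixed parameters carry no SE."""
    ram = result.ram
    X = data.values_for(ram.spec.observed_names())
    patterns = _group_patterns(X)
    info = _numeric_hessian(ram, patterns, result.theta)
    q = ram.q
    se = np.full(q, np.nan)
    vcov = None
    try:
        vcov = np.linalg.inv(info)
        d = np.diag(vcov)
        bad = d <= 0
        se = np.where(bad, np.nan, np.sqrt(np.abs(d)))
        if bad.any():
            labels = [ram.free_map[k].label for k in np.flatnonzero(bad)]
            result.warnings.append(f"non-positive information diagonal for {labels}")
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(info)
        d = np.diag(vcov)
        se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        result.warnings.append("observed information singular; SEs from pseudo-inverse")
    result.se = se
    result.vcov = vcov
    result.estimates = _estimates_table(result, se=se)
    return result


def standardize(result: FitResult, ram: RamMatrices | None = None) -> pd.DataFrame:
    """Standardized solution: each directed coefficient a->b rescaled by
    sd(a)/sd(b) using model-implied standard deviations (latents
    included); covariances become correlations; variances become
    residual-variance proportions."""
    ram = ram or result.ram
    return _standardized_vector(ram, result.theta, as_frame=True)


def _implied_sds(ram: RamMatrices, theta: np.ndarray) -> np.ndarray:
    A, S, M = ram.materialize(theta)
    B = np.linalg.inv(np.eye(ram.m) - A)
    C = B @ S @ B.T
    d = np.diag(C).copy()
    if np.any(d <= 0):
        bad = [ram.names[i] for i in np.flatnonzero(d <= 0)]
        raise ValueError(f"non-positive model-implied variance for {bad}")
    return np.sqrt(d)


def _standardized_vector(ram: RamMatrices, theta: np.ndarray, as_frame: bool = False):
    sd = _implied_sds(ram, theta)
    vals = np.empty(ram.q)
    for k, fp in enumerate(ram.free_map):
        v = theta[k]
        if fp.matrix == "A":
            vals[k] = v * sd[fp.j] / sd[fp.i]
        elif fp.matrix == "S":
            if fp.i == fp.j:
                vals[k] = v / sd[fp.i] ** 2
            else:
                vals[k] = v / (sd[fp.i] * sd[fp.j])
        else:
            vals[k] = v / sd[fp.i]
    if not as_frame:
        return vals
    rows = [
        {"label": fp.label, "kind": fp.kind, "standardized": vals[k]}
        for k, fp in enumerate(ram.free_map)
    ]
    # fixed loadings/paths are reported too (standardized value is informative)
    A, S, M = ram.materialize(theta)
    for lbl, val in ram.fixed_entries.items():
        if lbl.startswith(("loading:", "path:")):
            src, dst = lbl.split(":", 1)[1].split("->")
            i, j = ram.index_of(dst), ram.index_of(src)
            rows.append(
                {
                    "label": lbl,
                    "kind": "loading" if lbl.startswith("loading") else "path",
                    "standardized": val * sd[j] / sd[i],
                }
            )
    return pd.DataFrame(rows)


def standardized_se(result: FitResult) -> np.ndarray:
    """Delta-method SEs for the standardized free parameters."""
    if result.vcov is None:
        raise RuntimeError("fit has no parameter covariance; run standard_errors first")
    ram = result.ram
    theta = result.theta
    q = ram.q
    J = np.empty((q, q))
    base = _standardized_vector(ram, theta)
    for j in range(q):
        h = 1e-6 * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += h
        J[:, j] = (_standardized_vector(ram, tp) - base) / h
    var = np.einsum("ij,jk,ik->i", J, result.vcov, J)
    return np.sqrt(np.clip(var, 0.0, None))


def _estimates_table(result: FitResult, se: np.ndarray | None) -> pd.DataFrame:
    ram = result.ram
    theta = result.theta
    try:
        std = _standardized_vector(ram, theta)
    except ValueError:
        std = np.full(ram.q, np.nan)
    rows = []
    for k, fp in enumerate(ram.free_map):
        est = theta[k]
        s = se[k] if se is not None else np.nan
        z = est / s if (se is not None and np.isfinite(s) and s > 0) else np.nan
        pval = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append(
            {
                "label": fp.label,
                "kind": fp.kind,
                "estimate": est,
                "se": s,
                "z": z,
                "pvalue": pval,
                "standardized": std[k],
            }
        )
    for lbl, val in ram.fixed_entries.items():
        kind = lbl.split(":", 1)[0]
        try:
            sd = _implied_sds(ram, theta)
            if lbl.startswith(("loading:", "path:")):
                src, dst = lbl.split(":", 1)[1].split("->")
                sval = val * sd[ram.index_of(src)] / sd[ram.index_of(dst)]
            else:
                sval = np.nan
        except ValueError:
            sval = np.nan
        rows.append(
            {
                "label": lbl,
                "kind": kind,
                "estimate": val,
                "se": np.nan,  # fixed parameters carry no SE
                "z": np.nan,
                "pvalue": np.nan,
                "standardized": sval,
            }
        )
    df = pd.DataFrame(rows)
    if result.vcov is not None:
        try:
            sse = standardized_se(result)
            std_se = {fp.label: sse[k] for k, fp in enumerate(ram.free_map)}
            df["standardized_se"] = df["label"].map(std_se)
        except RuntimeError:
            pass
    return df


# ----------------------------------------------------------------------
# Saturated and baseline log-likelihoods
# ----------------------------------------------------------------------


def _complete_saturated(X: np.ndarray) -> float:
    n, p = X.shape
    mu = X.mean(axis=0)
    dev = X - mu
    Sigma = dev.T @ dev / n  # ML (not n-1)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("sample covariance not positive definite")
    return -0.5 * n * (p * np.log(2 * np.pi) + logdet + p)


def saturated_loglik(data: Dataset, names: list[str] | None = None, tol: float = 1e-10,
                     max_iter: int = 5000) -> float:
    """Maximized log-likelihood of the unrestricted multivariate normal.

    Complete data: closed form.  Incomplete data: EM for the MVN mean and
    covariance, iterated to a relative log-likelihood change below
    ``tol``; the returned value is the FIML log-likelihood at the EM
    solution.
    """
    names = names or data.columns
    X = data.values_for(names)
    mask = np.isnan(X)
    if not mask.any():
        return _complete_saturated(X)

    n, p = X.shape
    patterns = _group_patterns(X)
    # init from observed moments
    mu = np.nanmean(X, axis=0)
    Sigma = np.diag(np.nanvar(X, axis=0) + 1e-6)

    def fiml_ll(mu, Sigma):
        res = _pattern_loglik(patterns, mu, Sigma)
        return None if res is None else res[0]

    ll_old = fiml_ll(mu, Sigma)
    rows_obs = [np.flatnonzero(~mask[r]) for r in range(n)]
    for _ in range(max_iter):
        # E-step: expected sufficient statistics per row
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        for r in range(n):
            o = rows_obs[r]
            if o.size == 0:
                s1 += mu
                s2 += Sigma + np.outer(mu, mu)
                continue
            mis = np.setdiff1d(np.arange(p), o, assume_unique=True)
            xo = X[r, o]
            xhat = np.empty(p)
            xhat[o] = xo
            cov_add = np.zeros((p, p))
            if mis.size:
                Soo = Sigma[np.ix_(o, o)]
                Smo = Sigma[np.ix_(mis, o)]
                K = Smo @ np.linalg.inv(Soo)
                xhat[mis] = mu[mis] + K @ (xo - mu[o])
                cov_add[np.ix_(mis, mis)] = Sigma[np.ix_(mis, mis)] - K @ Smo.T
            s1 += xhat
            s2 += np.outer(xhat, xhat) + cov_add
        # M-step
        mu = s1 / n
        Sigma = s2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = fiml_ll(mu, Sigma)
        if ll is None:
            Sigma += 1e-8 * np.eye(p)
            ll = fiml_ll(mu, Sigma)
        if ll_old is not None and ll is not None:
            if abs(ll - ll_old) <= tol * (1.0 + abs(ll)):
                ll_old = ll
                break
        ll_old = ll
    return float(ll_old)


def baseline_loglik(data: Dataset, names: list[str] | None = None) -> tuple[float, int]:
    """Independence-baseline maximized log-likelihood and its parameter count.

    All variables mutually independent with free means and variances: the
    FIML likelihood separates by variable, so each contributes its
    univariate normal ML fit over its observed values.
    """
    names = names or data.columns
    X = data.values_for(names)
    ll = 0.0
    for j in range(X.shape[1]):
        x = X[:, j]
        x = x[~np.isnan(x)]
        nj = x.size
        var = x.var()  # ML
        if var <= 0:
            raise ValueError(f"variable {names[j]!r} has zero variance")
        ll += -0.5 * nj * (np.log(2 * np.pi) + np.log(var) + 1.0)
    return float(ll), 2 * len(names)
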