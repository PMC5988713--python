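"""Model testing and interpretation: chi-square, fit indices, modification
indices, backward path pruning, and direct/indirect effect decomposition.

Adequacy conventions: CFI and TLI above 0.90 are labelled adequate;
RMSEA at or below 0.05 good, up to 0.08 adequate, above 0.08 poor, with
a 90% confidence interval obtained by inverting the noncentral
chi-square distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ModelSpec, RamMatrices, build_ram, model_df, path_label, cov_label
from .estimation import (
    Dataset,
    FitResult,
    _group_patterns,
    _loglik_and_grad,
    _numeric_hessian,
    _implied_sds,
    fit,
    saturated_loglik,
    baseline_loglik,
)

__all__ = [
    "FitIndices",
    "EffectDecomposition",
    "chi_square",
    "fit_indices",
    "indices_for_fit",
    "modification_indices",
    "prune_paths",
    "decompose_effects",
]


class DegenerateModelError(ValueError):
    """Raised when fit indices are requested for a model without positive df."""


# ----------------------------------------------------------------------
# Chi-square and fit indices
# ----------------------------------------------------------------------


def chi_square(model_loglik: float, saturated_ll: float, df: int) -> tuple[float, int]:
    """Likelihood-ratio test statistic against the saturated model,
    clamped at zero."""
    T = max(0.0, 2.0 * (saturated_ll - model_loglik))
    return T, df


@dataclass
class FitIndices:
    chi2: float
    df: int
    pvalue: float
    chi2_baseline: float
    df_baseline: int
    cfi: float
    tli: float
    tli_raw: float
    rmsea: float
    rmsea_ci90: tuple[float, float]
    n: int
    labels: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "pvalue": self.pvalue,
            "chi2_baseline": self.chi2_baseline,
            "df_baseline": self.df_baseline,
            "cfi": self.cfi,
            "tli": self.tli,
            "tli_raw": self.tli_raw,
            "rmsea": self.rmsea,
            "rmsea_ci90": list(self.rmsea_ci90),
            "n": self.n,
            "labels": dict(self.labels),
        }


def _ncp_bound(T: float, df: int, prob: float) -> float:
    """Noncentrality lambda with ncx2.cdf(T; df, lambda) = prob (0 if none)."""
    if stats.chi2.cdf(T, df) < prob:
        return 0.0

    def f(lam):
        return stats.ncx2.cdf(T, df, lam) - prob

    hi = max(T, 1.0)
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e8:
            break
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14))


def fit_indices(
    T: float, df: int, T_b: float, df_b: int, n: int, rmsea_denominator: str = "n"
) -> FitIndices:
    """CFI, TLI and RMSEA (with 90% CI) from the model and baseline
    chi-squares.

    CFI = 1 - max(T-df, 0)/max(T_b-df_b, T-df, 0); TLI = ((T_b/df_b) -
    (T/df)) / ((T_b/df_b) - 1); RMSEA = sqrt(max(T-df, 0)/(df*n)).  The
    RMSEA denominator uses n by default (switchable to n-1).
    """
    if df <= 0 or df_b <= 0:
        raise DegenerateModelError(
            f"fit indices undefined for df={df}, baseline df={df_b}"
        )
    labels: dict[str, str] = {}
    d = max(T - df, 0.0)
    d_b = max(T_b - df_b, d, 0.0)
    cfi = 1.0 if d_b == 0 else 1.0 - d / d_b
    ratio_b = T_b / df_b
    if ratio_b <= 1.0:
        tli_raw = float("nan")
        labels["degenerate"] = "baseline chi-square does not exceed its df; TLI undefined"
        tli = float("nan")
    else:
        tli_raw = (ratio_b - T / df) / (ratio_b - 1.0)
        tli = min(max(tli_raw, 0.0), 1.0)
    cfi = min(max(cfi, 0.0), 1.0)

    denom = n if rmsea_denominator == "n" else n - 1
    rmsea = float(np.sqrt(max(T - df, 0.0) / (df * denom)))
    lam_lo = _ncp_bound(T, df, 0.95)
    lam_hi = _ncp_bound(T, df, 0.05)
    ci = (
        float(np.sqrt(lam_lo / (df * denom))),
        float(np.sqrt(lam_hi / (df * denom))),
    )

    labels["cfi"] = "adequate" if cfi > 0.90 else "poor"
    if np.isfinite(tli):
        labels["tli"] = "adequate" if tli > 0.90 else "poor"
    if rmsea <= 0.05:
        labels["rmsea"] = "good"
    elif rmsea <= 0.08:
        labels["rmsea"] = "adequate"
    else:
        labels["rmsea"] = "poor"

    return FitIndices(
        chi2=T,
        df=df,
        pvalue=float(stats.chi2.sf(T, df)),
        chi2_baseline=T_b,
        df_baseline=df_b,
        cfi=cfi,
        tli=tli,
        tli_raw=tli_raw,
        rmsea=rmsea,
        rmsea_ci90=ci,
        n=n,
        labels=labels,
    )


def indices_for_fit(result: FitResult, data: Dataset) -> FitIndices:
    """Convenience wrapper: saturated and baseline likelihoods computed on
    the model's observed variables, then indices."""
    names = result.ram.spec.observed_names()
    ll_sat = saturated_loglik(data, names)
    ll_base, q_base = baseline_loglik(data, names)
    p = len(names)
    df = model_df(result.ram.spec)
    df_base = p * (p + 3) // 2 - q_base
    T, _ = chi_square(result.loglik, ll_sat, df)
    T_b, _ = chi_square(ll_base, ll_sat, df_base)
    return fit_indices(T, df, T_b, df_base, result.n_obs)


# ----------------------------------------------------------------------
# Modification indices
# ----------------------------------------------------------------------


def _construct_names(spec: ModelSpec) -> list[str]:
    """Variables that act as structural nodes: latents plus observed
    variables that are not indicators of a latent."""
    indicators = {ind for _, ind in spec.loadings}
    return [v.name for v in spec.variables if v.name not in indicators]


def _candidate_additions(spec: ModelSpec) -> list[tuple[str, dict]]:
    """Absent structural paths among constructs, plus residual covariances
    among indicators of the same latent."""
    existing = {(p.source, p.target) for p in spec.structural_paths}
    covs = {tuple(sorted(c)) for c in spec.covariances}
    nodes = _construct_names(spec)
    out: list[tuple[str, dict]] = []
    for s in nodes:
        for t in nodes:
            if s == t or (s, t) in existing:
                continue
            out.append((path_label(s, t), {"type": "path", "source": s, "target": t}))
    for lat in spec.latent_names():
        inds = spec.indicators_of(lat)
        for a_i in range(len(inds)):
            for b_i in range(a_i + 1, len(inds)):
                a, b = inds[a_i], inds[b_i]
                if tuple(sorted((a, b))) in covs:
                    continue
                out.append((cov_label(a, b), {"type": "cov", "a": a, "b": b}))
    return out


def _augmented_spec(spec: ModelSpec, cand: dict) -> ModelSpec:
    from .model import Path

    if cand["type"] == "path":
        return replace(
            spec, structural_paths=spec.structural_paths + [Path(cand["source"], cand["target"])]
        )
    return replace(spec, covariances=spec.covariances + [(cand["a"], cand["b"])])


def modification_index_for(
    result: FitResult, data: Dataset, spec: ModelSpec, cand: dict
) -> float | None:
    """1-df score (Lagrange multiplier) statistic for freeing one candidate
    parameter at the restricted estimate; None if the augmented model is
    invalid (e.g. the path would create a cycle)."""
    from .model import SpecificationError

    try:
        aug = _augmented_spec(spec, cand)
        ram_aug = build_ram(aug)
    except SpecificationError:
        return None
    # embed the restricted estimate: matching labels keep their values,
    # the new parameter sits at 0
    theta_aug = np.zeros(ram_aug.q)
    old = {fp.label: result.theta[k] for k, fp in enumerate(result.ram.free_map)}
    for k, fp in enumerate(ram_aug.free_map):
        theta_aug[k] = old.get(fp.label, 0.0)
    X = data.values_for(aug.observed_names())
    patterns = _group_patterns(X)
    _, g = _loglik_and_grad(ram_aug, patterns, theta_aug)
    info = _numeric_hessian(ram_aug, patterns, theta_aug)
    # a 1-df statistic: restrict to the restricted parameter set plus the
    # single candidate (augmentation may create incidental free slots,
    # e.g. covariances among newly-used exogenous sources; they stay fixed
    # at zero here)
    cand_label = (
        path_label(cand["source"], cand["target"])
        if cand["type"] == "path"
        else cov_label(cand["a"], cand["b"])
    )
    keep = [
        k
        for k, fp in enumerate(ram_aug.free_map)
        if fp.label in old or fp.label == cand_label
    ]
    g = g[keep]
    info = info[np.ix_(keep, keep)]
    try:
        sol = np.linalg.solve(info, g)
    except np.linalg.LinAlgError:
        sol = np.linalg.lstsq(info, g, rcond=None)[0]
    return float(g @ sol)


def modification_indices(result: FitResult, data: Dataset, spec: ModelSpec) -> pd.DataFrame:
    """Score statistics for every currently-fixed-at-zero candidate,
    sorted descending; candidates that break identification are skipped
    with a note."""
    rows = []
    for label, cand in _candidate_additions(spec):
        mi = modification_index_for(result, data, spec, cand)
        if mi is None:
            rows.append({"candidate": label, "mi": np.nan, "note": "skipped: breaks identification"})
        else:
            rows.append({"candidate": label, "mi": mi, "note": ""})
    df = pd.DataFrame(rows)
    return df.sort_values("mi", ascending=False, na_position="last").reset_index(drop=True)


# ----------------------------------------------------------------------
# Backward pruning
# ----------------------------------------------------------------------


def prune_paths(
    data: Dataset,
    spec: ModelSpec,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[ModelSpec, FitResult, list[dict]]:
    """Backward elimination of non-significant structural paths.

    One path per iteration: the prunable path with the largest p-value at
    or above ``alpha`` is removed and the model refitted (warm-started
    from the surviving estimates) until every remaining prunable path has
    p below ``alpha``.  Loadings, covariances and paths from adjustment
    covariates are never removed.
    """
    spec.validate()
    log: list[dict] = []
    current = spec
    result = fit(data, current, seed=seed)
    if not result.converged:
        raise RuntimeError("initial fit did not converge; cannot prune")

    n_prunable = sum(
        1
        for p in current.structural_paths
        if p.prunable and p.source not in current.adjustment_covariates and p.fixed is None
    )
    for _ in range(n_prunable):
        worst_label, worst_p = None, alpha
        for p in current.structural_paths:
            if not p.prunable or p.fixed is not None:
                continue
            if p.source in current.adjustment_covariates:
                continue
            pv = result.pvalue(path_label(p.source, p.target))
            if np.isnan(pv):
                pv = 1.0  # unidentified SE: treat as non-significant
            if pv >= worst_p:
                worst_label, worst_p = (p.source, p.target), pv
        if worst_label is None:
            break
        src, dst = worst_label
        new_spec = current.drop_path(src, dst)
        # warm start: surviving parameters keep their estimates
        ram_new = build_ram(new_spec)
        old = {fp.label: result.theta[k] for k, fp in enumerate(result.ram.free_map)}
        starts = np.array(
            [old.get(fp.label, 0.0) for fp in ram_new.free_map], dtype=float
        )
        new_result = fit(data, new_spec, starts=starts, seed=seed)
        log.append(
            {
                "removed": path_label(src, dst),
                "pvalue": worst_p,
                "loglik_before": result.loglik,
                "loglik_after": new_result.loglik,
            }
        )
        if not new_result.converged:
            log.append({"removed": None, "pvalue": None, "note": "refit non-convergence; aborted"})
            return current, result, log
        current, result = new_spec, new_result
    return current, result, log


# ----------------------------------------------------------------------
# Effect decomposition
# ----------------------------------------------------------------------


@dataclass
class EffectDecomposition:
    source: str
    target: str
    direct: float
    indirect: float
    total: float
    direct_std: float
    indirect_std: float
    total_std: float
    se: dict = field(default_factory=dict)  # {"direct": (se, p), ...} unstandardized
    se_std: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "target": self.target,
            "direct": self.direct,
            "indirect": self.indirect,
            "total": self.total,
            "direct_std": self.direct_std,
            "indirect_std": self.indirect_std,
            "total_std": self.total_std,
            "se": self.se,
            "se_std": self.se_std,
        }


def _effects_at(ram: RamMatrices, theta: np.ndarray, i: int, j: int) -> np.ndarray:
    """(direct, indirect, total) for target i, source j at theta.

    Total effects over the directed (acyclic) part are the off-diagonal
    entries of (I - A)^{-1}; the direct effect is A itself.
    """
    A, _, _ = ram.materialize(theta)
    B = np.linalg.inv(np.eye(ram.m) - A)
    direct = A[i, j]
    total = B[i, j] - (1.0 if i == j else 0.0)
    return np.array([direct, total - direct, total])


def decompose_effects(
    result: FitResult, spec: ModelSpec, source: str, target: str
) -> EffectDecomposition:
    """Direct, indirect (sum over all mediating chains) and total effect
    of ``source`` on ``target``, with delta-method standard errors when a
    parameter covariance is available.  ``total = direct + indirect``
    holds by construction."""
    ram = result.ram
    try:
        i, j = ram.index_of(target), ram.index_of(source)
    except ValueError as exc:
        raise KeyError(f"source/target not in model: {exc}") from exc
    vals = _effects_at(ram, result.theta, i, j)
    sd = _implied_sds(ram, result.theta)
    scale = sd[j] / sd[i]
    vals_std = vals * scale

    se: dict = {}
    se_std: dict = {}
    if result.vcov is not None:
        q = ram.q
        J = np.empty((3, q))
        Js = np.empty((3, q))
        for k in range(q):
            h = 1e-6 * (1.0 + abs(result.theta[k]))
            tp = result.theta.copy()
            tp[k] += h
            vp = _effects_at(ram, tp, i, j)
            sp = _implied_sds(ram, tp)
            J[:, k] = (vp - vals) / h
            Js[:, k] = (vp * sp[j] / sp[i] - vals_std) / h
        for name, row, rows, v in (
            ("direct", J[0], Js[0], vals[0]),
            ("indirect", J[1], Js[1], vals[1]),
            ("total", J[2], Js[2], vals[2]),
        ):
            s = float(np.sqrt(max(row @ result.vcov @ row, 0.0)))
            z = v / s if s > 0 else np.nan
            pv = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            se[name] = {"se": s, "pvalue": pv}
            se_std[name] = {"se": float(np.sqrt(max(rows @ result.vcov @ rows, 0.0)))}

    return EffectDecomposition(
        source=source,
        target=target,
        direct=float(vals[0]),
        indirect=float(vals[1]),
        total=float(vals[2]),
        direct_std=float(vals_std[0]),
        indirect_std=float(vals_std[1]),
        total_std=float(vals_std[2]),
        se=se,
        se_std=se_std,
    )
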