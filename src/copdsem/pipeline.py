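"""End-to-end analysis pipeline: variable transformation, the three model
variants, estimation with backward pruning, tabular reporting, effect
decomposition, and the descriptive correlation/PCA layer.

Model variants
--------------
* Model 1 — whole sample: pack-years -> {FEV1, KCO} -> systemic outcome
  constructs, plus candidate direct pack-years -> outcome paths, with a
  musculoskeletal latent (ASMMI, hip/lumbar BMD, pinch, grip) and a
  cytokines latent (IL-6, IL-8, TNFa, MCP-1); age and gender adjust every
  endogenous construct and are exempt from pruning.
* Model 2 — the identical specification, fitted on the smoker subset
  (pack-years > 0) only.
* Model 3 — FEV1 and KCO replaced by a single pulmonary latent factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .model import ModelSpec, VariableDef, Path, path_label
from .estimation import Dataset, FitResult, fit
from .inference import (
    FitIndices,
    EffectDecomposition,
    indices_for_fit,
    prune_paths,
    decompose_effects,
)
from .cohort import (
    MODEL_VARIABLES,
    LOG_VARIABLES,
    MUSCULO_INDICATORS,
    CYTOKINE_INDICATORS,
    OBSERVED_OUTCOMES,
    OUTCOME_CONSTRUCTS,
    default_config,
    generate_cohort,
)

__all__ = [
    "transform_variables",
    "build_model",
    "run_analysis",
    "describe",
    "recovery_experiment",
    "AnalysisReport",
    "DescriptiveReport",
    "spec_to_dot",
]


# ----------------------------------------------------------------------
# Transformation
# ----------------------------------------------------------------------


def transform_variables(
    dataset: Dataset, log_list: list[str] | None = None
) -> Dataset:
    """Natural log applied to exactly the configured log-scale variables
    (default: every modeled parameter except age, gender, pack-years,
    FEV1 and KCO); everything else passes through unchanged."""
    log_list = LOG_VARIABLES if log_list is None else log_list
    df = dataset.df.copy()
    for v in log_list:
        if v not in df.columns:
            continue
        col = df[v]
        bad = col.notna() & (col <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"variable {v!r} has a non-positive value at row {row}; cannot log-transform"
            )
        df[v] = np.log(col)
    return Dataset(df, dataset.meta)


# ----------------------------------------------------------------------
# Model builders
# ----------------------------------------------------------------------


def _observed_defs() -> list[VariableDef]:
    defs = []
    for v in MODEL_VARIABLES:
        transform = "log" if v in LOG_VARIABLES else "raw"
        defs.append(VariableDef(v, kind="observed", transform=transform))
    return defs


def build_model(which: int) -> ModelSpec:
    """Construct the Model 1 / 2 / 3 specification.

    Candidate direct smoking->outcome paths start fully present and are
    left to the p<0.05 pruning rule, so sparse direct effects emerge from
    the data rather than from the specification.
    """
    if which not in (1, 2, 3):
        raise ValueError(f"unknown model variant {which}; expected 1, 2 or 3")

    variables = _observed_defs() + [
        VariableDef("musculoskeletal", kind="latent"),
        VariableDef("cytokines", kind="latent"),
    ]
    loadings = [("musculoskeletal", ind) for ind in MUSCULO_INDICATORS]
    loadings += [("cytokines", ind) for ind in CYTOKINE_INDICATORS]

    paths: list[Path] = []
    if which in (1, 2):
        lung = ["fev1", "kco"]
        covs = [("fev1", "kco")]  # residual covariance between the lung measures
    else:
        variables.append(VariableDef("pulmonary", kind="latent"))
        loadings += [("pulmonary", "fev1"), ("pulmonary", "kco")]
        lung = ["pulmonary"]
        covs = []

    for lv in lung:
        paths.append(Path("pack_years", lv))
        for out in OUTCOME_CONSTRUCTS:
            paths.append(Path(lv, out))
    for out in OUTCOME_CONSTRUCTS:
        paths.append(Path("pack_years", out))

    endogenous_constructs = lung + OUTCOME_CONSTRUCTS
    for cov in ("age", "gender"):
        for tgt in endogenous_constructs:
            paths.append(Path(cov, tgt, prunable=False))

    return ModelSpec(
        variables=variables,
        loadings=loadings,
        structural_paths=paths,
        covariances=covs,
        means_structure=True,
        adjustment_covariates=["age", "gender"],
    )


# ----------------------------------------------------------------------
# Analysis report
# ----------------------------------------------------------------------


def _round_floats(obj, ndigits: int = 8):
    """Recursively round floats for compact serialized reports."""
    if isinstance(obj, float):
        return round(obj, ndigits) if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


@dataclass
class AnalysisReport:
    model: int
    n_used: int
    spec: ModelSpec
    fit_result: FitResult
    indices: FitIndices
    pruning_log: list[dict]
    table: pd.DataFrame  # outcomes x {smoking, FEV1, KCO | pulmonary}
    decompositions: dict[str, EffectDecomposition]

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n_used": self.n_used,
            "indices": self.indices.to_dict(),
            "pruning_log": self.pruning_log,
            "table": self.table.reset_index().to_dict(orient="records"),
            "decompositions": {k: d.to_dict() for k, d in self.decompositions.items()},
            "fit": self.fit_result.to_dict(),
        }

    def to_json(self, path=None, **meta) -> str:
        payload = _round_floats({**meta, **self.to_dict()})
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def render_markdown(self) -> str:
        lines = [
            f"## Model {self.model} (n = {self.n_used})",
            "",
            "| Outcome | " + " | ".join(self.table.columns) + " |",
            "|" + "---|" * (len(self.table.columns) + 1),
        ]
        for outcome, row in self.table.iterrows():
            cells = [
                "NS" if not np.isfinite(v) else f"{v:.3f}" for v in row.to_numpy()
            ]
            lines.append(f"| {outcome} | " + " | ".join(cells) + " |")
        ind = self.indices
        lines += [
            "",
            f"Goodness of fit: RMSEA = {ind.rmsea:.3f} "
            f"(90% CI {ind.rmsea_ci90[0]:.3f}; {ind.rmsea_ci90[1]:.3f}), "
            f"CFI = {ind.cfi:.3f}, TLI = {ind.tli:.3f} "
            f"[chi2({ind.df}) = {ind.chi2:.1f}]",
        ]
        return "\n".join(lines)


def _coefficient_table(spec: ModelSpec, result: FitResult, sources: list[str]) -> pd.DataFrame:
    """Table-style standardized coefficients: rows = outcome constructs,
    columns = smoking / lung sources; NaN marks pruned (NS) paths."""
    est = result.estimates.set_index("label")
    present = {(p.source, p.target) for p in spec.structural_paths}
    data = {}
    for src in sources:
        col = []
        for out in OUTCOME_CONSTRUCTS:
            if (src, out) in present:
                col.append(float(est.loc[path_label(src, out), "standardized"]))
            else:
                col.append(np.nan)
        data[src] = col
    return pd.DataFrame(data, index=OUTCOME_CONSTRUCTS)


def run_analysis(
    dataset: Dataset, which: int, alpha: float = 0.05, seed: int = 0, prune: bool = True
) -> AnalysisReport:
    """Transform -> fit -> prune -> fit indices -> standardized table ->
    smoking effect decomposition, for one model variant."""
    data = dataset
    if which == 2:
        py = data.df["pack_years"].to_numpy()
        keep = np.nan_to_num(py, nan=0.0) > 0
        data = data.subset_rows(keep)
    data = transform_variables(data)

    spec = build_model(which)
    if prune:
        final_spec, result, log = prune_paths(data, spec, alpha=alpha, seed=seed)
    else:
        final_spec = spec
        result = fit(data, spec, seed=seed)
        log = []
    indices = indices_for_fit(result, data)
    sources = ["pack_years", "fev1", "kco"] if which in (1, 2) else ["pack_years", "pulmonary"]
    table = _coefficient_table(final_spec, result, sources)

    decomps = {}
    for out in OUTCOME_CONSTRUCTS:
        decomps[out] = decompose_effects(result, final_spec, "pack_years", out)

    return AnalysisReport(
        model=which,
        n_used=data.n,
        spec=final_spec,
        fit_result=result,
        indices=indices,
        pruning_log=log,
        table=table,
        decompositions=decomps,
    )


# ----------------------------------------------------------------------
# Descriptive layer: correlations, network, PCA
# ----------------------------------------------------------------------


@dataclass
class DescriptiveReport:
    correlations: pd.DataFrame
    pair_n: pd.DataFrame
    edges: pd.DataFrame  # var_a, var_b, r, sign, weight
    pca_loadings: pd.DataFrame
    pca_scores: pd.DataFrame
    variance_explained: np.ndarray
    groups: pd.Series | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "correlations": self.correlations.round(6).to_dict(),
            "pair_n": self.pair_n.to_dict(),
            "edges": self.edges.to_dict(orient="records"),
            "pca_loadings": self.pca_loadings.round(6).to_dict(),
            "variance_explained": [float(v) for v in self.variance_explained],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def describe(
    dataset: Dataset,
    variables: list[str] | None = None,
    n_components: int = 3,
    min_overlap: int = 3,
) -> DescriptiveReport:
    """Pairwise-complete Pearson correlations (with per-pair n and a
    signed edge list for network plotting) and a PCA of the standardized
    complete cases.  Modeled on the log scale, like the SEM."""
    data = transform_variables(dataset)
    variables = variables or [v for v in data.columns if v != "gender"]
    X = data.values_for(variables)
    p = len(variables)

    corr = np.full((p, p), np.nan)
    pair_n = np.zeros((p, p), dtype=int)
    for a in range(p):
        corr[a, a] = 1.0
        pair_n[a, a] = int(np.sum(~np.isnan(X[:, a])))
        for b in range(a + 1, p):
            ok = ~np.isnan(X[:, a]) & ~np.isnan(X[:, b])
            pair_n[a, b] = pair_n[b, a] = int(ok.sum())
            if ok.sum() >= min_overlap:
                xa, xb = X[ok, a], X[ok, b]
                if xa.std() > 0 and xb.std() > 0:
                    corr[a, b] = corr[b, a] = float(np.corrcoef(xa, xb)[0, 1])

    edges = []
    for a in range(p):
        for b in range(a + 1, p):
            r = corr[a, b]
            if np.isfinite(r):
                edges.append(
                    {
                        "var_a": variables[a],
                        "var_b": variables[b],
                        "r": r,
                        "sign": "negative" if r < 0 else "positive",
                        "weight": abs(r),
                    }
                )

    complete = ~np.isnan(X).any(axis=1)
    if complete.sum() < 2:
        raise ValueError("fewer than 2 complete-case rows; cannot run PCA")
    Xc = X[complete]
    Xs = (Xc - Xc.mean(axis=0)) / Xc.std(axis=0)
    k = min(n_components, p, Xc.shape[0])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Xs)
    loadings = pca.components_.T.copy()
    # sign convention: largest-magnitude loading positive per component
    for j in range(k):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0

    comp_names = [f"PC{j + 1}" for j in range(k)]
    groups = None
    if dataset.meta is not None and "group" in dataset.meta.columns:
        groups = dataset.meta["group"][complete].reset_index(drop=True)
    return DescriptiveReport(
        correlations=pd.DataFrame(corr, index=variables, columns=variables),
        pair_n=pd.DataFrame(pair_n, index=variables, columns=variables),
        edges=pd.DataFrame(edges),
        pca_loadings=pd.DataFrame(loadings, index=variables, columns=comp_names),
        pca_scores=pd.DataFrame(scores, columns=comp_names),
        variance_explained=pca.explained_variance_ratio_,
        groups=groups,
    )


# ----------------------------------------------------------------------
# Parameter-recovery experiment
# ----------------------------------------------------------------------


def recovery_experiment(
    reps: int = 50,
    n: int = 2000,
    seed: int = 0,
    config=None,
    z_crit: float = 1.959963984540054,
) -> pd.DataFrame:
    """Repeatedly generate complete cohorts from the configured structure
    and refit Model 1 without pruning; per printed generating path report
    the mean and SD of the standardized estimate, its bias, and 95%
    delta-method CI coverage of the generating value."""
    if reps < 2:
        raise ValueError("reps must be at least 2")
    config = config or default_config()
    cfg = config.scaled(n) if n != config.n else config
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=reps)

    printed = list(cfg.printed_paths)
    est: dict[tuple[str, str], list[float]] = {p: [] for p in printed}
    cover: dict[tuple[str, str], list[bool]] = {p: [] for p in printed}
    failures = 0
    for s in seeds:
        ds, truth = generate_cohort(cfg, seed=int(s))
        data = transform_variables(ds)
        result = fit(data, build_model(1), seed=int(s))
        if not result.converged:
            failures += 1
            continue
        tab = result.estimates.set_index("label")
        for src, tgt in printed:
            row = tab.loc[path_label(src, tgt)]
            v = float(row["standardized"])
            se = float(row.get("standardized_se", np.nan))
            est[(src, tgt)].append(v)
            t = truth.standardized_paths[(src, tgt)]
            if np.isfinite(se):
                cover[(src, tgt)].append(abs(v - t) <= z_crit * se)

    if failures >= 0.1 * reps:
        raise RuntimeError(f"{failures}/{reps} replicate fits failed to converge")

    rows = []
    for src, tgt in printed:
        vals = np.array(est[(src, tgt)])
        t = cfg.standardized_paths[(src, tgt)]
        rows.append(
            {
                "path": f"{src}->{tgt}",
                "truth": t,
                "mean_estimate": vals.mean(),
                "sd_estimate": vals.std(ddof=1),
                "bias": vals.mean() - t,
                "coverage": float(np.mean(cover[(src, tgt)])) if cover[(src, tgt)] else np.nan,
                "n_reps": len(vals),
                "n_failed": failures,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Diagram export
# ----------------------------------------------------------------------


def spec_to_dot(spec: ModelSpec, result: FitResult | None = None) -> str:
    """DOT rendering of the path diagram: latent variables as ellipses,
    observed as boxes, standardized coefficients as edge labels when a
    fit is supplied."""
    std = {}
    if result is not None and result.estimates is not None:
        for _, row in result.estimates.iterrows():
            std[row["label"]] = row["standardized"]
    lines = ["digraph sem {", "  rankdir=LR;"]
    for v in spec.variables:
        shape = "ellipse" if v.kind == "latent" else "box"
        lines.append(f'  "{v.name}" [shape={shape}];')
    for lat, ind in spec.loadings:
        lbl = std.get(f"loading:{lat}->{ind}")
        attr = f' [label="{lbl:.2f}"]' if lbl is not None and np.isfinite(lbl) else ""
        lines.append(f'  "{lat}" -> "{ind}"{attr};')
    for p in spec.structural_paths:
        lbl = std.get(path_label(p.source, p.target))
        attr = f' [label="{lbl:.2f}"]' if lbl is not None and np.isfinite(lbl) else ""
        lines.append(f'  "{p.source}" -> "{p.target}"{attr};')
    for a, b in spec.covariances:
        lines.append(f'  "{a}" -> "{b}" [dir=both, style=dashed];')
    lines.append("}")
    return "\n".join(lines)
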