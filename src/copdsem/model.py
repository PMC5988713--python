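"""Declarative structural equation model specification and its RAM matrix form.

A model is a set of observed and latent variables connected by directed
paths (regressions and factor loadings) and double-headed covariance
edges.  The RAM (reticular action model) translation collects every
coefficient into three matrices over the full variable set (observed and
latent):

* ``A`` — asymmetric matrix of directed-path coefficients; ``A[t, s]`` is
  the coefficient of source ``s`` in the linear equation of target ``t``.
* ``S`` — symmetric matrix of (residual) variances and covariances.
* ``M`` — mean / intercept vector.

With ``B = (I - A)^{-1}`` and ``F`` the filter onto observed rows, the
model-implied moments of the observed variables are
``mu = F B M`` and ``Sigma = F B S B' F'``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "VariableDef",
    "Path",
    "ModelSpec",
    "FreeParameter",
    "RamMatrices",
    "build_ram",
    "model_df",
    "parse_model",
    "serialize_model",
    "SpecificationError",
]


class SpecificationError(ValueError):
    """Raised when a model description violates a structural invariant."""


@dataclass(frozen=True)
class VariableDef:
    """One observed or latent variable in a model.

    ``transform`` records how a raw data column maps to the modeling
    scale (``raw`` = untouched, ``log`` = natural log, ``pending`` = not
    yet applied).  Latent variables never carry a transform.
    """

    name: str
    kind: str = "observed"  # "observed" | "latent"
    transform: str = "raw"  # "raw" | "log" | "pending"
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("observed", "latent"):
            raise SpecificationError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "latent" and self.transform not in ("raw",):
            raise SpecificationError(f"latent variable {self.name!r} cannot carry a transform")


@dataclass(frozen=True)
class Path:
    """A single-headed (directed) structural edge ``source -> target``.

    ``fixed`` pins the coefficient to a constant instead of freeing it.
    ``prunable`` marks the path as eligible for backward p-value pruning;
    adjustment-covariate paths and loadings are never prunable.
    """

    source: str
    target: str
    fixed: float | None = None
    prunable: bool = True


@dataclass
class ModelSpec:
    """A full path model: variables, loadings, structural paths, covariances."""

    variables: list[VariableDef]
    loadings: list[tuple[str, str]] = field(default_factory=list)  # (latent, indicator)
    structural_paths: list[Path] = field(default_factory=list)
    covariances: list[tuple[str, str]] = field(default_factory=list)
    means_structure: bool = True
    adjustment_covariates: list[str] = field(default_factory=list)
    # "loading": first loading of each latent fixed to 1 (default).
    # "variance": loadings free, exogenous-latent variance fixed to 1.
    latent_identification: str = "loading"

    # ------------------------------------------------------------------
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def observed_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "observed"]

    def latent_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "latent"]

    def indicators_of(self, latent: str) -> list[str]:
        return [ind for lat, ind in self.loadings if lat == latent]

    def endogenous_names(self) -> set[str]:
        """Variables receiving at least one directed edge (path or loading)."""
        endo = {p.target for p in self.structural_paths}
        endo |= {ind for _, ind in self.loadings}
        return endo

    def exogenous_observed(self) -> list[str]:
        endo = self.endogenous_names()
        return [v.name for v in self.variables if v.kind == "observed" and v.name not in endo]

    def validate(self) -> None:
        names = self.names()
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise SpecificationError(f"duplicate variable names: {dupes}")
        known = set(names)
        kind = {v.name: v.kind for v in self.variables}

        for lat, ind in self.loadings:
            for v in (lat, ind):
                if v not in known:
                    raise SpecificationError(f"loading references unknown variable {v!r}")
            if kind[lat] != "latent":
                raise SpecificationError(f"loading source {lat!r} is not latent")
            if kind[ind] != "observed":
                raise SpecificationError(f"indicator {ind!r} is not observed")
        for p in self.structural_paths:
            for v in (p.source, p.target):
                if v not in known:
                    raise SpecificationError(f"path references unknown variable {v!r}")
        for a, b in self.covariances:
            for v in (a, b):
                if v not in known:
                    raise SpecificationError(f"covariance references unknown variable {v!r}")

        for lat in self.latent_names():
            if not self.indicators_of(lat):
                raise SpecificationError(f"latent variable {lat!r} has no indicator")

        g = nx.DiGraph()
        g.add_nodes_from(known)
        g.add_edges_from((p.source, p.target) for p in self.structural_paths)
        g.add_edges_from(self.loadings)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise SpecificationError(f"directed-path graph contains a cycle: {cycle}")

        exo = set(self.exogenous_observed())
        for c in self.adjustment_covariates:
            if c not in exo:
                raise SpecificationError(
                    f"adjustment covariate {c!r} is not an exogenous observed variable"
                )
        if self.latent_identification not in ("loading", "variance"):
            raise SpecificationError(
                f"unknown latent identification {self.latent_identification!r}"
            )

    def drop_path(self, source: str, target: str) -> "ModelSpec":
        """A copy of the spec without the given structural path."""
        kept = [p for p in self.structural_paths if not (p.source == source and p.target == target)]
        if len(kept) == len(self.structural_paths):
            raise SpecificationError(f"no structural path {source!r} -> {target!r} to remove")
        return replace(self, structural_paths=kept)


@dataclass(frozen=True)
class FreeParameter:
    """One free scalar parameter and the matrix slot(s) it occupies.

    For symmetric ``S`` entries the (i, j) and (j, i) slots are filled
    with the same value.
    """

    label: str
    matrix: str  # "A" | "S" | "M"
    i: int
    j: int  # for "M" this is 0
    kind: str  # "loading" | "path" | "variance" | "covariance" | "mean"


@dataclass
class RamMatrices:
    """RAM translation of a :class:`ModelSpec`.

    ``A0``, ``S0``, ``M0`` hold fixed values; :meth:`materialize` fills
    the free slots from a parameter vector ``theta``.
    """

    spec: ModelSpec
    names: list[str]
    obs_idx: np.ndarray  # indices of observed variables within names
    A0: np.ndarray
    S0: np.ndarray
    M0: np.ndarray
    free_map: list[FreeParameter]
    fixed_entries: dict[str, float]  # label -> fixed value (e.g. unit loadings)

    @property
    def q(self) -> int:
        return len(self.free_map)

    @property
    def m(self) -> int:
        return len(self.names)

    @property
    def p(self) -> int:
        return len(self.obs_idx)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def labels(self) -> list[str]:
        return [fp.label for fp in self.free_map]

    def materialize(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.q,):
            raise ValueError(f"theta has shape {theta.shape}, expected ({self.q},)")
        A = self.A0.copy()
        S = self.S0.copy()
        M = self.M0.copy()
        for val, fp in zip(theta, self.free_map):
            if fp.matrix == "A":
                A[fp.i, fp.j] = val
            elif fp.matrix == "S":
                S[fp.i, fp.j] = val
                S[fp.j, fp.i] = val
            else:
                M[fp.i] = val
        return A, S, M

    def param_index(self, label: str) -> int:
        for k, fp in enumerate(self.free_map):
            if fp.label == label:
                return k
        raise KeyError(label)


def path_label(source: str, target: str) -> str:
    return f"path:{source}->{target}"


def loading_label(latent: str, indicator: str) -> str:
    return f"loading:{latent}->{indicator}"


def cov_label(a: str, b: str) -> str:
    x, y = sorted((a, b))
    return f"cov:{x}~{y}"


def var_label(name: str) -> str:
    return f"var:{name}"


def mean_label(name: str) -> str:
    return f"mean:{name}"


def build_ram(spec: ModelSpec) -> RamMatrices:
    """Translate a validated spec into RAM matrices with a deterministic
    free-parameter ordering (declaration order: loadings, paths,
    variances, covariances, means)."""
    spec.validate()
    names = spec.names()
    idx = {n: k for k, n in enumerate(names)}
    m = len(names)
    kind = {v.name: v.kind for v in spec.variables}
    endo = spec.endogenous_names()

    A0 = np.zeros((m, m))
    S0 = np.zeros((m, m))
    M0 = np.zeros(m)
    free: list[FreeParameter] = []
    fixed: dict[str, float] = {}

    # --- loadings -----------------------------------------------------
    seen_first: set[str] = set()
    for lat, ind in spec.loadings:
        i, j = idx[ind], idx[lat]
        lbl = loading_label(lat, ind)
        if spec.latent_identification == "loading" and lat not in seen_first:
            A0[i, j] = 1.0
            fixed[lbl] = 1.0
            seen_first.add(lat)
        else:
            free.append(FreeParameter(lbl, "A", i, j, "loading"))

    # --- structural paths --------------------------------------------
    for p in spec.structural_paths:
        i, j = idx[p.target], idx[p.source]
        lbl = path_label(p.source, p.target)
        if p.fixed is not None:
            A0[i, j] = p.fixed
            fixed[lbl] = p.fixed
        else:
            free.append(FreeParameter(lbl, "A", i, j, "path"))

    # --- variances ----------------------------------------------------
    for v in spec.variables:
        i = idx[v.name]
        lbl = var_label(v.name)
        if (
            v.kind == "latent"
            and spec.latent_identification == "variance"
            and v.name not in endo
        ):
            S0[i, i] = 1.0
            fixed[lbl] = 1.0
        else:
            free.append(FreeParameter(lbl, "S", i, i, "variance"))

    # --- covariances: explicit, then automatic exogenous-observed pairs
    cov_slots: set[tuple[int, int]] = set()
    for a, b in spec.covariances:
        i, j = idx[a], idx[b]
        key = (min(i, j), max(i, j))
        if i == j or key in cov_slots:
            continue
        cov_slots.add(key)
        free.append(FreeParameter(cov_label(a, b), "S", key[0], key[1], "covariance"))
    # exogenous observed predictors are allowed to correlate freely, but
    # only when they actually feed the structural part of the model
    sources = {p.source for p in spec.structural_paths}
    exo_obs = [v for v in spec.exogenous_observed() if v in sources]
    for r, a in enumerate(exo_obs):
        for b in exo_obs[r + 1 :]:
            i, j = idx[a], idx[b]
            key = (min(i, j), max(i, j))
            if key in cov_slots:
                continue
            cov_slots.add(key)
            free.append(FreeParameter(cov_label(a, b), "S", key[0], key[1], "covariance"))

    # --- means ---------------------------------------------------------
    if spec.means_structure:
        for v in spec.variables:
            if v.kind == "observed":
                free.append(FreeParameter(mean_label(v.name), "M", idx[v.name], 0, "mean"))
            # latent means stay fixed at 0

    obs_idx = np.array([idx[n] for n in spec.observed_names()], dtype=int)
    return RamMatrices(
        spec=spec,
        names=names,
        obs_idx=obs_idx,
        A0=A0,
        S0=S0,
        M0=M0,
        free_map=free,
        fixed_entries=fixed,
    )


def model_df(spec: ModelSpec, p: int | None = None) -> int:
    """Degrees of freedom: number of observed moments minus free parameters.

    With a means structure there are p(p+3)/2 moments (means plus
    lower-triangular covariance); without, p(p+1)/2.  A negative value is
    returned as-is (the model is then not identified).
    """
    ram = build_ram(spec)
    if p is None:
        p = ram.p
    moments = p * (p + 3) // 2 if spec.means_structure else p * (p + 1) // 2
    return moments - ram.q


# ----------------------------------------------------------------------
# Text interchange format (YAML/JSON-compatible mapping)
# ----------------------------------------------------------------------


def serialize_model(spec: ModelSpec) -> dict:
    """Canonical mapping representation of a spec (YAML/JSON friendly)."""
    doc: dict = {
        "variables": [
            {"name": v.name, "transform": v.transform, "units": v.units}
            for v in spec.variables
            if v.kind == "observed"
        ],
        "latent": {lat: spec.indicators_of(lat) for lat in spec.latent_names()},
        "paths": [
            {
                "from": p.source,
                "to": p.target,
                **({"fixed": p.fixed} if p.fixed is not None else {}),
                **({} if p.prunable else {"prunable": False}),
            }
            for p in spec.structural_paths
        ],
        "covariances": [[a, b] for a, b in spec.covariances],
        "adjust": list(spec.adjustment_covariates),
        "means_structure": spec.means_structure,
        "latent_identification": spec.latent_identification,
    }
    return doc


def model_to_yaml(spec: ModelSpec) -> str:
    return yaml.safe_dump(serialize_model(spec), sort_keys=False)


def parse_model(text: str | dict) -> ModelSpec:
    """Parse a model description document (YAML text or mapping).

    Blocks: ``variables`` (observed; names or mappings with transform /
    units), ``latent`` (mapping latent -> indicator list), ``paths``
    (``{from, to, fixed?, prunable?}`` or ``"a -> b"`` strings),
    ``covariances`` (pairs), ``adjust`` (exogenous covariates).
    """
    doc = yaml.safe_load(text) if isinstance(text, str) else text
    if not isinstance(doc, dict):
        raise SpecificationError("model document must be a mapping")

    variables: list[VariableDef] = []
    for item in doc.get("variables", []):
        if isinstance(item, str):
            variables.append(VariableDef(item))
        else:
            variables.append(
                VariableDef(
                    item["name"],
                    kind="observed",
                    transform=item.get("transform", "raw"),
                    units=item.get("units", ""),
                )
            )
    loadings: list[tuple[str, str]] = []
    for lat, inds in (doc.get("latent") or {}).items():
        variables.append(VariableDef(lat, kind="latent"))
        for ind in inds:
            loadings.append((lat, ind))

    paths: list[Path] = []
    for item in doc.get("paths") or []:
        if isinstance(item, str):
            src, _, dst = item.partition("->")
            paths.append(Path(src.strip(), dst.strip()))
        elif isinstance(item, (list, tuple)) and len(item) == 2:
            paths.append(Path(item[0], item[1]))
        else:
            paths.append(
                Path(
                    item["from"],
                    item["to"],
                    fixed=item.get("fixed"),
                    prunable=item.get("prunable", True),
                )
            )

    covs = [tuple(pair) for pair in (doc.get("covariances") or [])]
    spec = ModelSpec(
        variables=variables,
        loadings=loadings,
        structural_paths=paths,
        covariances=covs,
        means_structure=doc.get("means_structure", True),
        adjustment_covariates=list(doc.get("adjust") or []),
        latent_identification=doc.get("latent_identification", "loading"),
    )
    spec.validate()
    return spec


def parse_model_file(path) -> ModelSpec:
    with io.open(path, "r", encoding="utf-8") as fh:
        return parse_model(fh.read())
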