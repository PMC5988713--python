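"""Synthetic three-group cohort generator.

Emulates a cross-sectional study of smokers with COPD, smokers without
COPD and non-smokers, where smoking exposure (pack-years) affects
systemic/biological outcomes partly directly and partly through lung
function (FEV1, KCO).  Generation happens on a standardized scale
(every variable unit-variance in the generating population) so that the
configured standardized path coefficients *are* the ground truth for
parameter-recovery experiments; raw Table-style scales are applied as a
final presentation-only affine/exponential map and recorded in the
truth record.

Residual variances are set to 1 - R² per equation, where R² is computed
from the analytically propagated population covariance of the
predictors, so coefficients are exact by construction rather than
calibrated by simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .estimation import Dataset

__all__ = [
    "Marginal",
    "CohortConfig",
    "TruthRecord",
    "default_config",
    "generate_cohort",
    "apply_missingness",
    "MODEL_VARIABLES",
    "LOG_VARIABLES",
]


class CohortConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Marginal:
    """Raw-scale marginal of one variable.

    ``scale="normal"``: raw = loc + spread * z (loc/spread = mean/SD).
    ``scale="lognormal"``: raw = exp(m + s*z) with m = log(median) and
    s chosen so the quartiles match (q1, q3).
    """

    scale: str  # "normal" | "lognormal"
    loc: float  # mean, or median for lognormal
    spread: float  # SD, or (q1, q3)-implied log-SD for lognormal
    units: str = ""

    def to_raw(self, z: np.ndarray) -> np.ndarray:
        if self.scale == "normal":
            return self.loc + self.spread * z
        return np.exp(np.log(self.loc) + self.spread * z)


def lognormal_marginal(median: float, q1: float, q3: float, units: str = "") -> Marginal:
    # half the IQR of a standard normal spans 0.6745 SD
    s = float(np.log(q3 / q1) / (2.0 * stats.norm.ppf(0.75)))
    return Marginal("lognormal", median, s, units)


# modeled observed variables, in model declaration order
MODEL_VARIABLES: list[str] = [
    "age",
    "gender",
    "pack_years",
    "fev1",
    "kco",
    "asmmi",
    "bmd_hip",
    "bmd_lumbar",
    "pinch",
    "grip",
    "il6",
    "il8",
    "tnfa",
    "mcp1",
    "egfr",
    "homa_ir",
    "pwv",
    "telomere",
    "wbc",
    "crp",
]

# analyzed on the log scale: everything except age, gender, pack-years and
# the two lung-function percentages
LOG_VARIABLES: list[str] = [
    "asmmi",
    "bmd_hip",
    "bmd_lumbar",
    "pinch",
    "grip",
    "il6",
    "il8",
    "tnfa",
    "mcp1",
    "egfr",
    "homa_ir",
    "pwv",
    "telomere",
    "wbc",
    "crp",
]

MUSCULO_INDICATORS = ["asmmi", "bmd_hip", "bmd_lumbar", "pinch", "grip"]
CYTOKINE_INDICATORS = ["il6", "il8", "tnfa", "mcp1"]

# systemic outcomes modeled as single observed endogenous variables
OBSERVED_OUTCOMES = ["egfr", "homa_ir", "pwv", "telomere", "wbc", "crp"]
# all systemic outcome constructs (latents included), the targets of the
# candidate smoking / FEV1 / KCO paths
OUTCOME_CONSTRUCTS = ["musculoskeletal"] + OBSERVED_OUTCOMES + ["cytokines"]


@dataclass
class CohortConfig:
    """Generating structure of a synthetic cohort.

    ``standardized_paths`` maps (source, target) to the standardized
    coefficient of the generating linear equation; ``copd_group`` as a
    source denotes the generation-only COPD-membership shift that is not
    part of any fitted model.
    """

    group_sizes: tuple[int, int, int]  # (COPD, smokers w/o COPD, non-smokers)
    n_women: int
    age_mean: float
    age_sd: float
    packyears_mean: float  # mean of observed pack-years among smokers
    packyears_sd: float
    packyears_floor: float  # smokers are defined by exposure above this
    marginals: dict[str, Marginal]
    standardized_paths: dict[tuple[str, str], float]
    standardized_loadings: dict[tuple[str, str], float]
    missing_counts: dict[str, int]  # per-variable observed-N targets
    printed_paths: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(sum(self.group_sizes))

    def scaled(self, n: int) -> "CohortConfig":
        """Proportionally rescaled design (group sizes, women, observed
        counts) for recovery experiments at other sample sizes."""
        ratio = n / self.n
        g = [int(round(s * ratio)) for s in self.group_sizes]
        g[2] += n - sum(g)
        counts = {k: min(n, int(round(v * ratio))) for k, v in self.missing_counts.items()}
        return CohortConfig(
            group_sizes=(g[0], g[1], g[2]),
            n_women=int(round(self.n_women * ratio)),
            age_mean=self.age_mean,
            age_sd=self.age_sd,
            packyears_mean=self.packyears_mean,
            packyears_sd=self.packyears_sd,
            packyears_floor=self.packyears_floor,
            marginals=self.marginals,
            standardized_paths=dict(self.standardized_paths),
            standardized_loadings=dict(self.standardized_loadings),
            missing_counts=counts,
            printed_paths=list(self.printed_paths),
        )

    def validate(self) -> None:
        if any(s <= 0 for s in self.group_sizes):
            raise CohortConfigError(f"group sizes must be positive: {self.group_sizes}")
        if not (0 < self.n_women < self.n):
            raise CohortConfigError("n_women must be strictly between 0 and n")
        for v, c in self.missing_counts.items():
            if not (0 < c <= self.n):
                raise CohortConfigError(f"observed count for {v!r} out of range: {c}")
        # R² < 1 for every equation, via the analytic covariance propagation
        _population_plan(self)


@dataclass
class TruthRecord:
    """Generating parameters echoed verbatim for recovery comparison."""

    standardized_paths: dict
    standardized_loadings: dict
    printed_paths: list
    r_squared: dict
    group_sizes: tuple
    n_women: int
    seed: int
    marginal_map: dict

    def to_json(self, path=None) -> str:
        payload = {
            "standardized_paths": {f"{s}->{t}": v for (s, t), v in self.standardized_paths.items()},
            "standardized_loadings": {
                f"{s}->{t}": v for (s, t), v in self.standardized_loadings.items()
            },
            "printed_paths": [f"{s}->{t}" for s, t in self.printed_paths],
            "r_squared": self.r_squared,
            "group_sizes": list(self.group_sizes),
            "n_women": self.n_women,
            "seed": self.seed,
            "marginal_map": self.marginal_map,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


# ----------------------------------------------------------------------
# Default (study-design) configuration
# ----------------------------------------------------------------------


def default_config() -> CohortConfig:
    """The study design: 292 subjects (97 COPD / 96 smokers / 99
    non-smokers, 103 women), published marginal distributions and
    per-variable completeness, and the published standardized path
    coefficients as generating truth.

    Coefficients printed for the whole-sample model are used verbatim;
    non-significant cells are generated as true zeros.  Unprinted
    parameters (smoking→lung function, COPD-group shifts, age/gender
    effects, loadings) carry fixed documented defaults and are excluded
    from recovery acceptance.
    """
    marginals: dict[str, Marginal] = {
        "age": Marginal("normal", 59.4, 7.3, "years"),
        "fev1": Marginal("normal", 87.2, 29.3, "% predicted"),
        "kco": Marginal("normal", 83.0, 20.9, "% predicted"),
        "bmd_lumbar": lognormal_marginal(1.10, 0.98, 1.20, "g/cm^2"),
        "bmd_hip": lognormal_marginal(0.95, 0.85, 1.06, "g/cm^2"),
        "pinch": lognormal_marginal(6, 5, 8, "kg"),
        "grip": lognormal_marginal(37, 26, 45, "kg"),
        "asmmi": lognormal_marginal(7.4, 6.3, 8.3, "kg/m^2"),
        "egfr": lognormal_marginal(88.4, 72.6, 101.1, "mL/min"),
        "homa_ir": lognormal_marginal(1.93, 1.17, 2.81, ""),
        "telomere": lognormal_marginal(0.41, 0.35, 0.48, "T/S ratio"),
        "wbc": lognormal_marginal(6.30, 5.20, 7.70, "Giga/L"),
        "crp": lognormal_marginal(1.20, 0.40, 5.00, "mg/L"),
        "il6": lognormal_marginal(15.6, 13.2, 18.1, "pg/mL"),
        "il8": lognormal_marginal(46.4, 40.3, 51.7, "pg/mL"),
        "mcp1": lognormal_marginal(36.3, 27.5, 47.8, "pg/mL"),
        "tnfa": lognormal_marginal(68.1, 56.6, 82.1, "pg/mL"),
        # PWV marginal is not printed in the cohort table; realistic
        # aortic values for a cohort around age 59 (synthetic default)
        "pwv": lognormal_marginal(9.8, 8.3, 11.6, "m/s"),
    }

    printed = {
        ("fev1", "musculoskeletal"): 0.162,
        ("kco", "musculoskeletal"): 0.270,
        ("pack_years", "egfr"): 0.15,
        ("kco", "egfr"): 0.113,
        ("fev1", "homa_ir"): -0.122,
        ("fev1", "pwv"): -0.157,
        ("kco", "pwv"): -0.144,
        ("fev1", "telomere"): 0.254,
        ("pack_years", "wbc"): 0.288,
        ("fev1", "wbc"): -0.199,
        ("pack_years", "crp"): 0.173,
        ("fev1", "crp"): -0.295,
        ("fev1", "cytokines"): -0.278,
    }
    unprinted = {
        # smoking -> lung function: strong negative defaults (the printed
        # diagram values are not machine-readable)
        ("pack_years", "fev1"): -0.45,
        ("pack_years", "kco"): -0.35,
        # COPD-group shift on lung function, generation-only
        ("copd_group", "fev1"): -0.35,
        ("copd_group", "kco"): -0.25,
        # age and gender adjustments
        ("age", "musculoskeletal"): -0.20,
        ("age", "pwv"): 0.20,
        ("age", "telomere"): -0.20,
        ("age", "egfr"): -0.20,
        ("gender", "musculoskeletal"): -0.25,  # gender coded female = 1
    }
    loadings = {("musculoskeletal", ind): 0.75 for ind in MUSCULO_INDICATORS}
    loadings.update({("cytokines", ind): 0.75 for ind in CYTOKINE_INDICATORS})

    missing_counts = {
        "age": 292,
        "gender": 292,
        "pack_years": 285,  # 186 smokers completed + 99 known-zero non-smokers
        "fev1": 291,
        "kco": 242,
        "bmd_lumbar": 288,
        "bmd_hip": 289,
        "pinch": 242,
        "grip": 242,
        "asmmi": 284,
        "egfr": 267,
        "homa_ir": 278,
        "telomere": 265,
        "wbc": 270,
        "crp": 269,
        "il6": 264,
        "il8": 264,
        "mcp1": 264,
        "tnfa": 264,
        "pwv": 285,  # synthetic default (not printed)
    }

    cfg = CohortConfig(
        group_sizes=(97, 96, 99),
        n_women=103,
        age_mean=59.4,
        age_sd=7.3,
        packyears_mean=42.6,
        packyears_sd=24.8,
        packyears_floor=10.0,
        marginals=marginals,
        standardized_paths={**printed, **unprinted},
        standardized_loadings=loadings,
        missing_counts=missing_counts,
        printed_paths=list(printed.keys()),
    )
    cfg.validate()
    return cfg


# ----------------------------------------------------------------------
# Generation
# ----------------------------------------------------------------------


def _solve_truncnorm_params(mean: float, sd: float, floor: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) whose left-truncation at ``floor``
    has the requested mean and SD."""

    def resid(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a = (floor - mu) / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(resid, [mean, np.log(sd)], full_output=False)
    mu, sigma = float(sol[0]), float(np.exp(sol[1]))
    return mu, sigma


def _exogenous_moments(config: CohortConfig) -> dict:
    """Population moments of the standardized exogenous block under
    size-proportional group sampling."""
    n = config.n
    p_smoker = (config.group_sizes[0] + config.group_sizes[1]) / n
    p_copd = config.group_sizes[0] / n
    p_women = config.n_women / n
    mu_s, sd_s = config.packyears_mean, config.packyears_sd
    py_mean = p_smoker * mu_s
    py_var = p_smoker * (sd_s**2 + mu_s**2) - py_mean**2
    py_sd = float(np.sqrt(py_var))
    # both smoking groups share the pack-years distribution, so
    # cov(py, copd) = p_copd * mu_s * (1 - p_smoker)
    corr_py_copd = (p_copd * mu_s * (1.0 - p_smoker)) / (
        py_sd * np.sqrt(p_copd * (1.0 - p_copd))
    )
    return {
        "p_smoker": p_smoker,
        "p_copd": p_copd,
        "p_women": p_women,
        "py_mean": py_mean,
        "py_sd": py_sd,
        "corr_py_copd": float(corr_py_copd),
    }


def _generation_order(config: CohortConfig) -> list[tuple[str, dict[str, float]]]:
    """Endogenous variables in topological order with their standardized
    coefficient maps (loadings folded in as single-predictor equations)."""
    eqs: dict[str, dict[str, float]] = {}
    for (src, tgt), val in config.standardized_paths.items():
        eqs.setdefault(tgt, {})[src] = val
    order = ["fev1", "kco", "musculoskeletal", "cytokines"] + OBSERVED_OUTCOMES
    out = [(name, eqs.get(name, {})) for name in order]
    for (lat, ind), lam in config.standardized_loadings.items():
        out.append((ind, {lat: lam}))
    return out


def _population_plan(config: CohortConfig) -> tuple[list[tuple[str, dict, float]], dict]:
    """Analytic covariance propagation: per equation the residual SD such
    that the generated variable has unit population variance; raises if
    any implied R² reaches 1."""
    ex = _exogenous_moments(config)
    names = ["age", "gender", "pack_years", "copd_group"]
    K = np.eye(4)
    rho = ex["corr_py_copd"]
    K[2, 3] = K[3, 2] = rho
    idx = {n: i for i, n in enumerate(names)}

    plan: list[tuple[str, dict, float]] = []
    r2_map: dict[str, float] = {}
    for name, beta in _generation_order(config):
        missing = [s for s in beta if s not in idx]
        if missing:
            raise CohortConfigError(f"equation for {name!r} uses ungenerated sources {missing}")
        srcs = list(beta)
        b = np.array([beta[s] for s in srcs])
        sub = np.array([[K[idx[a], idx[c]] for c in srcs] for a in srcs])
        r2 = float(b @ sub @ b)
        if r2 >= 1.0:
            raise CohortConfigError(
                f"equation for {name!r} implies R^2 = {r2:.3f} >= 1; "
                f"coefficients {beta} are inconsistent with unit variances"
            )
        r2_map[name] = r2
        # extend K
        m = K.shape[0]
        newK = np.eye(m + 1)
        newK[:m, :m] = K
        cov_new = np.zeros(m)
        for s in srcs:
            cov_new += beta[s] * K[idx[s], :]
        newK[m, :m] = cov_new
        newK[:m, m] = cov_new
        K = newK
        idx[name] = m
        plan.append((name, beta, float(np.sqrt(1.0 - r2))))
    return plan, r2_map


def generate_cohort(config: CohortConfig, seed: int = 0) -> tuple[Dataset, TruthRecord]:
    """Draw one cohort from the configured structure.

    Exogenous design first (fixed group sizes and women count, normal
    age, floor-truncated normal pack-years in smokers, zero in
    non-smokers), then every endogenous variable in topological order by
    its standardized linear equation with Normal(0, 1 - R²) residuals,
    then the presentation map onto raw scales.  Bit-reproducible under a
    fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n
    n_copd, n_smoker, n_non = config.group_sizes
    group = np.array(["copd"] * n_copd + ["smoker"] * n_smoker + ["nonsmoker"] * n_non)

    ex = _exogenous_moments(config)
    women = np.zeros(n)
    women[rng.choice(n, config.n_women, replace=False)] = 1.0
    age_raw = config.age_mean + config.age_sd * rng.standard_normal(n)

    mu0, sigma0 = _solve_truncnorm_params(
        config.packyears_mean, config.packyears_sd, config.packyears_floor
    )
    a0 = (config.packyears_floor - mu0) / sigma0
    smoker_mask = group != "nonsmoker"
    py_raw = np.zeros(n)
    py_raw[smoker_mask] = stats.truncnorm.rvs(
        a0, np.inf, loc=mu0, scale=sigma0, size=int(smoker_mask.sum()), random_state=rng
    )

    z: dict[str, np.ndarray] = {
        "age": (age_raw - config.age_mean) / config.age_sd,
        "gender": (women - ex["p_women"]) / np.sqrt(ex["p_women"] * (1 - ex["p_women"])),
        "pack_years": (py_raw - ex["py_mean"]) / ex["py_sd"],
        "copd_group": ((group == "copd").astype(float) - ex["p_copd"])
        / np.sqrt(ex["p_copd"] * (1 - ex["p_copd"])),
    }

    plan, r2_map = _population_plan(config)
    for name, beta, resid_sd in plan:
        lin = np.zeros(n)
        for s, b in beta.items():
            lin += b * z[s]
        z[name] = lin + resid_sd * rng.standard_normal(n)

    cols: dict[str, np.ndarray] = {}
    for v in MODEL_VARIABLES:
        if v == "age":
            cols[v] = age_raw
        elif v == "gender":
            cols[v] = women
        elif v == "pack_years":
            cols[v] = py_raw
        else:
            cols[v] = config.marginals[v].to_raw(z[v])

    df = pd.DataFrame(cols, columns=MODEL_VARIABLES)
    meta = pd.DataFrame({"group": group})
    truth = TruthRecord(
        standardized_paths=dict(config.standardized_paths),
        standardized_loadings=dict(config.standardized_loadings),
        printed_paths=list(config.printed_paths),
        r_squared=r2_map,
        group_sizes=config.group_sizes,
        n_women=config.n_women,
        seed=seed,
        marginal_map={
            v: asdict(m) for v, m in config.marginals.items()
        },
    )
    return Dataset(df, meta), truth


def apply_missingness(
    dataset: Dataset, missing_counts: dict[str, int], seed: int = 0
) -> Dataset:
    """Blank cells uniformly at random (MCAR), independently per variable,
    so that each variable's observed count exactly equals its target."""
    n = dataset.n
    df = dataset.df.copy()
    rng = np.random.default_rng(seed)
    for v in df.columns:
        target = missing_counts.get(v, n)
        k = n - int(target)
        if k < 0:
            raise CohortConfigError(f"observed-count target for {v!r} exceeds n")
        if k:
            df.loc[rng.choice(n, k, replace=False), v] = np.nan
    return Dataset(df, dataset.meta)
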