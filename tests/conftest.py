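"""Shared fixtures: small toy models and simulators used across the suite."""

import numpy as np
import pandas as pd
import pytest

from copdsem.model import ModelSpec, VariableDef, Path
from copdsem.estimation import Dataset


# ----------------------------------------------------------------------
# Mediation chain x -> m -> y with standardized coefficients a, b
# ----------------------------------------------------------------------

CHAIN_A, CHAIN_B = 0.5, 0.4


def make_chain_spec(extra_path: bool = False) -> ModelSpec:
    paths = [Path("x", "m"), Path("m", "y")]
    if extra_path:
        paths.append(Path("x", "y"))
    return ModelSpec(
        variables=[VariableDef("x"), VariableDef("m"), VariableDef("y")],
        structural_paths=paths,
    )


def simulate_chain(n: int, seed: int, a: float = CHAIN_A, b: float = CHAIN_B) -> Dataset:
    """Unit-variance chain: var(m)=a^2+res, var(y)=b^2+res with res chosen
    so all marginal variances are exactly 1."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a * x + np.sqrt(1 - a**2) * rng.standard_normal(n)
    y = b * m + np.sqrt(1 - b**2) * rng.standard_normal(n)
    return Dataset(pd.DataFrame({"x": x, "m": m, "y": y}))


# ----------------------------------------------------------------------
# Four-variable model with one truly-zero candidate path (x2 -> y)
# ----------------------------------------------------------------------


def make_four_var_spec(with_null_path: bool = True) -> ModelSpec:
    paths = [Path("x1", "m"), Path("m", "y")]
    if with_null_path:
        paths.append(Path("x2", "y"))
    return ModelSpec(
        variables=[VariableDef("x1"), VariableDef("x2"), VariableDef("m"), VariableDef("y")],
        structural_paths=paths,
    )


def simulate_four_var(n: int, seed: int) -> Dataset:
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    m = 0.5 * x1 + np.sqrt(0.75) * rng.standard_normal(n)
    y = 0.4 * m + np.sqrt(0.84) * rng.standard_normal(n)  # x2 has no effect
    return Dataset(pd.DataFrame({"x1": x1, "x2": x2, "m": m, "y": y}))


# ----------------------------------------------------------------------
# Single-factor measurement model
# ----------------------------------------------------------------------


def make_factor_spec(k: int = 4, identification: str = "loading") -> ModelSpec:
    names = [f"y{j + 1}" for j in range(k)]
    return ModelSpec(
        variables=[VariableDef(nm) for nm in names] + [VariableDef("f", kind="latent")],
        loadings=[("f", nm) for nm in names],
        latent_identification=identification,
    )


def simulate_factor(n: int, seed: int, k: int = 4, loading: float = 0.8) -> Dataset:
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    cols = {
        f"y{j + 1}": loading * f + np.sqrt(1 - loading**2) * rng.standard_normal(n)
        for j in range(k)
    }
    return Dataset(pd.DataFrame(cols))


@pytest.fixture(scope="session")
def chain_data() -> Dataset:
    return simulate_chain(800, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design synthetic cohort with its published missingness."""
    from copdsem.cohort import default_config, generate_cohort, apply_missingness

    cfg = default_config()
    ds, truth = generate_cohort(cfg, seed=1)
    masked = apply_missingness(ds, cfg.missing_counts, seed=1)
    return cfg, masked, truth
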