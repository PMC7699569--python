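"""Synthetic data generators.

Every stage of the pipeline is testable without any download: these
generators produce balanced panels whose per-variable means, standard
deviations and ranges emulate the study's published summary statistics,
piecewise-linear responses with known hinge structure for parameter
recovery, the two-predictor toy surface sin(1.5 pi x1) cos(0.5 pi x2),
and calibration beds for the endogeneity and causality screens.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .mars import BasisTerm, hinge_eval
from .panel import DesignMatrix, PanelDataset

__all__ = [
    "VarMoments",
    "PanelSpec",
    "PiecewiseSpec",
    "default_panel_spec",
    "gen_panel",
    "gen_piecewise_response",
    "gen_figure1_grid",
    "gen_endogenous_system",
    "gen_granger_pair",
]


@dataclass(frozen=True)
class VarMoments:
    """Target marginal moments of one panel variable."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if not self.min < self.max:
            raise ValueError(f"need min < max, got [{self.min}, {self.max}]")
        if not self.min <= self.mean <= self.max:
            raise ValueError(
                f"infeasible moments: mean {self.mean} outside "
                f"[{self.min}, {self.max}]"
            )


@dataclass(frozen=True)
class PanelSpec:
    """Shape, moments and temporal persistence of a synthetic panel."""

    n_countries: int = 14
    n_years: int = 23
    variables: dict[str, VarMoments] = field(default_factory=dict)
    persistence: float = 0.8
    seed: int = 0
    start_year: int = 1995

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence < 1.0:
            raise ValueError("persistence must lie in [0, 1)")
        if self.n_countries < 1 or self.n_years < 1:
            raise ValueError("panel dimensions must be positive")


@dataclass(frozen=True)
class PiecewiseSpec:
    """Ground-truth piecewise-linear signal: intercept plus hinge-product
    terms with known coefficients, plus optional Gaussian noise."""

    terms: tuple[BasisTerm, ...]
    intercept: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for t in self.terms:
            if t.coefficient is None:
                raise ValueError("every ground-truth term needs a coefficient")


def default_panel_spec(seed: int = 0) -> PanelSpec:
    """The shipped moment spec emulating the study's 14 x 23 x 7 panel."""
    raw = json.loads(
        resources.files("panelmars.data").joinpath("table_moments.json").read_text()
    )
    variables = {
        name: VarMoments(m["mean"], m["sd"], m["min"], m["max"])
        for name, m in raw["variables"].items()
    }
    return PanelSpec(
        n_countries=raw["n_countries"],
        n_years=raw["n_years"],
        variables=variables,
        persistence=raw["persistence"],
        seed=seed,
        start_year=raw["start_year"],
    )


def gen_panel(spec: PanelSpec) -> PanelDataset:
    """Balanced panel of stationary Gaussian AR(1) series.

    Each (country, variable) series follows z_t = rho z_{t-1} +
    sqrt(1-rho^2) eps_t with standard-normal marginals, is scaled to the
    target mean and sd, and finally clipped to [min, max] (range fidelity
    is prioritised over exact sd; the clipping shrinks the sd by a few
    percent at most for the shipped moments).
    """
    if not spec.variables:
        raise ValueError("spec has no variables")
    rng = np.random.default_rng(spec.seed)
    rho = spec.persistence
    innov_sd = np.sqrt(1.0 - rho**2)
    countries = [f"C{i + 1:02d}" for i in range(spec.n_countries)]
    years = list(range(spec.start_year, spec.start_year + spec.n_years))
    records = []
    for c in countries:
        series = {}
        for name, m in spec.variables.items():
            z = np.empty(spec.n_years)
            z[0] = rng.standard_normal()
            eps = rng.standard_normal(spec.n_years - 1)
            for t in range(1, spec.n_years):
                z[t] = rho * z[t - 1] + innov_sd * eps[t - 1]
            x = np.clip(m.mean + m.sd * z, m.min, m.max)
            series[name] = x
        for t, yr in enumerate(years):
            records.append(
                {"country": c, "year": yr}
                | {name: series[name][t] for name in spec.variables}
            )
    return PanelDataset(pd.DataFrame.from_records(records))


def gen_piecewise_response(X: DesignMatrix, spec: PiecewiseSpec) -> np.ndarray:
    """Evaluate the ground-truth signal on a design, plus Gaussian noise.

    Every hinge knot must coincide with an observed value of its variable
    so that the knot is recoverable from the candidate set.
    """
    for t in spec.terms:
        for h in t.factors:
            observed = X.column(h.var)  # raises on unknown variable
            if not h.linear and not np.any(np.isclose(observed, h.knot)):
                raise ValueError(
                    f"knot {h.knot} of {h.var!r} is not an observed value"
                )
    y = np.full(X.n, float(spec.intercept))
    for t in spec.terms:
        col = np.ones(X.n)
        for h in t.factors:
            col = col * hinge_eval(h, X.column(h.var))
        y = y + t.coefficient * col
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + spec.noise_sd * rng.standard_normal(X.n)
    return y


def gen_figure1_grid(n_per_axis: int) -> DesignMatrix:
    """Uniform grid on [0,1]^2 with the exact two-predictor toy surface
    y = sin(1.5 pi x1) * cos(0.5 pi x2)."""
    if n_per_axis < 2:
        raise ValueError("n_per_axis must be >= 2")
    axis = np.linspace(0.0, 1.0, n_per_axis)
    x1, x2 = np.meshgrid(axis, axis, indexing="ij")
    x1, x2 = x1.ravel(), x2.ravel()
    y = np.sin(1.5 * np.pi * x1) * np.cos(0.5 * np.pi * x2)
    rows = [("grid", i) for i in range(x1.size)]
    return DesignMatrix(y, np.column_stack([x1, x2]), rows, ["x1", "x2"])


def gen_endogenous_system(
    n: int, endogeneity: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Calibration bed for the Hausman test.

    Structural equation y = 1 + 2 x + e with a single regressor
    x = 0.8 z + u; the error e correlates with the regressor's
    unobserved component u by the stated amount (corr(u, e) =
    ``endogeneity``), while the instrument z is independent of e.

    Returns (y, exog, endog, instruments) where exog is the constant
    column.
    """
    if n < 30:
        raise ValueError("n must be >= 30")
    if not -1.0 <= endogeneity <= 1.0:
        raise ValueError("endogeneity must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    u = rng.standard_normal(n)
    v = rng.standard_normal(n)
    e = endogeneity * u + np.sqrt(1.0 - endogeneity**2) * v
    x = 0.8 * z + u
    y = 1.0 + 2.0 * x + e
    return y, np.ones((n, 1)), x[:, None], z[:, None]


def gen_granger_pair(
    causal: bool,
    effect_size: float,
    spec: PanelSpec | None = None,
    seed: int | None = None,
) -> PanelDataset:
    """Calibration bed for the stacked Granger test.

    Generates a balanced panel with two series, CAUSE and EFFECT.  The
    cause is a stationary AR(1) with the spec's persistence; the effect
    follows effect_t = 0.5 effect_{t-1} (+ effect_size * cause_{t-1} if
    ``causal``) + noise.  With ``causal=False`` the two series are fully
    independent.
    """
    if spec is None:
        spec = PanelSpec(variables={})
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    rho = spec.persistence
    innov = np.sqrt(1.0 - rho**2)
    countries = [f"C{i + 1:02d}" for i in range(spec.n_countries)]
    years = list(range(spec.start_year, spec.start_year + spec.n_years))
    records = []
    for cname in countries:
        T = spec.n_years
        c = np.empty(T)
        e = np.empty(T)
        c[0] = rng.standard_normal()
        e[0] = rng.standard_normal()
        eps_c = rng.standard_normal(T - 1)
        eps_e = rng.standard_normal(T - 1)
        for t in range(1, T):
            c[t] = rho * c[t - 1] + innov * eps_c[t - 1]
            drive = effect_size * c[t - 1] if causal else 0.0
            e[t] = 0.5 * e[t - 1] + drive + eps_e[t - 1]
        for t, yr in enumerate(years):
            records.append(
                {"country": cname, "year": yr, "CAUSE": c[t], "EFFECT": e[t]}
            )
    return PanelDataset(pd.DataFrame.from_records(records))
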