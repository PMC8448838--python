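"""Validation: growth-curve models, exponential fits and Pearson agreement.

Three closed-form models describe the expected temporal features of
vascularized tumor growth over the 30-day window (time in hours):

* total cancer-cell count, Gompertz:  n(t) = n₀·exp[(α_n/β_n)(1 − e^{−β_n t})]
  with (n₀, α_n, β_n) = (10⁶, 0.09, 0.01);
* mean microvascular length, logistic:  g(t) = g₀ + α_g/(1 + e^{−(t−t_½)/β_g})
  with (g₀, α_g, β_g, t_½) = (0, 58.5³, 62, 360);
* branch-point count, exponential:  b(t) = b₀ + α_b·e^{β_b t} with
  (b₀, α_b, β_b) = (0, 0.05, 16).

The printed branch-model shape parameter overflows when evaluated in hours
over the window, so the default validation path estimates (b₀, α_b, β_b)
from the simulated series by least squares and reports the agreement of the
fitted exponential form.  Tumor doubling time comes from a log-linear
least-squares fit; agreement between simulated and model series is the
squared Pearson correlation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import ConvexHull, QhullError

from .params import NECROSIS

#: printed growth-model parameters (time in hours)
GOMPERTZ_DEFAULTS = {"n0": 1e6, "alpha": 0.09, "beta": 0.01}
LOGISTIC_DEFAULTS = {"g0": 0.0, "alpha": 58.5**3, "beta": 62.0, "t_half": 360.0}
BRANCH_DEFAULTS = {"b0": 0.0, "alpha": 0.05, "beta": 16.0}


@dataclasses.dataclass
class GrowthModelParams:
    n0: float = GOMPERTZ_DEFAULTS["n0"]
    alpha_n: float = GOMPERTZ_DEFAULTS["alpha"]
    beta_n: float = GOMPERTZ_DEFAULTS["beta"]
    g0: float = LOGISTIC_DEFAULTS["g0"]
    alpha_g: float = LOGISTIC_DEFAULTS["alpha"]
    beta_g: float = LOGISTIC_DEFAULTS["beta"]
    t_half: float = LOGISTIC_DEFAULTS["t_half"]
    b0: float = BRANCH_DEFAULTS["b0"]
    alpha_b: float = BRANCH_DEFAULTS["alpha"]
    beta_b: float = BRANCH_DEFAULTS["beta"]


def gompertz_count(t, p: GrowthModelParams = GrowthModelParams()):
    """Gompertz cell count n(t); saturates at n₀·e^{α_n/β_n}."""
    if p.beta_n == 0:
        raise ValueError("beta_n must be nonzero")
    t = np.asarray(t, dtype=float)
    return p.n0 * np.exp(p.alpha_n / p.beta_n * (1.0 - np.exp(-p.beta_n * t)))


def logistic_length(t, p: GrowthModelParams = GrowthModelParams()):
    """Logistic mean vessel length g(t) with inflection at t_half."""
    if p.beta_g == 0:
        raise ValueError("beta_g must be nonzero")
    t = np.asarray(t, dtype=float)
    return p.g0 + p.alpha_g / (1.0 + np.exp(-(t - p.t_half) / p.beta_g))


def exp_branches(t, p: GrowthModelParams = GrowthModelParams()):
    """Branch count b(t) = b₀ + α_b·e^{β_b t}, evaluated literally."""
    t = np.asarray(t, dtype=float)
    if p.alpha_b == 0.0:
        return p.b0 + np.zeros_like(t)
    with np.errstate(over="raise"):
        try:
            return p.b0 + p.alpha_b * np.exp(p.beta_b * t)
        except FloatingPointError as err:
            raise OverflowError(
                "exp_branches overflows with these parameters over this time "
                "range; use fit_exp_branches to estimate them from a series"
            ) from err


def fit_exp_branches(t, b) -> tuple[GrowthModelParams, np.ndarray]:
    """Least-squares fit of (b₀, α_b, β_b) to a branch-count series.

    Returns the fitted parameters (only the branch triple is meaningful)
    and the fitted curve.  Initialized from a log-linear fit of the
    positive increments so near-affine series are handled gracefully.
    """
    t = np.asarray(t, dtype=float)
    b = np.asarray(b, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points")
    span = b.max() - b.min()
    if span == 0:
        p = GrowthModelParams(b0=float(b[0]), alpha_b=0.0, beta_b=0.0)
        return p, np.full_like(t, b[0])
    beta0 = 1.0 / max(t.max() - t.min(), 1.0)
    alpha0 = span / max(np.exp(beta0 * t.max()) - np.exp(beta0 * t.min()), 1e-12)
    p0 = [float(b.min()) - alpha0 * np.exp(beta0 * t.min()) + 0.0, alpha0, beta0]

    def f(tt, b0, a, k):
        return b0 + a * np.exp(np.clip(k * tt, -700, 700))

    popt, _ = optimize.curve_fit(f, t, b, p0=p0, maxfev=20000)
    p = GrowthModelParams(b0=float(popt[0]), alpha_b=float(popt[1]),
                          beta_b=float(popt[2]))
    return p, f(t, *popt)


def fit_exponential(t, n) -> dict:
    """Log-linear least-squares fit of an exponential growth series.

    Returns the rate k (per hour), the doubling time in hours and days
    (``None`` for non-growing series), and the R² of the fit of log n on t.
    """
    t = np.asarray(t, dtype=float)
    n = np.asarray(n, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 points")
    if np.any(n <= 0):
        raise ValueError("exponential fit requires strictly positive counts")
    logn = np.log(n)
    k, intercept = np.polyfit(t, logn, 1)
    pred = k * t + intercept
    ss_res = float(((logn - pred) ** 2).sum())
    ss_tot = float(((logn - logn.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    doubling_h = float(np.log(2) / k) if k > 0 else None
    return {
        "rate_per_h": float(k),
        "n0": float(np.exp(intercept)),
        "doubling_h": doubling_h,
        "doubling_d": doubling_h / 24.0 if doubling_h is not None else None,
        "r2": float(r2),
    }


def pearson_r2(x, y) -> tuple[float, float]:
    """Squared Pearson correlation and its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length series of at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation is undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r * r), float(p)


# -- time-series extraction ---------------------------------------------------

SERIES_COLUMNS = [
    "episode", "n_cells", "n_viable", "n_proliferation", "n_migration",
    "n_quiescence", "n_hypoxia", "n_necrosis", "total_vessel_um",
    "mean_vessel_um", "n_vessel_paths", "branch_points", "tumor_area_cm2",
    "vessel_density_um_per_cm2",
]


@dataclasses.dataclass
class ValidationSeries:
    """Per-episode observables extracted from a simulation run."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SERIES_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"series missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def t_hours(self) -> np.ndarray:
        return self.frame["episode"].to_numpy(dtype=float)


def census_row(episode: int, grid, vessels) -> dict:
    """One census record of the current world state."""
    pop = grid.cells
    counts = np.zeros(5, dtype=int)
    if pop is not None and pop.n > 0:
        counts = np.bincount(pop.phen[: pop.n], minlength=5)
    area = tumor_area_cm2(grid)
    total_um = vessels.total_length_um if vessels is not None else 0.0
    return {
        "episode": episode,
        "n_cells": int(counts.sum()),
        "n_viable": int(counts.sum() - counts[NECROSIS]),
        "n_proliferation": int(counts[0]),
        "n_migration": int(counts[1]),
        "n_quiescence": int(counts[2]),
        "n_hypoxia": int(counts[3]),
        "n_necrosis": int(counts[4]),
        "total_vessel_um": float(total_um),
        "mean_vessel_um": float(vessels.mean_path_length_um()) if vessels else 0.0,
        "n_vessel_paths": int(vessels.n_paths) if vessels else 0,
        "branch_points": int(vessels.n_branch_points) if vessels else 0,
        "tumor_area_cm2": float(area),
        "vessel_density_um_per_cm2": float(total_um / area) if area > 0 else 0.0,
    }


def tumor_area_cm2(grid) -> float:
    """Convex-hull area (cm²) of the TMEs holding at least one viable cell."""
    pop = grid.cells
    if pop is None or pop.n == 0:
        return 0.0
    viable = pop.phen[: pop.n] != NECROSIS
    if not viable.any():
        return 0.0
    sites = np.unique(pop.tme[: pop.n][viable])
    a_site = grid.config.tme_area_cm2
    if sites.size < 3:
        return float(sites.size * a_site)
    rows, cols = np.divmod(sites, grid.n)
    pts = np.column_stack([cols, rows]).astype(float)
    try:
        hull = ConvexHull(pts)
        hull_sites = hull.volume  # 2-D: area, in TME units
    except QhullError:  # collinear sites
        return float(sites.size * a_site)
    return float(max(hull_sites, sites.size) * a_site)


def extract_series(history: list[dict] | pd.DataFrame) -> ValidationSeries:
    """Assemble the per-episode census into a :class:`ValidationSeries`."""
    frame = pd.DataFrame(history) if not isinstance(history, pd.DataFrame) else history
    if len(frame) == 0:
        frame = pd.DataFrame(columns=SERIES_COLUMNS)
    return ValidationSeries(frame[SERIES_COLUMNS].reset_index(drop=True))


def validation_report(series: ValidationSeries,
                      initial_cells: float | None = None) -> dict:
    """Doubling time plus per-model Pearson R² for one simulated run.

    The Gompertz model is rescaled to the run's initial cell count (its
    printed n₀ refers to the full-scale configuration); the logistic and
    (fitted) exponential branch models are compared as printed.
    """
    f = series.frame
    t = series.t_hours
    out: dict = {}
    n = f["n_cells"].to_numpy(dtype=float)
    if (n > 0).all() and len(f) >= 3:
        out["exponential_fit"] = fit_exponential(t, n)
        if np.ptp(n) > 0:
            p = GrowthModelParams(n0=initial_cells if initial_cells else n[0])
            model_n = gompertz_count(t, p)
            out["gompertz_r2"], out["gompertz_p"] = pearson_r2(n, model_n)
    g = f["mean_vessel_um"].to_numpy(dtype=float)
    if len(f) >= 3 and np.ptp(g) > 0:
        model_g = logistic_length(t)
        out["logistic_r2"], out["logistic_p"] = pearson_r2(g, model_g)
    b = f["branch_points"].to_numpy(dtype=float)
    if len(f) >= 3 and np.ptp(b) > 0:
        _, fitted = fit_exp_branches(t, b)
        if np.ptp(fitted) > 0:
            out["branch_r2"], out["branch_p"] = pearson_r2(b, fitted)
    return out
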