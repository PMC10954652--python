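"""Synthetic inputs with known ground truth for every pipeline stage.

Generates paired categorical landscapes whose cell-level transitions
follow a prescribed stochastic matrix, Likert-style expert survey
responses, zero-inflated plot counts, scheme agreement matrices, and
seasonal observation stacks with a linear trend — each alongside the
ground truth it realizes, so downstream estimators can be checked against
known answers. Cells are spatially independent (the downstream accounting
is purely area-based) and zones are contiguous column blocks, mimicking
counties without modelling geography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .change import ClassScheme, LandcoverGrid, TransitionMatrix
from .resources import ADMISSIBLE_SCORES

__all__ = [
    "LandscapeSpec",
    "SeriesSpec",
    "gen_landscape_pair",
    "gen_survey",
    "gen_plot_samples",
    "gen_seasonal_stack",
    "gen_agreement_matrix",
]


@dataclass(frozen=True)
class LandscapeSpec:
    scheme: ClassScheme
    shape: tuple[int, int] = (100, 100)
    mixing: tuple[float, ...] = ()
    transition: tuple[tuple[float, ...], ...] = ()
    cell_area: float = 0.0009  # 30 m cells, km²
    n_zones: int = 1
    start_year: int = 2000
    end_year: int = 2020

    def __post_init__(self) -> None:
        k = len(self.scheme.class_ids)
        mix = np.asarray(self.mixing if self.mixing else [1.0 / k] * k, dtype=float)
        P = np.asarray(self.transition if self.transition else np.eye(k), dtype=float)
        if len(mix) != k or not np.isclose(mix.sum(), 1.0):
            raise ValueError("mixing proportions must cover all classes and sum to 1")
        if P.shape != (k, k) or (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be a k×k row-stochastic matrix")
        object.__setattr__(self, "mixing", tuple(mix))
        object.__setattr__(self, "transition", tuple(map(tuple, P)))


@dataclass(frozen=True)
class SeriesSpec:
    n_years: int = 25
    start_year: int = 1997
    slope: float = 0.0
    intercept: float = 0.5
    noise_sd: float = 0.01
    obs_per_season: int = 11
    season: str = "fall"
    shape: tuple[int, int] = (4, 4)
    pixel_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("need at least 3 years")
        if self.noise_sd < 0 or self.pixel_sd < 0:
            raise ValueError("noise sd must be nonnegative")


def gen_landscape_pair(
    spec: LandscapeSpec, seed: int = 0
) -> tuple[LandcoverGrid, LandcoverGrid, TransitionMatrix]:
    """Simulate a two-date landscape with known transition areas.

    Start-date cells are iid draws from the mixing proportions; each cell
    then moves to its end-date class by one step of the prescribed
    stochastic matrix. The realized (not expected) transition areas are
    returned as ground truth.
    """
    rng = np.random.default_rng(seed)
    ids = np.array(spec.scheme.class_ids)
    k = len(ids)
    P = np.asarray(spec.transition)
    n = spec.shape[0] * spec.shape[1]
    i0 = rng.choice(k, size=n, p=np.asarray(spec.mixing))
    # vectorized one-step Markov transition via per-row inverse CDF
    cdf = P.cumsum(axis=1)
    u = rng.random(n)
    i1 = (u[:, None] > cdf[i0]).sum(axis=1)
    counts = np.bincount(i0 * k + i1, minlength=k * k).reshape(k, k)
    truth = TransitionMatrix(
        pd.DataFrame(counts * spec.cell_area, index=ids, columns=ids, dtype=float),
        spec.start_year, spec.end_year, spec.scheme.labels)
    zones = None
    if spec.n_zones > 1:
        cols = np.minimum(
            np.arange(spec.shape[1]) * spec.n_zones // spec.shape[1],
            spec.n_zones - 1)
        zones = np.broadcast_to(cols, spec.shape).copy()
    g0 = LandcoverGrid(ids[i0].reshape(spec.shape), spec.cell_area, spec.scheme, zones)
    g1 = LandcoverGrid(ids[i1].reshape(spec.shape), spec.cell_area, spec.scheme, zones)
    return g0, g1, truth


def gen_survey(
    true_means: dict,
    n_respondents: int = 30,
    dispersion: float = 0.15,
    season: str = "spring",
    resource: str = "nectar",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate rating-scale responses around per-class true means.

    Each response is the admissible level nearest to truth + normal noise,
    so outputs always lie on the 5-level scale.
    """
    rng = np.random.default_rng(seed)
    levels = np.array(ADMISSIBLE_SCORES)
    rows = []
    for class_id, mu in true_means.items():
        if not 0.0 <= mu <= 1.0:
            raise ValueError("true means must lie in [0, 1]")
        raw = mu + rng.normal(0.0, dispersion, n_respondents)
        scores = levels[np.abs(raw[:, None] - levels).argmin(axis=1)]
        for r, s in enumerate(scores):
            rows.append({"respondent_id": f"r{r:03d}", "season": season,
                         "resource": resource, "class_id": class_id,
                         "score": float(s)})
    return pd.DataFrame(rows)


def gen_plot_samples(
    class_specs: dict,
    n_per_class: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate zero-inflated plot densities per class.

    ``class_specs`` maps class_id → (pi_zero, count_params) where
    count_params is {"lam": …} for Poisson counts or {"mu": …, "alpha": …}
    for negative-binomial counts of the non-zero component.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for class_id, (pi_zero, params) in class_specs.items():
        if not 0.0 <= pi_zero <= 1.0:
            raise ValueError("pi_zero must lie in [0, 1]")
        nz = rng.random(n_per_class) >= pi_zero
        dens = np.zeros(n_per_class)
        if "lam" in params:
            dens[nz] = rng.poisson(params["lam"], nz.sum())
        else:
            n = 1.0 / params["alpha"]
            dens[nz] = rng.negative_binomial(n, n / (n + params["mu"]), nz.sum())
        for s, d in enumerate(dens):
            rows.append({"sample_id": f"{class_id}-{s:04d}", "class_id": class_id,
                         "density": float(d), "year": 2015, "source": "synthetic",
                         "quality_flag": "include"})
    return pd.DataFrame(rows)


def gen_seasonal_stack(
    spec: SeriesSpec, seed: int = 0
) -> tuple[list[tuple[pd.Timestamp, np.ndarray]], pd.Series]:
    """Simulate a multi-year within-season observation stack.

    Every observation lattice sits around that year's true value
    (intercept + slope·year) with observation noise ``noise_sd`` and
    optional per-pixel noise. Returns the stack and the true yearly
    series (the noiseless line).
    """
    rng = np.random.default_rng(seed)
    from .trends import SEASON_MONTHS

    months = SEASON_MONTHS[spec.season]
    years = np.arange(spec.start_year, spec.start_year + spec.n_years)
    truth = pd.Series(spec.intercept + spec.slope * years, index=years,
                      name=spec.season)
    stack = []
    days = np.linspace(1, 28, max(spec.obs_per_season // len(months), 1)).astype(int)
    for y in years:
        dates = [pd.Timestamp(int(y), m, int(d)) for m in months for d in days]
        dates = dates[: spec.obs_per_season]
        for ts in dates:
            base = truth.loc[y] + rng.normal(0.0, spec.noise_sd)
            layer = np.full(spec.shape, base)
            if spec.pixel_sd > 0:
                layer = layer + rng.normal(0.0, spec.pixel_sd, spec.shape)
            stack.append((ts, layer))
    return stack, truth


def gen_agreement_matrix(
    n_target: int,
    n_source: int,
    concentration: float = 10.0,
    seed: int = 0,
    target_ids: list | None = None,
    source_ids: list | None = None,
) -> pd.DataFrame:
    """Random scheme-agreement matrix with rows on the simplex.

    Each target class gets a preferred source class (cycled); its row is a
    Dirichlet draw with extra weight ``concentration`` on that source, so
    large concentrations approach one-hot (permutation-like) rows and
    concentration 0 gives a flat Dirichlet.
    """
    if n_target < 1 or n_source < 1:
        raise ValueError("dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_target):
        alpha = np.ones(n_source)
        alpha[t % n_source] += concentration
        rows.append(rng.dirichlet(alpha))
    return pd.DataFrame(
        np.array(rows),
        index=target_ids if target_ids is not None else list(range(n_target)),
        columns=source_ids if source_ids is not None else list(range(n_source)))
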