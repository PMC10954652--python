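"""Per-class habitat-resource distributions.

Builds, for every land-cover class and season, a probability distribution
of resource value — either a unitless 0–1 nectar/milkweed suitability
score elicited from experts on a 5-level rating scale, or a milkweed
density in plants per hectare fitted to field plot counts. Includes the
crosswalk that translates scores between classification schemes via
agreement matrices, crop-composition weighting for a single cropland
class, zero-inflated count fitting with information-criterion model
selection, and the special-case rules for data-sparse classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ADMISSIBLE_SCORES",
    "ResourceDistribution",
    "CountFit",
    "aggregate_survey",
    "crosswalk_distributions",
    "crop_weighted_value",
    "fit_count_distribution",
    "apply_special_rules",
    "sample_value",
    "registry_to_frame",
    "registry_from_frame",
    "normal_registry",
]

# the 5 admissible rating-scale levels experts may assign
ADMISSIBLE_SCORES = (0.10, 0.25, 0.50, 0.75, 0.95)

_FAMILIES = {
    "normal", "beta", "exponential", "negative_binomial",
    "zero_inflated_poisson", "zero_inflated_negative_binomial",
    "zero_inflated_bernoulli", "point_mass",
}


def _moments(family: str, params: dict) -> tuple[float, float]:
    """Closed-form mean and SD for each supported family."""
    if family == "point_mass":
        return params["value"], 0.0
    if family == "normal":
        return params["mean"], params["sd"]
    if family == "beta":
        a, b = params["a"], params["b"]
        m = a / (a + b)
        v = a * b / ((a + b) ** 2 * (a + b + 1.0))
        return m, math.sqrt(v)
    if family == "exponential":
        return params["scale"], params["scale"]
    if family == "negative_binomial":
        mu, alpha = params["mu"], params["alpha"]
        return mu, math.sqrt(mu + alpha * mu * mu)
    if family == "zero_inflated_poisson":
        pi, lam = params["pi"], params["lam"]
        m = (1.0 - pi) * lam
        v = (1.0 - pi) * lam * (1.0 + pi * lam)
        return m, math.sqrt(v)
    if family == "zero_inflated_negative_binomial":
        pi, mu, alpha = params["pi"], params["mu"], params["alpha"]
        m = (1.0 - pi) * mu
        v = (1.0 - pi) * (mu + alpha * mu * mu) + pi * (1.0 - pi) * mu * mu
        return m, math.sqrt(v)
    if family == "zero_inflated_bernoulli":
        p = (1.0 - params["pi"]) * params["p"]
        return p, math.sqrt(p * (1.0 - p))
    raise ValueError(f"unknown family {family!r}")


@dataclass(frozen=True)
class ResourceDistribution:
    """A per-class, per-season resource-value distribution.

    ``units`` is ``"score"`` for the unitless 0–1 suitability index and
    ``"plants_per_ha"`` for milkweed densities. ``mean`` and ``sd`` are
    the distribution's closed-form moments, kept alongside the family
    parameters so moment-based (expectation) and draw-based (Monte Carlo)
    consumers agree.
    """

    class_id: object
    season: str
    resource: str
    family: str
    params: dict
    units: str = "score"
    mean: float = field(default=None)  # type: ignore[assignment]
    sd: float = field(default=None)  # type: ignore[assignment]
    notes: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        m, s = _moments(self.family, self.params)
        if self.mean is None:
            object.__setattr__(self, "mean", m)
        if self.sd is None:
            object.__setattr__(self, "sd", s)

    def sample(self, rng: np.random.Generator, size: int = 1,
               truncation: str = "clip") -> np.ndarray:
        return sample_value(self, rng, size=size, truncation=truncation)


def point_mass(class_id, season, resource, value=0.0, units="score", notes="") -> ResourceDistribution:
    return ResourceDistribution(class_id, season, resource, "point_mass",
                                {"value": float(value)}, units=units, notes=notes)


# ---------------------------------------------------------------------------
# survey aggregation and scheme crosswalk

def aggregate_survey(responses: pd.DataFrame, class_id, season: str,
                     resource: str) -> ResourceDistribution:
    """Aggregate expert rating-scale responses for one class/season/resource.

    Responses are treated as approximately normal across respondents (as
    the elicitation data were): the distribution is a normal with the
    sample mean and the n−1 sample SD. Requires at least two respondents.
    """
    sub = responses[(responses["class_id"] == class_id)
                    & (responses["season"] == season)
                    & (responses["resource"] == resource)]
    if sub["respondent_id"].duplicated().any():
        raise ValueError("duplicate respondent for one class/season/resource cell")
    bad = ~np.isclose(sub["score"].values[:, None], np.array(ADMISSIBLE_SCORES)).any(axis=1)
    if bad.any():
        raise ValueError(f"scores outside the admissible levels: "
                         f"{sorted(set(sub['score'].values[bad]))}")
    if len(sub) < 2:
        raise ValueError("need >= 2 respondents to estimate an SD")
    return ResourceDistribution(
        class_id, season, resource, "normal",
        {"mean": float(sub["score"].mean()), "sd": float(sub["score"].std(ddof=1))},
        units="score", notes=f"n={len(sub)} respondents")


def crosswalk_distributions(
    source_dists: dict,
    agreement: pd.DataFrame,
    season: str,
    resource: str,
    sd_mode: str = "weighted_sd",
) -> dict:
    """Translate per-source-class normal scores to a target scheme.

    ``agreement.loc[target, source]`` is the fraction of the target class's
    area composed of each source class; each target row must sum to 1.
    The target distribution is normal with mean ``Σ p·mean_s`` and, under
    the default ``sd_mode="weighted_sd"``, SD ``Σ p·sd_s`` (a weighted
    average of SDs). ``sd_mode="pooled"`` instead pools the mixture
    variance, ``sqrt(Σ p·(sd² + mean²) − mean_target²)``.
    """
    if sd_mode not in ("weighted_sd", "pooled"):
        raise ValueError("sd_mode must be 'weighted_sd' or 'pooled'")
    rowsum = agreement.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-9):
        raise ValueError(f"agreement rows must sum to 1; got {rowsum.to_dict()}")
    if (agreement.values < -1e-12).any() or (agreement.values > 1 + 1e-12).any():
        raise ValueError("agreement proportions must lie in [0, 1]")
    out = {}
    for target in agreement.index:
        p = agreement.loc[target]
        active = p[p > 0]
        missing = [s for s in active.index if s not in source_dists]
        if missing:
            raise ValueError(f"no source distribution for {missing}")
        means = np.array([source_dists[s].mean for s in active.index])
        sds = np.array([source_dists[s].sd for s in active.index])
        w = active.values
        m = float(w @ means)
        if sd_mode == "weighted_sd":
            s = float(w @ sds)
        else:
            s = float(math.sqrt(max(w @ (sds**2 + means**2) - m * m, 0.0)))
        out[target] = ResourceDistribution(
            target, season, resource, "normal", {"mean": m, "sd": s},
            units="score", notes=f"crosswalk({sd_mode})")
    return out


def crop_weighted_value(
    crop_values: pd.DataFrame,
    exclude: tuple[str, ...] = (),
    value_col: str = "mean",
    sd_col: str = "sd",
    share_col: str = "share",
) -> tuple[float, float]:
    """Collapse per-crop-type seasonal values into one cropland-class value.

    Shares are renormalized over the crops kept after exclusions (e.g. a
    grass/sod category that cannot be attributed cleanly); the result is
    the share-weighted mean and share-weighted-mean SD.
    """
    kept = crop_values[~crop_values["crop"].isin(exclude)]
    if kept.empty:
        raise ValueError("no crops left after exclusions")
    w = kept[share_col].to_numpy(dtype=float)
    if w.sum() <= 0:
        raise ValueError("crop shares sum to zero")
    w = w / w.sum()
    return float(w @ kept[value_col].to_numpy()), float(w @ kept[sd_col].to_numpy())


# ---------------------------------------------------------------------------
# count-distribution fitting

def _ll_exponential(x: np.ndarray, scale: float) -> float:
    return float(stats.expon.logpdf(x, scale=scale).sum())


def _ll_nb(k: np.ndarray, mu: float, alpha: float) -> float:
    n = 1.0 / alpha
    p = n / (n + mu)
    return float(stats.nbinom.logpmf(k, n, p).sum())


def _ll_zip(k: np.ndarray, pi: float, lam: float) -> float:
    zero = k == 0
    ll = np.empty(len(k))
    ll[zero] = np.log(pi + (1.0 - pi) * math.exp(-lam))
    ll[~zero] = math.log1p(-pi) + stats.poisson.logpmf(k[~zero], lam)
    return float(ll.sum())


def _ll_zinb(k: np.ndarray, pi: float, mu: float, alpha: float) -> float:
    n = 1.0 / alpha
    p = n / (n + mu)
    zero = k == 0
    ll = np.empty(len(k))
    ll[zero] = np.log(pi + (1.0 - pi) * math.exp(n * math.log(p)))
    ll[~zero] = math.log1p(-pi) + stats.nbinom.logpmf(k[~zero], n, p)
    return float(ll.sum())


def _ll_zibern(b: np.ndarray, q: float) -> float:
    # presence probability q = (1-pi)*p; pi and p are not separately
    # identifiable from presence data, so fit the compound probability
    return float(stats.bernoulli.logpmf(b, q).sum())


def _fit_zip(k: np.ndarray) -> dict:
    def nll(theta):
        pi = 1.0 / (1.0 + math.exp(-theta[0]))
        lam = math.exp(theta[1])
        return -_ll_zip(k, pi, lam)

    mean_pos = k[k > 0].mean() if (k > 0).any() else 1.0
    res = optimize.minimize(nll, x0=[0.0, math.log(mean_pos)], method="Nelder-Mead")
    pi = 1.0 / (1.0 + math.exp(-res.x[0]))
    return {"pi": float(pi), "lam": float(math.exp(res.x[1])), "_ll": -float(res.fun)}


def _fit_nb(k: np.ndarray) -> dict:
    def nll(theta):
        return -_ll_nb(k, math.exp(theta[0]), math.exp(theta[1]))

    mu0 = max(k.mean(), 1e-3)
    var0 = max(k.var(), mu0 + 1e-3)
    alpha0 = max((var0 - mu0) / mu0**2, 1e-3)
    res = optimize.minimize(nll, x0=[math.log(mu0), math.log(alpha0)], method="Nelder-Mead")
    return {"mu": float(math.exp(res.x[0])), "alpha": float(math.exp(res.x[1])),
            "_ll": -float(res.fun)}


def _fit_zinb(k: np.ndarray) -> dict:
    def nll(theta):
        pi = 1.0 / (1.0 + math.exp(-theta[0]))
        return -_ll_zinb(k, pi, math.exp(theta[1]), math.exp(theta[2]))

    mean_pos = k[k > 0].mean() if (k > 0).any() else 1.0
    res = optimize.minimize(nll, x0=[0.0, math.log(mean_pos), 0.0], method="Nelder-Mead",
                            options={"maxiter": 2000})
    pi = 1.0 / (1.0 + math.exp(-res.x[0]))
    return {"pi": float(pi), "mu": float(math.exp(res.x[1])),
            "alpha": float(math.exp(res.x[2])), "_ll": -float(res.fun)}


@dataclass
class CountFit:
    """Result of fitting candidate count families to plot densities."""

    best: ResourceDistribution
    aic: dict[str, float]
    loglik: dict[str, float]
    params: dict[str, dict]
    zero_proportion: float
    n: int
    sparse: bool


DEFAULT_CANDIDATES = ("zero_inflated_bernoulli", "exponential",
                      "negative_binomial", "zero_inflated_poisson")


def fit_count_distribution(
    samples: pd.DataFrame,
    class_id=None,
    season: str = "spring",
    resource: str = "milkweed",
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
    min_samples: int = 20,
    density_col: str = "density",
) -> CountFit:
    """Fit candidate families to one class's plot densities, select by AIC.

    Densities (plants/ha, ≥ 0) are rounded to integer counts for the
    discrete candidates; the exponential is fitted to the raw values. The
    "zero-inflated Bernoulli" candidate models presence only (the compound
    presence probability is what the data identify). Ties in AIC break
    toward the family with fewer parameters. An all-zero class collapses to
    a point mass at zero, and fewer than ``min_samples`` included samples
    flags the fit as sparse so callers can defer to special-case rules.
    """
    if "quality_flag" in samples.columns:
        samples = samples[samples["quality_flag"].fillna("include") == "include"]
    if class_id is not None and "class_id" in samples.columns:
        samples = samples[samples["class_id"] == class_id]
    x = samples[density_col].to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative densities are not valid plot samples")
    n = len(x)
    sparse = n < min_samples
    zero_prop = float((x == 0).mean()) if n else 1.0
    if n == 0 or (x == 0).all():
        return CountFit(point_mass(class_id, season, resource, 0.0,
                                   units="plants_per_ha", notes="all-zero; sparse"),
                        {}, {}, {}, zero_prop, n, True)

    k = np.round(x).astype(int)
    b = (x > 0).astype(int)
    npar = {"exponential": 1, "zero_inflated_bernoulli": 1,
            "negative_binomial": 2, "zero_inflated_poisson": 2,
            "zero_inflated_negative_binomial": 3}
    loglik, params = {}, {}
    for fam in candidates:
        if fam == "exponential":
            scale = float(x.mean())
            params[fam] = {"scale": scale}
            loglik[fam] = _ll_exponential(x, scale)
        elif fam == "zero_inflated_bernoulli":
            q = float(b.mean())
            params[fam] = {"pi": 1.0 - q, "p": 1.0}
            # a presence/absence model assigns zero probability to counts
            # above 1, so it only competes when the data are presence-like
            loglik[fam] = _ll_zibern(b, q) if (k <= 1).all() else -np.inf
        elif fam == "negative_binomial":
            fit = _fit_nb(k)
            loglik[fam] = fit.pop("_ll")
            params[fam] = fit
        elif fam == "zero_inflated_poisson":
            fit = _fit_zip(k)
            loglik[fam] = fit.pop("_ll")
            params[fam] = fit
        elif fam == "zero_inflated_negative_binomial":
            fit = _fit_zinb(k)
            loglik[fam] = fit.pop("_ll")
            params[fam] = fit
        else:
            raise ValueError(f"unknown candidate family {fam!r}")
    aic = {fam: 2.0 * npar[fam] - 2.0 * ll for fam, ll in loglik.items()}
    best_fam = min(aic, key=lambda f: (round(aic[f], 9), npar[f]))
    best = ResourceDistribution(class_id, season, resource, best_fam,
                                params[best_fam], units="plants_per_ha",
                                notes=f"AIC-selected, n={n}" + (", sparse" if sparse else ""))
    return CountFit(best, aic, loglik, params, zero_prop, n, sparse)


# ---------------------------------------------------------------------------
# special-case rules

def apply_special_rules(
    dists: dict,
    zero_classes: tuple = (),
    midpoint_rules: dict | None = None,
) -> dict:
    """Apply data-sparsity overrides to a per-class distribution set.

    ``zero_classes`` are set to a point mass at zero (classes with no
    resource observed, e.g. open water). ``midpoint_rules`` maps a target
    class to its two neighbour classes: the target takes the neighbours'
    common family with every parameter at the midpoint of the two fits.
    When the neighbour fits disagree in family, the target falls back to a
    normal at the moment midpoint (flagged in its notes).
    """
    out = dict(dists)
    proto = next(iter(dists.values())) if dists else None
    season = proto.season if proto else "spring"
    resource = proto.resource if proto else "milkweed"
    units = proto.units if proto else "score"
    for c in zero_classes:
        prev = out.get(c)
        out[c] = point_mass(c, prev.season if prev else season,
                            prev.resource if prev else resource, 0.0,
                            units=prev.units if prev else units,
                            notes="set to zero: no resource observed in samples")
    for target, (lo, hi) in (midpoint_rules or {}).items():
        if lo not in out or hi not in out:
            raise ValueError(f"midpoint rule for {target!r} needs both {lo!r} and {hi!r}")
        dlo, dhi = out[lo], out[hi]
        if dlo.family == dhi.family:
            params = {k: 0.5 * (dlo.params[k] + dhi.params[k]) for k in dlo.params}
            out[target] = ResourceDistribution(
                target, dlo.season, dlo.resource, dlo.family, params,
                units=dlo.units, notes=f"parameter midpoint of {lo!r} and {hi!r}")
        else:
            out[target] = ResourceDistribution(
                target, dlo.season, dlo.resource, "normal",
                {"mean": 0.5 * (dlo.mean + dhi.mean), "sd": 0.5 * (dlo.sd + dhi.sd)},
                units=dlo.units,
                notes=f"moment midpoint of {lo!r} ({dlo.family}) and {hi!r} ({dhi.family})")
    return out


# ---------------------------------------------------------------------------
# sampling

def sample_value(dist: ResourceDistribution, rng: np.random.Generator,
                 size: int = 1, truncation: str = "clip") -> np.ndarray:
    """Draw from a resource distribution with a bounded-support policy.

    ``truncation="clip"`` (default) clips score draws to [0, 1] and density
    draws to ≥ 0; ``"reject"`` redraws out-of-range values instead (same
    bounds, renormalized distribution); ``"none"`` returns raw draws. Count
    families have nonnegative support, so the policy only matters for the
    normal family.
    """
    if truncation not in ("clip", "reject", "none"):
        raise ValueError(f"unknown truncation policy {truncation!r}")
    f, p = dist.family, dist.params
    if f == "point_mass":
        return np.full(size, p["value"], dtype=float)
    if f == "normal":
        x = rng.normal(p["mean"], p["sd"], size)
        lo, hi = (0.0, 1.0) if dist.units == "score" else (0.0, np.inf)
        if truncation == "clip":
            return np.clip(x, lo, hi)
        if truncation == "reject":
            if p["sd"] == 0:
                return np.clip(x, lo, hi)
            a = (lo - p["mean"]) / p["sd"]
            b = (hi - p["mean"]) / p["sd"]
            return stats.truncnorm.rvs(a, b, loc=p["mean"], scale=p["sd"],
                                       size=size, random_state=rng)
        return x
    if f == "beta":
        return rng.beta(p["a"], p["b"], size)
    if f == "exponential":
        return rng.exponential(p["scale"], size)
    if f == "negative_binomial":
        n = 1.0 / p["alpha"]
        return rng.negative_binomial(n, n / (n + p["mu"]), size).astype(float)
    if f == "zero_inflated_poisson":
        nz = rng.random(size) >= p["pi"]
        out = np.zeros(size)
        out[nz] = rng.poisson(p["lam"], nz.sum())
        return out
    if f == "zero_inflated_negative_binomial":
        nz = rng.random(size) >= p["pi"]
        out = np.zeros(size)
        n = 1.0 / p["alpha"]
        out[nz] = rng.negative_binomial(n, n / (n + p["mu"]), nz.sum())
        return out
    if f == "zero_inflated_bernoulli":
        return ((rng.random(size) >= p["pi"])
                & (rng.random(size) < p["p"])).astype(float)
    raise ValueError(f"unknown family {f!r}")


# ---------------------------------------------------------------------------
# registry I/O

def registry_to_frame(dists: dict) -> pd.DataFrame:
    """Serialize a per-class distribution set to a tidy registry table."""
    import json

    rows = [{"class_id": d.class_id, "season": d.season, "resource": d.resource,
             "family": d.family, "params": json.dumps(d.params), "mean": d.mean,
             "sd": d.sd, "units": d.units, "notes": d.notes}
            for d in dists.values()]
    return pd.DataFrame(rows)


def registry_from_frame(frame: pd.DataFrame) -> dict:
    import json

    out = {}
    for _, r in frame.iterrows():
        out[r["class_id"]] = ResourceDistribution(
            r["class_id"], r["season"], r["resource"], r["family"],
            json.loads(r["params"]), units=r["units"], notes=r.get("notes", ""))
    return out


def normal_registry(table: pd.DataFrame, season: str, resource: str,
                    mean_col: str, sd_col: str, units: str = "score") -> dict:
    """Build normal (or point-mass-at-zero) distributions from a moment table.

    Used to reconstruct published per-class mean/SD summaries: rows whose
    mean and SD are both zero become point masses.
    """
    out = {}
    for _, r in table.iterrows():
        c = r["class"]
        if r[mean_col] == 0 and r[sd_col] == 0:
            out[c] = point_mass(c, season, resource, 0.0, units=units)
        else:
            out[c] = ResourceDistribution(
                c, season, resource, "normal",
                {"mean": float(r[mean_col]), "sd": float(r[sd_col])}, units=units)
    return out
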