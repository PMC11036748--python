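"""Relative selection strength (RSS) and used-habitat calibration (UHC).

RSS turns fitted step-selection coefficients into effect sizes: the log-RSS
for location x1 over x2 is the coefficient contrast ``beta' (x1 - x2)``, and
its exp is the relative probability of selecting x1 over x2.  Curves are
traced across the hormone range (the 0.2–0.8 population quantiles of FGM,
about 1,200–2,600 µg·g⁻¹) with parametric-bootstrap confidence ribbons drawn
from MVN(beta_hat, vcov).

UHC validates a fitted model by simulation: repeatedly draw coefficients
from their sampling distribution, sample one "predicted used" step per
held-out stratum with weights exp(beta' x), and compare the density of a
covariate at those predicted points against its density at the actually
observed used points.  A well-calibrated model keeps the observed density
inside the simulation envelope; a covariate wrongly omitted from the model
shows up as an envelope violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .issa import DEFAULT_TERMS, SsfFit, fit_ssf


def model_x(
    dist: float,
    fgm_z: float = 0.0,
    period: int = 0,
    days: float = 0.0,
    terms: list[str] | None = None,
) -> np.ndarray:
    """Covariate vector of the hormone-interaction model at one location.

    ``dist`` is distance to cover in 100-m units (so 200 m from cover = 2).
    """
    vals = {
        "dist_end": dist,
        "dist_fgm": dist * fgm_z,
        "dist_fgm_period": dist * fgm_z * period,
        "dist_fgm_days": dist * fgm_z * days,
        "log_length": 0.0,
        "cos_turn": 0.0,
    }
    return np.array([vals[t] for t in (terms or DEFAULT_TERMS)])


def log_rss(fit: SsfFit, x1: np.ndarray, x2: np.ndarray) -> float:
    """log relative selection strength for x1 over x2: beta' (x1 - x2)."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if x1.shape != (len(fit.coef),) or x2.shape != (len(fit.coef),):
        raise ValueError(
            f"covariate vectors must have length {len(fit.coef)} to match the fit"
        )
    return float(fit.coef @ (x1 - x2))


@dataclass
class RssQuery:
    """A location pair swept across an FGM grid.

    ``dist1``/``dist2`` are the distances to cover (100-m units) of the two
    locations; the hormone, period and days-since-calving covariates are
    shared by both (the contrast isolates the distance terms).
    """

    dist1: float = 2.0  # 200 m from cover
    dist2: float = 0.0  # within cover
    fgm_grid: np.ndarray = field(default_factory=lambda: np.linspace(-0.84, 0.84, 25))
    period: int = 0
    days: float = 0.0
    n_boot: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")


def rss_curve(fit: SsfFit, query: RssQuery) -> pd.DataFrame:
    """Log-RSS across the FGM grid with a percentile parametric bootstrap CI.

    Columns: fgm_z, log_rss, ci_low, ci_high.  Coefficient draws come from
    MVN(beta_hat, vcov); a non-PSD vcov is repaired to its nearest PSD
    matrix (eigenvalue clipping) with a warning.
    """
    vcov = np.asarray(fit.vcov, float)
    w, v = np.linalg.eigh(0.5 * (vcov + vcov.T))
    if w.min() < -1e-10 * max(w.max(), 1e-300):
        import warnings

        warnings.warn("vcov not positive semi-definite; clipping eigenvalues")
    w = np.clip(w, 0, None)
    root = v * np.sqrt(w)

    rng = np.random.default_rng(query.seed)
    draws = fit.coef + rng.standard_normal((query.n_boot, len(fit.coef))) @ root.T

    rows = []
    for z in np.asarray(query.fgm_grid, float):
        dx = model_x(query.dist1, z, query.period, query.days, fit.terms) - model_x(
            query.dist2, z, query.period, query.days, fit.terms
        )
        vals = draws @ dx
        lo, hi = np.percentile(vals, [2.5, 97.5])
        rows.append(
            dict(fgm_z=z, log_rss=float(fit.coef @ dx), ci_low=lo, ci_high=hi)
        )
    return pd.DataFrame(rows)


def rss_period_panels(fit: SsfFit, query: RssQuery | None = None) -> dict[str, pd.DataFrame]:
    """The two standard comparison panels: pre vs post calving (days fixed
    at 0) and calf ages 0/30/60 days (period fixed post-calving)."""
    query = query or RssQuery()
    out = {}
    for label, period, days in [("pre", 0, 0.0), ("post", 1, 0.0)]:
        q = RssQuery(query.dist1, query.dist2, query.fgm_grid, period, days,
                     query.n_boot, query.seed)
        out[f"period:{label}"] = rss_curve(fit, q)
    for days in (0.0, 30.0, 60.0):
        q = RssQuery(query.dist1, query.dist2, query.fgm_grid, 1, days,
                     query.n_boot, query.seed)
        out[f"days:{days:g}"] = rss_curve(fit, q)
    return out


# ---------------------------------------------------------------------------
# used-habitat calibration
# ---------------------------------------------------------------------------

@dataclass
class UhcResult:
    covariate: str
    grid: np.ndarray
    observed: np.ndarray  # density at observed used points (test strata)
    available: np.ndarray  # density at available points
    env_low: np.ndarray
    env_high: np.ndarray
    sim_mean: np.ndarray
    coverage: float  # fraction of grid points with observed inside envelope


def _kde(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE (Silverman bandwidth) renormalized to integrate to 1 on
    the evaluation grid."""
    values = np.asarray(values, float)
    if values.std() < 1e-12:  # degenerate: represent as a narrow Gaussian
        bw = max(1e-3, 1e-3 * (grid[-1] - grid[0]))
        dens = stats.norm.pdf(grid, loc=values.mean(), scale=bw)
    else:
        dens = stats.gaussian_kde(values, bw_method="silverman")(grid)
    area = np.trapezoid(dens, grid)
    return dens / area


def uhc_validate(
    design: pd.DataFrame,
    model_terms: list[str] | None = None,
    eval_covariates: list[str] | None = None,
    split: float = 0.5,
    n_sims: int = 1000,
    n_grid: int = 512,
    seed: int = 0,
) -> dict[str, UhcResult]:
    """Used-habitat calibration by train/test split.

    The design is split by bout (respecting stratum dependence), the model
    refitted on the training bouts, and for each of ``n_sims`` coefficient
    draws one predicted-used step is sampled per test stratum with weights
    ``exp(beta' x)``.  For every evaluation covariate (which may include
    terms *omitted* from the model) the observed-used density is compared
    with the pointwise 2.5–97.5% envelope of the predicted-used densities.
    """
    model_terms = list(model_terms or DEFAULT_TERMS)
    eval_covariates = list(eval_covariates or model_terms)
    rng = np.random.default_rng(seed)

    bout_ids = design["bout_id"].unique()
    rng.shuffle(bout_ids)
    n_train = int(round(split * len(bout_ids)))
    train_b = set(bout_ids[:n_train])
    test = design[~design["bout_id"].isin(train_b)]
    if test["stratum"].nunique() < 10:
        raise ValueError("test split has fewer than 10 strata")
    fit = fit_ssf(design[design["bout_id"].isin(train_b)], terms=model_terms)

    g, _ = pd.factorize(test["stratum"].to_numpy())
    order = np.argsort(g, kind="stable")
    test = test.iloc[order]
    g = g[order]
    n_strata = g.max() + 1
    Xm = test[model_terms].to_numpy(float)
    used_rows = test["used"].to_numpy() == 1

    w, v = np.linalg.eigh(0.5 * (fit.vcov + fit.vcov.T))
    root = v * np.sqrt(np.clip(w, 0, None))

    out: dict[str, UhcResult] = {}
    covs = {c: test[c].to_numpy(float) for c in eval_covariates}
    grids = {}
    for c, vals in covs.items():
        lo, hi = vals.min(), vals.max()
        pad = 0.1 * (hi - lo + 1e-9)
        grids[c] = np.linspace(lo - pad, hi + pad, n_grid)

    sims = {c: np.empty((n_sims, n_grid)) for c in eval_covariates}
    for s in range(n_sims):
        beta = fit.coef + root @ rng.standard_normal(len(fit.coef))
        key = Xm @ beta + rng.gumbel(size=len(test))
        seg_max = np.full(n_strata, -np.inf)
        np.maximum.at(seg_max, g, key)
        sel = key == seg_max[g]  # exactly one per stratum a.s.
        for c in eval_covariates:
            sims[c][s] = _kde(covs[c][sel], grids[c])

    for c in eval_covariates:
        observed = _kde(covs[c][used_rows], grids[c])
        available = _kde(covs[c][~used_rows], grids[c])
        lo = np.percentile(sims[c], 2.5, axis=0)
        hi = np.percentile(sims[c], 97.5, axis=0)
        coverage = float(((observed >= lo) & (observed <= hi)).mean())
        out[c] = UhcResult(
            covariate=c,
            grid=grids[c],
            observed=observed,
            available=available,
            env_low=lo,
            env_high=hi,
            sim_mean=sims[c].mean(axis=0),
            coverage=coverage,
        )
    return out
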