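"""Integrated step-selection analysis (iSSA) with hormone-interaction terms.

A *bout* is the GPS subset in the 20 h preceding one fecal sample's
deposition — the window over which circulating glucocorticoids were being
metabolized into the measured fecal metabolites.  Within each bout, observed
movement *steps* (consecutive fix pairs with a defined turn angle) are each
matched with K *available* steps drawn from movement kernels (gamma step
lengths, von Mises turn angles) fitted to the observed steps.  The selection
model is a conditional logistic regression — one used step against its K
available steps per stratum — with design

    dist_end + dist_end:fgm_z + dist_end:fgm_z:period + dist_end:fgm_z:days

where ``dist_end`` is the distance to forest/shrubland cover at the step's
end point in units of 100 m, ``fgm_z`` the standardized fecal glucocorticoid
metabolite concentration at the start of the bout, ``period`` a pre(0)/
post(1)-calving indicator, and ``days`` days since calving (0 pre-calving).

Two estimation routes are provided: direct Newton maximization of the
conditional logistic likelihood, and the equivalent Poisson log-linear model
with one free intercept per stratum (the intercepts have a closed-form
profile update, which makes the reformulation practical at many strata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .landscape import DIST_UNIT_M, LandscapeGrid
from .synthetic import CalvingEvent, FgmSample, Track

HOUR = np.timedelta64(3600, "s")

#: model terms, in reporting order
DEFAULT_TERMS = ["dist_end", "dist_fgm", "dist_fgm_period", "dist_fgm_days"]

#: optional movement-correction terms (off by default)
MOVEMENT_TERMS = ["log_length", "cos_turn"]

#: step lengths below this floor (metres) are clamped before gamma fitting
LENGTH_FLOOR_M = 1.0


# ---------------------------------------------------------------------------
# bouts and steps
# ---------------------------------------------------------------------------

@dataclass
class Bout:
    """The ≤20-h GPS subset preceding one fecal sample."""

    bout_id: str
    individual_id: str
    sample_id: str
    track: Track  # fixes with deposition-20h < t <= deposition
    fgm_z: float
    period: int  # 0 pre-calving, 1 post
    days_since: float  # 0 if pre
    retained: bool = True
    exclusion_reason: str | None = None

    @property
    def n_fixes(self) -> int:
        return len(self.track)


@dataclass
class Step:
    start: tuple[float, float]
    end: tuple[float, float]
    t_start: np.datetime64
    t_end: np.datetime64
    length: float
    turn_angle: float
    prev_bearing: float
    used: bool = True
    stratum_id: str | None = None


def wrap_angle(a):
    """Wrap angles to (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    out = -(np.mod(-a + np.pi, 2 * np.pi) - np.pi)
    return out if out.ndim else float(out)


def make_bouts(
    tracks: list[Track],
    samples: list[FgmSample],
    events: list[CalvingEvent],
    window_hours: float = 20.0,
    identities: dict[str, str] | None = None,
    min_fixes: int = 3,
) -> list[Bout]:
    """Build one bout per accepted sample from the GPS window preceding it.

    ``identities`` maps sample_id -> accepted individual (defaults to each
    sample's suspected individual).  FGM concentrations are standardized to
    zero mean / unit sample SD across the given samples.  Bouts with fewer
    than ``min_fixes`` fixes (no estimable turn angle) or with no calving
    record for their individual-year are flagged ``retained=False``.
    """
    by_ind = {t.individual_id: t for t in tracks}
    ev_by = {(e.individual_id, e.calving_date.year): e for e in events}
    conc = np.array([s.concentration for s in samples], dtype=float)
    if len(conc) < 2:
        raise ValueError("need at least 2 samples to standardize FGM")
    z = (conc - conc.mean()) / conc.std(ddof=1)

    bouts = []
    for s, zi in zip(samples, z):
        ind = (identities or {}).get(s.sample_id, s.suspected_individual)
        dep = s.deposition_time
        win = np.timedelta64(int(window_hours * 3600), "s")
        year = dep.astype("datetime64[Y]").astype(int) + 1970
        bout = Bout(
            bout_id=f"bout-{s.sample_id}",
            individual_id=ind,
            sample_id=s.sample_id,
            track=Track(ind, np.array([], dtype="datetime64[s]"), [], []),
            fgm_z=float(zi),
            period=0,
            days_since=0.0,
        )
        ev = ev_by.get((ind, year))
        if ev is None:
            bout.retained = False
            bout.exclusion_reason = "no calving record for individual-year"
            bouts.append(bout)
            continue
        dep_date = dep.astype("datetime64[D]")
        calv = np.datetime64(ev.calving_date.isoformat(), "D")
        bout.period = int(dep_date >= calv)
        bout.days_since = float(max(0, (dep_date - calv).astype(int)))
        tr = by_ind.get(ind)
        if tr is None:
            bout.retained = False
            bout.exclusion_reason = "no track for individual"
            bouts.append(bout)
            continue
        bout.track = tr.slice_time(dep - win, dep)
        if bout.n_fixes < min_fixes:
            bout.retained = False
            bout.exclusion_reason = f"<{min_fixes} fixes in window"
        bouts.append(bout)
    return bouts


def build_steps(bout: Bout) -> list[Step]:
    """Observed steps of one bout with defined turn angles (n_fixes - 2)."""
    tr = bout.track
    if bout.n_fixes < 3:
        raise ValueError("bout needs at least 3 fixes to define a turn angle")
    if (np.diff(tr.t).astype(int) == 0).any():
        raise ValueError("duplicate timestamps in bout")
    dx = np.diff(tr.x)
    dy = np.diff(tr.y)
    bearings = np.arctan2(dy, dx)
    lengths = np.hypot(dx, dy)
    steps = []
    for i in range(1, len(bearings)):
        steps.append(
            Step(
                start=(tr.x[i], tr.y[i]),
                end=(tr.x[i + 1], tr.y[i + 1]),
                t_start=tr.t[i],
                t_end=tr.t[i + 1],
                length=float(lengths[i]),
                turn_angle=wrap_angle(bearings[i] - bearings[i - 1]),
                prev_bearing=float(bearings[i - 1]),
                used=True,
                stratum_id=f"{bout.bout_id}:{i}",
            )
        )
    return steps


def used_step_table(bouts: list[Bout]) -> pd.DataFrame:
    """Flatten retained bouts into one used-step row per stratum."""
    rows = []
    for b in bouts:
        if not b.retained:
            continue
        for st in build_steps(b):
            rows.append(
                dict(
                    stratum=st.stratum_id,
                    bout_id=b.bout_id,
                    individual_id=b.individual_id,
                    sx=st.start[0], sy=st.start[1],
                    ex=st.end[0], ey=st.end[1],
                    length=st.length,
                    turn=st.turn_angle,
                    prev_bearing=st.prev_bearing,
                    fgm_z=b.fgm_z,
                    period=b.period,
                    days_since=b.days_since,
                )
            )
    if not rows:
        raise ValueError("no retained bouts with usable steps")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# movement kernels
# ---------------------------------------------------------------------------

@dataclass
class KernelFit:
    """Gamma step-length and von Mises turn-angle maximum-likelihood fit."""

    shape: float
    scale: float
    mu: float
    kappa: float

    def __post_init__(self) -> None:
        if min(self.shape, self.scale, self.kappa) <= 0:
            raise ValueError("kernel parameters must be positive")


def fit_kernels(lengths: np.ndarray, angles: np.ndarray) -> KernelFit:
    """MLE gamma (lengths, metres; loc fixed at 0) and von Mises (angles)."""
    lengths = np.maximum(np.asarray(lengths, float), LENGTH_FLOOR_M)
    if len(lengths) < 10:
        raise ValueError("need at least 10 steps to fit movement kernels")
    k, _, theta = stats.gamma.fit(lengths, floc=0)
    kappa, mu, _ = stats.vonmises.fit(np.asarray(angles, float), fscale=1)
    return KernelFit(shape=float(k), scale=float(theta),
                     mu=float(wrap_angle(mu)), kappa=float(max(kappa, 1e-8)))


def fit_kernels_by_individual(
    used: pd.DataFrame, min_steps: int = 50
) -> dict[str, KernelFit]:
    """Per-individual kernels where ≥min_steps used steps exist, else pooled.

    The pooled fit is stored under the key ``"__pooled__"`` and used as the
    fallback for data-poor individuals.
    """
    pooled = fit_kernels(used["length"].to_numpy(), used["turn"].to_numpy())
    out = {"__pooled__": pooled}
    for ind, grp in used.groupby("individual_id"):
        if len(grp) >= min_steps:
            out[ind] = fit_kernels(grp["length"].to_numpy(), grp["turn"].to_numpy())
    return out


def generate_available(
    used_step: Step | pd.Series,
    kernels: KernelFit,
    K: int,
    seed: int | np.random.Generator,
    landscape: LandscapeGrid | None = None,
    max_retries: int = 10,
) -> np.ndarray:
    """Draw K available steps matched to one used step.

    Returns an array of shape (K, 4): end x, end y, length, turn angle.
    Available steps share the used step's start point and prior bearing; if a
    landscape is given, off-grid end points are redrawn up to ``max_retries``
    times, after which they are flagged NaN (covariate missing).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(used_step, Step):
        sx, sy = used_step.start
        pb = used_step.prev_bearing
    else:
        sx, sy, pb = used_step["sx"], used_step["sy"], used_step["prev_bearing"]
    out = np.empty((K, 4))
    out[:] = np.nan
    todo = np.arange(K)
    for _ in range(max_retries):
        n = len(todo)
        if n == 0:
            break
        lengths = rng.gamma(kernels.shape, kernels.scale, size=n)
        turns = rng.vonmises(kernels.mu, kernels.kappa, size=n)
        ex = sx + lengths * np.cos(pb + turns)
        ey = sy + lengths * np.sin(pb + turns)
        ok = (
            np.ones(n, dtype=bool)
            if landscape is None
            else landscape.contains(ex, ey)
        )
        out[todo[ok], 0] = ex[ok]
        out[todo[ok], 1] = ey[ok]
        out[todo[ok], 2] = lengths[ok]
        out[todo[ok], 3] = turns[ok]
        todo = todo[~ok]
    return out


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def build_design(
    used: pd.DataFrame,
    landscape: LandscapeGrid,
    kernels: dict[str, KernelFit] | KernelFit,
    K: int = 40,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Assemble the stratified design: 1 used + K available rows per stratum.

    Columns: stratum, used flag, end coordinates, length/turn, the covariate
    ``dist_end`` (distance to cover at the step end, 100-m units), the bout
    covariates, and the interaction columns of the selection model.  Strata
    whose available steps could not all be placed on the landscape are
    dropped (covariate missing).
    """
    rng = np.random.default_rng(seed)
    recs = []
    dropped = 0
    for _, row in used.iterrows():
        kern = (
            kernels if isinstance(kernels, KernelFit)
            else kernels.get(row["individual_id"], kernels["__pooled__"])
        )
        av = generate_available(row, kern, K, rng.integers(2**31), landscape)
        if np.isnan(av[:, 0]).any() or not landscape.contains(row["ex"], row["ey"]):
            dropped += 1
            continue
        base = dict(
            stratum=row["stratum"], bout_id=row["bout_id"],
            individual_id=row["individual_id"], fgm_z=row["fgm_z"],
            period=row["period"], days_since=row["days_since"],
        )
        recs.append(dict(base, used=1, ex=row["ex"], ey=row["ey"],
                         length=row["length"], turn=row["turn"]))
        for k in range(K):
            recs.append(dict(base, used=0, ex=av[k, 0], ey=av[k, 1],
                             length=av[k, 2], turn=av[k, 3]))
    if not recs:
        raise ValueError("no strata could be placed on the landscape")
    df = pd.DataFrame(recs)
    df["dist_end"] = landscape.dist_to_cover(
        df["ex"].to_numpy(), df["ey"].to_numpy(), units="100m"
    )
    add_interactions(df)
    df.attrs["K"] = K
    df.attrs["n_dropped_strata"] = dropped
    return df


def add_interactions(df: pd.DataFrame) -> pd.DataFrame:
    """Derive the hormone-interaction and movement-correction columns in place."""
    df["dist_fgm"] = df["dist_end"] * df["fgm_z"]
    df["dist_fgm_period"] = df["dist_end"] * df["fgm_z"] * df["period"]
    df["dist_fgm_days"] = df["dist_end"] * df["fgm_z"] * df["days_since"]
    df["log_length"] = np.log(np.maximum(df["length"], LENGTH_FLOOR_M))
    df["cos_turn"] = np.cos(df["turn"])
    return df


# ---------------------------------------------------------------------------
# conditional logistic / Poisson-trick estimation
# ---------------------------------------------------------------------------

@dataclass
class SsfFit:
    """Fitted step-selection coefficients with uncertainty."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_strata: int
    K: int | None
    mode: str
    converged: bool
    n_iter: int = 0

    @property
    def ci_low(self) -> np.ndarray:
        return self.coef - 1.96 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.coef + 1.96 * self.se

    @property
    def exp_coef(self) -> np.ndarray:
        return np.exp(self.coef)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "exp_coef": self.exp_coef,
                "exp_ci_low": np.exp(self.ci_low),
                "exp_ci_high": np.exp(self.ci_high),
            },
            index=self.terms,
        )

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "coef": self.coef.tolist(),
            "se": self.se.tolist(),
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "n_strata": self.n_strata,
            "K": self.K,
            "mode": self.mode,
            "converged": self.converged,
        }


def _design_arrays(design: pd.DataFrame, terms: list[str]):
    codes, _ = pd.factorize(design["stratum"].to_numpy())
    order = np.argsort(codes, kind="stable")
    X = design[terms].to_numpy(float)[order]
    y = design["used"].to_numpy(int)[order]
    g = codes[order]
    counts = np.bincount(g)
    used_per = np.bincount(g, weights=y)
    if not np.allclose(used_per, 1):
        raise ValueError("every stratum must contain exactly one used step")
    if (counts < 2).any():
        raise ValueError("every stratum needs at least one available step")
    return X, y, g, len(counts)


def _screen_columns(X: np.ndarray, g: np.ndarray, terms: list[str]):
    """Identify estimable columns.

    Columns constant within every stratum do not enter the conditional
    likelihood at all (the matched design absorbs them); they are dropped
    with a NaN coefficient, as R's clogit does.  Genuine collinearity among
    the remaining columns is an error naming the offending columns.
    """
    counts = np.bincount(g)
    Xc = X - np.apply_along_axis(
        lambda c: np.bincount(g, weights=c)[g] / counts[g], 0, X
    )
    scale = np.abs(X).max(axis=0) + 1.0
    keep = np.abs(Xc).max(axis=0) > 1e-10 * scale
    Xk = Xc[:, keep]
    if Xk.shape[1] == 0:
        raise np.linalg.LinAlgError("no within-stratum variation in any column")
    s = np.linalg.svd(Xk, compute_uv=False)
    if s[0] > 0 and s[-1] / s[0] < 1e-10:
        _, _, v = np.linalg.svd(Xk)
        kept_terms = [t for t, k in zip(terms, keep) if k]
        bad = [kept_terms[i] for i in np.nonzero(np.abs(v[-1]) > 1e-3)[0]]
        raise np.linalg.LinAlgError(
            f"singular design: collinear columns {bad} (within-stratum)"
        )
    return keep


def _clogit_quantities(X, g, n_strata, beta):
    """Conditional log-likelihood pieces shared by both estimation modes."""
    eta = X @ beta
    # per-stratum log-sum-exp
    mx = np.full(n_strata, -np.inf)
    np.maximum.at(mx, g, eta)
    expe = np.exp(eta - mx[g])
    denom = np.bincount(g, weights=expe, minlength=n_strata)
    p = expe / denom[g]
    lse = mx + np.log(denom)
    mean_x = np.vstack(
        [np.bincount(g, weights=p * X[:, j], minlength=n_strata) for j in range(X.shape[1])]
    ).T  # (n_strata, p)
    info = (X.T * p) @ X - mean_x.T @ mean_x
    return p, lse, mean_x, info


def conditional_loglik(X, y, g, n_strata, beta) -> float:
    eta = X @ beta
    mx = np.full(n_strata, -np.inf)
    np.maximum.at(mx, g, eta)
    denom = np.bincount(g, weights=np.exp(eta - mx[g]), minlength=n_strata)
    return float(eta[y == 1].sum() - (mx + np.log(denom)).sum())


def fit_ssf(
    design: pd.DataFrame,
    terms: list[str] | None = None,
    mode: str = "clogit",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> SsfFit:
    """Fit the step-selection model.

    ``mode='clogit'`` maximizes the conditional logistic likelihood by Newton
    iteration.  ``mode='poisson_trick'`` fits the equivalent Poisson model
    with one free intercept per stratum by block-coordinate IRLS (closed-form
    intercept profile, Newton step on the slopes with the intercept block
    profiled out of the information).  Both return the same coefficients up
    to numerical tolerance; SEs come from the observed information.
    """
    all_terms = list(terms or DEFAULT_TERMS)
    X_full, y, g, n_strata = _design_arrays(design, all_terms)
    keep = _screen_columns(X_full, g, all_terms)
    if not keep.all():
        import warnings

        dropped = [t for t, k in zip(all_terms, keep) if not k]
        warnings.warn(
            f"dropping stratum-constant terms {dropped}: not estimable in a "
            "conditional (matched-stratum) likelihood"
        )
    X = X_full[:, keep]
    terms = [t for t, k in zip(all_terms, keep) if k]
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    used_x = X[y == 1].sum(axis=0)
    converged = False
    it = 0
    ll = -np.inf

    for it in range(1, max_iter + 1):
        if mode == "clogit":
            pr, lse, _, info = _clogit_quantities(X, g, n_strata, beta)
            score = used_x - np.vstack([np.bincount(g, weights=pr * X[:, j]) for j in range(p_dim)]).sum(axis=1)
            ll_new = float((X[y == 1] @ beta).sum() - lse.sum())
        elif mode == "poisson_trick":
            # profile intercepts: alpha_s = -logsumexp_s(eta) makes each
            # stratum's fitted Poisson total equal its observed total (=1)
            eta = X @ beta
            mx = np.full(n_strata, -np.inf)
            np.maximum.at(mx, g, eta)
            denom = np.bincount(g, weights=np.exp(eta - mx[g]), minlength=n_strata)
            alpha = -(mx + np.log(denom))
            mu = np.exp(alpha[g] + eta)
            score = X.T @ (y - mu)
            I_bb = (X.T * mu) @ X
            I_ba = np.vstack(
                [np.bincount(g, weights=mu * X[:, j], minlength=n_strata) for j in range(p_dim)]
            )
            I_aa = np.bincount(g, weights=mu, minlength=n_strata)  # ≡ 1 after profiling
            info = I_bb - (I_ba / I_aa) @ I_ba.T
            ll_new = float((y * (alpha[g] + eta)).sum() - mu.sum())
        else:
            raise ValueError(f"unknown mode {mode!r}")

        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step halving against divergence
        t = 1.0
        while t > 1e-4 and not np.isfinite(
            conditional_loglik(X, y, g, n_strata, beta + t * step)
        ):
            t /= 2
        beta = beta + t * step
        if np.linalg.norm(beta) > 50:
            converged = False  # complete/quasi-separation
            ll = ll_new
            break
        if np.abs(score).max() < 1e-6 or abs(ll_new - ll) < tol * (abs(ll) + 1):
            converged = True
            ll = ll_new
            break
        ll = ll_new

    # observed information at the optimum (conditional-likelihood scale)
    _, _, _, info = _clogit_quantities(X, g, n_strata, beta)
    vcov = np.linalg.inv(info)
    vcov = 0.5 * (vcov + vcov.T)
    # expand back to the requested term list (NaN for dropped columns)
    p_all = len(all_terms)
    coef_out = np.full(p_all, np.nan)
    vcov_out = np.full((p_all, p_all), np.nan)
    ki = np.nonzero(keep)[0]
    coef_out[ki] = beta
    vcov_out[np.ix_(ki, ki)] = vcov
    return SsfFit(
        terms=all_terms,
        coef=coef_out,
        se=np.sqrt(np.diag(vcov_out)),
        vcov=vcov_out,
        loglik=conditional_loglik(X, y, g, n_strata, beta),
        n_strata=n_strata,
        K=design.attrs.get("K"),
        mode=mode,
        converged=converged,
        n_iter=it,
    )


def fit_ssf_mixed(
    design: pd.DataFrame,
    terms: list[str] | None = None,
    penalty: float = 1.0,
    max_iter: int = 100,
) -> SsfFit:
    """Approximate random-slopes variant: per-individual coefficient
    deviations shrunk by an L2 (Gaussian) penalty.

    This is a penalized-likelihood stand-in for the mixed conditional model
    (random intercepts are absorbed by the strata); it is provided behind
    this separate entry point and is not used by the fixed-effects pipeline.
    Returned coefficients are the population-level (unpenalized) terms.
    """
    terms = list(terms or DEFAULT_TERMS)
    inds = pd.factorize(design["individual_id"])[0]
    n_ind = inds.max() + 1
    cols = {}
    for j, term in enumerate(terms):
        for i in range(n_ind):
            cols[f"{term}__dev{i}"] = design[term].to_numpy() * (inds == i)
    aug = design.copy()
    for k, v in cols.items():
        aug[k] = v
    all_terms = terms + list(cols)
    X, y, g, n_strata = _design_arrays(aug, all_terms)
    p_main = len(terms)
    pen = np.zeros(len(all_terms))
    pen[p_main:] = penalty
    beta = np.zeros(len(all_terms))
    used_x = X[y == 1].sum(axis=0)
    for _ in range(max_iter):
        pr, lse, _, info = _clogit_quantities(X, g, n_strata, beta)
        score = used_x - np.vstack(
            [np.bincount(g, weights=pr * X[:, j]) for j in range(X.shape[1])]
        ).sum(axis=1) - pen * beta
        info_p = info + np.diag(pen)
        try:
            step = np.linalg.solve(info_p, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(score).max() < 1e-6:
            break
    vcov = np.linalg.inv(info + np.diag(pen))[:p_main, :p_main]
    return SsfFit(
        terms=terms,
        coef=beta[:p_main],
        se=np.sqrt(np.diag(vcov)),
        vcov=0.5 * (vcov + vcov.T),
        loglik=conditional_loglik(X, y, g, n_strata, beta),
        n_strata=n_strata,
        K=design.attrs.get("K"),
        mode="penalized_mixed",
        converged=True,
    )


def ratio_sensitivity(
    used: pd.DataFrame,
    landscape: LandscapeGrid,
    kernels: dict[str, KernelFit] | KernelFit,
    ratios=(1, 5, 10, 30, 40, 100),
    terms: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit the model over a ladder of available:used ratios K.

    Returns one row per (K, term) with the estimate and SE, plus a
    ``stability`` column: max over terms of |beta(K) - beta(K_max)| /
    SE(K_max), a scale-free measure of how much estimates move relative to
    the best-resolved fit.
    """
    ratios = sorted(int(k) for k in ratios)
    if min(ratios) < 1 or max(ratios) > 1000:
        raise ValueError("ratios must lie in [1, 1000]")
    terms = list(terms or DEFAULT_TERMS)
    rng = np.random.default_rng(seed)
    fits: dict[int, SsfFit] = {}
    for K in ratios:
        design = build_design(used, landscape, kernels, K=K, seed=rng.integers(2**31))
        fits[K] = fit_ssf(design, terms=terms)
    K_max = max(ratios)
    ref = fits[K_max]
    rows = []
    for K in ratios:
        f = fits[K]
        stab = float(np.max(np.abs(f.coef - ref.coef) / ref.se))
        for j, term in enumerate(terms):
            rows.append(
                dict(K=K, term=term, coef=f.coef[j], se=f.se[j], stability=stab)
            )
    return pd.DataFrame(rows)
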