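"""Desk-scale simulation studies with known generating truth.

These drivers wire the synthetic generator to the estimation stack for
round-trip checks: simulate hormone bouts from a known selection model,
refit, and ask whether confidence intervals cover the generating
coefficients.  They are the work-horses of the package's validation suite
and of the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .issa import (
    DEFAULT_TERMS,
    Bout,
    SsfFit,
    build_design,
    fit_kernels,
    fit_ssf,
    used_step_table,
)
from .landscape import LandscapeGrid, make_landscape
from .synthetic import SimConfig, simulate_bout


@dataclass
class IssaStudy:
    """One simulated bout study plus everything needed to refit it."""

    landscape: LandscapeGrid
    bouts: list[Bout]
    used: pd.DataFrame
    config: SimConfig
    truth: dict[str, float]


def simulate_issa_study(
    n_individuals: int = 13,
    bouts_per_individual: int = 6,
    config: SimConfig | None = None,
    landscape: LandscapeGrid | None = None,
    seed: int = 0,
) -> IssaStudy:
    """Simulate ~n_individuals x bouts_per_individual hormone bouts.

    Each bout has a hormone state z ~ N(0, 1), a pre/post-calving period
    (half each), and for post bouts an integer days-since-calving uniform on
    [0, 84] (the span of post-calving sampling in the emulated study).
    Movement follows the configured kernels with the effective selection
    coefficient implied by the configured betas; no hiding behaviour, so the
    fitted model matches the generating process exactly.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    landscape = landscape or make_landscape(seed=rng.integers(2**31))
    bouts: list[Bout] = []
    for i in range(n_individuals):
        ind = f"elk-{i:02d}"
        for b in range(bouts_per_individual):
            z = float(rng.standard_normal())
            period = int(rng.random() < 0.5)
            days = float(rng.integers(0, 85)) if period else 0.0
            tr = simulate_bout(
                landscape, config, z, period, days,
                individual_id=ind,
                start_xy=_interior_point(landscape, rng),
                seed=rng.integers(2**31),
            )
            bouts.append(
                Bout(
                    bout_id=f"{ind}-b{b}",
                    individual_id=ind,
                    sample_id=f"{ind}-s{b}",
                    track=tr,
                    fgm_z=z,
                    period=period,
                    days_since=days,
                )
            )
    return IssaStudy(
        landscape=landscape,
        bouts=bouts,
        used=used_step_table(bouts),
        config=config,
        truth=dict(config.betas),
    )


def refit_study(study: IssaStudy, K: int = 40, seed: int = 0, mode: str = "clogit") -> SsfFit:
    """The full estimation pipeline on a simulated study: pooled kernel fit
    on used steps, K available steps per stratum, conditional-logistic fit."""
    kernels = fit_kernels(study.used["length"].to_numpy(), study.used["turn"].to_numpy())
    design = build_design(study.used, study.landscape, kernels, K=K, seed=seed)
    return fit_ssf(design, mode=mode)


def coverage_study(
    n_replicates: int = 100,
    n_individuals: int = 13,
    bouts_per_individual: int = 6,
    K: int = 40,
    monitored: tuple[str, ...] = ("dist_end", "dist_fgm", "dist_fgm_days"),
    config: SimConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate/refit n_replicates studies; per replicate and monitored
    term, record the estimate, CI, and whether the CI covers the truth.

    The same landscape is reused across replicates (the landscape is a
    design fixture, not a random effect under study)."""
    config = config or SimConfig()
    term_to_beta = {
        "dist_end": "dist",
        "dist_fgm": "dist_fgm",
        "dist_fgm_period": "dist_fgm_period",
        "dist_fgm_days": "dist_fgm_days",
    }
    rng = np.random.default_rng(seed)
    landscape = make_landscape(seed=rng.integers(2**31))
    rows = []
    for r in range(n_replicates):
        study = simulate_issa_study(
            n_individuals, bouts_per_individual, config, landscape,
            seed=int(rng.integers(2**31)),
        )
        fit = refit_study(study, K=K, seed=int(rng.integers(2**31)))
        for term in monitored:
            j = fit.terms.index(term)
            truth = study.truth[term_to_beta[term]]
            rows.append(
                dict(
                    replicate=r, term=term, truth=truth, coef=fit.coef[j],
                    se=fit.se[j], ci_low=fit.ci_low[j], ci_high=fit.ci_high[j],
                    covered=bool(fit.ci_low[j] <= truth <= fit.ci_high[j]),
                    converged=fit.converged,
                )
            )
    return pd.DataFrame(rows)


def calving_detection_study(
    n_train: int = 11,
    n_test: int = 10,
    suppression: float = 0.15,
    n_repeats: int = 100,
    season_days: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate observed + unobserved calving events and measure detection
    error.

    ``n_train`` tracks with known (observed) events train the classifier;
    ``n_test`` tracks with hidden events are screened.  Returns one row per
    test event with the estimated date, truth, and signed error in days.
    """
    from datetime import date, timedelta

    from .calving import DetectorConfig, screen_tracks, train_event_classifier
    from .synthetic import CalvingEvent, simulate_track

    rng = np.random.default_rng(seed)
    landscape = make_landscape(seed=rng.integers(2**31))
    cfg = SimConfig(calving_suppression=suppression)
    dcfg = DetectorConfig(n_repeats=n_repeats, seed=int(rng.integers(2**31)))

    def sim(ind: str) -> tuple:
        calv = date(2019, 5, 20) + timedelta(days=int(rng.integers(0, 25)))
        ev = CalvingEvent(ind, calv)
        tr = simulate_track(
            landscape, cfg, None, ev, individual_id=ind,
            start_time="2019-05-15", n_fixes=48 * season_days,
            start_xy=_interior_point(landscape, rng), seed=int(rng.integers(2**31)),
        )
        return tr, ev

    training = [sim(f"train-{i:02d}") for i in range(n_train)]
    testing = [sim(f"test-{i:02d}") for i in range(n_test)]
    det = train_event_classifier(training, dcfg)
    preds = screen_tracks([t for t, _ in testing], det, dcfg,
                          seed=int(rng.integers(2**31)))
    rows = []
    for tr, ev in testing:
        p = preds[tr.individual_id]
        rows.append(
            dict(
                individual_id=tr.individual_id,
                truth=ev.calving_date,
                estimate=None if p is None else p.calving_date,
                error_days=(
                    np.nan if p is None else (p.calving_date - ev.calving_date).days
                ),
                detected=p is not None,
                threshold=det.threshold,
            )
        )
    return pd.DataFrame(rows)


def uhc_contrast_study(
    n_individuals: int = 13,
    bouts_per_individual: int = 6,
    K: int = 40,
    n_sims: int = 1000,
    config: SimConfig | None = None,
    seed: int = 0,
):
    """Used-habitat calibration of the full hormone-interaction model versus
    a misspecified model omitting the dist x FGM interaction, both fitted to
    the same interaction-generated data.

    Returns (full UhcResult dict, reduced UhcResult dict); the reduced
    model's miscalibration shows up on the omitted ``dist_fgm`` covariate.
    """
    from .rss import uhc_validate

    rng = np.random.default_rng(seed)
    study = simulate_issa_study(
        n_individuals, bouts_per_individual, config, seed=int(rng.integers(2**31))
    )
    kernels = fit_kernels(study.used["length"].to_numpy(), study.used["turn"].to_numpy())
    design = build_design(study.used, study.landscape, kernels, K=K,
                          seed=int(rng.integers(2**31)))
    eval_covs = ["dist_end", "dist_fgm"]
    full = uhc_validate(design, model_terms=DEFAULT_TERMS,
                        eval_covariates=eval_covs, n_sims=n_sims,
                        seed=int(rng.integers(2**31)))
    reduced_terms = [t for t in DEFAULT_TERMS if t != "dist_fgm"]
    reduced = uhc_validate(design, model_terms=reduced_terms,
                           eval_covariates=eval_covs, n_sims=n_sims,
                           seed=int(rng.integers(2**31)))
    return full, reduced


def simulate_prepost_samples(
    n_individuals: int = 13,
    samples_per_individual: int = 3,
    period_effect_sd: float = 0.0,
    intercept_sd: float = 0.5,
    within_sd: float = 1.0,
    years: tuple[int, ...] = (2019, 2020),
    seed: int = 0,
):
    """Hormone samples with a known pre/post-calving effect (in pooled-SD
    units) for the hierarchical GLM's coverage studies (~76 samples at the
    defaults, matching the emulated analysis size)."""
    from datetime import date, timedelta

    from .synthetic import CalvingEvent, FgmSample

    rng = np.random.default_rng(seed)
    base_mean, base_sd = 1900.0, 450.0
    samples, events = [], []
    for year in years:
        for i in range(n_individuals):
            ind = f"elk-{i:02d}"
            calv = date(year, 6, 1) + timedelta(days=int(rng.integers(0, 20)))
            events.append(CalvingEvent(ind, calv))
            icpt = rng.normal(0, intercept_sd)
            for j in range(samples_per_individual):
                dep = np.datetime64(f"{year}-05-15", "s") + np.timedelta64(
                    int(rng.integers(0, 80)), "D"
                ) + np.timedelta64(10, "h")
                post = int(dep.astype("datetime64[D]") >= np.datetime64(calv.isoformat()))
                z = icpt + period_effect_sd * post + rng.normal(0, within_sd)
                samples.append(
                    FgmSample(
                        sample_id=f"{ind}-{year}-{j}",
                        suspected_individual=ind,
                        collection_time=dep + np.timedelta64(3, "h"),
                        deposition_time=dep,
                        concentration=float(max(base_mean + base_sd * z, 1.0)),
                    )
                )
    return samples, events


def prepost_null_coverage(n_replicates: int = 100, seed: int = 0) -> pd.DataFrame:
    """Replicated null simulations of the pre/post hormone model: does the
    95% interval for the period effect cover zero?"""
    from .prepost import fit_prepost

    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_replicates):
        samples, events = simulate_prepost_samples(
            period_effect_sd=0.0, seed=int(rng.integers(2**31))
        )
        eff = fit_prepost(samples, events, engine="likelihood")["period"]
        rows.append(
            dict(replicate=r, estimate=eff.estimate, ci_low=eff.ci_low,
                 ci_high=eff.ci_high, covers_zero=bool(eff.ci_low <= 0 <= eff.ci_high))
        )
    return pd.DataFrame(rows)


def _interior_point(landscape: LandscapeGrid, rng) -> tuple[float, float]:
    xmin, xmax, ymin, ymax = landscape.extent
    return (
        float(rng.uniform(xmin + 0.25 * (xmax - xmin), xmax - 0.25 * (xmax - xmin))),
        float(rng.uniform(ymin + 0.25 * (ymax - ymin), ymax - 0.25 * (ymax - ymin))),
    )
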