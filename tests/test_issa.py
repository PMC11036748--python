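from datetime import date

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from cortisel.issa import (
    DEFAULT_TERMS,
    Bout,
    KernelFit,
    add_interactions,
    build_design,
    build_steps,
    fit_kernels,
    fit_kernels_by_individual,
    fit_ssf,
    generate_available,
    make_bouts,
    used_step_table,
    wrap_angle,
)
from cortisel.synthetic import CalvingEvent, FgmSample, Track


def fix_track(xy, individual="a", start="2019-06-01T00:00", step_min=30):
    xy = np.asarray(xy, float)
    t = np.datetime64(start, "s") + np.timedelta64(step_min * 60, "s") * np.arange(len(xy))
    return Track(individual, t, xy[:, 0], xy[:, 1])


def bout_from_xy(xy, fgm_z=0.0, period=0, days=0.0):
    return Bout("b0", "a", "s0", fix_track(xy), fgm_z, period, days)


# ---------------------------------------------------------------------------
# bout construction
# ---------------------------------------------------------------------------

class TestMakeBouts:
    @staticmethod
    def _sample(sid, ind, dep, conc=1800.0):
        dep = np.datetime64(dep, "s")
        return FgmSample(sample_id=sid, suspected_individual=ind,
                         collection_time=dep + np.timedelta64(2, "h"),
                         deposition_time=dep, concentration=conc)

    def test_window_filter_matches_brute_force(self):
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.normal(0, 100, size=(200, 2)), axis=0)
        tr = fix_track(xy, start="2019-06-01T00:00")
        dep = "2019-06-03T06:00"
        s = self._sample("s1", "a", dep, 1500.0)
        s2 = self._sample("s2", "a", "2019-06-02T00:00", 2500.0)
        ev = [CalvingEvent("a", date(2019, 6, 2))]
        bouts = make_bouts([tr], [s, s2], ev)
        dep64 = np.datetime64(dep, "s")
        lo = dep64 - np.timedelta64(20, "h")
        expected = [(t, x) for t, x in zip(tr.t, tr.x) if lo < t <= dep64]
        assert bouts[0].n_fixes == len(expected)
        np.testing.assert_array_equal(bouts[0].track.x, [x for _, x in expected])

    def test_deposition_on_calving_date_is_post_with_zero_days(self):
        tr = fix_track(np.zeros((100, 2)) + np.arange(100)[:, None],
                       start="2019-06-01T00:00")
        s = self._sample("s1", "a", "2019-06-02T10:00")
        s2 = self._sample("s2", "a", "2019-06-01T10:00", 2100.0)
        bouts = make_bouts([tr], [s, s2], [CalvingEvent("a", date(2019, 6, 2))])
        assert bouts[0].period == 1 and bouts[0].days_since == 0.0
        assert bouts[1].period == 0 and bouts[1].days_since == 0.0

    def test_short_window_bouts_flagged_not_retained(self):
        # track covering only the second sample's window
        tr = fix_track([(0, 0), (50, 0), (100, 0), (150, 0)], start="2019-06-02T09:00")
        s_ok = self._sample("ok", "a", "2019-06-02T11:00")
        s_short = self._sample("short", "a", "2019-06-05T00:00", 2000.0)
        bouts = make_bouts([tr], [s_ok, s_short], [CalvingEvent("a", date(2019, 6, 1))])
        assert bouts[0].retained
        assert not bouts[1].retained and "fixes" in bouts[1].exclusion_reason

    def test_sample_without_calving_record_excluded(self):
        tr = fix_track(np.zeros((10, 2)), start="2019-06-01T00:00")
        s = self._sample("s1", "a", "2019-06-01T04:00")
        s2 = self._sample("s2", "a", "2019-06-01T05:00", 2500.0)
        bouts = make_bouts([tr], [s, s2], events=[])
        assert not bouts[0].retained
        assert "calving" in bouts[0].exclusion_reason

    def test_fgm_standardized_across_samples(self):
        tr = fix_track(np.cumsum(np.ones((300, 2)) * 10, axis=0),
                       start="2019-06-01T00:00")
        ss = [self._sample(f"s{i}", "a", f"2019-06-0{i+1}T10:00", 1000.0 + 400 * i)
              for i in range(4)]
        ev = [CalvingEvent("a", date(2019, 6, 2))]
        bouts = make_bouts([tr], ss, ev)
        zs = np.array([b.fgm_z for b in bouts])
        assert zs.mean() == pytest.approx(0.0, abs=1e-12)
        assert zs.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# step geometry
# ---------------------------------------------------------------------------

class TestBuildSteps:
    def test_collinear_fixes_give_zero_turn(self):
        steps = build_steps(bout_from_xy([(0, 0), (100, 0), (200, 0)]))
        assert len(steps) == 1
        assert steps[0].turn_angle == pytest.approx(0.0)
        assert steps[0].length == pytest.approx(100.0)

    @pytest.mark.parametrize("third,expected", [((100, 100), np.pi / 2),
                                                ((100, -100), -np.pi / 2)])
    def test_right_angle_turns(self, third, expected):
        steps = build_steps(bout_from_xy([(0, 0), (100, 0), third]))
        assert steps[0].turn_angle == pytest.approx(expected)

    def test_matches_independent_geometry_oracle(self):
        rng = np.random.default_rng(1)
        xy = np.cumsum(rng.normal(0, 80, size=(20, 2)), axis=0)
        steps = build_steps(bout_from_xy(xy))
        assert len(steps) == 18
        for i, st in enumerate(steps, start=1):
            p0, p1, p2 = xy[i - 1], xy[i], xy[i + 1]
            length = np.linalg.norm(p2 - p1)
            b1 = np.arctan2(*(p1 - p0)[::-1])
            b2 = np.arctan2(*(p2 - p1)[::-1])
            turn = np.angle(np.exp(1j * (b2 - b1)))
            assert st.length == pytest.approx(length)
            assert st.turn_angle == pytest.approx(turn)

    def test_duplicate_timestamps_rejected(self):
        t = np.array(["2019-06-01T00:00", "2019-06-01T00:30", "2019-06-01T00:30"],
                     dtype="datetime64[s]")
        with pytest.raises(ValueError):
            Track("a", t, [0.0, 1.0, 2.0], [0.0, 0.0, 0.0])

    def test_too_few_fixes_rejected(self):
        with pytest.raises(ValueError, match="3 fixes"):
            build_steps(bout_from_xy([(0, 0), (1, 1)]))


def test_wrap_angle_maps_to_half_open_interval():
    a = wrap_angle(np.array([0.0, np.pi, -np.pi, 3 * np.pi / 2, -3 * np.pi]))
    assert ((a > -np.pi) & (a <= np.pi)).all()
    assert a[1] == pytest.approx(np.pi)
    assert a[2] == pytest.approx(np.pi)  # -pi wraps to +pi


# ---------------------------------------------------------------------------
# movement kernels
# ---------------------------------------------------------------------------

class TestKernels:
    def test_gamma_recovery_within_ten_percent(self):
        rng = np.random.default_rng(2)
        lengths = rng.gamma(2.0, 100.0, size=2000)
        angles = rng.vonmises(0.0, 1.2, size=2000)
        fit = fit_kernels(lengths, angles)
        assert fit.shape == pytest.approx(2.0, rel=0.10)
        assert fit.scale == pytest.approx(100.0, rel=0.10)
        assert fit.kappa == pytest.approx(1.2, rel=0.10)

    def test_degenerate_angles_give_large_kappa_zero_mu(self):
        rng = np.random.default_rng(3)
        fit = fit_kernels(rng.gamma(2.0, 100.0, 500), np.zeros(500))
        assert fit.kappa > 50
        assert fit.mu == pytest.approx(0.0, abs=1e-6)

    def test_uniform_angles_give_near_zero_kappa(self):
        rng = np.random.default_rng(4)
        fit = fit_kernels(rng.gamma(2.0, 100.0, 2000),
                          rng.uniform(-np.pi, np.pi, 2000))
        assert fit.kappa < 0.1

    def test_zero_length_steps_floored_not_fatal(self):
        rng = np.random.default_rng(5)
        lengths = np.concatenate([np.zeros(20), rng.gamma(2.0, 100.0, 480)])
        fit = fit_kernels(lengths, rng.vonmises(0, 1, 500))
        assert fit.shape > 0 and fit.scale > 0

    def test_per_individual_fits_with_pooled_fallback(self, small_study):
        kernels = fit_kernels_by_individual(small_study.used, min_steps=50)
        assert "__pooled__" in kernels
        rich = small_study.used["individual_id"].value_counts()
        for ind, n in rich.items():
            if n >= 50:
                assert ind in kernels


class TestGenerateAvailable:
    def test_degenerate_kernels_give_closed_form_endpoint(self):
        # kappa huge -> turn = mu = 0; shape huge with tiny scale -> length ~ k*theta
        kern = KernelFit(shape=1e6, scale=1e-4, mu=0.0, kappa=1e7)
        st = pd.Series(dict(sx=10.0, sy=20.0, prev_bearing=np.pi / 2))
        out = generate_available(st, kern, K=1, seed=0)
        assert out[0, 0] == pytest.approx(10.0, abs=0.5)  # straight "north"
        assert out[0, 1] == pytest.approx(20.0 + 100.0, rel=0.05)

    def test_empirical_distribution_matches_generating_kernels(self):
        kern = KernelFit(shape=2.0, scale=150.0, mu=0.0, kappa=0.8)
        st = pd.Series(dict(sx=0.0, sy=0.0, prev_bearing=0.3))
        out = generate_available(st, kern, K=100_000, seed=1)
        lengths, turns = out[:, 2], out[:, 3]
        ks_len = stats.kstest(lengths, stats.gamma(a=2.0, scale=150.0).cdf)
        ks_turn = stats.kstest(turns, stats.vonmises(kappa=0.8).cdf)
        assert ks_len.pvalue > 0.01
        assert ks_turn.pvalue > 0.01

    def test_invalid_K_rejected(self):
        kern = KernelFit(2.0, 150.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            generate_available(pd.Series(dict(sx=0, sy=0, prev_bearing=0)),
                               kern, K=0, seed=0)


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

class TestDesign:
    def test_step_ending_on_cover_has_zero_distance(self, single_cover_grid):
        df = pd.DataFrame(dict(ex=[250.0], ey=[250.0], length=[10.0], turn=[0.0],
                               fgm_z=[1.0], period=[1], days_since=[3.0]))
        df["dist_end"] = single_cover_grid.dist_to_cover(
            df.ex.to_numpy(), df.ey.to_numpy(), units="100m")
        add_interactions(df)
        assert df.loc[0, "dist_end"] == 0.0
        assert df.loc[0, "dist_fgm"] == 0.0

    def test_zero_fgm_bout_zeroes_every_interaction(self, small_study):
        from cortisel.issa import fit_kernels

        used = small_study.used.copy()
        used["fgm_z"] = 0.0
        kern = fit_kernels(used["length"].to_numpy(), used["turn"].to_numpy())
        design = build_design(used.head(50), small_study.landscape, kern, K=5, seed=0)
        assert (design[["dist_fgm", "dist_fgm_period", "dist_fgm_days"]] == 0).all().all()

    def test_interaction_columns_are_elementwise_products(self, small_fit, small_study):
        from cortisel.issa import fit_kernels

        kern = fit_kernels(small_study.used["length"].to_numpy(),
                           small_study.used["turn"].to_numpy())
        design = build_design(small_study.used.head(40), small_study.landscape,
                              kern, K=3, seed=5)
        np.testing.assert_allclose(design["dist_fgm"],
                                   design["dist_end"] * design["fgm_z"])
        np.testing.assert_allclose(design["dist_fgm_period"],
                                   design["dist_end"] * design["fgm_z"] * design["period"])
        np.testing.assert_allclose(design["dist_fgm_days"],
                                   design["dist_end"] * design["fgm_z"] * design["days_since"])

    def test_stratum_sizes_are_one_used_plus_K(self, small_study):
        from cortisel.issa import fit_kernels

        kern = fit_kernels(small_study.used["length"].to_numpy(),
                           small_study.used["turn"].to_numpy())
        design = build_design(small_study.used.head(30), small_study.landscape,
                              kern, K=7, seed=3)
        sizes = design.groupby("stratum")["used"].agg(["count", "sum"])
        assert (sizes["count"] == 8).all()
        assert (sizes["sum"] == 1).all()


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def naive_conditional_nll(beta, X, y, strata):
    """Independent brute-force conditional logistic likelihood (loops)."""
    nll = 0.0
    for s in np.unique(strata):
        m = strata == s
        eta = X[m] @ beta
        nll -= eta[y[m] == 1][0] - np.log(np.exp(eta).sum())
    return nll


@pytest.fixture(scope="module")
def toy_design():
    """10 strata, 2 covariates, known softmax-generated choices."""
    rng = np.random.default_rng(42)
    beta_true = np.array([-0.8, 0.5])
    rows = []
    for s in range(10):
        X = rng.normal(size=(6, 2))
        p = np.exp(X @ beta_true)
        p /= p.sum()
        used = rng.choice(6, p=p)
        for j in range(6):
            rows.append(dict(stratum=f"s{s}", used=int(j == used),
                             a=X[j, 0], b=X[j, 1]))
    return pd.DataFrame(rows)


class TestFitSsf:
    def test_clogit_matches_brute_force_likelihood_oracle(self, toy_design):
        fit = fit_ssf(toy_design, terms=["a", "b"], mode="clogit")
        X = toy_design[["a", "b"]].to_numpy()
        y = toy_design["used"].to_numpy()
        strata = toy_design["stratum"].to_numpy()
        res = optimize.minimize(naive_conditional_nll, np.zeros(2),
                                args=(X, y, strata), method="Nelder-Mead",
                                options=dict(xatol=1e-10, fatol=1e-12))
        np.testing.assert_allclose(fit.coef, res.x, atol=1e-5)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_poisson_trick_equals_clogit(self, toy_design):
        f1 = fit_ssf(toy_design, terms=["a", "b"], mode="clogit")
        f2 = fit_ssf(toy_design, terms=["a", "b"], mode="poisson_trick")
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-5)
        np.testing.assert_allclose(f1.se, f2.se, rtol=1e-4)

    def test_poisson_trick_equals_clogit_on_simulated_study(self, small_study):
        from cortisel.recovery import refit_study

        f1 = refit_study(small_study, K=10, seed=3, mode="clogit")
        f2 = refit_study(small_study, K=10, seed=3, mode="poisson_trick")
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-5)

    def test_null_data_estimates_within_three_se(self):
        rng = np.random.default_rng(7)
        rows = []
        for s in range(500):
            X = rng.normal(size=(5, 2))
            used = rng.integers(5)  # uniform choice: beta = 0
            for j in range(5):
                rows.append(dict(stratum=s, used=int(j == used),
                                 a=X[j, 0], b=X[j, 1]))
        fit = fit_ssf(pd.DataFrame(rows), terms=["a", "b"])
        assert (np.abs(fit.coef) < 3 * fit.se).all()

    def test_likelihood_is_local_maximum(self, toy_design):
        fit = fit_ssf(toy_design, terms=["a", "b"])
        X = toy_design[["a", "b"]].to_numpy()
        y = toy_design["used"].to_numpy()
        strata = toy_design["stratum"].to_numpy()
        base = naive_conditional_nll(fit.coef, X, y, strata)
        rng = np.random.default_rng(0)
        for _ in range(20):
            pert = fit.coef + rng.normal(0, 0.05, size=2)
            assert naive_conditional_nll(pert, X, y, strata) >= base - 1e-10

    def test_stratum_constant_covariate_leaves_other_terms_unchanged(self, toy_design):
        df = toy_design.copy()
        rng = np.random.default_rng(1)
        const = {s: rng.normal() for s in df["stratum"].unique()}
        df["c"] = df["stratum"].map(const)
        f_base = fit_ssf(toy_design, terms=["a", "b"])
        # a stratum-constant covariate cannot enter the conditional
        # likelihood: it is dropped (NaN coefficient) and the remaining
        # coefficients are exactly unchanged
        with pytest.warns(UserWarning, match="stratum-constant"):
            f_aug = fit_ssf(df, terms=["a", "b", "c"])
        assert np.isnan(f_aug.coef[2])
        np.testing.assert_allclose(f_aug.coef[:2], f_base.coef, atol=1e-8)

    def test_duplicated_column_reported_as_collinear(self, toy_design):
        df = toy_design.copy()
        df["a2"] = df["a"]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_ssf(df, terms=["a", "b", "a2"])

    def test_separation_flagged_as_nonconverged(self):
        rows = []
        rng = np.random.default_rng(9)
        for s in range(30):
            x = rng.normal(size=5)
            used = int(np.argmax(x))  # perfectly separable
            for j in range(5):
                rows.append(dict(stratum=s, used=int(j == used), a=x[j]))
        fit = fit_ssf(pd.DataFrame(rows), terms=["a"])
        assert not fit.converged

    def test_stratum_without_used_row_rejected(self, toy_design):
        df = toy_design.copy()
        df.loc[df["stratum"] == "s0", "used"] = 0
        with pytest.raises(ValueError, match="exactly one used"):
            fit_ssf(df, terms=["a", "b"])

    def test_ci_and_exp_scale_outputs(self, toy_design):
        fit = fit_ssf(toy_design, terms=["a", "b"])
        assert (fit.ci_low < fit.coef).all() and (fit.coef < fit.ci_high).all()
        np.testing.assert_allclose(fit.exp_coef, np.exp(fit.coef))
        w = np.linalg.eigvalsh(fit.vcov)
        assert (w > 0).all()
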