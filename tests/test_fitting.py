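"""Weighted least squares, profile likelihood and model comparison."""

import numpy as np
import pandas as pd
import pytest

from mbw.fitting import (
    FitResult,
    chi_squared,
    compare_models,
    fit_alpha,
    fit_competition,
    fit_hill,
    fit_kd,
    predict_curve,
    profile_ci,
    saturation_normalize_dataset,
)
from mbw.synthetic_data import SyntheticConfig, generate, generate_competition_suite

DESIGN = tuple(np.geomspace(0.25, 4.0, 29)) + (100.0,)


def single_dataset(kd, noise=0.0, seed=0, **kw):
    cfg = SyntheticConfig(
        model="single",
        params={"kd": kd},
        prey_ratios=DESIGN,
        noise=noise,
        seed=seed,
        technical_replicates=1,
        biological_replicates=1,
        noisy_normalizer=False,
        **kw,
    )
    return generate(cfg)


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def test_chi_squared_values():
    assert chi_squared([1.0, 2.0], [1.0, 2.0], [0.1, 0.2]) == 0.0
    assert chi_squared([3.0], [1.0], [1.0]) == 4.0
    y = [1.0, 0.0, 3.0]
    f = [0.0, 1.0, 1.0]
    s = [1.0, 2.0, 4.0]
    assert chi_squared(y, f, s, "sigma") == pytest.approx(1 + 0.5 + 1)
    assert chi_squared(y, f, s, "variance") == pytest.approx(1 + 0.25 + 0.25)


def test_chi_squared_validation():
    with pytest.raises(ValueError):
        chi_squared([1.0], [1.0], [0.0])
    with pytest.raises(ValueError):
        chi_squared([1.0, 2.0], [1.0], [1.0])
    with pytest.raises(ValueError):
        chi_squared([1.0], [1.0], [1.0], weighting="bogus")


# ---------------------------------------------------------------------------
# profile confidence intervals
# ---------------------------------------------------------------------------

def _quadratic_fit(grid):
    chis = (grid - 1.0) ** 2
    return FitResult(
        model="single",
        estimates={"kd": 1.0},
        chi2_min=0.0,
        rss=0.0,
        n_points=10,
        sigma=np.ones(10),
        profiles={"kd": np.column_stack([grid, chis])},
    )


def test_profile_ci_quadratic_closed_form():
    grid = np.geomspace(1e-3, 1e3, 20001)
    fit = _quadratic_fit(grid)
    lo, hi, ident = profile_ci(
        fit, "kd", 0.95, objective=lambda v: (v - 1.0) ** 2
    )
    # upper crossing of (theta-1)^2 = 3.841; the lower crossing at
    # 1 - sqrt(3.841) < 0 lies outside the positive scan range, so the
    # lower bound is non-identifiable there
    assert hi == pytest.approx(1 + np.sqrt(3.8415), abs=1e-3)
    assert lo == -np.inf and not ident
    lo2, hi2, ident2 = profile_ci(fit, "kd", 0.68, objective=lambda v: (v - 1.0) ** 2)
    assert ident2
    assert lo2 == pytest.approx(1 - np.sqrt(0.9889), abs=1e-3)
    assert hi2 == pytest.approx(1 + np.sqrt(0.9889), abs=1e-3)


def test_profile_ci_flat_left_plateau_non_identifiable():
    grid = np.geomspace(1e-3, 1e3, 501)
    chis = np.where(grid < 1.0, 0.5, 0.5 + 20 * np.log(grid) ** 2)
    fit = _quadratic_fit(grid)
    fit.profiles["kd"] = np.column_stack([grid, chis])
    fit.chi2_min = 0.5
    lo, hi, ident = profile_ci(fit, "kd", 0.95)
    assert not ident
    assert lo == -np.inf
    assert np.isfinite(hi)


def test_profile_ci_unknown_param():
    fit = _quadratic_fit(np.geomspace(0.1, 10, 11))
    with pytest.raises(KeyError):
        profile_ci(fit, "alpha")


# ---------------------------------------------------------------------------
# single-site K_D fitting
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kd_true", [1.0, 0.5])
def test_fit_kd_noiseless_recovery(kd_true):
    fit = fit_kd(single_dataset(kd_true))
    assert fit.estimates["kd"] == pytest.approx(kd_true, abs=1e-4)
    assert fit.identifiable["kd"]


def test_fit_kd_scale_invariance():
    """An overall scale on raw signals cancels in saturation normalization,
    leaving the estimate unchanged."""
    ds = single_dataset(1.3, noise=0.05, seed=5)
    fit1 = fit_kd(saturation_normalize_dataset(ds), seed=0)
    scaled = ds.assign(signal=3.7 * ds.signal, signal_sd=3.7 * ds.signal_sd)
    a, b = saturation_normalize_dataset(ds), saturation_normalize_dataset(scaled)
    assert np.allclose(a.signal, b.signal, rtol=1e-12)
    fit2 = fit_kd(b, seed=0)
    assert fit2.estimates["kd"] == pytest.approx(fit1.estimates["kd"], rel=1e-4)


def test_fit_kd_profile_monotone_away_from_minimum():
    fit = fit_kd(single_dataset(1.0))
    prof = fit.profiles["kd"]
    imin = int(np.argmin(prof[:, 1]))
    assert np.all(np.diff(prof[: imin + 1, 1]) <= 1e-9)
    assert np.all(np.diff(prof[imin:, 1]) >= -1e-9)


def test_fit_kd_estimator_consistency():
    """Error of the K_D estimate shrinks as the design grows."""
    kd_true = 1.0
    rmse = {}
    for n in (10, 30, 100):
        design = tuple(np.geomspace(0.25, 4.0, n - 1)) + (100.0,)
        ests = []
        for rep in range(30):
            cfg = SyntheticConfig(
                model="single",
                params={"kd": kd_true},
                prey_ratios=design,
                noise=0.05,
                seed=900 + rep,
                technical_replicates=1,
                biological_replicates=1,
                noisy_normalizer=False,
            )
            f = fit_kd(generate(cfg), n_starts=4, seed=rep, profile_points=2)
            ests.append(f.estimates["kd"])
        err = np.array(ests) - kd_true
        rmse[n] = float(np.sqrt(np.mean(err**2)))
    assert rmse[100] < rmse[30] < rmse[10]
    assert abs(np.mean(err)) < 0.02  # essentially unbiased at n=100


def test_fit_kd_warns_on_sparse_design():
    cfg = SyntheticConfig(
        model="single",
        params={"kd": 1.0},
        prey_ratios=(0.5, 1.0, 100.0),
        noise=0.0,
        technical_replicates=1,
        biological_replicates=1,
    )
    with pytest.warns(UserWarning, match="distinct ratio"):
        fit_kd(generate(cfg))


# ---------------------------------------------------------------------------
# cooperativity fitting
# ---------------------------------------------------------------------------

def competition_suite(alpha, model="cooperative", noise=0.03, seed=7, kds=None):
    if kds is None:
        kds = {"kd_prey": 1.0, "kd_comp": 0.5}
        if model == "dimer-network":
            kds["kd_dimer"] = 0.5
    return generate_competition_suite(
        alpha,
        kds,
        competitor_ratios=(2.0, 1.0),
        config=SyntheticConfig(
            model=model,
            prey_ratios=DESIGN,
            noise=noise,
            seed=seed,
            technical_replicates=1,
            biological_replicates=1,
            prey="TTG1",
            competitor="GL1",
        ),
    )


TRIMER_BOUNDS = {"kd_prey": (0.8, 1.2), "kd_comp": (0.4, 0.6)}


def test_fit_alpha_independent_binding():
    suite = competition_suite(1.0, noise=0.0)
    fit = fit_alpha(suite, kd_bounds=TRIMER_BOUNDS, profile_points=2)
    assert fit.estimates["alpha"] == pytest.approx(1.0, abs=0.02)


def test_fit_alpha_recovery_within_ci():
    suite = competition_suite(0.2, noise=0.03, seed=7)
    fit = fit_alpha(
        suite, kd_bounds=TRIMER_BOUNDS, weighting="variance", profile_points=41
    )
    lo, hi, level = fit.ci["alpha"]
    assert level == 0.95
    assert lo <= 0.2 <= hi
    assert fit.estimates["alpha"] == pytest.approx(0.2, abs=0.08)


def test_fit_alpha_requires_bounds_and_data():
    with pytest.raises(ValueError):
        fit_alpha([], kd_bounds=TRIMER_BOUNDS)
    with pytest.raises(ValueError):
        fit_alpha(competition_suite(0.5, noise=0.0), kd_bounds={"kd_prey": (0.8, 1.2)})


def test_fit_competition_fixed_parameters():
    """Equal bounds pin a parameter; only the rest are optimized."""
    suite = competition_suite(0.4, model="dimer-network", noise=0.0, seed=3)
    fit = fit_competition(
        suite,
        "dimer-network",
        {
            "alpha": (1e-3, 1e2),
            "kd_prey": (1.0, 1.0),
            "kd_comp": (0.5, 0.5),
            "kd_dimer": (0.5, 0.5),
        },
        n_starts=4,
    )
    assert fit.estimates["kd_prey"] == 1.0
    assert fit.estimates["alpha"] == pytest.approx(0.4, abs=5e-3)


def test_weak_information_flags_lower_bound_non_identifiable():
    """Strong negative cooperativity data: decreasing alpha below the
    estimate barely changes the curve, so the chi2 profile plateaus and the
    lower confidence bound never crosses the threshold."""
    suite = competition_suite(0.005, noise=0.03, seed=2)
    fit = fit_alpha(
        suite, kd_bounds=TRIMER_BOUNDS, weighting="variance",
        profile_points=41, alpha_bounds=(1e-6, 1e2),
    )
    lo, hi, _ = fit.ci["alpha"]
    assert not fit.identifiable["alpha"]
    assert lo == -np.inf
    assert np.isfinite(hi)


# ---------------------------------------------------------------------------
# Hill fit and model comparison
# ---------------------------------------------------------------------------

def test_fit_hill_recovers_orders():
    rng = np.random.default_rng(0)
    x = np.geomspace(0.1, 5, 40)
    z = np.ones_like(x)
    true = predict_curve(
        "hill",
        {"a": 1.0, "b": 0.0, "c": 0.5, "d": 2.0, "n": 1, "m": 4},
        x,
        1.0,
        normalize=False,
    )
    ds = pd.DataFrame({"prey_ratio": x, "competitor_ratio": z, "signal": true})
    fit = fit_hill(ds, orders=(1, 2, 4, 6))
    assert fit.rss < 1e-10
    assert int(fit.estimates["m"]) == 4


def test_compare_models_tie_broken_by_parameter_count():
    base = dict(chi2_min=1.0, rss=1.0, n_points=10, sigma=np.ones(10),
                data_digest="abc")
    small = FitResult(model="competitive", estimates={"k1": 1, "k2": 1}, **base)
    big = FitResult(
        model="cooperative", estimates={"k1": 1, "k2": 1, "a": 1}, **base
    )
    cmp = compare_models([("cooperative", big), ("competitive", small)])
    assert cmp.best == "competitive"
    assert cmp.table.aic.iloc[0] < cmp.table.aic.iloc[1]


def test_compare_models_requires_same_data():
    a = FitResult(model="m1", estimates={"k": 1}, chi2_min=1, rss=1, n_points=5,
                  sigma=np.ones(5), data_digest="aaa")
    b = FitResult(model="m2", estimates={"k": 1}, chi2_min=1, rss=1, n_points=5,
                  sigma=np.ones(5), data_digest="bbb")
    with pytest.raises(ValueError):
        compare_models([("m1", a), ("m2", b)])


def test_cooperative_beats_competitive_on_cooperative_data():
    suite = competition_suite(0.2, noise=0.03, seed=21)
    coop = fit_competition(
        suite, "cooperative", {**TRIMER_BOUNDS, "alpha": (1e-3, 1e2)}, n_starts=4
    )
    comp = fit_competition(suite, "competitive", TRIMER_BOUNDS, n_starts=4)
    ranked = compare_models([("cooperative", coop), ("competitive", comp)], "aic")
    assert ranked.best == "cooperative"


def test_inhibitor_extension_beats_competitive_on_sequestration_data():
    kds = {"kd_prey": 0.5, "kd_comp": 2.7, "kd_cross": 1.0}
    suite = generate_competition_suite(
        0.0,
        kds,
        competitor_ratios=(1.0,),
        config=SyntheticConfig(
            model="inhibitor",
            prey_ratios=DESIGN,
            noise=0.03,
            seed=4,
            technical_replicates=1,
            biological_replicates=1,
            prey="GL1",
            competitor="TRY",
        ),
    )
    bounds = {"kd_prey": (0.4, 0.6), "kd_comp": (2.4, 3.0)}
    ext = fit_competition(
        suite, "inhibitor", {**bounds, "kd_cross": (1e-2, 1e2)}, n_starts=4
    )
    comp = fit_competition(suite, "competitive", bounds, n_starts=4)
    assert ext.rmse < comp.rmse
    ranked = compare_models([("inhibitor", ext), ("competitive", comp)], "rmse")
    assert ranked.best == "inhibitor"
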