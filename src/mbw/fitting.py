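"""Weighted least-squares estimation with profile-likelihood identifiability.

The agreement between a titration dataset and a binding model is scored by
the weighted sum of squared residuals

    chi2(theta) = sum_i (y_i - f(x_i, theta))^2 / sigma_i

which divides each squared residual by sigma_i (the per-point measurement
error) - this is the convention used in the original analysis and the
package default.  The conventional variance weighting (division by
sigma_i^2, under which chi2 is the proper -2 log-likelihood of Gaussian
errors) is available via ``weighting="variance"`` and is the right choice
whenever calibrated confidence intervals are needed.

Confidence intervals come from the chi2 profile: the interval at confidence
level q is the set of parameter values whose profile chi2 stays within
Delta_q of the minimum, where Delta_q is the q-quantile of the chi2
distribution with one degree of freedom (3.841 at 95%, 0.989 at 68%).  A
parameter is *identifiable* when both crossings exist within the scanned
range; a profile that stays below the threshold out to the scan limit marks
the corresponding bound as non-identifiable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .binding_models import (
    SATURATION_RATIO,
    HillModelParams,
    competitive_bound,
    hill_signal,
    single_site_complex,
)
from .reaction_network import solve_conservation

__all__ = [
    "FitResult",
    "ModelComparison",
    "chi_squared",
    "predict_curve",
    "fit_kd",
    "fit_competition",
    "fit_alpha",
    "fit_hill",
    "profile_ci",
    "saturation_normalize_dataset",
    "compare_models",
    "MODELS",
]

MODELS = ("single", "competitive", "cooperative", "inhibitor", "dimer-network", "hill")

_PROFILE_POINTS = 201
_PROFILE_SPAN = 1e3
_KD_START_RANGE = (1e-2, 1e2)
_N_STARTS = 16


# ---------------------------------------------------------------------------
# chi-squared and model curves
# ---------------------------------------------------------------------------

def chi_squared(y, f, sigma, weighting: str = "sigma") -> float:
    """Weighted sum of squared residuals.

    ``weighting="sigma"`` divides squared residuals by sigma_i (the package
    default); ``"variance"`` divides by sigma_i^2.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    s = np.asarray(sigma, dtype=float)
    if y.shape != f.shape:
        raise ValueError("data and model curves have different lengths")
    s = np.broadcast_to(s, y.shape)
    if np.any(s <= 0):
        raise ValueError("measurement errors must be strictly positive")
    r2 = (y - f) ** 2
    if weighting == "sigma":
        return float(np.sum(r2 / s))
    if weighting == "variance":
        return float(np.sum(r2 / s**2))
    raise ValueError(f"unknown weighting {weighting!r}")


def _free_from_weights(comp, weights, y0, z0):
    """Free (x, y, z) of a three-protein speciation problem, batched.

    The system is defined by its species' protein content ``comp`` and
    thermodynamic weights; totals are (1, y0, z0) per titration point.
    """
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    z0 = np.broadcast_to(np.asarray(z0, dtype=float), y0.shape)
    T = np.stack([np.ones_like(y0), y0, z0], axis=-1)
    free = solve_conservation(np.asarray(comp, float), np.asarray(weights, float), T)
    return free[:, 0], free[:, 1], free[:, 2]


def _trimer_species(y0, z0, k1, k2, alpha):
    """Vectorized cooperative-trimer equilibrium; returns (x, y, z) free."""
    comp = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1), (1, 1, 1)]
    weights = [1, 1, 1, 1 / k1, 1 / k2, alpha / (k1 * k2)]
    return _free_from_weights(comp, weights, y0, z0)


def _inhibitor_species(y0, z0, k1, k2, k3):
    comp = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1)]
    weights = [1, 1, 1, 1 / k1, 1 / k2, 1 / k3]
    return _free_from_weights(comp, weights, y0, z0)


def _dimer_network_structure():
    """Species content and per-subunit weight exponents of the 22-species
    network (bait GL3 with prey on the WD site, competitor on the MYB site).

    Returns (comp, weight_fn) where weight_fn(k_prey, k_comp, k_dimer, alpha)
    gives the thermodynamic weights in the same species order.  Equivalent to
    the weights :func:`mbw.reaction_network.build_network` derives by walking
    the reaction graph (asserted in the test suite); duplicated here in
    closed form so fit objectives avoid re-enumerating reactions.
    """
    # subunit states: (competitor on MYB site?, prey on WD site?)
    states = [(0, 0), (1, 0), (0, 1), (1, 1)]
    comp = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]  # free GL3*, prey, competitor
    kinds: list[tuple] = [("free",), ("free",), ("free",)]
    for c, p in states[1:]:
        comp.append((1, p, c))
        kinds.append(("mono", (c, p)))
    for s1 in states:
        for s2 in states:
            comp.append((2, s1[1] + s2[1], s1[0] + s2[0]))
            kinds.append(("dimer", s1, s2))
    # note: "free GL3" above is the empty monomer scaffold; comp[0] fixes it

    def weight_fn(k_prey, k_comp, k_dimer, alpha):
        def u(state):
            c, p = state
            w = 1.0
            if c:
                w /= k_comp
            if p:
                w /= k_prey
            if c and p:
                w *= alpha
            return w

        out = []
        for kind in kinds:
            if kind[0] == "free":
                out.append(1.0)
            elif kind[0] == "mono":
                out.append(u(kind[1]))
            else:
                out.append(u(kind[1]) * u(kind[2]) / k_dimer)
        return np.array(out)

    return np.array(comp, dtype=float), weight_fn


_DIMER_COMP, _DIMER_WEIGHTS = _dimer_network_structure()


def _raw_signal(model: str, params: Mapping[str, float], y0, z0):
    """Un-normalized bound-prey signal at prey ratios ``y0``, competitor ``z0``."""
    y0 = np.asarray(y0, dtype=float)
    if model == "single":
        return single_site_complex(y0, params["kd"])
    if model == "competitive":
        return competitive_bound(y0, z0, params["kd_prey"], params["kd_comp"])
    if model == "cooperative":
        k1, k2, al = params["kd_prey"], params["kd_comp"], params["alpha"]
        x, y, z = _trimer_species(y0, z0, k1, k2, al)
        return x * y / k1 + al * x * y * z / (k1 * k2)  # prey in dimer and trimer
    if model == "inhibitor":
        k1, k2, k3 = params["kd_prey"], params["kd_comp"], params["kd_cross"]
        x, y, z = _inhibitor_species(y0, z0, k1, k2, k3)
        return x * y / k1  # only the bait-bound prey is pulled down
    if model == "dimer-network":
        weights = _DIMER_WEIGHTS(
            params["kd_prey"], params["kd_comp"], params["kd_dimer"], params["alpha"]
        )
        _, free_prey, _ = _free_from_weights(_DIMER_COMP, weights, y0, z0)
        # prey bound to the bait scaffold = total prey minus free prey
        return y0 - free_prey
    if model == "hill":
        hp = params if isinstance(params, HillModelParams) else HillModelParams(
            a=params["a"],
            b=params["b"],
            c=params["c"],
            d=params["d"],
            n=int(params["n"]),
            m=int(params["m"]),
        )
        return hill_signal(y0, np.broadcast_to(np.asarray(z0, float), y0.shape), hp)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def predict_curve(
    model: str,
    params: Mapping[str, float],
    prey_ratios,
    competitor_ratio: float = 0.0,
    normalize: bool = True,
    saturation_ratio: float = SATURATION_RATIO,
):
    """Saturation-normalized model curve at the given prey:bait ratios.

    The curve is divided by the model value at ``saturation_ratio`` (same
    competitor amount), mirroring the normalization of the measured signals
    by the signal at saturating prey.
    """
    y0 = np.atleast_1d(np.asarray(prey_ratios, dtype=float))
    if not normalize:
        return _raw_signal(model, params, y0, competitor_ratio)
    full = np.concatenate([y0, [saturation_ratio]])
    raw = _raw_signal(model, params, full, competitor_ratio)
    c_max = raw[-1]
    if not c_max > 0:
        raise ValueError("model curve is identically zero; cannot normalize")
    return raw[:-1] / c_max


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Estimate, chi2 profile, confidence interval and identifiability."""

    model: str
    estimates: dict[str, float]
    chi2_min: float
    rss: float
    n_points: int
    sigma: np.ndarray = field(repr=False)
    weighting: str = "sigma"
    level: float = 0.95
    df: int = 1
    profiles: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    ci: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    identifiable: dict[str, bool] = field(default_factory=dict)
    data_digest: str = ""

    @property
    def n_params(self) -> int:
        return len(self.estimates)

    @property
    def rmse(self) -> float:
        return float(np.sqrt(self.rss / self.n_points))

    def aic(self) -> float:
        """AIC under the n ln(RSS/n) + 2k convention."""
        return float(self.n_points * np.log(self.rss / self.n_points)) + 2.0 * self.n_params

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": self.estimates,
            "chi2_min": self.chi2_min,
            "rss": self.rss,
            "rmse": self.rmse,
            "aic": self.aic(),
            "n_points": self.n_points,
            "weighting": self.weighting,
            "level": self.level,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "identifiable": self.identifiable,
            "profiles": {k: np.asarray(v).tolist() for k, v in self.profiles.items()},
        }


@dataclass
class ModelComparison:
    """Cross-model goodness-of-fit table with a deterministic ranking."""

    table: pd.DataFrame
    criterion: str
    aic_convention: str = "n*ln(RSS/n) + 2k"

    @property
    def ranking(self) -> list[str]:
        return list(self.table["model"])

    @property
    def best(self) -> str:
        return self.ranking[0]


# ---------------------------------------------------------------------------
# sigma resolution
# ---------------------------------------------------------------------------

def _resolve_sigma(data: pd.DataFrame) -> np.ndarray | None:
    """Per-point measurement errors.

    Preference order: explicit positive ``signal_sd``; replicate standard
    deviation within each design point; otherwise ``None`` (a constant error
    is then fitted from the residuals).
    """
    if "signal_sd" in data and np.all(np.asarray(data["signal_sd"]) > 0):
        return np.asarray(data["signal_sd"], dtype=float)
    group_cols = [
        c for c in ("prey_ratio", "competitor_ratio") if c in data.columns
    ]
    if "replicate" in data.columns and group_cols:
        sd = data.groupby(group_cols)["signal"].transform("std")
        if sd.notna().all() and (sd > 0).all():
            return np.asarray(sd, dtype=float)
    return None


def saturation_normalize_dataset(data: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw signals by the measured saturation signal.

    Divides ``signal`` (and ``signal_sd``) by the mean measured signal at the
    saturation design point - the largest prey ratio - within each biological
    replicate: the assay's normalization convention.  Any overall scale
    applied to raw signals cancels, so fits on the normalized output are
    scale invariant.  Fit functions expect data in this convention (the
    synthetic generator emits it directly).
    """
    out = data.copy()
    x = np.asarray(out["prey_ratio"], dtype=float)
    y = np.array(out["signal"], dtype=float)
    sd = (
        np.array(out["signal_sd"], dtype=float)
        if "signal_sd" in out.columns
        else None
    )
    if "replicate" in out.columns:
        bio = out["replicate"].astype(str).str.split("_").str[0].to_numpy()
    else:
        bio = np.zeros(len(y))
    for group in pd.unique(bio):
        mask = bio == group
        sat = mask & (x >= 0.999 * x[mask].max())
        norm = float(np.mean(y[sat]))
        if norm <= 0:
            raise ValueError("saturation signal must be positive to normalize")
        y[mask] = y[mask] / norm
        if sd is not None:
            sd[mask] = sd[mask] / norm
    out["signal"] = y
    if sd is not None:
        out["signal_sd"] = sd
    return out


def _constant_sigma(y, model_curve):
    resid = np.asarray(y) - np.asarray(model_curve)
    n = max(len(resid) - 1, 1)
    const = float(np.sqrt(np.sum(resid**2) / n))
    return np.full(len(resid), max(const, 1e-12))


# ---------------------------------------------------------------------------
# profiles and confidence intervals
# ---------------------------------------------------------------------------

def _delta(level: float, df: int = 1) -> float:
    return float(stats.chi2.ppf(level, df))


def profile_ci(
    fit: FitResult, param: str, level: float = 0.95, objective=None
) -> tuple[float, float, bool]:
    """Confidence bounds from the stored chi2 profile.

    Bounds are where the profile crosses ``chi2_min + Delta_level`` (one
    degree of freedom), refined by root finding when the profile
    ``objective`` callable is supplied.  A profile that never crosses on one
    side within the scanned range leaves that bound non-identifiable
    (returned as -inf/+inf); the parameter is identifiable only if both
    bounds are finite.
    """
    if param not in fit.profiles:
        raise KeyError(f"no profile stored for parameter {param!r}")
    prof = np.asarray(fit.profiles[param])
    lo, hi, lo_ok, hi_ok = _ci_bounds(
        prof[:, 0], prof[:, 1], fit.chi2_min, _delta(level, fit.df), objective
    )
    if not lo_ok:
        lo = -np.inf
    if not hi_ok:
        hi = np.inf
    return lo, hi, bool(lo_ok and hi_ok)


def _profile_grid(estimate: float, span: float, points: int) -> np.ndarray:
    return np.geomspace(estimate / span, estimate * span, points)


def _ci_bounds(grid, chis, chi2_min, delta, objective=None):
    """Threshold crossings of a profile, refined by root finding.

    The grid localizes each crossing to one bracket; when ``objective`` is
    given the bound is the exact root of chi2(theta) - (chi2_min + delta)
    inside that bracket (the log grid spans decades, so interpolation alone
    would misplace crossings that sit close to the minimum).
    """
    thr = min(chi2_min, float(np.min(chis))) + delta
    imin = int(np.argmin(chis))

    def scan(direction):
        idx = range(imin, 0, -1) if direction < 0 else range(imin, len(grid) - 1)
        for i in idx:
            j = i + direction
            if (chis[i] <= thr) and (chis[j] > thr):
                a, b = sorted((grid[i], grid[j]))
                if objective is not None:
                    from scipy.optimize import brentq

                    fa, fb = objective(a) - thr, objective(b) - thr
                    if fa == 0.0:
                        return float(a), True
                    if fb == 0.0:
                        return float(b), True
                    if fa * fb < 0:
                        return float(
                            brentq(lambda v: objective(v) - thr, a, b,
                                   xtol=1e-12, rtol=1e-10)
                        ), True
                    # nuisance re-optimization can shift the profile slightly
                    # relative to the stored grid; fall back to interpolation
                # log-space interpolation on the stored profile
                la, lb = np.log(grid[i]), np.log(grid[j])
                w = (thr - chis[i]) / (chis[j] - chis[i])
                return float(np.exp(la + w * (lb - la))), True
        return float(grid[0] if direction < 0 else grid[-1]), False

    lo, lo_ok = scan(-1)
    hi, hi_ok = scan(+1)
    return lo, hi, lo_ok, hi_ok


# ---------------------------------------------------------------------------
# single-K_D fit
# ---------------------------------------------------------------------------

def fit_kd(
    data: pd.DataFrame,
    model: str = "single",
    weighting: str = "sigma",
    level: float = 0.95,
    seed: int = 0,
    n_starts: int = _N_STARTS,
    profile_points: int = _PROFILE_POINTS,
    profile_span: float = _PROFILE_SPAN,
) -> FitResult:
    """Estimate a relative dissociation constant from a titration dataset.

    ``data`` uses the binding-dataset dialect (``prey_ratio``, ``signal``,
    optional ``signal_sd``/``replicate``).  The model curve and the data are
    both saturation-normalized.  Multi-start bounded optimization guards
    against local minima; the confidence interval at ``level`` comes from
    the chi2 profile on a log grid.
    """
    if model != "single":
        raise ValueError("fit_kd estimates the single-site model; use fit_alpha "
                         "for competition models")
    x = np.asarray(data["prey_ratio"], dtype=float)
    y = np.asarray(data["signal"], dtype=float)
    sigma_fixed = _resolve_sigma(data)
    n = len(y)
    if n < 5 or len(np.unique(x)) < 5:
        import warnings

        warnings.warn(
            "fewer than 5 distinct ratio points; the K_D estimate may be poorly "
            "constrained",
            stacklevel=2,
        )

    def curve(kd):
        return predict_curve("single", {"kd": kd}, x)

    def objective(log10kd, sigma):
        kd = 10.0 ** float(np.asarray(log10kd).ravel()[0])
        return chi_squared(y, curve(kd), sigma, weighting)

    rng = np.random.default_rng(seed)
    starts = rng.uniform(
        np.log10(_KD_START_RANGE[0]), np.log10(_KD_START_RANGE[1]), n_starts
    )
    sigma0 = sigma_fixed if sigma_fixed is not None else np.ones_like(y)
    best = None
    for s0 in starts:
        res = optimize.minimize(
            objective,
            x0=[s0],
            args=(sigma0,),
            method="L-BFGS-B",
            bounds=[(-4.0, 4.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimization starts failed")
    kd_hat = float(10.0 ** best.x[0])

    sigma = (
        sigma_fixed if sigma_fixed is not None else _constant_sigma(y, curve(kd_hat))
    )
    resid = y - curve(kd_hat)
    rss = float(np.sum(resid**2))
    chi2_min = chi_squared(y, curve(kd_hat), sigma, weighting)

    grid = _profile_grid(kd_hat, profile_span, profile_points)
    prof = np.array([[g, chi_squared(y, curve(g), sigma, weighting)] for g in grid])

    fit = FitResult(
        model=model,
        estimates={"kd": kd_hat},
        chi2_min=chi2_min,
        rss=rss,
        n_points=n,
        sigma=sigma,
        weighting=weighting,
        level=level,
        profiles={"kd": prof},
        data_digest=_digest(y),
    )
    lo, hi, ident = profile_ci(
        fit, "kd", level, objective=lambda g: chi_squared(y, curve(g), sigma, weighting)
    )
    fit.ci["kd"] = (lo, hi, level)
    fit.identifiable["kd"] = ident
    return fit


def _digest(y: np.ndarray) -> str:
    return hashlib.sha1(np.asarray(y, dtype=float).tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cooperativity fit across competition suites
# ---------------------------------------------------------------------------

_MODEL_PARAMS = {
    "competitive": ["kd_prey", "kd_comp"],
    "cooperative": ["alpha", "kd_prey", "kd_comp"],
    "inhibitor": ["kd_prey", "kd_comp", "kd_cross"],
    "dimer-network": ["alpha", "kd_prey", "kd_comp", "kd_dimer"],
}


def fit_competition(
    datasets: Sequence[pd.DataFrame],
    model: str,
    param_bounds: Mapping[str, tuple[float, float]],
    weighting: str = "sigma",
    level: float = 0.95,
    seed: int = 0,
    n_starts: int = _N_STARTS,
    profile: Sequence[str] = (),
    profile_points: int = _PROFILE_POINTS,
    profile_span: float = _PROFILE_SPAN,
) -> FitResult:
    """Joint weighted least-squares fit of a competition model.

    ``datasets`` each hold one competitor:bait ratio (their
    ``competitor_ratio`` column); the chi2 objective sums over all of them.
    ``param_bounds`` maps every model parameter to its allowed interval; an
    interval with equal endpoints fixes the parameter.  Parameters named in
    ``profile`` get a chi2 profile on a log grid, with all other free
    parameters re-optimized (warm-started) at every grid point, plus the
    derived confidence interval and identifiability flag at ``level``.
    """
    if len(datasets) == 0:
        raise ValueError("at least one competition dataset is required")
    if model not in _MODEL_PARAMS:
        raise ValueError(
            f"fit_competition supports {sorted(_MODEL_PARAMS)}, not {model!r}"
        )
    names = _MODEL_PARAMS[model]
    for name in names:
        if name not in param_bounds:
            raise ValueError(f"param_bounds must provide an interval for {name}")

    per_set = []
    for ds in datasets:
        z0 = float(np.asarray(ds["competitor_ratio"])[0])
        x = np.asarray(ds["prey_ratio"], dtype=float)
        y = np.asarray(ds["signal"], dtype=float)
        per_set.append((x, y, z0, _resolve_sigma(ds)))
    n = sum(len(y) for _, y, _, _ in per_set)

    fixed = {k: float(param_bounds[k][0]) for k in names
             if param_bounds[k][0] == param_bounds[k][1]}
    free = [k for k in names if k not in fixed]
    log_bounds = [tuple(np.log(param_bounds[k])) for k in free]

    def unpack(theta):
        params = dict(fixed)
        for name, t in zip(free, theta):
            params[name] = float(np.exp(t))
        return params

    def chi2_of(params, sigmas):
        total = 0.0
        for (x, y, z0, _), sg in zip(per_set, sigmas):
            f = predict_curve(model, params, x, z0)
            total += chi_squared(y, f, sg, weighting)
        return total

    def sigmas_for(params):
        out = []
        for x, y, z0, sigma in per_set:
            if sigma is not None:
                out.append(sigma)
            else:
                f = predict_curve(model, params, x, z0)
                const = float(np.sqrt(np.sum((y - f) ** 2) / max(len(y) - 1, 1)))
                out.append(np.full_like(y, max(const, 1e-12)))
        return out

    sigma0 = [s if s is not None else np.ones(len(y)) for (_, y, _, s) in per_set]
    mid = np.array([0.5 * (b[0] + b[1]) for b in log_bounds])
    rng = np.random.default_rng(seed)

    best = None
    if free:
        for i in range(n_starts):
            x0 = mid.copy()
            if i > 0:  # first start from the bound midpoints
                x0 = np.array(
                    [rng.uniform(b[0], b[1]) for b in log_bounds]
                )
            res = optimize.minimize(
                lambda th: chi2_of(unpack(th), sigma0),
                x0=x0,
                method="L-BFGS-B",
                bounds=log_bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError("all optimization starts failed")
        theta_hat = best.x
    else:
        theta_hat = np.empty(0)

    params_hat = unpack(theta_hat)
    sigmas = sigmas_for(params_hat)
    chi2_min = chi2_of(params_hat, sigmas)
    rss = 0.0
    for x, y, z0, _ in per_set:
        rss += float(np.sum((y - predict_curve(model, params_hat, x, z0)) ** 2))

    fit = FitResult(
        model=model,
        estimates=params_hat,
        chi2_min=chi2_min,
        rss=rss,
        n_points=n,
        sigma=np.concatenate(sigmas),
        weighting=weighting,
        level=level,
        data_digest=_digest(np.concatenate([y for _, y, _, _ in per_set])),
    )

    for pname in profile:
        if pname in fixed or profile_points < 2:
            continue
        others = [k for k in free if k != pname]
        other_bounds = [log_bounds[free.index(k)] for k in others]
        est = params_hat[pname]
        lo_b, hi_b = param_bounds[pname]
        lo_g, hi_g = max(lo_b, est / profile_span), min(hi_b, est * profile_span)
        # an estimate pinned at a bound still needs the full admissible range
        # scanned on the open side to locate the far threshold crossing
        if est <= lo_b * (1 + 1e-9):
            hi_g = hi_b
        if est >= hi_b / (1 + 1e-9):
            lo_g = lo_b
        grid = np.geomspace(lo_g, hi_g, profile_points)
        prof = np.empty((len(grid), 2))
        order = np.argsort(np.abs(np.log(grid) - np.log(params_hat[pname])))
        warm = [theta_hat[free.index(k)] for k in others]
        for rank in order:
            g = grid[rank]

            def nuisance_obj(th):
                params = dict(fixed)
                params[pname] = float(g)
                for name, t in zip(others, th):
                    params[name] = float(np.exp(t))
                return chi2_of(params, sigmas)

            if others:
                res = optimize.minimize(
                    nuisance_obj, x0=warm, method="L-BFGS-B", bounds=other_bounds
                )
                warm = list(res.x)
                prof[rank] = (g, res.fun)
            else:
                prof[rank] = (g, nuisance_obj([]))
        fit.profiles[pname] = prof

        def profile_objective(value, _warm=[list(theta_hat[free.index(k)] for k in others)]):
            params = dict(fixed)
            params[pname] = float(value)

            def obj(th):
                for name, t in zip(others, th):
                    params[name] = float(np.exp(t))
                return chi2_of(params, sigmas)

            if not others:
                return obj([])
            res = optimize.minimize(
                obj, x0=_warm[0], method="L-BFGS-B", bounds=other_bounds
            )
            _warm[0] = list(res.x)
            return float(res.fun)

        lo, hi, ident = profile_ci(fit, pname, level, objective=profile_objective)
        fit.ci[pname] = (lo, hi, level)
        fit.identifiable[pname] = ident
    return fit


def fit_alpha(
    datasets: Sequence[pd.DataFrame],
    kd_bounds: Mapping[str, tuple[float, float]],
    model: str = "cooperative",
    weighting: str = "sigma",
    level: float = 0.95,
    seed: int = 0,
    n_starts: int = _N_STARTS,
    profile_points: int = _PROFILE_POINTS,
    profile_span: float = _PROFILE_SPAN,
    alpha_bounds: tuple[float, float] = (1e-4, 1e2),
) -> FitResult:
    """Estimate the cooperativity parameter from competition titrations.

    The dissociation constants are nuisance parameters constrained to the
    intervals estimated from the single-binding experiments (``kd_bounds``,
    e.g. ``{"kd_prey": (0.8, 1.2), "kd_comp": (0.4, 0.6)}``; a dimer-network
    fit additionally takes ``kd_dimer``; an interval with equal endpoints
    fixes the constant).  Only the cooperativity parameter is profiled; at
    each profile point the constrained K_Ds are re-optimized.
    """
    if model not in ("cooperative", "dimer-network"):
        raise ValueError("fit_alpha supports the cooperative and dimer-network models")
    bounds = dict(kd_bounds)
    bounds["alpha"] = alpha_bounds
    return fit_competition(
        datasets,
        model,
        bounds,
        weighting=weighting,
        level=level,
        seed=seed,
        n_starts=n_starts,
        profile=("alpha",),
        profile_points=profile_points,
        profile_span=profile_span,
    )


# ---------------------------------------------------------------------------
# Hill-type saturation fit
# ---------------------------------------------------------------------------

def fit_hill(
    data: pd.DataFrame,
    orders: Sequence[int] = tuple(range(1, 13)),
    weighting: str = "sigma",
) -> FitResult:
    """Fit the Hill-type saturation model by least squares.

    The four term weights are estimated with non-negativity bounds; the two
    integer Hill orders are searched exhaustively over ``orders`` (default
    1..12) and the pair with the lowest residual sum of squares wins.
    """
    x = np.asarray(data["prey_ratio"], dtype=float)
    z = (
        np.asarray(data["competitor_ratio"], dtype=float)
        if "competitor_ratio" in data
        else np.zeros_like(x)
    )
    y = np.asarray(data["signal"], dtype=float)

    def residuals(coefs, n, m):
        hp = HillModelParams(*np.maximum(coefs, 0.0), n=n, m=m)
        return hill_signal(x, z, hp) - y

    best = None
    for n_h in orders:
        for m_h in orders:
            res = optimize.least_squares(
                residuals,
                x0=np.ones(4),
                bounds=(0.0, np.inf),
                args=(n_h, m_h),
                method="trf",
            )
            rss = float(np.sum(res.fun**2))
            key = (rss, n_h + m_h)
            if best is None or key < best[0]:
                best = (key, res.x, n_h, m_h)
    (rss, _), coefs, n_h, m_h = best
    params = HillModelParams(*coefs, n=n_h, m=m_h)
    sigma = _resolve_sigma(data)
    if sigma is None:
        sigma = _constant_sigma(y, hill_signal(x, z, params))
    chi2_min = chi_squared(y, hill_signal(x, z, params), sigma, weighting)
    return FitResult(
        model="hill",
        estimates={
            "a": params.a,
            "b": params.b,
            "c": params.c,
            "d": params.d,
            "n": float(n_h),
            "m": float(m_h),
        },
        chi2_min=chi2_min,
        rss=rss,
        n_points=len(y),
        sigma=sigma,
        weighting=weighting,
        data_digest=_digest(y),
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def compare_models(
    fits: Sequence[tuple[str, FitResult]], criterion: str = "aic"
) -> ModelComparison:
    """Rank fitted models on the same data by AIC or RMSE.

    AIC uses the n ln(RSS/n) + 2k convention (recorded in the output); ties
    are broken in favour of fewer parameters, then model name.
    """
    if criterion not in ("aic", "rmse"):
        raise ValueError("criterion must be 'aic' or 'rmse'")
    digests = {fit.data_digest for _, fit in fits}
    if len(digests) > 1:
        raise ValueError("model comparison requires fits on identical data")
    rows = []
    for name, fit in fits:
        rows.append(
            {
                "model": name,
                "rmse": fit.rmse,
                "aic": fit.aic(),
                "n_params": fit.n_params,
                "n_points": fit.n_points,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        [criterion, "n_params", "model"], kind="mergesort"
    )
    return ModelComparison(table=table.reset_index(drop=True), criterion=criterion)
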