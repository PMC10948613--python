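"""Equilibrium binding models for GL3-centred protein interactions.

All models describe closed systems at thermodynamic equilibrium, written in
the normalized (dimensionless) convention used throughout the package: every
concentration is divided by the total amount of the bait protein GL3, so the
bait total is 1, prey/competitor amounts enter as molar ratios (``y0_bar``,
``z0_bar``) and dissociation constants are *relative* dissociation constants
(``kd_bar`` = K_D / [GL3]_total).  This is the natural parameterization for
pull-down assays in which absolute concentrations are unknown but ratios are
measured (e.g. by quantitative Western blot).

Models
------
single site
    One prey ``y`` binding one bait ``x``; the bound complex has a closed
    form (the physical root of the mass-balance quadratic).
competitive
    Two ligands ``y`` and ``z`` competing for a single site on ``x``; the
    bound fraction has an exact trigonometric closed form (the real root of
    the mass-balance cubic).
cooperative trimer
    ``y`` and ``z`` bind distinct sites on ``x`` and may be bound
    simultaneously; the second binding event sees its dissociation constant
    divided by a cooperativity parameter ``alpha`` (alpha < 1: negative
    cooperativity, alpha = 1: independent sites, alpha > 1: positive).
inhibitor extension
    Competitive model plus direct ``y``-``z`` association (the prey is
    sequestered by the competitor in solution).
Hill-type saturation
    A phenomenological saturation function allowing higher-order prey
    stoichiometry, used for model comparison when mechanistic models
    underfit S-shaped titration curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import root

__all__ = [
    "SATURATION_RATIO",
    "RelativeKD",
    "CooperativityRegime",
    "CooperativityAlpha",
    "TrimerState",
    "HillModelParams",
    "single_site_complex",
    "saturation_normalize",
    "single_site_curve",
    "competitive_bound",
    "cooperative_trimer_equilibrium",
    "inhibitor_equilibrium",
    "hill_signal",
]

#: Prey:bait ratio treated as the saturation point when normalizing model
#: curves.  At this ratio the bound fraction exceeds 99% of its asymptote for
#: every relative K_D at or below ~3, which covers all estimates handled here.
SATURATION_RATIO = 100.0

_CONSERVATION_RTOL = 1e-9


class CooperativityRegime(str, Enum):
    """Qualitative interpretation of the cooperativity parameter."""

    negative = "negative"
    independent = "independent"
    positive = "positive"


@dataclass(frozen=True)
class RelativeKD:
    """A dimensionless dissociation constant (K_D over total bait) with its
    95% confidence bounds."""

    value: float
    lower95: float = float("nan")
    upper95: float = float("nan")

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"relative K_D must be positive, got {self.value}")
        if math.isfinite(self.lower95) and math.isfinite(self.upper95):
            if not (self.lower95 <= self.value <= self.upper95):
                raise ValueError("confidence bounds must bracket the estimate")


@dataclass(frozen=True)
class CooperativityAlpha:
    """Multiplicative modifier of a K_D once the partner site is occupied."""

    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"cooperativity must be non-negative, got {self.value}")

    @property
    def regime(self) -> CooperativityRegime:
        if self.value < 1:
            return CooperativityRegime.negative
        if self.value == 1:
            return CooperativityRegime.independent
        return CooperativityRegime.positive


@dataclass(frozen=True)
class TrimerState:
    """Equilibrium speciation of a three-protein system (normalized units).

    ``xyz`` is populated by the cooperative model, ``yz`` by the inhibitor
    extension; the unused species is zero in each case.
    """

    free_x: float
    free_y: float
    free_z: float
    xy: float
    xz: float
    yz: float = 0.0
    xyz: float = 0.0

    def totals(self) -> tuple[float, float, float]:
        """Recovered (x0, y0, z0) totals implied by the speciation."""
        x0 = self.free_x + self.xy + self.xz + self.xyz
        y0 = self.free_y + self.xy + self.yz + self.xyz
        z0 = self.free_z + self.xz + self.yz + self.xyz
        return x0, y0, z0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.free_x, self.free_y, self.free_z, self.xy, self.xz, self.yz, self.xyz]
        )


@dataclass(frozen=True)
class HillModelParams:
    """Coefficients of the saturation function with higher-order prey terms.

    ``n`` and ``m`` are integer Hill orders of the prey on its own and in the
    ternary term; ``a``..``d`` are non-negative weights of the four binding
    terms (monomeric, homo-oligomeric, ternary, higher-order ternary).
    """

    a: float
    b: float
    c: float
    d: float
    n: int
    m: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("Hill coefficients must be non-negative")
        if self.n < 1 or self.m < 1:
            raise ValueError("Hill orders must be integers >= 1")


# ---------------------------------------------------------------------------
# single-site model
# ---------------------------------------------------------------------------

def single_site_complex(y0_bar, kd_bar):
    """Bound-complex fraction c/x0 for single-site reversible binding.

    The mass balance at equilibrium gives a quadratic in the complex; the
    physical branch is the smaller root (the larger one exceeds the totals).

    Parameters
    ----------
    y0_bar : float or array
        Prey:bait molar ratio (total prey over total bait), >= 0.
    kd_bar : float or array
        Relative dissociation constant, >= 0 (0 is the stoichiometric limit).

    Returns
    -------
    float or ndarray
        Complex amount as a fraction of total bait, in [0, min(1, y0_bar)].
    """
    y0 = np.asarray(y0_bar, dtype=float)
    kd = np.asarray(kd_bar, dtype=float)
    if np.any(y0 < 0) or np.any(kd < 0):
        raise ValueError("y0_bar and kd_bar must be non-negative")
    s = 1.0 + y0 + kd
    disc = s * s - 4.0 * y0
    # disc >= (1 - y0)^2 >= 0 analytically; clip guards rounding at equality
    c = 0.5 * (s - np.sqrt(np.clip(disc, 0.0, None)))
    out = np.clip(c, 0.0, np.minimum(1.0, y0))
    if np.isscalar(y0_bar) and np.isscalar(kd_bar):
        return float(out)
    return out


def saturation_normalize(curve: Sequence[float], c_max: float | None = None):
    """Normalize a binding curve by its value at saturation.

    Parameters
    ----------
    curve : sequence of float
        Complex amounts along a titration, the last/largest design point
        being the saturation plateau.
    c_max : float, optional
        Saturation value.  Defaults to the maximum of ``curve`` (appropriate
        when the design includes a saturating ratio).

    Returns
    -------
    ndarray
        ``curve / c_max``; equals 1 at the saturation point.
    """
    values = np.asarray(curve, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalize an empty curve")
    if c_max is None:
        c_max = float(np.max(values))
    if c_max <= 0:
        raise ValueError("saturation value is zero; curve cannot be normalized")
    return values / c_max


def single_site_curve(y0_bar, kd_bar, saturation_ratio: float = SATURATION_RATIO):
    """Saturation-normalized single-site binding curve.

    Evaluates :func:`single_site_complex` on ``y0_bar`` and divides by the
    model value at ``saturation_ratio``, mirroring the experimental
    normalization of pull-down signals by the signal at saturating prey.
    """
    c = single_site_complex(y0_bar, kd_bar)
    c_max = single_site_complex(saturation_ratio, kd_bar)
    return saturation_normalize(np.atleast_1d(c), c_max) if np.ndim(c) else float(
        c / c_max
    )


# ---------------------------------------------------------------------------
# competitive model (exact cubic solution)
# ---------------------------------------------------------------------------

def competitive_bound(y0_bar, z0_bar, kdy_bar, kdz_bar, _clamp_tol: float = 1e-12):
    """Bait-prey complex ``xy`` with a competitor ``z`` for the same site.

    Uses the exact trigonometric solution of the mass-balance cubic for the
    free bait concentration: with

        a = K_y + K_z + y0 + z0 - 1
        b = K_z (y0 - 1) + K_y (z0 - 1) + K_y K_z
        c = -K_y K_z
        theta = arccos[ (-2 a^3 + 9 a b - 27 c) / (2 sqrt((a^2 - 3 b)^3)) ]

    the free bait is x = [2 sqrt(a^2 - 3b) cos(theta/3) - a] / 3 and the
    complex is xy = y0 * x / (K_y + x).  All quantities are normalized by the
    bait total.

    Raises
    ------
    ValueError
        If the arccos argument leaves [-1, 1] by more than ``_clamp_tol``
        (arguments inside the tolerance band are clamped; drift of that size
        occurs legitimately at boundary cases such as z0 = 0).
    """
    y0 = np.asarray(y0_bar, dtype=float)
    z0 = np.asarray(z0_bar, dtype=float)
    ky = np.asarray(kdy_bar, dtype=float)
    kz = np.asarray(kdz_bar, dtype=float)
    if np.any(y0 < 0) or np.any(z0 < 0):
        raise ValueError("totals must be non-negative")
    if np.any(ky <= 0) or np.any(kz <= 0):
        raise ValueError("dissociation constants must be positive")

    a = ky + kz + y0 + z0 - 1.0
    b = kz * (y0 - 1.0) + ky * (z0 - 1.0) + ky * kz
    c = -ky * kz
    p = a * a - 3.0 * b  # always > 0 for admissible inputs
    arg = (-2.0 * a**3 + 9.0 * a * b - 27.0 * c) / (2.0 * np.sqrt(p**3))
    over = np.abs(arg) - 1.0
    if np.any(over > _clamp_tol):
        raise ValueError(
            "arccos argument outside [-1, 1] beyond tolerance "
            f"(max excess {float(np.max(over)):.3e}); inputs are outside the "
            "physical domain of the closed form"
        )
    theta = np.arccos(np.clip(arg, -1.0, 1.0))
    x_free = (2.0 * np.sqrt(p) * np.cos(theta / 3.0) - a) / 3.0
    x_free = np.clip(x_free, 0.0, None)
    xy = y0 * x_free / (ky + x_free)
    out = np.clip(xy, 0.0, np.minimum(1.0, y0))
    if all(np.isscalar(v) for v in (y0_bar, z0_bar, kdy_bar, kdz_bar)):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# numerical equilibria: cooperative trimer and inhibitor extension
# ---------------------------------------------------------------------------

def _damped_fixed_point(update, free0, totals, rtol=1e-13, max_iter=400):
    """Damped fixed-point iteration on free concentrations.

    ``update(free) -> free_new`` must implement the exact mass-balance
    updates (each free concentration = total / (1 + bound factors)).  Damping
    in log space (geometric averaging) makes the iteration a contraction for
    all admissible binding problems encountered here.
    """
    free = np.array(free0, dtype=float)
    scale = np.maximum(np.asarray(totals, dtype=float), 1.0)
    for _ in range(max_iter):
        new = update(free)
        # geometric damping; zeros propagate exactly
        mixed = np.where((free > 0) & (new > 0), np.sqrt(free * new), new)
        if np.all(np.abs(mixed - free) <= rtol * scale):
            return mixed
        free = mixed
    return None


def _trimer_from_free(x, y, z, kd1, kd2, alpha):
    xy = x * y / kd1
    xz = x * z / kd2
    xyz = alpha * x * y * z / (kd1 * kd2)
    return TrimerState(free_x=x, free_y=y, free_z=z, xy=xy, xz=xz, xyz=xyz)


def cooperative_trimer_equilibrium(
    y0_bar: float,
    z0_bar: float,
    kd1_bar: float,
    kd2_bar: float,
    alpha: float,
) -> TrimerState:
    """Equilibrium of the two-site cooperative trimer model.

    Ligand ``y`` binds ``x`` with relative K_D ``kd1_bar`` and ``z`` with
    ``kd2_bar``; when the other ligand is already bound the K_D of the second
    event is divided by ``alpha``.  Equivalently the ternary complex carries
    a thermodynamic weight ``alpha * y * z / (kd1 * kd2)`` relative to free
    bait.  With ``alpha = 0`` the ternary complex is forbidden and the model
    reduces exactly to the competitive model.

    The observable pull-down signal of a Renilla-tagged ``y`` in this model
    is ``xy + xyz`` (the prey is recovered both in the dimer and in the
    trimer), normalized at saturation.

    Returns
    -------
    TrimerState
        Species concentrations satisfying conservation to 1e-9 relative and
        all equilibrium relations simultaneously.
    """
    if min(y0_bar, z0_bar) < 0 or min(kd1_bar, kd2_bar) <= 0 or alpha < 0:
        raise ValueError("totals/alpha must be >= 0 and dissociation constants > 0")

    k1, k2, al = float(kd1_bar), float(kd2_bar), float(alpha)
    y0, z0 = float(y0_bar), float(z0_bar)

    def update(free):
        x, y, z = free
        x = 1.0 / (1.0 + y / k1 + z / k2 + al * y * z / (k1 * k2))
        y = y0 / (1.0 + x / k1 + al * x * z / (k1 * k2))
        z = z0 / (1.0 + x / k2 + al * x * y / (k1 * k2))
        return np.array([x, y, z])

    free = _damped_fixed_point(update, [1.0, y0, z0], [1.0, y0, z0])
    if free is None:
        free = _root_fallback(update, [1.0, y0, z0])
    state = _trimer_from_free(free[0], free[1], free[2], k1, k2, al)
    _check_conservation(state, 1.0, y0, z0)
    return state


def inhibitor_equilibrium(
    y0_bar: float,
    z0_bar: float,
    kd1_bar: float,
    kd2_bar: float,
    kd3_bar: float,
) -> TrimerState:
    """Equilibrium of the competitive model extended with prey-competitor
    association.

    On top of the single-site competition of ``y`` and ``z`` for ``x``, the
    prey and the competitor associate directly (``y + z`` with relative K_D
    ``kd3_bar``), sequestering both from the bait.  As ``kd3_bar`` grows
    large the model reduces to the plain competitive model; lowering it
    monotonically depletes the bait-prey complex.
    """
    if min(y0_bar, z0_bar) < 0 or min(kd1_bar, kd2_bar, kd3_bar) <= 0:
        raise ValueError("totals must be >= 0 and dissociation constants > 0")

    k1, k2, k3 = float(kd1_bar), float(kd2_bar), float(kd3_bar)
    y0, z0 = float(y0_bar), float(z0_bar)

    def update(free):
        x, y, z = free
        x = 1.0 / (1.0 + y / k1 + z / k2)
        y = y0 / (1.0 + x / k1 + z / k3)
        z = z0 / (1.0 + x / k2 + y / k3)
        return np.array([x, y, z])

    free = _damped_fixed_point(update, [1.0, y0, z0], [1.0, y0, z0])
    if free is None:
        free = _root_fallback(update, [1.0, y0, z0])
    x, y, z = free
    state = TrimerState(
        free_x=x, free_y=y, free_z=z, xy=x * y / k1, xz=x * z / k2, yz=y * z / k3
    )
    _check_conservation(state, 1.0, y0, z0)
    return state


def _root_fallback(update, totals):
    """Multivariate root fallback when the damped iteration stalls."""
    totals = np.asarray(totals, dtype=float)
    positive = totals > 0
    tiny = 1e-300

    def residual(logfree):
        free = np.where(positive, np.exp(logfree), 0.0)
        new = update(free)
        return np.where(positive, np.log(np.maximum(new, tiny)) - logfree, 0.0)

    start = np.log(np.maximum(totals * 0.5, 1e-12))
    sol = root(residual, start, method="hybr")
    res = np.abs(residual(sol.x))
    if np.max(res) > 1e-9:
        raise RuntimeError(
            f"equilibrium solver failed to converge (residual norm {np.max(res):.3e})"
        )
    return np.where(positive, np.exp(sol.x), 0.0)


def _check_conservation(state: TrimerState, x0, y0, z0):
    got = state.totals()
    want = (x0, y0, z0)
    for g, w in zip(got, want):
        if abs(g - w) > _CONSERVATION_RTOL * max(1.0, w):
            raise RuntimeError(
                f"conservation violated: recovered totals {got}, expected {want}"
            )


# ---------------------------------------------------------------------------
# Hill-type higher-order saturation
# ---------------------------------------------------------------------------

def hill_signal(x, z, params: HillModelParams):
    """Saturation signal with higher-order prey terms.

    s = (a x + b x^n + c x z + d x^m z) / (1 + a x + b x^n + c x z + d x^m z)

    Monotone increasing in ``x``; 0 at ``x = 0``; approaches 1 as ``x`` grows
    for positive coefficients.
    """
    xv = np.asarray(x, dtype=float)
    zv = np.asarray(z, dtype=float)
    if np.any(xv < 0) or np.any(zv < 0):
        raise ValueError("x and z must be non-negative")
    num = (
        params.a * xv
        + params.b * xv**params.n
        + params.c * xv * zv
        + params.d * xv**params.m * zv
    )
    out = num / (1.0 + num)
    if np.isscalar(x) and np.isscalar(z):
        return float(out)
    return out
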