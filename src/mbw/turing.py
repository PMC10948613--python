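"""Linear stability analysis of an activator-inhibitor model with variable
complex order.

The dimensionless reaction-diffusion system is

    du/dt = f(u, v) + laplacian(u),   f = a - b u + u^n / v
    dv/dt = g(u, v) + d laplacian(v), g = u^n - v

with activator ``u``, inhibitor ``v``, production ``a``, degradation ``b``,
diffusion ratio ``d`` and complex order ``n`` (the classical case is n = 2;
higher n emulates higher-order activator complexes).  Around the uniform
reference state u0 = a/b, v0 = (a/b)^n the Jacobian entries are

    f_u = b (n - a) / a      f_v = -(a/b)^(-n)
    g_u = n (a/b)^(n-1)      g_v = -1

and a diffusion-driven (Turing) instability requires all four conditions

    c1:  b (n - a) / a < 1              (stability without diffusion, trace)
    c2:  b > 0                          (stability without diffusion, det)
    c3:  d b (n - a) / a > 1            (diffusion destabilizes)
    c4:  (d b (n - a) / a - 1)^2 > 4 d b  (real positive growth band)

as strict inequalities.  Scanning (a, b) at fixed d yields the Turing space;
its area and centroid quantify how patterning robustness changes with the
complex order n.

Note on the reference state: g vanishes exactly at (u0, v0), while f retains
its constant source term there (the exact activator balance would put u0 at
(a+1)/b).  The analysis uses the printed reference state and its exact
partial derivatives, which is the standard simplification for a >> 1 and is
what the area/centroid statistics quantify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AIParams",
    "TuringGrid",
    "reaction_terms",
    "steady_state",
    "jacobian_entries",
    "turing_conditions",
    "turing_space",
]


@dataclass(frozen=True)
class AIParams:
    """Parameters of the dimensionless activator-inhibitor system."""

    a: float  # activator production
    b: float  # activator degradation
    n_order: int = 2  # complex order of the activator
    d: float = 10.0  # inhibitor:activator diffusion ratio

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0 or self.d <= 0:
            raise ValueError("a, b and d must be positive")
        if self.n_order < 1:
            raise ValueError("complex order must be an integer >= 1")


def reaction_terms(u, v, params: AIParams):
    """Reaction kinetics (f, g) of the activator-inhibitor system."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    f = params.a - params.b * u + u**params.n_order / v
    g = u**params.n_order - v
    return f, g


def steady_state(params: AIParams) -> tuple[float, float]:
    """Uniform reference state (u0, v0) = (a/b, (a/b)^n)."""
    if params.b <= 0:
        raise ValueError("b must be positive")
    u0 = params.a / params.b
    return u0, u0**params.n_order


def jacobian_entries(params: AIParams) -> tuple[float, float, float, float]:
    """Partial derivatives (f_u, f_v, g_u, g_v) at the reference state."""
    a, b, n = params.a, params.b, params.n_order
    if a <= 0:
        raise ValueError("a must be positive")
    u0 = a / b
    f_u = b * (n - a) / a
    f_v = -(u0 ** (-n))
    g_u = n * u0 ** (n - 1)
    g_v = -1.0
    return f_u, f_v, g_u, g_v


def turing_conditions(params: AIParams) -> tuple[bool, bool, bool, bool]:
    """The four diffusion-driven-instability conditions (strict)."""
    a, b, n, d = params.a, params.b, params.n_order, params.d
    t = b * (n - a) / a
    c1 = t < 1.0
    c2 = b > 0.0
    c3 = d * t > 1.0
    c4 = (d * t - 1.0) ** 2 > 4.0 * d * b
    return c1, c2, c3, c4


@dataclass
class TuringGrid:
    """Masks of the four conditions over an (a, b) grid, with summaries."""

    a_values: np.ndarray
    b_values: np.ndarray
    n_order: int
    d: float
    c1: np.ndarray = field(repr=False)  # (len(b), len(a)) boolean masks
    c2: np.ndarray = field(repr=False)
    c3: np.ndarray = field(repr=False)
    c4: np.ndarray = field(repr=False)

    @property
    def combined(self) -> np.ndarray:
        return self.c1 & self.c2 & self.c3 & self.c4

    @property
    def cell_area(self) -> float:
        da = float(self.a_values[1] - self.a_values[0])
        db = float(self.b_values[1] - self.b_values[0])
        return da * db

    @property
    def area(self) -> float:
        """Turing-space area: number of admissible cells times cell area."""
        return float(np.count_nonzero(self.combined)) * self.cell_area

    @property
    def centroid(self) -> tuple[float, float]:
        """(a, b) centroid of the admissible region."""
        mask = self.combined
        if not mask.any():
            return float("nan"), float("nan")
        A, B = np.meshgrid(self.a_values, self.b_values)
        return float(A[mask].mean()), float(B[mask].mean())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: a, b, n, c1..c4, in_turing_space."""
        A, B = np.meshgrid(self.a_values, self.b_values)
        return pd.DataFrame(
            {
                "a": A.ravel(),
                "b": B.ravel(),
                "n": self.n_order,
                "c1": self.c1.ravel(),
                "c2": self.c2.ravel(),
                "c3": self.c3.ravel(),
                "c4": self.c4.ravel(),
                "in_turing_space": self.combined.ravel(),
            }
        )

    def summary(self) -> dict:
        ca, cb = self.centroid
        return {
            "n": self.n_order,
            "d": self.d,
            "area": self.area,
            "centroid_a": ca,
            "centroid_b": cb,
            "n_cells": int(np.count_nonzero(self.combined)),
            "grid": [len(self.a_values), len(self.b_values)],
        }


def turing_space(
    a_max: float = 10.0,
    b_max: float = 10.0,
    resolution: int = 500,
    n_order: int = 2,
    d: float = 10.0,
    a_min: float | None = None,
    b_min: float | None = None,
) -> TuringGrid:
    """Evaluate the four conditions on a uniform (a, b) grid.

    The grid covers (0, a_max] x (0, b_max] with ``resolution`` cells per
    axis, sampled at cell centres (the axes exclude 0, where the model is
    undefined).  Boundary cells where a condition holds only with equality
    are excluded (strict inequalities).
    """
    if resolution < 50:
        raise ValueError("resolution must be at least 50 cells per axis")
    da = a_max / resolution
    db = b_max / resolution
    a_vals = (np.arange(resolution) + 0.5) * da if a_min is None else np.linspace(
        a_min, a_max, resolution
    )
    b_vals = (np.arange(resolution) + 0.5) * db if b_min is None else np.linspace(
        b_min, b_max, resolution
    )
    A, B = np.meshgrid(a_vals, b_vals)
    t = B * (n_order - A) / A
    c1 = t < 1.0
    c2 = B > 0.0
    c3 = d * t > 1.0
    c4 = (d * t - 1.0) ** 2 > 4.0 * d * B
    return TuringGrid(
        a_values=a_vals,
        b_values=b_vals,
        n_order=n_order,
        d=d,
        c1=c1,
        c2=c2,
        c3=c3,
        c4=c4,
    )
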