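"""Stimulus domains, priors over them, and stimulus-reward maps.

Everything downstream (escort response functions, the Bayesian observer,
the resource-allocation optimizers, the synthetic experiment generators)
works with the three containers defined here:

``StimulusDomain``
    a bounded one-dimensional stimulus space with an evaluation grid,
``Prior``
    a normalized density over that grid (the environmental statistics
    ``f(s)``), and
``RewardMap``
    the stimulus-reward association ``R(s)`` of a context.

Orientation stimuli are handled in degrees throughout; the canonical
orientation prior is ``f(s) = omega / (a - cos 4s)`` with the cosine taken on
the angle expressed in radians, which gives the 90-degree periodicity of edge
statistics in natural scenes (cardinal orientations most frequent).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline

from .errors import InvalidCDFError, InvalidPriorError, InvalidSteepnessError

__all__ = [
    "StimulusDomain",
    "Prior",
    "RewardMap",
    "make_orientation_prior",
    "make_diagonality_prior",
    "prior_from_cdf",
    "orientation_to_diagonality",
]

#: normalization tolerance used when validating priors
NORM_TOL = 1e-6


@dataclass(frozen=True)
class StimulusDomain:
    """A bounded 1-D stimulus space with a fixed evaluation grid.

    Parameters
    ----------
    lower, upper : float
        Domain bounds in stimulus units (e.g. degrees of orientation).
    circular : bool
        Whether the domain wraps (orientation spaces do).
    n_grid : int
        Number of evaluation points; at least 64.
    """

    lower: float
    upper: float
    circular: bool = False
    n_grid: int = 1024

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"need lower < upper, got [{self.lower}, {self.upper}]")
        if self.n_grid < 64:
            raise ValueError(f"grid size must be >= 64, got {self.n_grid}")

    @property
    def grid(self) -> np.ndarray:
        """Strictly increasing grid spanning [lower, upper] inclusive."""
        return np.linspace(self.lower, self.upper, self.n_grid)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, s) -> np.ndarray:
        return (np.asarray(s) >= self.lower) & (np.asarray(s) <= self.upper)


@dataclass(frozen=True)
class Prior:
    """A normalized stimulus density ``f(s)`` tabulated on a domain grid.

    ``a`` and ``omega`` are only set for the parametric orientation prior
    ``f(s) = omega / (a - cos 4s)``: ``a > 1`` is the steepness (elevation) of
    the density at the cardinals and ``omega`` the normalizing constant. The
    closed-form observer moments require them; grid-based operations do not.
    """

    domain: StimulusDomain
    density: np.ndarray
    a: float | None = None
    omega: float | None = None

    def __post_init__(self):
        dens = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "density", dens)
        if dens.shape != (self.domain.n_grid,):
            raise InvalidPriorError(
                f"density shape {dens.shape} does not match grid ({self.domain.n_grid},)"
            )
        if np.any(dens < 0):
            raise InvalidPriorError("density must be non-negative everywhere")
        total = np.trapezoid(dens, self.domain.grid)
        if abs(total - 1.0) > 1e-4:
            raise InvalidPriorError(
                f"density must integrate to 1 (trapezoid integral = {total:.6g})"
            )

    @property
    def grid(self) -> np.ndarray:
        return self.domain.grid

    def pdf(self, s) -> np.ndarray:
        """Density at arbitrary stimuli by linear interpolation on the grid."""
        return np.interp(np.asarray(s, dtype=float), self.grid, self.density)

    def cdf_values(self) -> np.ndarray:
        """Cumulative distribution on the grid (trapezoid accumulation)."""
        c = cumulative_trapezoid(self.density, self.grid, initial=0.0)
        return c / c[-1]

    def cdf(self, s) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), self.grid, self.cdf_values())

    def ppf(self, u) -> np.ndarray:
        """Inverse CDF (quantile function) by monotone interpolation."""
        return np.interp(np.asarray(u, dtype=float), self.cdf_values(), self.grid)

    def is_normalized(self, tol: float = NORM_TOL) -> bool:
        return abs(np.trapezoid(self.density, self.grid) - 1.0) <= tol


def _normalize(domain: StimulusDomain, raw: np.ndarray) -> np.ndarray:
    total = np.trapezoid(raw, domain.grid)
    if total <= 0:
        raise InvalidPriorError("cannot normalize a non-positive density")
    return raw / total


def make_orientation_prior(a: float, domain: StimulusDomain | None = None) -> Prior:
    """The parametric orientation prior ``f(s) = omega / (a - cos 4s)``.

    ``s`` is in degrees; the cosine acts on the angle in radians so the
    density has period 90 degrees with maxima at the cardinal orientations
    (0 and 90 degrees) and minima at the obliques (45 and 135 degrees).
    ``a = 1.85`` reproduces the distribution of edge orientations in natural
    scenes used in the behavioural tasks; ``a -> infinity`` tends to uniform.

    Raises
    ------
    InvalidSteepnessError
        If ``a <= 1`` (the density would be unbounded at the cardinals).
    """
    if a <= 1:
        raise InvalidSteepnessError(f"steepness a must exceed 1, got a={a}")
    if domain is None:
        domain = StimulusDomain(0.0, 180.0, circular=True)
    s = domain.grid
    raw = 1.0 / (a - np.cos(4.0 * np.radians(s)))
    density = _normalize(domain, raw)
    # omega is defined by f = omega / (a - cos 4s); read it off the normalization
    omega = density[0] * (a - np.cos(4.0 * np.radians(s[0])))
    return Prior(domain=domain, density=density, a=a, omega=omega)


def orientation_to_diagonality(s_deg) -> np.ndarray:
    """Fold an orientation (degrees) onto the diagonality axis [0, 45].

    Diagonality is the distance to the nearest cardinal axis: 0 at cardinal
    orientations (0/90/180 degrees), 45 at the obliques (45/135 degrees).
    """
    s = np.mod(np.asarray(s_deg, dtype=float), 90.0)
    return 45.0 - np.abs(45.0 - s)


def make_diagonality_prior(a: float, n_grid: int = 1024) -> Prior:
    """The orientation prior folded onto the diagonality axis [0, 45] degrees.

    The orientation density has period 90 and is symmetric about 45, so the
    fold simply doubles the density; the binary task's decision axis lives
    here (cardinal at 0, oblique at 45). ``a`` and ``omega`` are preserved on
    the folded scale so the closed-form observer moments stay valid.
    """
    if a <= 1:
        raise InvalidSteepnessError(f"steepness a must exceed 1, got a={a}")
    domain = StimulusDomain(0.0, 45.0, circular=False, n_grid=n_grid)
    d = domain.grid
    raw = 1.0 / (a - np.cos(4.0 * np.radians(d)))
    density = _normalize(domain, raw)
    omega = density[0] * (a - np.cos(4.0 * np.radians(d[0])))
    return Prior(domain=domain, density=density, a=a, omega=omega)


def prior_from_cdf(points, domain: StimulusDomain | None = None) -> Prior:
    """Reconstruct a density from sampled CDF points ``(stimulus, cumulative)``.

    Used e.g. to recover a stimulus prior from a published cumulative
    distribution (the blowfly contrast statistics are reported this way).
    A monotone (PCHIP) interpolant of the CDF is differentiated and
    renormalized on the target grid.

    Raises
    ------
    InvalidCDFError
        If fewer than 5 points are given, cumulative values decrease, or lie
        outside [0, 1].
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise InvalidCDFError("need at least 5 (stimulus, cumulative) pairs")
    s, c = pts[:, 0], pts[:, 1]
    order = np.argsort(s)
    s, c = s[order], c[order]
    if np.any(np.diff(c) < 0):
        raise InvalidCDFError("cumulative values must be non-decreasing")
    if c.min() < -1e-9 or c.max() > 1 + 1e-9:
        raise InvalidCDFError("cumulative values must lie in [0, 1]")
    if domain is None:
        domain = StimulusDomain(float(s[0]), float(s[-1]))
    # cubic-spline derivative (clipped at zero): more accurate than a
    # shape-preserving interpolant near density peaks, and a monotone CDF
    # keeps undershoot negligible
    interp = CubicSpline(s, c)
    dens = np.clip(interp.derivative()(domain.grid), 0.0, None)
    return Prior(domain=domain, density=_normalize(domain, dens))


@dataclass(frozen=True)
class RewardMap:
    """A stimulus-reward association ``R(s)`` on a domain grid.

    ``kind`` is one of ``constant`` (accuracy context: every correct choice
    pays the same), ``linear`` (reward affine in the stimulus, the classic
    economic setting), or ``tabulated`` (arbitrary maps, e.g. unimodal
    reward peaking mid-domain). Tabulated maps are completed by linear
    interpolation between provided points.
    """

    domain: StimulusDomain
    values: np.ndarray
    kind: str = "tabulated"

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (self.domain.n_grid,):
            raise ValueError("reward values must be tabulated on the domain grid")
        if self.kind not in ("constant", "linear", "tabulated"):
            raise ValueError(f"unknown reward map kind {self.kind!r}")
        if self.kind == "constant" and np.ptp(vals) > 1e-12:
            raise ValueError("constant reward map has non-identical values")

    @classmethod
    def constant(cls, domain: StimulusDomain, value: float = 1.0) -> "RewardMap":
        return cls(domain, np.full(domain.n_grid, float(value)), kind="constant")

    @classmethod
    def linear(cls, domain: StimulusDomain, intercept: float = 0.0,
               slope: float = 1.0) -> "RewardMap":
        return cls(domain, intercept + slope * domain.grid, kind="linear")

    @classmethod
    def from_points(cls, domain: StimulusDomain, points) -> "RewardMap":
        """Tabulated map linearly interpolated between (stimulus, reward) points."""
        pts = np.asarray(points, dtype=float)
        order = np.argsort(pts[:, 0])
        vals = np.interp(domain.grid, pts[order, 0], pts[order, 1])
        return cls(domain, vals, kind="tabulated")

    def __call__(self, s) -> np.ndarray:
        return np.interp(np.asarray(s, dtype=float), self.domain.grid, self.values)


# -- plain-text serialization ------------------------------------------------

def save_table(path, x: np.ndarray, y: np.ndarray, header: str) -> None:
    """Write a two-column (stimulus, value) text table with a one-line header."""
    arr = np.column_stack([x, y])
    np.savetxt(path, arr, header=header, comments="# ")


def load_table(path):
    """Read a two-column text table; returns (x, y)."""
    arr = np.loadtxt(path)
    return arr[:, 0], arr[:, 1]


def save_prior(path, prior: Prior) -> None:
    save_table(path, prior.grid, prior.density, "stimulus density")


def load_prior(path, circular: bool = False) -> Prior:
    x, y = load_table(path)
    domain = StimulusDomain(float(x[0]), float(x[-1]), circular=circular,
                            n_grid=len(x))
    dens = np.interp(domain.grid, x, y)
    return Prior(domain, _normalize(domain, dens))
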