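"""Reaction force, critical points, four-region work integration and
electronic flux along the IRC.

The force is F(ξ) = -dE/dξ, computed with second-order central differences
on the (possibly non-uniform) grid and one-sided stencils at the ends.  Its
global minimum (before the transition state) and maximum (after) split the
path into four regions; the work in each region is W = -∫F dξ, which by
construction equals the energy change across the region.  The electronic
flux is J(ξ) = -dμ/dξ with the same differencing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from ircmech.exceptions import NumericalError, ValidationError
from ircmech.io_formats import IRCProfile


@dataclass
class ForceProfile:
    xi: np.ndarray
    force: np.ndarray
    method: str = "central-3pt"

    def __post_init__(self) -> None:
        if len(self.xi) != len(self.force):
            raise ValidationError("force length does not match grid")
        if not np.all(np.isfinite(self.force)):
            raise ValidationError("non-finite force value")


@dataclass
class FluxProfile:
    xi: np.ndarray
    flux: np.ndarray
    method: str = "central-3pt"

    def __post_init__(self) -> None:
        if len(self.xi) != len(self.flux):
            raise ValidationError("flux length does not match grid")
        if not np.all(np.isfinite(self.flux)):
            raise ValidationError("non-finite flux value")


@dataclass
class WorkDecomposition:
    """Force critical points and the four region works (kcal/mol)."""

    xi_force_min: float
    xi_ts: float
    xi_force_max: float
    W1: float
    W2: float
    W3: float
    W4: float
    region_bounds: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if not (self.xi_force_min < self.xi_ts < self.xi_force_max):
            raise ValidationError(
                "critical points must satisfy xi_force_min < xi_ts < xi_force_max"
            )

    @property
    def works(self) -> tuple[float, float, float, float]:
        return (self.W1, self.W2, self.W3, self.W4)

    @property
    def total(self) -> float:
        return self.W1 + self.W2 + self.W3 + self.W4

    @property
    def activation_work(self) -> float:
        return self.W1 + self.W2


def _derivative(xi: np.ndarray, y: np.ndarray) -> np.ndarray:
    # np.gradient: 3-point non-uniform central differences, one-sided at ends
    return np.gradient(y, xi, edge_order=1)


def _maybe_smooth(y: np.ndarray, window: int | None, polyorder: int = 3) -> np.ndarray:
    if window is None or window <= 1:
        return y
    if window % 2 == 0:
        window += 1
    if window >= len(y):
        raise ValidationError("smoothing window exceeds profile length")
    return savgol_filter(y, window_length=window, polyorder=min(polyorder, window - 1))


def reaction_force(profile: IRCProfile, smooth_window: int | None = None) -> ForceProfile:
    """F(ξ) = -dE/dξ.

    ``smooth_window`` applies an odd-width Savitzky-Golay filter to the
    energy before differentiation (off by default).
    """
    if profile.n_points < 5:
        raise ValidationError(
            f"reaction force needs at least 5 points, got {profile.n_points}"
        )
    energy = _maybe_smooth(profile.energy, smooth_window)
    method = "central-3pt" + ("+savgol" if smooth_window else "")
    return ForceProfile(xi=profile.xi, force=-_derivative(profile.xi, energy), method=method)


def electronic_flux(profile: IRCProfile, smooth_window: int | None = None) -> FluxProfile:
    """J(ξ) = -dμ/dξ from the chemical-potential channel."""
    if profile.chem_potential is None:
        raise ValidationError("profile has no chemical-potential channel")
    if profile.n_points < 5:
        raise ValidationError(
            f"electronic flux needs at least 5 points, got {profile.n_points}"
        )
    mu = _maybe_smooth(profile.chem_potential, smooth_window)
    method = "central-3pt" + ("+savgol" if smooth_window else "")
    return FluxProfile(xi=profile.xi, flux=-_derivative(profile.xi, mu), method=method)


def _refine_extremum(xi: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through (xi, y) at i-1, i, i+1.

    Falls back to the grid point at the ends or for a degenerate fit.
    """
    if i == 0 or i == len(xi) - 1:
        return float(xi[i]), float(y[i])
    x0, x1, x2 = xi[i - 1], xi[i], xi[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    coeffs = np.polyfit([x0, x1, x2], [y0, y1, y2], 2)
    a, b, _ = coeffs
    if a == 0.0:
        return float(x1), float(y1)
    xv = -b / (2.0 * a)
    if not (x0 <= xv <= x2):
        return float(x1), float(y1)
    return float(xv), float(np.polyval(coeffs, xv))


def locate_critical_points(
    force: ForceProfile, ts_xi: float | None = 0.0, energy: np.ndarray | None = None
) -> tuple[float, float, float]:
    """Locate (ξ at force minimum, ξ at TS, ξ at force maximum).

    The transition state defaults to ξ=0; if the grid does not bracket a
    force minimum before the TS and a maximum after it, no barrier is
    detected and a :class:`NumericalError` is raised.  Extrema are refined by
    a local quadratic through the extremum and its neighbours; ties break
    toward the point nearer the TS.
    """
    xi, f = force.xi, force.force
    if ts_xi is None:
        if energy is None:
            raise ValidationError("either ts_xi or an energy channel is required")
        i_ts = int(np.argmax(energy))
        xi_ts, _ = _refine_extremum(xi, energy, i_ts)
    else:
        xi_ts = float(ts_xi)
    if not (xi[0] < xi_ts < xi[-1]):
        raise NumericalError("transition state lies outside the grid")

    left = np.flatnonzero(xi < xi_ts)
    right = np.flatnonzero(xi > xi_ts)
    if len(left) < 3 or len(right) < 3:
        raise NumericalError("no barrier detected: too few points on one side of the TS")

    # ties toward the TS: scan from the TS outward keeps the nearer index
    i_min_rel = len(left) - 1 - int(np.argmin(f[left][::-1]))
    i_min = left[i_min_rel]
    i_max = right[int(np.argmax(f[right]))]

    interior_min = 0 < i_min < len(xi) - 1
    interior_max = 0 < i_max < len(xi) - 1
    if not (interior_min and interior_max) or f[i_min] >= 0 or f[i_max] <= 0:
        raise NumericalError("no barrier detected: force profile lacks a min/max pair")

    xi_min, _ = _refine_extremum(xi, f, i_min)
    xi_max, _ = _refine_extremum(xi, f, i_max)
    if not (xi_min < xi_ts < xi_max):
        raise NumericalError("refined critical points do not bracket the transition state")
    return xi_min, xi_ts, xi_max


def reaction_works(
    profile: IRCProfile,
    critical_points: tuple[float, float, float],
    force: ForceProfile | None = None,
) -> WorkDecomposition:
    """W = -∫F dξ over each of the four force regions.

    Since the force is the exact negative derivative of the energy, each
    region work equals the energy difference across the region; boundary
    energies at refined off-grid critical points come from a local quadratic
    interpolant.  The four works therefore partition the path exactly:
    W1+...+W4 telescopes to E(end) - E(start) and W1+W2 to the activation
    energy.
    """
    xi_min, xi_ts, xi_max = critical_points
    if force is None:
        force = reaction_force(profile)
    xi = profile.xi
    if not (xi[0] <= xi_min < xi_ts < xi_max <= xi[-1]):
        raise ValidationError("critical points fall outside the grid")

    bounds = [float(xi[0]), float(xi_min), float(xi_ts), float(xi_max), float(xi[-1])]
    energies = [_energy_at(xi, profile.energy, b) for b in bounds]
    works = [energies[i + 1] - energies[i] for i in range(4)]
    region_bounds = tuple((bounds[i], bounds[i + 1]) for i in range(4))
    return WorkDecomposition(
        xi_force_min=float(xi_min),
        xi_ts=float(xi_ts),
        xi_force_max=float(xi_max),
        W1=works[0],
        W2=works[1],
        W3=works[2],
        W4=works[3],
        region_bounds=region_bounds,
    )


def _energy_at(xi: np.ndarray, energy: np.ndarray, x: float) -> float:
    """Energy at x: exact at grid points, local quadratic off-grid."""
    i = int(np.argmin(np.abs(xi - x)))
    if xi[i] == x:
        return float(energy[i])
    i = min(max(i, 1), len(xi) - 2)
    sel = slice(i - 1, i + 2)
    return float(np.polyval(np.polyfit(xi[sel], energy[sel], 2), x))
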