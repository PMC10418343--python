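"""Closed-form synthetic racemization datasets with known ground truth.

Every channel is built from logistic and Gaussian primitives whose
derivatives and integrals are analytic, so downstream numerics (force,
works, flux, evolution percentages, synchronicity, Hammett fits) can be
checked against exact values without any quantum-chemistry run.

Channel model on the grid ξ ∈ [ξ_min, ξ_max] (reactant side negative,
transition state at ξ = 0, intermediate side positive), with
σ(u) = 1/(1+e^(-u)) and s(ξ) = σ(ξ/w):

* energy      E(ξ) = ΔE_RI·s(ξ) + A'·exp(-ξ²/(2w²)), A' scaled so that
              E(0) - E(ξ_min) equals the requested barrier height.
* chem. pot.  μ(ξ) = μ_R - Δμ·s(ξ), so the flux J = -dμ/dξ = Δμ·s'(ξ) is
              negative near the TS for the default Δμ < 0.
* Wiberg      B_break(ξ) = B_R·(1 - σ((ξ-d)/λ)),
              B_form(ξ)  = B_I·σ((ξ-d')/λ').
* charge      q(ξ) = q0 - Δq·exp(-(ξ-ξ_q)²/(2w²)) (transient dip).
* dipole/dihedral/attack angle: endpoint-normalized logistics.

Two presets encode the qualitative aromatic/aliphatic contrasts: the
aromatic-like profile has a transition state much closer in energy to the
intermediate than the aliphatic-like one has a small TS-intermediate gap,
a late dihedral change and a decreasing dipole; the aliphatic-like preset
has an early dihedral change, an increasing dipole, larger works and higher
bond-evolution percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from ircmech.constants import DEFAULT_TEMPERATURE_K, GAS_CONSTANT_KCAL, LOG10_FACTOR
from ircmech.exceptions import ValidationError
from ircmech.io_formats import GeometrySeries, IRCProfile, StationaryPoint
from ircmech.lfer import HammettEntry, HammettSeries

BREAK_BOND = "C1-H5"
FORM_BOND = "H5-O6"
CHIRAL_ATOM = "C1"
ATOM_LABELS = ["C1", "C2", "N3", "C4", "H5", "O6"]


def _sigmoid(u: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(u, dtype=float)))


def _dsigmoid(u: np.ndarray | float) -> np.ndarray | float:
    s = _sigmoid(u)
    return s * (1.0 - s)


@dataclass
class LogisticParams:
    """Midpoint and steepness of one logistic transition."""

    midpoint: float
    steepness: float

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValidationError("logistic steepness must be positive")

    def curve(self, xi: np.ndarray | float) -> np.ndarray | float:
        return _sigmoid((np.asarray(xi, dtype=float) - self.midpoint) / self.steepness)

    def normalized(self, xi: np.ndarray | float, lo: float, hi: float):
        """Logistic rescaled to hit exactly 0 at ξ=lo and 1 at ξ=hi."""
        s_lo, s_hi = self.curve(lo), self.curve(hi)
        return (self.curve(xi) - s_lo) / (s_hi - s_lo)


@dataclass
class SyntheticSpec:
    """All knobs of the synthetic generator, with ground-truth-friendly
    closed-form shapes.  Energies kcal/mol, lengths Angstrom, angles degrees,
    dipole Debye, charge e."""

    barrier_height: float = 22.0
    barrier_width: float = 0.5
    step_E_RI: float = 6.0
    mu_R: float = -60.0
    mu_drop: float = -4.0
    # Wiberg channels
    wbi_break_B_R: float = 0.90
    wbi_break: LogisticParams = field(default_factory=lambda: LogisticParams(-0.15, 0.35))
    wbi_form_B_I: float = 0.70
    wbi_form: LogisticParams = field(default_factory=lambda: LogisticParams(-0.05, 0.35))
    # chiral-carbon charge dip
    charge_q0: float = -0.20
    charge_dip: float = 0.35
    charge_center: float = 0.15
    # dihedral (pyramidalization) and attack angle
    dihedral_theta_R: float = 120.0
    dihedral_delta: float = 35.0
    dihedral: LogisticParams = field(default_factory=lambda: LogisticParams(1.0, 0.4))
    angle_R: float = 172.0
    angle_delta: float = 2.0
    angle: LogisticParams = field(default_factory=lambda: LogisticParams(0.0, 0.5))
    # dipole
    dipole_R: float = 6.0
    dipole_delta: float = -2.0
    dipole: LogisticParams = field(default_factory=lambda: LogisticParams(0.0, 0.5))
    # bond-length endpoints for the toy trajectory; the forming-length
    # logistic lags its WBI counterpart so length curves read as more
    # asynchronous than WBI curves
    r_break_R: float = 1.09
    r_break_I: float = 2.40
    r_form_R: float = 2.30
    r_form_I: float = 0.96
    len_break: LogisticParams | None = None
    len_form: LogisticParams | None = None
    # grid
    xi_min: float = -3.0
    xi_max: float = 3.0
    n_points: int = 601
    # stochastics
    seed: int = 0
    noise_sd: float | Mapping[str, float] = 0.0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.barrier_height <= 0:
            raise ValidationError("barrier height must be positive")
        if self.barrier_width <= 0:
            raise ValidationError("barrier width must be positive")
        if self.n_points < 21:
            raise ValidationError("grid needs at least 21 points")
        if not (self.xi_min < 0.0 < self.xi_max):
            raise ValidationError("grid must satisfy xi_min < 0 < xi_max")
        sds = (
            self.noise_sd.values()
            if isinstance(self.noise_sd, Mapping)
            else [self.noise_sd]
        )
        if any(sd < 0 for sd in sds):
            raise ValidationError("noise_sd must be non-negative")
        if self.len_break is None:
            self.len_break = LogisticParams(self.wbi_break.midpoint, self.wbi_break.steepness)
        if self.len_form is None:
            self.len_form = LogisticParams(
                self.wbi_form.midpoint + 0.4, self.wbi_form.steepness
            )

    # -- closed-form channels ----------------------------------------------
    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.xi_min, self.xi_max, self.n_points)

    def _noise(self, channel: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd.get(channel, 0.0))
        return float(self.noise_sd)

    @property
    def gaussian_amplitude(self) -> float:
        """A' such that E(0) - E(ξ_min) equals barrier_height."""
        w = self.barrier_width
        s = _sigmoid(np.array([self.xi_min / w, 0.0]))
        step_part = self.step_E_RI * (s[1] - s[0])
        denom = 1.0 - np.exp(-self.xi_min**2 / (2.0 * w**2))
        return (self.barrier_height - step_part) / denom

    def energy_fn(self, xi):
        w = self.barrier_width
        return self.step_E_RI * _sigmoid(np.asarray(xi) / w) + (
            self.gaussian_amplitude * np.exp(-np.asarray(xi) ** 2 / (2.0 * w**2))
        )

    def force_fn(self, xi):
        """F = -dE/dξ, analytic."""
        xi = np.asarray(xi, dtype=float)
        w = self.barrier_width
        dstep = self.step_E_RI * _dsigmoid(xi / w) / w
        dgauss = self.gaussian_amplitude * (-xi / w**2) * np.exp(-(xi**2) / (2.0 * w**2))
        return -(dstep + dgauss)

    def _d2E(self, xi):
        xi = np.asarray(xi, dtype=float)
        w = self.barrier_width
        u = xi / w
        s = _sigmoid(u)
        d2step = self.step_E_RI * (s * (1 - s) * (1 - 2 * s)) / w**2
        d2gauss = (
            self.gaussian_amplitude
            / w**2
            * (u**2 - 1.0)
            * np.exp(-(xi**2) / (2.0 * w**2))
        )
        return d2step + d2gauss

    def mu_fn(self, xi):
        return self.mu_R - self.mu_drop * _sigmoid(np.asarray(xi) / self.barrier_width)

    def flux_fn(self, xi):
        """J = -dμ/dξ = Δμ·s'(ξ); negative near the TS for Δμ < 0."""
        w = self.barrier_width
        return self.mu_drop * _dsigmoid(np.asarray(xi) / w) / w

    def wbi_break_fn(self, xi):
        return self.wbi_break_B_R * (1.0 - self.wbi_break.curve(xi))

    def wbi_form_fn(self, xi):
        return self.wbi_form_B_I * self.wbi_form.curve(xi)

    def charge_fn(self, xi):
        xi = np.asarray(xi, dtype=float)
        w = self.barrier_width
        return self.charge_q0 - self.charge_dip * np.exp(
            -((xi - self.charge_center) ** 2) / (2.0 * w**2)
        )

    def dipole_fn(self, xi):
        return self.dipole_R + self.dipole_delta * self.dipole.normalized(
            xi, self.xi_min, self.xi_max
        )

    def dihedral_fn(self, xi):
        return self.dihedral_theta_R + self.dihedral_delta * self.dihedral.normalized(
            xi, self.xi_min, self.xi_max
        )

    def angle_fn(self, xi):
        return self.angle_R + self.angle_delta * self.angle.normalized(
            xi, self.xi_min, self.xi_max
        )

    def r_break_fn(self, xi):
        return self.r_break_R + (self.r_break_I - self.r_break_R) * (
            self.len_break.normalized(xi, self.xi_min, self.xi_max)
        )

    def r_form_fn(self, xi):
        return self.r_form_R + (self.r_form_I - self.r_form_R) * (
            self.len_form.normalized(xi, self.xi_min, self.xi_max)
        )


@dataclass
class GroundTruth:
    """Exact values implied by a :class:`SyntheticSpec` (noise-free)."""

    xi_force_min: float
    xi_ts: float
    xi_force_max: float
    W1: float
    W2: float
    W3: float
    W4: float
    barrier: float
    dE_total: float
    flux_at_ts: float
    wbi_stationary: dict[str, tuple[float, float, float]]
    percent_evolution: dict[str, float]
    mean_evolution: float
    synchronicity: float
    charge_min_xi: float
    dipole_change: float
    force_fn: Callable = None
    flux_fn: Callable = None
    energy_fn: Callable = None

    @property
    def works(self) -> tuple[float, float, float, float]:
        return (self.W1, self.W2, self.W3, self.W4)


def _first_d2E_root(spec: SyntheticSpec, side: int) -> float:
    """First root of E'' moving outward from ξ=0 on the given side (+1/-1).

    E''(0) < 0 (barrier curvature); the nearest sign change on each side is
    the force extremum bounding the electronic-reordering region.
    """
    end = spec.xi_max if side > 0 else spec.xi_min
    probes = side * np.geomspace(1e-6, abs(end), 4096)
    vals = spec._d2E(probes)
    pos = np.flatnonzero(vals > 0)
    if not len(pos):
        raise ValidationError("degenerate spec: no force extremum on one side of the TS")
    j = pos[0]
    a, b = (probes[j - 1], probes[j]) if j > 0 else (side * 1e-12, probes[j])
    lo, hi = (a, b) if a < b else (b, a)
    return float(brentq(spec._d2E, lo, hi, xtol=1e-14))


def _ground_truth(spec: SyntheticSpec) -> GroundTruth:
    lo, hi = spec.xi_min, spec.xi_max
    # force extrema: nearest roots of E'' on either side of the TS
    xi1 = _first_d2E_root(spec, -1)
    xi3 = _first_d2E_root(spec, +1)
    E = spec.energy_fn
    works = (
        float(E(xi1) - E(lo)),
        float(E(0.0) - E(xi1)),
        float(E(xi3) - E(0.0)),
        float(E(hi) - E(xi3)),
    )

    stationary: dict[str, tuple[float, float, float]] = {}
    pct: dict[str, float] = {}
    for bond, fn in ((BREAK_BOND, spec.wbi_break_fn), (FORM_BOND, spec.wbi_form_fn)):
        b_r, b_ts, b_i = float(fn(lo)), float(fn(0.0)), float(fn(hi))
        stationary[bond] = (b_r, b_ts, b_i)
        pct[bond] = 100.0 * (b_ts - b_r) / (b_i - b_r)
    vals = np.array(list(pct.values()))
    mean = float(vals.mean())
    sy = 1.0 - float(np.sum(np.abs(vals - mean)) / mean) / (2 * len(vals) - 2)

    return GroundTruth(
        xi_force_min=float(xi1),
        xi_ts=0.0,
        xi_force_max=float(xi3),
        W1=works[0],
        W2=works[1],
        W3=works[2],
        W4=works[3],
        barrier=float(E(0.0) - E(lo)),
        dE_total=float(E(hi) - E(lo)),
        flux_at_ts=float(spec.flux_fn(0.0)),
        wbi_stationary=stationary,
        percent_evolution=pct,
        mean_evolution=mean,
        synchronicity=sy,
        charge_min_xi=spec.charge_center,
        dipole_change=spec.dipole_delta,
        force_fn=spec.force_fn,
        flux_fn=spec.flux_fn,
        energy_fn=spec.energy_fn,
    )


def make_profile(spec: SyntheticSpec) -> tuple[IRCProfile, GroundTruth]:
    """Generate an IRC profile plus the exact ground truth it encodes."""
    xi = spec.grid
    rng = np.random.default_rng(spec.seed)
    # draw noise in a fixed channel order so that datasets are reproducible
    def noisy(values: np.ndarray, channel: str) -> np.ndarray:
        sd = spec._noise(channel)
        draw = rng.normal(0.0, 1.0, size=len(values))  # always consume the stream
        return values + sd * draw

    profile = IRCProfile(
        xi=xi,
        energy=noisy(spec.energy_fn(xi), "energy"),
        chem_potential=noisy(spec.mu_fn(xi), "mu"),
        charges={CHIRAL_ATOM: noisy(spec.charge_fn(xi), "charge")},
        wbi={
            BREAK_BOND: noisy(spec.wbi_break_fn(xi), "wbi"),
            FORM_BOND: noisy(spec.wbi_form_fn(xi), "wbi"),
        },
        dipole=noisy(spec.dipole_fn(xi), "dipole"),
        meta={
            "species": spec.name,
            "temperature": DEFAULT_TEMPERATURE_K,
            "units": "kcal/mol",
            "seed": spec.seed,
        },
    )
    return profile, _ground_truth(spec)


# ---------------------------------------------------------------------------
# Toy trajectory
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, theta_deg: float,
          phi_deg: float) -> np.ndarray:
    """Place atom d at distance r from c, angle(b,c,d)=theta, torsion(a,b,c,d)=phi."""
    theta = np.radians(theta_deg)
    phi = np.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * np.cos(theta), r * np.sin(theta) * np.cos(phi), r * np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_trajectory(spec: SyntheticSpec) -> GeometrySeries:
    """Six-atom toy trajectory (C1, C2, N3, C4, H5, O6) whose descriptors are
    exactly the analytic curves of the spec.

    Per frame: d(C1,H5) and d(H5,O6) follow the bond-length logistics, the
    C1-H5-O6 angle follows the attack-angle curve, and the N3-C2-C1-C4
    torsion follows the dihedral curve.
    """
    xi = spec.grid
    r1 = np.atleast_1d(spec.r_break_fn(xi))
    r2 = np.atleast_1d(spec.r_form_fn(xi))
    alpha = np.radians(np.atleast_1d(spec.angle_fn(xi)))
    theta = np.atleast_1d(spec.dihedral_fn(xi))

    c1 = np.zeros(3)
    c2 = 1.54 * np.array([np.cos(np.radians(120.0)), np.sin(np.radians(120.0)), 0.0])

    frames = np.empty((len(xi), 6, 3))
    for k in range(len(xi)):
        h5 = np.array([r1[k], 0.0, 0.0])
        o6 = h5 + r2[k] * np.array([-np.cos(alpha[k]), np.sin(alpha[k]), 0.0])
        # N3 bonded to C2; torsion H5-C1-C2-N3 held fixed so the reactive
        # dihedral change is carried entirely by C4
        n3 = _nerf(np.array([1.0, 0.0, 0.0]), c1, c2, 1.47, 109.5, 60.0)
        c4 = _nerf(n3, c2, c1, 1.52, 109.5, theta[k])
        frames[k, 0] = c1
        frames[k, 1] = c2
        frames[k, 2] = n3
        frames[k, 3] = c4
        frames[k, 4] = h5
        frames[k, 5] = o6
    return GeometrySeries(xi=xi, labels=list(ATOM_LABELS), coords=frames)


# ---------------------------------------------------------------------------
# Stationary points
# ---------------------------------------------------------------------------

def make_stationary_points(
    spec: SyntheticSpec,
    T: float = DEFAULT_TEMPERATURE_K,
    dS_activation: float = -0.005,
) -> list[StationaryPoint]:
    """Reactant / TS / intermediate records consistent with the profile.

    Enthalpies equal the synthetic electronic energies at the grid ends and
    ξ=0; the TS entropy is offset by ``dS_activation`` so activation
    thermochemistry has a known answer.
    """
    lo, hi = spec.xi_min, spec.xi_max
    points = []
    S_R = 0.100  # kcal/(mol K), arbitrary but consistent baseline
    for role, x, S in (
        ("reactant", lo, S_R),
        ("transition_state", 0.0, S_R + dS_activation),
        ("intermediate", hi, S_R),
    ):
        E = float(spec.energy_fn(x))
        H = E
        G = H - T * S
        points.append(
            StationaryPoint(
                role=role,
                E=E,
                H=H,
                G=G,
                S=S,
                charges={CHIRAL_ATOM: float(spec.charge_fn(x))},
                wbi={
                    BREAK_BOND: float(spec.wbi_break_fn(x)),
                    FORM_BOND: float(spec.wbi_form_fn(x)),
                },
            )
        )
    return points


# ---------------------------------------------------------------------------
# Hammett series
# ---------------------------------------------------------------------------

def make_hammett_series(
    rho_true: float,
    sigma_list: Sequence[tuple[str, float]] | Sequence[float],
    T: float = DEFAULT_TEMPERATURE_K,
    noise_sd: float = 0.0,
    seed: int = 0,
    dH_reference: float = 25.0,
    dS_activation: float = -0.005,
) -> HammettSeries:
    """Substituent series with an exactly known reaction constant.

    ΔH‡_X = ΔH‡_H - 2.303·R·T·ρ_true·σ_X (+ Gaussian noise); ΔS‡ is the
    same for every entry, so the noiseless enthalpy-form intercept is 0 and
    the free-energy and enthalpy fits coincide.
    """
    entries_in: list[tuple[str, float]] = []
    for item in sigma_list:
        if isinstance(item, (tuple, list)):
            entries_in.append((str(item[0]), float(item[1])))
        else:
            entries_in.append((f"sigma={float(item):+.2f}", float(item)))
    if len(entries_in) < 3:
        raise ValidationError("need at least 3 substituents")
    if not any(s == 0.0 for _, s in entries_in):
        raise ValidationError("series must include a sigma=0 reference substituent")

    rng = np.random.default_rng(seed)
    factor = LOG10_FACTOR * GAS_CONSTANT_KCAL * T
    entries = []
    for label, sigma in entries_in:
        dH = dH_reference - factor * rho_true * sigma + noise_sd * rng.normal()
        dG = dH - T * dS_activation
        entries.append(HammettEntry(label=label, sigma=sigma, dH=dH, dG=dG))
    return HammettSeries(entries=entries, T=T)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def aromatic_like(seed: int = 0, noise_sd: float | Mapping[str, float] = 0.0) -> SyntheticSpec:
    """Aromatic-style preset: TS close in energy to the intermediate, small
    attack-angle variation, late dihedral change, decreasing dipole, moderate
    bond-evolution percentages."""
    return SyntheticSpec(
        name="aromatic_like",
        barrier_height=22.0,
        barrier_width=0.5,
        step_E_RI=16.0,
        mu_drop=-4.0,
        wbi_break=LogisticParams(-0.15, 0.35),
        wbi_form=LogisticParams(-0.05, 0.35),
        charge_center=0.15,
        dihedral=LogisticParams(1.0, 0.4),
        angle_delta=2.0,
        angle_R=172.0,
        dipole_R=6.0,
        dipole_delta=-2.0,
        seed=seed,
        noise_sd=noise_sd,
    )


def aliphatic_like(seed: int = 0, noise_sd: float | Mapping[str, float] = 0.0) -> SyntheticSpec:
    """Aliphatic-style preset: larger barrier and works, TS and intermediate
    nearly isoenergetic, early dihedral change, increasing dipole, high
    bond-evolution percentages, larger flux magnitude."""
    return SyntheticSpec(
        name="aliphatic_like",
        barrier_height=28.0,
        barrier_width=0.5,
        step_E_RI=24.0,
        mu_drop=-7.0,
        wbi_break=LogisticParams(-0.45, 0.35),
        wbi_form=LogisticParams(-0.35, 0.35),
        charge_center=0.05,
        dihedral=LogisticParams(-0.8, 0.4),
        angle_delta=12.0,
        angle_R=160.0,
        dipole_R=4.0,
        dipole_delta=3.0,
        seed=seed,
        noise_sd=noise_sd,
    )


PRESETS: dict[str, Callable[..., SyntheticSpec]] = {
    "aromatic_like": aromatic_like,
    "aliphatic_like": aliphatic_like,
}


def preset(name: str, seed: int = 0, noise_sd: float | Mapping[str, float] = 0.0) -> SyntheticSpec:
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return PRESETS[name](seed=seed, noise_sd=noise_sd)


def with_overrides(spec: SyntheticSpec, **kwargs) -> SyntheticSpec:
    """Functional update helper (dataclasses.replace with validation)."""
    return replace(spec, **kwargs)
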