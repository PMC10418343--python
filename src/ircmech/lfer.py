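"""Activation thermochemistry and Hammett linear free-energy analysis.

The rate-ratio response used throughout is

    y_X = (Δ‡_H - Δ‡_X) / (2.303 * R * T)

with Δ‡ either the activation free energy or the activation enthalpy of the
unsubstituted reference (H) and substituent X.  Ordinary least squares of
y_X on the substituent constant σ_X gives the reaction constant ρ (slope);
for the enthalpy response the intercept carries the entropy difference

    Δ(ΔS) = 2.303 * R * intercept.

A positive ρ indicates negative charge build-up in the rate-determining
step.  The activation-energy convention is Ea = ΔH‡ + R*T (solution-phase
transition-state theory, unimolecular step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ircmech.constants import DEFAULT_TEMPERATURE_K, GAS_CONSTANT_KCAL, LOG10_FACTOR
from ircmech.exceptions import NumericalError, ValidationError
from ircmech.io_formats import StationaryPoint


@dataclass
class ActivationParameters:
    """ΔH‡, ΔG‡, ΔS‡ and Ea at temperature T.

    Invariants: dS = (dH - dG)/T and Ea = dH + R*T.
    """

    dH: float
    dG: float
    dS: float
    Ea: float
    T: float


@dataclass
class HammettEntry:
    label: str
    sigma: float
    dH: float | None = None
    dG: float | None = None


@dataclass
class HammettSeries:
    """Substituent series with activation parameters at temperature T.

    Exactly one entry must have σ = 0 (the unsubstituted reference).
    """

    entries: list[HammettEntry]
    T: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        refs = [e for e in self.entries if e.sigma == 0.0]
        if len(refs) != 1:
            raise ValidationError(
                f"series needs exactly one sigma=0 reference entry, found {len(refs)}"
            )
        self._reference = refs[0]

    @property
    def reference(self) -> HammettEntry:
        return self._reference

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class HammettFit:
    rho: float
    intercept: float
    r: float
    n: int
    response_used: str
    delta_delta_S: float | None = None
    T: float = DEFAULT_TEMPERATURE_K

    @property
    def charge_interpretation(self) -> str:
        """Mechanistic sign rule: positive ρ means negative charge developed."""
        if self.rho > 0:
            return "negative charge developed"
        if self.rho < 0:
            return "positive charge developed"
        return "no charge sensitivity"


def activation_parameters(
    reactant: StationaryPoint, ts: StationaryPoint, T: float
) -> ActivationParameters:
    """Activation thermochemistry between a reactant and its transition state."""
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")
    for sp, name in ((reactant, "reactant"), (ts, "transition state")):
        if sp.H is None or sp.G is None:
            raise ValidationError(f"{name} record lacks H and/or G")
    dH = ts.H - reactant.H
    dG = ts.G - reactant.G
    dS = (dH - dG) / T
    Ea = dH + GAS_CONSTANT_KCAL * T
    return ActivationParameters(dH=dH, dG=dG, dS=dS, Ea=Ea, T=T)


def log_rate_ratio(dG_H: float, dG_X: float, T: float) -> float:
    """log(k/k0) = (ΔG‡_H - ΔG‡_X) / (2.303 R T)."""
    if T <= 0:
        raise ValidationError(f"temperature must be positive, got {T}")
    return (dG_H - dG_X) / (LOG10_FACTOR * GAS_CONSTANT_KCAL * T)


def entropy_from_intercept(intercept: float) -> float:
    """Δ(ΔS) = 2.303 * R * intercept, in kcal mol^-1 K^-1."""
    return LOG10_FACTOR * GAS_CONSTANT_KCAL * float(intercept)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    if len(x) < 3:
        raise ValidationError(f"need at least 3 points to fit, got {len(x)}")
    if np.ptp(x) == 0:
        raise NumericalError("singular fit: all predictor values identical")
    if np.ptp(y) == 0:
        raise NumericalError("degenerate fit: constant response, correlation undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def hammett_fit(series: HammettSeries, response: str = "enthalpy") -> HammettFit:
    """OLS of y_X = (Δ‡_H - Δ‡_X)/(2.303 R T) on σ_X over all entries.

    ``response`` selects the free-energy or the enthalpy form; the reference
    entry contributes (0, 0) by construction.  For the enthalpy response the
    entropy difference 2.303*R*intercept is attached.
    """
    if response not in ("free_energy", "enthalpy"):
        raise ValidationError(f"unknown response {response!r}")
    attr = "dG" if response == "free_energy" else "dH"
    ref_val = getattr(series.reference, attr)
    if ref_val is None:
        raise ValidationError(f"reference entry lacks {attr}")
    sigmas, ys = [], []
    for entry in series.entries:
        val = getattr(entry, attr)
        if val is None:
            raise ValidationError(f"entry {entry.label!r} lacks {attr}")
        sigmas.append(entry.sigma)
        ys.append(log_rate_ratio(ref_val, val, series.T))
    slope, intercept, r = _ols(np.asarray(sigmas), np.asarray(ys))
    dds = entropy_from_intercept(intercept) if response == "enthalpy" else None
    return HammettFit(
        rho=slope,
        intercept=intercept,
        r=r,
        n=len(series),
        response_used=response,
        delta_delta_S=dds,
        T=series.T,
    )


def correlate_with_sigma(
    values: Sequence[float], sigmas: Sequence[float]
) -> tuple[float, float, float]:
    """OLS + Pearson r of an arbitrary per-substituent quantity against σ."""
    values = np.asarray(values, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if len(values) != len(sigmas):
        raise ValidationError("values and sigmas must pair up")
    return _ols(sigmas, values)


@dataclass
class ChargeEnergyCorrelation:
    slope: float
    intercept: float
    r: float
    constant_function: bool = False


def charge_energy_correlation(
    charges: Sequence[float],
    activation_energies: Sequence[float],
    slope_epsilon: float = 1e-6,
) -> ChargeEnergyCorrelation:
    """OLS + Pearson r of a per-species atomic charge (response) against
    activation energy (predictor).

    A fit whose |slope| falls below ``slope_epsilon`` is flagged as a
    constant function: the charge barely moves with activation energy, so a
    high r carries no mechanistic leverage.
    """
    charges = np.asarray(charges, dtype=float)
    ea = np.asarray(activation_energies, dtype=float)
    if len(charges) != len(ea):
        raise ValidationError("charges and activation energies must pair up")
    slope, intercept, r = _ols(ea, charges)
    return ChargeEnergyCorrelation(
        slope=slope,
        intercept=intercept,
        r=r,
        constant_function=abs(slope) < slope_epsilon,
    )


def load_sigma_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the substituent-constant table (columns: substituent, sigma).

    Defaults to the editable Hansch-type table shipped with the package.
    """
    if path is None:
        ref = resources.files("ircmech").joinpath("data/sigma_constants.csv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p)
    return pd.read_csv(path)
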