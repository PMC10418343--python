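"""Electronic descriptor evolution: NBO charges, dipole and Wiberg bond
indices along the IRC, per-bond percentage evolution, and synchronicity.

Percentage evolution of bond i between reactant (R), transition state (TS)
and intermediate (I) Wiberg indices:

    %Ev_i = 100 * (B_TS - B_R) / (B_I - B_R)

Synchronicity over n >= 2 bonds:

    Sy = 1 - [ sum_i |%Ev_i - mean| / mean ] / (2n - 2)

Sy = 1 iff every bond has progressed equally at the TS.  Values outside
[0, 100]% ("overshoot") and negative Sy are reported as-is with a warning,
never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ircmech.exceptions import ValidationError
from ircmech.io_formats import IRCProfile, StationaryPoint, normalize_bond_label
from ircmech.structure import DescriptorSeries, EvolutionCurve, length_evolution_curve

logger = logging.getLogger(__name__)


@dataclass
class BondEvolution:
    bond: str
    B_R: float
    B_TS: float
    B_I: float
    percent_evolution: float

    @property
    def timing(self) -> str:
        """'early' below 50%, 'late' above, 'synchronous' at exactly 50%."""
        if self.percent_evolution < 50.0:
            return "early"
        if self.percent_evolution > 50.0:
            return "late"
        return "synchronous"


@dataclass
class SynchronicityResult:
    evolutions: list[BondEvolution]
    mean_evolution: float
    synchronicity: float


def percent_evolution(B_R: float, B_TS: float, B_I: float) -> float:
    """100 * (B_TS - B_R) / (B_I - B_R)."""
    if B_I == B_R:
        raise ValidationError(
            "percent evolution undefined: reactant and intermediate bond indices equal"
        )
    value = 100.0 * (B_TS - B_R) / (B_I - B_R)
    if not (0.0 <= value <= 100.0):
        logger.warning("percent evolution %.3f%% outside [0, 100]: TS overshoot", value)
    return value


def synchronicity(evolutions: Sequence[BondEvolution | float]) -> SynchronicityResult:
    """Sy = 1 - [Σ|%Ev_i - mean|/mean]/(2n-2) over n >= 2 bond evolutions.

    Accepts either :class:`BondEvolution` records or bare percentages.
    """
    if len(evolutions) < 2:
        raise ValidationError("synchronicity needs at least 2 bond evolutions")
    records: list[BondEvolution] = []
    for i, ev in enumerate(evolutions):
        if isinstance(ev, BondEvolution):
            records.append(ev)
        else:
            records.append(BondEvolution(f"bond{i}", np.nan, np.nan, np.nan, float(ev)))
    pct = np.array([r.percent_evolution for r in records])
    mean = float(np.mean(pct))
    if mean == 0.0:
        raise ValidationError("synchronicity undefined: mean evolution is zero")
    n = len(pct)
    sy = 1.0 - float(np.sum(np.abs(pct - mean)) / mean) / (2 * n - 2)
    if sy < 0.0:
        logger.warning("negative synchronicity %.4f: extreme asynchrony", sy)
    return SynchronicityResult(evolutions=records, mean_evolution=mean, synchronicity=sy)


def stationary_evolutions(
    points: Iterable[StationaryPoint] | Mapping[str, StationaryPoint],
    bonds: Sequence[str],
) -> SynchronicityResult:
    """Per-bond %Ev and synchronicity from stationary-point Wiberg indices.

    Requires reactant, transition_state and intermediate records, each with a
    Wiberg index for every requested bond.
    """
    if isinstance(points, Mapping):
        by_role = dict(points)
    else:
        by_role = {sp.role: sp for sp in points}
    for role in ("reactant", "transition_state", "intermediate"):
        if role not in by_role:
            raise ValidationError(f"missing stationary point with role {role!r}")
    if len(bonds) < 2:
        raise ValidationError("synchronicity needs at least 2 bonds")

    evolutions = []
    for bond in bonds:
        key = normalize_bond_label(bond)
        for role in ("reactant", "transition_state", "intermediate"):
            if key not in by_role[role].wbi:
                raise ValidationError(f"bond {key!r} missing from {role!r} Wiberg indices")
        b_r = by_role["reactant"].wbi[key]
        b_ts = by_role["transition_state"].wbi[key]
        b_i = by_role["intermediate"].wbi[key]
        evolutions.append(
            BondEvolution(key, b_r, b_ts, b_i, percent_evolution(b_r, b_ts, b_i))
        )
    return synchronicity(evolutions)


# ---------------------------------------------------------------------------
# Channel extraction
# ---------------------------------------------------------------------------

def charge_series(profile: IRCProfile, atom: str) -> DescriptorSeries:
    """NBO charge of one atom along the path (e)."""
    if atom not in profile.charges:
        raise ValidationError(
            f"no charge channel for atom {atom!r} (have {sorted(profile.charges)})"
        )
    return DescriptorSeries(profile.xi, profile.charges[atom], f"q({atom})", "charge", "e")


def dipole_series(profile: IRCProfile) -> DescriptorSeries:
    """Molecular dipole magnitude along the path (Debye)."""
    if profile.dipole is None:
        raise ValidationError("profile has no dipole channel")
    return DescriptorSeries(profile.xi, profile.dipole, "dipole", "dipole", "debye")


def wbi_series(profile: IRCProfile, bond: str) -> DescriptorSeries:
    """Wiberg bond index of one bond along the path (dimensionless)."""
    key = normalize_bond_label(bond)
    if key not in profile.wbi:
        raise ValidationError(
            f"no Wiberg channel for bond {key!r} (have {sorted(profile.wbi)})"
        )
    return DescriptorSeries(profile.xi, profile.wbi[key], f"wbi({key})", "wbi", "")


def wbi_evolution_curve(
    profile: IRCProfile, breaking_bond: str, forming_bond: str
) -> EvolutionCurve:
    """Breaking-vs-forming progress curve on Wiberg indices.

    Same normalization as the bond-length evolution curve but using the WBI
    channels; raises on a flat channel.
    """
    b = wbi_series(profile, breaking_bond)
    f = wbi_series(profile, forming_bond)
    for series in (b, f):
        if series.total_variation == 0.0:
            raise ValidationError(f"flat Wiberg channel {series.descriptor}")
    return length_evolution_curve(b, f)
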