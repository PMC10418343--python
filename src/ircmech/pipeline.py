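"""End-to-end orchestration: load or synthesize a dataset, run the
energetics / structure / electronics / LFER stages, and emit a
machine-readable report with provenance metadata.

Reports are plain dicts of floats serialized at 12 significant digits, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from ircmech import electronics, energetics, structure, synthetic
from ircmech.constants import DEFAULT_TEMPERATURE_K
from ircmech.exceptions import IrcmechError, ValidationError
from ircmech.io_formats import (
    IRCProfile,
    read_irc_table,
    read_stationary_points,
    read_xyz_trajectory,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class AnalysisConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``preset`` (synthetic) or ``irc_table`` (file input) must
    be given.
    """

    preset: str | None = None
    irc_table: str | None = None
    trajectory: str | None = None
    stationary_points: str | None = None
    species: str | None = None
    units: str = "kcal"
    chiral_carbon: str = "C1"
    acid_hydrogen: str = "H5"
    nucleophile_oxygen: str = "O6"
    dihedral_atoms: tuple[str, str, str, str] = ("N3", "C2", "C1", "C4")
    breaking_bond: str = "C1-H5"
    forming_bond: str = "H5-O6"
    temperature: float = DEFAULT_TEMPERATURE_K
    seed: int = 0
    noise_sd: float = 0.0
    smooth_window: int | None = None

    def __post_init__(self) -> None:
        if (self.preset is None) == (self.irc_table is None):
            raise ValidationError(
                "config must set exactly one of 'preset' or 'irc_table'"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "dihedral_atoms" in doc:
            doc["dihedral_atoms"] = tuple(doc["dihedral_atoms"])
        return cls(**doc)

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict

        d = asdict(self)
        d["dihedral_atoms"] = list(d["dihedral_atoms"])
        return d


def _round_sig(x: float, digits: int = 12) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(f"{x:.{digits}g}")


def _round_payload(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {k: _round_payload(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_payload(v) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return _round_sig(float(obj))
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


class _Stage:
    """Context manager that prefixes errors with the failing stage name."""

    def __init__(self, name: str, species: str):
        self.name = name
        self.species = species

    def __enter__(self):
        logger.info("stage %s (%s) starting", self.name, self.species)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, IrcmechError):
            raise type(exc)(
                f"stage {self.name!r} failed for species {self.species!r}: {exc}"
            ) from exc
        return False


def run_analysis(config: AnalysisConfig) -> dict[str, Any]:
    """Run all applicable stages and return the report dict."""
    species = config.species or config.preset or "input"

    geoms = None
    stationary = None
    truth = None
    with _Stage("load", species):
        if config.preset is not None:
            spec = synthetic.preset(config.preset, seed=config.seed, noise_sd=config.noise_sd)
            profile, truth = synthetic.make_profile(spec)
            geoms = synthetic.make_trajectory(spec)
            stationary = synthetic.make_stationary_points(spec, T=config.temperature)
        else:
            profile = read_irc_table(config.irc_table, units=config.units)
            if config.trajectory:
                geoms = read_xyz_trajectory(config.trajectory)
            if config.stationary_points:
                by_species = read_stationary_points(config.stationary_points)
                key = config.species if config.species in by_species else next(iter(by_species))
                stationary = by_species[key]

    report: dict[str, Any] = {"species": species}

    with _Stage("energetics", species):
        force = energetics.reaction_force(profile, smooth_window=config.smooth_window)
        cps = energetics.locate_critical_points(force, ts_xi=0.0, energy=profile.energy)
        works = energetics.reaction_works(profile, cps, force=force)
        report["works"] = {
            "xi_force_min": works.xi_force_min,
            "xi_ts": works.xi_ts,
            "xi_force_max": works.xi_force_max,
            "W1": works.W1,
            "W2": works.W2,
            "W3": works.W3,
            "W4": works.W4,
            "activation_work": works.activation_work,
            "total": works.total,
        }
        if profile.chem_potential is not None:
            flux = energetics.electronic_flux(profile, smooth_window=config.smooth_window)
            i_ts = profile.ts_index()
            report["flux"] = {
                "at_ts": float(flux.flux[i_ts]),
                "min": float(np.min(flux.flux)),
                "max": float(np.max(flux.flux)),
            }

    if geoms is not None:
        with _Stage("structure", species):
            d_break = structure.distance_series(
                geoms, config.chiral_carbon, config.acid_hydrogen
            )
            d_form = structure.distance_series(
                geoms, config.acid_hydrogen, config.nucleophile_oxygen
            )
            attack = structure.angle_series(
                geoms,
                config.chiral_carbon,
                config.acid_hydrogen,
                config.nucleophile_oxygen,
            )
            dihedral = structure.dihedral_series(geoms, *config.dihedral_atoms)
            curve = structure.length_evolution_curve(d_break, d_form)
            report["structure"] = {
                "breaking_distance": d_break.summary(),
                "forming_distance": d_form.summary(),
                "attack_angle": attack.summary()
                | {"total_variation": attack.total_variation},
                "dihedral": dihedral.summary()
                | {"total_variation": dihedral.total_variation},
                "length_curve_deviation": curve.deviation,
            }

    with _Stage("electronics", species):
        elec: dict[str, Any] = {}
        if config.chiral_carbon in profile.charges:
            elec["chiral_charge"] = electronics.charge_series(
                profile, config.chiral_carbon
            ).summary()
        if profile.dipole is not None:
            dip = electronics.dipole_series(profile)
            elec["dipole"] = dip.summary() | {
                "end_to_end_change": float(dip.values[-1] - dip.values[0])
            }
        if profile.wbi:
            curve = electronics.wbi_evolution_curve(
                profile, config.breaking_bond, config.forming_bond
            )
            elec["wbi_curve_deviation"] = curve.deviation
        if stationary is not None:
            sync = electronics.stationary_evolutions(
                stationary, [config.breaking_bond, config.forming_bond]
            )
            elec["percent_evolution"] = {
                ev.bond: ev.percent_evolution for ev in sync.evolutions
            }
            elec["mean_evolution"] = sync.mean_evolution
            elec["synchronicity"] = sync.synchronicity
        report["electronics"] = elec

    if truth is not None:
        report["ground_truth"] = {
            "W1": truth.W1,
            "W2": truth.W2,
            "W3": truth.W3,
            "W4": truth.W4,
            "xi_force_min": truth.xi_force_min,
            "xi_force_max": truth.xi_force_max,
            "flux_at_ts": truth.flux_at_ts,
            "mean_evolution": truth.mean_evolution,
            "synchronicity": truth.synchronicity,
        }

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    report["provenance"] = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
    }
    return _round_payload(report)


# ---------------------------------------------------------------------------
# Cross-species comparison
# ---------------------------------------------------------------------------

_COMPARE_FIELDS = {
    "W1": ("works", "W1"),
    "W2": ("works", "W2"),
    "W3": ("works", "W3"),
    "W4": ("works", "W4"),
    "activation_work": ("works", "activation_work"),
    "flux_at_ts": ("flux", "at_ts"),
    "mean_evolution": ("electronics", "mean_evolution"),
    "synchronicity": ("electronics", "synchronicity"),
}


@dataclass
class ComparisonResult:
    table: pd.DataFrame
    differences: pd.DataFrame
    flags: dict[str, bool] = field(default_factory=dict)


def compare_series(reports: Sequence[Mapping[str, Any]]) -> ComparisonResult:
    """Tidy cross-species table of works, %Ev, Sy and trend flags.

    Requires at least two reports sharing at least one comparable field.
    Differences are taken against the first report; trend flags (computed,
    never asserted) record the aromatic-vs-aliphatic orderings of interest.
    """
    if len(reports) < 2:
        raise ValidationError("comparison needs at least two reports")
    rows = []
    for rep in reports:
        row: dict[str, Any] = {"species": rep.get("species", "?")}
        for col, (sect, key) in _COMPARE_FIELDS.items():
            row[col] = rep.get(sect, {}).get(key) if isinstance(rep.get(sect), Mapping) else None
        rows.append(row)
    table = pd.DataFrame(rows)
    shared = [c for c in _COMPARE_FIELDS if table[c].notna().all()]
    if not shared:
        raise ValidationError("reports have no shared comparable fields")
    table = table[["species"] + shared]

    diffs = table[shared].astype(float) - table[shared].astype(float).iloc[0]
    diffs.insert(0, "species", table["species"])

    flags: dict[str, bool] = {}
    named = {row["species"]: row for row in rows}
    if "aromatic_like" in named and "aliphatic_like" in named:
        aro, ali = named["aromatic_like"], named["aliphatic_like"]
        if aro.get("mean_evolution") is not None and ali.get("mean_evolution") is not None:
            flags["aliphatic_higher_evolution"] = (
                ali["mean_evolution"] > aro["mean_evolution"]
            )
        if aro.get("W1") is not None and ali.get("W1") is not None:
            flags["aromatic_smaller_W1"] = aro["W1"] < ali["W1"]
    return ComparisonResult(table=table, differences=diffs, flags=flags)
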