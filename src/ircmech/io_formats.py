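"""External representations: IRC tables, XYZ trajectories, stationary-point
thermochemistry and result reports.

All readers validate on construction and convert to the canonical internal
units (kcal/mol, e, Debye, Angstrom, degrees, K).  Delimited text uses comma
or tab, auto-detected; bond labels are order-normalized so that ``"H5-O6"``
and ``"O6-H5"`` name the same channel.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ircmech.constants import HARTREE_TO_KCAL
from ircmech.exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

_ROLES = ("reactant", "transition_state", "intermediate", "product")

_LABEL_RE = re.compile(r"^([A-Za-z]+)(\d*)$")


def _label_key(label: str) -> tuple[str, int]:
    """Natural sort key for atom labels like ``C1``, ``H5``, ``O6``."""
    m = _LABEL_RE.match(label)
    if m is None:
        return (label, 0)
    elem, num = m.groups()
    return (elem, int(num) if num else 0)


def normalize_bond_label(label: str) -> str:
    """Return the canonical order-normalized form of a bond label.

    ``"O6-H5"`` and ``"H5-O6"`` both normalize to ``"H5-O6"``.
    """
    parts = label.split("-")
    if len(parts) != 2 or not all(parts):
        raise ValidationError(f"malformed bond label {label!r}; expected 'A-B'")
    a, b = parts
    if _label_key(b) < _label_key(a):
        a, b = b, a
    return f"{a}-{b}"


def _as_finite_array(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"channel {name!r} must be one-dimensional")
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise ValidationError(f"channel {name!r} has non-finite value at row {bad[0]}")
    return arr


@dataclass
class IRCProfile:
    """A sampled reaction path: strictly increasing ξ grid plus per-point
    scalar channels.

    Energies and the chemical potential are stored in kcal/mol, charges in e,
    the dipole in Debye.  ``meta`` records species name, temperature and the
    units as read.
    """

    xi: np.ndarray
    energy: np.ndarray
    chem_potential: np.ndarray | None = None
    charges: dict[str, np.ndarray] = field(default_factory=dict)
    wbi: dict[str, np.ndarray] = field(default_factory=dict)
    dipole: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xi = _as_finite_array(self.xi, "xi")
        n = len(self.xi)
        if n < 3:
            raise ValidationError(f"IRC profile needs at least 3 points, got {n}")
        if not np.all(np.diff(self.xi) > 0):
            raise ValidationError("xi grid must be strictly increasing")
        self.energy = self._check_channel(self.energy, "energy")
        if self.chem_potential is not None:
            self.chem_potential = self._check_channel(self.chem_potential, "mu")
        self.charges = {k: self._check_channel(v, f"q_{k}") for k, v in self.charges.items()}
        self.wbi = {
            normalize_bond_label(k): self._check_channel(v, f"wbi_{k}")
            for k, v in self.wbi.items()
        }
        if self.dipole is not None:
            self.dipole = self._check_channel(self.dipole, "dipole")
        if self.meta.get("ts_centered"):
            i_ts = int(np.argmin(np.abs(self.xi)))
            if int(np.argmax(self.energy)) != i_ts:
                raise ValidationError(
                    "profile flagged ts_centered but the energy maximum is not at "
                    "the grid point nearest xi=0"
                )

    def _check_channel(self, values: Sequence[float], name: str) -> np.ndarray:
        arr = _as_finite_array(values, name)
        if len(arr) != len(self.xi):
            raise ValidationError(
                f"channel {name!r} has {len(arr)} values for {len(self.xi)} grid points"
            )
        return arr

    @property
    def n_points(self) -> int:
        return len(self.xi)

    def ts_index(self) -> int:
        """Index of the grid point nearest ξ=0."""
        return int(np.argmin(np.abs(self.xi)))


@dataclass
class StationaryPoint:
    """Thermochemistry (kcal/mol) and optional electronic data for one
    optimized structure in a given mechanistic role."""

    role: str
    E: float | None = None
    H: float | None = None
    G: float | None = None
    S: float | None = None
    charges: dict[str, float] = field(default_factory=dict)
    wbi: dict[str, float] = field(default_factory=dict)
    geometry: "GeometrySeries | None" = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {_ROLES}")
        self.wbi = {normalize_bond_label(k): float(v) for k, v in self.wbi.items()}

    def check_consistency(self, temperature: float, tol: float = 1e-6) -> bool:
        """Check G = H - T*S; log a warning (but keep the record) on mismatch."""
        if None in (self.H, self.G, self.S):
            return True
        resid = self.G - (self.H - temperature * self.S)
        if abs(resid) > tol:
            logger.warning(
                "role %s: G inconsistent with H - T*S by %.6g kcal/mol at T=%.4g K",
                self.role, resid, temperature,
            )
            return False
        return True


@dataclass
class GeometrySeries:
    """Cartesian frames (Angstrom) aligned to a ξ grid.

    ``coords`` has shape (n_frames, n_atoms, 3); atom order is constant
    across frames.
    """

    xi: np.ndarray
    labels: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.xi = _as_finite_array(self.xi, "xi")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != len(self.xi):
            raise ValidationError(
                f"{self.coords.shape[0]} frames for {len(self.xi)} xi values"
            )
        if self.coords.shape[1] != len(self.labels):
            raise ValidationError("label count does not match atom count")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("atom labels must be unique within a frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinate in trajectory")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"unknown atom label {label!r}") from None


# ---------------------------------------------------------------------------
# IRC tables
# ---------------------------------------------------------------------------

_DEFAULT_COLUMN_MAP = {"xi": "xi", "energy": "E"}


def read_irc_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    units: str = "kcal",
    meta: Mapping[str, Any] | None = None,
) -> IRCProfile:
    """Read a delimited IRC table into an :class:`IRCProfile`.

    Required columns (after ``column_map`` renaming): ``xi`` and ``E``.
    Optional: ``mu``, ``dipole``, per-atom charges ``q_<label>`` and per-bond
    Wiberg indices ``wbi_<A>-<B>``.  ``units="hartree"`` converts energy-like
    channels to kcal/mol exactly once (recorded in ``meta``).
    """
    path = Path(path)
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    for key in ("xi", "energy"):
        if cmap[key] not in df.columns:
            raise FormatError(
                f"{path}: missing mandatory column {cmap[key]!r} (have {list(df.columns)})"
            )

    for col in df.columns:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValidationError(f"{path}: NaN in column {col!r} at row {bad[0]}")

    df = df.sort_values(cmap["xi"], kind="mergesort").reset_index(drop=True)
    xi = df[cmap["xi"]].to_numpy(dtype=float)
    if np.any(np.diff(xi) <= 0):
        dup = xi[np.flatnonzero(np.diff(xi) <= 0)[0]]
        raise ValidationError(f"{path}: xi grid not strictly increasing (duplicate near {dup})")

    scale = HARTREE_TO_KCAL if units == "hartree" else 1.0
    full_meta: dict[str, Any] = {"source": str(path), "units": "kcal/mol"}
    if units == "hartree":
        full_meta["converted_from"] = "hartree"
    if meta:
        full_meta.update(meta)

    charges: dict[str, np.ndarray] = {}
    wbi: dict[str, np.ndarray] = {}
    mu = None
    dipole = None
    mu_col = cmap.get("mu", "mu")
    dipole_col = cmap.get("dipole", "dipole")
    if mu_col in df.columns:
        mu = df[mu_col].to_numpy(dtype=float) * scale
    if dipole_col in df.columns:
        dipole = df[dipole_col].to_numpy(dtype=float)
    for col in df.columns:
        if col.startswith("q_"):
            charges[col[2:]] = df[col].to_numpy(dtype=float)
        elif col.startswith("wbi_"):
            wbi[col[4:]] = df[col].to_numpy(dtype=float)

    return IRCProfile(
        xi=xi,
        energy=df[cmap["energy"]].to_numpy(dtype=float) * scale,
        chem_potential=mu,
        charges=charges,
        wbi=wbi,
        dipole=dipole,
        meta=full_meta,
    )


def write_irc_table(profile: IRCProfile, path: str | Path) -> Path:
    """Write an IRC profile as a comma-delimited table at full precision."""
    path = Path(path)
    data: dict[str, np.ndarray] = {"xi": profile.xi, "E": profile.energy}
    if profile.chem_potential is not None:
        data["mu"] = profile.chem_potential
    for label, vals in profile.charges.items():
        data[f"q_{label}"] = vals
    for bond, vals in profile.wbi.items():
        data[f"wbi_{bond}"] = vals
    if profile.dipole is not None:
        data["dipole"] = profile.dipole
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

_XI_TOKEN_RE = re.compile(r"xi\s*=\s*([-+0-9.eEdD]+)")


def read_xyz_trajectory(
    path: str | Path, xi_source: Sequence[float] | None = None
) -> GeometrySeries:
    """Read a concatenated multi-frame XYZ file.

    ξ values come from an ``xi=<float>`` token in each comment line, or from
    the ``xi_source`` sidecar sequence (one value per frame).  Frames are
    returned in ξ order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[np.ndarray] = []
    labels_per_frame: list[list[str]] = []
    comments: list[str] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise FormatError(f"{path}: expected atom count at line {i + 1}") from exc
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            raise FormatError(f"{path}: truncated frame at line {i + 1}")
        comments.append(lines[i + 1])
        labels: list[str] = []
        coords = np.empty((natoms, 3))
        for j in range(natoms):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise FormatError(f"{path}: malformed atom line {i + 3 + j}")
            labels.append(parts[0])
            coords[j] = [float(p) for p in parts[1:4]]
        frames.append(coords)
        labels_per_frame.append(labels)
        i += 2 + natoms

    if not frames:
        raise FormatError(f"{path}: no frames found")
    ref = labels_per_frame[0]
    for k, labels in enumerate(labels_per_frame):
        if labels != ref:
            raise ValidationError(f"{path}: frame {k} atom labels/order differ from frame 0")

    if xi_source is not None:
        xi = np.asarray(list(xi_source), dtype=float)
        if len(xi) != len(frames):
            raise ValidationError(
                f"{path}: sidecar xi list has {len(xi)} values for {len(frames)} frames"
            )
    else:
        xi_vals = []
        for k, comment in enumerate(comments):
            m = _XI_TOKEN_RE.search(comment)
            if m is None:
                raise FormatError(
                    f"{path}: frame {k} comment lacks an 'xi=<float>' token and no "
                    "sidecar xi list was given"
                )
            xi_vals.append(float(m.group(1).replace("D", "e").replace("d", "e")))
        xi = np.asarray(xi_vals)

    order = np.argsort(xi, kind="mergesort")
    return GeometrySeries(xi=xi[order], labels=ref, coords=np.stack(frames)[order])


def write_xyz_trajectory(geoms: GeometrySeries, path: str | Path) -> Path:
    """Write a multi-frame XYZ file with ``xi=<float>`` comment tokens."""
    path = Path(path)
    out: list[str] = []
    for k in range(geoms.n_frames):
        out.append(str(len(geoms.labels)))
        out.append(f"xi={geoms.xi[k]:.17g}")
        for label, (x, y, z) in zip(geoms.labels, geoms.coords[k]):
            out.append(f"{label} {x:.17g} {y:.17g} {z:.17g}")
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# Stationary points
# ---------------------------------------------------------------------------

def read_stationary_points(path: str | Path) -> dict[str, list[StationaryPoint]]:
    """Read a YAML/JSON config of stationary-point thermochemistry.

    Layout::

        species_name:
          T: 383.45            # optional; enables G = H - T*S checking
          points:
            - {role: reactant, E: ..., H: ..., G: ..., S: ..., charges: {...}, wbi: {...}}
            - {role: transition_state, ...}
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise FormatError(f"{path}: expected a mapping of species records")
    result: dict[str, list[StationaryPoint]] = {}
    for species, record in doc.items():
        if not isinstance(record, Mapping) or "points" not in record:
            raise FormatError(f"{path}: species {species!r} lacks a 'points' list")
        temperature = record.get("T")
        points: list[StationaryPoint] = []
        seen_roles: set[str] = set()
        for raw in record["points"]:
            sp = StationaryPoint(
                role=raw["role"],
                E=raw.get("E"),
                H=raw.get("H"),
                G=raw.get("G"),
                S=raw.get("S"),
                charges=dict(raw.get("charges", {})),
                wbi=dict(raw.get("wbi", {})),
            )
            if sp.role in seen_roles:
                raise ValidationError(f"{path}: duplicate role {sp.role!r} for {species!r}")
            seen_roles.add(sp.role)
            if temperature is not None:
                sp.check_consistency(float(temperature))
            points.append(sp)
        result[species] = points
    return result


def write_stationary_points(
    species: Mapping[str, Iterable[StationaryPoint]],
    path: str | Path,
    temperature: float | None = None,
) -> Path:
    path = Path(path)
    doc: dict[str, Any] = {}
    for name, points in species.items():
        rec: dict[str, Any] = {"points": []}
        if temperature is not None:
            rec["T"] = float(temperature)
        for sp in points:
            raw: dict[str, Any] = {"role": sp.role}
            for key in ("E", "H", "G", "S"):
                val = getattr(sp, key)
                if val is not None:
                    raw[key] = float(val)
            if sp.charges:
                raw["charges"] = {k: float(v) for k, v in sp.charges.items()}
            if sp.wbi:
                raw["wbi"] = {k: float(v) for k, v in sp.wbi.items()}
            rec["points"].append(raw)
        doc[name] = rec
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(results: Any, path: str | Path, format: str = "auto") -> Path:
    """Write a result object to disk.

    ``format`` may be ``"csv"``, ``"json"`` or ``"auto"`` (by extension,
    default JSON).  Tabular results get a full-precision value column plus a
    rounded display column; anything else is serialized as a structured JSON
    document.
    """
    path = Path(path)
    if format == "auto":
        format = "csv" if path.suffix.lower() in (".csv", ".tsv", ".txt") else "json"

    # tabular rendering for the decomposition type; everything else is JSON
    from ircmech.energetics import WorkDecomposition

    if format == "csv":
        if isinstance(results, WorkDecomposition):
            rows = [
                {
                    "region": i + 1,
                    "xi_from": lo,
                    "xi_to": hi,
                    "work_kcal_mol": w,
                    "work_display": round(w, 3),
                }
                for i, ((lo, hi), w) in enumerate(
                    zip(results.region_bounds, results.works)
                )
            ]
            pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
            return path
        if isinstance(results, IRCProfile):
            return write_irc_table(results, path)
        if isinstance(results, (list, tuple)) and not results:
            path.write_text("value\n")
            return path
        if isinstance(results, pd.DataFrame):
            results.to_csv(path, index=False, float_format="%.17g")
            return path
        raise FormatError(f"no csv rendering for {type(results).__name__}")

    try:
        payload = _jsonable(results)
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    return path
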