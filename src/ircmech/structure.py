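"""Geometric descriptors along the IRC: distances, the attack angle,
dihedral evolution and breaking-vs-forming bond-length progress curves.

Angles and dihedrals are reported unsigned in [0, 180] degrees; a signed
dihedral is available behind a flag.  All descriptors are invariant to rigid
rotation and translation of the frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ircmech.exceptions import ValidationError
from ircmech.io_formats import GeometrySeries


@dataclass
class DescriptorSeries:
    """One geometric/electronic descriptor sampled on the ξ grid."""

    xi: np.ndarray
    values: np.ndarray
    descriptor: str
    kind: str  # distance | angle | dihedral | charge | dipole | wbi
    units: str = ""

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.xi) != len(self.values):
            raise ValidationError("descriptor length does not match grid")

    @property
    def total_variation(self) -> float:
        """max - min of the descriptor over the path."""
        return float(np.max(self.values) - np.min(self.values))

    def argmin_xi(self) -> float:
        return float(self.xi[int(np.argmin(self.values))])

    def argmax_xi(self) -> float:
        return float(self.xi[int(np.argmax(self.values))])

    def summary(self) -> dict[str, float]:
        return {
            "min": float(np.min(self.values)),
            "max": float(np.max(self.values)),
            "xi_at_min": self.argmin_xi(),
            "xi_at_max": self.argmax_xi(),
            "start": float(self.values[0]),
            "end": float(self.values[-1]),
        }


def _positions(geoms: GeometrySeries, *labels: str) -> list[np.ndarray]:
    if len(set(labels)) != len(labels):
        raise ValidationError(f"atom labels must be distinct, got {labels}")
    return [geoms.coords[:, geoms.index_of(lab), :] for lab in labels]


def distance_series(geoms: GeometrySeries, a: str, b: str) -> DescriptorSeries:
    """Euclidean distance between atoms ``a`` and ``b`` per frame (Angstrom)."""
    pa, pb = _positions(geoms, a, b)
    d = np.linalg.norm(pb - pa, axis=1)
    return DescriptorSeries(geoms.xi, d, f"d({a},{b})", "distance", "angstrom")


def angle_series(geoms: GeometrySeries, a: str, b: str, c: str) -> DescriptorSeries:
    """Angle at vertex ``b`` spanned by ``a`` and ``c``, in degrees."""
    pa, pb, pc = _positions(geoms, a, b, c)
    u = pa - pb
    v = pc - pb
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValidationError("zero-length arm in angle computation")
    cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return DescriptorSeries(geoms.xi, ang, f"angle({a},{b},{c})", "angle", "degrees")


def dihedral_series(
    geoms: GeometrySeries, a: str, b: str, c: str, d: str, signed: bool = False
) -> DescriptorSeries:
    """Torsion of the atom chain a-b-c-d, atan2-based.

    Unsigned in [0, 180] degrees by default; ``signed=True`` returns the
    signed torsion in (-180, 180].
    """
    pa, pb, pc, pd = _positions(geoms, a, b, c, d)
    b1 = pb - pa
    b2 = pc - pb
    b3 = pd - pc
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=1) < 1e-12) or np.any(
        np.linalg.norm(n2, axis=1) < 1e-12
    ):
        raise ValidationError("degenerate dihedral: three consecutive atoms collinear")
    b2n = b2 / np.linalg.norm(b2, axis=1)[:, None]
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, b2n), n2)
    ang = np.degrees(np.arctan2(y, x))
    if not signed:
        ang = np.abs(ang)
    return DescriptorSeries(
        geoms.xi, ang, f"dihedral({a},{b},{c},{d})", "dihedral", "degrees"
    )


@dataclass
class EvolutionCurve:
    """Normalized breaking-vs-forming progress pairs along the path.

    ``deviation`` is the signed value of (forming - breaking) progress at the
    point of largest magnitude: negative means the forming coordinate lags
    (curve below the diagonal when breaking progress is on the x axis).
    """

    p_break: np.ndarray
    p_form: np.ndarray
    deviation: float

    @property
    def max_abs_deviation(self) -> float:
        return abs(self.deviation)


def _normalized_progress(values: np.ndarray, name: str) -> np.ndarray:
    start, end = values[0], values[-1]
    if end == start:
        raise ValidationError(f"{name}: endpoints are equal, progress undefined")
    return np.clip((values - start) / (end - start), 0.0, 1.0)


def length_evolution_curve(
    breaking: DescriptorSeries, forming: DescriptorSeries
) -> EvolutionCurve:
    """Compare normalized progress of a breaking vs a forming coordinate.

    Progress is (value - start)/(end - start), clipped to [0, 1], with the
    first and last grid points as normalization endpoints.
    """
    if len(breaking.xi) != len(forming.xi) or not np.allclose(
        breaking.xi, forming.xi
    ):
        raise ValidationError("breaking and forming series must share a grid")
    pb = _normalized_progress(breaking.values, breaking.descriptor)
    pf = _normalized_progress(forming.values, forming.descriptor)
    diff = pf - pb
    deviation = float(diff[int(np.argmax(np.abs(diff)))])
    return EvolutionCurve(p_break=pb, p_form=pf, deviation=deviation)
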