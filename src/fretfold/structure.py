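"""Dye accessible-volume modelling and Forster distance-to-FRET conversion.

Fluorophores on flexible linkers sample a cloud of sterically allowed
positions around their attachment atom.  This module implements a grid
accessible-volume (AV) model: candidate dye positions within the linker
length of the attachment point are kept if the dye sphere clears every
obstacle atom, and the cloud's centroid is the mean dye position.  The
distance between donor and acceptor mean positions (R_mp convention)
converts to a predicted FRET efficiency through E = 1 / (1 + (R/R0)^6).

The simplification relative to full AV implementations: a single dye-sphere
radius and straight-line reachability (no linker-path search, no
three-radius dye ellipsoid).  That level of geometry is sufficient for
mean-position distances between stem-attached cyanine dyes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Atom",
    "DyeModel",
    "AccessibleVolume",
    "read_coordinates",
    "compute_av",
    "mean_dye_distance",
    "forster_efficiency",
    "distance_from_efficiency",
    "VDW_RADII",
    "DEFAULT_RADIUS",
]

#: van der Waals radii (A) for elements common in nucleic acids
VDW_RADII = {
    "H": 1.10, "C": 1.70, "N": 1.55, "O": 1.52,
    "P": 1.80, "S": 1.80, "MG": 1.73, "K": 2.75, "NA": 2.27,
}
DEFAULT_RADIUS = 1.7


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    position: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class DyeModel:
    """Geometric dye parameters: attachment point and linker dimensions (A)."""

    attachment: tuple[float, float, float]
    linker_length: float = 20.0
    linker_width: float = 4.5      # metadata only in this simplified model
    dye_radius: float = 3.5

    def __post_init__(self) -> None:
        if not (self.linker_length > self.dye_radius > 0):
            raise ValueError("need linker_length > dye_radius > 0")


@dataclass
class AccessibleVolume:
    """Sterically allowed dye positions on a cubic grid."""

    grid_spacing: float
    points: np.ndarray               # (n, 3) allowed positions in A

    @property
    def occluded(self) -> bool:
        return self.points.shape[0] == 0

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def mean_position(self) -> np.ndarray:
        if self.occluded:
            raise ValueError("accessible volume is fully occluded")
        return self.points.mean(axis=0)

    @property
    def volume(self) -> float:
        """Occupied volume in A^3 (point count x grid cell volume)."""
        return self.n_points * self.grid_spacing**3


def _element_from_record(line: str) -> str:
    elem = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not elem:
        # fall back on the atom-name column convention
        name = line[12:16].strip()
        elem = "".join(ch for ch in name if ch.isalpha())[:1].upper()
    return elem


def read_coordinates(pdb_text: str) -> list[Atom]:
    """Obstacle atoms (positions + van der Waals radii) from PDB text.

    Parses ATOM/HETATM records with fixed-column coordinates; a malformed
    record raises a ValueError naming the offending line number.  Unknown
    elements receive the default 1.7 A radius with a warning.
    """
    atoms: list[Atom] = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise ValueError(f"line {lineno}: truncated coordinate record")
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as err:
            raise ValueError(f"line {lineno}: unparsable coordinates") from err
        element = _element_from_record(line)
        radius = VDW_RADII.get(element)
        if radius is None:
            warnings.warn(
                f"line {lineno}: unknown element {element!r}, "
                f"using default radius {DEFAULT_RADIUS} A",
                stacklevel=2,
            )
            radius = DEFAULT_RADIUS
        atoms.append(Atom(line[12:16].strip(), element, (x, y, z), radius))
    return atoms


def compute_av(
    dye: DyeModel,
    obstacles: list[Atom] | None = None,
    grid_spacing: float = 1.0,
) -> AccessibleVolume:
    """Accessible volume of a dye around its attachment point.

    Grid points within the linker length of the attachment survive if the
    dye sphere clears every obstacle (centre distance >= obstacle radius +
    dye radius).  Zero surviving points is an explicit fully-occluded
    result, not an error.
    """
    if not (0.5 <= grid_spacing <= 2.0):
        raise ValueError("grid_spacing must lie in [0.5, 2] A")
    att = np.asarray(dye.attachment, dtype=float)
    L = dye.linker_length
    ax = np.arange(-L, L + grid_spacing / 2, grid_spacing)
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + att
    keep = np.einsum("ij,ij->i", pts - att, pts - att) <= L * L
    pts = pts[keep]

    if obstacles:
        centers = np.array([a.position for a in obstacles])
        radii = np.array([a.radius for a in obstacles]) + dye.dye_radius
        # only obstacles that can reach the linker sphere matter
        near = np.linalg.norm(centers - att, axis=1) <= L + radii
        centers, radii = centers[near], radii[near]
        for c, r in zip(centers, radii):
            d2 = np.einsum("ij,ij->i", pts - c, pts - c)
            pts = pts[d2 >= r * r]
            if pts.size == 0:
                break
    return AccessibleVolume(grid_spacing=grid_spacing, points=pts)


def mean_dye_distance(av_donor: AccessibleVolume,
                      av_acceptor: AccessibleVolume) -> float:
    """Distance between mean dye positions (R_mp convention), in A."""
    return float(np.linalg.norm(av_donor.mean_position - av_acceptor.mean_position))


def forster_efficiency(distance: float, r0: float = 60.0) -> float:
    """FRET efficiency E = 1 / (1 + (R/R0)^6) for inter-dye distance R (A)."""
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if r0 <= 0:
        raise ValueError("R0 must be > 0")
    return 1.0 / (1.0 + (distance / r0) ** 6)


def distance_from_efficiency(e: float, r0: float = 60.0) -> float:
    """Inverse of `forster_efficiency`: R = R0 * (1/E - 1)^(1/6)."""
    if not (0.0 < e <= 1.0):
        raise ValueError("efficiency must lie in (0, 1]")
    return r0 * (1.0 / e - 1.0) ** (1.0 / 6.0)
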