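"""Molecular geometries, XYZ I/O, fragmentation channels, and bundled fixtures.

Geometries are equilibrium structures of neutral molecules; a
:class:`FragmentationChannel` assigns one positive integer charge per atom,
describing complete atomization into cations.  Bundled fixtures are idealized
structures built from standard literature bond lengths and angles (C=C 1.33 Å,
C–Cl 1.73 Å, C–H 1.08 Å, sp² angles); any user geometry can be supplied as an
XYZ file instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MolecularGeometry",
    "FragmentationChannel",
    "read_xyz",
    "write_xyz",
    "fixture_geometry",
    "dihedral_angle",
    "ELEMENT_MASSES",
]

# Standard atomic weights (u); Cl is the 35Cl isotopic mass because the
# coincidence channels of interest select the 35Cl+ fragment.
ELEMENT_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014101778,
    "He": 4.002602,
    "Li": 6.94,
    "Be": 9.0121831,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Ne": 20.1797,
    "Na": 22.98976928,
    "Mg": 24.305,
    "Al": 26.9815385,
    "Si": 28.085,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 34.96885268,  # 35Cl
    "Ar": 39.948,
    "K": 39.0983,
    "Ca": 40.078,
    "Fe": 55.845,
    "Br": 78.9183376,  # 79Br
    "I": 126.90447,
    "Kr": 83.798,
    "Xe": 131.293,
}


class XYZParseError(ValueError):
    """Raised when an XYZ file is malformed; the message names the bad line."""


@dataclass(frozen=True)
class MolecularGeometry:
    """A labeled molecular structure: element symbols, masses (u), positions (Å)."""

    label: str
    elements: tuple[str, ...]
    masses: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "positions", positions)
        n = len(self.elements)
        if n < 2:
            raise ValueError("a geometry needs at least 2 atoms")
        if masses.shape != (n,) or positions.shape != (n, 3):
            raise ValueError(
                f"inconsistent lengths: {n} elements, masses {masses.shape}, "
                f"positions {positions.shape}"
            )
        if not np.all(masses > 0):
            raise ValueError("all masses must be positive")
        if not np.all(np.isfinite(positions)):
            raise ValueError("all coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def approx_equal(self, other: "MolecularGeometry", tol: float = 1e-6) -> bool:
        return (
            self.elements == other.elements
            and np.allclose(self.masses, other.masses, atol=1e-9)
            and np.allclose(self.positions, other.positions, atol=tol)
        )


@dataclass(frozen=True)
class FragmentationChannel:
    """Per-atom integer charges (units of e) for complete atomization into cations."""

    charges: np.ndarray

    def __post_init__(self) -> None:
        charges = np.asarray(self.charges, dtype=int)
        object.__setattr__(self, "charges", charges)
        if charges.ndim != 1 or charges.size == 0:
            raise ValueError("charges must be a non-empty 1D sequence")
        if not np.all(charges >= 1):
            raise ValueError("every fragment charge must be >= 1")

    @classmethod
    def all_singly_charged(cls, geometry: MolecularGeometry) -> "FragmentationChannel":
        return cls(np.ones(geometry.n_atoms, dtype=int))

    def validate_for(self, geometry: MolecularGeometry) -> None:
        if len(self.charges) != geometry.n_atoms:
            raise ValueError(
                f"channel has {len(self.charges)} charges but geometry "
                f"'{geometry.label}' has {geometry.n_atoms} atoms"
            )


def read_xyz(path: str | Path) -> MolecularGeometry:
    """Read a standard XYZ file (count line, comment line, ``El x y z`` rows, Å).

    Masses are looked up from the bundled element-mass table; the comment line
    becomes the geometry label.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise XYZParseError(f"{path}: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"{path}, line 1: expected an atom count, got {lines[0]!r}")
    if len(lines) < n + 2:
        raise XYZParseError(
            f"{path}: count line says {n} atoms but only {max(len(lines) - 2, 0)} atom rows present"
        )
    label = lines[1].strip()
    elements: list[str] = []
    positions = np.empty((n, 3))
    for i in range(n):
        lineno = i + 3
        parts = lines[i + 2].split()
        if len(parts) < 4:
            raise XYZParseError(f"{path}, line {lineno}: expected 'El x y z', got {lines[i + 2]!r}")
        el = parts[0].capitalize()
        if el not in ELEMENT_MASSES:
            raise XYZParseError(f"{path}, line {lineno}: unknown element symbol {parts[0]!r}")
        try:
            positions[i] = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"{path}, line {lineno}: non-numeric coordinate in {lines[i + 2]!r}")
        elements.append(el)
    masses = np.array([ELEMENT_MASSES[e] for e in elements])
    return MolecularGeometry(label, tuple(elements), masses, positions)


def write_xyz(geometry: MolecularGeometry, path: str | Path) -> None:
    """Write a geometry as a standard XYZ file (coordinates in Å)."""
    path = Path(path)
    rows = [str(geometry.n_atoms), geometry.label]
    for el, (x, y, z) in zip(geometry.elements, geometry.positions):
        rows.append(f"{el} {x:.8f} {y:.8f} {z:.8f}")
    path.write_text("\n".join(rows) + "\n")


def dihedral_angle(positions: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Dihedral angle i–j–k–l in degrees, in [0, 180]."""
    p = np.asarray(positions, float)
    b1, b2, b3 = p[j] - p[i], p[k] - p[j], p[l] - p[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------

_CC = 1.33  # C=C (Å)
_CCL = 1.73  # C–Cl (Å)
_CH = 1.08  # C–H (Å)
_SP2 = 120.0  # sp2 bond angle (deg)


def _dce_frame() -> tuple[np.ndarray, np.ndarray]:
    """The two sp2 carbons of an ethylene skeleton on the x axis."""
    c1 = np.array([_CC / 2, 0.0, 0.0])
    c2 = np.array([-_CC / 2, 0.0, 0.0])
    return c1, c2


def _sp2_dir(sign_x: float, sign_y: float) -> np.ndarray:
    # direction 60 deg off the +/-x axis, toward +/-y (sp2 geometry)
    ang = math.radians(180.0 - _SP2)  # 60 deg
    return np.array([sign_x * math.cos(ang), sign_y * math.sin(ang), 0.0])


def _build(label: str, elements: list[str], positions: list[np.ndarray]) -> MolecularGeometry:
    masses = np.array([ELEMENT_MASSES[e] for e in elements])
    return MolecularGeometry(label, tuple(elements), masses, np.array(positions))


def _rotate_about_x(v: np.ndarray, deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([v[0], c * v[1] - s * v[2], s * v[1] + c * v[2]])


def _fixture_cis_dce() -> MolecularGeometry:
    c1, c2 = _dce_frame()
    h1 = c1 + _CH * _sp2_dir(+1, +1)
    h2 = c2 + _CH * _sp2_dir(-1, +1)
    cl1 = c1 + _CCL * _sp2_dir(+1, -1)
    cl2 = c2 + _CCL * _sp2_dir(-1, -1)
    return _build("cis_dce", ["H", "H", "C", "C", "Cl", "Cl"], [h1, h2, c1, c2, cl1, cl2])


def _fixture_trans_dce() -> MolecularGeometry:
    c1, c2 = _dce_frame()
    h1 = c1 + _CH * _sp2_dir(+1, +1)
    h2 = c2 + _CH * _sp2_dir(-1, -1)
    cl1 = c1 + _CCL * _sp2_dir(+1, -1)
    cl2 = c2 + _CCL * _sp2_dir(-1, +1)
    return _build("trans_dce", ["H", "H", "C", "C", "Cl", "Cl"], [h1, h2, c1, c2, cl1, cl2])


def _fixture_twisted_dce() -> MolecularGeometry:
    # cis structure with one CHCl group rotated 90 deg about the C=C axis:
    # the midpoint of the cis<->trans torsional transition (H-C-C-H dihedral 90 deg)
    cis = _fixture_cis_dce()
    pos = [p.copy() for p in cis.positions]
    for idx in (1, 3, 5):  # h2, c2 (on axis, unchanged), cl2
        pos[idx] = _rotate_about_x(pos[idx], 90.0)
    return _build("twisted_dce", list(cis.elements), pos)


def _fixture_dce_11() -> MolecularGeometry:
    # 1,1-DCE: both Cl on one carbon, both H on the other; planar
    c1, c2 = _dce_frame()
    cl1 = c1 + _CCL * _sp2_dir(+1, -1)
    cl2 = c1 + _CCL * _sp2_dir(+1, +1)
    h1 = c2 + _CH * _sp2_dir(-1, +1)
    h2 = c2 + _CH * _sp2_dir(-1, -1)
    return _build("dce_11", ["H", "H", "C", "C", "Cl", "Cl"], [h1, h2, c1, c2, cl1, cl2])


def _fixture_isoxazole() -> MolecularGeometry:
    # Idealized planar 5-ring O1-N2=C3-C4=C5-O1 with ring bond ~1.38 Å,
    # H on C3, C4, C5 pointing radially outward.
    edge = 1.38
    r = edge / (2.0 * math.sin(math.pi / 5.0))
    ring = {}
    for k, name in enumerate(["O", "N", "C3", "C4", "C5"]):
        ang = math.pi / 2.0 + 2.0 * math.pi * k / 5.0
        ring[name] = np.array([r * math.cos(ang), r * math.sin(ang), 0.0])
    hs = []
    for name in ["C3", "C4", "C5"]:
        u = ring[name] / np.linalg.norm(ring[name])
        hs.append(ring[name] + _CH * u)
    elements = ["H", "H", "H", "C", "C", "C", "N", "O"]
    positions = hs + [ring["C3"], ring["C4"], ring["C5"], ring["N"], ring["O"]]
    return _build("isoxazole", elements, positions)


_FIXTURES = {
    "cis_dce": _fixture_cis_dce,
    "trans_dce": _fixture_trans_dce,
    "twisted_dce": _fixture_twisted_dce,
    "dce_11": _fixture_dce_11,
    "isoxazole": _fixture_isoxazole,
}


def fixture_geometry(name: str) -> MolecularGeometry:
    """Return a bundled idealized geometry.

    Available: ``cis_dce``, ``trans_dce``, ``twisted_dce`` (1,2-DCE at the 90°
    H–C–C–H torsional midpoint), ``dce_11`` (1,1-dichloroethylene) and
    ``isoxazole``.  Atom ordering puts light elements first (H, then C, then
    heavier), matching the fragment-slot convention 1–2 = H⁺, 3–4 = C⁺,
    5–6 = Cl⁺ used throughout the analysis.
    """
    try:
        return _FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
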