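"""Per-event momentum-space descriptors.

Two families of features are built from the fragment momenta of each event:

* recoil-frame Cartesian components ``p{slot}{axis}`` (3 per fragment, 18 for
  a six-body channel), and
* internal momentum coordinates, invariant to rotation of the whole momentum
  set: pair distances ``d_ij = |p_j − p_i|``, pair angles
  ``theta_ij = ∠(p_i, p_j)``, and plane–plane angles ``phi_ijkl`` between the
  planes spanned by (p_i, p_j) and (p_k, p_l).

Slot indices follow the convention 1–2 = H⁺, 3–4 = C⁺, 5–6 = Cl⁺ for the
dichloroethylene channel (element groups in ascending-mass order); within a
group, slots are assigned by ascending recoil-frame azimuthal angle so the
features are well defined despite identical ions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .explosion import EventEnsemble, ExplosionEvent
from .frames import FrameConvention, azimuthal_angle, rotate_ensemble

__all__ = [
    "FeatureMatrix",
    "canonical_slot_assignment",
    "pair_distance",
    "pair_angle",
    "plane_angle",
    "build_features",
    "DEFAULT_PLANE_QUADRUPLES",
]

# 1-based slot quadruples; (1,2,5,6) is the H-plane vs Cl-plane angle
DEFAULT_PLANE_QUADRUPLES: tuple[tuple[int, int, int, int], ...] = (
    (1, 2, 5, 6),
    (1, 2, 3, 4),
    (3, 4, 5, 6),
)

_FEATURE_FAMILIES = ("cartesian", "pair_distance", "pair_angle", "plane_angle")


@dataclass(frozen=True)
class FeatureMatrix:
    """A named per-event descriptor table.

    ``values`` is (n_events, n_features); p and d columns are in atomic units
    of momentum, theta/phi columns in degrees.  ``labels`` carries optional
    per-event structure labels.
    """

    names: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray | None = None
    event_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[1] != len(self.names):
            raise ValueError("values must be (n_events, n_features) matching names")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.labels is not None:
            object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
            if len(self.labels) != values.shape[0]:
                raise ValueError("labels length must match number of events")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def select(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.names.index(n) for n in names]
        return FeatureMatrix(tuple(names), self.values[:, idx], self.labels, self.event_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.names))
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        if self.event_ids is not None:
            df.insert(0, "event_id", self.event_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy() if "label" in df.columns else None
        ids = df.pop("event_id").to_numpy() if "event_id" in df.columns else None
        return cls(tuple(df.columns), df.to_numpy(float), labels, ids)

    @classmethod
    def concatenate(cls, mats: list["FeatureMatrix"]) -> "FeatureMatrix":
        names = mats[0].names
        for m in mats[1:]:
            if m.names != names:
                raise ValueError("feature name schemas differ")
        labels = (
            np.concatenate([m.labels for m in mats])
            if all(m.labels is not None for m in mats)
            else None
        )
        return cls(names, np.vstack([m.values for m in mats]), labels)


# ---------------------------------------------------------------------------
# Scalar descriptor operations
# ---------------------------------------------------------------------------

def pair_distance(p_i: np.ndarray, p_j: np.ndarray) -> float | np.ndarray:
    """d_ij = |p_j − p_i| (a.u.); broadcasting over leading axes."""
    d = np.linalg.norm(np.asarray(p_j, float) - np.asarray(p_i, float), axis=-1)
    return float(d) if d.ndim == 0 else d


def pair_angle(p_i: np.ndarray, p_j: np.ndarray) -> float | np.ndarray:
    """theta_ij = angle between p_i and p_j, degrees in [0, 180]."""
    p_i = np.asarray(p_i, float)
    p_j = np.asarray(p_j, float)
    ni = np.linalg.norm(p_i, axis=-1)
    nj = np.linalg.norm(p_j, axis=-1)
    if np.any(ni == 0) or np.any(nj == 0):
        raise ValueError("pair_angle undefined for a zero vector")
    cosang = (p_i * p_j).sum(axis=-1) / (ni * nj)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(ang) if ang.ndim == 0 else ang


def plane_angle(p_i: np.ndarray, p_j: np.ndarray, p_k: np.ndarray, p_l: np.ndarray) -> float | np.ndarray:
    """phi_ijkl = angle between the plane normals p_i × p_j and p_k × p_l,
    degrees in [0, 180].  Normals are taken in index order (no folding to
    [0, 90]), so plane orientation information is preserved."""
    n1 = np.cross(np.asarray(p_i, float), np.asarray(p_j, float))
    n2 = np.cross(np.asarray(p_k, float), np.asarray(p_l, float))
    m1 = np.linalg.norm(n1, axis=-1)
    m2 = np.linalg.norm(n2, axis=-1)
    if np.any(m1 == 0):
        raise ValueError("plane_angle: first pair (p_i, p_j) is collinear")
    if np.any(m2 == 0):
        raise ValueError("plane_angle: second pair (p_k, p_l) is collinear")
    cosang = (n1 * n2).sum(axis=-1) / (m1 * m2)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(ang) if ang.ndim == 0 else ang


# ---------------------------------------------------------------------------
# Slot canonicalization
# ---------------------------------------------------------------------------

def _slot_blocks(elements: tuple[str, ...], masses: np.ndarray) -> list[np.ndarray]:
    """Group fragment indices by species, groups ordered by ascending mass."""
    order = {}
    for idx, (el, m) in enumerate(zip(elements, masses)):
        order.setdefault((float(m), el), []).append(idx)
    return [np.array(order[key]) for key in sorted(order)]


def canonical_slot_assignment(event: ExplosionEvent) -> np.ndarray:
    """Slot permutation for one recoil-frame event.

    Within each identical-element group, fragments are assigned to slots by
    ascending azimuthal angle; ties break by ascending p_z, then input order.
    Returns an index array ``perm`` such that ``event.momenta[perm]`` is in
    canonical slot order.
    """
    return _canonical_perms(event.momenta[None], event.fragment_elements, event.fragment_masses)[0]


def _canonical_perms(momenta: np.ndarray, elements: tuple[str, ...], masses: np.ndarray) -> np.ndarray:
    """Batch slot permutations; momenta shape (n_events, n_frag, 3)."""
    n = momenta.shape[0]
    blocks = _slot_blocks(elements, np.asarray(masses))
    perm = np.empty((n, momenta.shape[1]), dtype=int)
    pos = 0
    az = np.degrees(np.arctan2(momenta[..., 1], momenta[..., 0])) % 360.0
    for cols in blocks:
        if len(cols) == 1:
            perm[:, pos] = cols[0]
        else:
            sub_az = az[:, cols]
            sub_pz = momenta[:, cols, 2]
            # lexsort: last key is primary -> azimuth, then p_z, stable on input order
            order = np.lexsort((sub_pz, sub_az), axis=1)
            perm[:, pos : pos + len(cols)] = cols[order]
        pos += len(cols)
    return perm


# ---------------------------------------------------------------------------
# Feature-matrix construction
# ---------------------------------------------------------------------------

def build_features(
    ensemble: EventEnsemble,
    convention: FrameConvention | None,
    feature_set: tuple[str, ...] = _FEATURE_FAMILIES,
    plane_quadruples: tuple[tuple[int, int, int, int], ...] | None = None,
    identical_ion_order: str = "random",
    seed: int = 0,
    slot_order: str = "azimuth",
) -> FeatureMatrix:
    """Build the per-event feature matrix for an ensemble.

    The ensemble is rotated into the recoil frame (pass ``convention=None``
    if already rotated), fragments are assigned to slots, and the requested
    feature families are computed.  Although d/theta/phi are
    rotation-invariant, they are evaluated after the recoil-frame rotation so
    all families share one canonical slot ordering.

    slot_order
        "azimuth" (default): canonical per-event assignment — within each
        identical-element group, slots by ascending recoil-frame azimuth
        (required when same-species ions are experimentally
        indistinguishable; permutation-invariant).  "input": keep the input
        fragment order — appropriate with ``identical_ion_order="fixed"`` on
        simulated data, where true atom identity is known.  The azimuth sort
        is discontinuous where same-species azimuths cross, which slices
        classes with an ill-defined frame roll (e.g. back-to-back reference
        momenta) into artificial sub-clusters; input order avoids that.
    """
    unknown = set(feature_set) - set(_FEATURE_FAMILIES)
    if unknown:
        raise ValueError(f"unknown feature families {sorted(unknown)}; choose from {_FEATURE_FAMILIES}")
    if slot_order not in ("azimuth", "input"):
        raise ValueError("slot_order must be 'azimuth' or 'input'")
    if plane_quadruples is None:
        plane_quadruples = DEFAULT_PLANE_QUADRUPLES
    if convention is not None:
        ensemble, _ = rotate_ensemble(ensemble, convention, identical_ion_order, seed)

    if slot_order == "azimuth":
        perms = _canonical_perms(ensemble.momenta, ensemble.fragment_elements, ensemble.fragment_masses)
        p = np.take_along_axis(ensemble.momenta, perms[:, :, None], axis=1)  # (n, f, 3)
    else:
        p = ensemble.momenta
    nf = p.shape[1]

    names: list[str] = []
    cols: list[np.ndarray] = []
    if "cartesian" in feature_set:
        for s in range(nf):
            for ax, axname in enumerate("xyz"):
                names.append(f"p{s + 1}{axname}")
                cols.append(p[:, s, ax])
    if "pair_distance" in feature_set:
        for i, j in combinations(range(nf), 2):
            names.append(f"d_{i + 1}{j + 1}")
            cols.append(pair_distance(p[:, i], p[:, j]))
    if "pair_angle" in feature_set:
        for i, j in combinations(range(nf), 2):
            names.append(f"theta_{i + 1}{j + 1}")
            cols.append(pair_angle(p[:, i], p[:, j]))
    if "plane_angle" in feature_set:
        for i, j, k, l in plane_quadruples:
            for s in (i, j, k, l):
                if not (1 <= s <= nf):
                    raise ValueError(f"plane quadruple {(i, j, k, l)} references slot {s} > {nf}")
            names.append(f"phi_{i}{j}{k}{l}")
            cols.append(plane_angle(p[:, i - 1], p[:, j - 1], p[:, k - 1], p[:, l - 1]))
    return FeatureMatrix(tuple(names), np.column_stack(cols), ensemble.labels, ensemble.event_ids)
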