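"""Recoil-frame (molecular-frame) rotations, Newton plots, azimuthal distributions.

Each event is rotated into a frame defined by its own fragment momenta: one
reference vector (e.g. the difference of the two Cl⁺ momentum unit vectors)
is placed along +x, a second (e.g. their sum, the bisector) fixes the x–y
plane with positive y, and z completes a right-handed frame.  This removes
the random lab-frame orientation, so structure shows up directly in the
rotated momenta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .explosion import EventEnsemble, ExplosionEvent

__all__ = [
    "FrameConvention",
    "DegenerateFrameError",
    "AzimuthalDistribution",
    "builtin_convention",
    "rotate_to_recoil_frame",
    "rotate_ensemble",
    "azimuthal_angle",
    "newton_histogram",
    "azimuthal_distribution",
]

_X_MODES = ("unit_difference", "difference", "sum")
_PLANE_MODES = ("difference", "sum")

# minimum angle (rad) between the x reference and the plane reference
_DEGENERACY_TOL = 1e-6


class DegenerateFrameError(ValueError):
    """The frame references are (nearly) collinear; the rotation is undefined."""


@dataclass(frozen=True)
class FrameConvention:
    """Per-event frame definition.

    ``x_ref = (i, j)`` with ``x_mode`` builds the +x reference from fragments
    i and j (0-based): ``unit_difference`` = p̂_j − p̂_i, ``difference`` =
    p_j − p_i, ``sum`` = p_i + p_j.  ``plane_ref``/``plane_mode`` build the
    vector that must lie in the x–y half-plane with positive y.
    """

    x_ref: tuple[int, int]
    x_mode: str = "unit_difference"
    plane_ref: tuple[int, int] = (0, 1)
    plane_mode: str = "sum"
    name: str = ""

    def __post_init__(self) -> None:
        if self.x_mode not in _X_MODES:
            raise ValueError(f"x_mode must be one of {_X_MODES}")
        if self.plane_mode not in _PLANE_MODES:
            raise ValueError(f"plane_mode must be one of {_PLANE_MODES}")


_BUILTINS = {
    # DCE slot order: H, H, C, C, Cl, Cl (0-based indices)
    # cis: difference of the two Cl+ momentum unit vectors along +x,
    #      their sum (the bisector) in the upper x-y plane
    "cis_dce": FrameConvention((4, 5), "unit_difference", (4, 5), "sum", name="cis_dce"),
    # trans: Cl+ momenta are near back-to-back so their sum is ill-defined;
    #        the difference of the two C+ momenta fixes the plane instead
    "trans_dce": FrameConvention((4, 5), "difference", (2, 3), "difference", name="trans_dce"),
    # isoxazole slot order: H, H, H, C, C, C, N, O
    "isoxazole": FrameConvention((6, 7), "difference", (6, 7), "sum", name="isoxazole"),
}


def builtin_convention(name: str) -> FrameConvention:
    """Named frame conventions: ``cis_dce``, ``trans_dce``, ``isoxazole``."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise KeyError(f"unknown convention {name!r}; available: {sorted(_BUILTINS)}") from None


def _reference_vectors(momenta: np.ndarray, convention: FrameConvention) -> tuple[np.ndarray, np.ndarray]:
    """Batch reference vectors; momenta shape (..., n_frag, 3)."""
    i, j = convention.x_ref
    pi, pj = momenta[..., i, :], momenta[..., j, :]
    if convention.x_mode == "unit_difference":
        a = pj / np.linalg.norm(pj, axis=-1, keepdims=True) - pi / np.linalg.norm(pi, axis=-1, keepdims=True)
    elif convention.x_mode == "difference":
        a = pj - pi
    else:
        a = pi + pj
    k, l = convention.plane_ref
    pk, pl = momenta[..., k, :], momenta[..., l, :]
    b = pl - pk if convention.plane_mode == "difference" else pk + pl
    return a, b


def _rotation_matrices(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotations mapping a→+x and b into the upper x–y half-plane.

    Returns (R, degenerate_mask); R has shape (..., 3, 3) with rows x̂, ŷ, ẑ.
    """
    na = np.linalg.norm(a, axis=-1, keepdims=True)
    nb = np.linalg.norm(b, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        xhat = a / na
        bu = b / nb
        cross = np.cross(xhat, bu)
        sin_angle = np.linalg.norm(cross, axis=-1)
        degenerate = ~np.isfinite(sin_angle) | (sin_angle < _DEGENERACY_TOL)
        b_perp = bu - (bu * xhat).sum(axis=-1, keepdims=True) * xhat
        yhat = b_perp / np.linalg.norm(b_perp, axis=-1, keepdims=True)
        zhat = np.cross(xhat, yhat)
    R = np.stack([xhat, yhat, zhat], axis=-2)
    return R, degenerate


def rotate_to_recoil_frame(event: ExplosionEvent, convention: FrameConvention) -> ExplosionEvent:
    """Rotate one event into the recoil frame defined by ``convention``.

    The rotation is proper (det = +1) and therefore preserves every momentum
    magnitude.  Raises :class:`DegenerateFrameError` when the two reference
    vectors are collinear — the documented failure mode of a bisector-based
    convention on back-to-back reference momenta.
    """
    a, b = _reference_vectors(event.momenta, convention)
    R, degenerate = _rotation_matrices(a, b)
    if degenerate:
        raise DegenerateFrameError(
            f"frame references are collinear for convention "
            f"{convention.name or convention!r} (event_id={event.event_id})"
        )
    return ExplosionEvent(
        event.momenta @ R.T,
        event.fragment_elements,
        event.fragment_charges,
        event.fragment_masses,
        structure_label=event.structure_label,
        event_id=event.event_id,
    )


def rotate_ensemble(
    ensemble: EventEnsemble,
    convention: FrameConvention,
    identical_ion_order: str = "random",
    seed: int = 0,
) -> tuple[EventEnsemble, int]:
    """Rotate every event into the recoil frame; returns (rotated, n_skipped).

    Degenerate-frame events are dropped and counted rather than raising.

    identical_ion_order
        "random" (default): fragments within each identical-element group are
        randomly permuted per event before the frame is built, mirroring the
        experimental indistinguishability of same-species ions (this
        symmetrizes Newton plots exactly as the two-fold detection ambiguity
        does).  "fixed": input order kept — appropriate for simulated data
        where true atom identity is known.
    """
    if identical_ion_order not in ("random", "fixed"):
        raise ValueError("identical_ion_order must be 'random' or 'fixed'")
    momenta = ensemble.momenta
    if identical_ion_order == "random":
        rng = np.random.default_rng(seed)
        momenta = momenta.copy()
        elements = np.array(ensemble.fragment_elements)
        for el in np.unique(elements):
            cols = np.flatnonzero(elements == el)
            if len(cols) < 2:
                continue
            # independent random permutation of the group, per event
            perms = rng.permuted(np.tile(cols, (len(ensemble), 1)), axis=1)
            momenta[:, cols, :] = np.take_along_axis(
                momenta, perms[:, :, None], axis=1
            )
    a, b = _reference_vectors(momenta, convention)
    R, degenerate = _rotation_matrices(a, b)
    keep = ~degenerate
    if not np.any(keep):
        raise DegenerateFrameError("all events are degenerate under this convention")
    rotated = np.einsum("nij,nfj->nfi", R[keep], momenta[keep])
    out = EventEnsemble(
        rotated,
        ensemble.fragment_elements,
        ensemble.fragment_charges,
        ensemble.fragment_masses,
        ensemble.labels[keep],
        ensemble.event_ids[keep],
        provenance={**ensemble.provenance, "frame_convention": convention.name or "custom"},
        n_failed=ensemble.n_failed,
    )
    return out, int((~keep).sum())


def azimuthal_angle(p: np.ndarray) -> float | np.ndarray:
    """Angle of (p_x, p_y) counter-clockwise from +x, degrees in [0, 360)."""
    p = np.asarray(p, dtype=float)
    px, py = p[..., 0], p[..., 1]
    if np.any(px**2 + py**2 == 0):
        raise ValueError("azimuthal angle undefined for zero in-plane projection")
    ang = np.degrees(np.arctan2(py, px)) % 360.0
    return float(ang) if ang.ndim == 0 else ang


def newton_histogram(
    ensemble: EventEnsemble,
    convention: FrameConvention | None = None,
    bins: int = 100,
    range_au: float | None = None,
    identical_ion_order: str = "random",
    seed: int = 0,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-species 2D (p_x, p_y) histograms in the recoil frame (a.u.).

    Pass ``convention=None`` for an already-rotated ensemble.  Returns
    ``{element: (counts, x_edges, y_edges)}``.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if convention is not None:
        ensemble, _ = rotate_ensemble(ensemble, convention, identical_ion_order, seed)
    if range_au is None:
        range_au = float(np.abs(ensemble.momenta[:, :, :2]).max()) * 1.05
    edges = np.linspace(-range_au, range_au, bins + 1)
    out = {}
    elements = np.array(ensemble.fragment_elements)
    for el in dict.fromkeys(ensemble.fragment_elements):  # preserve order
        cols = np.flatnonzero(elements == el)
        px = ensemble.momenta[:, cols, 0].ravel()
        py = ensemble.momenta[:, cols, 1].ravel()
        H, xe, ye = np.histogram2d(px, py, bins=[edges, edges])
        out[el] = (H, xe, ye)
    return out


@dataclass(frozen=True)
class AzimuthalDistribution:
    """Normalized per-fragment-slot azimuthal-angle histograms, degrees in [0, 360)."""

    bin_edges: np.ndarray  # (n_bins + 1,)
    densities: np.ndarray  # (n_slots, n_bins), each row sums to 1
    slot_elements: tuple[str, ...]

    def __post_init__(self) -> None:
        sums = self.densities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each slot distribution must sum to 1")


def azimuthal_distribution(
    ensemble: EventEnsemble,
    convention: FrameConvention | None = None,
    bins: int = 72,
    identical_ion_order: str = "random",
    seed: int = 0,
) -> AzimuthalDistribution:
    """Azimuthal-angle distribution per fragment slot in the recoil frame,
    integrated over momentum magnitude and normalized to unit sum."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if convention is not None:
        ensemble, _ = rotate_ensemble(ensemble, convention, identical_ion_order, seed)
    edges = np.linspace(0.0, 360.0, bins + 1)
    angles = azimuthal_angle(ensemble.momenta)  # (n_events, n_slots)
    densities = np.stack(
        [np.histogram(angles[:, s], bins=edges)[0] / len(ensemble) for s in range(ensemble.n_fragments)]
    )
    return AzimuthalDistribution(edges, densities, ensemble.fragment_elements)
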