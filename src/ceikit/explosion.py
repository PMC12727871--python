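"""Classical point-charge Coulomb-explosion simulator.

The model: a neutral molecule is ionized instantaneously ("vertical"
ionization) so that every atom becomes a point charge at its current position;
the only force afterwards is pairwise Coulomb repulsion, and the molecule
fragments completely into atomic cations with no internal energy.  Initial
conditions emulate the spread of a real ensemble: each atom is displaced from
equilibrium by an isotropic Gaussian (σ per Cartesian component), and a fixed
total kinetic energy is randomly partitioned among the atoms with isotropic
directions, net linear momentum removed, and speeds rescaled so the total is
exact.

Newton's equations m_i r̈_i = Σ_{j≠i} q_i q_j (r_i − r_j)/r_ij³ (atomic units)
are integrated with an adaptive high-order Runge–Kutta scheme until the
remaining Coulomb potential energy is a negligible fraction of the total
energy; the asymptotic fragment momenta are the observable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.integrate import solve_ivp

from . import units
from .molgeom import FragmentationChannel, MolecularGeometry

__all__ = [
    "InitialConditionSpec",
    "IntegratorConfig",
    "ExplosionEvent",
    "EventEnsemble",
    "TrajectoryError",
    "sample_initial_conditions",
    "coulomb_potential_energy",
    "propagate_event",
    "simulate_ensemble",
    "kinetic_energy_release",
]


class TrajectoryError(RuntimeError):
    """Raised when a trajectory cannot be integrated to the asymptotic regime."""


@dataclass(frozen=True)
class InitialConditionSpec:
    """Ensemble sampling parameters.

    sigma
        Gaussian positional spread per Cartesian component (Å).
    e_kin_total
        Total initial kinetic energy per event (eV), randomly partitioned
        among the atoms.
    n_samples
        Ensemble size (default 20,000).
    seed
        Base seed; the full ensemble is reproducible from it.
    sigma_mode
        "radial" (default): sigma is the root-mean-square total displacement
        of an atom (each Cartesian component has SD sigma/sqrt(3)).
        "component": sigma is the SD of each Cartesian displacement component
        (RMS total displacement sigma*sqrt(3)).
    """

    sigma: float = 0.25
    e_kin_total: float = 0.5
    n_samples: int = 20_000
    seed: int = 0
    sigma_mode: str = "radial"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.e_kin_total < 0:
            raise ValueError("e_kin_total must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.sigma_mode not in ("component", "radial"):
            raise ValueError("sigma_mode must be 'component' or 'radial'")


@dataclass(frozen=True)
class IntegratorConfig:
    """Adaptive integrator controls.

    rel_tol
        Per-step relative error tolerance.
    termination_fraction
        Integration stops once the remaining Coulomb potential energy drops
        below this fraction of the (conserved) total energy; the resulting
        momentum-magnitude bias is below termination_fraction/2 relative.
    max_steps
        Cap on right-hand-side evaluations per trajectory.
    """

    rel_tol: float = 1e-8
    termination_fraction: float = 1e-4
    max_steps: int = 200_000

    def __post_init__(self) -> None:
        if not (0 < self.termination_fraction < 1):
            raise ValueError("termination_fraction must be in (0, 1)")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be > 0")


@dataclass(frozen=True)
class ExplosionEvent:
    """Asymptotic fragment momenta (a.u.) of one explosion, with identities."""

    momenta: np.ndarray  # (n_frag, 3), atomic units
    fragment_elements: tuple[str, ...]
    fragment_charges: np.ndarray  # integer e
    fragment_masses: np.ndarray  # u
    structure_label: str = ""
    event_id: int = 0

    def __post_init__(self) -> None:
        momenta = np.atleast_2d(np.asarray(self.momenta, dtype=float))
        object.__setattr__(self, "momenta", momenta)
        object.__setattr__(self, "fragment_elements", tuple(self.fragment_elements))
        object.__setattr__(self, "fragment_charges", np.asarray(self.fragment_charges, dtype=int))
        object.__setattr__(self, "fragment_masses", np.asarray(self.fragment_masses, dtype=float))
        n = momenta.shape[0]
        if momenta.shape != (n, 3) or not np.all(np.isfinite(momenta)):
            raise ValueError("momenta must be a finite (n, 3) array")
        if not (len(self.fragment_elements) == n == len(self.fragment_charges) == len(self.fragment_masses)):
            raise ValueError("fragment field lengths inconsistent")

    @property
    def n_fragments(self) -> int:
        return self.momenta.shape[0]

    @property
    def momentum_sum(self) -> np.ndarray:
        return self.momenta.sum(axis=0)


@dataclass
class EventEnsemble:
    """A stack of explosion events sharing one fragment composition.

    Momenta are stored columnar as an (n_events, n_fragments, 3) array in
    atomic units; indexing returns an :class:`ExplosionEvent` view.
    """

    momenta: np.ndarray  # (n_events, n_frag, 3)
    fragment_elements: tuple[str, ...]
    fragment_charges: np.ndarray
    fragment_masses: np.ndarray
    labels: np.ndarray  # (n_events,) str
    event_ids: np.ndarray  # (n_events,) int
    provenance: dict = field(default_factory=dict)
    n_failed: int = 0

    def __post_init__(self) -> None:
        self.momenta = np.asarray(self.momenta, dtype=float)
        self.fragment_elements = tuple(self.fragment_elements)
        self.fragment_charges = np.asarray(self.fragment_charges, dtype=int)
        self.fragment_masses = np.asarray(self.fragment_masses, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.event_ids = np.asarray(self.event_ids, dtype=int)
        n, f = self.momenta.shape[0], self.momenta.shape[1]
        if self.momenta.ndim != 3 or self.momenta.shape[2] != 3:
            raise ValueError("momenta must have shape (n_events, n_fragments, 3)")
        if not (len(self.fragment_elements) == f == len(self.fragment_charges) == len(self.fragment_masses)):
            raise ValueError("fragment metadata lengths inconsistent")
        if self.labels.shape != (n,) or self.event_ids.shape != (n,):
            raise ValueError("labels/event_ids must have one entry per event")
        if len(np.unique(self.event_ids)) != n:
            raise ValueError("event_ids must be unique")

    def __len__(self) -> int:
        return self.momenta.shape[0]

    @property
    def n_fragments(self) -> int:
        return self.momenta.shape[1]

    def __getitem__(self, i: int) -> ExplosionEvent:
        return ExplosionEvent(
            self.momenta[i],
            self.fragment_elements,
            self.fragment_charges,
            self.fragment_masses,
            structure_label=str(self.labels[i]),
            event_id=int(self.event_ids[i]),
        )

    def __iter__(self) -> Iterator[ExplosionEvent]:
        for i in range(len(self)):
            yield self[i]

    def subset(self, index: np.ndarray) -> "EventEnsemble":
        index = np.asarray(index)
        return EventEnsemble(
            self.momenta[index],
            self.fragment_elements,
            self.fragment_charges,
            self.fragment_masses,
            self.labels[index],
            self.event_ids[index],
            provenance=dict(self.provenance),
            n_failed=self.n_failed,
        )

    def with_momenta(self, momenta: np.ndarray) -> "EventEnsemble":
        return EventEnsemble(
            momenta,
            self.fragment_elements,
            self.fragment_charges,
            self.fragment_masses,
            self.labels,
            self.event_ids,
            provenance=dict(self.provenance),
            n_failed=self.n_failed,
        )

    @staticmethod
    def concatenate(ensembles: list["EventEnsemble"]) -> "EventEnsemble":
        first = ensembles[0]
        for e in ensembles[1:]:
            if e.fragment_elements != first.fragment_elements:
                raise ValueError("cannot concatenate ensembles with different compositions")
        momenta = np.concatenate([e.momenta for e in ensembles])
        labels = np.concatenate([e.labels for e in ensembles])
        ids = np.arange(momenta.shape[0])
        return EventEnsemble(
            momenta,
            first.fragment_elements,
            first.fragment_charges,
            first.fragment_masses,
            labels,
            ids,
            provenance={"concatenated_from": [dict(e.provenance) for e in ensembles]},
            n_failed=sum(e.n_failed for e in ensembles),
        )


# ---------------------------------------------------------------------------
# Initial conditions
# ---------------------------------------------------------------------------

def sample_initial_conditions(
    geometry: MolecularGeometry, spec: InitialConditionSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Draw an ensemble of initial states.

    Returns ``(positions, velocities)`` with shapes (n_samples, n_atoms, 3) in
    Å and Å/fs.  Each atom is displaced by independent N(0, σ²) per Cartesian
    component; kinetic-energy fractions come from a flat Dirichlet simplex
    with isotropic velocity directions; the center-of-mass momentum is removed
    and speeds rescaled so the total kinetic energy equals ``e_kin_total``
    exactly.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_atoms = geometry.n_atoms
    n = spec.n_samples
    sigma = spec.sigma if spec.sigma_mode == "component" else spec.sigma / np.sqrt(3.0)
    positions = geometry.positions[None, :, :] + rng.normal(0.0, 1.0, (n, n_atoms, 3)) * sigma

    velocities = np.zeros((n, n_atoms, 3))
    if spec.e_kin_total > 0:
        fractions = rng.dirichlet(np.ones(n_atoms), size=n)  # (n, n_atoms)
        directions = rng.normal(size=(n, n_atoms, 3))
        directions /= np.linalg.norm(directions, axis=2, keepdims=True)
        masses = geometry.masses  # u
        speeds = np.sqrt(2.0 * fractions * spec.e_kin_total / (masses * units.U_ANGFS_SQ_TO_EV))
        velocities = speeds[:, :, None] * directions
        # remove net linear momentum, then rescale to the exact total KE
        total_mass = masses.sum()
        v_com = (masses[None, :, None] * velocities).sum(axis=1, keepdims=True) / total_mass
        velocities -= v_com
        ke = 0.5 * units.U_ANGFS_SQ_TO_EV * (masses[None, :, None] * velocities**2).sum(axis=(1, 2))
        velocities *= np.sqrt(spec.e_kin_total / ke)[:, None, None]
    return positions, velocities


# ---------------------------------------------------------------------------
# Potential and propagation
# ---------------------------------------------------------------------------

def coulomb_potential_energy(positions: np.ndarray, charges: np.ndarray) -> float:
    """Total Coulomb energy Σ_{i<j} k q_i q_j / r_ij in eV (positions in Å)."""
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    iu, ju = np.triu_indices(len(charges), k=1)
    diff = positions[iu] - positions[ju]
    r = np.sqrt((diff * diff).sum(axis=1))
    if np.any(r == 0):
        raise ValueError("coincident atoms: Coulomb potential is singular")
    return float(units.COULOMB_CONSTANT_EV_ANG * (charges[iu] * charges[ju] / r).sum())


def _pe_au(r: np.ndarray, q: np.ndarray, iu: np.ndarray, ju: np.ndarray) -> float:
    diff = r[iu] - r[ju]
    dist = np.sqrt((diff * diff).sum(axis=1))
    return float((q[iu] * q[ju] / dist).sum())


def propagate_event(
    positions: np.ndarray,
    velocities: np.ndarray,
    masses: np.ndarray,
    charges: np.ndarray,
    config: IntegratorConfig = IntegratorConfig(),
    *,
    elements: tuple[str, ...] | None = None,
    structure_label: str = "",
    event_id: int = 0,
    return_diagnostics: bool = False,
) -> ExplosionEvent | tuple[ExplosionEvent, dict]:
    """Integrate one trajectory to the asymptotic regime.

    Inputs in interface units (Å, Å/fs, u, e); the returned event carries the
    asymptotic momenta in atomic units.  Raises :class:`TrajectoryError` if
    the step cap is exceeded or the state becomes non-finite.

    With ``return_diagnostics=True`` also returns a dict with the energy
    audit (eV): initial total energy, final kinetic and potential energy, the
    relative energy drift |KE_f + PE_f − E_i|/E_i, and integration counters.
    """
    n = len(masses)
    r0 = np.asarray(positions, float) * units.ANGSTROM_TO_BOHR
    v0 = np.asarray(velocities, float) * units.ANG_FS_TO_AU_VELOCITY
    m = np.asarray(masses, float) * units.AMU_TO_ME
    q = np.asarray(charges, float)
    iu, ju = np.triu_indices(n, k=1)

    pe0 = _pe_au(r0, q, iu, ju)
    ke0 = 0.5 * (m[:, None] * v0**2).sum()
    e_total = pe0 + ke0
    if e_total <= 0:
        raise ValueError("total energy must be positive for an explosion")

    nfev = 0
    max_steps = config.max_steps

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        nonlocal nfev
        nfev += 1
        if nfev > max_steps:
            raise TrajectoryError(
                f"max_steps={max_steps} exceeded at t={t:.3g} a.u. "
                f"(label={structure_label!r}, event_id={event_id})"
            )
        r = y[: 3 * n].reshape(n, 3)
        v = y[3 * n :]
        diff = r[iu] - r[ju]
        dist2 = (diff * diff).sum(axis=1)
        f_pair = (q[iu] * q[ju] / (dist2 * np.sqrt(dist2)))[:, None] * diff
        acc = np.zeros((n, 3))
        np.add.at(acc, iu, f_pair)
        np.add.at(acc, ju, -f_pair)
        acc /= m[:, None]
        return np.concatenate([v, acc.ravel()])

    def far_field(t: float, y: np.ndarray) -> float:
        return _pe_au(y[: 3 * n].reshape(n, 3), q, iu, ju) - config.termination_fraction * e_total

    far_field.terminal = True  # type: ignore[attr-defined]
    far_field.direction = -1  # type: ignore[attr-defined]

    y0 = np.concatenate([r0.ravel(), v0.ravel()])
    sol = solve_ivp(
        rhs,
        (0.0, 1e12),
        y0,
        method="DOP853",
        rtol=config.rel_tol,
        atol=1e-14,
        events=far_field,
    )
    if sol.status != 1:
        raise TrajectoryError(
            f"integration did not reach the asymptotic regime (status={sol.status}, "
            f"label={structure_label!r}, event_id={event_id}): {sol.message}"
        )
    yf = sol.y[:, -1]
    if not np.all(np.isfinite(yf)):
        raise TrajectoryError("non-finite state encountered during integration")
    vf = yf[3 * n :].reshape(n, 3)
    momenta = m[:, None] * vf  # a.u.
    if elements is None:
        elements = tuple("X" for _ in range(n))
    event = ExplosionEvent(
        momenta,
        elements,
        np.asarray(charges, int),
        np.asarray(masses, float),
        structure_label=structure_label,
        event_id=event_id,
    )
    if not return_diagnostics:
        return event
    rf = yf[: 3 * n].reshape(n, 3)
    ke_f = 0.5 * (m[:, None] * vf**2).sum()
    pe_f = _pe_au(rf, q, iu, ju)
    diagnostics = {
        "e_initial_ev": e_total * units.HARTREE_TO_EV,
        "ke_final_ev": ke_f * units.HARTREE_TO_EV,
        "pe_final_ev": pe_f * units.HARTREE_TO_EV,
        "energy_drift_rel": abs(ke_f + pe_f - e_total) / e_total,
        "t_final_au": float(sol.t[-1]),
        "nfev": nfev,
    }
    return event, diagnostics


def simulate_ensemble(
    geometry: MolecularGeometry,
    channel: FragmentationChannel,
    spec: InitialConditionSpec,
    config: IntegratorConfig = IntegratorConfig(),
) -> EventEnsemble:
    """Simulate a full explosion ensemble for one geometry and channel.

    All initial conditions are drawn up front from ``spec.seed`` (so the
    seed↔event mapping is independent of any trajectory failures); each is
    then integrated with :func:`propagate_event`.  Failed trajectories are
    skipped with a warning; more than 1% failures raises.
    """
    channel.validate_for(geometry)
    positions, velocities = sample_initial_conditions(geometry, spec)
    momenta = []
    ids = []
    n_failed = 0
    for k in range(spec.n_samples):
        try:
            ev = propagate_event(
                positions[k],
                velocities[k],
                geometry.masses,
                channel.charges,
                config,
                elements=geometry.elements,
                structure_label=geometry.label,
                event_id=k,
            )
        except TrajectoryError:
            n_failed += 1
            continue
        momenta.append(ev.momenta)
        ids.append(k)
    if n_failed > 0:
        warnings.warn(f"{n_failed} of {spec.n_samples} trajectories failed and were skipped")
    if n_failed > 0.01 * spec.n_samples:
        raise TrajectoryError(
            f"{n_failed}/{spec.n_samples} trajectories failed (> 1%); check inputs"
        )
    momenta_arr = np.stack(momenta)
    labels = np.array([geometry.label] * len(ids), dtype=object)
    provenance = {
        "geometry_label": geometry.label,
        "charges": channel.charges.tolist(),
        "sigma_angstrom": spec.sigma,
        "sigma_mode": spec.sigma_mode,
        "e_kin_total_ev": spec.e_kin_total,
        "n_samples": spec.n_samples,
        "seed": spec.seed,
        "rel_tol": config.rel_tol,
        "termination_fraction": config.termination_fraction,
    }
    return EventEnsemble(
        momenta_arr,
        geometry.elements,
        channel.charges,
        geometry.masses,
        labels,
        np.array(ids),
        provenance=provenance,
        n_failed=n_failed,
    )


def kinetic_energy_release(event: ExplosionEvent) -> tuple[np.ndarray, float]:
    """Per-fragment kinetic energies p²/2m and their total, in eV."""
    m_au = event.fragment_masses * units.AMU_TO_ME
    per_fragment = (event.momenta**2).sum(axis=1) / (2.0 * m_au) * units.HARTREE_TO_EV
    return per_fragment, float(per_fragment.sum())
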