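"""Coincidence-detection imperfections and the momentum-conservation gate.

In a complete-coincidence measurement every fragment of one molecule is
detected, so the vector sum of the fragment momenta must vanish.  Gating on
|Σ p_i| therefore rejects false coincidences — events whose fragments came
from more than one molecule — and makes the retained data background-free.
This module models the two dominant imperfections directly in momentum
space: finite per-ion detection efficiency and false-coincidence chimeras.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .explosion import EventEnsemble, ExplosionEvent

__all__ = [
    "GateConfig",
    "GateResult",
    "DetectionOutcome",
    "momentum_sum_gate",
    "apply_gate",
    "apply_detection_efficiency",
    "mix_false_coincidences",
]


@dataclass(frozen=True)
class GateConfig:
    """Momentum-sum gate: accept iff |Σ p_i| ≤ threshold.

    In ``relative`` mode (default) the threshold is a fraction of the event's
    RMS fragment momentum; in ``absolute`` mode it is in a.u. directly.
    """

    threshold: float = 0.05
    mode: str = "relative"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.mode not in ("relative", "absolute"):
            raise ValueError("mode must be 'relative' or 'absolute'")


@dataclass(frozen=True)
class GateResult:
    accept: bool
    residual: float  # |Σ p_i| in a.u.


def _residuals(momenta: np.ndarray) -> np.ndarray:
    return np.linalg.norm(momenta.sum(axis=-2), axis=-1)


def _thresholds(momenta: np.ndarray, config: GateConfig) -> np.ndarray:
    if config.mode == "absolute":
        return np.full(momenta.shape[:-2], config.threshold)
    rms = np.sqrt((momenta**2).sum(axis=-1).mean(axis=-1))
    return config.threshold * rms


def momentum_sum_gate(event: ExplosionEvent, config: GateConfig = GateConfig()) -> GateResult:
    """Gate one complete event on its momentum-sum residual."""
    residual = float(_residuals(event.momenta[None])[0])
    threshold = float(_thresholds(event.momenta[None], config)[0])
    return GateResult(accept=residual <= threshold, residual=residual)


def apply_gate(
    ensemble: EventEnsemble, config: GateConfig = GateConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized gate over an ensemble: returns (accept_mask, residuals)."""
    residuals = _residuals(ensemble.momenta)
    return residuals <= _thresholds(ensemble.momenta, config), residuals


@dataclass(frozen=True)
class DetectionOutcome:
    """Result of applying finite per-ion detection efficiency."""

    ensemble: EventEnsemble
    detected: np.ndarray  # (n_events, n_fragments) bool
    complete: np.ndarray  # (n_events,) bool

    @property
    def complete_fraction(self) -> float:
        return float(self.complete.mean())

    def complete_events(self) -> EventEnsemble:
        return self.ensemble.subset(np.flatnonzero(self.complete))


def apply_detection_efficiency(
    ensemble: EventEnsemble, efficiency: float, seed: int = 0
) -> DetectionOutcome:
    """Retain each fragment independently with probability ``efficiency``.

    The expected complete-event fraction is efficiency ** n_fragments.
    Deterministic given the seed.
    """
    if not (0 < efficiency <= 1):
        raise ValueError("efficiency must be in (0, 1]")
    rng = np.random.default_rng(seed)
    detected = rng.random((len(ensemble), ensemble.n_fragments)) < efficiency
    return DetectionOutcome(ensemble, detected, detected.all(axis=1))


def mix_false_coincidences(
    ensemble_a: EventEnsemble,
    ensemble_b: EventEnsemble,
    fraction: float,
    seed: int = 0,
) -> tuple[EventEnsemble, np.ndarray]:
    """Contaminate ``ensemble_a`` with false-coincidence chimeras.

    Exactly ``round(fraction * n)`` events of a copy of ``ensemble_a`` have a
    random proper, nonempty subset of their fragments replaced by the same
    fragments of a random event from ``ensemble_b`` — the momentum signature
    of two molecules contributing to one detected event.  Returns the mixed
    ensemble and a boolean truth mask (True = chimera).
    """
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    if ensemble_a.fragment_elements != ensemble_b.fragment_elements:
        raise ValueError("ensembles have incompatible fragment compositions")
    rng = np.random.default_rng(seed)
    n = len(ensemble_a)
    nf = ensemble_a.n_fragments
    n_chimera = int(round(fraction * n))
    momenta = ensemble_a.momenta.copy()
    is_chimera = np.zeros(n, dtype=bool)
    targets = rng.choice(n, size=n_chimera, replace=False)
    partners = rng.integers(0, len(ensemble_b), size=n_chimera)
    for t, partner in zip(targets, partners):
        k = int(rng.integers(1, nf))  # proper nonempty subset size
        swap = rng.choice(nf, size=k, replace=False)
        momenta[t, swap] = ensemble_b.momenta[partner, swap]
        is_chimera[t] = True
    mixed = ensemble_a.with_momenta(momenta)
    mixed.provenance["false_coincidence_fraction"] = fraction
    return mixed, is_chimera
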