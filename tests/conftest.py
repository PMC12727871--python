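"""Shared simulation fixtures.

The heavy ensembles use the study conditions (six-body singly-charged
channel; narrow sampling σ = 0.25 Å RMS displacement, E_kin = 0.5 eV;
broadened sampling 0.5 Å / 3 eV) and are session-scoped so every test that
needs them shares one simulation run.
"""

import numpy as np
import pytest

import ceikit as ck


def simulate(name, seed, n, sigma=0.25, e_kin=0.5, rel_tol=1e-8):
    geom = ck.fixture_geometry(name)
    spec = ck.InitialConditionSpec(sigma=sigma, e_kin_total=e_kin, n_samples=n, seed=seed)
    return ck.simulate_ensemble(
        geom,
        ck.FragmentationChannel.all_singly_charged(geom),
        spec,
        ck.IntegratorConfig(rel_tol=rel_tol),
    )


@pytest.fixture(scope="session")
def narrow_ensembles():
    """2000-event ensembles of all four DCE geometries at narrow conditions."""
    return {
        name: simulate(name, seed, 2000)
        for name, seed in [("cis_dce", 1), ("trans_dce", 2), ("twisted_dce", 3), ("dce_11", 4)]
    }


@pytest.fixture(scope="session")
def broadened_pair():
    """Broadened twisted/1,1-DCE ensembles (0.5 Å, 3 eV), 600 events each."""
    return {
        name: simulate(name, seed, 600, sigma=0.5, e_kin=3.0)
        for name, seed in [("twisted_dce", 30), ("dce_11", 40)]
    }


@pytest.fixture(scope="session")
def holdout_pair():
    """Held-out narrow cis/trans ensembles simulated with fresh seeds."""
    return {
        name: simulate(name, seed, 400) for name, seed in [("cis_dce", 100), ("trans_dce", 200)]
    }


@pytest.fixture(scope="session")
def cis_small():
    return simulate("cis_dce", 11, 120)


@pytest.fixture(scope="session")
def trans_small():
    return simulate("trans_dce", 12, 120)


def tile_ensemble(ensemble, n_copies):
    """Repeat an ensemble's events to reach a larger count (momenta reused)."""
    momenta = np.tile(ensemble.momenta, (n_copies, 1, 1))
    n = momenta.shape[0]
    return ck.EventEnsemble(
        momenta,
        ensemble.fragment_elements,
        ensemble.fragment_charges,
        ensemble.fragment_masses,
        np.tile(ensemble.labels, n_copies),
        np.arange(n),
        provenance=dict(ensemble.provenance),
    )
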