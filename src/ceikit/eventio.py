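"""Event-table I/O: HDF5 (one group per ensemble) and flat CSV.

HDF5 layout per group: ``/momenta`` (n_events × n_frag × 3, a.u.),
``/elements``, ``/charges``, ``/masses``, ``/labels``, ``/event_ids``, with
provenance stored as group attributes.  The CSV form is one row per fragment
with columns event_id, structure_label, frag_index, element, charge, mass_u,
px_au, py_au, pz_au — the same schema an externally supplied per-event
momentum table (e.g. from experiment) should use.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .explosion import EventEnsemble

__all__ = ["write_events_h5", "read_events_h5", "write_events_csv", "read_events_csv"]

CSV_COLUMNS = [
    "event_id",
    "structure_label",
    "frag_index",
    "element",
    "charge",
    "mass_u",
    "px_au",
    "py_au",
    "pz_au",
]


def write_events_h5(ensemble: EventEnsemble, path: str | Path, group: str = "ensemble") -> None:
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("momenta", data=ensemble.momenta)
        g.create_dataset("elements", data=np.array(ensemble.fragment_elements, dtype="S"))
        g.create_dataset("charges", data=ensemble.fragment_charges)
        g.create_dataset("masses", data=ensemble.fragment_masses)
        g.create_dataset("labels", data=np.array([str(l) for l in ensemble.labels], dtype="S"))
        g.create_dataset("event_ids", data=ensemble.event_ids)
        g.attrs["provenance"] = json.dumps(ensemble.provenance)
        g.attrs["n_failed"] = ensemble.n_failed


def read_events_h5(path: str | Path, group: str = "ensemble") -> EventEnsemble:
    with h5py.File(path, "r") as f:
        g = f[group]
        return EventEnsemble(
            g["momenta"][()],
            tuple(s.decode() for s in g["elements"][()]),
            g["charges"][()],
            g["masses"][()],
            np.array([s.decode() for s in g["labels"][()]], dtype=object),
            g["event_ids"][()],
            provenance=json.loads(g.attrs.get("provenance", "{}")),
            n_failed=int(g.attrs.get("n_failed", 0)),
        )


def write_events_csv(ensemble: EventEnsemble, path: str | Path) -> None:
    n, f = len(ensemble), ensemble.n_fragments
    df = pd.DataFrame(
        {
            "event_id": np.repeat(ensemble.event_ids, f),
            "structure_label": np.repeat([str(l) for l in ensemble.labels], f),
            "frag_index": np.tile(np.arange(f), n),
            "element": np.tile(ensemble.fragment_elements, n),
            "charge": np.tile(ensemble.fragment_charges, n),
            "mass_u": np.tile(ensemble.fragment_masses, n),
            "px_au": ensemble.momenta[:, :, 0].ravel(),
            "py_au": ensemble.momenta[:, :, 1].ravel(),
            "pz_au": ensemble.momenta[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> EventEnsemble:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event CSV missing columns: {sorted(missing)}")
    first = df[df.event_id == df.event_id.iloc[0]].sort_values("frag_index")
    f = len(first)
    n = len(df) // f
    if n * f != len(df):
        raise ValueError("event CSV rows are not a whole number of events")
    df = df.sort_values(["event_id", "frag_index"], kind="stable")
    momenta = df[["px_au", "py_au", "pz_au"]].to_numpy(float).reshape(n, f, 3)
    ids = df["event_id"].to_numpy()[::f]
    labels = df["structure_label"].to_numpy(object)[::f]
    return EventEnsemble(
        momenta,
        tuple(first["element"]),
        first["charge"].to_numpy(int),
        first["mass_u"].to_numpy(float),
        labels,
        ids,
        provenance={"source": str(path)},
    )
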