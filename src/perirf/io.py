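"""Flat-file formats: trial sets as TSV tables + JSON sidecar, models and
decoding maps as JSON/TSV.

A trial set directory contains ``events.tsv`` (trial, t_on_ms, cell —
probe onsets, 7 ms frames, 0-based column-major grid cells), ``spikes.tsv``
(trial, spike_time_ms), and ``meta.json`` (schema version, grid geometry,
trial span, provenance).  Writers and readers round-trip exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import ProbeGrid
from .synth import EVENT_DTYPE, TrialSet
from .encoder import SModel
from .basis import build_basis

__all__ = ["write_trials", "read_trials", "write_model", "read_model", "write_map"]

SCHEMA_VERSION = 1

_HEADER = (
    "# units: ms relative to saccade onset (t=0); grid cells 0-based, "
    "column-major (cell = col * n_rows + row)\n"
)


def write_trials(trials: TrialSet, path) -> None:
    """Write a TrialSet to ``path`` (directory; created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ev = pd.DataFrame(
        {
            "trial": trials.events["trial"],
            "t_on_ms": trials.events["t_on"],
            "cell": trials.events["cell"],
        }
    )
    sp_trial, sp_bin = np.nonzero(trials.spikes)
    sp = pd.DataFrame(
        {"trial": sp_trial, "spike_time_ms": sp_bin + trials.t_min}
    )
    for name, df in (("events.tsv", ev), ("spikes.tsv", sp)):
        with open(path / name, "w") as fh:
            fh.write(_HEADER)
            df.to_csv(fh, sep="\t", index=False)
    g = trials.grid
    meta = {
        "schema_version": SCHEMA_VERSION,
        "t_min_ms": trials.t_min,
        "t_max_ms": trials.t_max,
        "n_trials": trials.n_trials,
        "grid": {
            "n_cols": g.n_cols,
            "n_rows": g.n_rows,
            "spacing_x_dva": g.spacing_x,
            "spacing_y_dva": g.spacing_y,
            "rf1_index": g.rf1_index,
            "rf2_index": g.rf2_index,
            "fp1_index": g.fp1_index,
            "fp2_index": g.fp2_index,
        },
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def read_trials(path) -> TrialSet:
    """Inverse of :func:`write_trials`; validates schema and event ordering."""
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"missing sidecar {meta_file}")
    meta = json.loads(meta_file.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(
            f"schema version {meta.get('schema_version')} != {SCHEMA_VERSION}"
        )
    g = meta["grid"]
    grid = ProbeGrid(
        n_cols=g["n_cols"], n_rows=g["n_rows"],
        spacing_x=g["spacing_x_dva"], spacing_y=g["spacing_y_dva"],
        rf1_index=g["rf1_index"], rf2_index=g["rf2_index"],
        fp1_index=g["fp1_index"], fp2_index=g["fp2_index"],
    )
    ev_df = pd.read_csv(path / "events.tsv", sep="\t", comment="#")
    sp_df = pd.read_csv(path / "spikes.tsv", sep="\t", comment="#")
    ev = np.empty(len(ev_df), dtype=EVENT_DTYPE)
    ev["trial"] = ev_df["trial"]
    ev["t_on"] = ev_df["t_on_ms"]
    ev["cell"] = ev_df["cell"]
    t_min, t_max = meta["t_min_ms"], meta["t_max_ms"]
    n_bins = t_max - t_min + 1
    spikes = np.zeros((meta["n_trials"], n_bins), dtype=np.uint8)
    if len(sp_df):
        spikes[sp_df["trial"], sp_df["spike_time_ms"] - t_min] = 1
    return TrialSet(grid=grid, events=ev, spikes=spikes, t_min=t_min, t_max=t_max)


def write_model(model: SModel, path) -> None:
    """Serialize an SModel to a single JSON file (weights, mask, scalars)."""
    g = model.grid
    sel = np.argwhere(model.selected)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "grid": {
            "n_cols": g.n_cols, "n_rows": g.n_rows,
            "spacing_x_dva": g.spacing_x, "spacing_y_dva": g.spacing_y,
            "rf1_index": g.rf1_index, "rf2_index": g.rf2_index,
            "fp1_index": g.fp1_index, "fp2_index": g.fp2_index,
        },
        "selected": sel.tolist(),
        "kappa": model.kappa[model.selected].tolist(),
        "h_weights": model.h_weights.tolist(),
        "b_weights": model.b_weights.tolist(),
        "b0": model.b0,
        "r0": model.r0,
        "rmax": model.rmax,
    }
    Path(path).write_text(json.dumps(payload))


def read_model(path) -> SModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("unsupported model schema version")
    g = payload["grid"]
    grid = ProbeGrid(
        n_cols=g["n_cols"], n_rows=g["n_rows"],
        spacing_x=g["spacing_x_dva"], spacing_y=g["spacing_y_dva"],
        rf1_index=g["rf1_index"], rf2_index=g["rf2_index"],
        fp1_index=g["fp1_index"], fp2_index=g["fp2_index"],
    )
    basis = build_basis()
    selected = np.zeros((grid.n_cells, basis.n_delay, basis.n_time), dtype=bool)
    kappa = np.zeros_like(selected, dtype=float)
    idx = np.array(payload["selected"], dtype=int).reshape(-1, 3)
    vals = np.array(payload["kappa"], dtype=float)
    selected[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    kappa[idx[:, 0], idx[:, 1], idx[:, 2]] = vals
    return SModel(
        grid=grid, basis=basis, kappa=kappa, selected=selected,
        h_weights=np.array(payload["h_weights"]),
        b_weights=np.array(payload["b_weights"]),
        b0=payload["b0"], r0=payload["r0"], rmax=payload["rmax"],
    )


def write_map(dmap, path) -> None:
    """Decoding map as a long-form TSV (probe, t_ms, tau_ms, auc) with a
    JSON metadata header line."""
    path = Path(path)
    meta = {
        "kind": dmap.kind, "probe": int(dmap.probe),
        "units": "ms re saccade onset (t), ms before response (tau)",
    }
    rows = []
    for a, t in enumerate(dmap.t_values):
        for b, tau in enumerate(dmap.tau_values):
            rows.append((int(dmap.probe), float(t), float(tau), float(dmap.auc[a, b])))
    df = pd.DataFrame(rows, columns=["probe", "t_ms", "tau_ms", "auc"])
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        df.to_csv(fh, sep="\t", index=False)
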