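"""File formats: sensorgram CSV, peak-list/annotation TSV, ensemble PDB.

All formats are plain text. Sensorgrams use columns
``curve_id, phase, conc_M, time_s, signal``; aggregation traces
``time_min, signal_320nm, sample_id``; titration schedules
``point, ratio, L0_mM``. Ensembles are written as multi-model PDB
files of C-alpha beads (chains A/B, tail residues 1 to tail length,
structured residues from the scaffold numbering), via biotite.
"""

from __future__ import annotations

import json
from pathlib import Path

import biotite.structure as struc
import biotite.structure.io.pdb as pdb
import numpy as np
import pandas as pd

from .kinetics import Sensorgram
from .tail import Scaffold, TailEnsemble

__all__ = [
    "read_sensorgrams",
    "write_sensorgrams",
    "read_aggregation",
    "write_ensemble_pdb",
    "read_ensemble_pdb",
    "write_truth_json",
    "read_truth_json",
]


def write_sensorgrams(curves: list[Sensorgram], path) -> None:
    frames = []
    for c in curves:
        frames.append(pd.DataFrame({
            "curve_id": c.curve_id, "phase": c.phase, "conc_M": c.conc,
            "time_s": c.t, "signal": c.y}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensorgrams(path) -> list[Sensorgram]:
    df = pd.read_csv(path)
    required = {"curve_id", "phase", "conc_M", "time_s", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sensorgram CSV missing columns {sorted(missing)}")
    out = []
    for (cid, phase), grp in df.groupby(["curve_id", "phase"], sort=False):
        out.append(Sensorgram(str(cid), str(phase),
                              float(grp["conc_M"].iloc[0]),
                              grp["time_s"].to_numpy(),
                              grp["signal"].to_numpy()))
    return out


def read_aggregation(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"time_min", "signal_320nm", "sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"aggregation CSV missing columns {sorted(missing)}")
    return df


def _ensemble_to_atoms(scaffold: Scaffold, coords_one_model: np.ndarray,
                       tail_len: int) -> struc.AtomArray:
    """One model: tails (residues 1..tail_len) then scaffold beads."""
    n_chains = coords_one_model.shape[0]
    chain_ids = scaffold.chain_ids
    n_atoms = n_chains * tail_len + len(scaffold.coords)
    arr = struc.AtomArray(n_atoms)
    pos = np.empty((n_atoms, 3))
    i = 0
    for k, ch in enumerate(chain_ids):
        for j in range(tail_len):
            arr.chain_id[i] = ch
            arr.res_id[i] = j + 1
            pos[i] = coords_one_model[k, j]
            i += 1
    for b in range(len(scaffold.coords)):
        arr.chain_id[i] = scaffold.chains[b]
        arr.res_id[i] = int(scaffold.residues[b])
        pos[i] = scaffold.coords[b]
        i += 1
    arr.coord = pos
    arr.atom_name[:] = "CA"
    arr.res_name[:] = "GLY"
    arr.element[:] = "C"
    arr.hetero[:] = False
    return arr


def write_ensemble_pdb(scaffold: Scaffold, ensemble: TailEnsemble,
                       path) -> None:
    """Multi-model PDB: one model per conformer (C-alpha beads only)."""
    tail_len = ensemble.tail_length
    models = [_ensemble_to_atoms(scaffold, ensemble.coords[m], tail_len)
              for m in range(len(ensemble))]
    stack = struc.stack(models)
    f = pdb.PDBFile()
    pdb.set_structure(f, stack)
    f.write(str(path))


def read_ensemble_pdb(path, tail_len: int = 28):
    """Read a multi-model bead PDB back into (scaffold beads, ensemble).

    Returns ``(chains, residues, scaffold_coords, tail_coords)`` where
    ``tail_coords`` has shape (models, chains, tail_len, 3).
    """
    f = pdb.PDBFile.read(str(path))
    stack = pdb.get_structure(f)
    first = stack[0]
    tail_mask = first.res_id <= tail_len
    chain_ids = sorted(set(first.chain_id))
    tails = np.empty((stack.stack_depth(), len(chain_ids), tail_len, 3))
    for m in range(stack.stack_depth()):
        model = stack[m]
        for k, ch in enumerate(chain_ids):
            sel = (model.chain_id == ch) & (model.res_id <= tail_len)
            order = np.argsort(model.res_id[sel])
            tails[m, k] = model.coord[sel][order]
    scaf = first[~tail_mask]
    return (scaf.chain_id, scaf.res_id, scaf.coord, tails)


def write_truth_json(truth, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(truth, default=default, indent=1))


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())
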