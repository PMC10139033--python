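"""File-format adapters: multi-model PDB trajectories, fingerprint CSV/JSON,
score-table CSV with a direction sidecar.

PDB parsing/writing is delegated to biotite; everything is normalised into
the package's own containers on the way in.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ScoreTable, FingerprintDataset, Trajectory, make_atom_table

__all__ = [
    "write_trajectory_pdb",
    "read_trajectory_pdb",
    "write_reference_pdb",
    "write_fingerprint_csv",
    "read_fingerprint_csv",
    "write_score_table",
    "read_score_table",
]

_ELEMENT_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
}

_LIGAND_RES = ("LIG", "UNL", "UNK")
_SOLVENT_RES = ("HOH", "WAT", "SOL")
_BACKBONE_NAMES = ("N", "CA", "C", "O")


def _to_atom_array_stack(traj: Trajectory):
    import biotite.structure as struc

    n_atoms = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n_atoms)
    stack.coord = traj.coords.astype(np.float32)
    atoms = traj.atoms
    stack.chain_id = np.where(
        atoms["chain"] == "protein", "A", np.where(atoms["chain"] == "ligand", "B", "W")
    ).astype("U4")
    stack.res_id = atoms["residue_index"].to_numpy(dtype=int)
    stack.res_name = atoms["residue_name"].to_numpy().astype("U5")
    stack.atom_name = atoms["atom_name"].to_numpy().astype("U6")
    stack.element = atoms["element"].to_numpy().astype("U2")
    stack.hetero = (atoms["chain"] != "protein").to_numpy()
    return stack


def write_trajectory_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL records;
    occupancy and B-factor columns zero-filled)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(traj))
    pdb.write(str(path))


def write_reference_pdb(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    """Write one frame as a single-model reference PDB."""
    from biotite.structure.io.pdb import PDBFile

    stack = _to_atom_array_stack(traj)
    pdb = PDBFile()
    pdb.set_structure(stack[frame])
    pdb.write(str(path))


def read_trajectory_pdb(path: str | Path, time_per_frame: float = 2.0) -> Trajectory:
    """Read a (multi-model) PDB into the internal trajectory container."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    if pdb.get_model_count() == 0:
        raise ValueError(f"no models in {path}")
    stack = pdb.get_structure(model=None)
    records = []
    for i in range(stack.array_length()):
        res_name = str(stack.res_name[i])
        atom_name = str(stack.atom_name[i])
        element = str(stack.element[i]).upper()
        element = element if len(element) <= 1 else element.capitalize()
        backbone = (
            atom_name in _BACKBONE_NAMES
            and res_name not in _LIGAND_RES
            and res_name not in _SOLVENT_RES
        )
        mass = _ELEMENT_MASS.get(element.upper(), 12.011)
        records.append(
            (int(stack.res_id[i]), res_name, atom_name, element, backbone, mass)
        )
    atoms = make_atom_table(records)
    return Trajectory(
        coords=np.asarray(stack.coord, dtype=float),
        atoms=atoms,
        time_per_frame=time_per_frame,
    )


def write_fingerprint_csv(ds: FingerprintDataset, csv_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write the dataset as CSV (compound_id, bit_..., pIC50) plus an
    optional JSON metadata sidecar (planted bits, seed, spec echoes)."""
    ds.to_frame().to_csv(csv_path, index=False)
    if meta_path is not None:
        with open(meta_path, "w") as fh:
            json.dump(
                {"fingerprint_name": ds.fingerprint_name, **ds.metadata}, fh, indent=2
            )


def read_fingerprint_csv(csv_path: str | Path, meta_path: str | Path | None = None) -> FingerprintDataset:
    frame = pd.read_csv(csv_path)
    bit_cols = [c for c in frame.columns if c.startswith("bit_")]
    metadata = {}
    name = "unknown"
    if meta_path is not None:
        with open(meta_path) as fh:
            metadata = json.load(fh)
        name = metadata.pop("fingerprint_name", name)
    return FingerprintDataset(
        ids=frame["compound_id"].astype(str).tolist(),
        bits=frame[bit_cols].to_numpy(),
        activity=frame["pIC50"].to_numpy(dtype=float),
        fingerprint_name=name,
        metadata=metadata,
    )


def write_score_table(table: ScoreTable, csv_path: str | Path, sidecar_path: str | Path) -> None:
    """CSV with one column per protocol plus a JSON sidecar holding score
    directions (and labels if present)."""
    frame = pd.DataFrame(table.scores, columns=table.protocol_names)
    frame.insert(0, "compound_id", table.compound_ids)
    if table.labels is not None:
        frame["active"] = table.labels.astype(int)
    frame.to_csv(csv_path, index=False)
    with open(sidecar_path, "w") as fh:
        json.dump({"directions": table.directions}, fh, indent=2)


def read_score_table(csv_path: str | Path, sidecar_path: str | Path) -> ScoreTable:
    frame = pd.read_csv(csv_path)
    with open(sidecar_path) as fh:
        directions = json.load(fh)["directions"]
    protocols = [c for c in frame.columns if c not in ("compound_id", "active")]
    labels = frame["active"].to_numpy(dtype=bool) if "active" in frame.columns else None
    return ScoreTable(
        compound_ids=frame["compound_id"].astype(str).tolist(),
        protocol_names=protocols,
        scores=frame[protocols].to_numpy(dtype=float),
        directions={p: directions[p] for p in protocols},
        labels=labels,
    )
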